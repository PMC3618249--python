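"""Asynchronous, threshold-gated stochastic simulation core.

One step of the simulation:

1. Every rule in the active set whose condition no longer holds on the
   ``(previous, current)`` states is dropped (stale).
2. One rule is drawn uniformly at random from the satisfied remainder and
   executed: each of its action terms adds the rule's effect score to the
   target component's rule firing score (RFS); when the RFS reaches the
   component's threshold the action is applied to the attribute and the RFS
   resets to zero, otherwise only the increment is recorded.
3. The previous-state map rolls forward, and the active set is extended with
   every rule whose condition newly became satisfied plus every persistent
   rule whose condition still holds.

A run terminates when the active set empties (quiescent) or after
``max_steps`` steps.  Identical model/disease/drug inputs and seed produce a
bit-identical trace.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace

from .core_model import (
    AttributeRef,
    ModelSpec,
    Rule,
    ValidationError,
    apply_action,
    evaluate_condition,
)
from .model_io import DiseaseSpec, DrugSpec

__all__ = [
    "EngineConfig",
    "FiringRecord",
    "SimulationTrace",
    "SimulationState",
    "initialize",
    "step",
    "update_component_set",
    "run_simulation",
    "QUIESCENT",
    "MAX_STEPS",
]

QUIESCENT = "quiescent"
MAX_STEPS = "max_steps"

#: attribute type used to mark drug injection
PRESENCE_TYPE = "presence"
PRESENT = "present"


@dataclass(frozen=True)
class EngineConfig:
    """Switches for the documented semantic variants.

    ``strict_threshold`` restores a literal strictly-greater-than crossing
    test (default is >=, so a unit effect score fires a unit-threshold
    component in one hit).  ``rfs_per_attribute`` accumulates firing scores
    per attribute instead of pooling them per component.
    """

    strict_threshold: bool = False
    rfs_per_attribute: bool = False
    max_steps: int = 10_000


@dataclass(frozen=True)
class FiringRecord:
    """One executed rule: its state changes and sub-threshold increments."""

    step: int
    rule_id: str
    #: (ref, old_state, new_state, rfs_after) per applied action
    changes: tuple[tuple[AttributeRef, str, str, float], ...]
    #: (rfs key, value after increment) per sub-threshold increment
    increments: tuple[tuple[tuple, float], ...]


@dataclass
class SimulationTrace:
    """Time-ordered record of one run."""

    seed: int
    initial_states: dict[AttributeRef, str]
    records: list[FiringRecord] = field(default_factory=list)
    terminal_states: dict[AttributeRef, str] = field(default_factory=dict)
    termination: str = ""
    n_steps: int = 0

    @property
    def fired_rule_ids(self) -> set[str]:
        return {r.rule_id for r in self.records}

    def replay(self) -> dict[AttributeRef, str]:
        """Re-derive terminal states by applying recorded changes in order."""
        states = dict(self.initial_states)
        for record in self.records:
            for ref, old, new, _ in record.changes:
                if states[ref] != old:
                    raise ValidationError(
                        f"trace is inconsistent at step {record.step}: {ref} "
                        f"was {states[ref]}, record expects {old}"
                    )
                states[ref] = new
        return states


@dataclass
class SimulationState:
    """Mutable state of a running simulation."""

    model: ModelSpec
    config: EngineConfig
    step: int
    states: dict[AttributeRef, str]
    prev_states: dict[AttributeRef, str]
    rfs: dict[tuple, float]
    active_rules: dict[str, None]  # insertion-ordered set
    trace: SimulationTrace
    rng: random.Random
    _changed_last: set[AttributeRef] = field(default_factory=set)
    _lhs_index: dict[AttributeRef, list[str]] = field(default_factory=dict)
    _rule_order: dict[str, int] = field(default_factory=dict)

    def rfs_key(self, ref: AttributeRef) -> tuple:
        return tuple(ref) if self.config.rfs_per_attribute else ref.component_key


def _lhs_satisfied(
    rule: Rule,
    prev: dict[AttributeRef, str],
    curr: dict[AttributeRef, str],
    model: ModelSpec,
) -> bool:
    for ref, cond in rule.lhs:
        if not evaluate_condition(
            prev[ref], curr[ref], cond, model.state_domains[ref.attribute_type]
        ):
            return False
    return True


def initialize(
    model: ModelSpec,
    disease: DiseaseSpec | None,
    drugs: DrugSpec | None,
    seed: int,
    config: EngineConfig | None = None,
) -> SimulationState:
    """Build the t=0 state: defaults, disease overrides, drug injection.

    The initial active set contains every rule whose condition holds on the
    transition from the all-default state to the overridden one (this covers
    persistent disease rules whose conditions hold at rest).
    """
    config = config or EngineConfig()
    disease = disease or DiseaseSpec()
    drugs = drugs or DrugSpec()

    defaults: dict[AttributeRef, str] = {}
    for ref in model.attribute_refs():
        defaults[ref] = model.domain_of(ref).default_state

    overrides: dict[AttributeRef, str] = {}
    for ref, state in disease.initial_states.items():
        model.resolve(ref)
        model.domain_of(ref).index(state)
        overrides[ref] = state
    for name in drugs.drugs:
        comp = model.components.get(("drug", name))
        if comp is None:
            raise ValidationError(f"drug {name!r} is not a declared drug component")
        injected = False
        for atype, aname in comp.attributes:
            if atype == PRESENCE_TYPE:
                ref = AttributeRef("drug", name, atype, aname)
                if ref in overrides and overrides[ref] != PRESENT:
                    raise ValidationError(
                        f"conflicting initial overrides for {ref}"
                    )
                overrides[ref] = PRESENT
                injected = True
        if not injected:
            raise ValidationError(
                f"drug {name!r} has no '{PRESENCE_TYPE}' attribute to inject"
            )

    curr = dict(defaults)
    curr.update(overrides)
    prev = defaults

    active: dict[str, None] = {}
    for rid, rule in model.rules.items():
        if _lhs_satisfied(rule, prev, curr, model):
            active[rid] = None

    lhs_index: dict[AttributeRef, list[str]] = {}
    order: dict[str, int] = {}
    for i, (rid, rule) in enumerate(model.rules.items()):
        order[rid] = i
        for ref, _ in rule.lhs:
            lhs_index.setdefault(ref, []).append(rid)

    return SimulationState(
        model=model,
        config=config,
        step=0,
        states=curr,
        prev_states=prev,
        rfs={},
        active_rules=active,
        trace=SimulationTrace(seed=seed, initial_states=dict(curr)),
        rng=random.Random(seed),
        _changed_last={ref for ref, s in curr.items() if prev[ref] != s},
        _lhs_index=lhs_index,
        _rule_order=order,
    )


def update_component_set(
    state: SimulationState, rule: Rule, model: ModelSpec
) -> tuple[tuple, tuple]:
    """Apply one verified rule's action terms under the threshold gate.

    Mutates the RFS accumulators only; the computed state changes are
    returned (with sub-threshold increments) for the caller to apply, so the
    condition context of the step stays intact while actions are resolved.
    """
    config = state.config
    changes: list[tuple[AttributeRef, str, str, float]] = []
    increments: list[tuple[tuple, float]] = []
    pending: dict[AttributeRef, str] = {}
    for ref, action in rule.rhs:
        key = state.rfs_key(ref)
        value = state.rfs.get(key, 0.0) + rule.effect_score
        threshold = model.components[ref.component_key].threshold
        crossed = value > threshold if config.strict_threshold else value >= threshold
        if crossed:
            state.rfs[key] = 0.0
            old = pending.get(ref, state.states[ref])
            new = apply_action(
                old, action, model.state_domains[ref.attribute_type]
            )
            pending[ref] = new
            if new != old:
                changes.append((ref, old, new, 0.0))
        else:
            state.rfs[key] = value
            increments.append((key, value))
    return tuple(changes), tuple(increments)


def step(state: SimulationState, model: ModelSpec | None = None) -> SimulationState:
    """Advance the simulation by one asynchronous update step."""
    model = model or state.model
    prev, curr = state.prev_states, state.states

    satisfied: list[str] = []
    stale: list[str] = []
    for rid in state.active_rules:
        if _lhs_satisfied(model.rules[rid], prev, curr, model):
            satisfied.append(rid)
        else:
            stale.append(rid)

    fired: Rule | None = None
    changes: tuple = ()
    increments: tuple = ()
    if satisfied:
        fired = model.rules[satisfied[state.rng.randrange(len(satisfied))]]
        changes, increments = update_component_set(state, fired, model)

    changed_now = {ref for ref, _, _, _ in changes}
    touched = state._changed_last | changed_now
    candidate_ids = sorted(
        {rid for ref in touched for rid in state._lhs_index.get(ref, ())},
        key=state._rule_order.__getitem__,
    )
    held_before = {
        rid: _lhs_satisfied(model.rules[rid], prev, curr, model)
        for rid in candidate_ids
    }

    # roll (prev, curr) forward: prev becomes the pre-change current states
    for ref in state._changed_last:
        prev[ref] = curr[ref]
    for ref, _, new, _ in changes:
        curr[ref] = new

    for rid in stale:
        del state.active_rules[rid]
    if fired is not None:
        state.active_rules.pop(fired.rule_id, None)
    for rid in candidate_ids:
        rule = model.rules[rid]
        if _lhs_satisfied(rule, prev, curr, model):
            if rule.persistent or not held_before[rid]:
                state.active_rules[rid] = None
    if (
        fired is not None
        and fired.persistent
        and _lhs_satisfied(fired, prev, curr, model)
    ):
        state.active_rules[fired.rule_id] = None

    if fired is not None:
        state.trace.records.append(
            FiringRecord(state.step, fired.rule_id, changes, increments)
        )
    state._changed_last = changed_now
    state.step += 1
    return state


def run_simulation(
    model: ModelSpec,
    disease: DiseaseSpec | None = None,
    drugs: DrugSpec | None = None,
    seed: int = 0,
    max_steps: int | None = None,
    config: EngineConfig | None = None,
) -> SimulationTrace:
    """Run to quiescence or ``max_steps``; returns the completed trace."""
    config = config or EngineConfig()
    if max_steps is not None:
        config = replace(config, max_steps=max_steps)
    if config.max_steps <= 0:
        raise ValidationError(f"max_steps must be > 0, got {config.max_steps}")
    state = initialize(model, disease, drugs, seed, config)
    while state.active_rules and state.step < config.max_steps:
        step(state)
    trace = state.trace
    trace.terminal_states = dict(state.states)
    trace.termination = QUIESCENT if not state.active_rules else MAX_STEPS
    trace.n_steps = state.step
    return trace
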