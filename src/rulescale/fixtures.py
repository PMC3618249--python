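"""Packaged models, a random model generator, and a brute-force oracle.

``build_t2d_fixture`` loads the repository's mini type-2-diabetes model: a
class-level reconstruction of how 22 antidiabetic drugs act on a
molecule/cell/organ hierarchy, with a persistent insulin-resistance disease
process competing against drug-induced rules.

``generate_random_model`` produces seeded-deterministic random models whose
rule graph is a DAG over a fixed attribute order (so every run terminates),
optionally guaranteeing a directed rule chain from each drug to the
phenotype criterion attribute.

``brute_force_reachable`` exhaustively enumerates every firing order under
the same condition/action/threshold semantics as the engine and returns all
distinct quiescent terminal states — the testing oracle for the engine's
stochastic scheduling.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from importlib.resources import files

from .core_model import (
    AttributeRef,
    Component,
    ModelSpec,
    Rule,
    StateDomain,
    ValidationError,
)
from .engine import EngineConfig, _lhs_satisfied, initialize, update_component_set
from .model_io import DiseaseSpec, DrugSpec, read_component_file, read_rule_file
from .converters import OdeSystem, PetriNetSpec, PetriTransition

__all__ = [
    "GLUCOSE",
    "INSULIN",
    "build_t2d_fixture",
    "GeneratorParams",
    "generate_random_model",
    "ReachabilityResult",
    "brute_force_reachable",
    "build_demo_ode_system",
    "build_demo_petri_net",
]

_DATA = files("rulescale") / "data"

#: the disease-diagnosis criterion attribute of the packaged model
GLUCOSE = AttributeRef("organ", "circulation", "metabolite", "glucose")
INSULIN = AttributeRef("organ", "circulation", "hormone", "insulin")


def build_t2d_fixture() -> tuple[ModelSpec, DiseaseSpec, list[str]]:
    """Load the packaged mini-T2D model.

    Returns the model, the patient disease spec (insulin resistance plus
    elevated circulation glucose), and the 22-drug catalogue.
    """
    from .model_io import read_disease_file

    model = read_component_file(str(_DATA / "t2d_components.yaml"))
    read_rule_file(str(_DATA / "t2d_rules.txt"), model)
    disease = read_disease_file(str(_DATA / "t2d_disease.yaml"), model)
    catalogue = [
        name for (ctype, name) in model.components if ctype == "drug"
    ]
    return model, disease, catalogue


# ---------------------------------------------------------------------------
# random model generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneratorParams:
    """Counts and fractions controlling the random model generator."""

    n_organs: int = 1
    n_cells: int = 2
    n_genes_per_cell: int = 2
    n_drugs: int = 1
    n_rules: int = 5
    disease_rule_fraction: float = 0.0
    persistent_fraction: float = 0.0
    seed: int = 0
    guaranteed_path: bool = True
    organ_threshold: float = 60.0

    def __post_init__(self) -> None:
        for name in ("n_organs", "n_cells", "n_genes_per_cell", "n_drugs", "n_rules"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in ("disease_rule_fraction", "persistent_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValidationError(f"{name} must be within [0, 1]")


_TERNARY = ("low", "normal", "high")


def _ternary_domain(name: str) -> StateDomain:
    return StateDomain(name, _TERNARY, ("up", "down"), ("up", "down"), "normal")


def generate_random_model(
    params: GeneratorParams,
) -> tuple[ModelSpec, DiseaseSpec, list[str]]:
    """Seeded-deterministic random model, disease spec and drug catalogue.

    Rules only point "forward" along a fixed attribute order (drug presences,
    then cell genes, then organ metabolites), so the rule-dependency graph is
    acyclic and — absent persistent rules — every simulation terminates.
    """
    rng = random.Random(params.seed)
    model = ModelSpec()
    model.add_domain(_ternary_domain("gene"))
    model.add_domain(_ternary_domain("metabolite"))
    model.add_domain(
        StateDomain(
            "presence", ("absent", "present"), ("absent", "present"),
            ("absent", "present"), "absent",
        )
    )

    ordered: list[AttributeRef] = []
    drug_names = [f"drug{i}" for i in range(params.n_drugs)]
    for name in drug_names:
        model.add_component(Component("drug", name, (("presence", "status"),), 1.0))
        ordered.append(AttributeRef("drug", name, "presence", "status"))
    for c in range(params.n_cells):
        attrs = tuple(("gene", f"g{j}") for j in range(params.n_genes_per_cell))
        model.add_component(Component("cell", f"cell{c}", attrs, 1.0))
        ordered.extend(
            AttributeRef("cell", f"cell{c}", "gene", f"g{j}")
            for j in range(params.n_genes_per_cell)
        )
    for o in range(params.n_organs):
        model.add_component(
            Component(
                "organ", f"organ{o}", (("metabolite", "m0"),), params.organ_threshold
            )
        )
        ordered.append(AttributeRef("organ", f"organ{o}", "metabolite", "m0"))

    targets = [ref for ref in ordered if ref.attribute_type != "presence"]
    if params.n_rules > 0 and not targets:
        raise ValidationError("cannot generate rules for a model with no attributes")
    criterion = ordered[-1] if targets else None

    def condition_for(ref: AttributeRef) -> str:
        if ref.attribute_type == "presence":
            return "present"
        return rng.choice(("up", "down"))

    rules: list[Rule] = []

    def add_rule(src: AttributeRef, cond: str, tgt: AttributeRef, action: str) -> None:
        rules.append(
            Rule(
                rule_id=f"G{len(rules) + 1:03d}",
                lhs=((src, cond),),
                rhs=((tgt, action),),
                provenance="generated",
            )
        )

    if params.guaranteed_path and criterion is not None:
        genes = [r for r in targets if r.attribute_type == "gene"]
        for name in drug_names:
            if len(rules) >= params.n_rules:
                break
            drug_ref = AttributeRef("drug", name, "presence", "status")
            if genes and len(rules) + 1 < params.n_rules:
                hop = rng.choice(genes)
                add_rule(drug_ref, "present", hop, "up")
                add_rule(hop, "up", criterion, rng.choice(("up", "down")))
            else:
                add_rule(drug_ref, "present", criterion, rng.choice(("up", "down")))

    attempts = 0
    while len(rules) < params.n_rules:
        attempts += 1
        if attempts > 1000 * params.n_rules:
            raise ValidationError(
                "could not place the requested number of rules (too few attributes?)"
            )
        i = rng.randrange(len(ordered))
        src = ordered[i]
        later = [t for t in targets if ordered.index(t) > i]
        if not later:
            continue
        tgt = rng.choice(later)
        add_rule(src, condition_for(src), tgt, rng.choice(("up", "down")))

    disease_ids = []
    for rule in rules:
        if rng.random() < params.persistent_fraction:
            rule.persistent = True
        if rng.random() < params.disease_rule_fraction:
            rule.is_disease_rule = True
            disease_ids.append(rule.rule_id)
        model.add_rule(rule)

    initial: dict[AttributeRef, str] = {}
    if targets:
        ref = rng.choice(targets)
        domain = model.domain_of(ref)
        abnormal = [s for s in domain.states if s != domain.default_state]
        initial[ref] = rng.choice(abnormal)
    disease = DiseaseSpec(
        name=f"generated-{params.seed}",
        initial_states=initial,
        disease_rule_ids=tuple(disease_ids),
    )
    return model, disease, drug_names


# ---------------------------------------------------------------------------
# exhaustive scheduling oracle
# ---------------------------------------------------------------------------

@dataclass
class ReachabilityResult:
    """All distinct terminal states reachable under any firing order."""

    terminal_states: set[frozenset]
    complete: bool
    n_explored: int

    def as_dicts(self) -> list[dict[AttributeRef, str]]:
        return [dict(items) for items in sorted(self.terminal_states, key=sorted)]


def brute_force_reachable(
    model: ModelSpec,
    disease: DiseaseSpec | None = None,
    drugs: DrugSpec | None = None,
    max_depth: int = 200,
    max_nodes: int = 500_000,
    config: EngineConfig | None = None,
) -> ReachabilityResult:
    """Depth-first enumeration of every possible firing order.

    Shares the engine's condition/action/threshold implementation, so it
    tests scheduling only.  Depth-capped or node-capped searches return
    ``complete=False`` and include the capped states among the terminals.
    """
    config = config or EngineConfig()
    state0 = initialize(model, disease, drugs, seed=0, config=config)
    rule_ids = list(model.rules)

    def canon(curr, prev, rfs, active):
        return (
            tuple(sorted(curr.items())),
            tuple(sorted(prev.items())),
            tuple(sorted((k, v) for k, v in rfs.items() if v)),
            frozenset(active),
        )

    start = (dict(state0.states), dict(state0.prev_states), {}, set(state0.active_rules))
    terminals: set[frozenset] = set()
    visited = {canon(*start)}
    stack = [(start, 0)]
    complete = True
    explored = 0

    while stack:
        (curr, prev, rfs, active), depth = stack.pop()
        explored += 1
        if not active:
            terminals.add(frozenset(curr.items()))
            continue
        if depth >= max_depth or explored > max_nodes:
            terminals.add(frozenset(curr.items()))
            complete = False
            continue

        satisfied = [
            rid
            for rid in rule_ids
            if rid in active and _lhs_satisfied(model.rules[rid], prev, curr, model)
        ]
        removed_base = active - set(satisfied)  # stale rules all dropped
        choices = satisfied or [None]
        for choice in choices:
            curr2 = dict(curr)
            rfs2 = dict(rfs)
            changes = ()
            if choice is not None:
                shim = _OracleShim(config, curr, rfs2)
                changes, _ = update_component_set(shim, model.rules[choice], model)
            prev2 = dict(curr)
            for ref, _, new, _ in changes:
                curr2[ref] = new
            removed = removed_base | ({choice} if choice else set())
            active2 = {rid for rid in active if rid not in removed}
            for rid, rule in model.rules.items():
                if _lhs_satisfied(rule, prev2, curr2, model):
                    if rule.persistent or not _lhs_satisfied(rule, prev, curr, model):
                        active2.add(rid)
            node = (curr2, prev2, rfs2, active2)
            key = canon(*node)
            if key not in visited:
                visited.add(key)
                stack.append((node, depth + 1))

    return ReachabilityResult(terminals, complete, explored)


class _OracleShim:
    """Minimal stand-in for SimulationState inside update_component_set."""

    def __init__(self, config: EngineConfig, states: dict, rfs: dict):
        self.config = config
        self.states = states
        self.rfs = rfs

    def rfs_key(self, ref: AttributeRef) -> tuple:
        return tuple(ref) if self.config.rfs_per_attribute else ref.component_key


# ---------------------------------------------------------------------------
# converter demo fixtures
# ---------------------------------------------------------------------------

def build_demo_ode_system() -> tuple[OdeSystem, ModelSpec]:
    """Three-variable glucose / insulin / beta-cell-mass demo ODE system.

    The equations and parameter values are repository data chosen so that
    insulin negatively influences glucose, glucose and beta-cell mass
    positively influence insulin, and the glucose influence on beta-cell
    mass changes sign at ``r1 / (2 * r2)`` = 175.
    """
    beta_mass = AttributeRef("cell", "beta-cell", "metabolite", "cell_mass")
    system = OdeSystem(
        variables={"G": GLUCOSE, "I": INSULIN, "B": beta_mass},
        expressions={
            "G": "R0 - (EG0 + SI*I)*G",
            "I": "sigma*B*G^2/(alpha^2 + G^2) - k*I",
            "B": "(-d0 + r1*G - r2*G^2)*B",
        },
        parameters={
            "R0": 864.0,
            "EG0": 1.44,
            "SI": 0.72,
            "sigma": 43.2,
            "alpha": 141.42,
            "k": 432.0,
            "d0": 0.06,
            "r1": 0.00084,
            "r2": 0.0000024,
        },
        ranges={"G": (0.0, 600.0), "I": (0.0, 50.0), "B": (1.0, 3000.0)},
    )
    model = ModelSpec()
    model.add_domain(_ternary_domain("metabolite"))
    model.add_domain(_ternary_domain("hormone"))
    model.add_component(
        Component(
            "organ", "circulation",
            (("metabolite", "glucose"), ("hormone", "insulin")), 60.0,
        )
    )
    model.add_component(Component("cell", "beta-cell", (("metabolite", "cell_mass"),), 1.0))
    return system, model


def build_demo_petri_net() -> tuple[PetriNetSpec, ModelSpec]:
    """Small place/transition net over hepatocyte genes, with companion model."""
    model = ModelSpec()
    model.add_domain(_ternary_domain("gene"))
    model.add_component(
        Component(
            "cell", "hepatocyte",
            (("gene", "PRKAB1"), ("gene", "PEPCK"), ("gene", "G6PC")), 1.0,
        )
    )
    ref = lambda name: AttributeRef("cell", "hepatocyte", "gene", name)
    net = PetriNetSpec(
        places={
            "P1": (ref("PRKAB1"), ("up", "down")),
            "P2": (ref("PEPCK"), ("up", "down")),
            "P3": (ref("G6PC"), ("up", "down")),
        },
        transitions=[
            PetriTransition((("P1", "up"),), (("P2", "down"),), "repression"),
            PetriTransition((("P1", "up"),), (("P3", "down"),), "repression"),
            PetriTransition(
                (("P2", "down"), ("P3", "down")), (("P1", "up"),), "joint feedback"
            ),
        ],
    )
    return net, model
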