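"""Domain types and state-transition semantics for qualitative rule-based models.

A model is a universe of *components* (organs, cells, drugs, ...) carrying
discretely-valued *attributes* (genes, metabolites, hormones, channels, drug
presence, ...), plus *rules* whose left-hand side detects state transitions on
source attributes and whose right-hand side perturbs target attributes.

Two kinds of attribute semantics are supported, both driven entirely by the
:class:`StateDomain` data:

* **ordered** domains (e.g. ``low < normal < high``) use the movement
  vocabulary ``up`` / ``down``.  Condition ``up`` holds on a ``(prev, curr)``
  pair when the state stepped one level upward, or is being held at the top
  level; ``down`` is the mirror image.  Action ``up`` moves the state one
  level up with an absorbing top; ``down`` mirrors with an absorbing bottom.
* **categorical** domains (e.g. ``close``/``open``, ``absent``/``present``)
  use the state labels themselves: condition ``open`` holds iff the current
  state equals ``open``; action ``open`` sets the state to ``open``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, NamedTuple

__all__ = [
    "ModelError",
    "ValidationError",
    "AttributeRef",
    "StateDomain",
    "Component",
    "Rule",
    "ModelSpec",
    "evaluate_condition",
    "apply_action",
    "validate_model",
]

#: movement labels understood by every ordered domain
ORDERED_LABELS = ("up", "down")


class ModelError(ValueError):
    """Base class for model construction / validation failures."""


class ValidationError(ModelError):
    """A label, reference, or file did not validate against the model."""


class AttributeRef(NamedTuple):
    """Fully qualified address of one attribute in a model.

    The 4-tuple ``(component_type, component_name, attribute_type,
    attribute_name)`` uniquely addresses one attribute; ``attribute_type``
    selects the :class:`StateDomain` governing its states.
    """

    component_type: str
    component_name: str
    attribute_type: str
    attribute_name: str

    def __str__(self) -> str:
        return ",".join(self)

    @property
    def component_key(self) -> tuple[str, str]:
        return (self.component_type, self.component_name)

    @classmethod
    def parse(cls, text: str) -> "AttributeRef":
        parts = [p.strip() for p in text.split(",")]
        if len(parts) != 4 or not all(parts):
            raise ValidationError(
                f"attribute reference must have 4 comma-separated fields, got {text!r}"
            )
        ctype, cname, atype, aname = parts
        return cls(ctype.lower(), cname, atype.lower(), aname)


@dataclass(frozen=True)
class StateDomain:
    """An attribute type's ordered state labels and its label vocabularies."""

    name: str
    states: tuple[str, ...]
    condition_labels: tuple[str, ...]
    action_labels: tuple[str, ...]
    default_state: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "states", tuple(self.states))
        object.__setattr__(self, "condition_labels", tuple(self.condition_labels))
        object.__setattr__(self, "action_labels", tuple(self.action_labels))
        if len(self.states) < 2:
            raise ValidationError(f"domain {self.name!r} needs at least 2 states")
        if len(set(self.states)) != len(self.states):
            raise ValidationError(f"domain {self.name!r} has duplicate state labels")
        if self.default_state not in self.states:
            raise ValidationError(
                f"domain {self.name!r}: default state {self.default_state!r} "
                f"is not one of {self.states}"
            )
        for label in (*self.condition_labels, *self.action_labels):
            if label not in self.states and label not in ORDERED_LABELS:
                raise ValidationError(
                    f"domain {self.name!r}: label {label!r} resolves to no "
                    f"transition relation (not a state, not in {ORDERED_LABELS})"
                )

    def index(self, state: str) -> int:
        try:
            return self.states.index(state)
        except ValueError:
            raise ValidationError(
                f"unknown state {state!r} for domain {self.name!r} "
                f"(states: {self.states})"
            ) from None


def evaluate_condition(
    prev_state: str, curr_state: str, condition: str, domain: StateDomain
) -> bool:
    """Truth of ``condition`` over the transition ``prev_state -> curr_state``.

    For movement labels the relation is the literal piecewise one: ``up``
    holds when the state moved one level up *or* is held at the top level
    (``high -> high`` re-satisfies ``up``); ``down`` mirrors at the bottom.
    Categorical labels test equality of the current state only.
    """
    if condition not in domain.condition_labels:
        raise ValidationError(
            f"unknown condition {condition!r} for domain {domain.name!r} "
            f"(conditions: {domain.condition_labels})"
        )
    if condition in domain.states:
        domain.index(prev_state)  # still validate both states
        return curr_state == condition
    i_prev = domain.index(prev_state)
    i_curr = domain.index(curr_state)
    top = len(domain.states) - 1
    if condition == "up":
        return i_curr == i_prev + 1 or (i_curr == i_prev == top)
    if condition == "down":
        return i_curr == i_prev - 1 or (i_curr == i_prev == 0)
    raise ValidationError(f"unknown condition label {condition!r}")  # pragma: no cover


def apply_action(curr_state: str, action: str, domain: StateDomain) -> str:
    """Successor state after ``action``; extremes are absorbing."""
    if action not in domain.action_labels:
        raise ValidationError(
            f"unknown action {action!r} for domain {domain.name!r} "
            f"(actions: {domain.action_labels})"
        )
    if action in domain.states:
        domain.index(curr_state)
        return action
    i = domain.index(curr_state)
    top = len(domain.states) - 1
    if action == "up":
        return domain.states[min(i + 1, top)]
    if action == "down":
        return domain.states[max(i - 1, 0)]
    raise ValidationError(f"unknown action label {action!r}")  # pragma: no cover


@dataclass
class Component:
    """A modelled entity holding attributes and a rule-execution threshold.

    ``threshold`` encodes the response timescale of the component: a state
    change is applied only once the accumulated firing score reaches it.
    """

    component_type: str
    name: str
    attributes: tuple[tuple[str, str], ...]  # (attribute_type, attribute_name)
    threshold: float

    def __post_init__(self) -> None:
        self.component_type = self.component_type.lower()
        self.attributes = tuple(
            (atype.lower(), aname) for atype, aname in self.attributes
        )
        if not self.threshold > 0:
            raise ValidationError(
                f"component {self.component_type},{self.name}: threshold must be "
                f"> 0, got {self.threshold}"
            )
        if len(set(self.attributes)) != len(self.attributes):
            raise ValidationError(
                f"component {self.component_type},{self.name}: duplicate attributes"
            )

    @property
    def key(self) -> tuple[str, str]:
        return (self.component_type, self.name)


@dataclass
class Rule:
    """A condition->action statement over attribute references.

    ``lhs`` is a conjunction of ``(AttributeRef, condition_label)`` terms;
    ``rhs`` a list of ``(AttributeRef, action_label)`` terms.  Each firing
    adds ``effect_score`` to the target component's firing score.
    """

    rule_id: str
    lhs: tuple[tuple[AttributeRef, str], ...]
    rhs: tuple[tuple[AttributeRef, str], ...]
    effect_score: float = 1.0
    is_disease_rule: bool = False
    persistent: bool = False
    provenance: str = ""

    def __post_init__(self) -> None:
        self.lhs = tuple(self.lhs)
        self.rhs = tuple(self.rhs)
        if not self.lhs:
            raise ValidationError(f"rule {self.rule_id}: empty condition side")
        if not self.rhs:
            raise ValidationError(f"rule {self.rule_id}: empty action side")
        if not self.effect_score > 0:
            raise ValidationError(
                f"rule {self.rule_id}: effect score must be > 0, got {self.effect_score}"
            )


@dataclass
class ModelSpec:
    """The full component/attribute/rule universe of one model."""

    state_domains: dict[str, StateDomain] = field(default_factory=dict)
    components: dict[tuple[str, str], Component] = field(default_factory=dict)
    rules: dict[str, Rule] = field(default_factory=dict)

    # -- construction -----------------------------------------------------
    def add_domain(self, domain: StateDomain) -> None:
        if domain.name in self.state_domains:
            raise ValidationError(f"duplicate state domain {domain.name!r}")
        self.state_domains[domain.name] = domain

    def add_component(self, component: Component) -> None:
        if component.key in self.components:
            raise ValidationError(
                f"duplicate component {component.component_type},{component.name}"
            )
        self.components[component.key] = component

    def add_rule(self, rule: Rule) -> None:
        if rule.rule_id in self.rules:
            raise ValidationError(f"duplicate rule id {rule.rule_id!r}")
        self.rules[rule.rule_id] = rule

    # -- queries ----------------------------------------------------------
    def domain_of(self, ref: AttributeRef) -> StateDomain:
        try:
            return self.state_domains[ref.attribute_type]
        except KeyError:
            raise ValidationError(
                f"attribute type {ref.attribute_type!r} of {ref} has no state domain"
            ) from None

    def has_attribute(self, ref: AttributeRef) -> bool:
        comp = self.components.get(ref.component_key)
        if comp is None:
            return False
        return (ref.attribute_type, ref.attribute_name) in comp.attributes

    def component_of(self, ref: AttributeRef) -> Component:
        try:
            return self.components[ref.component_key]
        except KeyError:
            raise ValidationError(
                f"component {ref.component_type},{ref.component_name} is not declared"
            ) from None

    def attribute_refs(self) -> Iterator[AttributeRef]:
        """All declared attributes, in component declaration order."""
        for comp in self.components.values():
            for atype, aname in comp.attributes:
                yield AttributeRef(comp.component_type, comp.name, atype, aname)

    def resolve(self, ref: AttributeRef) -> AttributeRef:
        """Validate that ``ref`` addresses a declared attribute; return it."""
        if not self.has_attribute(ref):
            raise ValidationError(f"attribute reference {ref} does not resolve")
        return ref


def validate_model(model: ModelSpec) -> list[str]:
    """Check every model invariant; return one message per violation.

    An empty report means the model is valid.  Violations are returned,
    never raised, so curators can see them all at once.
    """
    report: list[str] = []
    for key, comp in model.components.items():
        if key != comp.key:
            report.append(f"component keyed {key} declares itself as {comp.key}")
        for atype, aname in comp.attributes:
            if atype not in model.state_domains:
                report.append(
                    f"component {comp.component_type},{comp.name}: attribute "
                    f"({atype},{aname}) references undeclared state domain {atype!r}"
                )
    for rid, rule in model.rules.items():
        if rid != rule.rule_id:
            report.append(f"rule keyed {rid!r} declares id {rule.rule_id!r}")
        for side, terms, vocab in (
            ("condition", rule.lhs, "condition_labels"),
            ("action", rule.rhs, "action_labels"),
        ):
            for ref, label in terms:
                if not model.has_attribute(ref):
                    report.append(
                        f"rule {rule.rule_id}: dangling {side} reference {ref}"
                    )
                    continue
                domain = model.state_domains.get(ref.attribute_type)
                if domain is None:
                    report.append(
                        f"rule {rule.rule_id}: {ref} has no state domain"
                    )
                elif label not in getattr(domain, vocab):
                    report.append(
                        f"rule {rule.rule_id}: {side} {label!r} is not valid for "
                        f"domain {domain.name!r} of {ref}"
                    )
    return report
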