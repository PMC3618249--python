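"""Rule extraction from ODE systems and Petri nets.

ODE conversion cares about the *direction* of an influence, not its
magnitude: for each ordered variable pair the sign of the partial effect of
the source on the target's time derivative is estimated by central finite
differences over a grid spanning the declared variable ranges.  A uniformly
positive influence yields the rule pair ``source up -> target up`` /
``source down -> target down``; a negative influence yields the crossed
pair.  A sign that flips along the source axis (but is uniform across the
other variables) is partitioned at the estimated sign-change points and
emits per-sub-interval rule pairs; anything else is reported as
unconvertible.

Petri-net conversion is purely structural: each transition becomes one rule
whose condition terms come from the input places and whose action terms come
from the output places.  Token dynamics are not simulated — the rule engine
replaces them.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import sympy
import yaml

from .core_model import AttributeRef, Rule, ValidationError

__all__ = [
    "OdeSystem",
    "InfluenceEntry",
    "InfluenceReport",
    "PetriNetSpec",
    "PetriTransition",
    "classify_influence",
    "ode_to_rules",
    "petrinet_to_rules",
    "read_ode_system",
    "read_petri_net",
    "POSITIVE",
    "NEGATIVE",
    "NONE",
    "PARTITIONED",
    "UNCONVERTIBLE",
]

POSITIVE = "positive"
NEGATIVE = "negative"
NONE = "none"
PARTITIONED = "partitioned"
UNCONVERTIBLE = "unconvertible"

DEFAULT_GRID = 7
DEFAULT_FD_STEP = 1e-4  # relative to the source range width
DEFAULT_ZERO_TOL = 1e-9


@dataclass
class OdeSystem:
    """A system ``d(var)/dt = expression(vars, params)`` with variable ranges."""

    variables: dict[str, AttributeRef]
    expressions: dict[str, str]
    parameters: dict[str, float] = field(default_factory=dict)
    ranges: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for var, (lo, hi) in self.ranges.items():
            if not lo < hi:
                raise ValidationError(
                    f"variable {var!r}: invalid range ({lo}, {hi}); need lo < hi"
                )
        symbols = set(self.variables) | set(self.parameters)
        for var, text in self.expressions.items():
            if var not in self.variables:
                raise ValidationError(f"expression for undeclared variable {var!r}")
            for sym in self.sympify(var).free_symbols:
                if str(sym) not in symbols:
                    raise ValidationError(
                        f"expression for {var!r} uses undeclared symbol {sym} "
                        f"(declared: {sorted(symbols)})"
                    )

    def sympify(self, var: str) -> sympy.Expr:
        """Parse the expression for ``var`` (infix arithmetic; ``^`` = power)."""
        text = self.expressions[var].replace("^", "**")
        local = {name: sympy.Symbol(name) for name in self.variables}
        local.update({name: sympy.Symbol(name) for name in self.parameters})
        try:
            return sympy.sympify(text, locals=local)
        except (sympy.SympifyError, SyntaxError, TypeError) as exc:
            raise ValidationError(
                f"cannot parse expression for {var!r}: {self.expressions[var]!r} "
                f"({exc})"
            ) from exc

    def rhs(self, var: str) -> sympy.Expr:
        """Expression with parameter values substituted."""
        expr = self.sympify(var)
        subs = {sympy.Symbol(k): v for k, v in self.parameters.items()}
        return expr.subs(subs)


@dataclass(frozen=True)
class InfluenceEntry:
    """Classified influence of one source variable on one target derivative."""

    source: str
    target: str
    classification: str
    #: for PARTITIONED: ((lo, hi), sign) sub-intervals covering the source range
    segments: tuple[tuple[tuple[float, float], str], ...] = ()
    n_grid_points: int = 0
    n_positive: int = 0
    n_negative: int = 0
    n_zero: int = 0


@dataclass
class InfluenceReport:
    entries: dict[tuple[str, str], InfluenceEntry] = field(default_factory=dict)

    def unconvertible_pairs(self) -> list[tuple[str, str]]:
        return sorted(
            k for k, e in self.entries.items() if e.classification == UNCONVERTIBLE
        )


def _sign_array(values: np.ndarray, zero_tol: float) -> np.ndarray:
    signs = np.sign(values)
    signs[np.abs(values) <= zero_tol] = 0
    return signs.astype(int)


def classify_influence(
    system: OdeSystem,
    source: str,
    target: str,
    grid_points_per_dim: int = DEFAULT_GRID,
    fd_step: float = DEFAULT_FD_STEP,
    zero_tol: float = DEFAULT_ZERO_TOL,
) -> InfluenceEntry:
    """Estimate the sign of d/d(source) of the target's time derivative.

    Central finite differences are evaluated at every point of a grid over
    the declared ranges of the variables appearing in the target expression.
    """
    if grid_points_per_dim < 3:
        raise ValidationError("grid_points_per_dim must be >= 3")
    expr = system.rhs(target)
    free = {str(s) for s in expr.free_symbols}
    if source not in free:
        return InfluenceEntry(source, target, NONE)

    # source axis first, then the other free variables in declared order
    var_names = [source] + [v for v in system.variables if v in free and v != source]
    for name in var_names:
        if name not in system.ranges:
            raise ValidationError(
                f"variable {name!r} appears in d({target})/dt but has no range"
            )
    fn = sympy.lambdify([sympy.Symbol(v) for v in var_names], expr, modules="numpy")

    lo, hi = system.ranges[source]
    h = fd_step * (hi - lo)
    n = grid_points_per_dim
    axes = [np.linspace(lo + h, hi - h, n)]
    axes += [np.linspace(*system.ranges[v], n) for v in var_names[1:]]
    mesh = np.meshgrid(*axes, indexing="ij")

    def fd(source_axis: np.ndarray) -> np.ndarray:
        grids = np.meshgrid(source_axis, *axes[1:], indexing="ij")
        plus = fn(grids[0] + h, *grids[1:])
        minus = fn(grids[0] - h, *grids[1:])
        return np.broadcast_to(
            (np.asarray(plus) - np.asarray(minus)) / (2.0 * h), mesh[0].shape
        )

    derivs = fd(axes[0])
    signs = _sign_array(derivs, zero_tol)
    n_pos = int(np.sum(signs > 0))
    n_neg = int(np.sum(signs < 0))
    n_zero = int(np.sum(signs == 0))
    stats = dict(
        n_grid_points=signs.size, n_positive=n_pos, n_negative=n_neg, n_zero=n_zero
    )

    if n_pos == 0 and n_neg == 0:
        return InfluenceEntry(source, target, NONE, **stats)
    if n_neg == 0:
        return InfluenceEntry(source, target, POSITIVE, **stats)
    if n_pos == 0:
        return InfluenceEntry(source, target, NEGATIVE, **stats)

    # mixed signs: try a 1-D partition along the source axis
    flat = signs.reshape(n, -1)
    slice_signs: list[int] = []
    for i in range(n):
        present = set(flat[i]) - {0}
        if len(present) > 1:
            return InfluenceEntry(source, target, UNCONVERTIBLE, **stats)
        slice_signs.append(present.pop() if present else 0)

    mids = [float(np.mean(system.ranges[v])) for v in var_names[1:]]

    def g(s: float) -> float:
        return float(fn(s + h, *mids) - fn(s - h, *mids)) / (2.0 * h)

    breakpoints: list[float] = []
    seg_signs: list[int] = []
    last_sign = 0
    last_s = None
    for i, sign in enumerate(slice_signs):
        if sign == 0:
            continue
        if last_sign == 0:
            last_sign = sign
            seg_signs.append(sign)
        elif sign != last_sign:
            a, b = last_s, float(axes[0][i])
            for _ in range(60):  # bisection on the finite-difference estimate
                mid = 0.5 * (a + b)
                if _sign_array(np.array([g(mid)]), zero_tol)[0] == last_sign:
                    a = mid
                else:
                    b = mid
            breakpoints.append(0.5 * (a + b))
            last_sign = sign
            seg_signs.append(sign)
        last_s = float(axes[0][i])

    bounds = [lo, *breakpoints, hi]
    segments = tuple(
        ((bounds[i], bounds[i + 1]), POSITIVE if s > 0 else NEGATIVE)
        for i, s in enumerate(seg_signs)
    )
    return InfluenceEntry(source, target, PARTITIONED, segments=segments, **stats)


def _influence_rules(
    source_ref: AttributeRef,
    target_ref: AttributeRef,
    sign: str,
    rule_id_base: str,
    provenance: str,
) -> list[Rule]:
    if sign == POSITIVE:
        pairs = (("up", "up"), ("down", "down"))
    else:
        pairs = (("up", "down"), ("down", "up"))
    return [
        Rule(
            rule_id=f"{rule_id_base}{suffix}",
            lhs=((source_ref, cond),),
            rhs=((target_ref, action),),
            provenance=provenance,
        )
        for suffix, (cond, action) in zip(("a", "b"), pairs)
    ]


def ode_to_rules(
    system: OdeSystem,
    grid_points_per_dim: int = DEFAULT_GRID,
    fd_step: float = DEFAULT_FD_STEP,
    zero_tol: float = DEFAULT_ZERO_TOL,
    id_prefix: str = "ODE",
) -> tuple[list[Rule], InfluenceReport]:
    """Extract rules for every monotone (or partitionable) influence.

    Each positive influence emits ``source up -> target up`` and
    ``source down -> target down``; negative influences emit the crossed
    pair; partitioned influences emit one pair per sub-interval with the
    interval recorded in the rule provenance.  Self-influences and
    unconvertible pairs emit nothing (the latter are listed in the report).
    """
    report = InfluenceReport()
    rules: list[Rule] = []
    counter = 0
    for source, target in itertools.permutations(system.variables, 2):
        entry = classify_influence(
            system, source, target, grid_points_per_dim, fd_step, zero_tol
        )
        report.entries[(source, target)] = entry
        src_ref = system.variables[source]
        tgt_ref = system.variables[target]
        if entry.classification in (POSITIVE, NEGATIVE):
            counter += 1
            rules.extend(
                _influence_rules(
                    src_ref,
                    tgt_ref,
                    entry.classification,
                    f"{id_prefix}{counter:03d}",
                    provenance=f"ode:{source}->{target}:{entry.classification}",
                )
            )
        elif entry.classification == PARTITIONED:
            for (bounds, sign) in entry.segments:
                counter += 1
                rules.extend(
                    _influence_rules(
                        src_ref,
                        tgt_ref,
                        sign,
                        f"{id_prefix}{counter:03d}",
                        provenance=(
                            f"ode:{source}->{target}:{sign} on "
                            f"{source} in [{bounds[0]:.6g},{bounds[1]:.6g}]"
                        ),
                    )
                )
    return rules, report


# ---------------------------------------------------------------------------
# Petri nets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PetriTransition:
    inputs: tuple[tuple[str, str], ...]  # (place id, condition label)
    outputs: tuple[tuple[str, str], ...]  # (place id, action label)
    note: str = ""


@dataclass
class PetriNetSpec:
    """Structural place/transition net over model attributes."""

    places: dict[str, tuple[AttributeRef, tuple[str, ...]]]
    transitions: list[PetriTransition] = field(default_factory=list)

    def __post_init__(self) -> None:
        for i, t in enumerate(self.transitions):
            for place, _ in (*t.inputs, *t.outputs):
                if place not in self.places:
                    raise ValidationError(
                        f"transition {i}: arc references undeclared place {place!r}"
                    )


def petrinet_to_rules(net: PetriNetSpec, id_prefix: str = "PN") -> list[Rule]:
    """One rule per transition: inputs become conditions, outputs actions."""
    rules = []
    for i, t in enumerate(net.transitions, start=1):
        if not t.inputs:
            raise ValidationError(f"transition {i} has no input places")
        if not t.outputs:
            raise ValidationError(f"transition {i} has no output places")
        rules.append(
            Rule(
                rule_id=f"{id_prefix}{i:03d}",
                lhs=tuple((net.places[p][0], label) for p, label in t.inputs),
                rhs=tuple((net.places[p][0], label) for p, label in t.outputs),
                provenance=f"petri-net:{t.note}" if t.note else "petri-net",
            )
        )
    return rules


# ---------------------------------------------------------------------------
# file formats
# ---------------------------------------------------------------------------

def read_ode_system(path: str | Path) -> OdeSystem:
    """Load an ODE system from YAML.

    Layout::

        variables:
          G: {ref: "organ,circulation,metabolite,glucose", range: [0, 600]}
        equations:
          G: "R0 - (EG0 + SI*I)*G"
        parameters: {R0: 864, EG0: 1.44, SI: 0.72}
    """
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise ValidationError(f"{path}: ODE system file must be a mapping")
    variables = {}
    ranges = {}
    for name, spec in (doc.get("variables") or {}).items():
        if not isinstance(spec, dict) or "ref" not in spec:
            raise ValidationError(f"{path}: variable {name!r} needs a 'ref' mapping")
        variables[str(name)] = AttributeRef.parse(str(spec["ref"]))
        if "range" in spec:
            lo, hi = spec["range"]
            ranges[str(name)] = (float(lo), float(hi))
    return OdeSystem(
        variables=variables,
        expressions={str(k): str(v) for k, v in (doc.get("equations") or {}).items()},
        parameters={str(k): float(v) for k, v in (doc.get("parameters") or {}).items()},
        ranges=ranges,
    )


def read_petri_net(path: str | Path) -> PetriNetSpec:
    """Load a place/transition net from YAML.

    Layout::

        places:
          P1: {ref: "cell,hepatocyte,gene,X", vocabulary: [up, down]}
        transitions:
          - inputs: [[P1, up]]
            outputs: [[P2, up]]
            note: activation
    """
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise ValidationError(f"{path}: Petri-net file must be a mapping")
    places = {}
    for pid, spec in (doc.get("places") or {}).items():
        if not isinstance(spec, dict) or "ref" not in spec:
            raise ValidationError(f"{path}: place {pid!r} needs a 'ref' mapping")
        places[str(pid)] = (
            AttributeRef.parse(str(spec["ref"])),
            tuple(str(v) for v in spec.get("vocabulary", ())),
        )
    transitions = []
    for entry in doc.get("transitions") or ():
        transitions.append(
            PetriTransition(
                inputs=tuple((str(p), str(l)) for p, l in entry.get("inputs") or ()),
                outputs=tuple((str(p), str(l)) for p, l in entry.get("outputs") or ()),
                note=str(entry.get("note", "")),
            )
        )
    return PetriNetSpec(places=places, transitions=transitions)
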