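"""Monte Carlo ensembles, drug-effect pathway graphs, and efficacy screening.

An ensemble is a set of independently seeded runs of the same model /
disease / drug inputs (100 runs by default).  Aggregating which rules fired
across the ensemble yields a directed *drug effect pathway* graph rooted at
the injected drugs, with edge weights giving the fraction of runs in which
each rule fired at least once.  Efficacy of a drug set is judged by the
fraction of runs whose terminal state of a criterion attribute equals a
target state.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx

from .core_model import AttributeRef, ModelSpec, ValidationError
from .engine import PRESENCE_TYPE, EngineConfig, SimulationTrace, run_simulation
from .model_io import DiseaseSpec, DrugSpec

__all__ = [
    "Ensemble",
    "PathwayGraph",
    "EfficacyResult",
    "run_ensemble",
    "build_pathway_graph",
    "assess_efficacy",
    "screen_combinations",
    "efficacy_table_tsv",
]


@dataclass
class Ensemble:
    """Traces of ``n_runs`` seeded runs sharing the same inputs.

    Run ``i`` uses seed ``base_seed + i``.
    """

    model: ModelSpec
    disease: DiseaseSpec
    drugs: DrugSpec
    base_seed: int
    n_runs: int
    traces: list[SimulationTrace] = field(default_factory=list)


@dataclass
class PathwayGraph:
    """Monte-Carlo-aggregated rule-firing graph rooted at the drug nodes.

    Nodes are attribute references; each edge carries the rule id, the
    effect direction (the rule's action label), and the firing frequency
    (fraction of runs in which the rule fired at least once).
    """

    graph: nx.MultiDiGraph
    roots: tuple[AttributeRef, ...]

    @property
    def nodes(self) -> set[AttributeRef]:
        return set(self.graph.nodes)

    def edges(self) -> list[tuple]:
        """Deterministically ordered (source, target, rule_id, direction, frequency)."""
        rows = [
            (data["rule_id"], u, v, data["direction"], data["frequency"])
            for u, v, data in self.graph.edges(data=True)
        ]
        rows.sort()
        return [(u, v, rid, d, f) for rid, u, v, d, f in rows]

    def to_sif(self) -> str:
        """SIF export: ``source<TAB>rule_id:direction:frequency<TAB>target``."""
        lines = [
            f"{_node(u)}\t{rid}:{direction}:{freq:.3f}\t{_node(v)}"
            for u, v, rid, direction, freq in self.edges()
        ]
        return "\n".join(lines) + ("\n" if lines else "")

    def to_dot(self) -> str:
        """Graphviz DOT export with edge labels ``rule:direction:frequency``."""
        lines = ["digraph pathway {"]
        for node in sorted(self.graph.nodes):
            shape = "box" if node in self.roots else "ellipse"
            lines.append(f'  "{_node(node)}" [shape={shape}];')
        for u, v, rid, direction, freq in self.edges():
            lines.append(
                f'  "{_node(u)}" -> "{_node(v)}" '
                f'[label="{rid}:{direction}:{freq:.3f}"];'
            )
        lines.append("}")
        return "\n".join(lines) + "\n"


def _node(ref: AttributeRef) -> str:
    return ":".join(ref)


@dataclass
class EfficacyResult:
    """Verdict for one drug set against the disease criterion."""

    drugs: tuple[str, ...]
    criterion: AttributeRef
    target_state: str
    fraction: float
    effective: bool
    cutoff: float
    n_runs: int


def run_ensemble(
    model: ModelSpec,
    disease: DiseaseSpec | None,
    drugs: DrugSpec | None,
    n_runs: int = 100,
    base_seed: int = 0,
    max_steps: int | None = None,
    config: EngineConfig | None = None,
) -> Ensemble:
    """Run ``n_runs`` independent seeded simulations (Monte Carlo)."""
    if n_runs < 1:
        raise ValidationError(f"n_runs must be >= 1, got {n_runs}")
    disease = disease or DiseaseSpec()
    drugs = drugs or DrugSpec()
    traces = [
        run_simulation(
            model, disease, drugs, seed=base_seed + i, max_steps=max_steps,
            config=config,
        )
        for i in range(n_runs)
    ]
    return Ensemble(model, disease, drugs, base_seed, n_runs, traces)


def _drug_roots(model: ModelSpec, drugs: DrugSpec) -> tuple[AttributeRef, ...]:
    roots = []
    for name in drugs.drugs:
        comp = model.components.get(("drug", name))
        if comp is None:
            continue
        for atype, aname in comp.attributes:
            if atype == PRESENCE_TYPE:
                roots.append(AttributeRef("drug", name, atype, aname))
    return tuple(roots)


def build_pathway_graph(
    ensemble: Ensemble, min_frequency: float = 0.05
) -> PathwayGraph:
    """Aggregate an ensemble into a drug-effect pathway graph.

    Edges with firing frequency below ``min_frequency`` are pruned, and only
    nodes reachable from the injected drug roots are retained.
    """
    if not ensemble.traces:
        raise ValidationError("cannot build a pathway graph from an empty ensemble")
    n = len(ensemble.traces)
    counts: dict[str, int] = {}
    for trace in ensemble.traces:
        for rid in trace.fired_rule_ids:
            counts[rid] = counts.get(rid, 0) + 1

    graph = nx.MultiDiGraph()
    for rid, rule in ensemble.model.rules.items():
        freq = counts.get(rid, 0) / n
        if freq == 0 or freq < min_frequency:
            continue
        for lref, _ in rule.lhs:
            for rref, action in rule.rhs:
                graph.add_edge(
                    lref, rref, rule_id=rid, direction=action, frequency=freq
                )

    roots = _drug_roots(ensemble.model, ensemble.drugs)
    keep: set[AttributeRef] = set()
    for root in roots:
        if root in graph:
            keep.add(root)
            keep |= nx.descendants(graph, root)
    return PathwayGraph(graph=graph.subgraph(keep).copy(), roots=roots)


def assess_efficacy(
    ensemble: Ensemble,
    criterion: AttributeRef,
    target_state: str,
    cutoff: float = 0.5,
) -> EfficacyResult:
    """Fraction of runs whose terminal criterion state equals the target.

    The verdict is ``effective`` when the fraction reaches the cutoff
    (>= semantics).
    """
    ensemble.model.resolve(criterion)
    hits = sum(
        1 for t in ensemble.traces if t.terminal_states.get(criterion) == target_state
    )
    fraction = hits / len(ensemble.traces)
    return EfficacyResult(
        drugs=tuple(ensemble.drugs.drugs),
        criterion=criterion,
        target_state=target_state,
        fraction=fraction,
        effective=fraction >= cutoff,
        cutoff=cutoff,
        n_runs=len(ensemble.traces),
    )


def screen_combinations(
    model: ModelSpec,
    disease: DiseaseSpec | None,
    drug_names: list[str],
    criterion: AttributeRef,
    target_state: str,
    anchor: str | None = None,
    k: int = 2,
    n_runs: int = 100,
    base_seed: int = 0,
    cutoff: float = 0.5,
    max_steps: int | None = None,
    config: EngineConfig | None = None,
) -> list[EfficacyResult]:
    """Evaluate every k-drug combination (optionally anchored on one drug).

    With an anchor, all ``anchor + (k-1)-subset`` combinations of the
    remaining drugs are evaluated; otherwise all k-subsets.  Results are
    sorted by fraction descending, ties broken by drug names.
    """
    if k < 2:
        raise ValidationError(f"combination size k must be >= 2, got {k}")
    for name in drug_names:
        if ("drug", name) not in model.components:
            raise ValidationError(f"unknown drug {name!r} in drug list")
    if anchor is not None:
        if anchor not in drug_names:
            raise ValidationError(f"anchor {anchor!r} is not in the drug list")
        others = [d for d in drug_names if d != anchor]
        combos = [
            (anchor, *rest) for rest in itertools.combinations(others, k - 1)
        ]
    else:
        combos = list(itertools.combinations(drug_names, k))

    results = []
    for combo in combos:
        ensemble = run_ensemble(
            model,
            disease,
            DrugSpec(drugs=combo),
            n_runs=n_runs,
            base_seed=base_seed,
            max_steps=max_steps,
            config=config,
        )
        results.append(assess_efficacy(ensemble, criterion, target_state, cutoff))
    results.sort(key=lambda r: (-r.fraction, r.drugs))
    return results


def efficacy_table_tsv(results: list[EfficacyResult], header: dict | None = None) -> str:
    """Serialize screening results as TSV with a reproducibility header."""
    lines = [f"# {k}={v}" for k, v in (header or {}).items()]
    lines.append("drugs\tcriterion\ttarget_state\tfraction\tverdict\tcutoff\tn_runs")
    for r in results:
        verdict = "effective" if r.effective else "not_effective"
        lines.append(
            "\t".join(
                (
                    "+".join(r.drugs),
                    str(r.criterion),
                    r.target_state,
                    f"{r.fraction:.3f}",
                    verdict,
                    f"{r.cutoff:g}",
                    str(r.n_runs),
                )
            )
        )
    return "\n".join(lines) + "\n"
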