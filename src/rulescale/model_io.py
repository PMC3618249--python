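"""Readers and writers for the platform's input files and the trace file.

Four inputs drive a simulation:

* **component file** — YAML mapping with ``domains`` and ``components``
  sections; declares the state domains and the component/attribute universe.
* **rule file** — a line-oriented DSL, one rule per line::

      Cell,hepatocyte,gene,PRKAB1,up -> Cell,hepatocyte,gene,AGRP,up

  Conjunctive condition terms are joined with ``&``; trailing annotations
  ``@id=NAME @rs=FLOAT @disease @persistent @src=TEXT`` set the rule id,
  effect score, flags and provenance.
* **disease file** — YAML; abnormal initial attribute states plus the ids of
  disease-causing rules.
* **drug file** — YAML; names of drug components to inject at t=0.

The result of a run is written as a 9-column TSV, one row per state change.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING

import yaml

from .core_model import (
    AttributeRef,
    Component,
    ModelSpec,
    Rule,
    StateDomain,
    ValidationError,
)

if TYPE_CHECKING:  # pragma: no cover
    from .engine import SimulationTrace

__all__ = [
    "DiseaseSpec",
    "DrugSpec",
    "DEFAULT_THRESHOLDS",
    "read_component_file",
    "write_component_file",
    "read_rule_file",
    "write_rule_file",
    "parse_rule_line",
    "rule_to_line",
    "read_disease_file",
    "write_disease_file",
    "read_drug_file",
    "write_drug_file",
    "write_trace",
    "read_trace",
    "TRACE_COLUMNS",
]

#: per-component-type default rule-execution thresholds; molecule-scale
#: entities respond in a single hit, organ-scale ones need 60 accumulated hits
DEFAULT_THRESHOLDS = {
    "molecule": 1.0,
    "cell": 1.0,
    "drug": 1.0,
    "tissue": 60.0,
    "organ": 60.0,
}
FALLBACK_THRESHOLD = 1.0

TRACE_COLUMNS = (
    "step",
    "rule_id",
    "component_type",
    "component_name",
    "attribute_type",
    "attribute_name",
    "old_state",
    "new_state",
    "rfs_after",
)


@dataclass
class DiseaseSpec:
    """Abnormal initial attribute states plus disease-rule flags."""

    name: str = "disease"
    initial_states: dict[AttributeRef, str] = field(default_factory=dict)
    disease_rule_ids: tuple[str, ...] = ()


@dataclass
class DrugSpec:
    """Drug components to inject (each becomes present at t=0)."""

    drugs: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.drugs = tuple(self.drugs)


# ---------------------------------------------------------------------------
# component file
# ---------------------------------------------------------------------------

def _load_yaml(path: str | Path) -> object:
    path = Path(path)
    try:
        text = path.read_text()
    except OSError as exc:
        raise ValidationError(f"cannot read {path}: {exc}") from exc
    try:
        return yaml.safe_load(text)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        line = f" at line {mark.line + 1}" if mark is not None else ""
        raise ValidationError(f"parse error in {path}{line}: {exc}") from exc


def read_component_file(path: str | Path) -> ModelSpec:
    """Load domains and components; returns a ModelSpec without rules.

    Every component carries a threshold: explicit in the file, or defaulted
    from its component type (molecule/cell/drug 1.0, tissue/organ 60.0).
    """
    doc = _load_yaml(path)
    model = ModelSpec()
    if doc is None:
        return model
    if not isinstance(doc, dict):
        raise ValidationError(f"{path}: component file must be a mapping")
    for name, spec in (doc.get("domains") or {}).items():
        if not isinstance(spec, dict):
            raise ValidationError(f"{path}: domain {name!r} must be a mapping")
        try:
            domain = StateDomain(
                name=str(name).lower(),
                states=tuple(str(s) for s in spec["states"]),
                condition_labels=tuple(str(s) for s in spec.get("conditions", ())),
                action_labels=tuple(str(s) for s in spec.get("actions", ())),
                default_state=str(spec["default"]),
            )
        except KeyError as exc:
            raise ValidationError(
                f"{path}: domain {name!r} is missing key {exc}"
            ) from exc
        model.add_domain(domain)
    for entry in doc.get("components") or ():
        if not isinstance(entry, dict):
            raise ValidationError(f"{path}: component entries must be mappings")
        try:
            ctype = str(entry["type"]).lower()
            cname = str(entry["name"])
        except KeyError as exc:
            raise ValidationError(
                f"{path}: component entry is missing key {exc}"
            ) from exc
        attrs = []
        for item in entry.get("attributes") or ():
            parts = [p.strip() for p in str(item).split(",")]
            if len(parts) != 2 or not all(parts):
                raise ValidationError(
                    f"{path}: component {ctype},{cname}: attribute {item!r} "
                    f"must be 'type,name'"
                )
            atype = parts[0].lower()
            if atype not in model.state_domains:
                raise ValidationError(
                    f"{path}: component {ctype},{cname}: attribute {item!r} "
                    f"references unknown state domain {atype!r}"
                )
            attrs.append((atype, parts[1]))
        threshold = entry.get("threshold")
        if threshold is None:
            threshold = DEFAULT_THRESHOLDS.get(ctype, FALLBACK_THRESHOLD)
        model.add_component(
            Component(ctype, cname, tuple(attrs), float(threshold))
        )
    return model


def write_component_file(model: ModelSpec, path: str | Path) -> None:
    doc = {
        "domains": {
            d.name: {
                "states": list(d.states),
                "conditions": list(d.condition_labels),
                "actions": list(d.action_labels),
                "default": d.default_state,
            }
            for d in model.state_domains.values()
        },
        "components": [
            {
                "type": c.component_type,
                "name": c.name,
                "threshold": c.threshold,
                "attributes": [f"{a},{n}" for a, n in c.attributes],
            }
            for c in model.components.values()
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


# ---------------------------------------------------------------------------
# rule DSL
# ---------------------------------------------------------------------------

_ANNOTATION_RE = re.compile(r"@(\w+)(?:=(\S+))?")


def parse_rule_line(line: str, model: ModelSpec, default_id: str) -> Rule:
    """Parse one DSL line into a validated Rule."""
    body = line
    annotations: dict[str, str | None] = {}
    if "@" in line:
        body = line[: line.index("@")]
        for match in _ANNOTATION_RE.finditer(line):
            annotations[match.group(1)] = match.group(2)
    arrow = "->" if "->" in body else ("→" if "→" in body else None)
    if arrow is None:
        raise ValidationError(f"rule line has no '->': {line!r}")
    lhs_text, rhs_text = body.split(arrow, 1)

    def parse_terms(text: str, side: str) -> tuple[tuple[AttributeRef, str], ...]:
        terms = []
        for chunk in text.split("&"):
            parts = [p.strip() for p in chunk.split(",")]
            if len(parts) != 5 or not all(parts):
                raise ValidationError(
                    f"{side} term {chunk.strip()!r} must have 5 fields "
                    f"(component type, name, attribute type, name, label)"
                )
            ref = AttributeRef(parts[0].lower(), parts[1], parts[2].lower(), parts[3])
            if not model.has_attribute(ref):
                raise ValidationError(
                    f"{side} reference {ref} does not resolve to a declared attribute"
                )
            domain = model.domain_of(ref)
            vocab = (
                domain.condition_labels if side == "condition" else domain.action_labels
            )
            if parts[4] not in vocab:
                raise ValidationError(
                    f"{side} label {parts[4]!r} is not valid for domain "
                    f"{domain.name!r} of {ref} (allowed: {vocab})"
                )
            terms.append((ref, parts[4]))
        return tuple(terms)

    unknown = set(annotations) - {"id", "rs", "disease", "persistent", "src"}
    if unknown:
        raise ValidationError(f"unknown rule annotations: {sorted(unknown)}")
    rs = annotations.get("rs")
    return Rule(
        rule_id=str(annotations.get("id") or default_id),
        lhs=parse_terms(lhs_text, "condition"),
        rhs=parse_terms(rhs_text, "action"),
        effect_score=float(rs) if rs is not None else 1.0,
        is_disease_rule="disease" in annotations,
        persistent="persistent" in annotations,
        provenance=str(annotations.get("src") or ""),
    )


def rule_to_line(rule: Rule) -> str:
    """Serialize a rule back to its one-line DSL form."""
    lhs = " & ".join(f"{ref},{label}" for ref, label in rule.lhs)
    rhs = " & ".join(f"{ref},{label}" for ref, label in rule.rhs)
    parts = [f"{lhs} -> {rhs}", f"@id={rule.rule_id}"]
    if rule.effect_score != 1.0:
        parts.append(f"@rs={rule.effect_score:g}")
    if rule.is_disease_rule:
        parts.append("@disease")
    if rule.persistent:
        parts.append("@persistent")
    if rule.provenance:
        parts.append(f"@src={rule.provenance}")
    return " ".join(parts)


def read_rule_file(path: str | Path, model: ModelSpec) -> ModelSpec:
    """Attach the rules in ``path`` to ``model`` (components already loaded)."""
    path = Path(path)
    try:
        lines = path.read_text().splitlines()
    except OSError as exc:
        raise ValidationError(f"cannot read {path}: {exc}") from exc
    n = 0
    for lineno, raw in enumerate(lines, start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        n += 1
        try:
            rule = parse_rule_line(line, model, default_id=f"R{n:03d}")
            model.add_rule(rule)
        except ValidationError as exc:
            raise ValidationError(f"{path}:{lineno}: {exc}") from exc
    return model


def write_rule_file(model: ModelSpec, path: str | Path) -> None:
    lines = [rule_to_line(r) for r in model.rules.values()]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# disease and drug files
# ---------------------------------------------------------------------------

def read_disease_file(path: str | Path, model: ModelSpec) -> DiseaseSpec:
    doc = _load_yaml(path)
    if doc is None:
        return DiseaseSpec()
    if not isinstance(doc, dict):
        raise ValidationError(f"{path}: disease file must be a mapping")
    initial: dict[AttributeRef, str] = {}
    for entry in doc.get("states") or ():
        if not isinstance(entry, dict) or "attr" not in entry or "state" not in entry:
            raise ValidationError(
                f"{path}: each state entry needs 'attr' and 'state' keys, got {entry!r}"
            )
        ref = model.resolve(AttributeRef.parse(str(entry["attr"])))
        state = str(entry["state"])
        model.domain_of(ref).index(state)
        if ref in initial and initial[ref] != state:
            raise ValidationError(f"{path}: conflicting initial states for {ref}")
        initial[ref] = state
    rule_ids = tuple(str(r) for r in doc.get("rules") or ())
    for rid in rule_ids:
        rule = model.rules.get(rid)
        if rule is None:
            raise ValidationError(f"{path}: unknown disease rule id {rid!r}")
        if not rule.is_disease_rule:
            raise ValidationError(
                f"{path}: rule {rid!r} is not flagged @disease in the rule file"
            )
    return DiseaseSpec(
        name=str(doc.get("name", "disease")),
        initial_states=initial,
        disease_rule_ids=rule_ids,
    )


def write_disease_file(disease: DiseaseSpec, path: str | Path) -> None:
    doc = {
        "name": disease.name,
        "states": [
            {"attr": str(ref), "state": state}
            for ref, state in disease.initial_states.items()
        ],
        "rules": list(disease.disease_rule_ids),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_drug_file(path: str | Path, model: ModelSpec) -> DrugSpec:
    doc = _load_yaml(path)
    if doc is None:
        return DrugSpec()
    if not isinstance(doc, dict):
        raise ValidationError(f"{path}: drug file must be a mapping")
    names = tuple(str(d) for d in doc.get("drugs") or ())
    for name in names:
        if ("drug", name) not in model.components:
            raise ValidationError(
                f"{path}: drug {name!r} is not declared as a drug component"
            )
    return DrugSpec(drugs=names)


def write_drug_file(drugs: DrugSpec, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump({"drugs": list(drugs.drugs)}, sort_keys=False))


# ---------------------------------------------------------------------------
# trace file
# ---------------------------------------------------------------------------

def write_trace(
    trace: "SimulationTrace", path: str | Path, header: dict | None = None
) -> None:
    """Write all state changes of a run as TSV, one row per change.

    Rows are ordered by step then firing order.  ``header`` key/value pairs
    are emitted as ``# key=value`` comment lines for reproducibility.
    """
    lines = []
    meta = {"seed": trace.seed, "termination": trace.termination,
            "n_steps": trace.n_steps}
    if header:
        meta.update(header)
    for key, value in meta.items():
        lines.append(f"# {key}={value}")
    lines.append("\t".join(TRACE_COLUMNS))
    for record in trace.records:
        for ref, old, new, rfs_after in record.changes:
            lines.append(
                "\t".join(
                    (
                        str(record.step),
                        record.rule_id,
                        ref.component_type,
                        ref.component_name,
                        ref.attribute_type,
                        ref.attribute_name,
                        old,
                        new,
                        f"{rfs_after:g}",
                    )
                )
            )
    try:
        Path(path).write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise OSError(f"cannot write trace to {path}: {exc}") from exc


def read_trace(path: str | Path) -> list[tuple]:
    """Parse a written trace back into structured state-change records.

    Returns tuples ``(step, rule_id, AttributeRef, old, new, rfs_after)``.
    """
    rows: list[tuple] = []
    lines = Path(path).read_text().splitlines()
    header_seen = False
    for line in lines:
        if not line or line.startswith("#"):
            continue
        if not header_seen:
            if tuple(line.split("\t")) != TRACE_COLUMNS:
                raise ValidationError(f"{path}: unexpected trace header {line!r}")
            header_seen = True
            continue
        fields = line.split("\t")
        if len(fields) != len(TRACE_COLUMNS):
            raise ValidationError(f"{path}: malformed trace row {line!r}")
        rows.append(
            (
                int(fields[0]),
                fields[1],
                AttributeRef(fields[2], fields[3], fields[4], fields[5]),
                fields[6],
                fields[7],
                float(fields[8]),
            )
        )
    return rows
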