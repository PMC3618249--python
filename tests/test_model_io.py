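import pytest

from rulescale.core_model import AttributeRef, ValidationError
from rulescale.engine import run_simulation
from rulescale.model_io import (
    DiseaseSpec,
    DrugSpec,
    parse_rule_line,
    read_component_file,
    read_disease_file,
    read_drug_file,
    read_rule_file,
    read_trace,
    rule_to_line,
    write_component_file,
    write_disease_file,
    write_drug_file,
    write_rule_file,
    write_trace,
)

from conftest import GENE_S, base_model, chain_model

COMPONENTS_YAML = """
domains:
  gene:
    states: [low, normal, high]
    conditions: [up, down]
    actions: [up, down]
    default: normal
components:
  - type: cell
    name: hepatocyte
    attributes: [ "gene,PRKAB1", "gene,AGRP" ]
  - type: organ
    name: circulation
    attributes: [ "gene,X" ]
"""


@pytest.fixture
def components_file(tmp_path):
    path = tmp_path / "components.yaml"
    path.write_text(COMPONENTS_YAML)
    return path


class TestComponentFile:
    def test_thresholds_default_by_component_type(self, components_file):
        model = read_component_file(components_file)
        cell = model.components[("cell", "hepatocyte")]
        assert cell.threshold == 1.0
        assert ("gene", "PRKAB1") in cell.attributes
        assert model.components[("organ", "circulation")].threshold == 60.0

    def test_explicit_threshold_wins(self, tmp_path):
        path = tmp_path / "c.yaml"
        path.write_text(
            COMPONENTS_YAML.replace("name: hepatocyte", "name: hepatocyte\n    threshold: 5.0")
        )
        model = read_component_file(path)
        assert model.components[("cell", "hepatocyte")].threshold == 5.0

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.yaml"
        path.write_text("")
        model = read_component_file(path)
        assert not model.components and not model.state_domains

    def test_duplicate_component(self, tmp_path):
        path = tmp_path / "c.yaml"
        path.write_text(
            COMPONENTS_YAML + "  - {type: cell, name: hepatocyte, attributes: []}\n"
        )
        with pytest.raises(ValidationError, match="duplicate component"):
            read_component_file(path)

    def test_unknown_domain_reference(self, tmp_path):
        path = tmp_path / "c.yaml"
        path.write_text(
            COMPONENTS_YAML + '  - {type: cell, name: x, attributes: ["hormone,H"]}\n'
        )
        with pytest.raises(ValidationError, match="hormone"):
            read_component_file(path)

    def test_parse_error_reports_line(self, tmp_path):
        path = tmp_path / "c.yaml"
        path.write_text("domains:\n  gene: [unclosed\n")
        with pytest.raises(ValidationError, match="line"):
            read_component_file(path)

    def test_round_trip(self, components_file, tmp_path):
        model = read_component_file(components_file)
        out = tmp_path / "out.yaml"
        write_component_file(model, out)
        again = read_component_file(out)
        assert again.state_domains == model.state_domains
        assert again.components == model.components


class TestRuleFile:
    def test_worked_rule_defaults(self, components_file):
        model = read_component_file(components_file)
        rule = parse_rule_line(
            "Cell,hepatocyte,gene,PRKAB1,up -> Cell,hepatocyte,gene,AGRP,up",
            model,
            default_id="R001",
        )
        assert len(rule.lhs) == 1 and len(rule.rhs) == 1
        assert rule.effect_score == 1.0
        assert not rule.is_disease_rule and not rule.persistent
        assert rule.lhs[0] == (
            AttributeRef("cell", "hepatocyte", "gene", "PRKAB1"), "up"
        )

    def test_annotations(self, components_file):
        model = read_component_file(components_file)
        rule = parse_rule_line(
            "cell,hepatocyte,gene,PRKAB1,up -> cell,hepatocyte,gene,AGRP,up "
            "@id=X1 @rs=2.5 @disease @persistent @src=curated",
            model,
            default_id="R001",
        )
        assert rule.rule_id == "X1"
        assert rule.effect_score == 2.5
        assert rule.is_disease_rule and rule.persistent
        assert rule.provenance == "curated"

    def test_conjunction_round_trip(self, components_file):
        model = read_component_file(components_file)
        line = (
            "cell,hepatocyte,gene,PRKAB1,up & cell,hepatocyte,gene,AGRP,down "
            "-> organ,circulation,gene,X,up"
        )
        rule = parse_rule_line(line, model, default_id="R001")
        assert len(rule.lhs) == 2
        reparsed = parse_rule_line(rule_to_line(rule), model, default_id="R001")
        assert reparsed == rule

    def test_dangling_reference_names_line(self, components_file, tmp_path):
        model = read_component_file(components_file)
        path = tmp_path / "rules.txt"
        path.write_text(
            "# comment\n\n"
            "cell,hepatocyte,gene,NOPE,up -> cell,hepatocyte,gene,AGRP,up\n"
        )
        with pytest.raises(ValidationError, match=r"rules.txt:3"):
            read_rule_file(path, model)

    def test_invalid_condition_label(self, components_file):
        model = read_component_file(components_file)
        with pytest.raises(ValidationError, match="open"):
            parse_rule_line(
                "cell,hepatocyte,gene,PRKAB1,open -> cell,hepatocyte,gene,AGRP,up",
                model,
                default_id="R001",
            )

    def test_file_round_trip(self, components_file, tmp_path):
        model = read_component_file(components_file)
        (tmp_path / "rules.txt").write_text(
            "cell,hepatocyte,gene,PRKAB1,up -> cell,hepatocyte,gene,AGRP,up @rs=3\n"
            "cell,hepatocyte,gene,AGRP,up -> organ,circulation,gene,X,up @persistent\n"
        )
        read_rule_file(tmp_path / "rules.txt", model)
        write_rule_file(model, tmp_path / "rules2.txt")
        model2 = read_component_file(components_file)
        read_rule_file(tmp_path / "rules2.txt", model2)
        assert model2.rules == model.rules

    def test_sequential_default_ids(self, components_file, tmp_path):
        model = read_component_file(components_file)
        (tmp_path / "rules.txt").write_text(
            "cell,hepatocyte,gene,PRKAB1,up -> cell,hepatocyte,gene,AGRP,up\n"
            "cell,hepatocyte,gene,AGRP,up -> organ,circulation,gene,X,up\n"
        )
        read_rule_file(tmp_path / "rules.txt", model)
        assert list(model.rules) == ["R001", "R002"]


class TestDiseaseAndDrugFiles:
    @pytest.fixture
    def t2d_files(self, tmp_path, t2d_model):
        return tmp_path, t2d_model

    def test_disease_single_override(self, tmp_path, t2d_model):
        path = tmp_path / "d.yaml"
        path.write_text(
            'states:\n  - {attr: "organ,circulation,metabolite,glucose", state: high}\n'
        )
        disease = read_disease_file(path, t2d_model)
        glucose = AttributeRef("organ", "circulation", "metabolite", "glucose")
        assert disease.initial_states == {glucose: "high"}

    def test_empty_disease_file(self, tmp_path, t2d_model):
        path = tmp_path / "d.yaml"
        path.write_text("")
        disease = read_disease_file(path, t2d_model)
        assert disease.initial_states == {} and disease.disease_rule_ids == ()

    def test_unknown_attribute_errors(self, tmp_path, t2d_model):
        path = tmp_path / "d.yaml"
        path.write_text('states:\n  - {attr: "organ,circulation,metabolite,FOO", state: high}\n')
        with pytest.raises(ValidationError, match="does not resolve"):
            read_disease_file(path, t2d_model)

    def test_disease_rule_must_be_flagged(self, tmp_path, t2d_model):
        path = tmp_path / "d.yaml"
        path.write_text("rules: [MET1]\n")
        with pytest.raises(ValidationError, match="not flagged"):
            read_disease_file(path, t2d_model)

    def test_drug_file(self, tmp_path, t2d_model):
        path = tmp_path / "drugs.yaml"
        path.write_text("drugs: [metformin]\n")
        assert read_drug_file(path, t2d_model).drugs == ("metformin",)

    def test_unknown_drug(self, tmp_path, t2d_model):
        path = tmp_path / "drugs.yaml"
        path.write_text("drugs: [aspirin]\n")
        with pytest.raises(ValidationError, match="aspirin"):
            read_drug_file(path, t2d_model)

    def test_round_trips(self, tmp_path, t2d_model):
        disease = DiseaseSpec(
            name="x",
            initial_states={GENE_S: "high"},
            disease_rule_ids=("T2D1",),
        )
        write_disease_file(disease, tmp_path / "d.yaml")
        model = base_model()
        model.add_rule(
            parse_rule_line(
                "cell,c,gene,S,up -> cell,c,gene,A,up @id=T2D1 @disease",
                model,
                default_id="T2D1",
            )
        )
        assert read_disease_file(tmp_path / "d.yaml", model) == disease

        drugs = DrugSpec(drugs=("metformin", "acarbose"))
        write_drug_file(drugs, tmp_path / "drugs.yaml")
        assert read_drug_file(tmp_path / "drugs.yaml", t2d_model) == drugs


class TestTraceFile:
    def test_zero_firings_header_only(self, tmp_path):
        model = base_model()
        trace = run_simulation(model, seed=0)
        out = tmp_path / "trace.tsv"
        write_trace(trace, out)
        assert read_trace(out) == []
        lines = [l for l in out.read_text().splitlines() if not l.startswith("#")]
        assert len(lines) == 1  # column header only

    def test_single_firing_row(self, tmp_path):
        model = chain_model()
        trace = run_simulation(model, drugs=DrugSpec(("d",)), seed=1)
        out = tmp_path / "trace.tsv"
        write_trace(trace, out)
        rows = read_trace(out)
        r1_rows = [r for r in rows if r[1] == "r1"]
        assert len(r1_rows) == 1
        _, _, ref, old, new, rfs_after = r1_rows[0]
        assert ref == AttributeRef("cell", "c", "gene", "A")
        assert (old, new, rfs_after) == ("normal", "high", 0.0)

    def test_round_trip_matches_records(self, tmp_path):
        model = chain_model()
        trace = run_simulation(model, drugs=DrugSpec(("d",)), seed=1)
        out = tmp_path / "trace.tsv"
        write_trace(trace, out, header={"note": "test"})
        rows = read_trace(out)
        expected = [
            (rec.step, rec.rule_id, ref, old, new, rfs)
            for rec in trace.records
            for ref, old, new, rfs in rec.changes
        ]
        assert rows == expected

    def test_unwritable_path(self):
        model = base_model()
        trace = run_simulation(model, seed=0)
        with pytest.raises(OSError):
            write_trace(trace, "/nonexistent-dir/trace.tsv")


class TestLoadingOrder:
    def test_rules_require_components(self, tmp_path):
        from rulescale.core_model import ModelSpec

        (tmp_path / "rules.txt").write_text(
            "cell,c,gene,A,up -> cell,c,gene,B,up\n"
        )
        with pytest.raises(ValidationError):
            read_rule_file(tmp_path / "rules.txt", ModelSpec())
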