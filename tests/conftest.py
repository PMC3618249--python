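import pytest

from rulescale.core_model import (
    AttributeRef,
    Component,
    ModelSpec,
    Rule,
    StateDomain,
)
from rulescale.fixtures import build_t2d_fixture
from rulescale.model_io import DiseaseSpec


TERNARY = ("low", "normal", "high")


def ternary_domain(name="gene"):
    return StateDomain(name, TERNARY, ("up", "down"), ("up", "down"), "normal")


def presence_domain():
    return StateDomain(
        "presence", ("absent", "present"), ("absent", "present"),
        ("absent", "present"), "absent",
    )


def base_model(*, organ_threshold=60.0, with_organ=False):
    """Small model: one drug, one cell with genes A and B, optional organ."""
    model = ModelSpec()
    model.add_domain(ternary_domain("gene"))
    model.add_domain(ternary_domain("metabolite"))
    model.add_domain(presence_domain())
    model.add_component(Component("drug", "d", (("presence", "status"),), 1.0))
    model.add_component(
        Component("cell", "c", (("gene", "A"), ("gene", "B"), ("gene", "S")), 1.0)
    )
    if with_organ:
        model.add_component(
            Component("organ", "o", (("metabolite", "M"),), organ_threshold)
        )
    return model


def ref(component_type, name, attribute_type, attribute_name):
    return AttributeRef(component_type, name, attribute_type, attribute_name)


DRUG = ref("drug", "d", "presence", "status")
GENE_A = ref("cell", "c", "gene", "A")
GENE_B = ref("cell", "c", "gene", "B")
GENE_S = ref("cell", "c", "gene", "S")
ORGAN_M = ref("organ", "o", "metabolite", "M")


def chain_model():
    """drug present -> A up; A up -> B up."""
    model = base_model()
    model.add_rule(Rule("r1", ((DRUG, "present"),), ((GENE_A, "up"),)))
    model.add_rule(Rule("r2", ((GENE_A, "up"),), ((GENE_B, "up"),)))
    return model


@pytest.fixture(scope="session")
def t2d():
    return build_t2d_fixture()


@pytest.fixture(scope="session")
def t2d_model(t2d):
    return t2d[0]


@pytest.fixture(scope="session")
def t2d_disease(t2d):
    return t2d[1]


@pytest.fixture(scope="session")
def t2d_drugs(t2d):
    return t2d[2]


@pytest.fixture
def gene_domain():
    return ternary_domain()


@pytest.fixture
def channel_domain():
    return StateDomain("channel", ("close", "open"), ("close", "open"),
                       ("close", "open"), "open")


@pytest.fixture
def disease_s_high():
    """Disease spec putting gene S of the small model at 'high'."""
    return DiseaseSpec(name="test", initial_states={GENE_S: "high"})
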