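import json

import pytest

from mdagplan.mdag import MDag, Node
from mdagplan.recoverability import Estimand
from mdagplan.simulate import case_study_design, case_study_mdag

# the study graph as a parser-facing JSON document (exposure X, outcome Y,
# complete confounders C, incomplete confounders Z, three indicators)
STUDY_GRAPH_DOC = {
    "nodes": [
        {"name": "C", "kind": "substantive", "role": "confounder"},
        {"name": "Z", "kind": "substantive", "role": "confounder"},
        {"name": "X", "kind": "substantive", "role": "exposure"},
        {"name": "Y", "kind": "substantive", "role": "outcome"},
        {"name": "M_X", "kind": "missingness", "indicator_of": "X"},
        {"name": "M_Y", "kind": "missingness", "indicator_of": "Y"},
        {"name": "M_Z", "kind": "missingness", "indicator_of": "Z"},
    ],
    "edges": [
        ["C", "X"], ["C", "Y"], ["Z", "X"], ["Z", "Y"], ["X", "Y"],
        ["Z", "M_X"], ["Z", "M_Y"], ["Z", "M_Z"],
        ["X", "M_X"], ["X", "M_Y"], ["X", "M_Z"],
    ],
}

ROLES = {"X": "X", "Y": "Y", "Z": "Z", "C": "C", "M_X": "M_X", "M_Y": "M_Y", "M_Z": "M_Z"}


@pytest.fixture(scope="session")
def study_graph_text() -> str:
    return json.dumps(STUDY_GRAPH_DOC)


@pytest.fixture(scope="session")
def graph_a() -> MDag:
    """Study m-DAG without outcome-driven missingness (canonical type E)."""
    return case_study_mdag(outcome_arrows=False)


@pytest.fixture(scope="session")
def graph_b() -> MDag:
    """Alternative m-DAG where the outcome causes all indicators (type J)."""
    return case_study_mdag(outcome_arrows=True)


@pytest.fixture(scope="session")
def roles() -> dict:
    return dict(ROLES)


@pytest.fixture(scope="session")
def estimand() -> Estimand:
    return Estimand.regression("Y", "X", {"C", "Z"})


@pytest.fixture(scope="session")
def design_a():
    """Calibrated case-study design, outcome-independent missingness."""
    return case_study_design(mechanism="outcome_independent")


@pytest.fixture(scope="session")
def design_b():
    """Calibrated case-study design, outcome-dependent missingness."""
    return case_study_design(mechanism="outcome_dependent")


@pytest.fixture(scope="session")
def design_mar():
    """Calibrated variant where missingness depends on the complete confounders
    only, so CRA and standard MI are both valid and imputation models are
    correctly specified."""
    return case_study_design(mechanism="confounder_only")


@pytest.fixture
def chain_graph() -> MDag:
    return MDag([Node("a"), Node("b"), Node("c")], [("a", "b"), ("b", "c")])


@pytest.fixture
def collider_graph() -> MDag:
    return MDag([Node("a"), Node("b"), Node("c")], [("a", "c"), ("b", "c")])
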