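import numpy as np
import pytest

from gofp.alphabet import load_matrix, uniform_background
from gofp.library import LibraryParams, build_library
from gofp.ontology import parse_obo
from gofp.world import WorldParams, generate_world

TINY_OBO = """format-version: 1.2
ontology: go

[Term]
id: GO:0003674
name: molecular_function
namespace: molecular_function

[Term]
id: GO:0003824
name: catalytic activity
namespace: molecular_function
is_a: GO:0003674

[Term]
id: GO:0016787
name: hydrolase activity
namespace: molecular_function
is_a: GO:0003824

[Term]
id: GO:0004721
name: phosphoprotein phosphatase activity
namespace: molecular_function
is_a: GO:0016787

[Term]
id: GO:0004725
name: protein tyrosine phosphatase activity
namespace: molecular_function
is_a: GO:0004721

[Term]
id: GO:0008150
name: biological_process
namespace: biological_process
"""


@pytest.fixture(scope="session")
def tiny_obo_text():
    return TINY_OBO


@pytest.fixture(scope="session")
def tiny_dag():
    return parse_obo(TINY_OBO)


@pytest.fixture(scope="session")
def blosum62():
    return load_matrix("BLOSUM62")


@pytest.fixture(scope="session")
def uniform_bg():
    return uniform_background()


@pytest.fixture(scope="session")
def small_world():
    """A cheap world shared by read-only tests (2 folds x 2 functions)."""
    return generate_world(WorldParams(
        n_folds=2, n_functions=2, domains_per_cell=5, clusters_per_cell=4,
        fold_core_length=90, seed=11,
    ))


@pytest.fixture(scope="session")
def small_library(small_world):
    w = small_world
    params = LibraryParams(calibration_n_random=120, calibration_length=90)
    return build_library(w.domains, w.chains, w.dag, params, seed=11), params
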