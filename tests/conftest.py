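import numpy as np
import pytest

from omiclink.datamodel import Registry
from omiclink.fixtures import StudyDesign, simulate_study
from omiclink.linkage import build_linkmap


@pytest.fixture(scope="session")
def study():
    """Default two-group integrated study, seed 0."""
    return simulate_study(StudyDesign(seed=0))


@pytest.fixture(scope="session")
def study_dir(study, tmp_path_factory):
    d = tmp_path_factory.mktemp("study")
    study.write(d)
    return d


@pytest.fixture(scope="session")
def registry(study):
    reg = Registry()
    reg.register_dataset("expression", study.expression)
    reg.register_dataset("states", study.states)
    reg.register_dataset("genes", study.gene_features, kind="gene")
    reg.register_dataset("markers", study.marker_features, kind="marker")
    reg.register_dataset("clinical", study.clinical)
    return reg


@pytest.fixture(scope="session")
def linkmap(study):
    return build_linkmap(study.marker_features, study.gene_features)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
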