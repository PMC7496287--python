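import numpy as np
import pytest

import rbekit as rk


@pytest.fixture(scope="session")
def du145_distal_assay():
    """One simulated Du145 assay at the highest-LET proton condition."""
    arch = rk.study_archetypes()["Du145"]
    cond = rk.BeamCondition(rk.Radiation.PROTON, let_d=4.5)
    return rk.simulate_assay(rk.AssayDesign(), arch, cond, rng=123)


@pytest.fixture(scope="session")
def study_fixture_dir(tmp_path_factory):
    """Full synthetic study written as per-cell-line CSVs."""
    out = tmp_path_factory.mktemp("fixture")
    rk.make_study_fixture(7, out)
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
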