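import numpy as np
import pytest

import sysdecode as sd


@pytest.fixture(scope="session")
def small_grid():
    return sd.VolumeGrid.isotropic((12, 12, 12), 2.0)


@pytest.fixture(scope="session")
def fixture_small():
    """A reduced synthetic study (fewer studies) for decoder-level tests."""
    return sd.make_fixture(seed=11, n_studies=1200)


@pytest.fixture(scope="session")
def pipeline_result():
    """One full default-scale pipeline run shared by the end-to-end tests."""
    return sd.run_pipeline(sd.PipelineConfig(rng_seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
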