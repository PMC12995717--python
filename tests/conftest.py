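import numpy as np
import pytest
from hypothesis import settings

from echofuse import synthetic

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_study():
    """One rendered study at the generator's default conditions."""
    params = synthetic.SynthParams(n_studies=1, seed=42)
    videos, latents, patient_id, study_id, doppler = synthetic.generate_study(
        params, 0)
    return {"params": params.resolved(), "videos": videos, "latents": latents}


@pytest.fixture(scope="session")
def small_study():
    """A fast low-resolution study for pipeline-level tests."""
    params = synthetic.SynthParams(n_studies=1, frame_size=64, frame_count=24,
                                   seed=3)
    videos, latents, *_ = synthetic.generate_study(params, 0)
    return {"params": params.resolved(), "videos": videos, "latents": latents}


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
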