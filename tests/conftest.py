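import numpy as np
import pytest

from flymet import RespSynthSpec, gen_resp_trace


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def noise_free_spec():
    """Deterministic recording: known SMR, coupling, drift, no noise."""
    return RespSynthSpec(
        duration_s=2040,          # 1800-s fly segment -> 6 segments
        noise_sd_ppm=0.0,
        drift_ppm_per_s=0.003,
        smr_uW=17.637,
        activity_coupling_uW=0.5,
        mass_mg=1.0,
        seed=11,
    )


@pytest.fixture
def noise_free_trace(noise_free_spec):
    return gen_resp_trace(noise_free_spec)
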