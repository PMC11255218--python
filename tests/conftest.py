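import numpy as np
import pytest

from embryoscope.respirometry import OxygenTrace
from embryoscope.synthetic import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_config():
    """Noiseless, small synthetic dataset: exact round trips."""
    return SimulationConfig(seed=7, stages=range(10, 20), n_embryos_per_stage=3)


@pytest.fixture
def noisy_config():
    return SimulationConfig(
        seed=11,
        stages=range(10, 20),
        n_embryos_per_stage=5,
        noise_sd_o2=0.01,
        weight_sigma0=0.05,
        weight_sigma_slope=0.01,
        cq_noise_sd=0.15,
        loading_sd_log2=0.3,
    )


def make_linear_trace(slope_mg_l_h=-0.8, duration_min=20.0, interval_s=15.0,
                      o2_start=7.4, temperature=24.0, noise_sd=0.0, seed=0,
                      **kwargs):
    times = np.arange(0.0, duration_min * 60.0 + interval_s / 2, interval_s)
    o2 = o2_start + slope_mg_l_h * times / 3600.0
    if noise_sd > 0:
        o2 = o2 + np.random.default_rng(seed).normal(0, noise_sd, len(times))
    o2 = np.clip(o2, 0, None)
    defaults = dict(vial_id="T1", temperature=temperature,
                    chamber_volume_l=1.75e-3, is_blank=False, embryo_id="E1")
    defaults.update(kwargs)
    return OxygenTrace(times=times, o2=o2, **defaults)
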