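import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from rnptrack.fcs import CorrelationCurve, autocorrelate, bin_stream
from rnptrack.simulate import FCSSimConfig, simulate_fcs_stream

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def neff_matched_config(
    beam_waist: float,
    aspect_ratio: float,
    diffusion: float,
    duration: float,
    time_step: float,
    seed: int,
    brightness: float = 1e5,
) -> FCSSimConfig:
    """Single-species config with the particle count chosen for N_eff ~= 1."""
    box = (5 * beam_waist, 5 * beam_waist, 5 * aspect_ratio * beam_waist)
    veff = math.pi**1.5 * beam_waist**3 * aspect_ratio
    vbox = 8 * box[0] * box[1] * box[2]
    return FCSSimConfig(
        diffusion_coefficients=[diffusion],
        species_counts=[round(vbox / veff)],
        brightness=brightness,
        beam_waist=beam_waist,
        aspect_ratio=aspect_ratio,
        box_half_widths=box,
        time_step=time_step,
        duration=duration,
        seed=seed,
    )


@pytest.fixture(scope="session")
def short_sim():
    """A cheap seeded single-species acquisition shared across tests.

    Slow diffusion (D = 1e-10 m^2/s, tD = 100 us) at a coarse 10 us time
    step keeps the run to a few seconds while giving enough transits for
    amplitude and count-rate checks.
    """
    config = neff_matched_config(
        beam_waist=0.2e-6, aspect_ratio=3.0, diffusion=1e-10,
        duration=2.0, time_step=1e-5, seed=11,
    )
    stream = simulate_fcs_stream(config)
    trace = bin_stream(stream, config.time_step)
    curve = autocorrelate(trace, scheme="multi_tau", points_per_octave=16)
    return config, stream, curve


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_curve(params, lags) -> CorrelationCurve:
    from rnptrack.fcs import model_correlation

    return CorrelationCurve(lags=np.asarray(lags),
                            values=model_correlation(params, lags))
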