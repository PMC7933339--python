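import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from mwfp import (
    Chromatogram,
    PipelineConfig,
    SyntheticStudyConfig,
    run,
)

SEEDS = tuple(range(1, 21))


def gaussian_trace(
    centers,
    amplitudes,
    sigma=0.05,
    step=0.002,
    t_max=10.0,
    baseline=0.0,
    sample_id="X",
    wavelength="203",
):
    """Synthetic trace: unit-area Gaussians scaled by ``amplitudes``.

    ``amplitudes`` are peak heights; the underlying Gaussian area is
    height * sigma * sqrt(2*pi).
    """
    t = np.arange(0.0, t_max + step / 2, step)
    x = np.full_like(t, float(baseline))
    for c, a in zip(np.atleast_1d(centers), np.atleast_1d(amplitudes)):
        x = x + a * np.exp(-0.5 * ((t - c) / sigma) ** 2)
    return Chromatogram(sample_id, wavelength, t, x)


@pytest.fixture(scope="session")
def seed_sweep():
    """Full pipeline runs of the default synthetic study for 20 seeds."""
    results = []
    for seed in SEEDS:
        cfg = PipelineConfig(synthetic=SyntheticStudyConfig(seed=seed))
        results.append((cfg, run(cfg)))
    return results


@pytest.fixture(scope="session")
def small_study():
    """A small, fast synthetic study (6 samples, short gradient)."""
    from mwfp import simulate_study

    cfg = SyntheticStudyConfig(seed=11, group_sizes=(3, 3), t_max=45.0)
    study, truth = simulate_study(cfg)
    return cfg, study, truth
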