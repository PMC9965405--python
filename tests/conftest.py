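import numpy as np
import pytest

from releasekit import GeneratorConfig, ReleaseCurve, generate_release_curve

# Gompertz parameterizations of the two release media studied:
# phosphate-buffered saline and an acidic (pH 3) medium.
PBS_GOMPERTZ = {"Qmax": 83.0, "alpha": 0.83, "beta": -2.7}
PH3_GOMPERTZ = {"Qmax": 70.0, "alpha": 0.97, "beta": -1.5}


@pytest.fixture
def pbs_curve_noiseless() -> ReleaseCurve:
    """Exact Gompertz curve, 12 log-spaced times over 0.5-170 h."""
    return generate_release_curve(
        GeneratorConfig(params=PBS_GOMPERTZ, sigma_pct=0.0, clip=None)
    )


@pytest.fixture
def pbs_curve_noisy() -> ReleaseCurve:
    """One seeded noisy realization of the saturating release curve."""
    return generate_release_curve(GeneratorConfig(params=PBS_GOMPERTZ, seed=7))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
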