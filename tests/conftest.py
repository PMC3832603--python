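import numpy as np
import pytest

from oecfkit import BezierCurve, BiexpParams, OECFDataset, SyntheticTruth
from oecfkit import fixtures, invert_biexp, simulate_oecf
from oecfkit.bezier import eval_bezier


@pytest.fixture(scope="session")
def red_params() -> BiexpParams:
    """Published red-channel biexponential coefficients."""
    return fixtures.fixture_biexp("canon40d_red")


@pytest.fixture(scope="session")
def red_e_max(red_params) -> float:
    """Anchor exposure solved self-consistently from the red coefficients."""
    return invert_biexp(red_params, red_params.g_max)


@pytest.fixture(scope="session")
def all_fixture_names():
    return list(fixtures.CHANNELS)


@pytest.fixture
def known_curve() -> BezierCurve:
    """A monotone cubic Bezier used as ground truth in fitting tests."""
    return BezierCurve(
        control_x=np.array([0.05, 0.2, 0.6, 1.0]),
        control_y=np.array([0.12, 0.45, 0.82, 0.96]),
    )


@pytest.fixture
def curve_dataset(known_curve) -> OECFDataset:
    """20 noiseless samples taken exactly on ``known_curve``."""
    ts = np.linspace(0.0, 1.0, 20)
    x, y = eval_bezier(known_curve, ts)
    return OECFDataset(
        channel="synthetic", exposure=x, response=y,
        normalised=True, e_max=1.0, g_max=0.96,
    )


@pytest.fixture
def noisy_red_dataset(red_params) -> OECFDataset:
    """96-point synthetic ladder from the red-channel truth, noise SD 1."""
    truth = SyntheticTruth(red_params, noise_sd=1.0, seed=42)
    return simulate_oecf(truth)
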