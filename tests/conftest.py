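import numpy as np
import pytest

from shockhrv import RRIGenParams, RRISeries, generate_rri_series


@pytest.fixture
def constant_rri() -> RRISeries:
    """100 beats at a constant 800 ms."""
    return RRISeries.from_nn(np.full(100, 800.0))


@pytest.fixture
def lf_hf_rri() -> RRISeries:
    """5-min tachogram with LF (0.05 Hz, 20 ms) and HF (0.4 Hz, 10 ms) sinusoids."""
    return generate_rri_series(
        RRIGenParams(mean_rr=800, lf_amp=20, hf_amp=10, duration=300, seed=0)
    )


def match_beats(detected: np.ndarray, truth: np.ndarray, tol_s: float = 0.05):
    """Greedy nearest matching of detected to true beat times.

    Returns (sensitivity, per-matched-beat absolute errors in s, n_extra).
    """
    if len(detected) == 0:
        return 0.0, np.array([]), 0
    errs = np.abs(truth[:, None] - detected[None, :])
    nearest = errs.min(axis=1)
    hit = nearest <= tol_s
    extra = len(detected) - int(np.sum(errs.min(axis=0) <= tol_s))
    return float(np.mean(hit)), nearest[hit], max(extra, 0)
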