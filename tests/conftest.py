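import numpy as np
import pytest

from camseed import electropherogram as ep

KDA_STEP = 0.05


def gaussian_trace(
    peaks, grid_start=5.0, grid_stop=80.0, sigma=0.8, condition="reduced"
):
    """Noiseless multi-Gaussian trace with unit-area peaks scaled by weight."""
    grid = np.arange(grid_start, grid_stop, KDA_STEP)
    sig = np.zeros_like(grid)
    for kda, weight in peaks:
        amp = weight / (sigma * np.sqrt(2 * np.pi))
        sig = sig + amp * np.exp(-0.5 * ((grid - kda) / sigma) ** 2)
    return ep.Trace(grid, sig, condition)


def peak_table(apex_area_pairs, condition="reduced", sample_id="s"):
    """Build a quantified PeakTable directly from (apex, area) pairs."""
    peaks = [
        ep.Peak(apex_kda=a, height=1.0, area=ar) for a, ar in apex_area_pairs
    ]
    peaks = ep.percent_of_total(peaks)
    return ep.PeakTable(sample_id=sample_id, condition=condition, peaks=peaks)


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
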