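"""Electropherogram peak quantification.

Turns a capillary-electrophoresis trace (apparent size in kDa vs signal)
into a quantified peak table: morphological baseline removal, peak
detection, percent-of-total quantification (each peak as a percent of the
total integrated protein signal in the sample), nominal-peak matching with
a kDa tolerance, and detection of unresolved shoulders on a peak flank.

The trace is consumed on the apparent-size axis directly; instrument
migration-time-to-kDa calibration is taken as given.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, signal as sps

Condition = Literal["reduced", "nonreduced"]

#: Default peak-calling thresholds. The instrument software's own thresholds
#: are not published; these are this package's defaults and are surfaced
#: here so users can override them.
MIN_REL_HEIGHT = 0.02
MIN_SEPARATION_KDA = 1.0
MATCH_TOL_KDA = 1.5
BASELINE_WINDOW_KDA = 8.0


@dataclasses.dataclass(frozen=True)
class Trace:
    """A sampled electropherogram under one separation condition."""

    grid: np.ndarray
    signal: np.ndarray
    condition: Condition

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        sig = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "signal", sig)
        if grid.ndim != 1 or sig.ndim != 1 or grid.size != sig.size:
            raise ValueError("grid and signal must be 1-D and equal length")
        if grid.size < 16:
            raise ValueError("trace needs at least 16 samples")
        if not np.all(np.diff(grid) > 0):
            raise ValueError("grid must be strictly increasing")
        if self.condition not in ("reduced", "nonreduced"):
            raise ValueError(f"unknown condition {self.condition!r}")

    @property
    def step_kda(self) -> float:
        return float(np.median(np.diff(self.grid)))


@dataclasses.dataclass
class Peak:
    """One detected, integrated peak."""

    apex_kda: float
    height: float
    area: float
    percent: float = 0.0
    is_shoulder: bool = False


@dataclasses.dataclass
class PeakTable:
    """Quantified peaks of one sample under one condition."""

    sample_id: str
    condition: Condition
    peaks: list[Peak]

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: p.apex_kda)


def read_trace_csv(path, condition: Condition) -> Trace:
    """Read a two-column ``size_kda,signal`` CSV (header required)."""
    df = pd.read_csv(path)
    if not {"size_kda", "signal"} <= set(df.columns):
        raise ValueError("trace CSV must have columns size_kda, signal")
    return Trace(df["size_kda"].to_numpy(), df["signal"].to_numpy(), condition)


def write_trace_csv(trace: Trace, path) -> None:
    pd.DataFrame({"size_kda": trace.grid, "signal": trace.signal}).to_csv(
        path, index=False
    )


def write_peak_table(table: PeakTable, path) -> None:
    rows = [
        {
            "sample_id": table.sample_id,
            "condition": table.condition,
            "apex_kda": p.apex_kda,
            "height": p.height,
            "area": p.area,
            "percent": p.percent,
            "is_shoulder": p.is_shoulder,
        }
        for p in table.peaks
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def subtract_baseline(
    trace: Trace, window_kda: float = BASELINE_WINDOW_KDA
) -> Trace:
    """Remove a slowly varying baseline by morphological opening.

    The baseline is the grey opening (rolling minimum followed by rolling
    maximum over the same window) of the signal, which follows offsets and
    drifts but cannot follow features narrower than the window. The
    operation is idempotent: opening the residual yields zero.
    """
    step = trace.step_kda
    if window_kda <= step:
        raise ValueError("window_kda must exceed the grid spacing")
    span = trace.grid[-1] - trace.grid[0]
    if window_kda >= span:
        raise ValueError("window_kda wider than the full grid")
    size = max(3, int(round(window_kda / step)))
    baseline = ndimage.grey_opening(trace.signal, size=size, mode="nearest")
    return Trace(trace.grid, trace.signal - baseline, trace.condition)


def _smooth(sig: np.ndarray, window: int = 11) -> np.ndarray:
    """Savitzky-Golay smoothing used before derivative-based steps."""
    window = max(5, window) | 1
    if sig.size < window:
        return sig
    return sps.savgol_filter(sig, window_length=window, polyorder=3)


def detect_peaks(
    trace: Trace,
    min_rel_height: float = MIN_REL_HEIGHT,
    min_separation_kda: float = MIN_SEPARATION_KDA,
) -> list[Peak]:
    """Find and integrate local maxima of a baseline-subtracted trace.

    Maxima must rise at least ``min_rel_height`` of the global maximum above
    their surroundings (prominence criterion) and be separated by at least
    ``min_separation_kda``. Area is the trapezoidal integral of the raw
    signal between flanking minima; at the trace edges the boundary falls
    back to four estimated peak widths (sigma) from the apex.
    """
    sig = np.asarray(trace.signal, dtype=float)
    gmax = float(sig.max(initial=0.0))
    if gmax <= 0.0:
        return []
    step = trace.step_kda
    distance = max(1, int(round(min_separation_kda / step)))
    # smoothing window matched to the separation scale: features narrower
    # than min_separation are noise by definition
    smoothed = _smooth(sig, window=distance)
    idx, props = sps.find_peaks(
        smoothed,
        prominence=min_rel_height * float(smoothed.max()),
        distance=distance,
    )
    if idx.size == 0:
        return []
    # sigma estimate from the full width at half prominence-height
    widths = sps.peak_widths(smoothed, idx, rel_height=0.5)[0]
    sigmas = widths * step / 2.355

    peaks: list[Peak] = []
    for k, i in enumerate(idx):
        if k > 0:
            j0 = idx[k - 1] + int(np.argmin(smoothed[idx[k - 1]: i + 1]))
        else:
            j0 = max(0, i - int(round(4.0 * sigmas[k] / step)))
        if k < idx.size - 1:
            j1 = i + int(np.argmin(smoothed[i: idx[k + 1] + 1]))
        else:
            j1 = min(sig.size - 1, i + int(round(4.0 * sigmas[k] / step)))
        if j1 <= j0:
            continue
        area = float(np.trapezoid(sig[j0: j1 + 1], trace.grid[j0: j1 + 1]))
        if area <= 0.0:
            continue
        peaks.append(
            Peak(apex_kda=float(trace.grid[i]), height=float(sig[i]), area=area)
        )
    peaks.sort(key=lambda p: p.apex_kda)
    return peaks


def percent_of_total(peaks: Sequence[Peak]) -> list[Peak]:
    """Quantify each peak as a percent of total peak area.

    Shoulder-flagged peaks are excluded from the denominator and receive
    no percentage of their own, so the non-shoulder percents sum to 100.
    """
    main = [p for p in peaks if not p.is_shoulder]
    if not main:
        raise ValueError("no peaks to quantify")
    total = sum(p.area for p in main)
    if total <= 0.0:
        raise ValueError("total peak area is zero; nothing to quantify")
    out = []
    for p in peaks:
        pct = 0.0 if p.is_shoulder else 100.0 * p.area / total
        out.append(dataclasses.replace(p, percent=pct))
    return out


def match_peak(
    table: PeakTable, nominal_kda: float, tol_kda: float = MATCH_TOL_KDA
) -> Optional[Peak]:
    """Largest-area peak within ``tol_kda`` of a nominal size, if any.

    Ties on area are broken by apex proximity to the nominal value.
    """
    if tol_kda <= 0:
        raise ValueError("tol_kda must be positive")
    candidates = [
        p for p in table.peaks if abs(p.apex_kda - nominal_kda) <= tol_kda
    ]
    if not candidates:
        return None
    return max(
        candidates, key=lambda p: (p.area, -abs(p.apex_kda - nominal_kda))
    )


def detect_shoulder(
    trace: Trace,
    main_peak: Peak,
    side: Literal["higher", "lower"],
    window_kda: float = 4.0,
) -> bool:
    """True if the stated flank of a peak carries an unresolved shoulder.

    On a clean Gaussian flank the second derivative changes sign exactly
    once (at the inflection point). An unresolved secondary component adds
    further curvature sign changes while the first derivative keeps its
    sign (a resolved neighbour would make the first derivative cross zero
    and is a peak, not a shoulder).
    """
    if side not in ("higher", "lower"):
        raise ValueError("side must be 'higher' or 'lower'")
    sig = np.asarray(trace.signal, dtype=float)
    apex = int(np.argmin(np.abs(trace.grid - main_peak.apex_kda)))
    if apex == 0 or apex == sig.size - 1:
        raise ValueError("peak apex lies on the grid boundary")
    step = trace.step_kda
    # Savitzky-Golay derivative estimates: shoulder curvature excursions
    # are only ~1% of the apex curvature, so the window must stay well
    # below the peak width
    dwin = max(11, int(round(0.5 / step))) | 1
    if sig.size < dwin:
        raise ValueError("trace too short for derivative estimation")
    d1 = sps.savgol_filter(sig, dwin, polyorder=3, deriv=1, delta=step)
    d2 = sps.savgol_filter(sig, dwin, polyorder=3, deriv=2, delta=step)
    # the nominal apex may sit a few samples off the composite's true
    # local maximum; hill-climb so the flank analysis starts at the top
    smooth_sig = sps.savgol_filter(sig, dwin, polyorder=3)
    while 0 < apex < sig.size - 1:
        if smooth_sig[apex + 1] > smooth_sig[apex]:
            apex += 1
        elif smooth_sig[apex - 1] > smooth_sig[apex]:
            apex -= 1
        else:
            break
    if apex == 0 or apex == sig.size - 1:
        raise ValueError("peak apex lies on the grid boundary")
    w = max(4, int(round(window_kda / step)))
    if side == "higher":
        lo, hi = apex, min(sig.size - 1, apex + w)
    else:
        lo, hi = max(0, apex - w), apex
    if hi - lo < 6:
        raise ValueError("window too close to the grid boundary")
    d1_seg = d1[lo: hi + 1]
    d2_seg = d2[lo: hi + 1]
    # exclude samples adjacent to the apex where d1 ~ 0 by construction
    inner = slice(3, None) if side == "higher" else slice(None, -3)
    d1_in = d1_seg[inner]
    # first-derivative zero crossing => resolved neighbouring peak
    d1_mag = float(np.max(np.abs(d1_seg)))
    if d1_mag == 0.0:
        return False
    s1 = np.sign(d1_in[np.abs(d1_in) > 0.05 * d1_mag])
    if s1.size and np.any(s1[:-1] * s1[1:] < 0):
        return False
    d2_mag = float(np.max(np.abs(d2_seg)))
    if d2_mag == 0.0:
        return False
    # noise-adaptive floor: MAD of d2 over the trace estimates the noise
    # level (the trace is mostly flat), so noise wiggles cannot register
    # as curvature sign changes while true noiseless excursions of ~0.1%
    # of the apex curvature still do
    noise_floor = 3.0 * 1.4826 * float(np.median(np.abs(d2 - np.median(d2))))
    thresh = max(noise_floor, 1e-3 * d2_mag)
    s2 = np.sign(d2_seg[np.abs(d2_seg) > thresh])
    changes = int(np.sum(s2[:-1] * s2[1:] < 0))
    return changes >= 2


def quantify_trace(
    trace: Trace,
    sample_id: str = "sample",
    baseline_window_kda: float = BASELINE_WINDOW_KDA,
    min_rel_height: float = MIN_REL_HEIGHT,
    min_separation_kda: float = MIN_SEPARATION_KDA,
) -> PeakTable:
    """Full pipeline: baseline subtraction, detection, quantification."""
    flat = subtract_baseline(trace, baseline_window_kda)
    peaks = detect_peaks(flat, min_rel_height, min_separation_kda)
    if peaks:
        peaks = percent_of_total(peaks)
    return PeakTable(sample_id=sample_id, condition=trace.condition, peaks=peaks)
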