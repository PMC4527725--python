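"""ECG to clean, windowed NN series: R-peak detection, ectopy screening, windows.

Detection follows the classic derivative/energy chain (Pan–Tompkins style):
band-pass 5–30 Hz, differentiate, square, 150-ms moving-window integration,
adaptive signal/noise thresholding, then refinement of every detection to the
local absolute maximum of the (lightly smoothed) raw lead within ±50 ms.

Ectopy screening is an automated surrogate for manual review: an interval is
flagged when it deviates from the median of its nearest neighbours by more
than a fraction of that median, and a window whose edit fraction exceeds the
cap is rejected outright rather than repaired — analysis accepts only
(near-)ectopy-free data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as ss
from scipy.interpolate import CubicSpline

from .series import ECTOPIC, EDITED, NORMAL, ECGRecord, RRISeries, TimePoint

__all__ = [
    "EctopyPolicy",
    "EctopyReport",
    "SegmentRejectedError",
    "detect_r_peaks",
    "beats_to_rri",
    "flag_ectopy",
    "screen_ectopy",
    "extract_window",
]


def detect_r_peaks(ecg: ECGRecord) -> np.ndarray:
    """Detect R-peak times (seconds) in a single-lead ECG.

    Returns a strictly increasing array of beat times; an empty array signals
    the no-beats condition (e.g. a flat lead).  Non-finite samples are
    rejected.
    """
    x = ecg.samples
    if not np.all(np.isfinite(x)):
        raise ValueError("ECG contains non-finite samples")
    fs = ecg.sampling_rate
    if ecg.duration < 2.0:
        raise ValueError("ECG shorter than 2 s")
    if np.ptp(x) == 0:
        return np.array([])

    # zero-pad so beats at the record boundaries present as interior peaks
    pad = int(round(0.3 * fs))
    x = np.concatenate([np.zeros(pad), x, np.zeros(pad)])

    sos = ss.butter(3, [5.0, 30.0], btype="bandpass", fs=fs, output="sos")
    bp = ss.sosfiltfilt(sos, x)
    energy = np.gradient(bp) ** 2
    win = max(1, int(round(0.150 * fs)))
    integ = np.convolve(energy, np.ones(win) / win, mode="same")

    refractory = max(1, int(round(0.2 * fs)))
    cand, _ = ss.find_peaks(integ, distance=refractory)
    if len(cand) == 0:
        return np.array([])

    # adaptive signal/noise running estimates
    lead_in = integ[: int(2.0 * fs)]
    spki = 0.875 * float(np.max(lead_in))
    npki = 0.5 * float(np.mean(lead_in))
    accepted = []
    for idx in cand:
        h = integ[idx]
        thr = npki + 0.25 * (spki - npki)
        if h > thr:
            accepted.append(idx)
            spki = 0.125 * h + 0.875 * spki
        else:
            npki = 0.125 * h + 0.875 * npki
    if not accepted:
        return np.array([])

    # refine on the raw lead, lightly smoothed to suppress sample-level noise;
    # a kernel ~1/3 of a typical QRS width keeps a symmetric peak unbiased
    # while suppressing argmax jitter, and reflect boundaries keep a peak
    # truncated at the record edge unbiased too
    smooth_win = max(3, int(round(0.021 * fs)) | 1)
    kern = ss.windows.hann(smooth_win)
    kern = kern / kern.sum()
    absx = np.abs(ecg.samples - np.median(ecg.samples))
    core = np.convolve(np.pad(absx, smooth_win // 2, mode="reflect"), kern, mode="valid")
    smoothed = np.concatenate([np.zeros(pad), core, np.zeros(pad)])
    half = int(round(0.05 * fs))
    refined = []
    for idx in accepted:
        lo, hi = max(0, idx - half), min(len(x), idx + half + 1)
        refined.append(lo + int(np.argmax(smoothed[lo:hi])))
    refined = np.unique(refined)
    # collapse refinements that landed within one refractory of each other
    keep = [refined[0]]
    for idx in refined[1:]:
        if idx - keep[-1] >= refractory:
            keep.append(idx)
        elif smoothed[idx] > smoothed[keep[-1]]:
            keep[-1] = idx
    times = (np.asarray(keep, dtype=float) - pad) / fs
    times = times[(times >= 0) & (times <= ecg.duration)]
    return ecg.start_time + times


def beats_to_rri(beat_times) -> RRISeries:
    """Turn detected beat times into a tachogram (all intervals labeled normal)."""
    beat_times = np.asarray(beat_times, dtype=float)
    if len(beat_times) < 2:
        raise ValueError("need at least 2 beat times")
    if np.any(np.diff(beat_times) <= 0):
        raise ValueError("beat times must be strictly increasing")
    return RRISeries.from_beat_times(beat_times)


@dataclass(frozen=True)
class EctopyPolicy:
    """Automated ectopy rule: deviation-from-neighbourhood-median screening."""

    deviation_threshold: float = 0.20  # fraction of the neighbourhood median
    neighborhood: int = 5  # nearest other intervals entering the median
    max_edit_fraction: float = 0.05  # window rejected above this
    repair: str = "interpolate"  # or "delete"

    def __post_init__(self) -> None:
        if not 0 < self.deviation_threshold < 1:
            raise ValueError("deviation_threshold must be in (0, 1)")
        if self.neighborhood < 3 or self.neighborhood % 2 == 0:
            raise ValueError("neighborhood must be odd and >= 3")
        if self.repair not in ("interpolate", "delete"):
            raise ValueError("repair must be 'interpolate' or 'delete'")


@dataclass
class EctopyReport:
    flagged_indices: np.ndarray
    edit_fraction: float
    n_intervals: int
    repair: str
    rejected: bool = False


class SegmentRejectedError(RuntimeError):
    """Raised when a window's edit fraction exceeds the policy cap."""

    def __init__(self, report: EctopyReport):
        self.report = report
        super().__init__(
            f"segment rejected: edit fraction {report.edit_fraction:.3f} exceeds "
            f"cap; window unusable for HRV analysis"
        )


def flag_ectopy(rri: RRISeries, policy: EctopyPolicy = EctopyPolicy()) -> np.ndarray:
    """Boolean mask of intervals deviating from their local median.

    Interval ``k`` is flagged iff ``|NN_k - m| / m > deviation_threshold`` with
    ``m`` the median of the ``neighborhood`` nearest other intervals (ties
    broken toward earlier beats).
    """
    n = rri.n_intervals
    if n < policy.neighborhood + 1:
        raise ValueError("series shorter than the screening neighbourhood")
    nn = rri.nn_ms
    flags = np.zeros(n, dtype=bool)
    k = policy.neighborhood
    for i in range(n):
        cand = [j for j in range(max(0, i - k), min(n, i + k + 1)) if j != i]
        order = sorted(cand, key=lambda j: (abs(j - i), j))[:k]
        m = float(np.median(nn[order]))
        if m > 0 and abs(nn[i] - m) / m > policy.deviation_threshold:
            flags[i] = True
    return flags


def screen_ectopy(
    rri: RRISeries, policy: EctopyPolicy = EctopyPolicy()
) -> tuple[RRISeries, EctopyReport]:
    """Flag and repair ectopic intervals, or reject the window.

    Raises :class:`SegmentRejectedError` (carrying the report) when the edit
    fraction exceeds ``policy.max_edit_fraction``.
    """
    flags = flag_ectopy(rri, policy)
    idx = np.flatnonzero(flags)
    frac = len(idx) / rri.n_intervals
    report = EctopyReport(idx, frac, rri.n_intervals, policy.repair)
    if frac > policy.max_edit_fraction:
        report.rejected = True
        raise SegmentRejectedError(report)
    if len(idx) == 0:
        return rri.copy(), report

    labels = rri.labels.copy()
    if policy.repair == "interpolate":
        good = ~flags
        x_good = rri.onset_times[good]
        spline = CubicSpline(x_good, rri.nn_ms[good])
        nn = rri.nn_ms.copy()
        nn[idx] = spline(rri.onset_times[idx])
        labels[idx] = EDITED
        cleaned = RRISeries.from_nn(nn, start_time=rri.beat_times[0], labels=labels)
    else:  # delete
        nn = rri.nn_ms[~flags]
        labels = labels[~flags]
        cleaned = RRISeries.from_nn(nn, start_time=rri.beat_times[0], labels=labels)
    return cleaned, report


def extract_window(rri: RRISeries, timepoint: TimePoint, duration: float = 300.0) -> RRISeries:
    """Cut the 5-min (by default) analysis window starting at a time point.

    The window is half-open ``[offset, offset + duration)``; returned beat
    times are re-referenced to the window start.
    """
    t0 = timepoint.offset
    t1 = t0 + duration
    if rri.beat_times[0] > t0 or rri.beat_times[-1] < t1:
        raise ValueError(
            f"recording does not cover the {timepoint.label} window "
            f"[{t0:.0f}, {t1:.0f}) s"
        )
    mask = (rri.beat_times >= t0) & (rri.beat_times < t1)
    sel = np.flatnonzero(mask)
    if len(sel) < 2:
        raise ValueError(f"fewer than 2 beats inside the {timepoint.label} window")
    times = rri.beat_times[sel] - t0
    labels = rri.labels[sel[:-1]]
    return RRISeries.from_beat_times(times, labels=labels)
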