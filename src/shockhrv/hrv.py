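"""Time- and frequency-domain HRV for one ectopy-free 5-min window.

Band scheme
-----------
The spectral bands are the porcine scheme derived from pharmacological
autonomic blockade (atropine/propranolol) in pigs rather than the human
task-force bands: VLF [0.0, 0.02) Hz, LF [0.02, 0.09) Hz, HF [0.09, 2.0) Hz.
Pigs under mechanical ventilation can carry respiratory (HF) power well above
the human 0.4 Hz ceiling, hence the 2 Hz edge.

Spectral estimation
-------------------
Default path: spline resampling of the tachogram at 10 Hz (Nyquist 5 Hz,
comfortably above the 2 Hz HF edge), linear detrend, then a Welch PSD (Hann
taper, 150-s segments, 50 % overlap, per-segment linear detrend), one-sided in
ms²/Hz.  150-s segments give ~0.0067 Hz resolution — adequate to resolve the
0–0.02 Hz VLF band inside a 300-s window.  A Lomb–Scargle path consumes the
unevenly sampled tachogram directly, with no resampling.

Band powers integrate the PSD trapezoidally over each half-open band, the DC
bin excluded (the series is detrended/mean-removed, so "VLF from 0.0 Hz"
means from the first positive frequency).  Normalized units remove VLF and
total-power influence: LFnu = 100·LF/(LF+HF).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as ss
from scipy.interpolate import make_interp_spline

from .series import ECTOPIC, RRISeries

__all__ = [
    "BandScheme",
    "PIG_BANDS",
    "HRVTimeDomain",
    "UniformTachogram",
    "WelchConfig",
    "Spectrum",
    "HRVFrequencyDomain",
    "HRVResult",
    "time_domain",
    "resample_tachogram",
    "estimate_psd",
    "estimate_psd_lomb",
    "band_powers",
    "analyze_window",
]


@dataclass(frozen=True)
class BandScheme:
    """Contiguous half-open spectral bands [lo, hi) in Hz."""

    vlf: tuple[float, float] = (0.0, 0.02)
    lf: tuple[float, float] = (0.02, 0.09)
    hf: tuple[float, float] = (0.09, 2.0)

    def __post_init__(self) -> None:
        edges = [*self.vlf, *self.lf, *self.hf]
        if edges != sorted(edges) or len(set(edges[1:-1])) != 2:
            raise ValueError("bands must be contiguous, non-overlapping, increasing")
        if self.vlf[0] < 0:
            raise ValueError("bands must start at or above 0 Hz")


#: The porcine autonomic-blockade band scheme.
PIG_BANDS = BandScheme()


@dataclass(frozen=True)
class HRVTimeDomain:
    variance: float  # ms², sample (n-1) variance of NN
    sdnn: float  # ms
    rmssd: float  # ms
    mean_rr: float  # ms
    n_beats: int


def time_domain(rri: RRISeries) -> HRVTimeDomain:
    """Variance, SDNN and RMSSD of the NN intervals.

    Variance and SDNN use the sample (n−1) estimator; RMSSD averages over the
    natural n−1 successive differences.  Windows still containing unrepaired
    ectopic intervals are refused.
    """
    nn = rri.nn_ms
    if len(nn) < 2:
        raise ValueError("need at least 2 NN intervals")
    if np.any(rri.labels == ECTOPIC):
        raise ValueError("series contains unrepaired ectopic intervals")
    var = float(np.var(nn, ddof=1))
    rmssd = float(np.sqrt(np.mean(np.diff(nn) ** 2)))
    return HRVTimeDomain(var, math.sqrt(var), rmssd, float(np.mean(nn)), rri.n_beats)


@dataclass
class UniformTachogram:
    """Evenly resampled, linearly detrended (mean-removed) NN series."""

    rate: float  # Hz
    values: np.ndarray  # ms, detrended
    t0: float = 0.0


def resample_tachogram(
    rri: RRISeries, rate: float = 10.0, bands: BandScheme = PIG_BANDS, order: int = 5
) -> UniformTachogram:
    """Spline-resample NN(t) onto a uniform grid and linearly detrend.

    ``rate`` must exceed twice the HF upper edge (aliasing guard).  The grid
    spans the interval-onset times only — no spline extrapolation.

    ``order`` is the spline degree.  The default is quintic rather than the
    conventional cubic: with the porcine HF band reaching 2 Hz, respiratory
    oscillations sit at only ~3 beats per cycle, where a cubic spline
    attenuates band power by ~10 %; a quintic keeps the bias under ~3 % at
    the same cost (pass ``order=3`` for the conventional behaviour).
    """
    if rate <= 2.0 * bands.hf[1]:
        raise ValueError(
            f"resample rate {rate} Hz must exceed 2 x HF upper edge "
            f"({2 * bands.hf[1]} Hz)"
        )
    if rri.n_beats < max(4, order + 1):
        raise ValueError("too few beats to resample at this spline order")
    t = rri.onset_times
    spline = make_interp_spline(t, rri.nn_ms, k=order)
    grid = np.arange(t[0], t[-1], 1.0 / rate)
    x = ss.detrend(spline(grid), type="linear")
    return UniformTachogram(rate, x, t0=float(t[0]))


@dataclass(frozen=True)
class WelchConfig:
    segment_s: float = 150.0
    overlap: float = 0.5
    window: str = "hann"
    detrend: str | bool = "linear"  # False to disable (oracle comparisons)


@dataclass
class Spectrum:
    """One-sided PSD in ms²/Hz on a strictly increasing grid from 0 to Nyquist."""

    frequencies: np.ndarray  # Hz
    psd: np.ndarray  # ms²/Hz
    resample_rate: float | None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.psd = np.asarray(self.psd, dtype=float)
        if np.any(np.diff(self.frequencies) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(self.psd < -1e-12):
            raise ValueError("PSD must be non-negative")


def estimate_psd(tach: UniformTachogram, config: WelchConfig = WelchConfig()) -> Spectrum:
    """Welch PSD of the uniform tachogram."""
    n = len(tach.values)
    nperseg = int(round(config.segment_s * tach.rate))
    if nperseg > n:
        raise ValueError(
            f"Welch segment ({config.segment_s} s = {nperseg} samples) longer than "
            f"the series ({n} samples); shorten segment_s or analyze a longer window"
        )
    noverlap = int(nperseg * config.overlap)
    f, p = ss.welch(
        tach.values,
        fs=tach.rate,
        window=config.window,
        nperseg=nperseg,
        noverlap=noverlap,
        detrend=config.detrend,
        scaling="density",
        return_onesided=True,
    )
    meta = {
        "estimator": "welch",
        "segment_s": config.segment_s,
        "overlap": config.overlap,
        "window": config.window,
        "detrend": config.detrend,
    }
    return Spectrum(f, np.clip(p, 0.0, None), tach.rate, meta)


def estimate_psd_lomb(
    rri: RRISeries, bands: BandScheme = PIG_BANDS, oversample: int = 4
) -> Spectrum:
    """Lomb–Scargle PSD of the unevenly sampled tachogram (no resampling).

    The raw periodogram ``P`` is scaled to a one-sided density,
    ``2·P / (n / T)``, so that a sinusoid of amplitude A integrates to A²/2
    over its peak; the series is linearly detrended first.  The grid stops at
    the mean-beat-rate Nyquist (or the HF upper edge, whichever is lower):
    beyond it a quasi-regularly sampled tachogram shows only aliases.
    """
    t = rri.onset_times
    if len(t) < 4:
        raise ValueError("need at least 4 beats")
    span = t[-1] - t[0]
    y = rri.nn_ms - np.polyval(np.polyfit(t, rri.nn_ms, 1), t)
    df = 1.0 / (oversample * span)
    f_max = min(bands.hf[1], len(t) / (2.0 * span))
    freqs = np.arange(df, f_max + df, df)
    pgram = ss.lombscargle(t, y, 2.0 * np.pi * freqs)
    psd = 2.0 * pgram / (len(t) / span)
    # prepend a zero-power DC bin so the grid spans from 0
    freqs = np.concatenate([[0.0], freqs])
    psd = np.concatenate([[0.0], psd])
    meta = {"estimator": "lomb-scargle", "oversample": oversample}
    return Spectrum(freqs, np.clip(psd, 0.0, None), None, meta)


@dataclass
class HRVFrequencyDomain:
    vlf_abs: float  # ms²
    lf_abs: float
    hf_abs: float
    total_power: float  # vlf + lf + hf, ms²
    vlf_pct: float
    lf_pct: float
    hf_pct: float
    lf_nu: float
    hf_nu: float
    lf_hf: float | None  # None when HF power is zero (undefined, not inf)


def _band_integral(f: np.ndarray, p: np.ndarray, lo: float, hi: float) -> float:
    """Trapezoidal PSD integral over [lo, hi), DC excluded."""
    lo = max(lo, f[f > 0][0] if np.any(f > 0) else lo)
    hi = min(hi, f[-1])
    if hi <= lo:
        return 0.0
    inner = (f > lo) & (f < hi)
    grid = np.concatenate([[lo], f[inner], [hi]])
    vals = np.interp(grid, f, p)
    return float(np.trapezoid(vals, grid))


def band_powers(spectrum: Spectrum, bands: BandScheme = PIG_BANDS) -> HRVFrequencyDomain:
    """Integrate the PSD into absolute, percentage and normalized band powers.

    Bands are clipped to the spectrum's frequency range (a Lomb–Scargle
    spectrum of a slow-beating tachogram legitimately ends below the HF upper
    edge); a spectrum that does not even reach the LF band is refused.
    """
    f, p = spectrum.frequencies, spectrum.psd
    if bands.lf[1] > f[-1] + 1e-9:
        raise ValueError("spectrum frequency range does not cover the LF band")
    vlf = _band_integral(f, p, *bands.vlf)
    lf = _band_integral(f, p, *bands.lf)
    hf = _band_integral(f, p, *bands.hf)
    total = vlf + lf + hf
    if total > 0:
        vlf_pct, lf_pct, hf_pct = (100.0 * b / total for b in (vlf, lf, hf))
    else:
        vlf_pct = lf_pct = hf_pct = 0.0
    if lf + hf > 0:
        lf_nu = 100.0 * lf / (lf + hf)
        hf_nu = 100.0 * hf / (lf + hf)
    else:
        lf_nu = hf_nu = 0.0
    lf_hf = lf / hf if hf > 0 else None
    return HRVFrequencyDomain(vlf, lf, hf, total, vlf_pct, lf_pct, hf_pct, lf_nu, hf_nu, lf_hf)


@dataclass
class HRVResult:
    """All metrics for one analyzed window, with estimator metadata."""

    time: HRVTimeDomain
    freq: HRVFrequencyDomain
    spectrum: Spectrum

    def to_row(self) -> dict:
        """One-row summary using the conventional column vocabulary."""
        return {
            "mean_RR": self.time.mean_rr,
            "variance": self.time.variance,
            "SDNN": self.time.sdnn,
            "RMSSD": self.time.rmssd,
            "n_beats": self.time.n_beats,
            "VLF_abs": self.freq.vlf_abs,
            "LF_abs": self.freq.lf_abs,
            "HF_abs": self.freq.hf_abs,
            "total_power": self.freq.total_power,
            "VLF_pct": self.freq.vlf_pct,
            "LF_pct": self.freq.lf_pct,
            "HF_pct": self.freq.hf_pct,
            "LF_nu": self.freq.lf_nu,
            "HF_nu": self.freq.hf_nu,
            "LF_HF": self.freq.lf_hf,
            "estimator": self.spectrum.metadata.get("estimator"),
        }


def analyze_window(
    rri: RRISeries,
    bands: BandScheme = PIG_BANDS,
    method: str = "welch",
    resample_rate: float = 10.0,
    welch: WelchConfig = WelchConfig(),
) -> HRVResult:
    """Full HRV analysis of one clean window (time + frequency domain)."""
    td = time_domain(rri)
    if method == "welch":
        tach = resample_tachogram(rri, rate=resample_rate, bands=bands)
        spec = estimate_psd(tach, welch)
    elif method == "lomb":
        spec = estimate_psd_lomb(rri, bands=bands)
    else:
        raise ValueError("method must be 'welch' or 'lomb'")
    return HRVResult(td, band_powers(spec, bands), spec)
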