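"""Synthetic data with known ground truth: tachograms, ECG waveforms, cohorts.

The RRI generator works directly in the tachogram domain: each NN interval is
the sum of a mean level, band-limited sinusoids (one per spectral band of the
porcine scheme) evaluated at the cumulative beat time, and white Gaussian
jitter.  A sinusoid of amplitude ``A`` ms therefore contributes ``A**2 / 2``
ms² to the NN variance and an equal amount of absolute power to its band,
giving exact analytic targets for the spectral pipeline.  This is a deliberate
simplification relative to integral-pulse-frequency-modulation models of sinus
node firing; see docs/methods.md.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort_defaults import DEFAULT_CELLS, POSITIVE_VARIABLES
from .series import (
    ECTOPIC,
    NORMAL,
    NS_MISSING_DEFAULT,
    TIMEPOINT_LABELS,
    ECGRecord,
    RRISeries,
)

__all__ = [
    "RRIGenParams",
    "ECGGenParams",
    "CohortGenParams",
    "generate_rri_series",
    "inject_ectopy",
    "generate_ecg",
    "generate_cohort",
]


@dataclass(frozen=True)
class RRIGenParams:
    """Parameters of the tachogram-domain RRI generator.

    Default oscillation frequencies sit mid-band in the porcine scheme:
    VLF 0.01 Hz, LF 0.05 Hz, and HF 0.4 Hz (a plausible ventilator rate for
    volume-controlled ventilation at 8 mL/kg with rate titrated to normocapnia).
    Amplitudes are in ms and default to zero so every oscillation is opt-in.
    """

    mean_rr: float  # ms
    duration: float = 300.0  # s
    lf_freq: float = 0.05  # Hz
    lf_amp: float = 0.0  # ms
    hf_freq: float = 0.4  # Hz
    hf_amp: float = 0.0  # ms
    vlf_freq: float = 0.01  # Hz
    vlf_amp: float = 0.0  # ms
    noise_sd: float = 0.0  # ms
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_rr <= 0:
            raise ValueError("mean_rr must be positive")
        if self.duration < 60:
            raise ValueError("duration must be at least 60 s")
        for name in ("lf_amp", "hf_amp", "vlf_amp", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("lf_freq", "hf_freq", "vlf_freq"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        # guard against NN <= 0: worst-case sinusoid sum plus 4-sigma jitter
        amp_sum = self.lf_amp + self.hf_amp + self.vlf_amp
        if amp_sum + 4.0 * self.noise_sd >= self.mean_rr:
            raise ValueError(
                "parameterization can produce non-positive NN intervals "
                "(amplitude sum + 4*noise_sd >= mean_rr)"
            )


def generate_rri_series(params: RRIGenParams) -> RRISeries:
    """Generate a tachogram covering at least ``params.duration`` seconds.

    NN(k) = mean_rr + sum_b amp_b * sin(2*pi*f_b*t_k + phi_b) + eps_k with
    ``t_k`` the cumulative beat time and random (seeded) band phases;
    bit-identical for a fixed seed.
    """
    rng = np.random.default_rng(params.seed)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=3)  # vlf, lf, hf
    comps = (
        (params.vlf_amp, params.vlf_freq, phases[0]),
        (params.lf_amp, params.lf_freq, phases[1]),
        (params.hf_amp, params.hf_freq, phases[2]),
    )
    nn: list[float] = []
    t = 0.0
    while t < params.duration:
        val = params.mean_rr
        for amp, f, phi in comps:
            if amp > 0:
                val += amp * math.sin(2.0 * math.pi * f * t + phi)
        if params.noise_sd > 0:
            val += rng.normal(0.0, params.noise_sd)
        if val <= 0:  # pragma: no cover - excluded by the parameter guard
            raise RuntimeError("generated non-positive NN interval")
        nn.append(val)
        t += val / 1000.0
    return RRISeries.from_nn(np.array(nn))


def inject_ectopy(rri: RRISeries, rate: float, magnitude: float, seed: int = 0) -> RRISeries:
    """Replace beats at random with premature/compensatory ectopic intervals.

    Each interval is independently selected with probability ``rate``;
    successive selected intervals alternate short ``NN*(1-magnitude)`` and long
    ``NN*(1+magnitude)`` so that, pairwise, cumulative recording time is
    conserved (exactly so on a constant series).  Selected intervals carry
    ectopic ground-truth labels.
    """
    if not 0 <= rate < 0.5:
        raise ValueError("rate must be in [0, 0.5)")
    if magnitude <= 0:
        raise ValueError("magnitude must be positive")
    out = rri.copy()
    if rate == 0:
        return out
    rng = np.random.default_rng(seed)
    selected = np.flatnonzero(rng.random(out.n_intervals) < rate)
    signs = np.where(np.arange(len(selected)) % 2 == 0, -1.0, 1.0)
    nn = out.nn_ms
    nn[selected] = nn[selected] * (1.0 + signs * magnitude)
    if np.any(nn <= 0):
        raise ValueError("magnitude >= 1 would produce non-positive intervals")
    labels = out.labels
    labels[selected] = ECTOPIC
    return RRISeries.from_nn(nn, start_time=rri.beat_times[0], labels=labels)


@dataclass(frozen=True)
class ECGGenParams:
    """Synthetic single-lead ECG: Gaussian QRS bumps plus white baseline noise."""

    sampling_rate: float = 1000.0  # Hz
    qrs_width: float = 60.0  # ms, approximate total width (6 sigma)
    qrs_amp: float = 1.0  # arbitrary units
    baseline_noise_sd: float = 0.0  # arbitrary units
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate < 250:
            raise ValueError("sampling_rate below 250 Hz undersamples the QRS")
        if self.qrs_width <= 0:
            raise ValueError("qrs_width must be positive")


def generate_ecg(rri: RRISeries, params: ECGGenParams) -> ECGRecord:
    """Render a tachogram as an ECG waveform with ground-truth beat times.

    One Gaussian bump of amplitude ``qrs_amp`` is centred at every beat time;
    sample count is ``ceil(total duration * sampling_rate)``.
    """
    beat_times = rri.beat_times - rri.beat_times[0]
    if len(beat_times) < 1:
        raise ValueError("RRI series is empty")
    fs = params.sampling_rate
    # pad half a mean interval past the final beat so its QRS is complete
    total = beat_times[-1] + float(np.mean(rri.nn_ms)) / 2000.0
    n = int(math.ceil(total * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)
    sigma = params.qrs_width / 1000.0 / 6.0
    half = 5.0 * sigma
    for tb in beat_times:
        lo = max(0, int((tb - half) * fs))
        hi = min(n, int((tb + half) * fs) + 1)
        if hi > lo:
            x[lo:hi] += params.qrs_amp * np.exp(-0.5 * ((t[lo:hi] - tb) / sigma) ** 2)
    if params.baseline_noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        x += rng.normal(0.0, params.baseline_noise_sd, size=n)
    return ECGRecord(fs, x, start_time=0.0, true_beat_times=beat_times)


@dataclass
class CohortGenParams:
    """Survivor / non-survivor cohort simulator parameters.

    ``cells`` maps ``(variable, group)`` to ``{timepoint: (mean, sd)}``; the
    default parameterizes a realistic 20-animal experiment (see
    ``cohort_defaults``).  ``missing`` removes time points per group; by default
    non-survivors lack all four post-resuscitation points.
    """

    n_survivor: int = 13
    n_nonsurvivor: int = 7
    cells: dict = field(default_factory=lambda: DEFAULT_CELLS)
    missing: dict = field(default_factory=lambda: {"NS": set(NS_MISSING_DEFAULT)})
    positive_variables: frozenset = POSITIVE_VARIABLES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_survivor < 1 or self.n_nonsurvivor < 1:
            raise ValueError("both groups need at least one animal")
        for (var, grp), row in self.cells.items():
            for tp, (mean, sd) in row.items():
                if tp not in TIMEPOINT_LABELS:
                    raise ValueError(f"unknown time point {tp!r} for {var}/{grp}")
                if sd < 0:
                    raise ValueError(f"negative sd for {var}/{grp}/{tp}")
        for grp, tps in self.missing.items():
            unknown = set(tps) - set(TIMEPOINT_LABELS)
            if unknown:
                raise ValueError(f"unknown missing time points {unknown} for group {grp}")


def generate_cohort(params: CohortGenParams) -> pd.DataFrame:
    """Draw a tidy long cohort table (animal_id, group, timepoint, variable, value).

    Values are normal draws, truncated at zero for physiologically positive
    variables; rows for a group's missing time points are absent entirely.
    Deterministic under the seed.
    """
    rng = np.random.default_rng(params.seed)
    animals = [("S", f"S{i+1:02d}") for i in range(params.n_survivor)] + [
        ("NS", f"NS{i+1:02d}") for i in range(params.n_nonsurvivor)
    ]
    rows = []
    for (var, grp), row in params.cells.items():
        truncate = var in params.positive_variables
        group_animals = [a for g, a in animals if g == grp]
        absent = params.missing.get(grp, set())
        for tp in TIMEPOINT_LABELS:
            if tp not in row or tp in absent:
                continue
            mean, sd = row[tp]
            if sd == 0:
                vals = np.full(len(group_animals), float(mean))
            elif truncate:
                a = (0.0 - mean) / sd  # lower bound at zero, in sd units
                vals = sps.truncnorm.rvs(
                    a, np.inf, loc=mean, scale=sd, size=len(group_animals),
                    random_state=rng,
                )
            else:
                vals = rng.normal(mean, sd, size=len(group_animals))
            for animal, v in zip(group_animals, vals):
                rows.append((animal, grp, tp, var, float(v)))
    df = pd.DataFrame(rows, columns=["animal_id", "group", "timepoint", "variable", "value"])
    df["timepoint"] = pd.Categorical(df["timepoint"], categories=TIMEPOINT_LABELS, ordered=True)
    return df.sort_values(["variable", "group", "animal_id", "timepoint"]).reset_index(drop=True)
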