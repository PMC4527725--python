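"""Core containers: RR-interval series, ECG records, and the protocol time grid.

The experiment's clock is the recording clock: beat times are seconds from the
start of the ECG record, NN intervals are milliseconds.  A series with ``n + 1``
beat times carries ``n`` intervals; per-interval labels attribute each interval
to the beat that opens it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "NORMAL",
    "ECTOPIC",
    "EDITED",
    "RRISeries",
    "ECGRecord",
    "TimePoint",
    "TIMEPOINT_LABELS",
    "NS_MISSING_DEFAULT",
    "protocol_timepoints",
]

# interval labels
NORMAL = "normal"
ECTOPIC = "ectopic"
EDITED = "edited"

#: Protocol time points, in order: baseline; three points during the 15-min
#: hemorrhage; two during the untreated shock hour; four after fluid
#: resuscitation.  Non-survivors die around resuscitation, so their records
#: end at Shock60.
TIMEPOINT_LABELS: tuple[str, ...] = (
    "Baseline",
    "Hemorrhage5",
    "Hemorrhage10",
    "Hemorrhage15",
    "Shock30",
    "Shock60",
    "R0",
    "R60",
    "R120",
    "R180",
)

#: Time points absent for non-survivors by default (post-resuscitation).
NS_MISSING_DEFAULT: frozenset[str] = frozenset({"R0", "R60", "R120", "R180"})


@dataclass(frozen=True)
class TimePoint:
    """A named protocol time point with its offset into the recording."""

    label: str
    offset: float  # seconds from recording start

    def __post_init__(self) -> None:
        if self.label not in TIMEPOINT_LABELS:
            raise ValueError(
                f"unknown time point {self.label!r}; expected one of {TIMEPOINT_LABELS}"
            )
        if self.offset < 0:
            raise ValueError("time-point offset must be non-negative")


def protocol_timepoints(spacing_s: float = 300.0) -> list[TimePoint]:
    """Evenly spaced placement of the ten protocol time points.

    Real offsets depend on the individual experiment log; this helper gives a
    canonical layout (one 5-min analysis window per time point, back to back)
    used by the synthetic end-to-end examples.
    """
    return [TimePoint(lab, i * spacing_s) for i, lab in enumerate(TIMEPOINT_LABELS)]


@dataclass
class RRISeries:
    """A tachogram: beat times (s) with NN intervals (ms) and per-interval labels.

    Invariants: beat times strictly increasing; ``nn_ms[k]`` equals
    ``(beat_times[k+1] - beat_times[k]) * 1000``; all intervals positive.
    """

    beat_times: np.ndarray  # shape (n+1,), seconds
    nn_ms: np.ndarray  # shape (n,), milliseconds
    labels: np.ndarray = field(default=None)  # shape (n,), dtype object/str

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.nn_ms = np.asarray(self.nn_ms, dtype=float)
        if self.beat_times.ndim != 1 or self.nn_ms.ndim != 1:
            raise ValueError("beat_times and nn_ms must be 1-D")
        if len(self.beat_times) != len(self.nn_ms) + 1:
            raise ValueError("need exactly one more beat time than NN intervals")
        diffs = np.diff(self.beat_times)
        if len(diffs) and not np.all(diffs > 0):
            raise ValueError("beat times must be strictly increasing")
        if not np.allclose(diffs * 1000.0, self.nn_ms, rtol=0, atol=1e-6):
            raise ValueError("nn_ms inconsistent with successive beat-time differences")
        if np.any(self.nn_ms <= 0):
            raise ValueError("all NN intervals must be positive")
        if self.labels is None:
            self.labels = np.full(len(self.nn_ms), NORMAL, dtype=object)
        else:
            self.labels = np.asarray(self.labels, dtype=object)
            if len(self.labels) != len(self.nn_ms):
                raise ValueError("one label per NN interval required")

    # -- constructors ---------------------------------------------------
    @classmethod
    def from_beat_times(cls, beat_times, labels=None) -> "RRISeries":
        beat_times = np.asarray(beat_times, dtype=float)
        if len(beat_times) < 2:
            raise ValueError("need at least 2 beat times")
        return cls(beat_times, np.diff(beat_times) * 1000.0, labels)

    @classmethod
    def from_nn(cls, nn_ms, start_time: float = 0.0, labels=None) -> "RRISeries":
        nn_ms = np.asarray(nn_ms, dtype=float)
        beat_times = start_time + np.concatenate([[0.0], np.cumsum(nn_ms) / 1000.0])
        return cls(beat_times, nn_ms, labels)

    # -- views ----------------------------------------------------------
    @property
    def n_beats(self) -> int:
        return len(self.beat_times)

    @property
    def n_intervals(self) -> int:
        return len(self.nn_ms)

    @property
    def duration(self) -> float:
        """Span of the series in seconds."""
        return float(self.beat_times[-1] - self.beat_times[0])

    @property
    def onset_times(self) -> np.ndarray:
        """Time of the beat opening each interval (the tachogram abscissa)."""
        return self.beat_times[:-1]

    def copy(self) -> "RRISeries":
        return RRISeries(self.beat_times.copy(), self.nn_ms.copy(), self.labels.copy())


@dataclass
class ECGRecord:
    """A single-lead ECG trace with uniform sampling.

    ``true_beat_times`` is populated by the synthetic generator so detection
    can be scored against ground truth; it is ``None`` for real recordings.
    """

    sampling_rate: float  # Hz
    samples: np.ndarray
    start_time: float = 0.0
    true_beat_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or len(self.samples) < 2:
            raise ValueError("ECG record needs at least 2 samples")

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(len(self.samples)) / self.sampling_rate

    @property
    def duration(self) -> float:
        return (len(self.samples) - 1) / self.sampling_rate
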