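"""Shared data model and signal/interval primitives.

All times are in seconds. Intervals are half-open ``[start, end)``; frame
index ``i`` of a raster covers ``[i/rate, (i+1)/rate)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import signal as sps

from .errors import DegenerateInputError, InvalidParameterError

#: Labels a hypnogram may carry.
VIGILANCE_STATES = frozenset(
    {"active_wake", "quiet_wake", "wake", "NREM", "REM", "artifact"}
)
#: Labels of an anesthesia staging interval set.
DEPTH_STATES = frozenset({"moderate", "deep", "unclassified"})
#: Labels of a burst-suppression segmentation.
SEGMENTATION_STATES = frozenset({"burst", "suppression"})

HYPNOGRAM_EPOCH_S = 5.0


@dataclass
class SignalTrace:
    """A uniformly sampled continuous recording (LFP, EEG or EMG).

    Parameters
    ----------
    samples
        The voltage (or z-scored) samples.
    rate
        Sampling rate in Hz, strictly positive.
    start_time
        Absolute time of the first sample, seconds.
    label
        Free-text channel name.
    units
        ``"mV"`` for raw voltage, ``"z"`` after standardization.
    """

    samples: np.ndarray
    rate: float
    start_time: float = 0.0
    label: str = ""
    units: str = "mV"

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise InvalidParameterError("trace must be a non-empty 1-D sequence")
        if not np.all(np.isfinite(self.samples)):
            raise InvalidParameterError("trace samples must all be finite")
        if not self.rate > 0:
            raise InvalidParameterError(f"rate must be > 0, got {self.rate}")
        if self.units not in ("mV", "z"):
            raise InvalidParameterError(f"units must be 'mV' or 'z', got {self.units!r}")

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) / self.rate


@dataclass
class IntervalSet:
    """Sorted, non-overlapping, half-open labeled intervals.

    Used for hypnograms, burst/suppression segmentations and anesthesia
    staging alike; the admissible label vocabulary is declared per use.
    """

    intervals: list[tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self):
        ivs = [(float(s), float(e), str(l)) for s, e, l in self.intervals]
        for s, e, l in ivs:
            if not s < e:
                raise InvalidParameterError(f"interval start {s} must precede end {e}")
        ivs.sort(key=lambda t: t[0])
        for (_, e0, _), (s1, _, _) in zip(ivs, ivs[1:]):
            if s1 < e0 - 1e-12:
                raise InvalidParameterError("intervals must not overlap")
        self.intervals = ivs

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self.intervals == other.intervals

    @property
    def labels(self) -> set[str]:
        return {l for _, _, l in self.intervals}

    @property
    def span(self) -> tuple[float, float]:
        if not self.intervals:
            return (0.0, 0.0)
        return (self.intervals[0][0], self.intervals[-1][1])

    def duration(self, label: str | None = None) -> float:
        """Total covered time, optionally restricted to one label."""
        return sum(e - s for s, e, l in self.intervals if label is None or l == label)

    def select(self, label: str) -> "IntervalSet":
        return IntervalSet([(s, e, l) for s, e, l in self.intervals if l == label])

    def label_at(self, t: float) -> str | None:
        """Label covering time ``t`` or None if uncovered (half-open lookup)."""
        for s, e, l in self.intervals:
            if s <= t < e:
                return l
        return None

    def overlap(self, start: float, end: float, label: str | None = None) -> float:
        """Covered time within ``[start, end)``, optionally for one label."""
        total = 0.0
        for s, e, l in self.intervals:
            if label is not None and l != label:
                continue
            total += max(0.0, min(e, end) - max(s, start))
        return total

    def merged(self) -> "IntervalSet":
        """Coalesce touching intervals of equal label."""
        out: list[tuple[float, float, str]] = []
        for s, e, l in self.intervals:
            if out and out[-1][2] == l and abs(out[-1][1] - s) < 1e-9:
                out[-1] = (out[-1][0], e, l)
            else:
                out.append((s, e, l))
        return IntervalSet(out)


@dataclass
class SpikeTrain:
    """Per-unit spike times with sorter quality metrics."""

    unit_id: str
    times: np.ndarray
    isi_violation_frac: float | None = None
    isolation_distance: float | None = None
    unit_class: str | None = None  # "RS" | "FS" | None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise InvalidParameterError("spike times must be 1-D")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise InvalidParameterError(f"unit {self.unit_id}: spike times must be strictly ascending")
        if self.isi_violation_frac is not None and not 0 <= self.isi_violation_frac <= 1:
            raise InvalidParameterError("isi_violation_frac must lie in [0, 1]")
        if self.isolation_distance is not None and self.isolation_distance < 0:
            raise InvalidParameterError("isolation_distance must be >= 0")
        if self.unit_class not in (None, "RS", "FS"):
            raise InvalidParameterError(f"unit_class must be RS or FS, got {self.unit_class!r}")

    @property
    def n_spikes(self) -> int:
        return self.times.size


@dataclass
class EventRaster:
    """Cells x frames matrix of nonnegative inferred calcium event amplitudes."""

    events: np.ndarray
    frame_rate: float = 10.0
    cell_ids: list[str] | None = None

    def __post_init__(self):
        self.events = np.asarray(self.events, dtype=float)
        if self.events.ndim != 2:
            raise InvalidParameterError("events must be a cells x frames matrix")
        if not np.all(np.isfinite(self.events)) or np.any(self.events < 0):
            raise InvalidParameterError("event amplitudes must be finite and >= 0")
        if not self.frame_rate > 0:
            raise InvalidParameterError("frame_rate must be > 0")
        if self.cell_ids is None:
            self.cell_ids = [f"cell{i}" for i in range(self.events.shape[0])]
        elif len(self.cell_ids) != self.events.shape[0]:
            raise InvalidParameterError("cell_ids length must match number of rows")

    @property
    def n_cells(self) -> int:
        return self.events.shape[0]

    @property
    def n_frames(self) -> int:
        return self.events.shape[1]

    @property
    def duration(self) -> float:
        return self.n_frames / self.frame_rate


def preprocess_trace(
    trace: SignalTrace,
    band: tuple[float, float] | None = None,
    standardize: bool = False,
) -> SignalTrace:
    """Band-pass filter and/or z-score a trace.

    The band-pass is a zero-phase forward-backward 4th-order Butterworth,
    so event times are not phase-shifted. Standardization maps the trace to
    zero mean and unit SD and relabels units to ``"z"``.
    """
    x = trace.samples
    if band is not None:
        if x.size < 2:
            raise InvalidParameterError("band-pass needs at least 2 samples")
        lo, hi = band
        if not 0 < lo < hi < trace.rate / 2:
            raise InvalidParameterError(
                f"band ({lo}, {hi}) must satisfy 0 < lo < hi < Nyquist ({trace.rate / 2})"
            )
        sos = sps.butter(4, [lo, hi], btype="bandpass", fs=trace.rate, output="sos")
        x = sps.sosfiltfilt(sos, x)
    units = trace.units
    if standardize:
        sd = float(np.std(x))
        if sd == 0:
            raise DegenerateInputError("cannot standardize a zero-variance trace")
        x = (x - np.mean(x)) / sd
        units = "z"
    return replace(trace, samples=np.asarray(x), units=units)


def extract_state_bouts(
    hypnogram: IntervalSet,
    state: str,
    min_dur_s: float = 300.0,
    max_interrupt_s: float = 30.0,
    vocabulary: Iterable[str] | None = None,
) -> IntervalSet:
    """Extended bouts of one vigilance state.

    A bout is a maximal run of ``state`` in which every contiguous
    interruption by other states is shorter than ``max_interrupt_s``; bouts
    spanning less than ``min_dur_s`` in total are discarded. Defaults match
    the >= 5 min / < 30 s interruption convention used when pairing imaging
    with sleep scoring.
    """
    vocab = set(vocabulary) if vocabulary is not None else set(VIGILANCE_STATES) | hypnogram.labels
    if state not in vocab:
        raise InvalidParameterError(f"unknown state label {state!r}")
    if len(hypnogram) == 0:
        return IntervalSet([])

    target = hypnogram.select(state).merged()
    if len(target) == 0:
        return IntervalSet([])

    runs: list[tuple[float, float]] = []
    cur_s, cur_e, _ = target.intervals[0]
    for s, e, _ in target.intervals[1:]:
        gap = s - cur_e  # contiguous non-target time of any other label
        if gap < max_interrupt_s:
            cur_e = e
        else:
            runs.append((cur_s, cur_e))
            cur_s, cur_e = s, e
    runs.append((cur_s, cur_e))

    bouts = [(s, e, state) for s, e in runs if e - s >= min_dur_s]
    return IntervalSet(bouts)
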