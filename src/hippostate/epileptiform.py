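"""High-voltage epileptiform event detection in LFP.

An event is a deflection whose z-scored amplitude (mean/SD taken over the
whole recording) crosses +-10, confirmed by a peak-to-peak excursion
greater than 10 z within a 30-ms window centered on the crossing. A 50-ms
dead time after each accepted event prevents double counting. Detection is
invariant to positive rescaling of the trace by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .core import IntervalSet, SignalTrace
from .errors import DegenerateInputError, InsufficientDataError

THRESHOLD_Z = 10.0
PTP_WINDOW_S = 0.030
DEAD_TIME_S = 0.050


@dataclass
class EpiEvents:
    """Detected epileptiform events."""

    times: np.ndarray  # seconds, at each event's extremum
    ptp_z: np.ndarray  # peak-to-peak amplitude in z units
    dead_time_s: float = DEAD_TIME_S

    def __post_init__(self):
        self.times = np.asarray(self.times, float)
        self.ptp_z = np.asarray(self.ptp_z, float)
        if self.times.size > 1:
            iei = np.diff(self.times)
            assert np.all(iei >= self.dead_time_s - 1e-9), "events closer than the dead time"

    @property
    def n_events(self) -> int:
        return self.times.size

    def rate_per_min(self, epochs: IntervalSet, label: str | None = None) -> float:
        """Events per minute within the given (optionally label-filtered) epochs."""
        total_s = epochs.duration(label)
        if total_s <= 0:
            raise InsufficientDataError("epochs have zero total duration")
        n = sum(
            1
            for t in self.times
            for s, e, l in epochs
            if (label is None or l == label) and s <= t < e
        )
        return 60.0 * n / total_s


class EpileptiformDetector(BaseEstimator):
    """Threshold / peak-to-peak / dead-time detector of pathological spikes.

    Parameters follow the published rule: 10-z bipolar threshold over the
    whole-recording z-score, >10-z peak-to-peak within 30 ms, 50-ms dead
    time anchored at the accepted extremum. ``min_ptp_z`` optionally raises
    the peak-to-peak bar (stands in for manual post-inspection).
    """

    def __init__(
        self,
        threshold_z: float = THRESHOLD_Z,
        ptp_window_s: float = PTP_WINDOW_S,
        dead_time_s: float = DEAD_TIME_S,
        min_ptp_z: float | None = None,
    ):
        self.threshold_z = threshold_z
        self.ptp_window_s = ptp_window_s
        self.dead_time_s = dead_time_s
        self.min_ptp_z = min_ptp_z

    def fit(self, X: SignalTrace, y=None) -> "EpileptiformDetector":
        trace = X
        if trace.duration < 1.0:
            raise InsufficientDataError("detection needs at least 1 s of signal")
        sd = float(np.std(trace.samples))
        if sd == 0:
            raise DegenerateInputError("zero-variance trace")
        z = (trace.samples - np.mean(trace.samples)) / sd

        half = max(1, int(round(self.ptp_window_s / 2 * trace.rate)))
        dead = int(round(self.dead_time_s * trace.rate))
        ptp_bar = self.min_ptp_z if self.min_ptp_z is not None else self.threshold_z

        cand = np.flatnonzero(np.abs(z) > self.threshold_z)
        times: list[float] = []
        ptps: list[float] = []
        last_idx = -np.inf
        for i in cand:
            if i - last_idx < dead:
                continue
            lo, hi = max(0, i - half), min(z.size, i + half + 1)
            w = z[lo:hi]
            ptp = float(w.max() - w.min())
            if ptp > ptp_bar:
                peak = lo + int(np.argmax(np.abs(w)))
                if times and (peak - last_idx) < dead:
                    continue
                times.append(trace.start_time + peak / trace.rate)
                ptps.append(ptp)
                last_idx = peak

        self.events_ = EpiEvents(
            times=np.array(times), ptp_z=np.array(ptps), dead_time_s=self.dead_time_s
        )
        return self

    def fit_predict(self, X: SignalTrace, y=None) -> EpiEvents:
        return self.fit(X).events_


def detect_epileptiform(
    trace: SignalTrace,
    threshold_z: float = THRESHOLD_Z,
    ptp_window_s: float = PTP_WINDOW_S,
    dead_time_s: float = DEAD_TIME_S,
) -> EpiEvents:
    """Detect epileptiform events; see :class:`EpileptiformDetector`."""
    return EpileptiformDetector(
        threshold_z=threshold_z, ptp_window_s=ptp_window_s, dead_time_s=dead_time_s
    ).fit_predict(trace)
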