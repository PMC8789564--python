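"""Single-unit statistics: QC, state-wise firing rates, gain factors, and
MEA baseline normalization.

The central statistic is the gain factor

    %Gain(a, b) = 100 * (a - b) / max(|a|, |b|)

with ``a`` the mean firing rate (MFR) in NREM sleep and ``b`` the MFR in
active wakefulness: negative gains mean the unit fires less in NREM. Units
are split at the median wake MFR and each subgroup is summarized by the
median gain with a bootstrap percentile 95% CI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import IntervalSet, SignalTrace, SpikeTrain
from .errors import (
    DegenerateInputError,
    EmptyResultError,
    InsufficientDataError,
    InvalidParameterError,
    MissingMetricError,
    UndefinedGainError,
)

ISI_VIOLATION_MAX = 0.005     # < 0.5% of ISIs below 2 ms
ISOLATION_DISTANCE_MIN = 10.0
WAKE_MFR_MIN_HZ = 0.05
STABILITY_DEVIATION_MAX = 0.30


@dataclass
class GainSummary:
    """Per-unit gains plus median-split subgroup summaries."""

    table: pd.DataFrame  # unit_id, mfr_aw, mfr_nrem, gain_pct, subgroup
    split_value: float   # median wake MFR, Hz
    subgroup_stats: dict  # subgroup -> {median, ci_low, ci_high, n}


@dataclass
class MeaNormalization:
    """Per-channel MFR series rescaled to percent of baseline."""

    normalized: pd.DataFrame          # channels x hours, % of baseline
    excluded_channels: dict[str, str]  # channel -> reason
    baseline_window: tuple[int, int]   # hour indices, half-open


def state_mfr(train: SpikeTrain, bouts: IntervalSet) -> float:
    """Mean firing rate within a set of bouts; spikes outside are ignored."""
    total = bouts.duration()
    if total <= 0:
        raise InsufficientDataError("bouts have zero total duration")
    t = train.times
    n = 0
    for s, e, _ in bouts:
        n += int(np.searchsorted(t, e, "left") - np.searchsorted(t, s, "left"))
    return n / total


def qc_units(
    trains: list[SpikeTrain],
    wake_bouts: IntervalSet,
    isi_violation_max: float = ISI_VIOLATION_MAX,
    isolation_distance_min: float = ISOLATION_DISTANCE_MIN,
    wake_mfr_min_hz: float = WAKE_MFR_MIN_HZ,
    stability_deviation_max: float = STABILITY_DEVIATION_MAX,
) -> tuple[list[str], dict[str, list[str]]]:
    """Apply the four single-unit inclusion criteria.

    A unit passes iff (1) its ISI-violation fraction is < 0.5%, (2) its
    isolation distance is > 10, (3) its MFR in active wakefulness is
    > 0.05 Hz, and (4) its firing rate is stable: the recording is split
    into three equal spans and no span's MFR may deviate more than 30% from
    the unit's overall MFR.

    Returns the included unit ids and a dict of exclusion reasons listing
    every failed criterion per excluded unit.
    """
    if wake_bouts.duration() <= 0:
        raise InvalidParameterError("wake_bouts must be nonempty")
    included: list[str] = []
    reasons: dict[str, list[str]] = {}
    rec_end = max(
        [wake_bouts.span[1]] + [t.times[-1] for t in trains if t.n_spikes]
    )
    for train in trains:
        if train.isi_violation_frac is None or train.isolation_distance is None:
            raise MissingMetricError(
                f"unit {train.unit_id}: missing quality metrics"
            )
        fails: list[str] = []
        if not train.isi_violation_frac < isi_violation_max:
            fails.append("refractory")
        if not train.isolation_distance > isolation_distance_min:
            fails.append("isolation_distance")
        if not state_mfr(train, wake_bouts) > wake_mfr_min_hz:
            fails.append("wake_mfr")
        overall = train.n_spikes / rec_end if rec_end > 0 else 0.0
        if overall > 0:
            edges = np.linspace(0.0, rec_end, 4)
            span_mfr = np.histogram(train.times, bins=edges)[0] / np.diff(edges)
            if np.any(np.abs(span_mfr - overall) / overall > stability_deviation_max):
                fails.append("stability")
        else:
            fails.append("stability")
        if fails:
            reasons[train.unit_id] = fails
        else:
            included.append(train.unit_id)
    return included, reasons


def gain_factor(a: float, b: float) -> float:
    """Normalized rate change, (a - b) / max(|a|, |b|) * 100, in percent."""
    if a == 0 and b == 0:
        raise UndefinedGainError("gain undefined for a = b = 0")
    return (a - b) / max(abs(a), abs(b)) * 100.0


def _bootstrap_median_ci(
    x: np.ndarray, n_boot: int = 10_000, alpha: float = 0.05, seed: int = 0
) -> tuple[float, float]:
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, x.size, size=(n_boot, x.size))
    meds = np.median(x[idx], axis=1)
    lo, hi = np.quantile(meds, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def summarize_gains(
    mfr_table: pd.DataFrame,
    n_boot: int = 10_000,
    seed: int = 0,
) -> GainSummary:
    """Median-split gain summary.

    ``mfr_table`` needs columns ``unit_id``, ``mfr_aw``, ``mfr_nrem``.
    Units are split at the median wake MFR; ties go to ``below_median``.
    Each subgroup is summarized by the median gain and a seeded bootstrap
    percentile 95% CI.
    """
    df = mfr_table.copy()
    required = {"unit_id", "mfr_aw", "mfr_nrem"}
    if not required <= set(df.columns):
        raise InvalidParameterError(f"mfr_table needs columns {sorted(required)}")
    if len(df) < 4:
        raise InsufficientDataError("median split needs at least 4 units")
    df["gain_pct"] = [
        gain_factor(a, b) for a, b in zip(df["mfr_nrem"], df["mfr_aw"])
    ]
    split = float(np.median(df["mfr_aw"]))
    df["subgroup"] = np.where(df["mfr_aw"] <= split, "below_median", "above_median")

    stats: dict[str, dict] = {}
    for i, (name, grp) in enumerate(sorted(df.groupby("subgroup"))):
        g = grp["gain_pct"].to_numpy()
        if g.size < 2:
            raise InsufficientDataError(f"subgroup {name} has fewer than 2 units")
        lo, hi = _bootstrap_median_ci(g, n_boot=n_boot, seed=seed + i)
        stats[name] = {
            "median": float(np.median(g)), "ci_low": lo, "ci_high": hi, "n": int(g.size)
        }
    return GainSummary(table=df, split_value=split, subgroup_stats=stats)


def normalize_to_baseline(
    channel_rates: pd.DataFrame,
    baseline_window: tuple[int, int],
    instability_max: float = 0.30,
) -> MeaNormalization:
    """Rescale each channel's hourly MFR series to percent of baseline.

    ``channel_rates`` is channels (rows, indexed by id) x hours (columns).
    A channel is excluded when any baseline point deviates more than 30%
    from that channel's baseline mean; included channels are rescaled so
    their baseline mean is exactly 100%.
    """
    b0, b1 = baseline_window
    n_hours = channel_rates.shape[1]
    if not (0 <= b0 < b1 <= n_hours):
        raise InvalidParameterError("baseline window must lie within the series")
    if b1 - b0 < 2:
        raise InvalidParameterError("baseline needs at least 2 points")

    excluded: dict[str, str] = {}
    rows = {}
    for ch, row in channel_rates.iterrows():
        base = row.iloc[b0:b1].to_numpy(float)
        mean = base.mean()
        if mean <= 0:
            excluded[str(ch)] = "silent_baseline"
            continue
        if np.any(np.abs(base - mean) / mean > instability_max):
            excluded[str(ch)] = "unstable_baseline"
            continue
        rows[ch] = row.to_numpy(float) / mean * 100.0
    if not rows:
        raise EmptyResultError("all channels excluded")
    normalized = pd.DataFrame.from_dict(rows, orient="index", columns=channel_rates.columns)
    return MeaNormalization(
        normalized=normalized, excluded_channels=excluded, baseline_window=(b0, b1)
    )


def detect_threshold_spikes(
    trace: SignalTrace, k_sd: float = 5.5, dead_time_s: float = 0.001
) -> np.ndarray:
    """Negative-going threshold crossings at mean - k_sd * SD (MEA-style).

    Expects a high-pass filtered trace (>= 200 Hz). Returns ascending spike
    times with a 1-ms dead time.
    """
    x = trace.samples
    sd = float(np.std(x))
    if sd == 0:
        raise DegenerateInputError("zero-variance trace")
    thr = float(np.mean(x)) - k_sd * sd
    below = x < thr
    crossings = np.flatnonzero(below & ~np.roll(below, 1))
    if below[0]:
        crossings = np.unique(np.concatenate([[0], crossings]))
    dead = max(1, int(round(dead_time_s * trace.rate)))
    keep: list[int] = []
    last = -dead
    for i in crossings:
        if i - last >= dead:
            keep.append(i)
            last = i
    return trace.start_time + np.asarray(keep, float) / trace.rate
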