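"""Burst-suppression segmentation and anesthetic-depth staging from LFP.

Deep (burst-suppression) anesthesia alternates high-voltage broadband
bursts with near-isoelectric suppressions. The record is cut into 500-ms
bins, each described by three features (max |v|, SD, first principal
component of its 1-100 Hz spectrum), all of which are bimodally lognormal
across the two regimes; a two-component Gaussian mixture on the transformed
features assigns each bin to burst or suppression. Burst runs separated by
< 2 s are merged and merged bursts lasting <= 2 s are rejected. The
burst-suppression ratio (BSR) is the per-coarse-bin fraction of time in
suppression; together with relative delta power it drives the
moderate/deep staging rules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from sklearn.base import BaseEstimator
from sklearn.decomposition import PCA
from sklearn.mixture import GaussianMixture

from .core import IntervalSet, SignalTrace
from .errors import InsufficientDataError, InvalidParameterError

BIN_DURATION_S = 0.5
COARSE_BIN_S = 52.428  # ~1 min (2**19 samples at 10 kHz)


@dataclass
class BinFeatures:
    """Per-500-ms-bin feature triples of an LFP record."""

    max_abs: np.ndarray
    sd: np.ndarray
    spec_pc1: np.ndarray
    bin_duration_s: float = BIN_DURATION_S
    start_time: float = 0.0

    def __post_init__(self):
        if not (len(self.max_abs) == len(self.sd) == len(self.spec_pc1)):
            raise InvalidParameterError("feature series must have equal length")

    @property
    def n_bins(self) -> int:
        return len(self.max_abs)

    def matrix(self) -> np.ndarray:
        return np.column_stack([self.max_abs, self.sd, self.spec_pc1])


@dataclass
class DepthSeries:
    """Coarse-bin BSR and relative delta power series."""

    bsr: np.ndarray
    rel_delta: np.ndarray
    coarse_bin_s: float = COARSE_BIN_S
    start_time: float = 0.0

    def __post_init__(self):
        self.bsr = np.asarray(self.bsr, float)
        self.rel_delta = np.asarray(self.rel_delta, float)
        if self.bsr.shape != self.rel_delta.shape:
            raise InvalidParameterError("bsr and rel_delta must have equal length")
        for name, v in (("bsr", self.bsr), ("rel_delta", self.rel_delta)):
            if v.size and (np.nanmin(v) < -1e-9 or np.nanmax(v) > 1 + 1e-9):
                raise InvalidParameterError(f"{name} values must lie in [0, 1]")


def compute_bin_features(trace: SignalTrace, bin_duration_s: float = BIN_DURATION_S) -> BinFeatures:
    """Cut the trace into 500-ms bins and extract the three features.

    ``spec_pc1`` is each bin's score on the first principal axis of the
    per-bin 1-100 Hz power spectra. The trailing partial bin is dropped.
    """
    if trace.rate < 250:
        raise InvalidParameterError("bin features need a sampling rate >= 250 Hz")
    if trace.duration < 1.0:
        raise InsufficientDataError("record must be at least 1 s long")
    nper = int(round(bin_duration_s * trace.rate))
    n_bins = trace.samples.size // nper
    if n_bins < 2:
        raise InsufficientDataError("record shorter than 2 bins")
    x = trace.samples[: n_bins * nper].reshape(n_bins, nper)

    max_abs = np.max(np.abs(x), axis=1)
    sd = np.std(x, axis=1)

    freqs, psd = sps.periodogram(x, fs=trace.rate, axis=1)
    band = (freqs >= 1.0) & (freqs <= 100.0)
    spectra = psd[:, band]
    if np.allclose(spectra, spectra[0]):
        pc1 = np.zeros(n_bins)
    else:
        # project all bins onto the first principal axis of their spectra
        pc1 = PCA(n_components=1, svd_solver="full").fit_transform(spectra)[:, 0]
        # orient so that high-power bins score positive (sign of PCA is arbitrary)
        power = spectra.sum(axis=1)
        if power.std() > 0 and np.corrcoef(pc1, power)[0, 1] < 0:
            pc1 = -pc1
    return BinFeatures(
        max_abs=max_abs, sd=sd, spec_pc1=pc1,
        bin_duration_s=bin_duration_s, start_time=trace.start_time,
    )


class BurstSuppressionClassifier(BaseEstimator):
    """Two-component Gaussian-mixture classifier of 500-ms LFP bins.

    Strictly positive features (max |v|, SD) are logged — the two regimes
    are lognormal in them — while the spectral PC score, which may be
    negative, is standardized. A single joint full-covariance mixture is
    fit on the 3-vectors; the component with the larger mean log-SD is
    burst. Initialization is a deterministic median split on log SD, so no
    random seed is involved.

    Attributes
    ----------
    mixture_ : fitted ``GaussianMixture``
    burst_component_ : int
        Index of the mixture component labeled burst.
    labels_ : ndarray of str
        Per-bin ``"burst"`` / ``"suppression"`` labels of the training bins.
    """

    def __init__(self, eps_scale: float = 1e-12):
        self.eps_scale = eps_scale

    def _transform(self, F: np.ndarray) -> np.ndarray:
        eps = self.eps_scale * max(float(np.max(F[:, 1])), 1.0)
        X = np.column_stack(
            [np.log(F[:, 0] + eps), np.log(F[:, 1] + eps), F[:, 2]]
        )
        sd = X[:, 2].std()
        X[:, 2] = (X[:, 2] - X[:, 2].mean()) / (sd if sd > 0 else 1.0)
        return X

    def fit(self, X: BinFeatures | np.ndarray, y=None) -> "BurstSuppressionClassifier":
        F = X.matrix() if isinstance(X, BinFeatures) else np.asarray(X, float)
        if F.shape[0] < 20:
            raise InsufficientDataError("mixture fit needs at least 20 bins")
        Z = self._transform(F)
        self.degenerate_ = bool(np.allclose(Z, Z[0]))
        if self.degenerate_:
            warnings.warn(
                "all feature vectors identical: no mixture exists, labeling all bins burst"
            )
            self.labels_ = np.full(F.shape[0], "burst", dtype=object)
            return self

        log_sd = Z[:, 1]
        hi = log_sd > np.median(log_sd)
        if hi.all() or (~hi).all():  # pragma: no cover - median split always bisects
            hi = log_sd >= log_sd.mean()
        means = np.vstack([Z[~hi].mean(axis=0), Z[hi].mean(axis=0)])
        precisions = np.stack(
            [
                np.linalg.inv(np.cov(Z[g].T) + 1e-6 * np.eye(3))
                for g in (~hi, hi)
            ]
        )
        gm = GaussianMixture(
            n_components=2,
            covariance_type="full",
            weights_init=np.array([(~hi).mean(), hi.mean()]),
            means_init=means,
            precisions_init=precisions,
            random_state=0,
        )
        gm.fit(Z)
        self.mixture_ = gm
        self.burst_component_ = int(np.argmax(gm.means_[:, 1]))  # larger mean log-SD
        self.labels_ = self._predict_transformed(Z)
        return self

    def _predict_transformed(self, Z: np.ndarray) -> np.ndarray:
        comp = self.mixture_.predict(Z)
        return np.where(comp == self.burst_component_, "burst", "suppression").astype(object)

    def fit_predict(self, X: BinFeatures | np.ndarray, y=None) -> np.ndarray:
        return self.fit(X).labels_


def classify_bins(features: BinFeatures) -> np.ndarray:
    """Label each 500-ms bin ``"burst"`` or ``"suppression"``."""
    return BurstSuppressionClassifier().fit_predict(features)


def segment_bursts(
    labels: np.ndarray,
    bin_duration_s: float = BIN_DURATION_S,
    start_time: float = 0.0,
    merge_gap_s: float = 2.0,
    min_burst_s: float = 2.0,
) -> IntervalSet:
    """Turn per-bin labels into a burst/suppression partition of the record.

    Burst runs separated by less than ``merge_gap_s`` of suppression are
    merged first; merged bursts of duration <= ``min_burst_s`` are then
    relabeled suppression.
    """
    labels = np.asarray(labels, dtype=object)
    if labels.size == 0:
        raise InvalidParameterError("labels must be nonempty")
    bad = set(labels) - {"burst", "suppression"}
    if bad:
        raise InvalidParameterError(f"unknown labels {bad}")

    is_burst = labels == "burst"
    # run-length encode
    runs: list[tuple[int, int, bool]] = []  # (start_bin, end_bin, is_burst)
    start = 0
    for i in range(1, labels.size + 1):
        if i == labels.size or is_burst[i] != is_burst[start]:
            runs.append((start, i, bool(is_burst[start])))
            start = i

    # merge bursts across short suppression gaps
    merged: list[tuple[int, int, bool]] = []
    for run in runs:
        if (
            run[2]
            and len(merged) >= 2
            and merged[-1][2] is False
            and merged[-2][2] is True
            and (merged[-1][1] - merged[-1][0]) * bin_duration_s < merge_gap_s
        ):
            gap = merged.pop()
            prev = merged.pop()
            merged.append((prev[0], run[1], True))
        else:
            merged.append(run)

    # reject short bursts
    final: list[tuple[int, int, bool]] = []
    for s, e, b in merged:
        if b and (e - s) * bin_duration_s <= min_burst_s:
            b = False
        if final and final[-1][2] == b:
            final[-1] = (final[-1][0], e, b)
        else:
            final.append((s, e, b))

    return IntervalSet(
        [
            (start_time + s * bin_duration_s, start_time + e * bin_duration_s,
             "burst" if b else "suppression")
            for s, e, b in final
        ]
    )


def _band_power(x: np.ndarray, rate: float, lo: float, hi: float) -> float:
    nper = min(int(rate), x.size)
    freqs, psd = sps.welch(x, fs=rate, nperseg=nper, noverlap=nper // 2)
    band = (freqs >= lo) & (freqs <= hi)
    return float(np.trapezoid(psd[band], freqs[band]))


def depth_metrics(
    trace: SignalTrace,
    seg: IntervalSet,
    coarse_bin_s: float = COARSE_BIN_S,
) -> DepthSeries:
    """Per-coarse-bin BSR and relative delta power.

    BSR is the suppression-time fraction of each ~1-min bin. Relative delta
    power is (1-4 Hz PSD)/(1-100 Hz PSD) per bin (averaged periodogram,
    1-s segments, 50% overlap), then z-scored across bins and min-max
    mapped to [0, 1]. The trailing partial coarse bin is dropped.
    """
    n_bins = int(trace.duration // coarse_bin_s)
    if n_bins < 1:
        raise InsufficientDataError(
            f"record ({trace.duration:.1f} s) shorter than one {coarse_bin_s} s bin"
        )
    nper = int(round(coarse_bin_s * trace.rate))
    bsr = np.empty(n_bins)
    ratio = np.empty(n_bins)
    for i in range(n_bins):
        t0 = trace.start_time + i * coarse_bin_s
        bsr[i] = seg.overlap(t0, t0 + coarse_bin_s, "suppression") / coarse_bin_s
        x = trace.samples[i * nper : (i + 1) * nper]
        broad = _band_power(x, trace.rate, 1.0, 100.0)
        ratio[i] = _band_power(x, trace.rate, 1.0, 4.0) / broad if broad > 0 else 0.0

    sd = ratio.std()
    z = (ratio - ratio.mean()) / sd if sd > 0 else np.zeros_like(ratio)
    rng = z.max() - z.min()
    rel_delta = (z - z.min()) / rng if rng > 0 else np.full_like(z, 0.5)
    return DepthSeries(
        bsr=np.clip(bsr, 0.0, 1.0), rel_delta=rel_delta,
        coarse_bin_s=coarse_bin_s, start_time=trace.start_time,
    )


def stage_anesthesia(
    depth: DepthSeries,
    merge_gap_s: float = 60.0,
    min_epoch_s: float = 60.0,
) -> IntervalSet:
    """Stage each coarse bin moderate/deep/unclassified and build epochs.

    Per-bin rules use strict inequalities exactly as stated: deep iff
    0.3 < BSR < 0.8; moderate iff BSR < 0.3 and relative delta power > 0.5.
    Per label, epochs separated by gaps < 60 s are merged, then epochs of
    duration <= 60 s are dropped; where a merged deep epoch overlaps a
    merged moderate epoch, deep takes precedence. Remaining time is
    unclassified.
    """
    if depth.bsr.size == 0:
        raise InvalidParameterError("depth series is empty")
    dt = depth.coarse_bin_s
    t0 = depth.start_time
    per_bin = np.full(depth.bsr.size, "unclassified", dtype=object)
    per_bin[(depth.bsr > 0.3) & (depth.bsr < 0.8)] = "deep"
    per_bin[(depth.bsr < 0.3) & (depth.rel_delta > 0.5)] = "moderate"

    def epochs_of(label: str) -> list[tuple[float, float]]:
        idx = np.flatnonzero(per_bin == label)
        if idx.size == 0:
            return []
        out: list[tuple[float, float]] = []
        s = idx[0]
        prev = idx[0]
        for i in idx[1:]:
            if (i - prev - 1) * dt < merge_gap_s:
                prev = i
            else:
                out.append((t0 + s * dt, t0 + (prev + 1) * dt))
                s = prev = i
        out.append((t0 + s * dt, t0 + (prev + 1) * dt))
        return [(a, b) for a, b in out if b - a > min_epoch_s]

    deep = epochs_of("deep")
    moderate = epochs_of("moderate")

    intervals: list[tuple[float, float, str]] = [(a, b, "deep") for a, b in deep]
    for a, b in moderate:  # clip moderate epochs around any overlapping deep epoch
        pieces = [(a, b)]
        for da, db, _ in intervals:
            pieces = [
                seg
                for pa, pb in pieces
                for seg in ((pa, min(pb, da)), (max(pa, db), pb))
                if seg[1] - seg[0] > 1e-9
            ]
        intervals.extend((pa, pb, "moderate") for pa, pb in pieces)

    intervals.sort()
    # fill the rest of the record as unclassified
    out: list[tuple[float, float, str]] = []
    cursor = t0
    end_rec = t0 + depth.bsr.size * dt
    for a, b, l in intervals:
        if a > cursor + 1e-9:
            out.append((cursor, a, "unclassified"))
        out.append((a, b, l))
        cursor = b
    if end_rec > cursor + 1e-9:
        out.append((cursor, end_rec, "unclassified"))
    return IntervalSet(out).merged()
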