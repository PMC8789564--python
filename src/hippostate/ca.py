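"""Post-deconvolution calcium raster analytics.

Works on inferred event rasters (cells x frames, 10 Hz by default) as
produced upstream by constrained NMF source extraction: ROI quality
filtering, per-cell mean calcium event rates (mCaR), population summaries
(number of active cells, median mCaR, total activity), per-100-ms relative
synchronization, and network-burst detection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage import measure
from sklearn.base import BaseEstimator

from .core import EventRaster
from .errors import (
    EmptyResultError,
    InsufficientDataError,
    InvalidParameterError,
)

PNR_MIN = 8.0
SIZE_PX_MIN = 30      # exclusive bounds: 30 < size < 300
SIZE_PX_MAX = 300
CIRCULARITY_MIN = 0.5
SYNC_BIN_S = 0.1
ANESTHESIA_SYNC_THRESHOLD = 0.05
EXPLORATION_PERCENTILE = 90.0


@dataclass
class RoiMetrics:
    """Quality metrics of one extracted ROI."""

    roi_id: str
    pnr: float
    size_px: float
    circularity: float

    def __post_init__(self):
        if min(self.pnr, self.size_px, self.circularity) < 0:
            raise InvalidParameterError(f"ROI {self.roi_id}: metrics must be >= 0")


@dataclass
class PopulationSummary:
    """Active-cell count, median mCaR and their product (total activity)."""

    n_active: int
    median_mcar: float
    total_activity: float


@dataclass
class NetworkBursts:
    """Synchronization vector and detected network bursts."""

    sync: np.ndarray                 # per-bin active-cell fraction in [0, 1]
    bin_s: float
    threshold: float
    peak_bins: np.ndarray            # int bin index of each burst peak
    extents: list[tuple[int, int]]   # half-open bin ranges
    cells_active: np.ndarray         # distinct active cells per burst
    event_sums: np.ndarray           # summed amplitudes (or event counts) per burst
    inter_burst_intervals: np.ndarray  # seconds between successive peaks
    subsample: np.ndarray            # seeded subsample of burst indices

    @property
    def n_bursts(self) -> int:
        return self.peak_bins.size


def circularity_from_mask(mask: np.ndarray) -> float:
    """Circularity 4*pi*A/P^2 of a binary ROI mask (1 = perfect circle)."""
    mask = np.asarray(mask, bool)
    area = float(mask.sum())
    if area == 0:
        raise InvalidParameterError("empty mask")
    perimeter = float(measure.perimeter(mask))
    if perimeter == 0:
        return 1.0
    return min(1.0, 4.0 * math.pi * area / perimeter**2)


def filter_rois(
    metrics: list[RoiMetrics],
    pnr_min: float = PNR_MIN,
    size_px_bounds: tuple[float, float] = (SIZE_PX_MIN, SIZE_PX_MAX),
    circularity_min: float = CIRCULARITY_MIN,
) -> tuple[list[str], dict[str, list[str]]]:
    """Keep ROIs with pnr >= 8, 30 < size < 300 px and circularity >= 0.5."""
    if not metrics:
        raise InvalidParameterError("metrics must be nonempty")
    lo, hi = size_px_bounds
    included: list[str] = []
    reasons: dict[str, list[str]] = {}
    for m in metrics:
        fails = []
        if not m.pnr >= pnr_min:
            fails.append("pnr")
        if not lo < m.size_px < hi:
            fails.append("size")
        if not m.circularity >= circularity_min:
            fails.append("circularity")
        if fails:
            reasons[m.roi_id] = fails
        else:
            included.append(m.roi_id)
    return included, reasons


def mcar(raster: EventRaster) -> np.ndarray:
    """Per-cell mean calcium event rate: summed amplitudes / duration (s)."""
    if raster.duration <= 0:
        raise InsufficientDataError("zero-duration raster")
    return raster.events.sum(axis=1) / raster.duration


def population_summary(
    rates: np.ndarray, active_threshold: float = 0.0
) -> PopulationSummary:
    """Nₐ (rates strictly above threshold), their median mCaR, and the product."""
    rates = np.asarray(rates, float)
    if rates.size < 1:
        raise InvalidParameterError("need at least one cell")
    active = rates[rates > active_threshold]
    if active.size == 0:
        raise EmptyResultError("no active cells above threshold")
    med = float(np.median(active))
    return PopulationSummary(
        n_active=int(active.size), median_mcar=med, total_activity=active.size * med
    )


def relative_change_pct(before: PopulationSummary, after: PopulationSummary) -> float:
    """Percent change of total activity between two summaries."""
    return 100.0 * (after.total_activity - before.total_activity) / before.total_activity


def relative_synchronization(raster: EventRaster, bin_s: float = SYNC_BIN_S) -> np.ndarray:
    """Fraction of detected cells with >= 1 event per time bin (default 100 ms)."""
    frames_per_bin = bin_s * raster.frame_rate
    if frames_per_bin < 1 - 1e-9:
        raise InvalidParameterError(
            f"bin ({bin_s} s) smaller than the frame interval ({1 / raster.frame_rate} s)"
        )
    if not math.isclose(frames_per_bin, round(frames_per_bin), abs_tol=1e-9):
        raise InvalidParameterError("bin must be a multiple of the frame interval")
    fpb = int(round(frames_per_bin))
    n_bins = raster.n_frames // fpb
    x = raster.events[:, : n_bins * fpb].reshape(raster.n_cells, n_bins, fpb)
    active = (x > 0).any(axis=2)
    return active.sum(axis=0) / raster.n_cells


class NetworkBurstDetector(BaseEstimator):
    """Detect network bursts as supra-threshold runs of the sync vector.

    In ``exploration`` mode the threshold is the 90th percentile of the
    session's own sync vector; in ``anesthesia`` mode it is the absolute
    value 0.05. Each contiguous supra-threshold run yields one burst whose
    peak is the (earliest) maximal bin; per burst the distinct active cells
    and the summed event amplitudes over the extent are reported, plus
    inter-peak intervals and a seeded subsample of bursts for pooling.
    """

    def __init__(
        self,
        mode: str = "exploration",
        subsample_k: int = 20,
        bin_s: float = SYNC_BIN_S,
        binary_counts: bool = False,
        seed: int = 0,
    ):
        self.mode = mode
        self.subsample_k = subsample_k
        self.bin_s = bin_s
        self.binary_counts = binary_counts
        self.seed = seed

    def fit(self, X: EventRaster, y=None) -> "NetworkBurstDetector":
        if self.mode not in ("exploration", "anesthesia"):
            raise InvalidParameterError(f"unknown mode {self.mode!r}")
        raster = X
        sync = relative_synchronization(raster, self.bin_s)
        thr = (
            ANESTHESIA_SYNC_THRESHOLD
            if self.mode == "anesthesia"
            else float(np.percentile(sync, EXPLORATION_PERCENTILE))
        )
        supra = sync > thr
        fpb = int(round(self.bin_s * raster.frame_rate))

        extents: list[tuple[int, int]] = []
        peaks: list[int] = []
        cells: list[int] = []
        sums: list[float] = []
        i = 0
        while i < sync.size:
            if supra[i]:
                j = i
                while j < sync.size and supra[j]:
                    j += 1
                extents.append((i, j))
                peaks.append(i + int(np.argmax(sync[i:j])))  # earliest max on ties
                seg = raster.events[:, i * fpb : j * fpb]
                cells.append(int(((seg > 0).any(axis=1)).sum()))
                sums.append(
                    float((seg > 0).sum()) if self.binary_counts else float(seg.sum())
                )
                i = j
            else:
                i += 1

        peak_arr = np.asarray(peaks, int)
        rng = np.random.default_rng(self.seed)
        k = min(self.subsample_k, peak_arr.size)
        subsample = np.sort(rng.choice(peak_arr.size, size=k, replace=False)) if k else np.array([], int)

        self.bursts_ = NetworkBursts(
            sync=sync,
            bin_s=self.bin_s,
            threshold=thr,
            peak_bins=peak_arr,
            extents=extents,
            cells_active=np.asarray(cells, int),
            event_sums=np.asarray(sums, float),
            inter_burst_intervals=np.diff(peak_arr) * self.bin_s,
            subsample=subsample,
        )
        return self

    def fit_predict(self, X: EventRaster, y=None) -> NetworkBursts:
        return self.fit(X).bursts_


def detect_network_bursts(
    raster: EventRaster,
    mode: str = "exploration",
    subsample_k: int = 20,
    seed: int = 0,
    **kwargs,
) -> NetworkBursts:
    """Detect network bursts; see :class:`NetworkBurstDetector`."""
    return NetworkBurstDetector(
        mode=mode, subsample_k=subsample_k, seed=seed, **kwargs
    ).fit_predict(raster)
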