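"""Population microstates: t-SNE/watershed clustering of co-activity patterns.

Frames with at least two co-active cells are collected, denoised by PCA
(components whose explained-variance share reaches the 30th percentile of
all shares are kept), embedded in 2-D by t-SNE (1000 iterations,
perplexity = floor(sqrt(N))), and converted into a density map smoothed by
a Gaussian kernel with sigma equal to 1/60 of the maximum embedded
coordinate. Watershed regions of the inverted density are the microstates.
A per-frame identity permutation (active-cell counts preserved, identities
shuffled) provides the randomization null, and affinity-propagation and
weighted-linkage hierarchical clusterings serve as validation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.cluster.hierarchy import fcluster, linkage
from skimage.feature import peak_local_max
from skimage.segmentation import watershed
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import AffinityPropagation
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .core import EventRaster
from .errors import (
    DegenerateInputError,
    EmptyResultError,
    InsufficientDataError,
    InvalidParameterError,
    NonConvergenceError,
)

MIN_COACTIVE = 2
TSNE_ITERATIONS = 1000
SHARE_PERCENTILE = 30.0
SIGMA_FRACTION = 1.0 / 60.0
GRID_SIZE = 256
GRID_MARGIN = 0.05
HCLUST_CUTOFF = 0.75


@dataclass
class FrameMatrix:
    """Active frames (rows) x cells, with indices into the source raster."""

    data: np.ndarray
    frame_indices: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, float)
        self.frame_indices = np.asarray(self.frame_indices, int)
        if self.data.shape[0] != self.frame_indices.size:
            raise InvalidParameterError("one frame index per row required")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_cells(self) -> int:
        return self.data.shape[1]


@dataclass
class MicrostateResult:
    """Embedding, density map and per-frame microstate labels."""

    embedding: np.ndarray       # frames x 2
    density: np.ndarray         # smoothed grid
    region_map: np.ndarray      # watershed label per grid cell
    sigma: float                # smoothing SD in embedding units
    labels: np.ndarray          # per-frame microstate id
    n_microstates: int


def select_active_frames(raster: EventRaster, min_coactive: int = MIN_COACTIVE) -> FrameMatrix:
    """Keep frames with at least ``min_coactive`` co-active cells."""
    active_per_frame = (raster.events > 0).sum(axis=0)
    keep = np.flatnonzero(active_per_frame >= min_coactive)
    if keep.size == 0:
        raise EmptyResultError("no frames with enough co-active cells")
    return FrameMatrix(data=raster.events[:, keep].T, frame_indices=keep)


def reduce_frames(frames: FrameMatrix, share_percentile: float = SHARE_PERCENTILE) -> np.ndarray:
    """Project frames onto the leading principal components.

    Each component's explained-variance share is the derivative of the
    cumulative explained variance; components whose share reaches the 30th
    percentile of all shares are retained.
    """
    if frames.n_frames < 3:
        raise InsufficientDataError("PCA reduction needs at least 3 frames")
    X = frames.data
    if np.allclose(X, X[0]):
        raise DegenerateInputError("frame matrix has rank 0 after centering")
    pca = PCA(svd_solver="full").fit(X)
    shares = pca.explained_variance_ratio_
    cut = np.percentile(shares, share_percentile)
    keep = shares >= cut
    return pca.transform(X)[:, keep]


def embed_frames(reduced: np.ndarray, iterations: int = TSNE_ITERATIONS, seed: int = 0) -> np.ndarray:
    """2-D t-SNE embedding with perplexity floor(sqrt(N)), seeded."""
    reduced = np.asarray(reduced, float)
    n = reduced.shape[0]
    if n < 10:
        raise InsufficientDataError("embedding needs at least 10 frames")
    perplexity = float(int(np.sqrt(n)))
    tsne = TSNE(
        n_components=2,
        perplexity=perplexity,
        max_iter=iterations,
        init="pca",
        random_state=seed,
    )
    return tsne.fit_transform(reduced)


def tsne_perplexity(n_frames: int) -> float:
    """The perplexity rule used by :func:`embed_frames`."""
    return float(int(np.sqrt(n_frames)))


def segment_microstates(
    coords: np.ndarray,
    grid_size: int = GRID_SIZE,
    margin: float = GRID_MARGIN,
    sigma_fraction: float = SIGMA_FRACTION,
) -> MicrostateResult:
    """Watershed the smoothed embedding density into microstates.

    The density map is a 2-D histogram of the embedded points on a
    ``grid_size`` x ``grid_size`` grid over the bounding box (plus margin),
    smoothed with sigma = ``max(|coordinate|) * sigma_fraction``. Watershed
    basins of the inverted density, seeded at its local maxima, tile the
    grid; each frame inherits its grid cell's region.
    """
    coords = np.asarray(coords, float)
    if coords.ndim != 2 or coords.shape[1] != 2 or coords.shape[0] < 2:
        raise InvalidParameterError("coords must be (n >= 2) x 2")
    if np.allclose(coords, coords[0]):
        warnings.warn("all embedded coordinates identical: single microstate")
        grid = np.zeros((grid_size, grid_size))
        return MicrostateResult(
            embedding=coords,
            density=grid,
            region_map=np.ones_like(grid, dtype=int),
            sigma=0.0,
            labels=np.ones(coords.shape[0], dtype=int),
            n_microstates=1,
        )

    mins = coords.min(axis=0)
    maxs = coords.max(axis=0)
    extent = np.maximum(maxs - mins, 1e-12)
    lo = mins - margin * extent
    hi = maxs + margin * extent
    cell = (hi - lo) / grid_size

    ix = np.clip(((coords[:, 0] - lo[0]) / cell[0]).astype(int), 0, grid_size - 1)
    iy = np.clip(((coords[:, 1] - lo[1]) / cell[1]).astype(int), 0, grid_size - 1)
    hist = np.zeros((grid_size, grid_size))
    np.add.at(hist, (ix, iy), 1.0)

    # the density grid lives in positive (shifted) coordinates; the kernel SD
    # is sigma_fraction of the largest coordinate of that shifted map
    sigma = float(np.max(hi - lo) * sigma_fraction)
    sigma_px = (sigma / cell[0], sigma / cell[1])
    density = ndimage.gaussian_filter(hist, sigma=sigma_px)

    peaks = peak_local_max(density, exclude_border=False)
    markers = np.zeros_like(density, dtype=int)
    for k, (px, py) in enumerate(peaks, start=1):
        markers[px, py] = k
    if markers.max() == 0:  # perfectly flat density
        markers[grid_size // 2, grid_size // 2] = 1
    region_map = watershed(-density, markers=markers, watershed_line=False)

    labels = region_map[ix, iy]
    used = np.unique(labels)
    relabel = {old: new for new, old in enumerate(used, start=1)}
    labels = np.array([relabel[l] for l in labels], int)
    return MicrostateResult(
        embedding=coords,
        density=density,
        region_map=region_map,
        sigma=sigma,
        labels=labels,
        n_microstates=int(used.size),
    )


def permute_frames(frames: FrameMatrix, seed: int = 0) -> FrameMatrix:
    """Per-frame identity shuffle preserving each frame's active-cell count.

    Within every frame the positive amplitudes are reassigned (in cell
    order) to a uniformly drawn cell subset of the same size; a frame with
    all cells active is therefore unchanged.
    """
    if frames.n_frames == 0:
        raise InvalidParameterError("frames must be nonempty")
    rng = np.random.default_rng(seed)
    out = np.zeros_like(frames.data)
    n_cells = frames.n_cells
    for r in range(frames.n_frames):
        row = frames.data[r]
        active = np.flatnonzero(row > 0)
        chosen = np.sort(rng.choice(n_cells, size=active.size, replace=False))
        out[r, chosen] = row[active]
    return FrameMatrix(data=out, frame_indices=frames.frame_indices.copy())


def cluster_quality(reduced: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Mean pairwise correlation of frame vectors within vs across clusters."""
    reduced = np.asarray(reduced, float)
    labels = np.asarray(labels)
    uniq, counts = np.unique(labels, return_counts=True)
    if uniq.size < 2:
        raise InsufficientDataError("need at least 2 clusters")
    if np.any(counts < 2):
        raise InsufficientDataError("every cluster needs at least 2 frames")
    C = np.corrcoef(reduced)
    same = labels[:, None] == labels[None, :]
    triu = np.triu(np.ones_like(same, bool), k=1)
    intra = float(C[same & triu].mean())
    inter = float(C[~same & triu].mean())
    return intra, inter


def _correlation_similarity(reduced: np.ndarray) -> np.ndarray:
    C = np.corrcoef(np.asarray(reduced, float))
    return np.nan_to_num(C, nan=0.0)


def apc_cluster(
    reduced: np.ndarray, convergence_iter: int = 10, max_iter: int = 500
) -> tuple[np.ndarray, np.ndarray]:
    """Affinity propagation on the frame correlation similarity matrix.

    Preference is the median off-diagonal similarity; convergence window 10.
    Returns (labels, exemplar frame indices).
    """
    reduced = np.asarray(reduced, float)
    if reduced.shape[0] < 3:
        raise InsufficientDataError("affinity propagation needs at least 3 frames")
    S = _correlation_similarity(reduced)
    off = S[~np.eye(S.shape[0], dtype=bool)]
    ap = AffinityPropagation(
        affinity="precomputed",
        preference=float(np.median(off)),
        convergence_iter=convergence_iter,
        max_iter=max_iter,
        random_state=0,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ap.fit(S)
    if ap.cluster_centers_indices_ is None or len(ap.cluster_centers_indices_) == 0:
        raise NonConvergenceError(
            f"affinity propagation did not converge in {ap.n_iter_} iterations",
            n_iter=int(ap.n_iter_),
        )
    return ap.labels_, np.asarray(ap.cluster_centers_indices_, int)


def hclust_cluster(reduced: np.ndarray, cutoff: float = HCLUST_CUTOFF) -> np.ndarray:
    """Weighted-linkage hierarchical clustering on correlation distance.

    Builds a bottom-up tree with weighted (WPGMA) linkage on the
    correlation distance 1 - r and cuts it at ``cutoff``.
    """
    reduced = np.asarray(reduced, float)
    if reduced.shape[0] < 2:
        raise InsufficientDataError("need at least 2 frames")
    Z = linkage(reduced, method="weighted", metric="correlation")
    return fcluster(Z, t=cutoff, criterion="distance")


class MicrostateClustering(ClusterMixin, BaseEstimator):
    """End-to-end t-SNE/watershed microstate clustering of active frames.

    ``fit`` takes an active-frame matrix (frames x cells, every row with at
    least two positive entries) or an :class:`EventRaster` from which active
    frames are selected first.

    Attributes
    ----------
    labels_ : per-frame microstate label
    n_microstates_ : number of populated watershed regions
    embedding_ : 2-D t-SNE coordinates
    result_ : full :class:`MicrostateResult`
    reduced_ : the post-PCA frame matrix
    """

    def __init__(
        self,
        min_coactive: int = MIN_COACTIVE,
        iterations: int = TSNE_ITERATIONS,
        share_percentile: float = SHARE_PERCENTILE,
        grid_size: int = GRID_SIZE,
        sigma_fraction: float = SIGMA_FRACTION,
        seed: int = 0,
    ):
        self.min_coactive = min_coactive
        self.iterations = iterations
        self.share_percentile = share_percentile
        self.grid_size = grid_size
        self.sigma_fraction = sigma_fraction
        self.seed = seed

    def fit(self, X, y=None) -> "MicrostateClustering":
        if isinstance(X, EventRaster):
            frames = select_active_frames(X, self.min_coactive)
        elif isinstance(X, FrameMatrix):
            frames = X
        else:
            frames = FrameMatrix(
                data=np.asarray(X, float), frame_indices=np.arange(len(X))
            )
        self.frames_ = frames
        self.reduced_ = reduce_frames(frames, self.share_percentile)
        self.embedding_ = embed_frames(self.reduced_, self.iterations, self.seed)
        self.result_ = segment_microstates(
            self.embedding_, grid_size=self.grid_size, sigma_fraction=self.sigma_fraction
        )
        self.labels_ = self.result_.labels
        self.n_microstates_ = self.result_.n_microstates
        return self
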