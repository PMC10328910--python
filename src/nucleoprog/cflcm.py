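"""Cell-feature-level co-occurrence matrix (CFLCM) aggregation.

Pixel-level Haralick texture quantifies how gray levels co-occur at a fixed
spatial offset.  The CFLCM lifts the same idea from pixels to nuclei: each
nucleus becomes a "pixel" carrying a quantized feature value, spatial
adjacency between nuclei (a symmetrized k-nearest-neighbour graph over
centroids) plays the role of the pixel offset, and the resulting
co-occurrence matrix measures how similar or dissimilar neighbouring nuclei
are — i.e. the spatial heterogeneity and pleomorphism of the tissue.

For each base feature of the per-nucleus manifest the ROI is summarized by
12 statistics: the plain sample mean and SD, plus 10 co-occurrence
statistics of the feature's CFLCM.  With the default 80-feature manifest
this yields the 960-element ROI feature vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError

logger = logging.getLogger(__name__)

__all__ = [
    "NeighborGraph",
    "CFLCMMatrix",
    "ROIFeatureVector",
    "SkipROIError",
    "CFLCM_STAT_NAMES",
    "ROI_STAT_NAMES",
    "quantize_feature",
    "build_neighbor_graph",
    "build_cflcm",
    "cflcm_statistics",
    "aggregate_roi",
    "aggregate_table",
    "roi_feature_names",
]

CFLCM_STAT_NAMES = [
    "contrast",
    "dissimilarity",
    "homogeneity",
    "asm",
    "entropy",
    "correlation",
    "cluster_shade",
    "cluster_prominence",
    "max_probability",
    "idm",
]

#: per-base-feature statistic order in the ROI vector (feature-major layout)
ROI_STAT_NAMES = ["mean", "sd"] + [f"cflcm_{s}" for s in CFLCM_STAT_NAMES]


class SkipROIError(ValueError):
    """ROI has too few nuclei to aggregate; callers should skip it."""


@dataclass
class NeighborGraph:
    """Undirected adjacency between nuclei, anchored at centroids."""

    n_nodes: int
    edges: np.ndarray  # (m, 2) int array, each row i < j
    method: str = "knn"
    k: int = 5


@dataclass
class CFLCMMatrix:
    """Normalized co-occurrence matrix over quantization levels."""

    matrix: np.ndarray
    bin_edges: np.ndarray
    degenerate: bool = False  # no edges: zero matrix


@dataclass
class ROIFeatureVector:
    case_id: str
    roi_id: str
    values: np.ndarray
    names: list[str] = field(default_factory=list)


def quantize_feature(values: np.ndarray, n_levels: int) -> tuple[np.ndarray, np.ndarray]:
    """Equal-frequency (quantile) binning into levels 1..n_levels.

    Constant input maps every value to level 1.  Returns (levels, edges)
    where ``edges`` are the n_levels+1 quantile boundaries used.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise SkipROIError("cannot quantize an empty value list")
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    edges = np.quantile(values, np.linspace(0, 1, n_levels + 1))
    if edges[0] == edges[-1]:
        return np.ones(values.size, dtype=np.intp), edges
    levels = np.searchsorted(edges[1:-1], values, side="left") + 1
    return levels.astype(np.intp), edges


def build_neighbor_graph(
    centroids: np.ndarray, method: str = "knn", k: int = 5
) -> NeighborGraph:
    """Spatial adjacency over nucleus centroids.

    ``knn`` (default): symmetrized k-nearest neighbours by Euclidean
    distance — an edge exists if either endpoint ranks the other among its k
    nearest.  Distance ties are broken by node index so the graph is
    deterministic even with duplicate centroids.  ``delaunay`` triangulates
    the centroids instead (falls back to knn on degenerate geometry).
    """
    pts = np.asarray(centroids, dtype=float)
    n = len(pts)
    if n == 0:
        raise SkipROIError("no centroids")
    if n == 1:
        return NeighborGraph(1, np.empty((0, 2), dtype=np.intp), method, k)
    if method == "delaunay":
        try:
            tri = Delaunay(pts)
            pairs = set()
            for simplex in tri.simplices:
                for a in range(3):
                    for b in range(a + 1, 3):
                        i, j = sorted((int(simplex[a]), int(simplex[b])))
                        pairs.add((i, j))
            edges = np.array(sorted(pairs), dtype=np.intp)
            return NeighborGraph(n, edges, "delaunay", k)
        except QhullError:
            logger.warning("degenerate geometry for Delaunay; falling back to knn")
    elif method != "knn":
        raise ValueError(f"unknown neighbor method {method!r}")
    k_eff = min(k, n - 1)
    # brute force keeps tie-breaking by index exact; n is at most a few hundred
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=-1)
    np.fill_diagonal(d2, np.inf)
    order = np.argsort(d2, axis=1, kind="stable")[:, :k_eff]
    pairs = set()
    for i in range(n):
        for j in order[i]:
            a, b = (i, int(j)) if i < j else (int(j), i)
            pairs.add((a, b))
    edges = np.array(sorted(pairs), dtype=np.intp)
    return NeighborGraph(n, edges, "knn", k)


def build_cflcm(
    levels: np.ndarray,
    graph: NeighborGraph,
    n_levels: int,
    bin_edges: np.ndarray | None = None,
) -> CFLCMMatrix:
    """Accumulate level pairs over graph edges; symmetric, normalized.

    Each undirected edge (i, j) contributes to cells (level_i, level_j) and
    (level_j, level_i).  With no edges the matrix is all-zero and flagged
    degenerate.
    """
    levels = np.asarray(levels)
    if levels.size != graph.n_nodes:
        raise ValueError("levels must cover every node")
    L = n_levels
    if bin_edges is None:
        bin_edges = np.array([])
    if graph.edges.shape[0] == 0:
        return CFLCMMatrix(np.zeros((L, L)), bin_edges, degenerate=True)
    li = levels[graph.edges[:, 0]] - 1
    lj = levels[graph.edges[:, 1]] - 1
    counts = np.bincount(li * L + lj, minlength=L * L).reshape(L, L)
    counts = counts + counts.T
    return CFLCMMatrix(counts / counts.sum(), bin_edges, degenerate=False)


def _stats_from_stack(P: np.ndarray) -> np.ndarray:
    """Vectorized CFLCM statistics for a stack of matrices (..., L, L)."""
    L = P.shape[-1]
    i = np.arange(L)[:, None].astype(float)
    j = np.arange(L)[None, :].astype(float)
    absdiff = np.abs(i - j)
    contrast = ((i - j) ** 2 * P).sum(axis=(-2, -1))
    dissimilarity = (absdiff * P).sum(axis=(-2, -1))
    homogeneity = (P / (1.0 + absdiff)).sum(axis=(-2, -1))
    asm = (P**2).sum(axis=(-2, -1))
    with np.errstate(divide="ignore", invalid="ignore"):
        logP = np.where(P > 0, np.log(np.where(P > 0, P, 1.0)), 0.0)
    entropy = -(P * logP).sum(axis=(-2, -1))
    px = P.sum(axis=-1)
    py = P.sum(axis=-2)
    idx = np.arange(L).astype(float)
    mu_x = (idx * px).sum(axis=-1)
    mu_y = (idx * py).sum(axis=-1)
    var_x = ((idx - mu_x[..., None]) ** 2 * px).sum(axis=-1)
    var_y = ((idx - mu_y[..., None]) ** 2 * py).sum(axis=-1)
    cross = (i * j * P).sum(axis=(-2, -1))
    denom = np.sqrt(var_x * var_y)
    with np.errstate(divide="ignore", invalid="ignore"):
        correlation = np.where(denom > 0, (cross - mu_x * mu_y) / np.where(denom > 0, denom, 1.0), 0.0)
    dev = i + j - mu_x[..., None, None] - mu_y[..., None, None]
    shade = (dev**3 * P).sum(axis=(-2, -1))
    prominence = (dev**4 * P).sum(axis=(-2, -1))
    max_prob = P.max(axis=(-2, -1))
    idm = (P / (1.0 + (i - j) ** 2)).sum(axis=(-2, -1))
    return np.stack(
        [
            contrast,
            dissimilarity,
            homogeneity,
            asm,
            entropy,
            correlation,
            shade,
            prominence,
            max_prob,
            idm,
        ],
        axis=-1,
    )


def cflcm_statistics(matrix: CFLCMMatrix | np.ndarray) -> np.ndarray:
    """The 10 heterogeneity statistics, in :data:`CFLCM_STAT_NAMES` order.

    A degenerate (all-zero) matrix yields all zeros.  A matrix that is
    neither normalized nor zero violates the contract.
    """
    P = matrix.matrix if isinstance(matrix, CFLCMMatrix) else np.asarray(matrix, float)
    total = P.sum()
    if total == 0:
        return np.zeros(len(CFLCM_STAT_NAMES))
    if abs(total - 1.0) > 1e-8:
        raise ValueError(f"CFLCM not normalized (sum={total})")
    return _stats_from_stack(P)


def aggregate_roi(
    features: np.ndarray,
    centroids: np.ndarray,
    n_levels: int = 8,
    method: str = "knn",
    k: int = 5,
    min_nuclei: int = 5,
) -> np.ndarray:
    """Aggregate an (n_nuclei, n_features) table into the ROI vector.

    Output layout is feature-major: for every base feature, the 12
    statistics of :data:`ROI_STAT_NAMES` (mean, SD with the n-1
    denominator, then the 10 CFLCM statistics).  Length is
    ``12 * n_features``; 960 under the default 80-feature manifest.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D table")
    n, F = X.shape
    if n < min_nuclei:
        raise SkipROIError(f"ROI has {n} nuclei, fewer than the minimum {min_nuclei}")
    graph = build_neighbor_graph(np.asarray(centroids, float), method=method, k=k)
    means = X.mean(axis=0)
    sds = X.std(axis=0, ddof=1)
    L = n_levels
    matrices = np.zeros((F, L, L))
    ei = graph.edges[:, 0]
    ej = graph.edges[:, 1]
    for f in range(F):
        levels, _ = quantize_feature(X[:, f], n_levels)
        if ei.size:
            li = levels[ei] - 1
            lj = levels[ej] - 1
            counts = np.bincount(li * L + lj, minlength=L * L).reshape(L, L)
            counts = counts + counts.T
            matrices[f] = counts / counts.sum()
    stats = np.zeros((F, len(CFLCM_STAT_NAMES)))
    nonzero = matrices.sum(axis=(-2, -1)) > 0
    if nonzero.any():
        stats[nonzero] = _stats_from_stack(matrices[nonzero])
    out = np.concatenate(
        [means[:, None], sds[:, None], stats], axis=1
    ).ravel()
    return out


def roi_feature_names(base_names: list[str]) -> list[str]:
    """Column names for the ROI vector, matching aggregate_roi's layout."""
    return [f"{b}__{s}" for b in base_names for s in ROI_STAT_NAMES]


def aggregate_table(
    nucleus_df: pd.DataFrame,
    feature_columns: list[str] | None = None,
    n_levels: int = 8,
    method: str = "knn",
    k: int = 5,
    min_nuclei: int = 5,
) -> pd.DataFrame:
    """Aggregate a per-nucleus table (many ROIs) to one row per ROI.

    Expects columns case_id, roi_id, centroid_row, centroid_col followed by
    feature columns.  ROIs below ``min_nuclei`` are skipped with a logged
    reason.
    """
    meta = {"case_id", "roi_id", "nucleus_id", "centroid_row", "centroid_col"}
    if feature_columns is None:
        feature_columns = [c for c in nucleus_df.columns if c not in meta]
    rows = []
    for (case_id, roi_id), grp in nucleus_df.groupby(["case_id", "roi_id"], sort=True):
        try:
            vec = aggregate_roi(
                grp[feature_columns].to_numpy(),
                grp[["centroid_row", "centroid_col"]].to_numpy(),
                n_levels=n_levels,
                method=method,
                k=k,
                min_nuclei=min_nuclei,
            )
        except SkipROIError as exc:
            logger.warning("skipping ROI %s/%s: %s", case_id, roi_id, exc)
            continue
        row = {"case_id": case_id, "roi_id": roi_id}
        row.update(dict(zip(roi_feature_names(feature_columns), vec)))
        rows.append(row)
    return pd.DataFrame(rows)
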