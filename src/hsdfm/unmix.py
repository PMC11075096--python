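"""Unsupervised endmember discovery (K-means) and NNLS abundance maps.

Stacked reflectance cubes are flattened to a pixel matrix X (n pixels x p
wavelengths).  Lloyd's K-means partitions the rows into k clusters
minimizing the within-cluster sum of squared distances; initial centers are
drawn uniformly from the distinct rows and the best of several random
restarts is kept.  Clusters are ranked by their share of the
between-cluster variance.  Continuous abundance maps come from per-pixel
nonnegative least squares against the endmember matrix U (p x k):
``m_j = argmin_{m >= 0} |U m - x_j|``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls as _scipy_nnls

from hsdfm.datacube import ConfigurationError, GridMismatchError, ReflectanceCube, WavelengthGrid

log = logging.getLogger(__name__)


@dataclass
class PixelMatrix:
    """n x p pixel-spectrum matrix with an index back onto the source rasters."""

    X: np.ndarray
    shapes: list[tuple[int, int]]     # raster shape of each stacked cube
    grid: WavelengthGrid

    @property
    def n_pixels(self) -> int:
        return self.X.shape[0]

    def offsets(self) -> list[int]:
        sizes = [m * n for m, n in self.shapes]
        return [0, *np.cumsum(sizes).tolist()]

    def unstack(self, column: np.ndarray) -> list[np.ndarray]:
        """Reshape an n-vector back into one raster per source cube."""
        column = np.asarray(column)
        if column.shape[0] != self.n_pixels:
            raise ConfigurationError("column length does not match pixel count")
        offs = self.offsets()
        return [
            column[offs[i]:offs[i + 1]].reshape(self.shapes[i])
            for i in range(len(self.shapes))
        ]


@dataclass
class ClusterResult:
    k: int
    centroids: np.ndarray             # (k, p)
    assignment: np.ndarray            # (n,) cluster index per pixel
    objective: float                  # within-cluster sum of squares
    n_iter: int
    seed: int
    restart_objectives: list[float] = field(default_factory=list)

    def partition(self) -> list[np.ndarray]:
        return [np.flatnonzero(self.assignment == i) for i in range(self.k)]


@dataclass
class ClusterRanking:
    order: np.ndarray                 # cluster indices, descending variance share
    shares: np.ndarray                # between-cluster variance share per cluster
    degenerate: bool = False

    def top(self, n: int = 3) -> np.ndarray:
        return self.order[:n]


@dataclass
class AbundanceMatrix:
    M: np.ndarray                     # (n, k) nonnegative abundances
    U: np.ndarray                     # (p, k) endmember matrix

    def __post_init__(self) -> None:
        if np.any(self.M < 0):
            raise ConfigurationError("abundances must be nonnegative")


def stack_cubes(cubes: list[ReflectanceCube]) -> PixelMatrix:
    """Stack cubes into one pixel matrix (rows are pixel spectra)."""
    if not cubes:
        raise ConfigurationError("need at least one cube")
    grid = cubes[0].grid
    for c in cubes[1:]:
        if c.grid != grid:
            raise GridMismatchError("stacked cubes must share one grid")
    X = np.vstack([c.pixels() for c in cubes])
    return PixelMatrix(X=X, shapes=[c.shape[:2] for c in cubes], grid=grid)


def _lloyd(
    X: np.ndarray, centers: np.ndarray, max_iter: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, float, int]:
    """Lloyd iterations; empty clusters are re-seeded from the farthest point."""
    k = centers.shape[0]
    sq_x = np.einsum("ij,ij->i", X, X)
    assignment = np.full(X.shape[0], -1, dtype=int)
    for it in range(1, max_iter + 1):
        d2 = sq_x[:, None] - 2.0 * X @ centers.T + np.einsum("ij,ij->i", centers, centers)
        new_assignment = np.argmin(d2, axis=1)
        dist_min = d2[np.arange(X.shape[0]), new_assignment]
        for i in range(k):
            members = new_assignment == i
            if not np.any(members):
                far = int(np.argmax(dist_min))
                centers[i] = X[far]
                new_assignment[far] = i
                dist_min[far] = 0.0
                log.info("k-means: empty cluster %d re-seeded from farthest point", i)
        if np.array_equal(new_assignment, assignment):
            break
        assignment = new_assignment
        for i in range(k):
            centers[i] = X[assignment == i].mean(axis=0)
    diff = X - centers[assignment]
    objective = float(np.einsum("ij,ij->", diff, diff))
    return centers, assignment, objective, it


def kmeans_endmembers(
    pm: PixelMatrix | np.ndarray,
    k: int = 5,
    restarts: int = 10,
    seed: int = 0,
    max_iter: int = 300,
) -> ClusterResult:
    """Best-of-restarts Lloyd K-means on pixel spectra.

    Initial centers for each restart are drawn uniformly (without
    replacement) from the distinct rows of X.  Deterministic for a fixed
    seed; the returned objective is the minimum over restarts.
    """
    X = pm.X if isinstance(pm, PixelMatrix) else np.asarray(pm, dtype=float)
    distinct = np.unique(X, axis=0)
    if k > distinct.shape[0]:
        raise ConfigurationError(
            f"k={k} exceeds the {distinct.shape[0]} distinct pixel spectra"
        )
    rng = np.random.default_rng(seed)
    best = None
    restart_objectives: list[float] = []
    for _ in range(restarts):
        idx = rng.choice(distinct.shape[0], size=k, replace=False)
        centers = distinct[idx].copy()
        centers, assignment, objective, n_iter = _lloyd(X, centers, max_iter, rng)
        restart_objectives.append(objective)
        if best is None or objective < best[2]:
            best = (centers, assignment, objective, n_iter)
    centers, assignment, objective, n_iter = best
    return ClusterResult(
        k=k, centroids=centers, assignment=assignment,
        objective=objective, n_iter=n_iter, seed=seed,
        restart_objectives=restart_objectives,
    )


def rank_clusters(cr: ClusterResult, pm: PixelMatrix | np.ndarray) -> ClusterRanking:
    """Order clusters by their share of the between-cluster variance.

    score_i = |S_i| * |mu_i - x_bar|^2, normalized to shares summing to 1.
    A single cluster (or coincident centroids) is degenerate: all shares 0.
    """
    X = pm.X if isinstance(pm, PixelMatrix) else np.asarray(pm, dtype=float)
    xbar = X.mean(axis=0)
    sizes = np.bincount(cr.assignment, minlength=cr.k)
    scores = sizes * np.einsum("ij,ij->i", cr.centroids - xbar, cr.centroids - xbar)
    total = scores.sum()
    degenerate = total == 0
    if degenerate:
        log.warning("rank_clusters: zero between-cluster variance (degenerate)")
        shares = np.zeros(cr.k)
    else:
        shares = scores / total
    order = np.argsort(-shares, kind="stable")
    return ClusterRanking(order=order, shares=shares, degenerate=degenerate)


def nnls_abundances(pm: PixelMatrix | np.ndarray, U: np.ndarray) -> AbundanceMatrix:
    """Per-pixel nonnegative least-squares abundances against endmembers U.

    U is (p, k); endmember spectra are its columns.  Rank deficiency is
    warned about but the (well-posed) NNLS solutions are still returned.
    """
    X = pm.X if isinstance(pm, PixelMatrix) else np.asarray(pm, dtype=float)
    U = np.asarray(U, dtype=float)
    if U.ndim != 2 or U.shape[0] != X.shape[1]:
        raise ConfigurationError("U must be (n_bands, k)")
    if np.any(np.linalg.norm(U, axis=0) == 0):
        raise ConfigurationError("endmember matrix has a zero column")
    if np.linalg.matrix_rank(U) < U.shape[1]:
        warnings.warn("endmember matrix U is rank deficient", stacklevel=2)
    M = np.empty((X.shape[0], U.shape[1]))
    for j in range(X.shape[0]):
        M[j], _ = _scipy_nnls(U, X[j])
    return AbundanceMatrix(M=M, U=U)


def abundance_to_maps(ab: AbundanceMatrix, pm: PixelMatrix) -> list[list[np.ndarray]]:
    """Column i of M reshaped to each source cube's raster.

    Returns one list of rasters (one per stacked cube) per cluster.
    """
    return [pm.unstack(ab.M[:, i]) for i in range(ab.M.shape[1])]


def abundance_composite(
    ab: AbundanceMatrix,
    pm: PixelMatrix,
    clusters: np.ndarray | list[int],
    cube_index: int = 0,
) -> np.ndarray:
    """RGB composite of up to three cluster abundance maps.

    Channel order follows ``clusters`` (e.g. the top-3 ranking); each
    channel is scaled to its own maximum so mixed pixels show blended color.
    """
    clusters = list(clusters)[:3]
    shape = pm.shapes[cube_index]
    rgb = np.zeros(shape + (3,))
    for ch, ci in enumerate(clusters):
        raster = pm.unstack(ab.M[:, ci])[cube_index]
        peak = raster.max()
        rgb[:, :, ch] = raster / peak if peak > 0 else 0.0
    return rgb
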