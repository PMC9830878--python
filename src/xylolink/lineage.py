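"""Kernel-smoothed gene-set maps and pseudotime expression profiles.

``local_abundance`` estimates each gene's local transcript abundance at each
cell as a Gaussian-kernel weighted average of normalized UMI counts over
cells, with distances taken in top-PC space (d = 10 by convention).  The
relative abundance ``r_ic = L_ic / mean_c(L_ic)`` averages to exactly 1 over
cells, and a gene set's per-cell score is the mean relative abundance over
its genes.  ``nw_regression`` is Nadaraya-Watson kernel regression of
expression on pseudotime, and ``moving_average_profiles`` computes
sliding-window (default 21 cells, step 1) means along a pseudotime ordering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, RegressorMixin, TransformerMixin

from .normalize import NormalizedMatrix
from .xspecies import OrthoMatrix

__all__ = [
    "GeneSetScore",
    "LineageProfile",
    "local_abundance",
    "geneset_relative_abundance",
    "nw_regression",
    "moving_average_profiles",
    "KernelSmoother",
    "NadarayaWatsonRegressor",
    "default_pc_bandwidth",
    "silverman_bandwidth",
]


@dataclass
class GeneSetScore:
    """Per-cell mean relative local abundance of a gene set."""

    scores: pd.Series            # per cell
    relative: pd.DataFrame       # cells x set genes, r_ic
    bandwidth: float
    missing_genes: list[str]


@dataclass
class LineageProfile:
    """Sliding-window means of features along a pseudotime-ordered lineage."""

    order: np.ndarray            # cell indices sorted by pseudotime
    window: int
    series: pd.DataFrame         # (n - window + 1) x features
    feature_max: pd.Series       # per-feature max over the lineage (display scale)
    feature_mean: pd.Series


def default_pc_bandwidth(coords: np.ndarray, k: int = 30) -> float:
    """Median distance to the k-th nearest neighbor (PC-space smoother default)."""
    from sklearn.neighbors import NearestNeighbors

    k = min(k, len(coords) - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    dist, _ = nn.kneighbors(coords)
    return float(np.median(dist[:, -1]))


def silverman_bandwidth(values: np.ndarray) -> float:
    """Silverman's rule of thumb on a 1D sample (NW regression default)."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    sd = values.std(ddof=1) if n > 1 else 0.0
    q75, q25 = np.percentile(values, [75, 25])
    scale = min([v for v in (sd, (q75 - q25) / 1.349) if v > 0], default=0.0)
    if scale <= 0:
        return max(1e-6, 1e-3 * max(abs(values).max(), 1.0))
    return 0.9 * scale * n ** (-1.0 / 5.0)


def local_abundance(
    values: np.ndarray, coords: np.ndarray, bandwidth: float
) -> np.ndarray:
    """Gaussian-kernel weighted average of ``values`` over cells.

    ``L_ic = sum_j K(||x_c - x_j|| / h) v_ij / sum_j K``, self-weight
    included.  ``values`` is cells x genes (dense), ``coords`` cells x d.
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    coords = np.asarray(coords, dtype=float)
    if not np.all(np.isfinite(coords)):
        raise ValueError("non-finite coordinates")
    values = np.asarray(values, dtype=float)
    if len(values) != len(coords):
        raise ValueError("values and coordinates are not aligned")
    d2 = cdist(coords, coords, "sqeuclidean")
    with np.errstate(under="ignore"):
        w = np.exp(-0.5 * d2 / bandwidth**2)
    return (w @ values) / w.sum(axis=1, keepdims=True)


def geneset_relative_abundance(
    nm: NormalizedMatrix,
    coords: np.ndarray,
    gene_set: list[str],
    bandwidth: float | None = None,
) -> GeneSetScore:
    """Mean relative local abundance of ``gene_set`` per cell.

    Duplicated genes in the set are deduplicated (warning); genes absent from
    the matrix are reported in ``missing_genes``.  Default bandwidth: median
    distance to the 30th nearest neighbor in ``coords``.
    """
    seen: dict[str, None] = {}
    dupes = []
    for g in gene_set:
        if g in seen:
            dupes.append(g)
        seen[g] = None
    if dupes:
        warnings.warn(f"duplicated genes in set deduplicated: {sorted(set(dupes))}",
                      stacklevel=2)
    genes = list(seen)
    idx = pd.Index(nm.gene_ids)
    present = [g for g in genes if g in idx]
    missing = [g for g in genes if g not in idx]
    if not present:
        raise ValueError("no gene of the set is present in the matrix")
    if bandwidth is None:
        bandwidth = default_pc_bandwidth(coords)

    vals = nm.dense()[:, idx.get_indexer(present)]
    local = local_abundance(vals, coords, bandwidth)
    mean_local = local.mean(axis=0)
    rel = np.ones_like(local)
    nz = mean_local > 0
    rel[:, nz] = local[:, nz] / mean_local[nz]  # constant-zero genes: r = 1
    rel_df = pd.DataFrame(rel, index=nm.cell_ids, columns=present)
    return GeneSetScore(rel_df.mean(axis=1), rel_df, float(bandwidth), missing)


def nw_regression(
    pseudotime: np.ndarray,
    values: np.ndarray,
    query: np.ndarray,
    bandwidth: float | None = None,
) -> np.ndarray:
    """Nadaraya-Watson Gaussian-kernel regression of ``values`` on ``pseudotime``.

    ``y^(q) = sum_j K((q - t_j)/h) y_j / sum_j K``.  Queries where every
    kernel weight underflows fall back to the nearest observation (warning).
    Default bandwidth: Silverman's rule on the pseudotime values.
    """
    t = np.asarray(pseudotime, dtype=float)
    y = np.asarray(values, dtype=float)
    q = np.asarray(query, dtype=float)
    if len(t) < 2:
        raise ValueError("need at least 2 observations")
    if len(t) != len(y):
        raise ValueError("pseudotime and values are not aligned")
    if bandwidth is None:
        bandwidth = silverman_bandwidth(t)
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    with np.errstate(under="ignore"):
        w = np.exp(-0.5 * ((q[:, None] - t[None, :]) / bandwidth) ** 2)
    totals = w.sum(axis=1)
    dead = totals == 0
    if dead.any():
        warnings.warn(
            f"{int(dead.sum())} queries beyond kernel support; "
            "nearest-neighbor fallback", stacklevel=2,
        )
        nearest = np.abs(q[dead, None] - t[None, :]).argmin(axis=1)
    out = np.empty(len(q))
    out[~dead] = (w[~dead] @ y) / totals[~dead]
    if dead.any():
        out[dead] = y[nearest]
    return out


def moving_average_profiles(
    ortho: OrthoMatrix,
    pseudotime: np.ndarray,
    window: int = 21,
    features: list[str] | None = None,
) -> LineageProfile:
    """Sliding-window means along the pseudotime ordering (step 1 cell).

    Pseudotime ties are broken by stable cell-index order.  The profile of a
    lineage with ``n`` cells and window ``w`` has ``n - w + 1`` windows.  The
    per-feature max and mean over the lineage are emitted alongside (used to
    rescale heatmap rows for display).
    """
    t = np.asarray(pseudotime, dtype=float)
    n = ortho.n_cells
    if len(t) != n:
        raise ValueError("pseudotime is not aligned with cells")
    if not 1 <= window <= n:
        raise ValueError(f"window {window} invalid for {n} cells")
    order = np.argsort(t, kind="stable")

    cols = ortho.group_ids
    mat = ortho.counts
    if features is not None:
        keep = pd.Index(ortho.group_ids).get_indexer(features)
        if (keep < 0).any():
            raise ValueError("unknown feature(s) requested")
        mat = mat[:, keep]
        cols = np.asarray(features, dtype=object)
    dense = np.asarray(mat.todense(), dtype=float)[order]

    csum = np.vstack([np.zeros((1, dense.shape[1])), np.cumsum(dense, axis=0)])
    windows = (csum[window:] - csum[:-window]) / window
    series = pd.DataFrame(windows, columns=cols)
    return LineageProfile(
        order=order, window=window, series=series,
        feature_max=pd.Series(dense.max(axis=0), index=cols),
        feature_mean=pd.Series(dense.mean(axis=0), index=cols),
    )


# ---------------------------------------------------------------------------
# estimator wrappers
# ---------------------------------------------------------------------------

class KernelSmoother(TransformerMixin, BaseEstimator):
    """Gaussian-kernel smoother over a fixed coordinate space (transform-shaped).

    ``fit(X)`` stores the coordinates; ``transform(V)`` smooths per-cell
    feature values ``V`` (cells x features) over those coordinates.
    """

    def __init__(self, bandwidth: float | None = None):
        self.bandwidth = bandwidth

    def fit(self, X, y=None):
        self.coords_ = np.asarray(X, dtype=float)
        self.bandwidth_ = (
            self.bandwidth if self.bandwidth is not None
            else default_pc_bandwidth(self.coords_)
        )
        return self

    def transform(self, V) -> np.ndarray:
        return local_abundance(np.asarray(V, dtype=float), self.coords_, self.bandwidth_)


class NadarayaWatsonRegressor(RegressorMixin, BaseEstimator):
    """Nadaraya-Watson kernel regressor (fit/predict-shaped).

    ``X`` is the (n, 1) pseudotime column, ``y`` the response.
    """

    def __init__(self, bandwidth: float | None = None):
        self.bandwidth = bandwidth

    def fit(self, X, y):
        X = np.asarray(X, dtype=float).reshape(len(y), -1)
        if X.shape[1] != 1:
            raise ValueError("NW regressor expects a single explanatory column")
        self.t_ = X.ravel()
        self.y_ = np.asarray(y, dtype=float)
        self.bandwidth_ = (
            self.bandwidth if self.bandwidth is not None else silverman_bandwidth(self.t_)
        )
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float).reshape(-1)
        return nw_regression(self.t_, self.y_, X, self.bandwidth_)
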