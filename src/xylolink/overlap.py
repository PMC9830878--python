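"""MST-based distribution-overlap statistic for two labeled cell populations.

Given a shared 2D embedding of cells from two species (or two batches), the
statistic is computed as follows:

1. build the Euclidean minimum spanning tree over all cells;
2. delete every cross-species edge (the deleted-edge count ``k`` is the
   classic two-sample interdigitation statistic: identical distributions
   interleave heavily, disjoint ones barely);
3. the resulting forest has exactly ``k + 1`` single-species subgraphs; each
   subgraph contributes its closeness-centrality center node (node with the
   smallest sum of within-subgraph tree-path distances; a singleton is its
   own center);
4. per species, a product-Gaussian kernel density ``f_S`` is fitted to the
   center nodes (unit mass) and weighted by the number of centers ``m_S``
   and the species' share of cells: ``w_S = m_S * (n_S / n) * f_S``; the two
   weighted fields are summed into one density map ``D = w_A + w_B``;
5. ``D`` is evaluated at every cell, divided by ``Z`` (the total over the
   reference species' cells), rescaled to [0, 1] (by the pair's own maximum,
   or by scale constants carried over from a designated reference pair so
   several pairs share one scale), and binned into ``n_bins`` equal-width
   bins; the overlap is the fraction of cells outside the lowest bin,
   reported as a percentage.

Two far-separated clouds yield two near-singleton center sets whose weighted
density is negligible on the reference scale, so almost every cell falls in
the lowest bin (overlap -> 0); two samples of one distribution yield centers
everywhere and an overlap near 100%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import squareform, pdist
from sklearn.base import BaseEstimator

from .io import LabeledEmbedding

__all__ = [
    "OverlapConfig",
    "OverlapResult",
    "SpeciesDensityField",
    "build_mst",
    "split_subgraphs",
    "component_centers",
    "weighted_density_map",
    "overlap_statistic",
    "MSTOverlap",
]


@dataclass
class OverlapConfig:
    """Tunables of the overlap statistic.

    ``mode='self'`` rescales densities by the pair's own maximum;
    ``mode='reference'`` divides by ``ref_scale=(Z_ref, max_ref)`` taken from
    a designated reference pair, so multi-pair panels share one scale.
    ``reference`` names the species whose cells define the normalization sum
    ``Z`` (defaults to the first species encountered).
    """

    n_bins: int = 500
    grid_size: tuple[int, int] = (250, 250)
    grid_margin: float = 0.05
    mode: str = "self"
    ref_scale: tuple[float, float] | None = None  # (Z_ref, max_ref)
    reference: str | None = None
    center_tie_rtol: float = 1e-9

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.mode not in ("self", "reference"):
            raise ValueError("mode must be 'self' or 'reference'")
        if self.mode == "reference" and self.ref_scale is None:
            raise ValueError("mode='reference' requires ref_scale=(Z_ref, max_ref)")


@dataclass
class SpeciesDensityField:
    """Weighted product-Gaussian KDE fitted to one species' center nodes."""

    centers: np.ndarray          # m x 2
    bandwidth: np.ndarray        # (hx, hy)
    weight: float                # m_S * n_S / n

    def density(self, points: np.ndarray) -> np.ndarray:
        """Unit-mass KDE ``f_S`` evaluated at ``points`` (q x 2)."""
        pts = np.atleast_2d(points)
        hx, hy = self.bandwidth
        out = np.empty(len(pts))
        norm = 2.0 * np.pi * hx * hy
        step = max(1, int(4e6 // max(len(self.centers), 1)))  # bound temporaries
        for lo in range(0, len(pts), step):
            chunk = pts[lo:lo + step]
            dx = (chunk[:, None, 0] - self.centers[None, :, 0]) / hx
            dy = (chunk[:, None, 1] - self.centers[None, :, 1]) / hy
            out[lo:lo + step] = np.exp(-0.5 * (dx**2 + dy**2)).mean(axis=1) / norm
        return out

    def weighted(self, points: np.ndarray) -> np.ndarray:
        """``w_S = m_S * (n_S/n) * f_S`` at ``points``."""
        return self.weight * self.density(points)


@dataclass
class OverlapResult:
    """Everything the statistic computes, including reusable scale constants."""

    edges: np.ndarray            # (n-1) x 3: i, j, length
    n_removed: int               # k, cross-species edges deleted
    component_of: np.ndarray     # per-cell subgraph id
    centers: dict[str, np.ndarray]        # species -> center cell indices
    fields: dict[str, SpeciesDensityField]
    density: np.ndarray          # D / Z at every cell (before [0,1] rescale)
    scaled_density: np.ndarray   # in [0, 1], what gets binned
    bin_proportions: np.ndarray  # p_1 ... p_{n_bins}, sums to 1
    overlap: float               # O = 1 - p_1, in [0, 1]
    z: float                     # normalization sum over reference cells
    vmax: float                  # max of D/Z over cells (this pair's scale)
    config: OverlapConfig = field(repr=False, default_factory=OverlapConfig)

    @property
    def n_subgraphs(self) -> int:
        return self.n_removed + 1

    @property
    def overlap_pct(self) -> float:
        return 100.0 * self.overlap

    @property
    def scale_constants(self) -> tuple[float, float]:
        """``(Z, vmax)`` to feed a later run in reference mode."""
        return (self.z, self.vmax)


# ---------------------------------------------------------------------------
# graph steps
# ---------------------------------------------------------------------------

def build_mst(points: np.ndarray) -> np.ndarray:
    """Euclidean MST of ``points`` (n x 2): returns (n-1) x 3 array [i, j, length].

    ``i < j`` in every row; rows are sorted by (length, i, j) so the edge
    list is deterministic for a given input.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("need at least 2 points in a 2D array")
    if not np.all(np.isfinite(pts)):
        raise ValueError("non-finite coordinates")
    dense = squareform(pdist(pts))
    # keep zero-length edges representable: shift all distances by +1, undo after
    tree = minimum_spanning_tree(csr_matrix(dense + 1.0))
    ii, jj = tree.nonzero()
    ww = np.asarray(tree[ii, jj]).ravel() - 1.0
    ww[ww < 0] = 0.0
    lo, hi = np.minimum(ii, jj), np.maximum(ii, jj)
    order = np.lexsort((hi, lo, ww))
    return np.column_stack([lo[order], hi[order], ww[order]])


def split_subgraphs(edges: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, int]:
    """Delete cross-label edges from the tree; return (component ids, k).

    The forest left after deleting ``k`` edges has exactly ``k + 1``
    components, each single-label.  Exactly two label values are required.
    """
    labels = np.asarray(labels)
    uniq = pd_unique(labels)
    if len(uniq) != 2:
        raise ValueError(
            f"overlap requires exactly 2 species labels, got {len(uniq)}"
        )
    n = len(labels)
    parent = np.arange(n)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    removed = 0
    for i, j, _w in edges:
        i, j = int(i), int(j)
        if labels[i] == labels[j]:
            parent[find(i)] = find(j)
        else:
            removed += 1
    roots = np.fromiter((find(i) for i in range(n)), dtype=int, count=n)
    _, comp = np.unique(roots, return_inverse=True)
    return comp, removed


def pd_unique(values: np.ndarray) -> list:
    """Unique values in order of first appearance."""
    seen: dict = {}
    for v in values:
        if v not in seen:
            seen[v] = None
    return list(seen)


def component_centers(
    component_of: np.ndarray,
    edges: np.ndarray,
    points: np.ndarray,
    tie_rtol: float = 1e-9,
) -> np.ndarray:
    """Center node of each subgraph: smallest sum of tree-path distances.

    Path distances use Euclidean edge lengths (paths in a tree are unique).
    Computed in O(n) per component with the two-pass re-rooting identity
    ``S(child) = S(parent) + (n_comp - 2 * subtree(child)) * w(edge)``.
    Singletons are their own center; near-ties (relative ``tie_rtol``) go to
    the lowest cell index.
    Returns one cell index per component id.
    """
    component_of = np.asarray(component_of)
    n = len(component_of)
    adj: list[list[tuple[int, float]]] = [[] for _ in range(n)]
    for i, j, w in edges:
        i, j = int(i), int(j)
        if component_of[i] == component_of[j]:
            adj[i].append((j, float(w)))
            adj[j].append((i, float(w)))

    n_comp = component_of.max() + 1
    centers = np.full(n_comp, -1, dtype=int)
    visited = np.zeros(n, dtype=bool)
    for comp in range(n_comp):
        nodes = np.where(component_of == comp)[0]
        if len(nodes) == 1:
            centers[comp] = nodes[0]
            continue
        root = int(nodes[0])
        # pass 1: iterative post-order to get subtree sizes and S(root)
        order: list[int] = []
        par = {root: (-1, 0.0)}
        stack = [root]
        visited[root] = True
        s_root = 0.0
        depth = {root: 0.0}
        while stack:
            u = stack.pop()
            order.append(u)
            for v, w in adj[u]:
                if not visited[v]:
                    visited[v] = True
                    par[v] = (u, w)
                    depth[v] = depth[u] + w
                    s_root += depth[v]
                    stack.append(v)
        size = {u: 1 for u in order}
        for u in reversed(order):
            p, _ = par[u]
            if p >= 0:
                size[p] += size[u]
        # pass 2: re-root
        m = len(nodes)
        dist_sum = {root: s_root}
        for u in order:
            p, w = par[u]
            if p >= 0:
                dist_sum[u] = dist_sum[p] + (m - 2 * size[u]) * w
        best = min(dist_sum.values())
        tol = tie_rtol * max(abs(best), 1e-300)
        winners = [u for u in nodes if dist_sum[int(u)] <= best + tol]
        centers[comp] = min(winners)
    return centers


# ---------------------------------------------------------------------------
# density steps
# ---------------------------------------------------------------------------

def _nrd_bandwidth(values: np.ndarray) -> float:
    """Per-axis normal-reference scale: 1.06 * min(sd, IQR/1.349) (no m factor)."""
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    q75, q25 = np.percentile(values, [75, 25])
    iqr = float(q75 - q25) / 1.349
    candidates = [v for v in (sd, iqr) if v > 0]
    return 1.06 * min(candidates) if candidates else 0.0


def _species_bandwidth(centers: np.ndarray, cells: np.ndarray) -> np.ndarray:
    """Per-axis bandwidths from center nodes; dispersion falls back to the
    species' cells when a single center (or zero spread) degenerates the rule."""
    m = len(centers)
    factor = m ** (-1.0 / 5.0)
    out = np.empty(2)
    for ax in range(2):
        scale = _nrd_bandwidth(centers[:, ax]) if m > 1 else 0.0
        if scale <= 0:
            if m > 1:
                warnings.warn("zero-variance center set; bandwidth from cells",
                              stacklevel=3)
            scale = _nrd_bandwidth(cells[:, ax])
        if scale <= 0:  # species collapsed to a point
            scale = 1e-6 * max(1.0, float(np.abs(cells[:, ax]).max()))
        out[ax] = scale * factor
    return out


def weighted_density_map(
    centers: dict[str, np.ndarray],
    cells: dict[str, np.ndarray],
) -> dict[str, SpeciesDensityField]:
    """Per-species weighted KDE fields from center-node coordinates.

    ``centers[s]`` is the m_S x 2 array of center coordinates and
    ``cells[s]`` the n_S x 2 coordinates of all cells of species ``s`` (used
    for the cell-count weights and the bandwidth fallback).  Returns the
    fields ``w_S``; the combined map is ``D(x) = sum_S w_S(x)``.
    """
    if not centers or any(len(c) == 0 for c in centers.values()):
        raise ValueError("need at least one center per species")
    n_total = sum(len(c) for c in cells.values())
    fields = {}
    for s, cen in centers.items():
        cen = np.atleast_2d(np.asarray(cen, dtype=float))
        h = _species_bandwidth(cen, np.asarray(cells[s], dtype=float))
        weight = len(cen) * len(cells[s]) / n_total
        fields[s] = SpeciesDensityField(cen, h, weight)
    return fields


def density_grid(
    fields: dict[str, SpeciesDensityField],
    points: np.ndarray,
    grid_size: tuple[int, int] = (250, 250),
    margin: float = 0.05,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Combined density map ``D`` on a grid covering ``points`` with a margin.

    The grid exists for map output and plots; the statistic itself evaluates
    kernels at cell coordinates directly.  The margin is the larger of the
    requested fraction of each axis range and 4 bandwidths, so that each
    unit-mass KDE integrates to ~1 over the grid.
    """
    pts = np.asarray(points, dtype=float)
    hmax = max(f.bandwidth.max() for f in fields.values())
    gx, gy = grid_size
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    pad = np.maximum(margin * (hi - lo), 4.0 * hmax)
    xs = np.linspace(lo[0] - pad[0], hi[0] + pad[0], gx)
    ys = np.linspace(lo[1] - pad[1], hi[1] + pad[1], gy)
    xx, yy = np.meshgrid(xs, ys, indexing="ij")
    quer = np.column_stack([xx.ravel(), yy.ravel()])
    dd = sum(f.weighted(quer) for f in fields.values()).reshape(gx, gy)
    return xs, ys, dd


# ---------------------------------------------------------------------------
# the statistic
# ---------------------------------------------------------------------------

def overlap_statistic(
    embedding: LabeledEmbedding, config: OverlapConfig | None = None
) -> OverlapResult:
    """Distribution overlap of the two species in ``embedding``."""
    cfg = config or OverlapConfig()
    pts = embedding.coordinates
    if pts.shape[1] != 2:
        raise ValueError("overlap statistic is defined on 2D embeddings")
    labels = embedding.species
    uniq = pd_unique(labels)
    if len(uniq) != 2:
        raise ValueError(f"exactly two species required, got {uniq}")
    for s in uniq:
        if (labels == s).sum() < 2:
            raise ValueError(f"species {s!r} has fewer than 2 cells")
    reference = cfg.reference if cfg.reference is not None else uniq[0]
    if reference not in uniq:
        raise ValueError(f"reference species {reference!r} absent from embedding")

    edges = build_mst(pts)
    comp, k = split_subgraphs(edges, labels)
    center_nodes = component_centers(comp, edges, pts, tie_rtol=cfg.center_tie_rtol)

    centers: dict[str, np.ndarray] = {}
    cells: dict[str, np.ndarray] = {}
    center_idx: dict[str, np.ndarray] = {}
    for s in uniq:
        idx = center_nodes[np.isin(center_nodes, np.where(labels == s)[0])]
        center_idx[s] = idx
        centers[s] = pts[idx]
        cells[s] = pts[labels == s]

    fields = weighted_density_map(centers, cells)
    d_cells = sum(f.weighted(pts) for f in fields.values())

    z_self = float(d_cells[labels == reference].sum())
    if z_self <= 0:
        raise FloatingPointError(
            f"normalization sum over reference {reference!r} cells is zero "
            f"(k={k}, centers={[len(c) for c in centers.values()]})"
        )
    if cfg.mode == "self":
        v = d_cells / z_self
        vmax = float(v.max())
        scaled = v / vmax
    else:
        z_ref, max_ref = cfg.ref_scale
        v = d_cells / z_ref
        vmax = float(v.max())
        scaled = np.clip(v / max_ref, 0.0, 1.0)

    bins = np.minimum((scaled * cfg.n_bins).astype(int), cfg.n_bins - 1)
    props = np.bincount(bins, minlength=cfg.n_bins) / len(bins)
    overlap = 1.0 - props[0]

    return OverlapResult(
        edges=edges, n_removed=k, component_of=comp,
        centers=center_idx, fields=fields,
        density=d_cells / z_self, scaled_density=scaled,
        bin_proportions=props, overlap=float(overlap),
        z=z_self, vmax=float((d_cells / z_self).max()),
        config=cfg,
    )


class MSTOverlap(BaseEstimator):
    """sklearn-style wrapper: ``fit(X, y)`` with coordinates and species labels.

    Fitted attributes: ``overlap_``, ``overlap_pct_``, ``n_cross_edges_``,
    ``n_subgraphs_``, ``bin_proportions_``, ``scale_constants_``, ``result_``.
    """

    def __init__(self, n_bins: int = 500, mode: str = "self",
                 ref_scale: tuple[float, float] | None = None,
                 reference: str | None = None):
        self.n_bins = n_bins
        self.mode = mode
        self.ref_scale = ref_scale
        self.reference = reference

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        emb = LabeledEmbedding(
            np.arange(len(y)).astype(str), X, y, np.zeros(len(y), dtype=object)
        )
        cfg = OverlapConfig(n_bins=self.n_bins, mode=self.mode,
                            ref_scale=self.ref_scale, reference=self.reference)
        self.result_ = overlap_statistic(emb, cfg)
        self.overlap_ = self.result_.overlap
        self.overlap_pct_ = self.result_.overlap_pct
        self.n_cross_edges_ = self.result_.n_removed
        self.n_subgraphs_ = self.result_.n_subgraphs
        self.bin_proportions_ = self.result_.bin_proportions
        self.scale_constants_ = self.result_.scale_constants
        return self
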