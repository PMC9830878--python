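"""Ortholog-group aggregation and cross-species cluster matching.

Within each species, gene counts are summed into ortholog-group columns
("ortholog transcript abundance"), normalized per cell by the total ortholog
abundance times a scale factor, and averaged within clusters; clusters of two
species are then compared all-against-all by Pearson correlation over the
shared ortholog groups, with best-hit / mutual-best-hit calls.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CellMatrix, OrthoGroupMap

__all__ = [
    "OrthoMatrix",
    "ClusterCorrelationMatrix",
    "aggregate_orthogroups",
    "normalize_ortho",
    "cluster_profile_correlation",
    "mutual_best_hits",
    "assign_deo_modules",
]


@dataclass
class OrthoMatrix:
    """Cells x ortholog-groups summed counts for one species.

    Groups with no member gene detected in the species are absent.
    ``unmapped_genes`` records genes dropped for lack of a group.
    """

    counts: sp.csr_matrix
    cell_ids: np.ndarray
    group_ids: np.ndarray
    species: str = ""
    normalized: bool = False
    scale_factor: float = 1000.0
    unmapped_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.group_ids = np.asarray(self.group_ids, dtype=object)

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]


@dataclass
class ClusterCorrelationMatrix:
    """Pearson r between cluster mean ortholog profiles of two species."""

    r: pd.DataFrame                 # clusters of A x clusters of B
    excluded: list[tuple[str, str]]  # (species, cluster) excluded and why-free list
    shared_groups: np.ndarray


def aggregate_orthogroups(m: CellMatrix, map_: OrthoGroupMap) -> OrthoMatrix:
    """Sum each cell's gene counts within ortholog groups.

    Each group column equals the sum of its member genes' columns; genes not
    covered by the map are dropped and reported in ``unmapped_genes``.
    """
    gene_to_group = map_.gene_to_group(m.species)
    group_ids = sorted({gene_to_group[g] for g in m.gene_ids if g in gene_to_group})
    if not group_ids:
        raise ValueError(f"no gene of species {m.species!r} is covered by the map")
    group_pos = {g: i for i, g in enumerate(group_ids)}

    rows, cols = [], []
    unmapped = []
    for j, gene in enumerate(m.gene_ids):
        grp = gene_to_group.get(gene)
        if grp is None:
            unmapped.append(str(gene))
        else:
            rows.append(j)
            cols.append(group_pos[grp])
    # genes x groups indicator; counts @ indicator sums member columns
    ind = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(m.n_genes, len(group_ids))
    )
    return OrthoMatrix(
        sp.csr_matrix(m.counts @ ind), m.cell_ids, np.asarray(group_ids, dtype=object),
        species=m.species, unmapped_genes=unmapped,
    )


def normalize_ortho(om: OrthoMatrix, scale_factor: float = 1000.0) -> OrthoMatrix:
    """Per-cell total-ortholog-abundance normalization (after aggregation)."""
    totals = np.asarray(om.counts.sum(axis=1)).ravel().astype(float)
    inv = np.zeros_like(totals)
    nz = totals > 0
    inv[nz] = scale_factor / totals[nz]
    return OrthoMatrix(
        sp.csr_matrix(sp.diags(inv) @ om.counts), om.cell_ids, om.group_ids,
        species=om.species, normalized=True, scale_factor=scale_factor,
        unmapped_genes=om.unmapped_genes,
    )


def _cluster_means(om: OrthoMatrix, clusters: np.ndarray,
                   exclude: set[str], min_cells: int) -> tuple[pd.DataFrame, list[str]]:
    clusters = np.asarray(clusters)
    mat = om.counts if om.normalized else normalize_ortho(om).counts
    means: dict[str, np.ndarray] = {}
    dropped: list[str] = []
    for lab in pd.unique(clusters):
        lab_s = str(lab)
        mask = clusters == lab
        if lab_s in exclude:
            dropped.append(lab_s)
            continue
        if mask.sum() < min_cells:   # cluster-eligibility rule
            dropped.append(lab_s)
            continue
        means[lab_s] = np.asarray(mat[mask].mean(axis=0)).ravel()
    return pd.DataFrame(means, index=om.group_ids), dropped


def cluster_profile_correlation(
    a: OrthoMatrix, clusters_a: np.ndarray,
    b: OrthoMatrix, clusters_b: np.ndarray,
    exclude: list[str] | None = None,
    min_cells: int = 5,
) -> ClusterCorrelationMatrix:
    """All-against-all Pearson r between cluster mean ortholog profiles.

    Profiles are per-cluster means of normalized ortholog abundance over the
    ortholog groups shared by both species.  Named clusters in ``exclude``
    and clusters below ``min_cells`` cells are left out (recorded).
    """
    excl = set(exclude or [])
    shared = np.asarray(
        sorted(set(map(str, a.group_ids)) & set(map(str, b.group_ids))), dtype=object
    )
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared ortholog groups; need >= 3")

    prof_a, drop_a = _cluster_means(a, clusters_a, excl, min_cells)
    prof_b, drop_b = _cluster_means(b, clusters_b, excl, min_cells)
    A = prof_a.loc[shared].to_numpy(dtype=float)   # groups x clusters(A)
    B = prof_b.loc[shared].to_numpy(dtype=float)

    Ac = A - A.mean(axis=0, keepdims=True)
    Bc = B - B.mean(axis=0, keepdims=True)
    sd_a = np.sqrt((Ac**2).sum(axis=0))
    sd_b = np.sqrt((Bc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Ac.T @ Bc) / np.outer(sd_a, sd_b)
    if np.any(sd_a == 0) or np.any(sd_b == 0):
        warnings.warn("constant cluster profile; correlations set to NaN", stacklevel=2)

    excluded = [(a.species, c) for c in drop_a] + [(b.species, c) for c in drop_b]
    return ClusterCorrelationMatrix(
        pd.DataFrame(r, index=prof_a.columns, columns=prof_b.columns), excluded, shared
    )


def mutual_best_hits(c: ClusterCorrelationMatrix) -> pd.DataFrame:
    """Best hit per row and per column, with a mutual flag.

    Returns one row per species-A cluster: its best species-B hit, the r, a
    ``mutual`` flag (argmaxes reciprocate) and a ``tie`` flag (exact ties,
    broken by label order).
    """
    r = c.r
    if r.empty:
        raise ValueError("empty correlation matrix")
    rows = []
    col_best = {col: r[col].idxmax() for col in r.columns}
    for idx in r.index:
        series = r.loc[idx]
        best = series.max()
        winners = [col for col in r.columns if series[col] == best]
        hit = winners[0]
        rows.append({
            "cluster_a": idx,
            "cluster_b": hit,
            "r": best,
            "mutual": col_best[hit] == idx,
            "tie": len(winners) > 1,
        })
    return pd.DataFrame(rows)


def assign_deo_modules(
    deo: dict[str, list[str]],
    cluster_modules: dict[str, int],
    log2_fc: dict[str, pd.Series] | None = None,
) -> pd.DataFrame:
    """Assign each differentially expressed ortholog group to one module.

    ``deo`` maps integrated-cluster id -> list of DEO group ids;
    ``cluster_modules`` maps cluster id -> module number (1-8).  An ortholog
    group differentially expressed in several clusters goes to the cluster
    where its log2 fold-change is largest (``log2_fc``: per-cluster series
    indexed by group id); without fold-change information such a group is
    left unresolved and flagged.
    """
    unknown = set(deo) - set(cluster_modules)
    if unknown:
        raise ValueError(f"clusters without a declared module: {sorted(unknown)}")
    membership: dict[str, list[str]] = {}
    for cluster, groups in deo.items():
        for g in groups:
            membership.setdefault(g, []).append(cluster)

    rows = []
    for g, clusters in sorted(membership.items()):
        if len(clusters) == 1:
            winner, resolved = clusters[0], True
        elif log2_fc is not None and all(
            c in log2_fc and g in log2_fc[c].index for c in clusters
        ):
            winner = max(clusters, key=lambda c: (log2_fc[c][g], c))
            resolved = True
        else:
            winner, resolved = None, False
        rows.append({
            "group_id": g,
            "cluster": winner,
            "module": cluster_modules[winner] if resolved else None,
            "resolved": resolved,
        })
    return pd.DataFrame(rows).set_index("group_id")
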