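"""Anchoring single-cell clusters to LCM bulk cell types.

Each cell's normalized expression vector is correlated (Pearson) against the
mean TPM profile of every LCM-captured cell type over the genes shared by the
two datasets; clusters are annotated to the cell type with the highest mean
correlation.  ``lcm_up_genes`` reproduces the bulk-side up-gene rule (mean
TPM floor plus a fold-change margin against *every* other cell type) and
``scup_lcmup_intersect`` forms the scUPlcmUP sets: genes upregulated in a
cluster and in its matched LCM cell type.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .de import DegCall
from .io import LcmProfile
from .normalize import NormalizedMatrix

__all__ = [
    "CellTypeCorrelation",
    "LcmUpSet",
    "correlate_cells_to_types",
    "annotate_clusters",
    "lcm_up_genes",
    "scup_lcmup_intersect",
]


@dataclass
class CellTypeCorrelation:
    """Pearson r between every cell and every LCM cell type."""

    r: pd.DataFrame              # cells x cell types
    shared_genes: np.ndarray
    constant_cells: np.ndarray   # cell ids with zero-variance vectors (r = NaN)


@dataclass
class LcmUpSet:
    """Per-cell-type bulk up-genes with the thresholds that defined them."""

    cell_type: str
    genes: set[str]
    min_tpm: float
    min_lfc: float
    log2_fc: pd.DataFrame | None = None  # focal vs each other type, for reporting


def correlate_cells_to_types(
    nm: NormalizedMatrix, lcm: LcmProfile, log_space: bool = False
) -> CellTypeCorrelation:
    """Per-cell Pearson correlation with each LCM cell type's mean TPM.

    Computed over the gene intersection of the two datasets.  By default both
    sides enter linearly (normalized UMI vs mean TPM); ``log_space`` applies
    log2(x+1) to both sides first.
    """
    shared = np.asarray(
        sorted(set(map(str, nm.gene_ids)) & set(map(str, lcm.gene_ids))), dtype=object
    )
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared genes; need >= 3")

    sc_idx = pd.Index(nm.gene_ids).get_indexer(shared)
    X = nm.dense()[:, sc_idx]                       # cells x shared genes
    T = lcm.mean.loc[shared].to_numpy(dtype=float)  # shared genes x types
    if log_space:
        X = np.log2(X + 1.0)
        T = np.log2(T + 1.0)

    Xc = X - X.mean(axis=1, keepdims=True)
    Tc = T - T.mean(axis=0, keepdims=True)
    x_sd = np.sqrt((Xc**2).sum(axis=1))
    t_sd = np.sqrt((Tc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ Tc) / np.outer(x_sd, t_sd)
    constant = x_sd == 0
    r[constant] = np.nan
    if np.any(t_sd == 0):
        warnings.warn("constant LCM profile over shared genes; r set to NaN", stacklevel=2)

    return CellTypeCorrelation(
        pd.DataFrame(r, index=nm.cell_ids, columns=lcm.cell_types),
        shared,
        np.asarray(nm.cell_ids)[constant],
    )


def annotate_clusters(corr: CellTypeCorrelation, clusters: np.ndarray) -> pd.DataFrame:
    """Best-hit cell type per cluster from mean per-type correlation.

    Returns a table indexed by cluster with the per-type mean r, the argmax
    ``cell_type`` ("undetermined" if every correlation in the cluster is
    NaN), and a ``tie`` flag (exact ties broken by declared type order).
    """
    clusters = np.asarray(clusters)
    if len(clusters) != len(corr.r):
        raise ValueError("cluster labels are not aligned with the correlation matrix")
    rows = []
    for lab in pd.unique(clusters):
        mean_r = corr.r[clusters == lab].mean(axis=0, skipna=True)
        if mean_r.isna().all():
            rows.append({"cluster": lab, "cell_type": "undetermined", "tie": False,
                         **{f"mean_r_{t}": np.nan for t in corr.r.columns}})
            continue
        best = mean_r.max()
        winners = [t for t in corr.r.columns if mean_r[t] == best]
        rows.append({
            "cluster": lab,
            "cell_type": winners[0],           # declared type order breaks ties
            "tie": len(winners) > 1,
            **{f"mean_r_{t}": mean_r[t] for t in corr.r.columns},
        })
    return pd.DataFrame(rows).set_index("cluster")


def lcm_up_genes(
    lcm: LcmProfile,
    focal: str,
    min_tpm: float = 4.0,
    min_lfc: float = 1.0,
    pseudocount: float = 1.0,
    adjusted_p: pd.Series | None = None,
    alpha: float = 0.05,
) -> LcmUpSet:
    """Bulk up-genes of ``focal``: mean TPM above the floor and log2FC >=
    ``min_lfc`` against *every* other cell type.

    Fold-changes are computed on mean TPM with a pseudocount.  If an
    externally computed ``adjusted_p`` series is supplied (e.g. from a bulk
    DE tool), genes must additionally satisfy ``adjusted_p < alpha``.
    """
    if focal not in lcm.cell_types:
        raise ValueError(f"cell type {focal!r} absent from profile")
    if len(lcm.cell_types) < 3:
        raise ValueError("need >= 3 cell types for the contrast design")
    mean = lcm.mean
    others = [t for t in lcm.cell_types if t != focal]
    lfc = pd.DataFrame({
        t: np.log2(mean[focal] + pseudocount) - np.log2(mean[t] + pseudocount)
        for t in others
    })
    keep = (mean[focal] > min_tpm) & (lfc >= min_lfc).all(axis=1)
    if adjusted_p is not None:
        keep &= adjusted_p.reindex(mean.index) < alpha
    return LcmUpSet(focal, set(mean.index[keep]), min_tpm, min_lfc, log2_fc=lfc)


def scup_lcmup_intersect(
    sc_up: dict[str, DegCall],
    lcm_up: dict[str, LcmUpSet],
    mapping: dict[str, str],
    gene_universe: set[str] | None = None,
) -> dict[str, set[str]]:
    """Per matched (cluster, cell type) pair, scUP ∩ lcmUP gene sets.

    ``mapping`` sends cluster -> annotated LCM cell type.  Clusters without a
    mapping (or mapped to a type without a bulk up-set) are skipped with a
    warning.  If given, ``gene_universe`` (genes present in both datasets)
    restricts the result.
    """
    out: dict[str, set[str]] = {}
    for cluster, call in sc_up.items():
        ct = mapping.get(cluster)
        if ct is None or ct not in lcm_up:
            warnings.warn(f"cluster {cluster!r} has no LCM match; skipped", stacklevel=2)
            continue
        inter = call.up & lcm_up[ct].genes
        if gene_universe is not None:
            inter &= gene_universe
        out[cluster] = inter
    return out
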