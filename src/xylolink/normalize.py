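"""Per-cell normalization of UMI counts.

Each cell's counts are divided by its total UMI count and multiplied by a
scale factor (default 1000), so every non-empty cell row sums to the scale
factor; all-zero cells stay all-zero.  A log2(x + pseudocount) transform is
applied separately, for plotting and log-space analyses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import StateError
from .io import CellMatrix

__all__ = ["NormalizedMatrix", "normalize_counts", "log_transform", "CountNormalizer"]


@dataclass
class NormalizedMatrix:
    """Cells x genes matrix of normalized (optionally log2) UMI counts."""

    values: sp.csr_matrix
    cell_ids: np.ndarray
    gene_ids: np.ndarray
    scale_factor: float = 1000.0
    log_transformed: bool = False
    pseudocount: float = 1.0
    species: str = ""

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values, dtype=float)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    def dense(self) -> np.ndarray:
        return np.asarray(self.values.todense())


def normalize_counts(m: CellMatrix, scale_factor: float = 1000.0) -> NormalizedMatrix:
    """Total-count normalization: cell row / row total * ``scale_factor``."""
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    totals = m.total_counts().astype(float)
    inv = np.zeros_like(totals)
    nz = totals > 0
    inv[nz] = scale_factor / totals[nz]  # all-zero cells stay all-zero
    values = sp.diags(inv) @ m.counts
    return NormalizedMatrix(
        values, m.cell_ids, m.gene_ids, scale_factor=scale_factor, species=m.species
    )


def log_transform(nm: NormalizedMatrix, pseudocount: float = 1.0) -> NormalizedMatrix:
    """Entry-wise ``log2(v + pseudocount)`` (monotone; 0 -> 0 when pseudocount=1)."""
    if nm.log_transformed:
        raise StateError("matrix is already log-transformed")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    dense = nm.dense()
    out = np.log2(dense + pseudocount)
    if pseudocount == 1.0:
        out[dense == 0] = 0.0  # keep exact zeros sparse-friendly
    return NormalizedMatrix(
        sp.csr_matrix(out), nm.cell_ids, nm.gene_ids,
        scale_factor=nm.scale_factor, log_transformed=True,
        pseudocount=pseudocount, species=nm.species,
    )


class CountNormalizer(TransformerMixin, BaseEstimator):
    """sklearn-style transformer wrapping :func:`normalize_counts`.

    Parameters
    ----------
    scale_factor : float, default=1000
        Target row sum after normalization.
    log : bool, default=False
        Apply log2(x + pseudocount) after scaling.
    pseudocount : float, default=1
        Offset used when ``log`` is enabled.

    The transformer is stateless: ``fit`` only validates parameters, each
    cell supplies its own size factor.
    """

    def __init__(self, scale_factor: float = 1000.0, log: bool = False,
                 pseudocount: float = 1.0):
        self.scale_factor = scale_factor
        self.log = log
        self.pseudocount = pseudocount

    def fit(self, X, y=None):
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        """Normalize a cells x genes array (dense or sparse) row-wise."""
        X = sp.csr_matrix(X, dtype=float)
        totals = np.asarray(X.sum(axis=1)).ravel()
        inv = np.zeros_like(totals)
        nz = totals > 0
        inv[nz] = self.scale_factor / totals[nz]
        out = np.asarray((sp.diags(inv) @ X).todense())
        if self.log:
            out = np.log2(out + self.pseudocount)
            if self.pseudocount == 1.0:
                out[out < 0] = 0.0
        return out
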