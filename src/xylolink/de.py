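"""Negative-binomial exact test with dispersion shrinkage (sSeq style).

The per-cluster differential-expression route mirrors the droplet-pipeline
convention: library-size factors ``s_i = total_i / median(total)``, a
method-of-moments gene-wise dispersion estimated on size-factor-normalized
counts, shrinkage of those dispersions toward a high quantile of their
across-gene distribution, and a two-sided exact test on the split of each
gene's pooled count between the two groups, conditional on the total.  For
genes whose summed counts exceed ``big_count`` (default 900) in *both*
groups, the exact enumeration is replaced by the asymptotic beta
approximation to the conditional split (edgeR-style, with a 0.5 continuity
correction).  P values are corrected across genes by Benjamini-Hochberg.

Shrinkage plug-in
-----------------
With per-gene MoM dispersions ``phi_g = max(0, (var - mean) / mean^2)`` over
the genes with positive mean, the shrinkage target is the ``zeta_quantile``
(default 0.995) quantile ``zeta`` of the ``phi_g``, and the weight is the
MSE-minimizing plug-in

    delta = [sum((phi_g - mean(phi))^2) / (G - 1)]
          / [sum((phi_g - zeta)^2)   / (G - 2)]

clipped to [0, 1]; the shrunk dispersion is
``phi~_g = delta * zeta + (1 - delta) * phi_g``.  When the denominator
degenerates (G < 3 or all dispersions equal the target) ``delta = 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from scipy.special import logsumexp

from .io import CellMatrix

__all__ = [
    "SSeqParams",
    "DeResult",
    "DegCall",
    "estimate_size_factors",
    "compute_sseq_params",
    "nb_exact_test",
    "nb_asymptotic_test",
    "sseq_exact_test",
    "bh_adjust",
    "call_degs",
    "one_vs_rest_degs",
]

#: per-group summed count above which (in both groups) the exact enumeration
#: switches to the asymptotic beta approximation
BIG_COUNT = 900

#: relative tie tolerance when summing split probabilities <= the observed one
#: (the convention used by classical exact two-sided tests)
_TIE_REL_TOL = 1e-7


@dataclass
class SSeqParams:
    """Global quantities shared by every gene's test."""

    size_factors: np.ndarray      # per cell, total / median total
    mean_g: np.ndarray            # per gene, mean of normalized counts
    var_g: np.ndarray             # per gene, sample variance of normalized counts
    phi_mm_g: np.ndarray          # per gene, MoM dispersion
    zeta_hat: float               # shrinkage target
    delta: float                  # shrinkage weight
    phi_g: np.ndarray             # per gene, shrunk dispersion


def estimate_size_factors(counts: sp.spmatrix | np.ndarray) -> np.ndarray:
    """Cell size factors: total counts divided by the median total."""
    totals = np.asarray(counts.sum(axis=1)).ravel().astype(float)
    med = np.median(totals)
    if med <= 0:
        raise ValueError("median cell total is zero; filter empty cells first")
    return totals / med


def compute_sseq_params(
    counts: sp.spmatrix | np.ndarray, zeta_quantile: float = 0.995
) -> SSeqParams:
    """Size factors and shrunk gene-wise dispersions for the exact test."""
    X = sp.csr_matrix(counts, dtype=float)
    n, g = X.shape
    size_factors = estimate_size_factors(X)
    inv = sp.diags(1.0 / size_factors)
    Y = inv @ X  # size-factor-normalized counts
    mean_g = np.asarray(Y.mean(axis=0)).ravel()
    mean_sq = np.asarray(Y.multiply(Y).mean(axis=0)).ravel()
    # sample variance (ddof=1)
    var_g = (mean_sq - mean_g**2) * n / max(n - 1, 1)
    var_g = np.maximum(var_g, 0.0)

    use = mean_g > 0
    phi_mm = np.zeros(g)
    phi_mm[use] = np.maximum(0.0, (var_g[use] - mean_g[use]) / mean_g[use] ** 2)

    if use.sum() >= 3:
        phi_use = phi_mm[use]
        zeta_hat = float(np.quantile(phi_use, zeta_quantile))
        gu = phi_use.size
        num = np.sum((phi_use - phi_use.mean()) ** 2) / (gu - 1)
        den = np.sum((phi_use - zeta_hat) ** 2) / (gu - 2)
        delta = 1.0 if den <= 0 or not np.isfinite(den) else float(np.clip(num / den, 0.0, 1.0))
    else:  # too few informative genes: full shrinkage to whatever target exists
        zeta_hat = float(phi_mm[use].mean()) if use.any() else 0.0
        delta = 1.0

    phi_g = delta * zeta_hat + (1.0 - delta) * phi_mm
    phi_g[~use] = 0.0
    return SSeqParams(size_factors, mean_g, var_g, phi_mm, zeta_hat, delta, phi_g)


# ---------------------------------------------------------------------------
# per-gene tests
# ---------------------------------------------------------------------------

def _nb_logpmf(k: np.ndarray | int, mean: float, phi: float) -> np.ndarray:
    """log pmf of NB with mean ``mean`` and dispersion ``phi`` (var = m + phi m^2).

    ``phi = 0`` is the Poisson limit.
    """
    if phi <= 0:
        return stats.poisson.logpmf(k, mean)
    r = 1.0 / phi
    p = 1.0 / (1.0 + phi * mean)
    return stats.nbinom.logpmf(k, r, p)


def nb_exact_test(x_a: int, x_b: int, s_a: float, s_b: float,
                  mu: float, phi: float) -> float:
    """Two-sided exact NB test on the split of ``x_a + x_b`` between groups.

    Group sums are modeled NB(mean = s * mu, dispersion = phi / s).  The
    p-value sums the probabilities of every split no more likely than the
    observed one, normalized by the total probability over all splits
    (conditioning on the pooled count).
    """
    total = int(x_a + x_b)
    if total == 0:
        return 1.0
    ks = np.arange(total + 1)
    log_a = _nb_logpmf(ks, s_a * mu, phi / s_a)
    log_b = _nb_logpmf(total - ks, s_b * mu, phi / s_b)
    log_all = log_a + log_b
    log_obs = log_all[int(x_a)]
    more_extreme = log_all <= log_obs + _TIE_REL_TOL * abs(log_obs)
    p = np.exp(logsumexp(log_all[more_extreme]) - logsumexp(log_all))
    return float(min(p, 1.0))


def nb_asymptotic_test(x_a: int, x_b: int, s_a: float, s_b: float,
                       mu: float, phi: float) -> float:
    """Beta approximation to the conditional split (edgeR-style, two-sided).

    Conditional on the total, ``x_a / total`` is approximately
    Beta(alpha_a, alpha_b) with ``alpha = s * mu / (1 + phi * mu)``; the
    two-sided p doubles the smaller tail with a 0.5 continuity correction.
    """
    total = x_a + x_b
    if total == 0:
        return 1.0
    alpha_a = s_a * mu / (1.0 + phi * mu)
    alpha_b = s_b * mu / (1.0 + phi * mu)
    median = stats.beta.median(alpha_a, alpha_b)
    if (x_a + 0.5) / total < median:
        p = 2.0 * stats.beta.cdf((x_a + 0.5) / total, alpha_a, alpha_b)
    else:
        p = 2.0 * stats.beta.sf((x_a - 0.5) / total, alpha_a, alpha_b)
    return float(min(p, 1.0))


# ---------------------------------------------------------------------------
# results containers
# ---------------------------------------------------------------------------

@dataclass
class DeResult:
    """Per-gene differential-expression table plus the global test quantities."""

    table: pd.DataFrame           # gene_id, mean_a, mean_b, log2_fc, p_value,
                                  # p_adjusted, test_used
    n_a: int
    n_b: int
    params: SSeqParams

    def __post_init__(self) -> None:
        p = self.table["p_value"].to_numpy()
        ok = ~np.isnan(p)
        if np.any((p[ok] < 0) | (p[ok] > 1)):
            raise ValueError("p-values outside [0, 1]")


@dataclass
class DegCall:
    """Thresholded DEG sets for one comparison."""

    up: set[str]
    down: set[str]
    alpha: float
    min_lfc: float
    eligible: bool = True
    ineligible_reason: str | None = field(default=None)

    @property
    def genes(self) -> set[str]:
        return self.up | self.down


# ---------------------------------------------------------------------------
# the test proper
# ---------------------------------------------------------------------------

def sseq_exact_test(
    m: CellMatrix,
    group_a: np.ndarray,
    group_b: np.ndarray,
    big_count: int = BIG_COUNT,
    zeta_quantile: float = 0.995,
    lfc_pseudocount: float = 1.0,
) -> DeResult:
    """Two-group differential expression over all genes of ``m``.

    ``group_a`` / ``group_b`` are disjoint boolean masks or index arrays over
    the cells of ``m``.  Genes with zero counts in both groups are marked
    ``skipped`` (p = NaN) and excluded from the BH correction.  log2
    fold-changes are computed on size-factor-normalized group means with a
    pseudocount.
    """
    mask_a = np.zeros(m.n_cells, dtype=bool)
    mask_a[np.asarray(group_a)] = True
    mask_b = np.zeros(m.n_cells, dtype=bool)
    mask_b[np.asarray(group_b)] = True
    if not mask_a.any() or not mask_b.any():
        raise ValueError("both groups must contain at least one cell")
    if (mask_a & mask_b).any():
        raise ValueError("groups must be disjoint")

    both = mask_a | mask_b
    sub = sp.csr_matrix(m.counts[both], dtype=float)
    in_a = mask_a[both]
    params = compute_sseq_params(sub, zeta_quantile=zeta_quantile)
    s = params.size_factors
    s_a, s_b = float(s[in_a].sum()), float(s[~in_a].sum())

    A = sub[in_a]
    B = sub[~in_a]
    sum_a = np.asarray(A.sum(axis=0)).ravel()
    sum_b = np.asarray(B.sum(axis=0)).ravel()
    norm_mean_a = np.asarray((sp.diags(1.0 / s[in_a]) @ A).mean(axis=0)).ravel()
    norm_mean_b = np.asarray((sp.diags(1.0 / s[~in_a]) @ B).mean(axis=0)).ravel()
    log2_fc = np.log2(lfc_pseudocount + norm_mean_a) - np.log2(lfc_pseudocount + norm_mean_b)

    g = sub.shape[1]
    pvals = np.full(g, np.nan)
    test_used = np.full(g, "skipped", dtype=object)
    for j in range(g):
        xa, xb = int(round(sum_a[j])), int(round(sum_b[j]))
        if xa + xb == 0:
            continue
        mu = (xa + xb) / (s_a + s_b)
        phi = float(params.phi_g[j])
        if xa > big_count and xb > big_count:
            pvals[j] = nb_asymptotic_test(xa, xb, s_a, s_b, mu, phi)
            test_used[j] = "asymptotic_beta"
        else:
            pvals[j] = nb_exact_test(xa, xb, s_a, s_b, mu, phi)
            test_used[j] = "nb_exact"

    table = pd.DataFrame({
        "gene_id": m.gene_ids,
        "mean_a": norm_mean_a,
        "mean_b": norm_mean_b,
        "log2_fc": log2_fc,
        "p_value": pvals,
        "p_adjusted": bh_adjust(pvals),
        "test_used": test_used,
    })
    return DeResult(table, n_a=int(mask_a.sum()), n_b=int(mask_b.sum()), params=params)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; NaNs pass through untouched.

    NaN entries (skipped genes) do not count toward ``m``.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    vals = p[ok]
    if np.any((vals < 0) | (vals > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = vals.size
    if m == 0:
        return out
    order = np.argsort(vals, kind="stable")
    ranked = vals[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    res = np.empty(m)
    res[order] = adjusted
    out[ok] = res
    return out


def call_degs(de: DeResult, alpha: float = 0.05, min_lfc: float = 1.0,
              min_cells: int = 5) -> DegCall:
    """Apply the DEG cutoffs: adjusted p < ``alpha`` and |log2FC| >= ``min_lfc``.

    A focal group with fewer than ``min_cells`` cells is ineligible and
    yields an empty call (cluster-eligibility rule).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    if de.n_a < min_cells:
        return DegCall(set(), set(), alpha, min_lfc, eligible=False,
                       ineligible_reason=f"group has {de.n_a} < {min_cells} cells")
    t = de.table
    sig = (t["p_adjusted"] < alpha) & (t["log2_fc"].abs() >= min_lfc)
    up = set(t.loc[sig & (t["log2_fc"] > 0), "gene_id"])
    down = set(t.loc[sig & (t["log2_fc"] < 0), "gene_id"])
    return DegCall(up, down, alpha, min_lfc)


def one_vs_rest_degs(
    m: CellMatrix,
    clusters: np.ndarray,
    alpha: float = 0.05,
    min_lfc: float = 1.0,
    min_cells: int = 5,
    big_count: int = BIG_COUNT,
) -> dict:
    """Per-cluster DEGs: each cluster tested against all remaining cells.

    Returns ``{cluster: (DegCall, DeResult)}``; clusters below the cell floor
    get an ineligible empty call with ``DeResult = None``.
    """
    clusters = np.asarray(clusters)
    labels = pd.unique(clusters)
    if len(labels) < 2:
        raise ValueError("need at least two clusters")
    out: dict = {}
    for lab in labels:
        inside = clusters == lab
        if inside.sum() < min_cells:
            out[lab] = (
                DegCall(set(), set(), alpha, min_lfc, eligible=False,
                        ineligible_reason=f"cluster has {int(inside.sum())} < {min_cells} cells"),
                None,
            )
            continue
        de = sseq_exact_test(m, np.where(inside)[0], np.where(~inside)[0],
                             big_count=big_count)
        out[lab] = (call_degs(de, alpha=alpha, min_lfc=min_lfc, min_cells=min_cells), de)
    return out


def write_de_table(de: DeResult, path) -> None:
    """Write the DE table as TSV (gene id, group means, log2FC, p, adjusted p)."""
    de.table.to_csv(path, sep="\t", index=False)
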