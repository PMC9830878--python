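"""Normalization, the NB exact test, BH correction and DEG calling."""

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings, strategies as st
from scipy import stats
from statsmodels.stats.multitest import multipletests

from xylolink.de import (
    bh_adjust,
    call_degs,
    compute_sseq_params,
    estimate_size_factors,
    nb_asymptotic_test,
    nb_exact_test,
    one_vs_rest_degs,
    sseq_exact_test,
)
from xylolink.errors import StateError
from xylolink.normalize import CountNormalizer, log_transform, normalize_counts

from .conftest import make_cell_matrix


class TestNormalize:
    def test_stated_formula(self):
        m = make_cell_matrix([[2, 3, 5]])
        nm = normalize_counts(m, scale_factor=1000)
        assert np.allclose(nm.dense(), [[200, 300, 500]])

    def test_zero_cell_stays_zero(self):
        nm = normalize_counts(make_cell_matrix([[0, 0], [1, 1]]))
        dense = nm.dense()
        assert np.all(dense[0] == 0) and np.all(np.isfinite(dense))

    def test_row_sums_equal_scale_factor(self, rng):
        m = make_cell_matrix(rng.poisson(4, size=(20, 30)) + 1)
        nm = normalize_counts(m)
        assert np.allclose(nm.dense().sum(axis=1), 1000.0, rtol=1e-9)

    def test_log_transform_values_and_monotonicity(self):
        nm = normalize_counts(make_cell_matrix([[2, 3, 5], [1, 0, 9]]))
        lg = log_transform(nm, pseudocount=1.0)
        dense = lg.dense()
        assert dense[0, 0] == pytest.approx(np.log2(201), abs=1e-9)
        assert dense[1, 1] == 0.0
        flat_raw = nm.dense().ravel()
        flat_log = dense.ravel()
        order = np.argsort(flat_raw)
        assert np.all(np.diff(flat_log[order]) >= -1e-12)

    def test_double_log_rejected(self):
        nm = log_transform(normalize_counts(make_cell_matrix([[1, 2]])))
        with pytest.raises(StateError):
            log_transform(nm)

    def test_transformer_matches_function(self, rng):
        counts = rng.poisson(3, size=(10, 8))
        est = CountNormalizer().fit(counts)
        m = make_cell_matrix(counts)
        assert np.allclose(est.transform(counts), normalize_counts(m).dense())


class TestSizeFactorsAndDispersion:
    def test_size_factors_median_one(self, rng):
        counts = rng.poisson(5, size=(31, 20)) + 1
        s = estimate_size_factors(sp.csr_matrix(counts))
        assert np.median(s) == pytest.approx(1.0)

    def test_poisson_data_shrinks_to_small_dispersion(self, rng):
        counts = rng.poisson(8, size=(200, 300))
        params = compute_sseq_params(sp.csr_matrix(counts))
        assert np.median(params.phi_g) < 0.05

    def test_delta_within_unit_interval(self, rng):
        counts = rng.negative_binomial(5, 0.5, size=(80, 120))
        params = compute_sseq_params(sp.csr_matrix(counts))
        assert 0.0 <= params.delta <= 1.0


class TestExactTest:
    def test_poisson_limit_equals_binomial_enumeration(self):
        """With zero dispersion and equal size factors the conditional split
        is Binomial(total, 1/2); enumeration oracle for pooled counts <= 30."""
        worst = 0.0
        for total in range(1, 31):
            pmf = stats.binom.pmf(np.arange(total + 1), total, 0.5)
            for x_a in range(total + 1):
                mine = nb_exact_test(x_a, total - x_a, 1.0, 1.0, total / 2.0, 0.0)
                oracle = float(pmf[pmf <= pmf[x_a] * (1 + 1e-7)].sum())
                worst = max(worst, abs(mine - min(oracle, 1.0)))
        assert worst < 1e-10

    def test_poisson_limit_unequal_size_factors(self):
        """Unequal size factors give Binomial(total, s_a/(s_a+s_b))."""
        s_a, s_b = 2.0, 1.0
        for total in (5, 12, 23):
            pmf = stats.binom.pmf(np.arange(total + 1), total, s_a / (s_a + s_b))
            for x_a in (0, total // 2, total):
                mine = nb_exact_test(x_a, total - x_a, s_a, s_b,
                                     total / (s_a + s_b), 0.0)
                oracle = float(pmf[pmf <= pmf[x_a] * (1 + 1e-7)].sum())
                assert mine == pytest.approx(min(oracle, 1.0), abs=1e-10)

    def test_identical_groups_are_null(self, rng):
        counts = np.vstack([rng.poisson(5, size=(10, 6))] * 2)
        m = make_cell_matrix(counts)
        de = sseq_exact_test(m, np.arange(10), np.arange(10, 20))
        assert np.allclose(de.table["log2_fc"], 0.0, atol=1e-12)
        assert np.allclose(de.table["p_value"].dropna(), 1.0, atol=1e-9)

    def test_antisymmetry_under_group_swap(self, rng):
        counts = rng.negative_binomial(2, 0.3, size=(40, 25))
        m = make_cell_matrix(counts)
        a, b = np.arange(15), np.arange(15, 40)
        de_ab = sseq_exact_test(m, a, b)
        de_ba = sseq_exact_test(m, b, a)
        assert np.allclose(de_ab.table["log2_fc"], -de_ba.table["log2_fc"])
        pa, pb = de_ab.table["p_value"], de_ba.table["p_value"]
        assert np.allclose(pa.fillna(-1), pb.fillna(-1), rtol=1e-9)

    def test_invariant_to_gene_reordering(self, rng):
        counts = rng.poisson(4, size=(30, 12))
        m = make_cell_matrix(counts)
        perm = rng.permutation(12)
        m_perm = make_cell_matrix(counts[:, perm], prefix="p")
        a, b = np.arange(15), np.arange(15, 30)
        p1 = sseq_exact_test(m, a, b).table["p_value"].to_numpy()
        p2 = sseq_exact_test(m_perm, a, b).table["p_value"].to_numpy()
        assert np.allclose(p1[perm], p2, equal_nan=True)

    def test_null_type_one_error_rate(self):
        """NB(mean 5, dispersion 0.1), 50 vs 50 cells, 2000 genes: raw
        p < 0.05 in [0.03, 0.07]."""
        rng = np.random.default_rng(7)
        counts = rng.negative_binomial(10, 10 / 15, size=(100, 2000))
        m = make_cell_matrix(counts)
        de = sseq_exact_test(m, np.arange(50), np.arange(50, 100))
        frac = float((de.table["p_value"] < 0.05).mean())
        assert 0.03 <= frac <= 0.07

    def test_power_for_planted_fourfold(self):
        """4-fold changes planted in 20 of 200 genes (mean 10, dispersion 0.1,
        50 vs 50 cells) are detected with power > 0.8 at the DEG cutoffs."""
        rng = np.random.default_rng(21)
        counts = rng.negative_binomial(10, 10 / 20.0, size=(100, 200))  # mean 10
        counts[:50, :20] = rng.negative_binomial(10, 10 / 50.0, size=(50, 20))  # mean 40
        m = make_cell_matrix(counts)
        de = sseq_exact_test(m, np.arange(50), np.arange(50, 100))
        sig = (de.table["p_adjusted"] < 0.05) & (de.table["log2_fc"].abs() >= 1)
        assert sig[:20].mean() > 0.8

    def test_big_count_switch_uses_beta(self, rng):
        counts = rng.poisson(60, size=(40, 3))  # group sums ~ 1200 > 900
        m = make_cell_matrix(counts)
        de = sseq_exact_test(m, np.arange(20), np.arange(20, 40))
        assert set(de.table["test_used"]) == {"asymptotic_beta"}
        # beta approximation stays close to the exact enumeration here
        for j in range(3):
            xa = counts[:20, j].sum()
            xb = counts[20:, j].sum()
            exact = nb_exact_test(xa, xb, 20.0, 20.0, (xa + xb) / 40.0, 0.01)
            approx = nb_asymptotic_test(xa, xb, 20.0, 20.0, (xa + xb) / 40.0, 0.01)
            assert approx == pytest.approx(exact, abs=0.05)

    def test_zero_gene_skipped(self):
        m = make_cell_matrix([[0, 1], [0, 2], [0, 3], [0, 4]])
        de = sseq_exact_test(m, np.arange(2), np.arange(2, 4))
        assert de.table.loc[0, "test_used"] == "skipped"
        assert np.isnan(de.table.loc[0, "p_value"])

    def test_empty_group_rejected(self):
        m = make_cell_matrix([[1], [2]])
        with pytest.raises(ValueError):
            sseq_exact_test(m, np.arange(2), np.array([], dtype=int))


class TestBH:
    def test_hand_worked_example(self):
        out = bh_adjust(np.array([0.01, 0.02, 0.04, 0.9]))
        assert np.allclose(out, [0.04, 0.04, 0.04 * 4 / 3, 0.9])

    def test_uniform_ties_and_singleton(self):
        assert np.allclose(bh_adjust(np.full(5, 0.2)), 0.2)
        assert bh_adjust(np.array([0.37]))[0] == pytest.approx(0.37)

    def test_nan_passthrough_excluded_from_m(self):
        out = bh_adjust(np.array([0.01, np.nan, 0.04]))
        assert np.isnan(out[1])
        assert np.allclose(out[[0, 2]], bh_adjust(np.array([0.01, 0.04])))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.2]))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=1000), st.booleans())
    def test_matches_brute_force_and_statsmodels(self, pvals, _dummy):
        p = np.asarray(pvals)
        # brute-force step-up definition: sort, p*m/rank, running min from top
        m = len(p)
        order = np.argsort(p, kind="stable")
        brute = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            running = min(running, p[order[rank - 1]] * m / rank)
            brute[order[rank - 1]] = running
        mine = bh_adjust(p)
        assert np.allclose(mine, brute, atol=1e-12)
        assert np.allclose(mine, multipletests(p, method="fdr_bh")[1], atol=1e-12)

    def test_adjusted_never_below_raw(self, rng):
        p = rng.uniform(size=200)
        assert np.all(bh_adjust(p) >= p - 1e-12)


class TestDegCalling:
    def test_threshold_boundaries(self, rng):
        counts = rng.poisson(5, size=(12, 4))
        m = make_cell_matrix(counts)
        de = sseq_exact_test(m, np.arange(6), np.arange(6, 12))
        de.table["p_adjusted"] = [0.01, 0.001, 0.2, 0.04]
        de.table["log2_fc"] = [1.2, 0.9, 3.0, -1.0]
        call = call_degs(de, alpha=0.05, min_lfc=1.0)
        assert call.up == {"g0"}       # significant and |lfc| >= 1, up
        assert call.down == {"g3"}     # |lfc| = 1 boundary is inclusive
        # g1 fails lfc despite tiny p; g2 fails alpha

    def test_small_cluster_ineligible(self, rng):
        counts = rng.poisson(5, size=(10, 3))
        m = make_cell_matrix(counts)
        de = sseq_exact_test(m, np.arange(4), np.arange(4, 10))
        call = call_degs(de)
        assert not call.eligible and call.genes == set()

    def test_one_vs_rest_recovers_planted_signal(self, rng):
        """Cluster 1 carries 20 genes at 8x mean; those genes and only (mostly)
        those come back as its up-DEGs."""
        n_per, g = 40, 120
        base = rng.lognormal(1.2, 0.4, size=g)
        mean = np.tile(base, (3 * n_per, 1))
        mean[:n_per, :20] *= 8.0
        counts = rng.poisson(mean)
        m = make_cell_matrix(counts)
        labels = np.repeat(["k1", "k2", "k3"], n_per)
        res = one_vs_rest_degs(m, labels)
        call, _ = res["k1"]
        planted = {f"g{j}" for j in range(20)}
        assert len(call.up & planted) / 20 >= 0.9
        assert len(call.up - planted) <= 3

    def test_shuffled_labels_bh_controlled(self, rng):
        counts = rng.poisson(6, size=(90, 300))
        labels = rng.permutation(np.repeat(["k1", "k2", "k3"], 30))
        res = one_vs_rest_degs(make_cell_matrix(counts), labels)
        total = sum(len(c.genes) for c, _ in res.values())
        assert total <= 0.05 * 300 * 3

    def test_single_cluster_rejected(self, rng):
        m = make_cell_matrix(rng.poisson(3, size=(10, 5)))
        with pytest.raises(ValueError):
            one_vs_rest_degs(m, np.repeat("only", 10))
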