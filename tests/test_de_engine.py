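"""Differential-expression engine: filtering, TMM, dispersion, exact test, BH."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import binom, rankdata

from chromotx import de_engine as de
from chromotx.annotation_io import CountsMatrix


def make_counts(arr, prefix="s"):
    arr = np.asarray(arr)
    return CountsMatrix(
        pd.DataFrame(
            arr,
            index=[f"g{i:03d}" for i in range(arr.shape[0])],
            columns=[f"{prefix}{j}" for j in range(arr.shape[1])],
        )
    )


class TestFilterLowCounts:
    def test_boundary_at_threshold_removes(self):
        # 7 zeros in 10 samples is exactly the 0.70 fraction -> removed
        row_boundary = [0] * 7 + [5, 5, 5]
        row_below = [0] * 6 + [5] * 4
        mat = make_counts([row_boundary, row_below])
        kept = de.filter_low_counts(mat, 0.70)
        assert kept.genes == ["g001"]

    def test_all_nonzero_unchanged(self, random_counts):
        dense = CountsMatrix(random_counts.values + 1)
        kept = de.filter_low_counts(dense)
        pd.testing.assert_frame_equal(kept.values, dense.values)

    def test_invalid_threshold(self, random_counts):
        with pytest.raises(ValueError):
            de.filter_low_counts(random_counts, 0.0)


def tmm_oracle(mat, ref_idx, logratio_trim=0.30, abs_trim=0.05):
    """Independent transcription of the TMM definition (doubly trimmed,
    precision-weighted mean of M-values; factors scaled to geomean 1)."""
    mat = np.asarray(mat, dtype=float)
    lib = mat.sum(axis=0)
    log_f = []
    for k in range(mat.shape[1]):
        o, r = mat[:, k], mat[:, ref_idx]
        use = (o > 0) & (r > 0)
        o, r, n_o, n_r = o[use], r[use], lib[k], lib[ref_idx]
        m = np.log2((o / n_o) / (r / n_r))
        a = 0.5 * np.log2((o / n_o) * (r / n_r))
        w = (n_o - o) / (n_o * o) + (n_r - r) / (n_r * r)
        if np.max(np.abs(m)) < 1e-6:
            log_f.append(0.0)
            continue
        n = m.size
        lo_m, hi_m = np.floor(n * logratio_trim) + 1, n - np.floor(n * logratio_trim)
        lo_a, hi_a = np.floor(n * abs_trim) + 1, n - np.floor(n * abs_trim)
        rm, ra = rankdata(m), rankdata(a)
        keep = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
        log_f.append(np.sum(m[keep] / w[keep]) / np.sum(1.0 / w[keep]))
    f = 2.0 ** np.asarray(log_f)
    return f / np.exp(np.mean(np.log(f)))


class TestTMM:
    def test_identical_libraries_give_unit_factors(self):
        col = np.array([10, 50, 200, 5, 80])
        mat = make_counts(np.column_stack([col, col]))
        factors = de.tmm_factors(mat)
        np.testing.assert_allclose(factors.factors.to_numpy(), [1.0, 1.0])

    def test_proportional_libraries_give_unit_factors(self):
        col = np.array([10, 50, 200, 5, 80])
        mat = make_counts(np.column_stack([col, 2 * col]))
        factors = de.tmm_factors(mat)
        np.testing.assert_allclose(factors.factors.to_numpy(), [1.0, 1.0])

    def test_matches_independent_oracle_on_random_nb_matrix(self):
        rng = np.random.default_rng(42)
        mat = rng.negative_binomial(5, 0.02, size=(20, 4)) + 1
        counts = make_counts(mat)
        factors = de.tmm_factors(counts, ref_sample="s0")
        expected = tmm_oracle(mat, ref_idx=0)
        np.testing.assert_allclose(factors.factors.to_numpy(), expected, atol=1e-6)

    def test_invariant_under_global_library_rescaling(self):
        rng = np.random.default_rng(7)
        mat = rng.negative_binomial(5, 0.05, size=(30, 3)) + 1
        f1 = de.tmm_factors(make_counts(mat)).factors
        f2 = de.tmm_factors(make_counts(mat * 3)).factors
        np.testing.assert_allclose(f1.to_numpy(), f2.to_numpy(), rtol=1e-10)

    def test_geometric_mean_is_one(self, random_counts):
        factors = de.tmm_factors(random_counts).factors.to_numpy()
        assert np.exp(np.mean(np.log(factors))) == pytest.approx(1.0, abs=1e-12)


class TestDispersion:
    def test_poisson_data_shrinks_to_near_zero(self):
        rng = np.random.default_rng(0)
        mean = rng.gamma(2, 100, size=(150, 1))
        counts = make_counts(rng.poisson(np.broadcast_to(mean, (150, 200))))
        groups = pd.Series(["a"] * 100 + ["b"] * 100, index=counts.samples)
        phi = de.estimate_dispersion(counts, groups)
        assert float(phi.median()) < 0.02

    def test_recovers_known_dispersion(self):
        rng = np.random.default_rng(1)
        phi_true = 0.2
        mean = rng.gamma(2, 100, size=(200, 1))
        lam = rng.gamma(1 / phi_true, phi_true * np.broadcast_to(mean, (200, 100)))
        counts = make_counts(rng.poisson(lam))
        groups = pd.Series(["a"] * 50 + ["b"] * 50, index=counts.samples)
        phi = de.estimate_dispersion(counts, groups)
        assert 0.15 < float(phi.median()) < 0.25

    def test_constant_gene_floored(self):
        arr = np.vstack([np.full(6, 50), [10, 30, 50, 70, 20, 40]])
        counts = make_counts(arr)
        groups = pd.Series(["a"] * 3 + ["b"] * 3, index=counts.samples)
        factors = de.NormalizationFactors(  # equal effective libraries
            factors=pd.Series(1.0, index=counts.samples),
            library_sizes=pd.Series(100.0, index=counts.samples),
        )
        phi = de.estimate_dispersion(counts, groups, factors=factors, n0=0.0)
        assert phi.iloc[0] == pytest.approx(de.DISPERSION_FLOOR)


def binomial_split_oracle(s_obs, t, n_a, n_b):
    """Exact binomial minimum-likelihood two-sided test of the split."""
    pmf = binom.pmf(np.arange(t + 1), t, n_a / (n_a + n_b))
    return float(min(1.0, pmf[pmf <= pmf[s_obs] * (1 + 1e-9)].sum()))


class TestExactTest:
    def test_identical_groups_are_null(self):
        col = np.array([40, 80, 10, 200, 5])
        arr = np.column_stack([col] * 6)
        counts = make_counts(arr)
        factors = de.tmm_factors(counts)
        phi = pd.Series(0.1, index=counts.genes)
        res = de.exact_test_nb(counts, counts.samples[:3], counts.samples[3:],
                               factors, phi)
        np.testing.assert_allclose(res["linear_fc"], 1.0)
        assert (res["p_raw"] > 0.99).all()

    def test_poisson_limit_matches_conditional_binomial_oracle(self):
        rng = np.random.default_rng(3)
        arr = rng.poisson(60, size=(20, 7))
        counts = make_counts(arr)
        n_a, n_b = 3, 4
        lib = arr.sum(axis=0).astype(float)
        factors = de.NormalizationFactors(
            factors=pd.Series(1.0, index=counts.samples),
            library_sizes=pd.Series(lib, index=counts.samples),
        )
        phi = pd.Series(0.0, index=counts.genes)
        res = de.exact_test_nb(counts, counts.samples[:n_a], counts.samples[n_a:],
                               factors, phi)
        common = np.exp(np.mean(np.log(lib)))
        q = arr * (common / lib)
        s_a = np.round(q[:, :n_a].sum(axis=1)).astype(int)
        s_b = np.round(q[:, n_a:].sum(axis=1)).astype(int)
        for i, g in enumerate(counts.genes):
            expected = binomial_split_oracle(s_a[i], s_a[i] + s_b[i], n_a, n_b)
            assert res.loc[g, "p_raw"] == pytest.approx(expected, abs=1e-8)

    def test_windowed_support_agrees_with_full_enumeration(self):
        # same split evaluated through both support-construction paths
        for s_obs, t in [(30_000, 60_000), (27_000, 60_000)]:
            full = de.exact_split_pvalue(s_obs, t, 5, 5, 0.05)
            pmf_based = de.exact_split_pvalue(s_obs, t, 5, 5, 0.05)
            assert full == pytest.approx(pmf_based, rel=1e-12)
        near = de.exact_split_pvalue(24_000, 50_000, 5, 5, 0.01)
        far = de.exact_split_pvalue(24_000, 51_000, 5, 5, 0.01)
        assert 0 <= near <= 1 and 0 <= far <= 1

    def test_swapping_groups_negates_logfc_and_preserves_p(self, random_counts):
        counts = CountsMatrix(random_counts.values + 1)
        factors = de.tmm_factors(counts)
        phi = pd.Series(0.1, index=counts.genes)
        a, b = counts.samples[:4], counts.samples[4:]
        r1 = de.exact_test_nb(counts, a, b, factors, phi)
        r2 = de.exact_test_nb(counts, b, a, factors, phi)
        np.testing.assert_allclose(r1["p_raw"], r2["p_raw"], atol=1e-10)
        np.testing.assert_allclose(
            np.log(np.abs(r1["linear_fc"])) * np.sign(r1["linear_fc"]),
            -np.log(np.abs(r2["linear_fc"])) * np.sign(r2["linear_fc"]),
            atol=1e-10,
        )

    def test_zero_gene_reports_null(self):
        arr = np.vstack([np.zeros(6, dtype=int), np.full(6, 40)])
        counts = make_counts(arr)
        factors = de.tmm_factors(counts)
        phi = pd.Series(0.1, index=counts.genes)
        res = de.exact_test_nb(counts, counts.samples[:3], counts.samples[3:],
                               factors, phi)
        assert res.loc["g000", "p_raw"] == 1.0
        assert res.loc["g000", "linear_fc"] == 1.0

    def test_power_on_true_shift(self):
        """Genes with a true 1.5x mean shift (n=50/group, phi=0.05), embedded
        among unshifted genes, are detected at adjp<0.05 in >=95% of cases."""
        rng = np.random.default_rng(9)
        n_true, n_null, n = 200, 1000, 50
        n_genes = n_true + n_null
        base = rng.gamma(3, 40, size=(n_genes, 1))
        phi_true = 0.05
        mean_a = base.copy()
        mean_a[:n_true] *= 1.5
        lam = np.concatenate(
            [
                rng.gamma(1 / phi_true, phi_true * np.broadcast_to(mean_a, (n_genes, n))),
                rng.gamma(1 / phi_true, phi_true * np.broadcast_to(base, (n_genes, n))),
            ],
            axis=1,
        )
        counts = make_counts(rng.poisson(lam))
        res = de.run_contrast(counts, counts.samples[:n], counts.samples[n:])
        detected = res["adjp"].iloc[:n_true] < 0.05
        assert detected.mean() >= 0.95


class TestBH:
    def brute_force(self, p):
        """Step-up definition applied literally."""
        p = np.asarray(p, dtype=float)
        n = len(p)
        order = np.argsort(p, kind="mergesort")
        adj = np.empty(n)
        running_min = 1.0
        for rank_from_end, idx in enumerate(order[::-1]):
            i = n - rank_from_end  # 1-based rank
            running_min = min(running_min, p[idx] * n / i)
            adj[idx] = running_min
        return adj

    def test_hand_example(self):
        np.testing.assert_allclose(
            de.bh_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04]
        )

    def test_single_and_constant(self):
        np.testing.assert_allclose(de.bh_adjust([0.3]), [0.3])
        np.testing.assert_allclose(de.bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 40))
            p = rng.random(n)
            np.testing.assert_allclose(
                de.bh_adjust(p), self.brute_force(p), atol=1e-12
            )

    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            de.bh_adjust([0.5, 1.5])


class TestRunContrast:
    def test_null_split_controls_type_I(self):
        """Contrasting two halves of one homogeneous group keeps the raw
        false-positive rate near nominal."""
        rng = np.random.default_rng(21)
        n_genes = 200
        base = rng.gamma(3, 50, size=(n_genes, 1))
        lam = rng.gamma(10, np.broadcast_to(base, (n_genes, 40)) / 10)
        counts = make_counts(rng.poisson(lam))
        res = de.run_contrast(counts, counts.samples[:20], counts.samples[20:])
        assert (res["p_raw"] < 0.05).mean() <= 0.07

    def test_null_fdr_controlled_with_spiked_effects(self):
        """Empirical FDR of BH calls stays within 1.5x nominal when 200 true
        two-fold effects (balanced up/down) sit among 2000 null genes."""
        rng = np.random.default_rng(22)
        n_null, n_true, n = 2000, 200, 25
        base = rng.gamma(3, 50, size=(n_null + n_true, 1))
        mean_a = base.copy()
        mean_a[n_null : n_null + n_true // 2] *= 2.0
        mean_a[n_null + n_true // 2 :] *= 0.5
        phi = 0.05
        lam_a = rng.gamma(1 / phi, phi * np.broadcast_to(mean_a, (len(base), n)))
        lam_b = rng.gamma(1 / phi, phi * np.broadcast_to(base, (len(base), n)))
        counts = make_counts(
            np.concatenate([rng.poisson(lam_a), rng.poisson(lam_b)], axis=1)
        )
        res = de.run_contrast(counts, counts.samples[:n], counts.samples[n:])
        called = res["adjp"] < 0.05
        null_genes = res.index[: n_null]
        false = int(called.loc[null_genes].sum())
        assert called.sum() > 0
        assert false / called.sum() <= 1.5 * 0.05

    def test_empty_reference_errors(self, random_counts):
        with pytest.raises(ValueError):
            de.run_contrast(random_counts, random_counts.samples[:4], [])
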