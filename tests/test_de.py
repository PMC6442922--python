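"""DE engine: size factors, dispersions, GLM fits, LRT, BH, full pipeline."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from mirpair import (
    DesignError,
    NormalizationError,
    SimParams,
    ValidationError,
    bh_adjust,
    estimate_dispersions,
    estimate_size_factors,
    fit_nb_glm,
    lrt_interaction,
    run_de,
    simulate_paired_counts,
)
from mirpair.de import ALPHA_MIN, build_design, validate_sample_sheet


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self, rng):
        col = rng.poisson(50, size=30)
        K = np.column_stack([col] * 4) + 1
        np.testing.assert_allclose(estimate_size_factors(K), np.ones(4), atol=1e-12)

    def test_doubled_column_hand_value(self):
        """Column 2 = 2 x column 1 -> factors (1/sqrt2, sqrt2)."""
        col = np.array([10, 40, 160, 700])
        K = np.column_stack([col, 2 * col])
        np.testing.assert_allclose(
            estimate_size_factors(K), [1 / np.sqrt(2), np.sqrt(2)], rtol=1e-12
        )

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_geometric_mean_one_convention(self, seed):
        rng = np.random.default_rng(seed)
        K = rng.poisson(rng.uniform(5, 200, size=(25, 1)), size=(25, 6)) + 1
        sf = estimate_size_factors(K)
        assert (sf > 0).all()
        assert abs(np.log(sf).mean()) < 1e-12

    def test_no_all_positive_gene_errors(self):
        K = np.array([[0, 5], [3, 0]])
        with pytest.raises(NormalizationError):
            estimate_size_factors(K)


class TestDispersions:
    def test_poisson_data_estimates_near_zero(self):
        # 40 samples, no design effects beyond the intercept-like subject terms
        rng = np.random.default_rng(0)
        rows = []
        for cond, prefix in (("performance", "P"), ("control", "C")):
            for j in range(10):
                for time in ("pre", "post"):
                    rows.append((f"{prefix}{j}_{time}", f"{prefix}{j}", cond, time))
        sheet = pd.DataFrame(rows, columns=["sample_id", "pair_id", "condition", "time"])
        X, _, _ = build_design(sheet)
        Y = rng.poisson(200.0, size=(150, 40)).astype(float)
        alpha, _ = estimate_dispersions(Y, np.ones(40), X)
        assert np.median(alpha) <= 0.01

    def test_known_dispersion_recovered(self):
        rng = np.random.default_rng(1)
        rows = []
        for cond, prefix in (("performance", "P"), ("control", "C")):
            for j in range(10):
                for time in ("pre", "post"):
                    rows.append((f"{prefix}{j}_{time}", f"{prefix}{j}", cond, time))
        sheet = pd.DataFrame(rows, columns=["sample_id", "pair_id", "condition", "time"])
        X, _, _ = build_design(sheet)
        true_alpha, mu = 0.5, 200.0
        r = 1 / true_alpha
        Y = rng.negative_binomial(r, r / (r + mu), size=(200, 40)).astype(float)
        alpha, _ = estimate_dispersions(Y, np.ones(40), X)
        inside = ((alpha >= 0.2) & (alpha <= 1.0)).mean()
        assert inside >= 0.9

    def test_constant_counts_clamp_to_lower_bound(self, toy_sheet):
        X, _, _ = build_design(toy_sheet)
        Y = np.full((3, 8), 50.0)
        alpha, _ = estimate_dispersions(Y, np.ones(8), X)
        # pinned against the bottom of the admissible range
        assert (alpha < 10 * ALPHA_MIN).all()


class TestGLMFit:
    def test_two_group_fit_recovers_group_means(self):
        rng = np.random.default_rng(2)
        y = np.concatenate([rng.poisson(80, 20), rng.poisson(160, 20)]).astype(float)
        X = np.column_stack([np.ones(40), np.repeat([0.0, 1.0], 20)])
        fit = fit_nb_glm(y, np.ones(40), X, alpha=0.05)
        fitted_means = np.exp([fit.coefficients[0], fit.coefficients.sum()])
        np.testing.assert_allclose(fitted_means, [y[:20].mean(), y[20:].mean()], rtol=1e-6)

    def test_matches_statsmodels_loglik_and_coefs(self):
        """Independent cross-check of the IRLS fit against statsmodels NB GLM."""
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(3)
        X = np.column_stack([np.ones(30), rng.normal(size=30), rng.integers(0, 2, 30)])
        mu = np.exp(2 + 0.5 * X[:, 1] + 0.8 * X[:, 2])
        alpha = 0.2
        y = rng.negative_binomial(1 / alpha, 1 / (1 + alpha * mu)).astype(float)
        sf = rng.uniform(0.5, 2.0, size=30)
        ours = fit_nb_glm(y, sf, X, alpha=alpha)
        ref = sm.GLM(
            y, X, family=sm.families.NegativeBinomial(alpha=alpha), offset=np.log(sf)
        ).fit()
        np.testing.assert_allclose(ours.coefficients, ref.params, rtol=1e-5, atol=1e-6)
        np.testing.assert_allclose(ours.log_likelihood, ref.llf, rtol=1e-8)

    def test_rank_deficient_design_names_columns(self):
        y = np.arange(10, dtype=float) + 1
        X = np.column_stack([np.ones(10), np.zeros(10)])
        with pytest.raises(DesignError, match="x1"):
            fit_nb_glm(y, np.ones(10), X, alpha=0.1, column_names=["intercept", "x1"])


class TestLRT:
    def test_identical_fits_give_zero_stat_p_one(self):
        y = np.array([5.0, 9, 7, 6, 8, 12])
        X = np.column_stack([np.ones(6), np.arange(6.0)])
        full = fit_nb_glm(y, np.ones(6), X, alpha=0.1)
        reduced = fit_nb_glm(y, np.ones(6), X[:, :1], alpha=0.1)
        # same fit compared with itself: identity case
        stat, p = lrt_interaction(full, full.__class__(
            coefficients=full.coefficients[:-1],
            log_likelihood=full.log_likelihood,
            mu=full.mu, alpha=full.alpha, converged=True,
        ))
        assert stat == 0.0 and p == 1.0
        stat2, p2 = lrt_interaction(full, reduced)
        assert stat2 >= 0.0 and 0.0 <= p2 <= 1.0

    def test_non_nested_designs_rejected(self):
        y = np.arange(6.0) + 1
        X = np.column_stack([np.ones(6), np.arange(6.0)])
        fit = fit_nb_glm(y, np.ones(6), X, alpha=0.1)
        with pytest.raises(ValidationError):
            lrt_interaction(fit, fit)

    def test_power_on_strong_planted_interaction(self):
        """|log2 interaction| = 1 at high counts and low dispersion is detected."""
        p = SimParams(
            n_mirnas=150,
            frac_de=1.0,
            baseline_log2_mean_range=(7.0, 10.0),
            dispersion_trend=(0.0, 0.05),
            interaction_lfc_range=(1.0, 1.0),
            seed=11,
        )
        counts, sheet, _ = simulate_paired_counts(p)
        de = run_de(counts, sheet)
        assert de["p_value"].median() < 0.01


class TestBH:
    def test_hand_example(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.5]), [0.04, 0.04, 0.04, 0.5]
        )

    def test_degenerate_inputs(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])

    def test_nan_passthrough(self):
        q = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(q[1])
        # the NaN does not count toward the number of tests
        np.testing.assert_allclose(q[[0, 2]], [0.02, 0.04])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])

    @staticmethod
    def _brute_force_bh(p):
        """Oracle: sort ascending, scale by m/rank, running min from the top."""
        p = list(p)
        m = len(p)
        order = sorted(range(m), key=lambda i: p[i])
        q = [None] * m
        best = 1.0
        for rank_from_top in range(m, 0, -1):
            i = order[rank_from_top - 1]
            best = min(best, p[i] * m / rank_from_top)
            q[i] = min(best, 1.0)
        return np.array(q)

    @given(st.integers(0, 2**31 - 1), st.integers(1, 60))
    @settings(max_examples=40, deadline=None)
    def test_matches_brute_force_oracle(self, seed, n):
        p = np.random.default_rng(seed).uniform(0, 1, size=n)
        np.testing.assert_allclose(bh_adjust(p), self._brute_force_bh(p), rtol=1e-12)

    def test_matches_statsmodels(self):
        mt = pytest.importorskip("statsmodels.stats.multitest")
        p = np.random.default_rng(0).uniform(0, 1, size=500)
        np.testing.assert_allclose(bh_adjust(p), mt.multipletests(p, method="fdr_bh")[1])


class TestRunDE:
    def test_row_count_preserved_and_all_zero_flagged(self, small_sim):
        counts, sheet, _ = small_sim
        counts = counts.copy()
        counts.iloc[3] = 0
        de = run_de(counts, sheet)
        assert len(de) == len(counts)
        assert de.iloc[3]["status"] == "all_zero"
        assert np.isnan(de.iloc[3]["p_value"])

    def test_full_model_likelihood_dominates_and_stat_nonneg(self, small_sim):
        counts, sheet, _ = small_sim
        de = run_de(counts, sheet)
        assert (de["lrt_stat"].dropna() >= 0).all()
        assert de["p_value"].dropna().between(0, 1).all()
        assert de["q_value"].dropna().between(0, 1).all()

    def test_size_factor_invariance_of_interaction_lfc(self):
        """Scaling one sample's counts scales its size factor and leaves
        interaction estimates essentially unchanged."""
        p = SimParams(n_mirnas=120, baseline_log2_mean_range=(6.0, 9.0), seed=21)
        counts, sheet, _ = simulate_paired_counts(p)
        de1 = run_de(counts, sheet)
        scaled = counts.copy()
        scaled.iloc[:, 0] *= 3
        sf1 = estimate_size_factors(counts.to_numpy(float))
        sf2 = estimate_size_factors(scaled.to_numpy(float))
        assert sf2[0] / sf1[0] == pytest.approx(3 * (sf2[1:] / sf1[1:]).mean(), rel=0.01)
        de2 = run_de(scaled, sheet)
        d = (de2["interaction_lfc"] - de1["interaction_lfc"]).abs()
        assert d[de1["base_mean"] >= 50].max() < 0.05

    def test_permuted_time_labels_yield_no_calls(self):
        """Swapping pre/post labels within subjects destroys the signal."""
        p = SimParams(n_mirnas=300, frac_de=0.1, seed=31)
        counts, sheet, _ = simulate_paired_counts(p)
        rng = np.random.default_rng(5)
        sheet_perm = sheet.copy()
        for pid in sheet["pair_id"].unique():
            if rng.random() < 0.5:
                idx = sheet_perm["pair_id"] == pid
                sheet_perm.loc[idx, "time"] = sheet_perm.loc[idx, "time"].map(
                    {"pre": "post", "post": "pre"}
                )
        # permuting labels within pairs, jointly in both arms
        de = run_de(counts, sheet_perm)
        assert (de["q_value"].dropna() < 0.05).sum() <= 3

    def test_sheet_invariants_enforced(self, toy_sheet):
        broken = toy_sheet.drop(index=0)
        with pytest.raises(ValidationError):
            validate_sample_sheet(broken)
        crossed = toy_sheet.copy()
        crossed.loc[0, "condition"] = "control"
        with pytest.raises(ValidationError):
            validate_sample_sheet(crossed)
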