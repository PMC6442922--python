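"""Synthetic-data generator: determinism, planted truth, marginal structure."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirpair import (
    SimParams,
    TargetScoreParams,
    ValidationError,
    observed_overlap,
    simulate_paired_counts,
    simulate_target_tables,
    simulate_universe_pair,
)
from mirpair.de import validate_sample_sheet


class TestPairedCounts:
    def test_shape_and_sheet_validity(self, small_sim):
        counts, sheet, _ = small_sim
        assert counts.shape == (200, 40)
        assert (counts.to_numpy() >= 0).all()
        validate_sample_sheet(sheet)
        assert list(counts.columns) == list(sheet["sample_id"])

    def test_seed_determinism(self):
        p = SimParams(n_mirnas=500, n_pairs_per_arm=10, seed=7)
        c1, s1, t1 = simulate_paired_counts(p)
        c2, s2, t2 = simulate_paired_counts(p)
        pd.testing.assert_frame_equal(c1, c2)
        assert t1 == t2

    def test_null_case_has_no_planted_effects(self):
        p = SimParams(n_mirnas=50, frac_de=0.0, seed=1)
        _, _, truth = simulate_paired_counts(p)
        assert truth.de_ids == ()
        assert truth.true_interaction_lfc == {}

    def test_nb_mean_matches_target(self):
        """Monte-Carlo check: with all effects zero, counts average to sf * 2^mu."""
        p = SimParams(
            n_mirnas=250,  # 250 genes x 40 samples = 10,000 draws
            baseline_log2_mean_range=(7.0, 7.0),
            pair_effect_sd=0.0,
            size_factor_range=(1.0, 1.0),
            frac_de=0.0,
            dispersion_trend=(3.0, 0.05),
            seed=5,
        )
        counts, _, _ = simulate_paired_counts(p)
        draws = counts.to_numpy().ravel()
        alpha = 3.0 / 128 + 0.05
        se = np.sqrt(128 + alpha * 128**2) / np.sqrt(draws.size)
        assert abs(draws.mean() - 128) < 3 * se

    def test_planted_truth_round_trip(self, small_sim):
        counts, sheet, truth = small_sim
        assert set(truth.de_ids) <= set(counts.index)
        assert len(truth.de_ids) == round(0.1 * 200)
        assert set(truth.true_interaction_lfc) == set(truth.de_ids)
        assert all(v != 0 for v in truth.true_interaction_lfc.values())
        assert set(truth.true_size_factors) == set(counts.columns)
        assert set(truth.true_dispersions) == set(counts.index)

    def test_column_sums_track_size_factors(self):
        # pair effects off so depth is the only column-level multiplier
        p = SimParams(n_mirnas=500, size_factor_range=(0.4, 2.5),
                      pair_effect_sd=0.0, seed=9)
        counts, sheet, truth = simulate_paired_counts(p)
        sums = counts.sum(axis=0).to_numpy(dtype=float)
        sf = np.array([truth.true_size_factors[s] for s in counts.columns])
        rho = stats.spearmanr(sums, sf).statistic
        assert rho > 0.9

    def test_invalid_params_rejected(self):
        with pytest.raises(ValidationError):
            SimParams(n_mirnas=0)
        with pytest.raises(ValidationError):
            SimParams(frac_de=1.5)
        with pytest.raises(ValidationError):
            SimParams(interaction_lfc_range=(2.0, 1.0))
        with pytest.raises(ValidationError):
            SimParams(dispersion_trend=(-1.0, 0.05))


class TestTargetTables:
    def test_empty_input_gives_empty_tables(self):
        pred, val = simulate_target_tables(0, 100, seed=1)
        assert len(pred) == 0 and len(val) == 0

    def test_seed_determinism(self):
        a = simulate_target_tables(20, 500, seed=3)
        b = simulate_target_tables(20, 500, seed=3)
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])

    def test_value_domains(self):
        pred, val = simulate_target_tables(30, 1000, seed=2)
        assert pred["pct"].between(0, 1).all()
        assert pred["contextpp"].between(-1, 0.2).all()
        assert set(val["evidence"]) <= {"reporter_assay", "western_blot", "weak"}
        # distributions straddle the downstream thresholds
        assert 0 < (pred["pct"] >= 0.2).mean() < 1
        assert 0 < (pred["contextpp"] <= -0.15).mean() < 1

    def test_scores_independent_of_annotations(self):
        """Joint pass rate of the conserved-family filter factorises into
        the product of the empirical marginal pass rates."""
        sp = TargetScoreParams(contextpp_mean=-0.15)
        pred, _ = simulate_target_tables(400, 8000, score_params=sp, seed=4)
        fam = pred[pred["family_class"].isin(["conserved", "broadly_conserved"])]
        p_site = (fam["site_class"] == "conserved").mean()
        p_pct = (fam["pct"] >= 0.2).mean()
        p_cpp = (fam["contextpp"] <= -0.15).mean()
        joint = (
            (fam["site_class"] == "conserved")
            & (fam["pct"] >= 0.2)
            & (fam["contextpp"] <= -0.15)
        ).mean()
        expected = p_site * p_pct * p_cpp
        se = np.sqrt(expected * (1 - expected) / len(fam))
        assert abs(joint - expected) < 4 * se


class TestUniversePair:
    def test_annotation_scale_defaults_and_planted_overlap(self):
        pair = simulate_universe_pair(seed=0)
        assert len(pair.universe_a) == 17926
        assert len(pair.universe_b) == 20219
        assert observed_overlap(pair.set_a, pair.set_b, pair.ortholog_map) == 25

    def test_zero_overlap_construction(self):
        pair = simulate_universe_pair(500, 600, (40, 40), 0, seed=1)
        assert observed_overlap(pair.set_a, pair.set_b, pair.ortholog_map) == 0

    @pytest.mark.parametrize("planted", [0, 5, 25, 50])
    def test_planted_overlap_exact(self, planted):
        pair = simulate_universe_pair(2000, 2500, (80, 90), planted, seed=planted)
        assert observed_overlap(pair.set_a, pair.set_b, pair.ortholog_map) == planted
        assert len(pair.set_a) == 80 and len(pair.set_b) == 90
        assert pair.set_a <= set(pair.universe_a)
        assert pair.set_b <= set(pair.universe_b)

    def test_many_to_one_map_and_coverage(self):
        pair = simulate_universe_pair(1000, 300, (30, 30), 10, seed=2, mapped_fraction=0.8)
        assert set(pair.ortholog_map) <= set(pair.universe_a)
        assert set(pair.ortholog_map.values()) <= set(pair.universe_b)
        assert len(pair.ortholog_map) == round(0.8 * 1000)
        # 1000 mapped genes into 300 targets forces many-to-one collisions
        assert len(set(pair.ortholog_map.values())) < len(pair.ortholog_map)

    def test_infeasible_overlap_rejected(self):
        with pytest.raises(ValidationError):
            simulate_universe_pair(100, 100, (10, 10), 11, seed=0)
        with pytest.raises(ValidationError):
            simulate_universe_pair(100, 100, (200, 10), 5, seed=0)
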