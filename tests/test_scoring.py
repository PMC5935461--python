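"""Plate normalization, replicate QC, interaction scoring and empirical FDR."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from chemogimap.scoring import (InteractionRecord, build_matrix, empirical_fdr,
                                normalize_plate, qc_replicates,
                                score_interaction, threshold_at_fdr)


class TestNormalizePlate:
    def test_median_hits_target_and_ratios_preserved(self):
        counts = np.array([[1000.0], [2000.0], [3000.0], [4000.0]])
        out = normalize_plate(counts, target_median=2000.0)
        # median 2500 -> scale 0.8
        assert np.allclose(out.ravel(), [800.0, 1600.0, 2400.0, 3200.0])
        assert np.median(out) == 2000.0

    def test_plate_with_double_median_is_halved(self):
        counts = np.full((5, 4), 4000.0)
        assert np.allclose(normalize_plate(counts), 2000.0)

    def test_plate_already_at_target_unchanged(self):
        counts = np.array([[1500.0, 2000.0, 2500.0, 2000.0]] * 3)
        assert np.allclose(normalize_plate(counts), counts)

    def test_all_zero_plate_is_an_error(self):
        with pytest.raises(ValueError, match="unusable"):
            normalize_plate(np.zeros((4, 4)))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            normalize_plate(np.array([[1.0, -1.0]]))


class TestReplicateQC:
    def test_identical_columns_pass_with_unit_correlation(self, rng):
        col = rng.uniform(500, 4000, size=40)
        res = qc_replicates(np.column_stack([col] * 4))
        assert res.passed and res.min_corr == pytest.approx(1.0)

    def test_permuted_column_fails_threshold(self, rng):
        base = rng.uniform(500, 4000, size=384)
        cols = [base * f for f in (1.0, 1.02, 0.98)]
        cols.append(rng.permutation(base))  # uncorrelated with the rest
        res = qc_replicates(np.column_stack(cols), min_corr=0.7)
        assert not res.passed
        assert res.min_corr < 0.3

    def test_constant_column_flagged_not_raised(self):
        counts = np.column_stack([np.arange(10.0), np.full(10, 7.0)])
        res = qc_replicates(counts)
        assert not res.passed
        assert np.isnan(res.min_corr)
        assert "constant" in res.detail


class TestScoreInteraction:
    def test_identical_conditions_give_null_score(self):
        reps = np.array([1900.0, 2100.0, 2000.0, 2050.0])
        rec = score_interaction(reps, reps)
        assert rec.p_value == pytest.approx(1.0)
        assert rec.S == 0.0
        assert rec.fold_change == pytest.approx(1.0)

    def test_floor_zero_matches_textbook_pooled_ttest(self):
        drug = np.array([900.0, 1100.0, 1000.0, 1000.0])
        veh = np.array([1900.0, 2100.0, 2000.0, 2000.0])
        rec = score_interaction(drug, veh, variance_floor=0.0)
        expected_p = stats.ttest_ind(drug, veh, equal_var=True).pvalue
        assert rec.p_value == pytest.approx(expected_p, rel=1e-12)
        assert rec.S < 0
        assert abs(rec.S) == pytest.approx(-np.log10(expected_p))

    def test_variance_floor_damps_tight_replicates(self):
        drug = np.array([999.0, 1000.0, 1001.0, 1000.0])
        veh = np.array([1999.0, 2000.0, 2001.0, 2000.0])
        loose = score_interaction(drug, veh, variance_floor=0.0)
        floored = score_interaction(drug, veh, variance_floor=150.0 ** 2)
        assert abs(floored.S) < abs(loose.S)

    def test_score_capped_at_16(self):
        drug = np.full(4, 100.0) + np.array([0.0, 0.01, -0.01, 0.0])
        veh = np.full(4, 4000.0) + np.array([0.0, 0.01, -0.01, 0.0])
        rec = score_interaction(drug, veh)
        assert abs(rec.S) <= 16.0
        assert rec.p_value >= 1e-16

    def test_zero_vehicle_median_is_an_error(self):
        with pytest.raises(ValueError, match="reference"):
            score_interaction(np.ones(4), np.zeros(4))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            score_interaction(np.array([1.0, -2.0, 1.0]), np.ones(3))

    def test_even_replicates_median_is_mean_of_central_pair(self):
        rec = score_interaction(np.array([1.0, 2.0, 3.0, 100.0]),
                                np.array([2.0, 2.0, 2.0, 2.0]),
                                variance_floor=1.0)
        assert rec.median_drug == pytest.approx(2.5)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(100.0, 5000.0), min_size=4, max_size=4),
           st.lists(st.floats(100.0, 5000.0), min_size=4, max_size=4))
    def test_antisymmetry_under_condition_swap(self, a, b):
        a, b = np.asarray(a), np.asarray(b)
        fwd = score_interaction(a, b)
        rev = score_interaction(b, a)
        assert fwd.S == pytest.approx(-rev.S, abs=1e-9)
        assert fwd.fold_change * rev.fold_change == pytest.approx(1.0, rel=1e-9)

    @settings(max_examples=20, deadline=None)
    @given(st.floats(0.1, 50.0))
    def test_scale_invariance_with_scaled_floor(self, scale):
        drug = np.array([900.0, 1050.0, 1000.0, 980.0])
        veh = np.array([1900.0, 2100.0, 2000.0, 2050.0])
        floor = 120.0 ** 2
        base = score_interaction(drug, veh, variance_floor=floor)
        scaled = score_interaction(drug * scale, veh * scale,
                                   variance_floor=floor * scale ** 2)
        assert scaled.S == pytest.approx(base.S, abs=1e-9)


def _matrix_from_scores(scores: dict[str, dict[str, float]]):
    records = [InteractionRecord(g, t, 2000.0, 2000.0, 1.0, 10 ** -abs(s), s)
               for g, row in scores.items() for t, s in row.items()]
    return build_matrix(records)


class TestBuildMatrix:
    def test_dense_two_by_two(self):
        m = _matrix_from_scores({"A": {"d1": 1.0, "d2": 2.0}, "B": {"d1": -1.0, "d2": 0.5}})
        assert m.S.shape == (2, 2)
        assert m.S.loc["B", "d1"] == -1.0

    def test_missing_cell_stays_missing(self):
        m = _matrix_from_scores({"A": {"d1": 1.0, "d2": 2.0}, "B": {"d1": -1.0}})
        assert np.isnan(m.S.loc["B", "d2"])
        assert m.S.notna().sum().sum() == 3  # records in == non-missing cells out

    def test_duplicate_pair_lists_offenders(self):
        rec = InteractionRecord("A", "d1", 2000.0, 2000.0, 1.0, 1.0, 0.0)
        with pytest.raises(ValueError, match=r"\('A', 'd1'\)"):
            build_matrix([rec, rec])

    def test_control_flags_from_labels(self):
        m = _matrix_from_scores({"GFP001": {"d1": 0.1}, "BRCA1": {"d1": -4.4}})
        assert m.controls == {"GFP001"}


class TestEmpiricalFDR:
    def test_no_control_beyond_threshold(self):
        m = _matrix_from_scores({f"GFP{i}": {"d1": s} for i, s in
                                 enumerate([0.5, -1.0, 2.0, -2.5])})
        res = empirical_fdr(m, 3.0)
        assert res.positive_pct == 0.0 and res.negative_pct == 0.0

    def test_five_percent_by_definition(self):
        scores = {f"GFP{i:03d}": {"d1": 3.5 if i < 5 else 0.0} for i in range(100)}
        res = empirical_fdr(_matrix_from_scores(scores), 3.0)
        assert res.positive_pct == pytest.approx(5.0)

    def test_monotone_non_increasing_in_threshold(self, null_screen):
        m = null_screen["matrix"]
        rates = [empirical_fdr(m, t).two_sided_pct for t in np.linspace(0, 6, 25)]
        assert all(a >= b for a, b in zip(rates, rates[1:]))

    def test_requires_controls(self):
        m = _matrix_from_scores({"BRCA1": {"d1": -4.4}})
        with pytest.raises(ValueError, match="control"):
            empirical_fdr(m, 3.0)

    def test_threshold_at_fdr_is_consistent(self, null_screen):
        m = null_screen["matrix"]
        thr = threshold_at_fdr(m, 10.0, tail="both")
        assert empirical_fdr(m, thr).two_sided_pct <= 10.0


class TestMonotonicityInEffectSize:
    def test_larger_planted_effects_score_higher(self):
        # fixed noise realization, increasing multiplicative effect
        rng = np.random.default_rng(0)
        veh = 2000.0 * np.exp(rng.normal(0, 0.08, size=4))
        noise = np.exp(rng.normal(0, 0.08, size=4))
        mags = [1.2, 1.5, 2.0, 3.0]
        scores = [abs(score_interaction(2000.0 * m * noise, veh).S) for m in mags]
        assert scores == sorted(scores)
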