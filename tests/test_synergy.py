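"""Median-effect fits, Loewe additivity, synergy score and combination index."""

import numpy as np
import pytest

from chemogimap.simulate import generate_dose_matrix
from chemogimap.synergy import (DoseResponseMatrix, MedianEffectFit,
                                combination_index, expected_additive_inhibition,
                                fit_median_effect, loewe_expected, synergy_score)


def _hill(doses, dm, m):
    doses = np.asarray(doses, dtype=float)
    with np.errstate(divide="ignore"):
        return np.where(doses > 0, 1.0 / (1.0 + (dm / doses) ** m), 0.0)


class TestMedianEffectFit:
    @pytest.mark.parametrize("dm,m", [(1.0, 1.0), (2.0, 3.0), (0.5, 1.7)])
    def test_exact_hill_data_recovered_exactly(self, dm, m):
        doses = np.logspace(-1, 1, 6) * dm
        fit = fit_median_effect(doses, _hill(doses, dm, m))
        assert fit.Dm == pytest.approx(dm, rel=1e-9)
        assert fit.m == pytest.approx(m, rel=1e-9)
        assert fit.fit_r2 == pytest.approx(1.0)

    def test_noisy_hill_median_dm_error_below_ten_percent(self):
        # 6 doses spanning the IC50 without saturating either asymptote
        errors = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            doses = np.logspace(-0.7, 0.7, 6) * 2.0
            fa = _hill(doses, 2.0, 1.5)
            noisy = np.clip(fa * (1.0 + rng.normal(0, 0.05, size=fa.shape)),
                            1e-4, 1 - 1e-4)
            fit = fit_median_effect(doses, noisy)
            errors.append(abs(fit.Dm - 2.0) / 2.0)
        assert np.median(errors) < 0.10

    def test_saturated_points_excluded_with_warning(self):
        doses = np.array([0.1, 0.5, 1.0, 2.0, 1000.0])
        fa = _hill(doses, 1.0, 2.0)
        fa[-1] = 1.0
        with pytest.warns(UserWarning, match="excluded"):
            fit = fit_median_effect(doses, fa)
        assert fit.Dm == pytest.approx(1.0, rel=1e-9)

    def test_too_few_usable_points_is_an_error(self):
        with pytest.raises(ValueError, match=">=3"):
            fit_median_effect(np.array([1.0, 2.0]), np.array([0.4, 0.6]))


class TestLoeweExpected:
    def test_self_combination_depends_only_on_total_dose(self):
        fit = MedianEffectFit(Dm=1.0, m=1.3, fit_r2=1.0)
        for d in (0.3, 1.0, 4.0):
            e_split = loewe_expected(fit, fit, d / 2, d / 2)
            assert e_split == pytest.approx(fit.effect_at_dose(d), abs=1e-8)

    def test_zero_partner_dose_reduces_to_monotherapy(self):
        fa = MedianEffectFit(Dm=1.0, m=1.0, fit_r2=1.0)
        fb = MedianEffectFit(Dm=3.0, m=2.0, fit_r2=1.0)
        assert loewe_expected(fa, fb, 2.0, 0.0) == pytest.approx(fa.effect_at_dose(2.0))
        assert loewe_expected(fa, fb, 0.0, 2.0) == pytest.approx(fb.effect_at_dose(2.0))
        assert loewe_expected(fa, fb, 0.0, 0.0) == 0.0

    def test_unequal_slopes_match_grid_oracle(self):
        """Brute-force fine-grid root search as the independent oracle."""
        fa = MedianEffectFit(Dm=1.0, m=0.8, fit_r2=1.0)
        fb = MedianEffectFit(Dm=2.5, m=2.2, fit_r2=1.0)
        grid = np.linspace(1e-6, 1 - 1e-6, 1_000_000)
        for da, db in [(0.5, 0.5), (2.0, 0.3), (0.1, 4.0)]:
            resid = np.abs(da / (fa.Dm * (grid / (1 - grid)) ** (1 / fa.m))
                           + db / (fb.Dm * (grid / (1 - grid)) ** (1 / fb.m)) - 1.0)
            oracle = grid[np.argmin(resid)]
            assert loewe_expected(fa, fb, da, db) == pytest.approx(oracle, abs=1e-5)


class TestSynergyScore:
    def test_self_combination_matrix_scores_zero(self):
        fit = MedianEffectFit(Dm=1.0, m=1.5, fit_r2=1.0)
        doses = np.array([0.0, 0.2, 0.5, 1.0, 2.0, 5.0])
        inh = np.zeros((len(doses), len(doses)))
        for i, da in enumerate(doses):
            for j, db in enumerate(doses):
                inh[i, j] = fit.effect_at_dose(da + db)
        matrix = DoseResponseMatrix(doses, doses, inh)
        score, excess = synergy_score(matrix)
        assert abs(score) < 1e-6
        assert np.abs(excess.to_numpy()).max() < 1e-6

    @pytest.mark.parametrize("regime,shift,sign", [
        ("synergistic", 0.5, 1), ("antagonistic", 2.0, -1)])
    def test_generated_regimes_have_matching_sign(self, regime, shift, sign):
        fa = MedianEffectFit(Dm=1.0, m=1.2, fit_r2=1.0)
        fb = MedianEffectFit(Dm=2.0, m=1.8, fit_r2=1.0)
        hits = 0
        for seed in range(20):
            matrix = generate_dose_matrix(fa, fb, regime, shift,
                                          noise_cv=0.05, seed=seed)
            score, _ = synergy_score(matrix)
            hits += int(np.sign(score) == sign)
        assert hits >= 19  # sign matches the generative regime >=95% of seeds

    def test_additive_regime_scores_zero_without_noise(self):
        fa = MedianEffectFit(Dm=1.0, m=1.0, fit_r2=1.0)
        fb = MedianEffectFit(Dm=2.0, m=2.0, fit_r2=1.0)
        matrix = generate_dose_matrix(fa, fb, "additive", noise_cv=0.0, seed=0)
        score, _ = synergy_score(matrix)
        assert abs(score) < 1e-6


class TestCombinationIndex:
    def test_additivity_identity_for_self_combination(self):
        fit = MedianEffectFit(Dm=1.0, m=1.0, fit_r2=1.0)
        ci, band = combination_index(0.5, 0.5, fit, fit, fa_observed=0.5)
        assert ci == pytest.approx(1.0)
        assert band == "non-synergistic"

    def test_closed_form_inversion_at_fa_075(self):
        # Dm=1, m=1: D(0.75) = 0.75/0.25 = 3, so doses (1.5, 1.5) are exactly additive
        fit = MedianEffectFit(Dm=1.0, m=1.0, fit_r2=1.0)
        ci, _ = combination_index(1.5, 1.5, fit, fit, fa_observed=0.75)
        assert ci == pytest.approx(1.0)

    def test_half_doses_give_ci_half(self):
        fit = MedianEffectFit(Dm=1.0, m=1.0, fit_r2=1.0)
        ci, band = combination_index(0.75, 0.75, fit, fit, fa_observed=0.75)
        assert ci == pytest.approx(0.5)
        assert band == "moderate synergy"

    def test_homogeneous_degree_one_in_doses(self):
        fa = MedianEffectFit(Dm=1.0, m=1.4, fit_r2=1.0)
        fb = MedianEffectFit(Dm=2.0, m=0.9, fit_r2=1.0)
        ci1, _ = combination_index(0.4, 0.6, fa, fb, 0.6)
        ci2, _ = combination_index(0.8, 1.2, fa, fb, 0.6)
        assert ci2 == pytest.approx(2.0 * ci1)

    def test_band_edges(self):
        fit = MedianEffectFit(Dm=1.0, m=1.0, fit_r2=1.0)
        assert combination_index(0.1, 0.1, fit, fit, 0.5)[1] == "strong synergy"
        assert combination_index(0.45, 0.45, fit, fit, 0.5)[1] == "slight synergy"


class TestExpectedAdditiveInhibition:
    @pytest.mark.parametrize("ea,eb,expected", [
        (0.5, 0.5, 0.75), (0.0, 0.3, 0.3), (1.0, 0.42, 1.0), (0.2, 0.0, 0.2)])
    def test_bliss_formula(self, ea, eb, expected):
        assert expected_additive_inhibition(ea, eb) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            expected_additive_inhibition(1.2, 0.1)


class TestDoseResponseMatrixValidation:
    def test_out_of_range_inhibition_clipped_with_warning(self):
        doses = np.array([0.0, 1.0, 2.0])
        inh = np.array([[0.0, 0.3, 0.5], [0.2, 0.6, 1.1], [0.4, 0.8, -0.1]])
        with pytest.warns(UserWarning, match="clipped"):
            m = DoseResponseMatrix(doses, doses, inh)
        assert m.inhibition.max() <= 1.0
        assert m.inhibition.min() >= 0.0

    def test_doses_must_start_at_zero_and_increase(self):
        with pytest.raises(ValueError):
            DoseResponseMatrix(np.array([0.5, 1.0]), np.array([0.0, 1.0]),
                               np.zeros((2, 2)))
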