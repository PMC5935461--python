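"""Signed-network drug-response prediction against expression/AUC panels."""

import numpy as np
import pandas as pd
import pytest

import chemogimap as cg
from chemogimap.predict import (SignedNetwork, evaluate_predictions,
                                gene_contributions, network_for_drug,
                                overlap_with_correlates, predict_sensitivity,
                                sliding_cutoff, standardize_expression)
from chemogimap.scoring import InteractionMatrix


def _matrix(scores: dict[str, float], treatment="drug"):
    return InteractionMatrix(S=pd.DataFrame({treatment: pd.Series(scores)}))


class TestNetworkForDrug:
    def test_cutoff_selects_signed_members(self):
        m = _matrix({"A": 6.5, "B": -6.8, "C": 2.0})
        net = network_for_drug(m, "drug", cutoff=5.0)
        assert net.members == {"A": 1, "B": -1}

    def test_cutoff_above_extremes_empties_network(self):
        m = _matrix({"A": 6.5, "B": -6.8})
        assert network_for_drug(m, "drug", cutoff=7.0).members == {}

    def test_networks_shrink_as_cutoff_rises(self, class_screen):
        m = class_screen["matrix"]
        t = m.treatments[0]
        prev = None
        for cutoff in (1.0, 2.0, 3.0, 5.0):
            members = set(network_for_drug(m, t, cutoff).members)
            if prev is not None:
                assert members <= prev
            prev = members

    def test_positive_cutoff_required(self):
        with pytest.raises(ValueError):
            network_for_drug(_matrix({"A": 1.0}), "drug", cutoff=0.0)


class TestPredictSensitivity:
    def test_single_gene_score_is_its_z(self):
        z = pd.DataFrame({"A": [1.2, -0.5]}, index=["L1", "L2"])
        scores = predict_sensitivity(z, SignedNetwork("d", {"A": 1}, 5.0))
        assert scores["L1"] == pytest.approx(1.2)

    def test_opposing_signs_cancel(self):
        z = pd.DataFrame({"A": [0.5], "B": [0.5]}, index=["L1"])
        scores = predict_sensitivity(z, SignedNetwork("d", {"A": 1, "B": -1}, 5.0))
        assert scores["L1"] == pytest.approx(0.0)

    def test_linear_in_z_and_antisymmetric_in_signs(self, rng):
        z = pd.DataFrame(rng.normal(size=(20, 5)),
                         columns=list("ABCDE"),
                         index=[f"L{i}" for i in range(20)])
        net = SignedNetwork("d", {"A": 1, "B": -1, "C": 1}, 3.0)
        base = predict_sensitivity(z, net)
        assert np.allclose(predict_sensitivity(2.0 * z, net), 2.0 * base)
        flipped = SignedNetwork("d", {g: -s for g, s in net.members.items()}, 3.0)
        assert np.allclose(predict_sensitivity(z, flipped), -base)

    def test_empty_usable_network_is_an_error(self):
        z = pd.DataFrame({"A": [1.0] * 10})
        with pytest.raises(ValueError):
            predict_sensitivity(z, SignedNetwork("d", {"MISSING": 1}, 5.0))


class TestEvaluatePredictions:
    def test_perfect_linear_relation(self):
        scores = pd.Series(np.linspace(-2, 2, 20), index=[f"L{i}" for i in range(20)])
        auc = -scores  # higher predicted sensitivity, lower AUC
        res = evaluate_predictions(scores, auc, "d")
        assert res.r == pytest.approx(-1.0)
        assert res.significant

    def test_discordant_direction_never_significant(self):
        scores = pd.Series(np.linspace(-2, 2, 20), index=[f"L{i}" for i in range(20)])
        res = evaluate_predictions(scores, scores, "d", direction="negative")
        assert res.r == pytest.approx(1.0)
        assert not res.significant

    def test_too_few_lines_skips_not_fails(self):
        scores = pd.Series([1.0, 2.0], index=["L1", "L2"])
        assert evaluate_predictions(scores, -scores, "d") is None

    def test_simulated_signal_recovers_negative_correlation(self, class_screen):
        truth = class_screen["truth"]
        matrix = class_screen["matrix"]
        z, auc = cg.generate_expression_response(truth, n_lines=60, snr=2.0, seed=5)
        t = "drugA1"
        net = network_for_drug(matrix, t, cutoff=3.0)
        res = evaluate_predictions(predict_sensitivity(z, net), auc[t], t)
        assert res.r < -0.5
        assert res.significant


class TestContributionsAndSlidingCutoff:
    def test_single_gene_contribution_equals_full_r(self, rng):
        z = pd.DataFrame({"A": rng.normal(size=40)}, index=[f"L{i}" for i in range(40)])
        auc = pd.Series(-z["A"] + 0.3 * rng.normal(size=40), index=z.index)
        net = SignedNetwork("d", {"A": 1}, 5.0)
        contrib = gene_contributions(z, net, auc)
        full = evaluate_predictions(predict_sensitivity(z, net), auc, "d")
        assert contrib["A"] == pytest.approx(abs(full.r))

    def test_planted_genes_outrank_decoys(self, rng):
        genes = ["P0", "P1", "P2"] + [f"N{i}" for i in range(30)]
        z = pd.DataFrame(rng.normal(size=(80, len(genes))), columns=genes,
                         index=[f"L{i}" for i in range(80)])
        signs = {g: (1 if i % 2 == 0 else -1) for i, g in enumerate(genes)}
        signal = sum(signs[g] * z[g] for g in genes[:3])
        auc = pd.Series(-1.5 * signal + rng.standard_normal(80), index=z.index)
        contrib = gene_contributions(z, SignedNetwork("d", signs, 3.0), auc)
        assert set(contrib.index[:3]) == {"P0", "P1", "P2"}

    def test_sliding_cutoff_counts_and_monotone_networks(self, class_screen):
        truth = class_screen["truth"]
        matrix = class_screen["matrix"]
        z, auc = cg.generate_expression_response(truth, n_lines=60, snr=2.0, seed=6)
        frame = sliding_cutoff(matrix, z, auc, cutoffs=[2.0, 3.0, 4.0])
        assert list(frame["cutoff"]) == [2.0, 3.0, 4.0]
        assert (frame["n_significant"] <= frame["n_evaluable"]).all()
        assert frame["n_significant"].iloc[0] >= 1


class TestOverlapWithCorrelates:
    def test_no_correlates_anywhere_gives_zero_overlap(self, rng):
        m = _matrix({f"G{i}": s for i, s in enumerate([4.0, -5.0, 3.5])})
        z = pd.DataFrame(rng.normal(size=(40, 3)), columns=["G0", "G1", "G2"],
                         index=[f"L{i}" for i in range(40)])
        auc = pd.DataFrame({"drug": rng.normal(size=40)}, index=z.index)
        res = overlap_with_correlates(m, z, auc, cutoff=3.0, p_thresh=1e-6)
        assert res.overlap_fraction == 0.0

    def test_fully_concordant_panel_gives_full_overlap(self, rng):
        genes = ["G0", "G1"]
        z = pd.DataFrame(rng.normal(size=(100, 2)), columns=genes,
                         index=[f"L{i}" for i in range(100)])
        # resistance interactions (S>0) with strongly negative expression-AUC r
        auc = pd.DataFrame({"drug": -z.sum(axis=1) + 0.1 * rng.normal(size=100)})
        m = _matrix({g: 4.0 for g in genes})
        res = overlap_with_correlates(m, z, auc, cutoff=3.0, p_thresh=0.01)
        assert res.overlap_fraction == pytest.approx(1.0)
        assert res.p_enrichment <= 1.0

    def test_planted_interactions_enriched_over_background(self, class_screen):
        truth = class_screen["truth"]
        matrix = class_screen["matrix"].drop_controls()
        z, auc = cg.generate_expression_response(truth, n_lines=60, snr=2.0, seed=7)
        res = overlap_with_correlates(matrix, z, auc, cutoff=3.0)
        assert res.overlap_fraction > res.background_fraction
        assert res.p_enrichment < 0.01


class TestStandardizeExpression:
    def test_zscore_columns(self, rng):
        expr = pd.DataFrame(rng.normal(5.0, 2.0, size=(30, 4)), columns=list("ABCD"))
        z = standardize_expression(expr)
        assert np.allclose(z.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(z.std(axis=0, ddof=0), 1.0, atol=1e-12)

    def test_constant_gene_dropped(self, rng):
        expr = pd.DataFrame({"A": rng.normal(size=10), "B": np.ones(10)})
        assert list(standardize_expression(expr).columns) == ["A"]

    def test_rank_normalization_bounds(self, rng):
        expr = pd.DataFrame({"A": rng.normal(size=11)})
        z = standardize_expression(expr, method="rank")
        assert z["A"].min() == pytest.approx(-1.0)
        assert z["A"].max() == pytest.approx(1.0)
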