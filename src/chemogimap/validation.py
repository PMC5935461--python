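"""End-to-end calibration and recovery benchmarks on synthetic screens.

Each routine runs a full pipeline stage on generator output with planted
ground truth and returns the measured quantities; the test suite asserts on
them and the acceptance script reports them. Problem sizes follow the
screen design the generator emulates (626 knockdowns per drug, 4 replicate
wells) or, for the permutation and prediction benchmarks, the smallest
panels on which the calibration targets are statistically resolvable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .consensus import DrugClassAnnotation, consensus_network
from .io import score_pipeline
from .predict import SignedNetwork, evaluate_predictions, gene_contributions, \
    predict_sensitivity
from .scoring import InteractionMatrix, empirical_fdr, threshold_at_fdr
from .simulate import GroundTruth, SimConfig, generate_dose_matrix, \
    generate_expression_response, generate_screen
from .synergy import MedianEffectFit, combination_index, fit_median_effect, \
    loewe_expected, synergy_score


def null_screen_calibration(seed: int, threshold: float = 3.0) -> dict:
    """Scored null screen: GFP-based FDR vs realized null-gene rate.

    A full-design screen (626 knockdowns x 4 drugs) with zero planted
    effects is generated and scored; GFP controls and null genes are
    exchangeable, so the fraction past |S| >= threshold must agree between
    the two groups. Agreement is quantified by a two-sided Fisher exact test
    on the two tail counts.
    """
    config = SimConfig(seed=seed)
    plates, truth = generate_screen(config)
    _, matrix = score_pipeline(plates)
    ctrl = matrix.control_scores()
    null_genes = [g for g, role in truth.gene_roles.items() if role == "null"]
    null_vals = matrix.S.loc[null_genes].to_numpy().ravel()
    null_vals = null_vals[~np.isnan(null_vals)]
    k_ctrl = int(np.sum(np.abs(ctrl) >= threshold))
    k_null = int(np.sum(np.abs(null_vals) >= threshold))
    table = [[k_ctrl, ctrl.size - k_ctrl], [k_null, null_vals.size - k_null]]
    fisher_p = float(stats.fisher_exact(table).pvalue)
    return {
        "gfp_fdr_pct": 100.0 * k_ctrl / ctrl.size,
        "null_gene_rate_pct": 100.0 * k_null / null_vals.size,
        "n_controls": int(ctrl.size),
        "n_null_scores": int(null_vals.size),
        "fisher_p": fisher_p,
    }


def planted_recovery(base_seed: int, n_seeds: int = 10, n_planted: int = 40,
                     effect_fold: float = 2.0, fdr_pct: float = 10.0) -> dict:
    """Sensitivity for planted >= 2x effects at the GFP-calibrated 10% FDR.

    Per seed, a full-design screen with ``n_planted`` planted interactions
    (alternating resistance/sensitivity at ``effect_fold``) is scored; the
    score threshold is set where the empirical (GFP) FDR reaches ``fdr_pct``,
    and a planted pair counts as recovered when it passes the threshold with
    the correct sign.
    """
    recovered = total = 0
    gfp_rates = []
    for i in range(n_seeds):
        config = SimConfig(seed=base_seed + i, n_planted=n_planted,
                           effect_sizes=(effect_fold,))
        plates, truth = generate_screen(config)
        _, matrix = score_pipeline(plates)
        thr = threshold_at_fdr(matrix, fdr_pct, tail="both")
        gfp_rates.append(empirical_fdr(matrix, thr).two_sided_pct)
        for g, t in truth.planted_pairs(min_fold=effect_fold):
            s = matrix.S.loc[g, t]
            total += 1
            recovered += int(not np.isnan(s) and abs(s) >= thr
                             and np.sign(s) == np.sign(np.log(truth.modifier(g, t))))
    return {
        "sensitivity_pct": 100.0 * recovered / total,
        "n_planted_total": total,
        "max_gfp_rate_pct": float(max(gfp_rates)),
        "fdr_target_pct": fdr_pct,
        "n_seeds": n_seeds,
    }


def consensus_null_calibration(base_seed: int, n_seeds: int = 20,
                               n_genes: int = 200, n_classes: int = 3,
                               drugs_per_class: int = 2, n_perm: int = 500,
                               fdr_target: float = 0.001) -> dict:
    """False consensus edges on fully null matrices vs the FDR target.

    Each gene x class pair is tested in both tails, so the expected false
    edge count per matrix is fdr_target x n_genes x n_classes x 2.
    """
    n_drugs = n_classes * drugs_per_class
    annotation = DrugClassAnnotation.from_mapping(
        {f"D{i}": f"C{i // drugs_per_class}" for i in range(n_drugs)})
    counts = []
    for i in range(n_seeds):
        rng = np.random.default_rng(base_seed + i)
        S = pd.DataFrame(rng.standard_normal((n_genes, n_drugs)),
                         index=[f"G{j:04d}" for j in range(n_genes)],
                         columns=[f"D{j}" for j in range(n_drugs)])
        edges = consensus_network(InteractionMatrix(S=S), annotation,
                                  fdr_target=fdr_target, n_perm=n_perm,
                                  seed=base_seed + i)
        counts.append(len(edges))
    expected = fdr_target * n_genes * n_classes * 2
    return {
        "mean_edges": float(np.mean(counts)),
        "total_edges": int(np.sum(counts)),
        "expected_edges_per_matrix": expected,
        "n_seeds": n_seeds,
        "n_tests_per_matrix": n_genes * n_classes * 2,
    }


def loewe_identities() -> dict:
    """Closed-form checks of the synergy machinery.

    Self-combination Loewe excess (must be 0), combination index on exactly
    additive dose pairs (must be 1), and median-effect refit error on exact
    Hill data (must vanish).
    """
    fit = MedianEffectFit(Dm=1.0, m=1.5, fit_r2=1.0)
    doses = np.array([0.0, 0.2, 0.5, 1.0, 2.0, 5.0])
    inh = np.array([[fit.effect_at_dose(da + db) for db in doses] for da in doses])
    from .synergy import DoseResponseMatrix
    score, excess = synergy_score(DoseResponseMatrix(doses, doses, inh))

    ci_fit = MedianEffectFit(Dm=1.0, m=1.0, fit_r2=1.0)
    ci_half, _ = combination_index(0.5, 0.5, ci_fit, ci_fit, fa_observed=0.5)
    ci_075, _ = combination_index(1.5, 1.5, ci_fit, ci_fit, fa_observed=0.75)

    gen = MedianEffectFit(Dm=2.0, m=3.0, fit_r2=1.0)
    grid = np.logspace(-1, 1, 6) * gen.Dm
    refit = fit_median_effect(grid, np.array([gen.effect_at_dose(d) for d in grid]))
    return {
        "self_combination_excess_max": float(np.abs(excess.to_numpy()).max()),
        "self_combination_score": float(score),
        "ci_additive_equal_doses": float(ci_half),
        "ci_additive_fa075": float(ci_075),
        "dm_refit_rel_error": abs(refit.Dm - gen.Dm) / gen.Dm,
        "m_refit_rel_error": abs(refit.m - gen.m) / gen.m,
    }


def _network_truth(n_planted: int, n_treatments: int, n_genes: int) -> GroundTruth:
    """Ground truth with ``n_planted`` signed effects per treatment."""
    truth = GroundTruth()
    genes = [f"GENE{i:04d}" for i in range(1, n_genes + 1)]
    for g in genes:
        truth.gene_roles[g] = "null"
    for t_i in range(n_treatments):
        t = f"DRUG{t_i + 1:02d}"
        for k in range(n_planted):
            g = genes[(t_i * n_planted + k) % n_genes]
            truth.effects[(g, t)] = 2.0 if k % 2 == 0 else 0.5
            truth.gene_roles[g] = "planted"
    return truth


def prediction_null_calibration(base_seed: int, n_seeds: int = 100,
                                n_lines: int = 30, alpha: float = 0.05) -> dict:
    """Significant-prediction rate when AUC is independent noise (snr = 0).

    Should approach ``alpha``: the one-sided concordant test fires at rate
    alpha under the null.
    """
    truth = _network_truth(n_planted=5, n_treatments=4, n_genes=40)
    n_sig = n_eval = 0
    for i in range(n_seeds):
        z, auc = generate_expression_response(truth, n_lines=n_lines, snr=0.0,
                                              seed=base_seed + i)
        for t in auc.columns:
            members = {g: int(np.sign(np.log(truth.modifier(g, t))))
                       for g in z.columns if truth.modifier(g, t) != 1.0}
            network = SignedNetwork(t, members, cutoff=3.0)
            res = evaluate_predictions(predict_sensitivity(z, network), auc[t], t,
                                       alpha=alpha)
            if res is not None:
                n_eval += 1
                n_sig += int(res.significant)
    return {"significant_rate_pct": 100.0 * n_sig / n_eval,
            "n_evaluations": n_eval, "alpha_pct": 100.0 * alpha}


def contribution_ranking_recovery(base_seed: int, n_seeds: int = 50,
                                  n_decoys: int = 50, n_lines: int = 100,
                                  snr: float = 1.0) -> dict:
    """How often leave-one-out contributions put planted genes on top.

    Three planted genes drive the response among ``n_decoys`` decoy network
    members; success means the top three contributions are exactly the
    planted genes.
    """
    planted = [f"GENE{i:04d}" for i in (1, 2, 3)]
    decoys = [f"DEC{i:03d}" for i in range(n_decoys)]
    truth = GroundTruth()
    for k, g in enumerate(planted):
        truth.effects[(g, "DRUG01")] = 2.0 if k % 2 == 0 else 0.5
        truth.gene_roles[g] = "planted"
    for g in decoys:
        truth.gene_roles[g] = "null"
    members = {g: int(np.sign(np.log(truth.modifier(g, "DRUG01")))) for g in planted}
    members |= {g: (1 if i % 2 == 0 else -1) for i, g in enumerate(decoys)}
    network = SignedNetwork("DRUG01", members, cutoff=3.0)
    wins = 0
    for i in range(n_seeds):
        z, auc = generate_expression_response(
            truth, n_lines=n_lines, snr=snr, seed=base_seed + i,
            genes=planted + decoys, treatments=["DRUG01"])
        contrib = gene_contributions(z, network, auc["DRUG01"])
        wins += int(set(contrib.index[:3]) == set(planted))
    return {"top_rank_fraction": wins / n_seeds, "n_seeds": n_seeds, "snr": snr}
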