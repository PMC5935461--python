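"""Predict cell-line drug response from signed interaction networks.

Generates an expression/AUC panel tied to the planted ground truth, runs
the sum-of-normalized-expression predictor across a sliding score cutoff,
and measures the overlap between map interactions and expression-response
correlates.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from screen_design import DATA, RESULTS, SEED

import chemogimap as cg
from chemogimap import io
from chemogimap.predict import (evaluate_predictions, network_for_drug,
                                overlap_with_correlates, predict_sensitivity,
                                sliding_cutoff)
from chemogimap.simulate import GroundTruth


def main() -> None:
    _, matrix = io.read_scores(RESULTS / "scores.tsv")
    truth_df = pd.read_csv(DATA / "truth.tsv", sep="\t")
    truth = GroundTruth(
        effects={(r["gene"], r["treatment"]): r["modifier"]
                 for _, r in truth_df.iterrows()},
        gene_roles={g: "null" for g in matrix.genes if g not in matrix.controls})
    z, auc = cg.generate_expression_response(truth, n_lines=60, snr=1.5,
                                             seed=SEED + 1,
                                             genes=[g for g in matrix.genes
                                                    if g not in matrix.controls],
                                             treatments=matrix.treatments)
    z.to_csv(DATA / "expression.tsv", sep="\t")
    auc.to_csv(DATA / "auc.tsv", sep="\t")

    grid = sliding_cutoff(matrix, z, auc, cutoffs=[2, 3, 4, 5, 6])
    grid.to_csv(RESULTS / "prediction_sliding_cutoff.tsv", sep="\t", index=False)
    print("significantly predicted drugs per score cutoff:")
    print(grid.to_string(index=False))

    rows = []
    for t in matrix.treatments:
        net = network_for_drug(matrix, t, cutoff=4.0)
        if not any(g in z.columns for g in net.members):
            continue
        res = evaluate_predictions(predict_sensitivity(z, net), auc[t], t)
        if res is not None:
            rows.append(vars(res))
    per_drug = pd.DataFrame(rows)
    per_drug.to_csv(RESULTS / "prediction_per_drug.tsv", sep="\t", index=False)
    print(f"\nat cutoff 4: {int(per_drug['significant'].sum())} of "
          f"{len(per_drug)} drugs predicted (expected direction r < 0)")

    ov = overlap_with_correlates(matrix.drop_controls(), z, auc, cutoff=3.0)
    print(f"\noverlap with expression-response correlates at |S| >= 3: "
          f"{100 * ov.overlap_fraction:.1f}% of {ov.n_past_cutoff} interactions "
          f"vs {100 * ov.background_fraction:.1f}% background "
          f"(hypergeometric p = {ov.p_enrichment:.1e})")
    print(f"wrote {RESULTS / 'prediction_sliding_cutoff.tsv'}, prediction_per_drug.tsv")


if __name__ == "__main__":
    main()
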