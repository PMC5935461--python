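"""Compare drug interaction profiles: class coherence and the trapping trend.

Drugs in the same class should have correlated genome-wide profiles; the
graded cross-linker-like signatures planted across the PARP class should
make profile similarity to the cross-linkers rise with trapping rank.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from screen_design import DATA, HR_SET, RESULTS

from chemogimap import io
from chemogimap.profiles import (class_coherence, overall_coherence,
                                 profile_correlations, set_average_score,
                                 trapping_trend)


def main() -> None:
    _, matrix = io.read_scores(RESULTS / "scores.tsv")
    annotation = io.read_annotation(DATA / "classes.csv")
    table = profile_correlations(matrix)
    table.long_form(annotation).to_csv(RESULTS / "profile_correlations.tsv",
                                       sep="\t", index=False)

    within, between, p = overall_coherence(table, annotation)
    print(f"profile correlation, same class {within:.3f} vs different class "
          f"{between:.3f} (p = {p:.2e})")
    print(class_coherence(table, annotation).to_string(index=False))

    mean_s, p_set, n = set_average_score(matrix, HR_SET, "PARPi_4")
    print(f"\nHR-like gene set vs strongest trapper: mean S = {mean_s:.2f} "
          f"over {n} genes (p = {p_set:.1e})")

    rho, p_rho, frame = trapping_trend(table, annotation, ["XLINK_1", "XLINK_2"])
    print(f"\ntrapping trend: Spearman rho = {rho:.2f} (p = {p_rho:.3f}) between "
          f"trapping rank and mean correlation with cross-linkers")
    print(frame.to_string(index=False))
    frame.to_csv(RESULTS / "trapping_trend.tsv", sep="\t", index=False)
    print(f"wrote {RESULTS / 'profile_correlations.tsv'}, trapping_trend.tsv")


if __name__ == "__main__":
    main()
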