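"""Generate the demonstration screen and write its raw inputs.

Produces the plate-level count table, the drug-class annotation, and the
planted ground truth under results/data/.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from screen_design import CLASS_MAP, DATA, TRAPPING_RANK, config

import chemogimap as cg
from chemogimap import io


def main() -> None:
    DATA.mkdir(parents=True, exist_ok=True)
    cfg = config()
    plates, truth = cg.generate_screen(cfg)
    io.write_plates(plates, DATA / "plates.csv")

    pd.DataFrame({
        "treatment": list(CLASS_MAP),
        "drug_class": list(CLASS_MAP.values()),
        "trapping_rank": [TRAPPING_RANK.get(t) for t in CLASS_MAP],
    }).to_csv(DATA / "classes.csv", index=False)

    pd.DataFrame(
        [{"gene": g, "treatment": t, "modifier": m}
         for (g, t), m in sorted(truth.effects.items())]
    ).to_csv(DATA / "truth.tsv", sep="\t", index=False)

    n_wells = len(plates[0].well_map)
    print(f"simulated {len(plates)} drug/vehicle plate pairs, "
          f"{n_wells} knockdowns each ({cfg.n_gfp_controls} GFP controls, 1 KIF11)")
    print(f"planted {len(truth.effects)} gene-drug effects "
          f"({sum(1 for m in truth.effects.values() if m < 1)} sensitivity, "
          f"{sum(1 for m in truth.effects.values() if m > 1)} resistance)")
    print(f"wrote {DATA / 'plates.csv'}, classes.csv, truth.tsv")


if __name__ == "__main__":
    main()
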