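"""Shared design of the demonstration screen used by the numbered drivers.

A mid-sized synthetic screen with the structures every downstream stage
needs: three drug classes (two 4-drug classes, one pair), planted class
signatures, graded cross-linker-like signatures across the "PARP" class
emulating rising trapping potency, and a handful of drug-private planted
interactions.
"""

from pathlib import Path

import chemogimap as cg

RESULTS = Path(__file__).resolve().parent.parent / "results"
DATA = RESULTS / "data"

SEED = 2018

CLASS_MAP = {
    "PARPi_1": "PARP inhibitor", "PARPi_2": "PARP inhibitor",
    "PARPi_3": "PARP inhibitor", "PARPi_4": "PARP inhibitor",
    "TOPO_1": "topoisomerase inhibitor", "TOPO_2": "topoisomerase inhibitor",
    "TOPO_3": "topoisomerase inhibitor", "TOPO_4": "topoisomerase inhibitor",
    "XLINK_1": "cross-linker", "XLINK_2": "cross-linker",
}

#: trapping potency rank within the PARP class (1 = weakest trapper)
TRAPPING_RANK = {"PARPi_1": 1, "PARPi_2": 2, "PARPi_3": 3, "PARPi_4": 4}

#: synthetic-lethal / resistance signatures shared within each class
CLASS_SIGNATURES = {
    "PARP inhibitor": {"GENE0001": 0.40, "GENE0002": 0.45, "GENE0003": 0.50,
                       "GENE0004": 2.20},
    "topoisomerase inhibitor": {"GENE0010": 0.40, "GENE0011": 0.50,
                                "GENE0012": 2.30, "GENE0013": 2.00},
    "cross-linker": {"GENE0020": 0.40, "GENE0021": 0.45, "GENE0022": 0.50},
}

#: the cross-linker signature bleeds into PARP drugs in proportion to
#: trapping rank: strong trappers phenocopy cross-linkers
TREATMENT_SIGNATURES = {
    drug: {g: m ** (rank / 4.0) for g, m in CLASS_SIGNATURES["cross-linker"].items()}
    for drug, rank in TRAPPING_RANK.items()
}

#: homologous-recombination-like gene set: sensitive to PARP + cross-linkers
HR_SET = ["GENE0001", "GENE0002", "GENE0003", "GENE0020", "GENE0021", "GENE0022"]


def config() -> cg.SimConfig:
    return cg.SimConfig(
        seed=SEED,
        n_genes=250,
        n_gfp_controls=60,
        class_map=CLASS_MAP,
        class_signatures=CLASS_SIGNATURES,
        treatment_signatures=TREATMENT_SIGNATURES,
        n_planted=12,
        effect_sizes=(2.0, 3.0),
    )
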