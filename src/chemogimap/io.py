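"""File formats, run manifests, and the end-to-end pipeline driver.

Screening data has no entrenched interchange standard, so all tabular
formats are documented plain CSV/TSV:

* plates:   CSV with columns plate_id, treatment_id, well, knockdown_label,
            replicate_index, condition {drug, vehicle}, count
* scores:   TSV with columns gene, treatment, median_vehicle, median_drug,
            fold_change, p_value, S (rows sorted by gene then treatment)
* classes:  CSV with columns treatment, drug_class [, trapping_rank]
* panels:   TSV matrices, cell-line rows x gene/treatment columns
* rescreen: TSV with columns gene, cell_line, p_value, direction

Every pipeline stage records a :class:`RunManifest` (inputs with content
hashes, config snapshot, seeds, version, timestamp) so identical manifests
reproduce identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .consensus import DrugClassAnnotation, consensus_network
from .preserve import RESCREEN_COLUMNS, validate_rescreen
from .profiles import profile_correlations
from .scoring import (InteractionMatrix, InteractionRecord, PlatePair,
                      build_matrix, score_plate)

PLATE_COLUMNS = ["plate_id", "treatment_id", "well", "knockdown_label",
                 "replicate_index", "condition", "count"]
SCORE_COLUMNS = ["gene", "treatment", "median_vehicle", "median_drug",
                 "fold_change", "p_value", "S"]


def write_plates(plates: list[PlatePair], path: str | Path) -> None:
    rows = []
    for plate in plates:
        for cond, counts in (("drug", plate.counts_drug), ("vehicle", plate.counts_vehicle)):
            for i, (well, label) in enumerate(plate.well_map.items()):
                for r in range(plate.n_rep):
                    rows.append((plate.plate_id, plate.treatment_id, well, label,
                                 r + 1, cond, counts[i, r]))
    pd.DataFrame(rows, columns=PLATE_COLUMNS).to_csv(path, index=False)


def read_plates(path: str | Path) -> list[PlatePair]:
    """Parse and validate the plates CSV; violations name the offending rows."""
    df = pd.read_csv(path)
    missing = set(PLATE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"plates file missing columns {sorted(missing)}")
    bad_cond = df.loc[~df["condition"].isin(["drug", "vehicle"])]
    if len(bad_cond):
        raise ValueError(f"condition outside {{drug, vehicle}} at rows {list(bad_cond.index)}")
    bad_count = df.loc[(df["count"] < 0) | df["count"].isna()]
    if len(bad_count):
        raise ValueError(f"negative or missing count at rows {list(bad_count.index)}")
    plates = []
    for (plate_id, treatment_id), grp in df.groupby(["plate_id", "treatment_id"], sort=True):
        well_map = dict(grp.drop_duplicates("well")[["well", "knockdown_label"]].values)
        wells = list(well_map)
        n_rep = int(grp["replicate_index"].max())
        arrays = {}
        for cond in ("drug", "vehicle"):
            sub = grp[grp["condition"] == cond]
            pivot = sub.pivot_table(index="well", columns="replicate_index",
                                    values="count", aggfunc="first")
            if pivot.isna().any().any():
                holes = pivot.index[pivot.isna().any(axis=1)]
                raise ValueError(f"plate {plate_id}: incomplete {cond} replicates "
                                 f"for wells {list(holes)}")
            arrays[cond] = pivot.loc[wells].to_numpy(dtype=float)
        plates.append(PlatePair(plate_id=str(plate_id), treatment_id=str(treatment_id),
                                well_map=well_map, counts_drug=arrays["drug"],
                                counts_vehicle=arrays["vehicle"], n_rep=n_rep))
    return plates


def write_scores(records: list[InteractionRecord], path: str | Path) -> None:
    """One row per gene-drug pair, sorted by gene then treatment."""
    df = pd.DataFrame([dataclasses.asdict(r) for r in records])[SCORE_COLUMNS]
    df = df.sort_values(["gene", "treatment"], ignore_index=True)
    df.to_csv(path, sep="\t", index=False)


def read_scores(path: str | Path) -> tuple[pd.DataFrame, InteractionMatrix]:
    df = pd.read_csv(path, sep="\t")
    missing = set(SCORE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"scores file missing columns {sorted(missing)}")
    records = [InteractionRecord(**{k: row[k] for k in SCORE_COLUMNS})
               for row in df.to_dict("records")]
    return df, build_matrix(records)


def read_annotation(path: str | Path) -> DrugClassAnnotation:
    return DrugClassAnnotation(pd.read_csv(path))


def read_panel(path: str | Path) -> pd.DataFrame:
    """TSV matrix with cell-line rows; empty cells become NaN."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_rescreen(path: str | Path) -> pd.DataFrame:
    return validate_rescreen(pd.read_csv(path, sep="\t")[RESCREEN_COLUMNS])


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Provenance record written next to every stage output."""

    stage: str
    inputs: dict[str, str] = field(default_factory=dict)   # path -> sha256
    config: dict = field(default_factory=dict)
    seed: int | None = None
    version: str = __version__
    timestamp: str = ""

    def add_input(self, path: str | Path) -> None:
        self.inputs[str(path)] = _sha256(path)

    def write(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        payload["timestamp"] = payload["timestamp"] or time.strftime(
            "%Y-%m-%dT%H:%M:%S", time.gmtime())
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def score_pipeline(plates: list[PlatePair], target_median: float = 2000.0,
                   min_corr: float = 0.7) -> tuple[list[InteractionRecord], InteractionMatrix]:
    """Normalize, QC and score all plates, then assemble the S matrix."""
    records: list[InteractionRecord] = []
    for plate in plates:
        recs, _, _ = score_plate(plate, target_median=target_median, min_corr=min_corr)
        records.extend(recs)
    if not records:
        raise ValueError("no plate passed QC; nothing to score")
    return records, build_matrix(records)


def run_pipeline(plates_path: str | Path, classes_path: str | Path, out_dir: str | Path,
                 fdr_target: float = 0.001, n_perm: int = 2000, seed: int = 0,
                 target_median: float = 2000.0, min_corr: float = 0.7) -> dict:
    """score -> consensus -> profiles on one plates file, with one manifest.

    Writes scores.tsv, consensus_edges.tsv, profile_correlations.tsv and
    manifest.json under ``out_dir``; returns a summary dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    plates = read_plates(plates_path)
    if not plates:
        raise ValueError("plates file contains no plates")
    annotation = read_annotation(classes_path)
    records, matrix = score_pipeline(plates, target_median, min_corr)
    write_scores(records, out / "scores.tsv")
    edges = consensus_network(matrix.drop_controls(), annotation,
                              fdr_target=fdr_target, n_perm=n_perm, seed=seed)
    edges.to_csv(out / "consensus_edges.tsv", sep="\t", index=False)
    table = profile_correlations(matrix)
    table.long_form(annotation).to_csv(out / "profile_correlations.tsv",
                                       sep="\t", index=False)
    manifest = RunManifest(stage="pipeline", seed=seed,
                           config={"fdr_target": fdr_target, "n_perm": n_perm,
                                   "target_median": target_median, "min_corr": min_corr})
    manifest.add_input(plates_path)
    manifest.add_input(classes_path)
    manifest.write(out / "manifest.json")
    n_scores = int(matrix.S.notna().sum().sum())
    return {"n_records": len(records), "n_scored_cells": n_scores,
            "n_edges": int(len(edges)),
            "outputs": [str(out / f) for f in
                        ("scores.tsv", "consensus_edges.tsv",
                         "profile_correlations.tsv", "manifest.json")]}
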