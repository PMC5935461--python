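"""Scoring of chemical-genetic interactions from paired plate counts.

A screen measures cell counts for each gene knockdown under a drug and under
vehicle (DMSO), over replicate wells. Each plate is median-centered to a
common per-well count, replicate concordance is checked, and every knockdown
is scored with a signed interaction score

    S = sign(log fold-change) * -log10(p),

where the p-value comes from a variance-moderated two-sample t-test of the
drug replicates against the vehicle replicates and the fold change is the
ratio of medians. Positive S means the knockdown confers drug resistance,
negative S means sensitization (potential synthetic lethality). The false
discovery rate at a score threshold is estimated empirically from
negative-control (GFP) knockdowns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

#: p-values are floored here so that scores stay finite; |S| <= 16.
P_FLOOR = 1e-16

#: Default per-well count every plate is rescaled to.
TARGET_MEDIAN = 2000.0

#: Minimum pairwise replicate correlation for a plate to pass QC.
MIN_REPLICATE_CORR = 0.7

NEGATIVE_CONTROL_PREFIX = "GFP"
POSITIVE_CONTROL_LABEL = "KIF11"


def is_negative_control(label: str) -> bool:
    """GFP knockdowns are the negative controls used for empirical FDR."""
    return str(label).upper().startswith(NEGATIVE_CONTROL_PREFIX)


def is_positive_control(label: str) -> bool:
    """Essential-gene (KIF11) knockdowns kill cells in both conditions."""
    return str(label).upper() == POSITIVE_CONTROL_LABEL


@dataclass
class PlatePair:
    """Paired drug/vehicle replicate counts for the knockdowns on one plate.

    ``counts_drug`` and ``counts_vehicle`` are wells x n_rep arrays aligned to
    ``well_map``, which maps each well (row) to its knockdown label.
    """

    plate_id: str
    treatment_id: str
    well_map: dict[str, str]
    counts_drug: np.ndarray
    counts_vehicle: np.ndarray
    n_rep: int = 4

    def __post_init__(self) -> None:
        self.counts_drug = np.asarray(self.counts_drug, dtype=float)
        self.counts_vehicle = np.asarray(self.counts_vehicle, dtype=float)
        n_wells = len(self.well_map)
        for name, arr in (("counts_drug", self.counts_drug),
                          ("counts_vehicle", self.counts_vehicle)):
            if arr.shape != (n_wells, self.n_rep):
                raise ValueError(
                    f"{name} has shape {arr.shape}, expected ({n_wells}, {self.n_rep})"
                )
            if np.any(arr < 0):
                raise ValueError(f"{name} contains negative counts")
        if self.n_rep < 2:
            raise ValueError("need at least 2 replicates per condition")

    @property
    def wells(self) -> list[str]:
        return list(self.well_map)


@dataclass
class InteractionRecord:
    """One scored gene-drug pair."""

    gene: str
    treatment: str
    median_vehicle: float
    median_drug: float
    fold_change: float
    p_value: float
    S: float


@dataclass
class InteractionMatrix:
    """Genes x treatments matrix of S scores with negative-control flags."""

    S: pd.DataFrame
    controls: frozenset[str] = field(default_factory=frozenset)

    @property
    def genes(self) -> list[str]:
        return list(self.S.index)

    @property
    def treatments(self) -> list[str]:
        return list(self.S.columns)

    def control_scores(self) -> np.ndarray:
        """All non-missing scores of negative-control knockdowns, pooled."""
        vals = self.S.loc[self.S.index.isin(self.controls)].to_numpy().ravel()
        return vals[~np.isnan(vals)]

    def noncontrol_scores(self) -> np.ndarray:
        vals = self.S.loc[~self.S.index.isin(self.controls)].to_numpy().ravel()
        return vals[~np.isnan(vals)]

    def drop_controls(self) -> "InteractionMatrix":
        keep = [g for g in self.S.index if g not in self.controls]
        return InteractionMatrix(S=self.S.loc[keep], controls=frozenset())


@dataclass
class QCResult:
    passed: bool
    min_corr: float
    detail: str = ""


def normalize_plate(counts: np.ndarray, target_median: float = TARGET_MEDIAN) -> np.ndarray:
    """Median-center a plate multiplicatively to ``target_median`` cells/well.

    Every entry is rescaled by a single factor so the median over all wells
    and replicates equals the target exactly; ratios between wells are
    untouched. Raises ``ValueError`` on an all-zero (unusable) plate.
    """
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    med = float(np.median(counts))
    if med <= 0:
        raise ValueError("plate median is zero; plate is unusable")
    return counts * (target_median / med)


def qc_replicates(counts: np.ndarray, min_corr: float = MIN_REPLICATE_CORR) -> QCResult:
    """Minimum pairwise Pearson correlation across replicate columns.

    A constant (zero-variance) replicate column cannot be correlated and is
    reported as a failure with a diagnostic rather than an exception.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[1] < 2:
        raise ValueError("need a wells x replicates matrix with >=2 columns")
    if counts.shape[0] < 3:
        raise ValueError("need at least 3 wells to assess replicate correlation")
    sds = counts.std(axis=0)
    if np.any(sds == 0):
        bad = [int(i) for i in np.flatnonzero(sds == 0)]
        return QCResult(False, float("nan"),
                        f"constant replicate column(s) {bad}: correlation undefined")
    r = np.corrcoef(counts.T)
    iu = np.triu_indices_from(r, k=1)
    min_r = float(r[iu].min())
    return QCResult(min_r >= min_corr, min_r)


def _floored_ttest(x: np.ndarray, y: np.ndarray, variance_floor: float) -> float:
    """Two-sided p from a pooled two-sample t with a variance floor.

    The pooled variance is bounded below by ``variance_floor`` (counts^2);
    with floor 0 this is exactly the textbook pooled two-sample t-test.
    """
    n1, n2 = len(x), len(y)
    df = n1 + n2 - 2
    s2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
    s2 = max(s2, variance_floor)
    diff = x.mean() - y.mean()
    if s2 == 0:
        return 1.0 if diff == 0 else P_FLOOR
    t = diff / math.sqrt(s2 * (1.0 / n1 + 1.0 / n2))
    return float(2.0 * stats.t.sf(abs(t), df))


def score_interaction(
    drug_reps: np.ndarray,
    vehicle_reps: np.ndarray,
    variance_floor: float = 0.0,
    gene: str = "",
    treatment: str = "",
) -> InteractionRecord:
    """Score one knockdown: fold change of medians + signed -log10 p.

    Both replicate vectors are expected to be plate-normalized. The p-value
    is floored at ``P_FLOOR`` so |S| never exceeds 16, and the sign of S
    follows the fold-change direction (resistance positive).
    """
    x = np.asarray(drug_reps, dtype=float)
    y = np.asarray(vehicle_reps, dtype=float)
    if np.any(x < 0) or np.any(y < 0):
        raise ValueError("replicate counts must be non-negative")
    if len(x) < 2 or len(y) < 2:
        raise ValueError("need at least 2 replicates in each condition")
    med_v = float(np.median(y))
    if med_v == 0:
        raise ValueError("vehicle median is zero: no viable reference")
    med_d = float(np.median(x))
    fold = med_d / med_v

    p = max(_floored_ttest(x, y, variance_floor), P_FLOOR)
    if fold == 1.0 or p >= 1.0:
        s = 0.0
    else:
        s = math.copysign(-math.log10(p), math.log(fold))
    return InteractionRecord(gene, treatment, med_v, med_d, fold, p, s)


def plate_variance_floor(counts_drug: np.ndarray, counts_vehicle: np.ndarray) -> float:
    """Plate-level variance moderation term.

    The median over wells of the per-knockdown pooled (drug+vehicle)
    variance. Used as the default floor in the moderated t-test so that
    wells with accidentally tight replicates do not produce huge scores.
    """
    n1 = counts_drug.shape[1]
    n2 = counts_vehicle.shape[1]
    s2 = ((n1 - 1) * counts_drug.var(axis=1, ddof=1)
          + (n2 - 1) * counts_vehicle.var(axis=1, ddof=1)) / (n1 + n2 - 2)
    return float(np.median(s2))


def score_plate(
    plate: PlatePair,
    target_median: float = TARGET_MEDIAN,
    min_corr: float = MIN_REPLICATE_CORR,
    variance_floor: float | str = "plate",
) -> tuple[list[InteractionRecord], QCResult, QCResult]:
    """Normalize, QC and score every well of one drug/vehicle plate pair.

    ``variance_floor="plate"`` uses :func:`plate_variance_floor` computed on
    the normalized counts; a number uses that floor directly. If either
    condition fails replicate QC the plate yields no records (missing cells,
    never zeros).
    """
    drug = normalize_plate(plate.counts_drug, target_median)
    veh = normalize_plate(plate.counts_vehicle, target_median)
    qc_d = qc_replicates(drug, min_corr)
    qc_v = qc_replicates(veh, min_corr)
    if not (qc_d.passed and qc_v.passed):
        return [], qc_d, qc_v
    floor = plate_variance_floor(drug, veh) if variance_floor == "plate" else float(variance_floor)
    records = [
        score_interaction(drug[i], veh[i], floor, gene=label, treatment=plate.treatment_id)
        for i, label in enumerate(plate.well_map.values())
    ]
    return records, qc_d, qc_v


def build_matrix(records: list[InteractionRecord]) -> InteractionMatrix:
    """Assemble records into a genes x treatments S matrix.

    Duplicate (gene, treatment) pairs are an error; unmatched cells are
    missing (NaN). Negative-control flags are derived from gene labels.
    """
    seen: dict[tuple[str, str], InteractionRecord] = {}
    dups = []
    for rec in records:
        key = (rec.gene, rec.treatment)
        if key in seen:
            dups.append(key)
        seen[key] = rec
    if dups:
        raise ValueError(f"duplicate (gene, treatment) records: {sorted(set(dups))}")
    genes = sorted({r.gene for r in records})
    treatments = sorted({r.treatment for r in records})
    S = pd.DataFrame(np.nan, index=genes, columns=treatments)
    for (g, t), rec in seen.items():
        S.loc[g, t] = rec.S
    controls = frozenset(g for g in genes if is_negative_control(g))
    return InteractionMatrix(S=S, controls=controls)


@dataclass
class FDRResult:
    threshold: float
    positive_pct: float
    negative_pct: float
    two_sided_pct: float
    n_controls: int


def empirical_fdr(matrix: InteractionMatrix, threshold: float) -> FDRResult:
    """Empirical FDR: percentage of negative-control scores past a threshold.

    Reported per tail (>= +threshold and <= -threshold) and combined
    (|S| >= threshold). Monotone non-increasing in the threshold.
    """
    ctrl = matrix.control_scores()
    if ctrl.size == 0:
        raise ValueError("matrix has no negative-control scores")
    pos = 100.0 * np.mean(ctrl >= threshold)
    neg = 100.0 * np.mean(ctrl <= -threshold)
    both = 100.0 * np.mean(np.abs(ctrl) >= threshold)
    return FDRResult(threshold, float(pos), float(neg), float(both), int(ctrl.size))


def threshold_at_fdr(matrix: InteractionMatrix, fdr_pct: float, tail: str = "both") -> float:
    """Smallest score threshold whose empirical FDR is <= ``fdr_pct``.

    ``tail`` selects which control-score tail calibrates the threshold:
    "positive", "negative" (both return a positive cutoff magnitude) or
    "both" (|S|).
    """
    ctrl = matrix.control_scores()
    if ctrl.size == 0:
        raise ValueError("matrix has no negative-control scores")
    if tail == "positive":
        vals = ctrl[ctrl > 0]
    elif tail == "negative":
        vals = -ctrl[ctrl < 0]
    elif tail == "both":
        vals = np.abs(ctrl)
    else:
        raise ValueError(f"unknown tail {tail!r}")
    # FDR uses the full control count in the denominator, as in empirical_fdr
    n = ctrl.size
    grid = np.sort(np.unique(np.concatenate([vals, [0.0]])))
    for thr in grid:
        if tail == "positive":
            rate = 100.0 * np.sum(ctrl >= thr) / n
        elif tail == "negative":
            rate = 100.0 * np.sum(ctrl <= -thr) / n
        else:
            rate = 100.0 * np.sum(np.abs(ctrl) >= thr) / n
        if rate <= fdr_pct:
            return float(thr)
    # no finite control score meets the target: step just past the extreme
    return float(grid[-1]) + 1e-9 if grid.size else 0.0
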