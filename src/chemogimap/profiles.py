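"""Drug interaction-profile comparisons.

A drug's genome-wide vector of S scores is a high-resolution phenotype:
drugs with a common mechanism of action (topoisomerase inhibitors, DNA
cross-linkers, PARP inhibitors, ...) show correlated profiles. This module
computes all-pairwise profile correlations, tests within-class coherence
against the between-class background, summarizes gene-set scores (e.g. the
homologous-recombination pathway against a PARP inhibitor) and quantifies
the PARP-trapping trend: the rank association between a PARP inhibitor's
trapping potency and how closely its profile resembles those of the DNA
cross-linkers cisplatin and mitomycin C.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .consensus import DrugClassAnnotation
from .scoring import InteractionMatrix

#: pairs supported by fewer shared genes than this are flagged low-support
MIN_SHARED_GENES = 30


@dataclass
class ProfileCorrelationTable:
    r: pd.DataFrame          # treatments x treatments Pearson r, pairwise-complete
    n_shared: pd.DataFrame   # shared non-missing gene counts per pair

    @property
    def treatments(self) -> list[str]:
        return list(self.r.index)

    def low_support(self, min_shared: int = MIN_SHARED_GENES) -> pd.DataFrame:
        return self.n_shared < min_shared

    def long_form(self, annotation: DrugClassAnnotation | None = None) -> pd.DataFrame:
        """Upper-triangle pairs as rows: treatment_a, treatment_b, r, n_shared."""
        rows = []
        ts = self.treatments
        for i, a in enumerate(ts):
            for b in ts[i + 1:]:
                row = {"treatment_a": a, "treatment_b": b,
                       "r": float(self.r.loc[a, b]),
                       "n_shared": int(self.n_shared.loc[a, b])}
                if annotation is not None:
                    try:
                        row["same_class"] = annotation.drug_class(a) == annotation.drug_class(b)
                    except KeyError:
                        row["same_class"] = False
                rows.append(row)
        return pd.DataFrame(rows)


def profile_correlations(matrix: InteractionMatrix) -> ProfileCorrelationTable:
    """All-pairwise Pearson correlations between drug profiles.

    Each pair uses its complete (both-non-missing) genes; listwise deletion
    across all drugs would discard far more data.
    """
    S = matrix.S
    if S.shape[1] < 2:
        raise ValueError("need at least 2 treatments")
    r = S.corr(method="pearson", min_periods=2)
    present = S.notna().astype(int)
    n_shared = present.T @ present
    return ProfileCorrelationTable(r=r, n_shared=n_shared)


def _fisher_z(r: np.ndarray) -> np.ndarray:
    return np.arctanh(np.clip(r, -0.999999, 0.999999))


def _within_between(table: ProfileCorrelationTable, annotation: DrugClassAnnotation,
                    exclude: set[str]) -> tuple[dict[str, list[float]], list[float]]:
    ts = [t for t in table.treatments if t not in exclude]
    within: dict[str, list[float]] = {}
    between: list[float] = []
    for i, a in enumerate(ts):
        for b in ts[i + 1:]:
            try:
                ca, cb = annotation.drug_class(a), annotation.drug_class(b)
            except KeyError:
                continue
            val = float(table.r.loc[a, b])
            if np.isnan(val):
                continue
            if ca == cb:
                within.setdefault(ca, []).append(val)
            else:
                between.append(val)
    return within, between


def class_coherence(table: ProfileCorrelationTable, annotation: DrugClassAnnotation,
                    exclude: set[str] | None = None) -> pd.DataFrame:
    """Within-class vs between-class profile correlation, per class.

    The background for every class is the pool of between-class pairs.
    Significance is a Welch two-sample t-test on Fisher z-transformed
    correlations. Combination treatments should be passed via ``exclude``.
    """
    within, between = _within_between(table, annotation, exclude or set())
    bg = np.asarray(between, dtype=float)
    rows = []
    for cls_name in sorted(within):
        vals = np.asarray(within[cls_name], dtype=float)
        p = np.nan
        if vals.size >= 2 and bg.size >= 2:
            p = float(stats.ttest_ind(_fisher_z(vals), _fisher_z(bg), equal_var=False).pvalue)
        rows.append({"drug_class": cls_name, "n_pairs": int(vals.size),
                     "mean_within_r": float(vals.mean()) if vals.size else np.nan,
                     "mean_between_r": float(bg.mean()) if bg.size else np.nan,
                     "p": p})
    return pd.DataFrame(rows, columns=["drug_class", "n_pairs", "mean_within_r",
                                       "mean_between_r", "p"])


def overall_coherence(table: ProfileCorrelationTable, annotation: DrugClassAnnotation,
                      exclude: set[str] | None = None) -> tuple[float, float, float]:
    """All within-class pairs vs all between-class pairs.

    Returns (mean within r, mean between r, Welch p on Fisher z values).
    """
    within, between = _within_between(table, annotation, exclude or set())
    w = np.asarray([v for vals in within.values() for v in vals], dtype=float)
    b = np.asarray(between, dtype=float)
    if w.size < 2 or b.size < 2:
        raise ValueError("need >=2 within-class and >=2 between-class pairs")
    p = float(stats.ttest_ind(_fisher_z(w), _fisher_z(b), equal_var=False).pvalue)
    return float(w.mean()), float(b.mean()), p


def set_average_score(matrix: InteractionMatrix, gene_set: list[str],
                      treatment: str) -> tuple[float, float, int]:
    """Mean S of a gene set for one drug, with a one-sample t-test vs zero.

    Returns (mean S, two-sided p, n genes used). Genes absent from the
    matrix or missing for this treatment are dropped.
    """
    if not gene_set:
        raise ValueError("gene set is empty")
    present = [g for g in gene_set if g in matrix.S.index]
    vals = matrix.S.loc[present, treatment].dropna().to_numpy(dtype=float)
    if vals.size < 2:
        raise ValueError("need >=2 set members with non-missing scores")
    if np.allclose(vals, vals[0]):
        p = 1.0 if vals[0] == 0 else 0.0
    else:
        p = float(stats.ttest_1samp(vals, 0.0).pvalue)
    return float(vals.mean()), p, int(vals.size)


def trapping_trend(table: ProfileCorrelationTable, annotation: DrugClassAnnotation,
                   reference_treatments: list[str]) -> tuple[float, float, pd.DataFrame]:
    """PARP-trapping trend: Spearman rho of trapping rank vs cross-linker similarity.

    For each annotated drug with a trapping rank, the mean profile
    correlation with the reference cross-linkers is computed; the trend is
    the Spearman rank correlation between trapping rank and that mean.
    """
    if "trapping_rank" not in annotation.table.columns:
        raise ValueError("annotation has no trapping_rank column")
    ranked = annotation.table.dropna(subset=["trapping_rank"])
    ranked = ranked[ranked["treatment"].isin(table.treatments)]
    if len(ranked) < 3:
        raise ValueError("need >=3 treatments with trapping ranks")
    refs = [t for t in reference_treatments if t in table.treatments]
    if not refs:
        raise ValueError("no reference treatment present in the correlation table")
    rows = []
    for _, row in ranked.iterrows():
        t = row["treatment"]
        mean_r = float(np.nanmean([table.r.loc[t, ref] for ref in refs]))
        rows.append({"treatment": t, "trapping_rank": float(row["trapping_rank"]),
                     "mean_r_with_refs": mean_r})
    frame = pd.DataFrame(rows)
    res = stats.spearmanr(frame["trapping_rank"], frame["mean_r_with_refs"])
    return float(res.statistic), float(res.pvalue), frame
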