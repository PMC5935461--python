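"""Gene <-> drug-class consensus network with a permutation-based FDR.

Drugs sharing a mechanism of action (e.g. the four PARP inhibitors, or the
topoisomerase inhibitors) should elicit concordant interaction profiles, so
scores are aggregated per drug class: the class statistic for a gene is the
unweighted mean S over class-member drugs. Significance is assessed against
a permutation null in which gene labels are shuffled independently within
each treatment column — this preserves each drug's marginal score
distribution while breaking any gene-class association. The per-edge FDR is
the fraction of pooled null class statistics at least as extreme, per tail
and per class.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scoring import InteractionMatrix

#: classes need at least this many member drugs to enter the consensus
MIN_CLASS_SIZE = 2

#: and a gene needs this many non-missing member scores for a statistic
MIN_MEMBER_SCORES = 2

DEFAULT_N_PERM = 10_000


@dataclass
class DrugClassAnnotation:
    """Treatment -> drug-class map, with optional PARP-trapping ranks."""

    table: pd.DataFrame  # columns: treatment, drug_class, optional trapping_rank

    def __post_init__(self) -> None:
        required = {"treatment", "drug_class"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"annotation missing columns {sorted(missing)}")
        if self.table["treatment"].duplicated().any():
            dup = self.table.loc[self.table["treatment"].duplicated(), "treatment"]
            raise ValueError(f"treatments annotated more than once: {list(dup)}")

    @classmethod
    def from_mapping(cls, mapping: dict[str, str],
                     trapping_rank: dict[str, float] | None = None) -> "DrugClassAnnotation":
        df = pd.DataFrame({"treatment": list(mapping), "drug_class": list(mapping.values())})
        if trapping_rank:
            df["trapping_rank"] = df["treatment"].map(trapping_rank)
        return cls(df)

    def drug_class(self, treatment: str) -> str:
        row = self.table.loc[self.table["treatment"] == treatment, "drug_class"]
        if row.empty:
            raise KeyError(f"treatment {treatment!r} not annotated")
        return str(row.iloc[0])

    def members(self, drug_class: str) -> list[str]:
        return list(self.table.loc[self.table["drug_class"] == drug_class, "treatment"])

    def consensus_classes(self, treatments: list[str] | None = None) -> dict[str, list[str]]:
        """Classes with >= MIN_CLASS_SIZE members (restricted to ``treatments``)."""
        out: dict[str, list[str]] = {}
        for cls_name, grp in self.table.groupby("drug_class"):
            members = list(grp["treatment"])
            if treatments is not None:
                members = [t for t in members if t in treatments]
            if len(members) >= MIN_CLASS_SIZE:
                out[str(cls_name)] = members
        return out


@dataclass
class ConsensusEdge:
    gene: str
    drug_class: str
    statistic: float
    sign: int
    fdr: float


def class_statistic(matrix: InteractionMatrix, annotation: DrugClassAnnotation,
                    gene: str, drug_class: str) -> float:
    """Mean S of one gene over the member drugs of one class.

    NaN when fewer than MIN_MEMBER_SCORES member scores are available.
    """
    members = [t for t in annotation.members(drug_class) if t in matrix.S.columns]
    vals = matrix.S.loc[gene, members].to_numpy(dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size < MIN_MEMBER_SCORES:
        return float("nan")
    return float(vals.mean())


def _class_stats_frame(S: pd.DataFrame, classes: dict[str, list[str]]) -> pd.DataFrame:
    """Genes x classes mean-S frame; cells with <2 member scores are NaN."""
    cols = {}
    for cls_name, members in classes.items():
        block = S[members]
        n_ok = block.notna().sum(axis=1)
        mean = block.mean(axis=1, skipna=True)
        mean[n_ok < MIN_MEMBER_SCORES] = np.nan
        cols[cls_name] = mean
    return pd.DataFrame(cols)


def class_statistics(matrix: InteractionMatrix, annotation: DrugClassAnnotation) -> pd.DataFrame:
    classes = annotation.consensus_classes(matrix.treatments)
    return _class_stats_frame(matrix.S, classes)


def permutation_null(matrix: InteractionMatrix, annotation: DrugClassAnnotation,
                     n_perm: int = DEFAULT_N_PERM, seed: int = 0,
                     exhaustive: bool = False) -> dict[str, np.ndarray]:
    """Pooled null distribution of class statistics, per class.

    Each permutation shuffles gene labels independently within every
    treatment column and recomputes all gene x class statistics; the null
    values of all genes and permutations are pooled per class.

    ``exhaustive=True`` enumerates every combination of within-column
    permutations instead of sampling (tiny matrices only).
    """
    classes = annotation.consensus_classes(matrix.treatments)
    if not classes:
        raise ValueError("no drug class has >=2 members among the matrix treatments")
    S = matrix.S
    members_all = sorted({t for m in classes.values() for t in m})
    vals = S[members_all].to_numpy(dtype=float)
    idx = {t: j for j, t in enumerate(members_all)}
    null: dict[str, list[np.ndarray]] = {c: [] for c in classes}

    def collect(perm_vals: np.ndarray) -> None:
        for cls_name, members in classes.items():
            block = perm_vals[:, [idx[t] for t in members]]
            n_ok = np.sum(~np.isnan(block), axis=1)
            with np.errstate(invalid="ignore"):
                means = np.nanmean(block, axis=1)
            means = means[n_ok >= MIN_MEMBER_SCORES]
            null[cls_name].append(means)

    n_genes, n_cols = vals.shape
    if exhaustive:
        total = math.factorial(n_genes) ** n_cols
        if total > 2_000_000:
            raise ValueError(f"{total} permutation combinations; too many to enumerate")
        perms = list(itertools.permutations(range(n_genes)))
        for combo in itertools.product(perms, repeat=n_cols):
            perm_vals = np.column_stack([vals[list(p), j] for j, p in enumerate(combo)])
            collect(perm_vals)
    else:
        if n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        rng = np.random.default_rng(seed)
        for _ in range(n_perm):
            collect(rng.permuted(vals, axis=0))
    return {c: np.concatenate(v) if v else np.empty(0) for c, v in null.items()}


def _tail_fraction(null_vals: np.ndarray, stat: float) -> float:
    """Fraction of null statistics at least as extreme, in stat's tail."""
    if null_vals.size == 0:
        return float("nan")
    if stat >= 0:
        return float(np.mean(null_vals >= stat))
    return float(np.mean(null_vals <= stat))


def consensus_network(matrix: InteractionMatrix, annotation: DrugClassAnnotation,
                      fdr_target: float = 0.001, n_perm: int = DEFAULT_N_PERM,
                      seed: int = 0, concordant_only: bool = False,
                      exhaustive: bool = False) -> pd.DataFrame:
    """Gene <-> drug-class edges passing the permutation FDR.

    Returns a frame with columns gene, drug_class, statistic, sign, fdr,
    sorted by (drug_class, gene). ``concordant_only`` additionally requires
    all member scores of an edge to share the statistic's sign.
    """
    if not (0.0 < fdr_target < 1.0):
        raise ValueError("fdr_target must be in (0, 1)")
    classes = annotation.consensus_classes(matrix.treatments)
    stats_frame = _class_stats_frame(matrix.S, classes)
    null = permutation_null(matrix, annotation, n_perm=n_perm, seed=seed,
                            exhaustive=exhaustive)
    rows = []
    for cls_name, members in classes.items():
        null_vals = null[cls_name]
        for gene, stat in stats_frame[cls_name].items():
            if np.isnan(stat):
                continue
            fdr = _tail_fraction(null_vals, float(stat))
            if fdr > fdr_target:
                continue
            if concordant_only:
                member_vals = matrix.S.loc[gene, members].dropna()
                if not (np.all(member_vals > 0) or np.all(member_vals < 0)):
                    continue
            rows.append({"gene": gene, "drug_class": cls_name,
                         "statistic": float(stat),
                         "sign": int(np.sign(stat)) if stat != 0 else 0,
                         "fdr": fdr})
    edges = pd.DataFrame(rows, columns=["gene", "drug_class", "statistic", "sign", "fdr"])
    return edges.sort_values(["drug_class", "gene"], ignore_index=True)


def edges_per_class(edges: pd.DataFrame) -> pd.Series:
    """Edge count per drug class (reported alongside the network)."""
    if edges.empty:
        return pd.Series(dtype=int)
    return edges.groupby("drug_class").size()
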