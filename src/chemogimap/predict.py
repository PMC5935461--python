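"""Expression-based drug-response prediction from the interaction map.

The signed interaction network of a drug (genes with |S| past a cutoff,
signed by resistance/sensitivity direction) is used, unsupervised, to score
cell lines: a line's predicted sensitivity is the sum over network genes of
sign(gene) x standardized expression. A gene whose knockdown causes
resistance (S > 0) contributes positively when highly expressed — losing it
protects the cell, so having a lot of it sensitizes. Predictions are
evaluated against drug-response AUC values (higher AUC = more resistant), so
a successful prediction correlates negatively with AUC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import InteractionMatrix

MIN_SHARED_LINES = 10


@dataclass
class SignedNetwork:
    """Signed gene membership for one drug at one score cutoff."""

    treatment: str
    members: dict[str, int]  # gene -> +1 (resistance) / -1 (sensitivity)
    cutoff: float


def standardize_expression(expr: pd.DataFrame, method: str = "zscore") -> pd.DataFrame:
    """Per-gene standardization across cell lines (rows=lines, cols=genes).

    ``zscore`` centers and scales each gene to mean 0, sd 1; ``rank``
    replaces values by within-gene ranks scaled to [-1, 1]. Genes with zero
    variance are dropped.
    """
    expr = expr.astype(float)
    sds = expr.std(axis=0, ddof=0)
    keep = sds[sds > 0].index
    expr = expr[keep]
    if method == "zscore":
        return (expr - expr.mean(axis=0)) / expr.std(axis=0, ddof=0)
    if method == "rank":
        ranks = expr.rank(axis=0)
        n = len(expr)
        return 2.0 * (ranks - 1) / (n - 1) - 1.0
    raise ValueError(f"unknown method {method!r}")


def network_for_drug(matrix: InteractionMatrix, treatment: str, cutoff: float) -> SignedNetwork:
    """Genes with S >= +cutoff (sign +1) or S <= -cutoff (sign -1)."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    col = matrix.S[treatment].dropna()
    members = {}
    for gene, s in col.items():
        if s >= cutoff:
            members[gene] = 1
        elif s <= -cutoff:
            members[gene] = -1
    return SignedNetwork(treatment=treatment, members=members, cutoff=cutoff)


def predict_sensitivity(z: pd.DataFrame, network: SignedNetwork) -> pd.Series:
    """Per-line predicted sensitivity: sum of sign(gene) x z(gene, line).

    Network genes absent from the expression panel are dropped; an empty
    usable network is an error. Linear in z and antisymmetric under flipping
    every network sign.
    """
    genes = [g for g in network.members if g in z.columns]
    if not genes:
        raise ValueError(f"no network gene for {network.treatment!r} present in expression panel")
    signs = np.array([network.members[g] for g in genes], dtype=float)
    scores = z[genes].to_numpy(dtype=float) @ signs
    return pd.Series(scores, index=z.index, name=network.treatment)


@dataclass
class PredictionResult:
    treatment: str
    r: float
    p: float            # two-sided
    significant: bool   # one-sided test in the concordant direction at alpha
    n_lines: int


def evaluate_predictions(scores: pd.Series, auc: pd.Series, treatment: str = "",
                         alpha: float = 0.05, direction: str = "negative",
                         min_lines: int = MIN_SHARED_LINES) -> PredictionResult | None:
    """Correlate predicted sensitivity with measured AUC.

    ``direction`` is the concordant sign of r ("negative" when higher AUC
    means resistance, the CTRP convention). The significance flag is a
    one-sided test in that direction at level ``alpha``, so under a null of
    independence it fires at rate alpha. Returns None (skip, not failure)
    below ``min_lines`` shared cell lines.
    """
    common = scores.index.intersection(auc.dropna().index)
    if len(common) < min_lines:
        return None
    x = scores.loc[common].to_numpy(dtype=float)
    y = auc.loc[common].to_numpy(dtype=float)
    res = stats.pearsonr(x, y)
    r, p_two = float(res.statistic), float(res.pvalue)
    concordant = (r < 0) if direction == "negative" else (r > 0)
    p_one = p_two / 2.0 if concordant else 1.0 - p_two / 2.0
    return PredictionResult(treatment=treatment, r=r, p=p_two,
                            significant=bool(p_one <= alpha), n_lines=int(len(common)))


def gene_contributions(z: pd.DataFrame, network: SignedNetwork, auc: pd.Series,
                       min_lines: int = MIN_SHARED_LINES) -> pd.Series:
    """Leave-one-out contribution of each network gene to prediction strength.

    Contribution = |r(full network)| - |r(network without the gene)|; a
    single-gene network's only contribution is the full |r|. Sorted
    descending.
    """
    full = evaluate_predictions(predict_sensitivity(z, network), auc,
                                network.treatment, min_lines=min_lines)
    if full is None:
        raise ValueError("too few shared cell lines for contribution analysis")
    base = abs(full.r)
    contribs = {}
    for gene in network.members:
        if gene not in z.columns:
            continue
        rest = {g: s for g, s in network.members.items() if g != gene}
        if not rest:
            contribs[gene] = base
            continue
        sub = SignedNetwork(network.treatment, rest, network.cutoff)
        res = evaluate_predictions(predict_sensitivity(z, sub), auc,
                                   network.treatment, min_lines=min_lines)
        contribs[gene] = base - abs(res.r) if res is not None else np.nan
    return pd.Series(contribs).sort_values(ascending=False)


def sliding_cutoff(matrix: InteractionMatrix, z: pd.DataFrame, auc: pd.DataFrame,
                   cutoffs: list[float], alpha: float = 0.05,
                   direction: str = "negative") -> pd.DataFrame:
    """Count significantly predicted drugs across a grid of score cutoffs.

    For each cutoff, every drug shared between the matrix and the response
    panel is evaluated with its network at that cutoff. Networks shrink as
    the cutoff rises (set inclusion), so stringent cutoffs use only the
    strongest interactions. Rows: cutoff, n_evaluable, n_significant.
    """
    shared = [t for t in matrix.treatments if t in auc.columns]
    rows = []
    for cutoff in cutoffs:
        n_eval = 0
        n_sig = 0
        for t in shared:
            network = network_for_drug(matrix, t, cutoff)
            if not any(g in z.columns for g in network.members):
                continue
            res = evaluate_predictions(predict_sensitivity(z, network), auc[t], t,
                                       alpha=alpha, direction=direction)
            if res is None:
                continue
            n_eval += 1
            n_sig += int(res.significant)
        rows.append({"cutoff": float(cutoff), "n_evaluable": n_eval, "n_significant": n_sig})
    return pd.DataFrame(rows)


@dataclass
class OverlapResult:
    overlap_fraction: float      # past-cutoff interactions with concordant correlate
    background_fraction: float   # same among all tested gene-drug pairs
    p_enrichment: float          # hypergeometric
    n_past_cutoff: int
    n_tested: int


def overlap_with_correlates(matrix: InteractionMatrix, z: pd.DataFrame, auc: pd.DataFrame,
                            cutoff: float, p_thresh: float = 0.01) -> OverlapResult:
    """Overlap between map interactions and expression-response correlates.

    A gene-drug pair "has a correlate" when the gene's expression correlates
    with response to that drug across cell lines (two-sided p < p_thresh) in
    the concordant direction: a resistance interaction (S > 0) pairs with a
    negative expression-AUC correlation (high expression = sensitive), and
    symmetrically for sensitivity. Enrichment of correlates among
    past-cutoff interactions over the all-tested background is assessed by a
    hypergeometric test.
    """
    shared = [t for t in matrix.treatments if t in auc.columns]
    if not shared:
        raise ValueError("no shared drugs between matrix and response panel")
    n_tested = 0
    n_corr_total = 0
    n_past = 0
    n_overlap = 0
    for t in shared:
        resp = auc[t].dropna()
        col = matrix.S[t].dropna()
        for gene, s in col.items():
            if gene not in z.columns or s == 0:
                continue
            common = z.index.intersection(resp.index)
            if len(common) < MIN_SHARED_LINES:
                continue
            res = stats.pearsonr(z.loc[common, gene], resp.loc[common])
            concordant = np.sign(res.statistic) == -np.sign(s)
            has_correlate = bool(res.pvalue < p_thresh and concordant)
            n_tested += 1
            n_corr_total += int(has_correlate)
            if abs(s) >= cutoff:
                n_past += 1
                n_overlap += int(has_correlate)
    if n_tested == 0:
        raise ValueError("no testable gene-drug pairs")
    overlap = n_overlap / n_past if n_past else 0.0
    background = n_corr_total / n_tested
    p = float(stats.hypergeom.sf(n_overlap - 1, n_tested, n_corr_total, n_past)) \
        if n_past else 1.0
    return OverlapResult(overlap, background, p, n_past, n_tested)
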