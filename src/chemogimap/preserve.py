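"""Cross-cell-line preservation of primary-screen interactions.

Interactions found in the primary (MCF10A) screen are rescreened in other
cell lines; an interaction is preserved in a line when it is significant
there (p below a threshold, default 0.01) with the same direction as the
primary fold change. The headline statistic is the cumulative preservation
rate as a function of primary-screen score cutoff: among interactions with
S past a cutoff, the fraction preserved in at least ``min_lines`` rescreened
lines. Stronger primary scores should preserve more often.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .scoring import InteractionMatrix

RESCREEN_COLUMNS = ["gene", "cell_line", "p_value", "direction"]

#: sliding-average window, in cutoff grid points (centered)
SMOOTH_WINDOW = 11


def validate_rescreen(rescreen: pd.DataFrame) -> pd.DataFrame:
    missing = set(RESCREEN_COLUMNS) - set(rescreen.columns)
    if missing:
        raise ValueError(f"rescreen table missing columns {sorted(missing)}")
    bad = rescreen[(rescreen["p_value"] <= 0) | (rescreen["p_value"] > 1)]
    if len(bad):
        raise ValueError(f"p_value out of (0,1] in rows {list(bad.index)}")
    return rescreen


def preserved_line_counts(primary: InteractionMatrix, rescreen: pd.DataFrame,
                          treatment: str, p_thresh: float = 0.01) -> pd.Series:
    """Per gene: number of rescreened lines where the interaction is preserved.

    Preservation requires per-line significance at ``p_thresh`` and the same
    direction as the primary interaction; direction is the sign of the
    per-line fold change as recorded in the rescreen table.
    """
    validate_rescreen(rescreen)
    primary_s = primary.S[treatment].dropna()
    hits = rescreen[rescreen["p_value"] < p_thresh]
    counts = pd.Series(0, index=primary_s.index, dtype=int)
    for gene, grp in hits.groupby("gene"):
        if gene not in primary_s.index:
            continue
        same_dir = np.sign(grp["direction"]) == np.sign(primary_s[gene])
        counts[gene] = int(same_dir.sum())
    return counts


def preservation_rate(primary: InteractionMatrix, rescreen: pd.DataFrame,
                      treatment: str, min_lines: int = 1, p_thresh: float = 0.01,
                      cutoffs: np.ndarray | None = None,
                      window: int = SMOOTH_WINDOW) -> pd.DataFrame:
    """Cumulative preservation curves over a score-cutoff grid.

    For each cutoff c: among genes with primary S >= c (positive tail) or
    S <= -c (negative tail), the fraction preserved in >= min_lines lines.
    Cutoffs with no qualifying genes are omitted. Raw rates are always
    emitted alongside a centered sliding average (``rate_smoothed``).
    """
    if cutoffs is None:
        cutoffs = np.arange(0.0, 8.5, 0.25)
    primary_s = primary.S[treatment].dropna()
    counts = preserved_line_counts(primary, rescreen, treatment, p_thresh)
    rows = []
    for tail, sel in (("positive", lambda c: primary_s >= c),
                      ("negative", lambda c: primary_s <= -c)):
        for c in cutoffs:
            mask = sel(float(c))
            n = int(mask.sum())
            if n == 0:
                continue
            rate = float((counts[mask.index[mask]] >= min_lines).mean())
            rows.append({"tail": tail, "cutoff": float(c), "n_interactions": n, "rate": rate})
    frame = pd.DataFrame(rows, columns=["tail", "cutoff", "n_interactions", "rate"])
    if frame.empty:
        return frame.assign(rate_smoothed=pd.Series(dtype=float))
    smoothed = []
    for _, grp in frame.groupby("tail", sort=False):
        smoothed.append(grp["rate"].rolling(window, center=True, min_periods=1).mean())
    frame["rate_smoothed"] = pd.concat(smoothed)
    return frame
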