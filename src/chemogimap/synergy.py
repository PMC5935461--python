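"""Dose-matrix drug-combination analysis.

Monotherapy dose responses are summarized by the median-effect (Hill) model

    fa = 1 / (1 + (Dm / D)^m),

fit by least squares on the log-linearized form log(fa/(1-fa)) = m log D -
m log Dm. From two fits, the Loewe-additive expectation at any dose pair
(a, b) is the effect E solving a/D_A(E) + b/D_B(E) = 1, where D_X(E) is the
dose of drug X alone producing E. Synergy is quantified as the mean excess
of observed inhibition over the Loewe surface across combination doses
(positive = synergy), and per dose pair by the Chou-Talalay combination
index CI = a/D_A(fa) + b/D_B(fa) (CI < 1 synergy, = 1 additivity, > 1
antagonism). A Bliss-independence expectation for a single dose pair is
also provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

_E_LO, _E_HI = 1e-9, 1.0 - 1e-9


@dataclass
class MedianEffectFit:
    """Median-effect parameters: Dm (IC50-equivalent), slope m, fit r^2."""

    Dm: float
    m: float
    fit_r2: float

    def effect_at_dose(self, dose: float) -> float:
        """Affected fraction at a monotherapy dose."""
        if dose <= 0:
            return 0.0
        return 1.0 / (1.0 + (self.Dm / dose) ** self.m)

    def dose_for_effect(self, fa: float) -> float:
        """Monotherapy dose producing affected fraction ``fa``."""
        if not (0.0 < fa < 1.0):
            raise ValueError("fa must be strictly inside (0, 1)")
        return self.Dm * (fa / (1.0 - fa)) ** (1.0 / self.m)


@dataclass
class DoseResponseMatrix:
    """Combination dose grid of growth-inhibition fractions.

    ``inhibition[i, j]`` is the inhibition at dose pair
    (doses_a[i], doses_b[j]); both axes include dose 0 and inhibition is
    clipped to [0, 1] (out-of-range input is counted and warned about).
    """

    doses_a: np.ndarray
    doses_b: np.ndarray
    inhibition: np.ndarray

    def __post_init__(self) -> None:
        self.doses_a = np.asarray(self.doses_a, dtype=float)
        self.doses_b = np.asarray(self.doses_b, dtype=float)
        inh = np.asarray(self.inhibition, dtype=float)
        if inh.shape != (len(self.doses_a), len(self.doses_b)):
            raise ValueError("inhibition shape does not match dose axes")
        for d in (self.doses_a, self.doses_b):
            if d[0] != 0 or np.any(np.diff(d) <= 0):
                raise ValueError("doses must start at 0 and increase strictly")
        n_out = int(np.sum((inh < 0) | (inh > 1)))
        if n_out:
            warnings.warn(f"{n_out} inhibition values outside [0, 1] were clipped")
        self.inhibition = np.clip(inh, 0.0, 1.0)

    def monotherapy_a(self) -> tuple[np.ndarray, np.ndarray]:
        return self.doses_a, self.inhibition[:, 0]

    def monotherapy_b(self) -> tuple[np.ndarray, np.ndarray]:
        return self.doses_b, self.inhibition[0, :]


def fit_median_effect(doses: np.ndarray, inhibition: np.ndarray) -> MedianEffectFit:
    """Fit the median-effect line to monotherapy (dose, inhibition) pairs.

    Points with fa exactly 0 or 1 (or dose 0) carry no information on the
    log-linearized scale and are excluded with a warning; at least 3 usable
    points are required.
    """
    doses = np.asarray(doses, dtype=float)
    fa = np.asarray(inhibition, dtype=float)
    usable = (doses > 0) & (fa > 0.0) & (fa < 1.0)
    n_dropped = int(np.sum((doses > 0) & ((fa <= 0.0) | (fa >= 1.0))))
    if n_dropped:
        warnings.warn(f"excluded {n_dropped} dose points with fa at 0 or 1")
    if usable.sum() < 3:
        raise ValueError("need >=3 doses with inhibition strictly inside (0, 1)")
    x = np.log(doses[usable])
    y = np.log(fa[usable] / (1.0 - fa[usable]))
    res = stats.linregress(x, y)
    m = float(res.slope)
    if m <= 0:
        raise ValueError("non-positive median-effect slope: response not increasing with dose")
    dm = float(np.exp(-res.intercept / m))
    return MedianEffectFit(Dm=dm, m=m, fit_r2=float(res.rvalue ** 2))


def loewe_expected(fit_a: MedianEffectFit, fit_b: MedianEffectFit,
                   dose_a: float, dose_b: float, tol: float = 1e-9) -> float:
    """Loewe-additive expected inhibition at a dose pair.

    Solves a/D_A(E) + b/D_B(E) = 1 for E on (0, 1) by bisection (brentq).
    A drug is exactly additive with itself, so the self-combination surface
    depends only on total dose.
    """
    if dose_a < 0 or dose_b < 0:
        raise ValueError("doses must be non-negative")
    if dose_a == 0 and dose_b == 0:
        return 0.0
    if dose_b == 0:
        return fit_a.effect_at_dose(dose_a)
    if dose_a == 0:
        return fit_b.effect_at_dose(dose_b)

    def f(e: float) -> float:
        return dose_a / fit_a.dose_for_effect(e) + dose_b / fit_b.dose_for_effect(e) - 1.0

    # f decreases in E: larger effects need larger equivalent doses
    if f(_E_LO) <= 0:
        return 0.0
    if f(_E_HI) >= 0:
        return 1.0
    return float(optimize.brentq(f, _E_LO, _E_HI, xtol=tol))


def loewe_surface(matrix: DoseResponseMatrix, fit_a: MedianEffectFit,
                  fit_b: MedianEffectFit) -> np.ndarray:
    exp = np.zeros_like(matrix.inhibition)
    for i, da in enumerate(matrix.doses_a):
        for j, db in enumerate(matrix.doses_b):
            exp[i, j] = loewe_expected(fit_a, fit_b, float(da), float(db))
    return exp


def synergy_score(matrix: DoseResponseMatrix,
                  fit_a: MedianEffectFit | None = None,
                  fit_b: MedianEffectFit | None = None,
                  normalization: str = "mean") -> tuple[float, pd.DataFrame]:
    """Loewe-excess synergy score for a dose matrix.

    Excess = observed - Loewe-expected inhibition per cell. The score is the
    mean excess over combination cells (both doses nonzero), which is
    grid-size free; ``normalization="total"`` sums instead. Monotherapy fits
    are taken from the matrix margins when not supplied. Positive score =
    synergy, negative = antagonism.
    """
    if fit_a is None:
        fit_a = fit_median_effect(*matrix.monotherapy_a())
    if fit_b is None:
        fit_b = fit_median_effect(*matrix.monotherapy_b())
    expected = loewe_surface(matrix, fit_a, fit_b)
    excess = matrix.inhibition - expected
    combo = np.outer(matrix.doses_a > 0, matrix.doses_b > 0)
    if normalization == "mean":
        score = float(excess[combo].mean())
    elif normalization == "total":
        score = float(excess[combo].sum())
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    frame = pd.DataFrame(excess, index=matrix.doses_a, columns=matrix.doses_b)
    return score, frame


#: Chou-Talalay qualitative CI bands
CI_BANDS = ((0.3, "strong synergy"), (0.7, "moderate synergy"), (1.0, "slight synergy"))


def combination_index(dose_a: float, dose_b: float, fit_a: MedianEffectFit,
                      fit_b: MedianEffectFit, fa_observed: float) -> tuple[float, str]:
    """Chou-Talalay combination index at an observed combined effect.

    CI = dose_a/D_A(fa) + dose_b/D_B(fa); homogeneous of degree 1 in the
    dose pair at fixed fa. Returns (CI, qualitative band).
    """
    if not (0.0 < fa_observed < 1.0):
        raise ValueError("fa_observed must be strictly inside (0, 1)")
    ci = dose_a / fit_a.dose_for_effect(fa_observed) + dose_b / fit_b.dose_for_effect(fa_observed)
    for upper, label in CI_BANDS:
        if ci < upper:
            return float(ci), label
    return float(ci), "non-synergistic"


def expected_additive_inhibition(e_a: float, e_b: float) -> float:
    """Bliss-independence expectation for combining two single-agent effects.

    e_a + e_b - e_a*e_b: the fraction affected if the two drugs hit
    independently. The Loewe alternative for a specific dose pair is
    :func:`loewe_expected`.
    """
    if not (0.0 <= e_a <= 1.0 and 0.0 <= e_b <= 1.0):
        raise ValueError("effects must be in [0, 1]")
    return e_a + e_b - e_a * e_b
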