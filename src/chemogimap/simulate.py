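"""Synthetic screen generator with planted ground truth.

Emulates the screen design end to end so every analysis stage can be tested
against a known answer: ~626 knockdowns per drug (scored genes plus GFP
negative controls and a KIF11 essential-gene positive control), four
replicate wells per condition, drug dosed at its IC50 (half-maximal kill),
multiplicative whole-plate effects, and lognormal count noise. Planted
gene-drug effects act as multiplicative growth modifiers in the drug
condition only (>1 resistance, <1 sensitivity); drug-class signatures plant
the same modifier across all member drugs of a class, driving correlated
profiles. Expression/response panels and combination dose matrices are
generated from the same ground truth for the prediction and synergy stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scoring import PlatePair
from .synergy import DoseResponseMatrix, MedianEffectFit, loewe_expected


@dataclass
class GroundTruth:
    """Planted effects: the oracle for recovery tests.

    ``effects`` maps (gene, treatment) to a multiplicative drug-condition
    growth modifier (1 = no interaction); ``gene_roles`` tags each knockdown
    as null / control_negative / control_positive / planted.
    """

    effects: dict[tuple[str, str], float] = field(default_factory=dict)
    gene_roles: dict[str, str] = field(default_factory=dict)
    class_signatures: dict[str, dict[str, float]] = field(default_factory=dict)

    def modifier(self, gene: str, treatment: str) -> float:
        return self.effects.get((gene, treatment), 1.0)

    def planted_pairs(self, min_fold: float = 1.0) -> list[tuple[str, str]]:
        """Planted (gene, treatment) pairs with |log modifier| >= log(min_fold)."""
        return [k for k, v in self.effects.items()
                if abs(np.log(v)) >= np.log(min_fold) - 1e-12]


@dataclass
class SimConfig:
    """Screen-generator settings mirroring the screen design.

    626 knockdowns per drug = 525 scored genes + 100 GFP negative controls
    + 1 KIF11 positive control; 4 replicate wells per condition; 2,000
    cells/well baseline; drugs dosed for half-maximal kill; 8% lognormal
    count noise (which puts a planted 1.5x effect at |S| ~ 3-6); 10%
    multiplicative plate effects.
    """

    seed: int
    n_genes: int = 525
    n_gfp_controls: int = 100
    n_treatments: int = 4
    n_rep: int = 4
    baseline_count: float = 2000.0
    drug_kill_fraction: float = 0.5
    count_noise_cv: float = 0.08
    plate_effect_sd: float = 0.10
    #: spread of per-knockdown proliferation rates (log scale). Knockdowns of
    #: growth-relevant genes differ a lot in viability; this spread is what
    #: makes replicate columns correlate and lets plates pass the 0.7 QC.
    viability_log_sd: float = 0.20
    n_planted: int = 0
    effect_sizes: tuple[float, ...] = (2.0,)
    class_map: dict[str, str] | None = None          # treatment -> drug class
    class_signatures: dict[str, dict[str, float]] | None = None  # class -> gene -> modifier
    #: per-drug planted effects on top of class signatures, e.g. graded
    #: cross-linker-like signatures across PARP inhibitors of rising trapping
    #: potency
    treatment_signatures: dict[str, dict[str, float]] | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("baseline_count", "drug_kill_fraction", "count_noise_cv"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def gene_names(self) -> list[str]:
        return [f"GENE{i:04d}" for i in range(1, self.n_genes + 1)]

    @property
    def gfp_names(self) -> list[str]:
        return [f"GFP{i:03d}" for i in range(1, self.n_gfp_controls + 1)]

    @property
    def treatment_names(self) -> list[str]:
        if self.class_map:
            return list(self.class_map)
        return [f"DRUG{i:02d}" for i in range(1, self.n_treatments + 1)]


def _lognoise(rng: np.random.Generator, cv: float, shape) -> np.ndarray:
    """Multiplicative lognormal noise with mean 1 and the given CV."""
    sigma = np.sqrt(np.log1p(cv ** 2))
    return np.exp(rng.normal(-0.5 * sigma ** 2, sigma, size=shape))


def _plant_effects(config: SimConfig, rng: np.random.Generator,
                   truth: GroundTruth) -> None:
    genes = config.gene_names
    treatments = config.treatment_names
    if config.n_planted:
        pairs = [(g, t) for g in genes for t in treatments]
        chosen = rng.choice(len(pairs), size=config.n_planted, replace=False)
        for k, pick in enumerate(chosen):
            g, t = pairs[pick]
            mag = float(config.effect_sizes[k % len(config.effect_sizes)])
            # alternate resistance (modifier mag) and sensitivity (1/mag)
            modifier = mag if k % 2 == 0 else 1.0 / mag
            truth.effects[(g, t)] = modifier
            truth.gene_roles[g] = "planted"
    if config.class_signatures and config.class_map:
        truth.class_signatures = {c: dict(sig) for c, sig in config.class_signatures.items()}
        for t, cls_name in config.class_map.items():
            for g, modifier in config.class_signatures.get(cls_name, {}).items():
                truth.effects[(g, t)] = truth.effects.get((g, t), 1.0) * modifier
                truth.gene_roles[g] = "planted"
    if config.treatment_signatures:
        for t, sig in config.treatment_signatures.items():
            for g, modifier in sig.items():
                truth.effects[(g, t)] = truth.effects.get((g, t), 1.0) * modifier
                truth.gene_roles[g] = "planted"


#: fraction of baseline proliferation retained after essential-gene knockdown
POSITIVE_CONTROL_VIABILITY = 0.15


def generate_screen(config: SimConfig) -> tuple[list[PlatePair], GroundTruth]:
    """One plate pair per treatment, every knockdown as a well.

    Vehicle counts ~ baseline x knockdown viability x plate effect x noise;
    drug counts additionally x drug_kill_fraction x planted effect modifier.
    GFP wells carry modifier exactly 1; KIF11 wells are strongly depleted in
    both conditions. Pure function of the config (which carries the seed).
    """
    rng = np.random.default_rng(config.seed)
    genes = config.gene_names
    labels = genes + config.gfp_names + ["KIF11"]
    truth = GroundTruth(gene_roles={g: "null" for g in genes})
    for g in config.gfp_names:
        truth.gene_roles[g] = "control_negative"
    truth.gene_roles["KIF11"] = "control_positive"
    _plant_effects(config, rng, truth)

    # per-knockdown proliferation under vehicle, stable across treatments
    viability = {g: float(v) for g, v in
                 zip(genes, np.exp(rng.normal(0.0, config.viability_log_sd, size=len(genes))))}
    for g in config.gfp_names:
        viability[g] = 1.0
    viability["KIF11"] = POSITIVE_CONTROL_VIABILITY

    plates = []
    n_wells = len(labels)
    base = np.array([config.baseline_count * viability[g] for g in labels])
    for t in config.treatment_names:
        modifiers = np.array([truth.modifier(g, t) for g in labels])
        pf_vehicle = float(np.exp(rng.normal(0.0, config.plate_effect_sd)))
        pf_drug = float(np.exp(rng.normal(0.0, config.plate_effect_sd)))
        veh = (base[:, None] * pf_vehicle
               * _lognoise(rng, config.count_noise_cv, (n_wells, config.n_rep)))
        drug = (base[:, None] * config.drug_kill_fraction * modifiers[:, None] * pf_drug
                * _lognoise(rng, config.count_noise_cv, (n_wells, config.n_rep)))
        plates.append(PlatePair(
            plate_id=f"plate_{t}",
            treatment_id=t,
            well_map={f"W{i:04d}": g for i, g in enumerate(labels, start=1)},
            counts_drug=drug,
            counts_vehicle=veh,
            n_rep=config.n_rep,
        ))
    return plates, truth


def generate_expression_response(truth: GroundTruth, n_lines: int, snr: float,
                                 seed: int, genes: list[str] | None = None,
                                 treatments: list[str] | None = None,
                                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expression and AUC panels tied to the planted network.

    Expression is standard normal per gene per line. For each treatment,
    AUC = -snr x sum over its planted genes of sign(log modifier) x z(gene)
    + unit Gaussian noise, so that low expression of a synthetic-lethal gene
    goes with resistance (high AUC) and snr = 0 gives pure noise.
    """
    rng = np.random.default_rng(seed)
    if genes is None:
        genes = sorted({g for g, _ in truth.effects} | {g for g, r in truth.gene_roles.items()
                                                        if r in ("null", "planted")})
    if treatments is None:
        treatments = sorted({t for _, t in truth.effects})
    lines = [f"LINE{i:03d}" for i in range(1, n_lines + 1)]
    z = pd.DataFrame(rng.standard_normal((n_lines, len(genes))), index=lines, columns=genes)
    auc = {}
    for t in treatments:
        signal = np.zeros(n_lines)
        for g in genes:
            mod = truth.modifier(g, t)
            if mod != 1.0:
                signal += np.sign(np.log(mod)) * z[g].to_numpy()
        auc[t] = -snr * signal + rng.standard_normal(n_lines)
    return z, pd.DataFrame(auc, index=lines)


def generate_rescreen(truth: GroundTruth, treatment: str, n_lines: int, seed: int,
                      attenuation: float = 0.7, line_sd: float = 0.3,
                      count_cv: float = 0.10, n_rep: int = 4,
                      baseline: float = 2000.0) -> pd.DataFrame:
    """Per-line rescreen of one drug, scored like the primary screen.

    Each line carries the planted log-effects attenuated by
    ``attenuation`` x a line-specific factor plus gene-line noise, so strong
    primary effects preserve more often — the trend the preservation curve
    should recover. Returns the long-form table gene, cell_line, p_value,
    direction.
    """
    from .scoring import score_interaction  # local to avoid cycle at import time

    rng = np.random.default_rng(seed)
    genes = sorted(g for g, r in truth.gene_roles.items() if r in ("null", "planted"))
    rows = []
    for li in range(1, n_lines + 1):
        line = f"RLINE{li:02d}"
        line_factor = float(np.exp(rng.normal(np.log(attenuation), 0.2)))
        for g in genes:
            log_eff = np.log(truth.modifier(g, treatment))
            line_log_eff = line_factor * log_eff + rng.normal(0.0, line_sd * abs(log_eff))
            veh = baseline * _lognoise(rng, count_cv, n_rep)
            drug = baseline * 0.5 * np.exp(line_log_eff) * _lognoise(rng, count_cv, n_rep)
            # rescale drug replicates as plate normalization would
            drug = drug / 0.5
            rec = score_interaction(drug, veh)
            rows.append({"gene": g, "cell_line": line, "p_value": rec.p_value,
                         "direction": int(np.sign(np.log(rec.fold_change)))
                         if rec.fold_change != 1.0 else 0})
    return pd.DataFrame(rows)


def generate_dose_matrix(fit_a: MedianEffectFit, fit_b: MedianEffectFit,
                         regime: str = "additive", shift: float = 1.0,
                         noise_cv: float = 0.0, seed: int = 0,
                         doses_a: np.ndarray | None = None,
                         doses_b: np.ndarray | None = None) -> DoseResponseMatrix:
    """Dose matrix sampled from a Loewe surface with a known synergy regime.

    Combination cells are evaluated at effective doses (d / shift); shift < 1
    boosts potency (synergy), shift > 1 masks it (antagonism), shift = 1 is
    exact additivity. Monotherapy margins are always exact so refits recover
    the generating parameters. Multiplicative noise with CV ``noise_cv`` is
    applied and the surface is clipped to [0, 1].
    """
    if regime == "additive":
        shift = 1.0
    elif regime == "synergistic":
        if shift >= 1.0:
            raise ValueError("synergistic regime needs shift < 1")
    elif regime == "antagonistic":
        if shift <= 1.0:
            raise ValueError("antagonistic regime needs shift > 1")
    else:
        raise ValueError(f"unknown regime {regime!r}")
    if doses_a is None:
        doses_a = np.array([0.0] + list(fit_a.Dm * np.logspace(-1, 1, 6)))
    if doses_b is None:
        doses_b = np.array([0.0] + list(fit_b.Dm * np.logspace(-1, 1, 6)))
    rng = np.random.default_rng(seed)
    inh = np.zeros((len(doses_a), len(doses_b)))
    for i, da in enumerate(doses_a):
        for j, db in enumerate(doses_b):
            if da > 0 and db > 0:
                inh[i, j] = loewe_expected(fit_a, fit_b, da / shift, db / shift)
            else:
                inh[i, j] = loewe_expected(fit_a, fit_b, da, db)
    if noise_cv > 0:
        inh = inh * _lognoise(rng, noise_cv, inh.shape)
        inh[0, 0] = 0.0
    return DoseResponseMatrix(doses_a=doses_a, doses_b=doses_b, inhibition=np.clip(inh, 0, 1))
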