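# Methods

`chemogimap` implements a quantitative chemical-genetic interaction mapping
pipeline: gene knockdowns are screened against a drug panel in paired
drug/vehicle multi-well plates, per-knockdown proliferation differences are
converted into signed interaction scores with an empirically calibrated
false-discovery rate, and the resulting gene × drug score matrix feeds four
downstream analyses — drug-class consensus networks, mechanism-of-action
profile comparisons, expression-based drug-response prediction, and
cross-cell-line preservation — plus a dose-matrix synergy toolkit. A
synthetic-screen generator with planted ground truth makes every stage
testable end to end.

## Interaction scoring

Each screened plate holds one knockdown per well with `n_rep = 4` replicate
wells per condition (drug at its IC50, or vehicle). The raw unit is a pair
of wells × replicates count matrices.

1. **Normalization.** Every plate is median-centered *multiplicatively* to
   2,000 cells per well: counts are rescaled by a single factor so the
   median over all entries hits the target exactly. Counts are positive and
   the quantity of interest is relative proliferation, so a multiplicative
   rescale (not an additive shift) is the right group action; it removes
   whole-plate effects (reagent batches, incubation time, overall drug
   kill) while preserving ratios between wells. An all-zero plate is
   unusable and raises.

2. **Replicate QC.** A plate passes when the minimum pairwise Pearson
   correlation across its replicate columns is ≥ 0.7. A constant column
   (zero variance) has undefined correlation and is reported as a QC
   failure with a diagnostic, not an exception. Failed plates contribute
   *missing* cells, never zeros.

3. **Score.** For each knockdown, the fold change is the ratio of medians
   (drug / vehicle; with four replicates the median is the mean of the
   central pair), and a two-sided p-value comes from a variance-moderated
   two-sample t-test on the replicate vectors: the pooled variance is
   bounded below by a floor, with `df = n1 + n2 − 2`. At floor 0 this is
   exactly the textbook pooled two-sample t-test, which pins the statistic
   to an independently checkable reference; we use the pooled-df form
   rather than Welch so that this identity holds exactly. The default floor
   is plate-level: the median over wells of the per-knockdown pooled
   variance, the standard moderation against spuriously tight replicates at
   n = 4. The score is

       S = sign(log fold-change) × (−log10 p),

   positive for resistance, negative for sensitization. p-values are
   floored at 1e−16 (|S| ≤ 16) so zero-variance replicates cannot produce
   infinite scores.

4. **Empirical FDR.** GFP knockdowns are true negatives by design, so the
   FDR at a threshold is the percentage of GFP scores beyond it — reported
   per tail (the null need not be symmetric) and two-sided. The inverse map
   (`threshold_at_fdr`) finds the smallest threshold meeting a target FDR.

## Consensus networks

The class statistic for a gene is the unweighted mean S over the member
drugs of a class (classes need ≥ 2 members; a gene needs ≥ 2 non-missing
member scores). The null is generated by shuffling gene labels
*independently within each treatment column*: this preserves every drug's
marginal score distribution — drug potency is not part of the null — while
destroying gene-class association. Null statistics are pooled across genes
and permutations per class, and an edge's FDR is the fraction of null
values at least as extreme in its tail. Each gene × class pair is tested in
both directions, so the expected false-edge count on null data is
`fdr_target × genes × classes × 2`. Default 10,000 permutations with a
recorded seed; tail resolution is limited by the pooled null size. For tiny
matrices an exhaustive enumeration of all within-column permutations is
available and is checked against sampling.

## Profile comparisons

Drug profiles (columns of the S matrix) are compared by Pearson correlation
over pairwise-complete genes (listwise deletion would discard far more
data); pairs sharing < 30 genes are flagged low-support. Class coherence
compares within-class pair correlations against the pooled between-class
background with a Welch t-test on Fisher z-transformed values — the z
transform makes correlation differences approximately normal, and under a
fully null simulator the resulting p-values are uniform (KS-checked over
seeds). Combination treatments should be excluded from coherence via the
`exclude` argument. Gene-set summaries use the mean S with a one-sample
t-test against zero. The trapping trend is the Spearman rank correlation
between annotated PARP-trapping potency and a drug's mean profile
correlation with reference cross-linkers.

## Drug-response prediction

For a drug, the signed network at cutoff c contains genes with S ≥ +c
(sign +1) or S ≤ −c (sign −1). With expression standardized per gene across
cell lines (z-score default; rank-normalization available), a line's
predicted sensitivity is Σ sign(g) · z(g, line): losing a gene whose
knockdown confers resistance protects the cell, so expressing it highly
sensitizes. Predictions are correlated with drug-response AUC, where higher
AUC means resistance, so the concordant direction is r < 0 (a config flag,
since AUC conventions vary). The significance flag is a one-sided test in
the concordant direction at level α = 0.05; under independence it fires at
rate α exactly, which is what the null-calibration benchmark asserts.
Two-sided p-values are reported alongside. Evaluations need ≥ 10 shared
cell lines; below that a drug is skipped, not failed. Gene contributions
are leave-one-out drops in |r|; the sliding-cutoff scan counts
significantly predicted drugs across a cutoff grid. The overlap analysis
calls a gene-drug pair "correlated" when expression vs response has
two-sided p < 0.01 in the concordant direction (positive S ↔ negative
expression-AUC correlation) and tests enrichment of correlated pairs among
past-cutoff interactions by a hypergeometric test against all tested pairs.

## Preservation

An interaction is preserved in a rescreened line when the per-line test is
significant (p < 0.01 default) with the same direction as the primary
interaction, "direction" being the sign of the per-line fold change. The
preservation curve reports, per score cutoff and tail, the fraction of
past-cutoff interactions preserved in ≥ `min_lines` lines; cutoffs with no
qualifying interactions are omitted. Raw rates are always emitted; a
centered 11-point sliding average is provided for display (the window is a
presentation choice).

## Synergy

Monotherapy curves are fit with the median-effect (Hill) model by least
squares on log(fa/(1−fa)) vs log D; points at fa ∈ {0, 1} carry no
information on that scale and are excluded (≥ 3 usable points required).
The Loewe-additive surface solves dose_a/D_A(E) + dose_b/D_B(E) = 1 by
bisection on E ∈ (1e−9, 1 − 1e−9) to 1e−9; a drug is exactly additive with
itself, which is the main correctness identity. The synergy score is the
mean Loewe excess (observed − expected inhibition) over combination cells
(both doses nonzero) — mean rather than total so the score does not scale
with grid size; a total-volume option exists. The Chou-Talalay combination
index CI = dose_a/D_A(fa) + dose_b/D_B(fa) is banded < 0.3 strong / 0.3–0.7
moderate / 0.7–1 slight synergy / ≥ 1 non-synergistic. The single-pair
additivity expectation is Bliss independence e_a + e_b − e_a·e_b by
default, with the Loewe surface as the alternative. Inhibition input is
clipped to [0, 1] with the out-of-range count warned.

## Synthetic screens

The generator emulates the screen design: 626 knockdowns per drug (525
scored genes + 100 GFP negative controls + 1 KIF11 essential-gene positive
control), 4 replicate wells per condition, a 2,000 cells/well baseline,
drugs dosed at half-maximal kill, and one drug/vehicle plate pair per
treatment. Vehicle counts are baseline × per-knockdown viability ×
plate effect × lognormal noise; drug counts additionally carry the kill
fraction and the planted (gene, drug) modifier (> 1 resistance, < 1
sensitivity; GFP exactly 1; KIF11 viability 0.15 in both conditions).
Key defaults, chosen once as a realistic operating point:

| parameter | default | rationale |
|---|---|---|
| `count_noise_cv` | 0.08 | replicate-level counting/seeding noise; puts a planted 1.5× effect at |S| ≈ 3–6 at n = 4, matching a usable screening dynamic range |
| `plate_effect_sd` | 0.10 | whole-plate multiplicative variation; removed exactly by median centering |
| `viability_log_sd` | 0.20 | spread of knockdown proliferation rates for growth-relevant genes; this well-to-well structure is what makes replicate columns correlate (~0.85) and plates pass the 0.7 QC |
| `drug_kill_fraction` | 0.5 | IC50 dosing |

Class signatures plant one modifier across all member drugs of a class
(driving consensus edges and profile coherence); per-treatment signatures
allow graded effects, e.g. cross-linker-like signatures rising with PARP
trapping rank. Expression/AUC panels draw standard-normal expression and
set AUC = −snr × Σ sign(log modifier) × z + unit noise, so low expression
of a synthetic-lethal gene accompanies resistance. Rescreens attenuate the
primary log-effects by a per-line factor plus gene-line noise and re-score
with the same t-test. Dose matrices are sampled from the Loewe surface with
a potency shift on combination cells (< 1 synergy, > 1 antagonism) and
exact monotherapy margins so refits recover the generating parameters. All
generators are pure functions of (config, seed).

What the generator does **not** emulate: well-position (edge) effects,
transfection-efficiency gradients, off-target knockdown effects, heavy-
tailed real-count noise, or correlated noise across drugs sharing plates.
Passing the calibration and recovery benchmarks therefore shows the
*statistics* behave as designed under the modeled noise, not that real
screens are free of these artifacts.

## Validation benchmark sizes

The benchmarks in `chemogimap.validation` (run by the test suite and
`scripts/acceptance.py`) use: one full-design null screen (626 × 4) for
FDR calibration; ten full-design screens with 40 planted 2× effects for
recovery; twenty null 200-gene × 3-class matrices at 500 permutations for
consensus calibration (pooled null of 10⁵ values per class resolves the
0.1% tail); 100 expression/AUC panels of 30 lines at snr 0 for prediction
calibration; and 50 panels of 100 lines with 3 planted genes among 50
decoys at snr 1 for contribution ranking. These sizes make each benchmark's
target statistically resolvable while keeping the whole suite fast.

## Known limitations

- The variance-moderation choice (plate-median floor, pooled df) is one
  reasonable member of a family; other shrinkage estimators would give
  slightly different tail behavior and hence FDR-threshold mappings.
- Empirical FDR resolution is limited by the number of control scores;
  per-tail estimates on few controls are coarse.
- The permutation FDR is marginal per class, not adjusted across classes.
- The contribution ranking at snr = 1 sits near its 90% design target
  (true success rate ≈ 0.92 under the benchmark conditions), so measured
  fractions fluctuate a few percent across seeds.
- Loewe roots are undefined where a fit's fa range cannot reach the
  required effect; the solver clamps to {0, 1} at the bracket ends.
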