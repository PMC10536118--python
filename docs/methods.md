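# Methods

`rilimet` implements an end-to-end metabolomic analysis of
radiation-induced lung injury (RILI) after whole-thorax irradiation
(WTI) in the rat, working from integrated LC-MS peak-area tables:
quality control and normalization, univariate differential screening,
cross-tissue marker-panel selection, OSC-KPLS injury triage, metabolite
correlation networks, trajectory analysis, and carnitine
palmitoyltransferase (CPT) surrogate-ratio statistics. Because no public
cohort accompanies the design it emulates, a first-class synthetic
cohort generator provides data with the statistical structure the
analysis assumes; every downstream stage is tested against it.

## Data model

A `SampleTable` is a samples x metabolites matrix of nonnegative peak
areas (or normalized intensities) plus per-sample metadata (animal,
tissue, dose in Gy, sampling day, study/QC role, tissue weight in mg)
and per-metabolite metadata (name, chemical class, acyl-chain token,
assigned internal-standard channel). Samples are always rows. Missing
measurements are NaN and never zero: zero is a legal measured intensity
and the missingness filter must distinguish the two. Structural
violations (duplicate or orphan ids) fail at construction; semantic
problems (negative cells, absent lung weights) are reported by
`validate_table` without raising.

## Synthetic cohorts

The generator emulates a WTI study: doses 0/10/20/35 Gy with 11/10/9/9
animals, plasma sampled at days 1/2/3/5 post-exposure, lung tissue at
day 5 from the same animals, pooled QC injections, internal-standard
(IS) channels and completely-at-random missingness.

Log-scale measurement model:

    log x(a, m, dose, day) = mu_m + u_a
        + dir_m * amp_m * sigma_e * f(dose/d_max) * g(day; onset_m)
        + eps,     u_a ~ N(0, sigma_a^2),  eps ~ N(0, sigma_e^2)

exponentiated to strictly positive abundances. Key parameters, with the
defaults that define the study conditions:

| parameter | default | meaning |
|---|---|---|
| `amplitude_sd` | 3.0 | max log shift in units of `residual_sd_log`, at the top dose and latest day |
| `residual_sd_log` | 0.3 | residual log-SD (≈30% CV, typical of peak areas) |
| `animal_sd_log` | 0.05 | shared per-animal log offset; metabolite-specific biological variation is part of the residual |
| `qc_rsd` | 0.05 | analytical CV of pooled QC injections |
| `qc_n` | 6 | QC injections per run |
| `missing_rate` | 0.05 | MCAR missingness among study samples |
| `n_metabolites` / `n_planted_markers` | 80 / 15 | panel plus decoys |

Dose-response shapes `f`: `linear` in dose fraction; `saturating`
(1-exp(-3d))/(1-exp(-3)); `high_dose_only` (a 35-Gy step). The time
profile `g` is 0 before the effect's onset day, 0.5 at the onset day
(an effect that "begins" at a day must be detectable there, not zero)
and ramps linearly to 1 at the latest day, making post-onset ratio
trajectories monotone in expectation.

The default effect library plants the regulation archetypes the
analysis is designed to find: long-chain acylcarnitines up from day 1
(saturating), free carnitine down, short-chain acylcarnitine C5:0 down
at the top dose only from day 2, branched-chain amino acids down from
day 3, taurine-conjugated bile acids down at day 5, urea down from
day 1. Later catalogue entries add the acyl-chain channels the CPT
ratios need (AC16:0/AC16:1/AC18:0/AC18:1 up; acetylcarnitine as an
unregulated denominator channel) and further lipid/amino-acid/bile-acid
patterns; everything beyond `n_planted_markers` is an amplitude-0
decoy. IS channels are constant-times-noise columns (spiked standards
carry no biology), so IS normalization is exercised non-trivially.

What the generator deliberately does not model: batch/run-order drift,
retention-time structure, intensity-dependent (non-MCAR) missingness,
correlated metabolite modules beyond the planted effects, and
between-metabolite covariance of biological noise. Passing tests
therefore demonstrate correctness of the statistical machinery under
the stated model, not robustness to those real-data pathologies.

## QC and normalization

Retention rule (strict inequalities): a metabolite is kept iff its
missing fraction over study samples is < 20% and its QC RSD
(sample SD / mean over QC injections, n-1 denominator, missing
excluded) is < 30%. A metabolite failing both counts once, under
missingness; an undefined QC RSD (zero/absent QC mean) removes the
metabolite with a note. The filter is idempotent and RSD is
scale-invariant. No imputation is performed anywhere in the univariate
path.

Normalization divides each channel by its sample's assigned IS value
(plasma), and additionally by tissue weight in mg (lung). IS columns
are consumed and dropped. The QC stability summary reports the fraction
of metabolites with QC RSD below 10/20/30% and flags each QC injection
whose first-principal-component score (unit-variance PCA on study + QC)
falls outside mean(QC scores) ± 2 SD of all samples' PC1 scores — a
concrete reading of the usual "QCs within two SD" scores-plot band;
using the all-sample SD keeps the rule meaningful when a QC itself is
the outlier.

## Differential screening

Control and irradiated animals are distinct, so between-group contrasts
use the Mann-Whitney U test (exact null when the pooled sample is
tie-free and n ≤ 20, otherwise normal approximation with tie and
continuity corrections); the paired Wilcoxon signed-rank test (exact
for n ≤ 25 tie-free; zero differences dropped; statistic reported as
W+) is reserved for within-animal day-vs-day contrasts; the lung screen
across the four dose groups is a one-way fixed-effects ANOVA.
Benjamini-Hochberg adjustment is applied across the metabolites of one
contrast (never pooled across days), and a metabolite is *significant*
iff p < 0.05 and q < 0.2. Fold changes are ratios of arithmetic group
means on the normalized scale. Metabolites with fewer than 3
observations in a group are excluded with a note.

Dose-wise log2 fold-change rows of the significant metabolites are
hierarchically clustered (Euclidean, average linkage) and cut into
three zones labelled in dendrogram-leaf order, reproducing the familiar
up / high-dose-only / down zoning of dose-response heatmaps.

## Chemometric engine

All multivariate models follow the Model → `fit()` → Results pattern.
Unit-variance (auto) scaling of X is the default (pareto and
center-only available); Y is centered, never scaled; classes are
one-hot encoded and predicted by argmax of the predicted indicators.
Missing cells are mean-imputed inside multivariate fits only, and the
results object records that this happened.

**PLS (NIPALS).** Deflation-based with deterministic initialization
from the first response column. Convergence is judged on the score
direction (sign-aligned) at 1e-10, with up to 2000 inner iterations —
near-degenerate eigenvalues of X'YY'X legitimately need several hundred
power-iteration steps. When Y has numerically no covariance with X the
weight vector is rounding noise; that case is detected and the
component falls back deterministically to the leading principal
direction (explaining ~0 of Y). VIP uses
sqrt(p · Σ_a SSY_a (w_ja/||w_a||)² / Σ_a SSY_a) with
SSY_a = (t_a't_a)||q_a||², so mean(VIP²) = 1 identically.

**OSC.** The classic iterative scheme (orthogonalize the leading score
against Y, regress it onto X, repeat) is a fixed-point search with two
failure modes we observed: limit cycles under near-degenerate spectra,
and — with covariance-style weights — weight vectors that overlap
class-mean directions, which silently strip class information from
*held-out* samples (training scores are protected by the explicit
orthogonalization; new samples are not). The implementation therefore
solves the constrained problem that iteration targets, directly:
maximize removed X-variance w'X'Xw subject to w ∈ null(Y'X) and
||w|| = 1, by eigendecomposition. The removed score t = Xw is then
exactly Y-orthogonal, the correction (w, p) annihilates class means by
construction, and the procedure is deterministic.

**Kernel PLS.** NIPALS in feature space on the double-centered kernel;
Gaussian kernel K_ij = exp(-γ||x_i-x_j||²) with the median-distance
heuristic γ = 1/median(pairwise squared distances) by default; test
kernels are centered against the training kernel. With a linear kernel
the predictions reproduce ordinary PLS to 1e-6 relative, which is
asserted in the tests.

**Validation.** Q² = 1 - PRESS/SS from venetian-blind cross-validation
(7 folds by default) on a seed-permuted interleaving, with SS taken
about the training-fold means. The response permutation test refits
R²Y and Q² under n_perm = 200 row permutations of Y and reports
empirical p = (1 + #{Q²_perm ≥ Q²_obs}) / (n_perm + 1).

## Marker-panel cascade and triage

The cascade is a filtration: (1) metabolites significant in lung
(ANOVA) ∩ plasma (union of per-day screens); the per-day plasma
contrast is control vs *each* dose (union over doses), since a pooled
contrast dilutes effects confined to the top dose; (2) per-tissue
2-component PLS-DA on the candidates keeps VIP > 1 in either tissue —
and, because mean(VIP²) = 1 makes that rule remove about half of any
equally-informative candidate set, the stage keeps at least k
candidates by descending cross-tissue max VIP so the final top-k
selection stays feasible; (3) lung-plasma Pearson correlation per
candidate across matched animals annotates (default) or filters
(|r| ≥ r_min); (4) a re-fit PLS-DA on the survivors ranks by VIP
(ties broken alphabetically) and keeps the top k = 7.

Triage maps 0/10/20/35 Gy to Control/Mild/Moderate/Severe and
evaluates the panel with an OSC(1)-filtered Gaussian-KPLS(2) classifier
per day. Scaling, OSC and KPLS are fit on the training fold only.
Cross-validated (leave-one-out default, k-fold available) and fitted
(training-set) accuracies are both computable and the scheme is
recorded on the result, because the two answer different questions and
apparent accuracy is systematically optimistic. A parallel KPLS on dose
in Gy yields continuous dose predictions.

A known limitation, visible in the synthetic experiments the test
suite runs: with ~10 animals per class and planted effects of 3
residual-SD at the top dose, adjacent dose groups differ by well under
one residual SD per marker, and no classifier — the OSC-KPLS stack or
a linear-discriminant reference — achieves high *leave-one-out*
per-class accuracy for the two intermediate classes; fitted accuracy
is markedly higher. Per-class LOO accuracy of the middle classes is
the quantity to watch when tuning panel size or effect assumptions.

Trajectories divide each irradiated group's mean by the same-day
control mean (undefined cells recorded as missing), report the first
day each metabolite reached significance, and flag monotone movement
of the ratio across days ≥ 2.

## Networks and CPT ratios

Per-group Pearson correlation networks connect metabolites with
|r| ≥ 0.7 and two-sided p < 0.05 on pairwise-complete observations
(≥ 4 pairs); the absolute-value threshold keeps strong negative edges,
which are sign-annotated. Degrees obey the handshake identity by
construction. Exports are Cytoscape-readable SIF and GraphML with
bit-stable ordering; per-edge p-values are unadjusted by default (BH
across pairs is available).

CPT surrogate ratios per sample: CPT1 = carnitine/(AC16:1 + AC18:0),
CPT2 = (AC16:0 + AC18:1)/AC2 — the CPT2 grouping parenthesized in
parallel with CPT1. Ratios are invariant to per-sample scaling, so IS
normalization constants cancel; lung channels are the default source.
Group statistics: median (25th, 75th percentiles) by the
linear-interpolation (type-7) quantile rule, tie-corrected
Kruskal-Wallis across dose groups, and pairwise Mann-Whitney tests of
each dose vs control (*/**/*** at 0.05/0.01/0.001) and vs the lowest
irradiated dose (# at 0.05), uncorrected to match the conventional
star notation. Under the default effect library the CPT1 ratio falls
and the CPT2 ratio rises with dose — a sign property the tests check.

## Degenerate inputs and tie-breaks

Zero within-group variance with unequal means → F = +inf, p = 0;
all-equal groups → Kruskal-Wallis p = 1 by convention; all-zero paired
differences → error ("degenerate pairing"); zero-variance columns under
uv scaling → error naming the column; zero/missing IS values → error
naming sample and channel; empty tissue intersection → warning and
empty set. All orderings exposed to the user (panel ranking, network
edges, exports) break ties lexically so repeated runs are
byte-identical.
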