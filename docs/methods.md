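# Methods

## The measurement and the profile

Synchronous fluorescence spectroscopy scans the excitation and emission
monochromators together with a fixed offset Δλ (here 30 nm) and records a
single intensity per excitation wavelength, condensing a sample's
excitation–emission landscape into one vector. A urine sample's profile on
the 250–550 nm grid (0.5 nm step, 601 points) — smoothed and acquired under
identical settings for every sample — is treated as its *urinary total
fluorescent metabolome profile* (uTFMP): a holistic fingerprint of the
fluorescent metabolites (tryptophan-pathway products, NADH-like compounds,
xanthurenic acid, kynurenine/xanthopterin, flavins).

Raw urine is strongly inner-filtered: at high concentration, absorption and
self-quenching suppress emission, so fluorescence is *non-monotonic* in
concentration. That is why samples are measured along a 1:3 geometric
dilution series (factors 3^k, k = 0…6, up to 729×, the geometric series
closest to a 1000-fold dilution). The package models the observed signal at
relative concentration c = 1/f as

    S_f(λ) = S_1(λ) · (1/f) · exp(q · (1 − 1/f)),

i.e. signal ∝ c·e^(−qc), the saturable-quenching form. With quench strength
q = 0 intensity scales exactly as 1/f; with q > 1 the per-wavelength maximum
sits at the interior concentration c = 1/q. The default q = 2 places the
undiluted sample past the fluorescence maximum, reproducing the qualitative
behaviour that motivates the dilution series.

### uTFMP construction

Two constructions are implemented and switchable:

- `max_over_dilutions` (default): per-wavelength maximum over the smoothed
  dilution series. Each fluorophore is captured at its least-quenched
  dilution; the construction is idempotent and dominates every individual
  dilution pointwise.
- `single_dilution`: the smoothed spectrum at one requested factor, kept
  for sensitivity analysis.

"Standardized" here means identical acquisition and processing settings for
all samples; no statistical standardization (z-scoring) of profiles is
applied at this stage.

## Smoothing

Savitzky–Golay filtering with window 11 points (5.0 nm) and polynomial
order 3, applied before any feature extraction. Edges are handled by
evaluating the polynomial fitted to the terminal window, so the filter is
exact on polynomials up to cubic everywhere — a property the tests verify
against an analytically derived kernel (the first row of (AᵀA)⁻¹Aᵀ for the
local Vandermonde design).

## Zones, features, markers

Nine named half-open intervals partition 250–500 nm on the excitation axis:

| zone | range (nm) | dominant fluorophores |
|------|-----------|----------------------|
| Z1a, Z1b | 250–275, 275–300 | indole derivatives, catecholamine metabolites |
| Z2 | 300–325 | 5-hydroxyindoleacetic acid |
| Z3 | 325–345 | 3-hydroxyanthranilic acid |
| Z4a, Z4b | 345–362.5, 362.5–380 | NADH-like metabolites |
| Z5 | 380–410 | xanthurenic acid |
| Z6 | 410–450 | kynurenine, xanthopterin |
| Z7 | 450–500 | flavins (FAD, riboflavin) |

Only the parent ranges of Z1 (250–300) and Z4 (345–380) are anchored in the
zone scheme's provenance; the sub-zone splits at the midpoints (275 and
362.5 nm) are **project conventions**, exposed in configuration and flagged
here deliberately.

Per-sample features:

- **Zone summary** — one value per zone; default statistic is the zone
  maximum (peak height), which is robust to within-zone band shifts. Mean
  and per-nm trapezoidal integral are available; the choice of statistic is
  a genuinely open design point.
- **Ratio markers** — Z4a/Z5 and Z6/Z7 quotients of zone summaries. Ratios
  cancel the global concentration/dilution factor of a sample, which is
  why they discriminate better than absolute intensities. Denominators are
  guarded at ε = 1e−9 with a logged warning.
- **Ternary peak codes** — code 2 ("peak") for a characteristic rise ≥ 15
  fluorescence units, 1 ("slight inclination") for a rise in [5, 15), 0
  otherwise. The printed bands 5–10 and ≥ 15 leave [10, 15) unassigned; the
  inclination band is widened to [5, 15) so the coding is total. Two
  readings of "rise" are implemented: `zone_rise` (default; the largest
  rise above any preceding point within the zone — a ≥ 15-unit jump between
  adjacent points 0.5 nm apart on smoothed data is physically implausible)
  and `consecutive_step` (the literal maximum first difference).

Two model input representations: `zones` (9 summaries + 9 peak codes + 2
ratios = 20 features) and `utfmp` (the full 601-point profile).

## Statistics

- Normality gate: Shapiro–Wilk per group at α = 0.05; any rejection routes
  the variable to Kruskal–Wallis with Dunn's post-hoc z-test (rank-sum with
  tie correction, Bonferroni ×3 capped at 1), otherwise one-way ANOVA with
  Tukey's HSD. Medians and interquartile ranges are always reported.
  Constant data degenerate to p = 1 rather than an error.
- Binomial proportions (sensitivity/specificity at each ROC threshold)
  carry 95% Wilson score intervals. Known limitation: the Wilson interval's
  coverage oscillates with the discreteness of the binomial; at n = 50,
  p = 1/2 exactly, its true coverage is Σ_{k=19..31} Binom(50, ½) = 0.935,
  a local dip below the nominal 95% (coverage averaged over p ∈ [0.4, 0.6]
  is 0.951).
- ROC: threshold sweep over unique scores; AUC by the Mann–Whitney statistic
  with ties counted half (identical to the trapezoidal area); AUC standard
  error and the test against AUC = 0.5 by the Hanley–McNeil normal
  approximation. Marker polarity is explicit: Z4a/Z5 rises in disease,
  Z6/Z7 falls, so correctly oriented AUCs are ≥ 0.5 by construction.

## Classification protocol

Control vs malignant only (benign samples are excluded from the suite but
kept for the benign-vs-control PLS-DA). Stratified 70:30 split; stratified
10-fold cross-validation on the training partition, repeated (10 repetitions
in the `desk` profile, 100 in `paper`); a final refit on the full training
partition is evaluated on the held-out 30%. Feature standardization is
fitted on the training side of every split and fold — never on held-out
data.

Models and fixed hyperparameters: random forest (150 trees, max depth 10),
RBF-kernel SVM (C = 1, inverse-variance gamma; AUC from signed decision
values), logistic regression (1000-iteration cap — the nominal "10.00"
iteration figure is read as a formatting artifact of 1,000), SGD with
logistic loss (α = 1e−4, "optimal" schedule). PLS-DA uses 2 latent
components on standardized features with a 0/1 response; class 1 is called
at a regressed response ≥ 0.5; R² is explained response variance on the
training partition and Q² its 10-fold cross-validated counterpart (pooled
PRESS).

Metric panel per fold: sensitivity, specificity, PPV, NPV, PLR, NLR,
accuracy, AUC. Ratios with zero denominators are reported as NaN with a
reason, never as 0. Because the aggregation of repeated-CV metrics admits
two readings, both are reported: the mean over folds then repetitions, and
the panel recomputed from pooled confusion counts (these differ for PLR/NLR,
which are nonlinear in the counts). Determinism: repetition r shuffles folds
with seed base + r; the whole suite is bit-for-bit reproducible from the
base seed.

## The synthetic cohort generator

No public cohort of this kind exists, so the generator *is* the study
population for every test. Each sample is

    baseline + Σ_b amplitude_b · mult_b(group) · G · L_b · N(λ; center_b + shift_b(group), width_b) + noise,

with eight Gaussian fluorophore bands (indoles 270/290, 5-HIAA 312, 3-HAA
335, NADH-like 360, xanthurenic 395, kynurenine/xanthopterin 430, flavins
470 nm), a log-normal global subject factor G (σ = 0.22 — overall urine
concentration, shared by all bands and cancelling in ratio markers), a
log-normal band-specific factor L_b (σ = 0.204; total per-band log-sd
≈ 0.3), and additive Gaussian noise with sd = 1.5 + 0.02 × signal. The
group effects encode the qualitative disease phenotype: indole and 5-HIAA
bands depressed in benign and further in malignant samples; a 3-HAA band
present **only** in malignant samples; the NADH-like band amplified
(×1.4–1.5) and red-shifted +6 nm in malignancy; xanthurenic acid carrying
no group effect; kynurenine/xanthopterin mildly depressed and flavins
elevated in disease, benign midway between control and malignant.

Band positions, widths and effect sizes are **calibration choices, not
measured values**. The one quantitative anchor is prescribed: effect sizes
were set, via the log-normal closed form for the Z6/Z7 log-ratio
(Δ = log(1.20/0.85) ≈ 0.345, within-group log-sd 0.204·√2), so the
large-sample control-vs-malignant AUC of the Z6/Z7 marker falls in
0.75–0.85; the realized value is ≈ 0.79. Urinalysis strip covariates are
Bernoulli draws at the per-group positivity rates of the emulated
population (e.g. leukocytes 4/96 control vs 61/77 malignant) with pH
N(6.06/6.43/5.69, 0.45²) clipped to 4.5–9; they are generated for
descriptive tabulation but never fed to the classifiers.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: Raman/scatter artifacts, instrument drift,
correlated metabolite physiology beyond one global concentration factor,
heavy-tailed outliers, or realistic *joint* separability. Because several
zones carry independent group effects, a multivariate classifier combines
them into near-perfect synthetic discrimination (suite AUCs ≈ 1.0) even
though each single marker is calibrated to ≈ 0.8; clinical cohorts are far
noisier, and the suite's synthetic metrics must not be read as expected
clinical performance. The generator answers protocol questions (leakage,
calibration under the null, determinism, direction recovery), not clinical
ones.

## Numerical choices and degenerate inputs

- Negative read-in intensities are clipped to 0 with a logged warning
  (baseline artifacts; fluorescence is nonnegative).
- Zone intervals are half-open [start, end): no grid point is counted
  twice; segmentation over Z1a…Z7 is an exact partition of [250, 500).
- Wilson bounds are clamped to exact 0/1 at k = 0 and k = n against
  floating-point residue.
- Kruskal–Wallis/ANOVA on globally constant data return p = 1 with all
  pairwise adjusted p = 1.
- PLS-DA Q² folds are clamped to the minority-class count; a single-class
  response is rejected.
- All randomness flows from explicit seeds (generator seed; CV base seed +
  repetition index); there is no global RNG state anywhere.

## Problem sizes

The default `desk` profile runs the full study-size cohort (96/23/77) with
10 CV repetitions — about one minute per representation on one CPU — and
`paper` raises the repetitions to 100. Calibration tests use 20 seeds with
50 samples per group under the null and the study-size cohort for
effect-direction recovery; the large-sample AUC check uses 1,500 per group.
These sizes are the package's desk-scale choices and are stated here so
they can be scaled up deliberately.
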