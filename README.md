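# utfmp — urinary fluorescence metabolome profiling

Screening for endometrial cancer today means transvaginal ultrasound,
hysteroscopy or biopsy — effective but invasive, and poorly suited to
routine use. Urine autofluorescence offers a cheap, non-invasive
alternative: the fluorescent metabolites of urine (indole derivatives,
5-HIAA, 3-hydroxyanthranilic acid, NADH-like compounds, xanthurenic acid,
kynurenine, flavins) shift with malignant metabolism, and a single
synchronous fluorescence scan (Δλ = 30 nm, 250–550 nm at 0.5 nm) condenses
them into one profile per sample — the *urinary total fluorescent metabolome
profile* (uTFMP).

This package implements the full analysis pipeline for such profiles, for
spectroscopists and biostatisticians working with urine autofluorescence
cohorts:

- **I/O** for wide/long spectra CSVs, dilution series (`sample@factor`
  columns) and sample metadata (`utfmp.io`);
- **preprocessing**: Savitzky–Golay smoothing (window 11, order 3), uTFMP
  construction from a quenched dilution series, segmentation into the nine
  fluorescent zones Z1a…Z7 (`utfmp.preprocess`);
- **features**: zone summaries, the Z4a/Z5 and Z6/Z7 ratio markers, and the
  ternary peak coding (2 = peak for a rise ≥ 15 fluorescence units,
  1 = slight inclination for [5, 15), 0 = flat) (`utfmp.features`);
- **statistics**: Shapiro–Wilk-gated Kruskal–Wallis + Dunn/Bonferroni or
  ANOVA + Tukey; ROC analysis with Wilson score intervals per threshold and
  Hanley–McNeil AUC errors (`utfmp.stats`);
- **classification**: PLS-DA (R²/Q²) and an RF / LR / SVM / SGD suite under
  a stratified 70:30 split with repeated stratified 10-fold CV
  (`utfmp.models`);
- **a seedable synthetic cohort generator** (`utfmp.synth`) emulating a
  three-group study population (96 control / 23 benign / 77 malignant) with
  the qualitative disease effects, so the whole pipeline is testable
  without clinical data.

Core quantities, in the field's notation: the spectral markers are zone
ratios R₁ = S(Z4a)/S(Z5) and R₂ = S(Z6)/S(Z7) with S the zone peak height;
their diagnostic value is the Mann–Whitney AUC
P(X_case > X_control) + ½P(=); PLS-DA reports R² (explained response
variance) and Q² (its cross-validated counterpart); the classifier panel is
sensitivity, specificity, PPV, NPV, PLR = sens/(1−spec),
NLR = (1−sens)/spec, accuracy and AUC.

## Worked example

The numbered scripts under `analysis/` run the study end to end on a
simulated cohort:

```bash
python analysis/01_simulate_cohort.py   # cohort + urinalysis tabulation
python analysis/02_build_features.py    # uTFMPs -> zone/ratio features
python analysis/03_marker_statistics.py # group tests + marker ROC
python analysis/04_classification.py    # PLS-DA + 4-model suite
```

`03_marker_statistics.py` prints, for the default seed:

```
ratio-marker ROC (AUC, SE, 95% CI, p vs 0.5):
     marker           comparison    auc  auc_se  ci_lower  ci_upper  p_value           polarity
Z4a_over_Z5    control_vs_benign 0.7826  0.0599    0.6651    0.9001   0.0000 higher_is_positive
 Z6_over_Z7    control_vs_benign 0.7092  0.0651    0.5816    0.8368   0.0019  lower_is_positive
Z4a_over_Z5 control_vs_malignant 0.7616  0.0373    0.6885    0.8348   0.0000 higher_is_positive
 Z6_over_Z7 control_vs_malignant 0.7955  0.0351    0.7266    0.8643   0.0000  lower_is_positive
```

Read: on this synthetic cohort the Z6/Z7 ratio separates malignant from
control samples with AUC 0.80 (95% CI 0.73–0.86) when *low* values flag
disease — the generator is calibrated so this one marker lands in
0.75–0.85, emulating a moderately strong single biomarker. The group tests
above it show the expected pattern: indole zones Z1a/Z1b strongly depressed
in malignancy (p < 1e−4), the malignant-only Z3 band, no Z5 effect, and
both ratios highly significant. `04_classification.py` then prints PLS-DA
R²/Q² and the cross-validated metric panel; note that multivariate models
combine several independent zone effects and reach near-perfect synthetic
AUCs — see `docs/methods.md` for why that must not be read as clinical
performance.

The same pipeline is available as a CLI (`utfmp simulate / features /
stats / classify / run`); `utfmp run --seed 2024 --profile desk` writes the
complete report bundle (features, tests, ROC, classifier metrics, confusion
matrices) plus a JSON manifest with config, seeds and output hashes under
`results/run/`. Real cohorts enter through the same door: point
`utfmp run` (or `RunConfig`) at your spectra/metadata CSVs instead of a
simulation spec.

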