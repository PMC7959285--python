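# gliospec

Raman spectroscopy of fresh brain tissue can separate glioma from healthy
parenchyma by its vibrational fingerprint — phenylalanine ring breathing at
1003 cm⁻¹, the choline/lipid bands, nucleic-acid phosphodiester modes — and
that separation can be learned by tree-ensemble classifiers well enough to be
interesting for intraoperative tissue assessment.  `gliospec` implements the
complete analysis workflow for a 63-sample ex-vivo point-spectroscopy cohort
as a tested, reusable Python library:

1. **Preprocessing** — truncation to 400–1700 cm⁻¹, removal of saturated
   acquisitions, median-filter cosmic-ray despiking, a signal-to-noise gate
   (S2N ≥ 3.5 at the 1004 cm⁻¹ phenylalanine reference), autofluorescence
   background subtraction by iterative modified polynomial fitting with a
   noise-aware clipping rule (Vancouver Raman Algorithm), interquartile-range
   outlier removal, and root-mean-square normalization — with full per-stage
   QC bookkeeping.
2. **Features** — a bundled 60-shift peak catalog (19 of the shifts novel for
   fresh-tissue glioma discrimination, 28 previously described), band
   intensities as window maxima, and one-way ANOVA F ranking with top-*k*
   selection.
3. **Classification** — leave-one-patient-out (LOPO) cross-validation of a
   random forest (150 trees, depth 5) and gradient-boosted trees
   (200 estimators, depth 5, learning rate 0.1), with optional nested
   grid-search, pooled confusion-matrix metrics and ROC/AUC
   (Tumor = positive class).
4. **Band statistics** — per-class mean ± SD spectra, two-tailed Mann–Whitney
   U tests per band (exact for small tie-free samples), Shapiro–Wilk
   normality, Benjamini–Hochberg adjusted p-values, and band intensity ratios
   (e.g. 720:701 cm⁻¹).
5. **Synthetic cohorts** — because the original spectra are not public, a
   ground-truthed generator reproduces the study conditions: 38 tumor + 25
   healthy single-patient samples, 20–30 spectra each, Lorentzian bands with
   class-dependent amplitudes, per-patient random effects, dominant smooth
   background, detector noise, cosmic-ray spikes and saturation.

The statistical core in the field's standard notation: band features are
ranked by the one-way F statistic
`F = (SS_between/(g−1)) / (SS_within/(n−g))` with `g = 2`; pooled LOPO
predictions give `accuracy = (TP+TN)/n`, precision/recall/F1 with tumor
positive, and AUC as the trapezoid area under the threshold-swept ROC —
equivalently the tie-corrected Mann–Whitney probability that a random tumor
spectrum outscores a random healthy one.

## Worked example

```python
from gliospec import (SimConfig, generate_cohort, run_preprocessing,
                      load_catalog, build_feature_table, run_lopo,
                      default_gb_spec)
from gliospec.peak_features import anova_f_scores, select_top_k

cohort, truth = generate_cohort(SimConfig(seed=1))      # 63 samples
processed, qc = run_preprocessing(cohort)
table = build_feature_table(processed, load_catalog().shifts)
table = table.select(select_top_k(anova_f_scores(table), 60))
result = run_lopo(table, default_gb_spec(seed=1))
print(result.metrics.to_dict())
```

Running the numbered drivers reproduces the full analysis; on seed 1 they
print:

```
$ python analysis/02_preprocess_spectra.py
preprocessing (seed 1): 1598 -> 1598 spectra
...
720:701 band ratio on class means: tumor 0.782 vs healthy 0.712

$ python analysis/04_classify_lopo.py
random_forest: accuracy=0.956 precision=0.938 recall=0.994 f1=0.965 auc=0.998 (63 patient folds)
gradient_boosting: accuracy=0.896 precision=0.874 recall=0.970 f1=0.920 auc=0.973 (63 patient folds)

$ python analysis/05_band_statistics.py
bands tested: 60; significant at alpha=0.05: 54
novel bands significant: 18 of 19
```

i.e. on the default synthetic cohort both ensembles discriminate tumor from
healthy spectra at/above the mid-0.8 accuracy range under patient-level
cross-validation, most catalog bands separate the classes, and the choline
720:701 ratio is higher in the tumor class — the qualitative structure the
workflow is designed to detect.  A `gliospec` command-line interface exposes
the same stages (`gliospec simulate | preprocess | features | classify |
stats | summarize | run-all`).

## Layout

```
src/gliospec/      library (spectra_io, preprocess, peak_features, classify,
                   band_stats, synthetic_data, pipeline, cli)
analysis/          numbered narrative drivers writing tables under results/
tests/             pytest suite incl. acceptance checks
docs/methods.md    models, parameters, design choices, limitations
```
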