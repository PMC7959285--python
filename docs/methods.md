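# Methods

## Scope and data model

The package analyzes single-point Raman spectra of fresh brain biopsies:
each acquisition is an ascending wavenumber axis (cm⁻¹) with intensities in
arbitrary detector counts, tagged with a sample id, a patient id and a
binary histopathological label (Tumor / Healthy).  All cross-acquisition
operations (mean spectra, band features) require a common axis; spectra are
aligned by linear interpolation onto a 400–1700 cm⁻¹ grid at 1 cm⁻¹ steps.
The 1 cm⁻¹ step is an implementation choice (the native sampling interval of
the instrument class is not standardized); it is the coarsest grid on which
every catalog shift is an exact grid point, and linear interpolation is
artifact-free at this resolution.  The original study spectra are not
public, so the synthetic generator (below) supplies cohorts with the same
statistical structure plus exact ground truth.

## Preprocessing chain

Stages run in a fixed order; each stage logs input/output counts and
per-spectrum rejection reasons into a QC report whose counts must chain
exactly (kept + removed = input).

1. **Truncation** to 400–1700 cm⁻¹ (fingerprint region; cuts the quartz/CaF₂
   window response below 400 and the quiet zone above 1700).
2. **Saturation removal**: a spectrum is discarded when ≥ `run_len` = 3
   consecutive points sit at or above the detector ceiling
   (`saturation_level`, default 65 000 counts, a 16-bit ADC).  Shorter
   ceiling runs are treated as cosmic rays and left to the despiker.
3. **Despiking**: points deviating from a 5-point running median by more
   than `z` = 10 robust noise sigmas are replaced by the median.  Cosmic
   rays are 1–2 channels wide; genuine bands (FWHM ≥ 8 cm⁻¹) deviate from a
   5-point median by at most ≈ A/(γ²+1) ≪ 10σ and survive untouched.  The
   noise sigma is estimated from successive differences,
   σ = median|Δᵢ|/(0.6745·√2), which is insensitive to smooth structure.
4. **Signal-to-noise gate** at the 1004 cm⁻¹ phenylalanine reference:
   S2N = (window max over ±10 cm⁻¹ − background)/σ, where background is the
   mean of the median intensities of the two flanking 20 cm⁻¹ windows
   (averaging the flank medians cancels linear background drift across the
   window).  Spectra with S2N < 3.5 are discarded.  The S2N formula itself
   is a design choice — the threshold and reference band are the protocol's,
   the estimator is ours (window-max minus flank-median over robust sigma:
   standard, parameter-light, testable).
5. **Background subtraction** (Vancouver Raman Algorithm family): iterate
   (a) least-squares polynomial fit (order 5, orthonormalized basis on a
   scaled axis, refit per iteration as a cheap projection); (b) DEV = SD of
   the residual over points not yet clipped as peaks; (c) clip every point
   above fit + DEV to fit + DEV; stop when DEV changes by < 1e-4
   relatively, when DEV is negligible relative to the signal scale
   (noise-free input converges in one pass), or after 100 iterations.  The
   fitted polynomial is the baseline; it never exceeds the input maximum.
6. **IQR outlier removal**: per spectrum, d = RMS deviation from the
   pointwise median spectrum of the whole set; Tukey fences at
   Q1 − 1.5·IQR / Q3 + 1.5·IQR on d.  Which scalar the rule acts on is not
   standardized; RMS-to-median-spectrum is a conventional shape-deviation
   score, and fences are computed on the full set (not per class) to avoid
   using labels before classification.  Fewer than 4 spectra: filter is
   skipped with a warning note.
7. **RMS normalization**: divide by √(mean squared intensity); output RMS is
   1 to 1e-9, making band intensities comparable across acquisitions.

## Features and ranking

The bundled catalog carries 60 shifts with tentative biochemical
assignments; 19 are flagged novel and 28 previously described (the remaining
13 have undefined assignments and carry neither flag).  Two bookkeeping
notes: the composite listing "975 and 977" is stored as two entries, and the
twice-listed 1603 is stored as 1603 (novel) + 1604 (previously described,
matching the previously-described shift list).  Band intensity is the window
maximum within ±3 cm⁻¹ of the catalog shift — tolerant of small
peak-position jitter — extracted after normalization.  Features are ranked
by the one-way ANOVA F statistic (two classes) and the top-60 kept,
descending F with ties broken by ascending shift.  Candidate screening from
class-mean spectra (local maxima above a prominence fraction, de-duplicated
within a separation window) reproduces the discovery procedure; the catalog
is the canonical feature set.

## Classification

Leave-one-patient-out: all spectra of one patient form the test fold
(spectra within a biopsy are strongly correlated; per-spectrum CV would leak
patient signal).  Default mode fixes the adopted hyperparameters — random
forest 150 trees / depth 5; gradient boosting 200 estimators / depth 5 /
learning rate 0.1 — while `nested_grid` re-selects them per training fold by
stratified 5-fold grid search (RF grid: depth {6,8,10,12} × trees
{50…450}; GB grid: estimators {100,150,200} × depth {5,8,10}), ties broken
toward the smaller model.  Gradient boosting uses scikit-learn's
histogram-based implementation with `min_samples_leaf` = 1 (the classic
boosted-tree default; the histogram variant's 20-sample floor would freeze
small LOPO training folds).  Held-out predictions are pooled across folds
into one confusion matrix (folds are one patient each and very unequal in
size; pooling is the stable convention) with Tumor as the positive class;
ROC is built by a threshold sweep over pooled tumor probabilities, AUC by
the trapezoid rule (ties at half weight, so AUC equals the normalized
Mann–Whitney statistic).  Fold-level seeds derive deterministically from the
spec seed, making the whole run bit-reproducible.  A majority-vote
sample-level aggregation is available but not default.

## Band statistics

Per catalog shift: class medians and direction, two-tailed Mann–Whitney U
(exact by enumeration when both groups ≤ 8 without ties, else normal
approximation with tie and continuity corrections), and Shapiro–Wilk
normality per class — reported but not gating the nonparametric test.  No
multiple-testing correction is applied to the headline table (per-band α =
0.05); a Benjamini–Hochberg column is emitted alongside for callers who want
it.  Mean ± SD envelopes use the sample (n−1) SD convention.

## Synthetic cohort generator

The generator defines the study conditions: 38 tumor + 25 healthy samples,
one patient per sample (the patient/sample multiplicity of the original
cohort is not fully specified; multiplicity is configurable), each
contributing a uniform 20–30 spectra (mean ≈ 25).  A spectrum is

  observed = Σ peaks + baseline + noise (+ spikes) (+ clipping),

with Lorentzian lines (natural Raman line shape, FWHM 9–15 cm⁻¹) at the 60
catalog shifts plus twelve prominent non-catalog bands (701/720 choline
pair, 830, 1064, 1087, 1126, 1300, 1440, 1740, …) so the class means show
the familiar strong lipid/protein structure.  Tumor-class amplitudes are
scaled by per-band multipliers: 1.30 / 0.78 for bands with an explicitly
stated tissue contrast, 1.18 / 0.85 for bands reported different without a
direction (assigned by biochemical category — nucleic acids, glycogen, heme,
calcification and protein up in tumor; lipids down), and 1.0 for the
undefined-assignment bands.  The 720:701 amplitude pair is set so the
tumor-class mean ratio exceeds the healthy one.  Each patient draws a
log-normal multiplier per band (`patient_effect_sd`), which makes
patient-held-out folds genuinely harder than i.i.d. splits; each spectrum
adds a random degree-5 polynomial background scaled to 5× the Raman
mean-square energy (autofluorescence dominance), i.i.d. Gaussian noise
(σ = 12 counts), and with probability 0.08 one to three single-channel
spikes of 300–3000 counts.  Artifact injection clones cohort members into
saturated / peakless / amplified-outlier variants for filter validation.

`patient_effect_sd` is the single calibration constant for cohort
separability, chosen once so that the default-configuration LOPO
gradient-boosting accuracy lands in the mid/high 0.80s — at or slightly
above the operating point the workflow is meant to realize, since the
acceptance comparisons are lower bounds.  Value: 0.14.

What the generator does **not** emulate: photon-count (Poisson) noise
statistics and detector response, wavenumber calibration drift, water/CaF₂
window artifacts, grade- or histology-dependent spectral structure
(histology labels follow the study proportions but do not modulate
spectra), and intra-sample spatial heterogeneity.  Passing tests therefore
demonstrate the pipeline's correctness and its ability to realize
study-level discrimination under the modeled variability — not clinical
performance on real tissue.

## Numerical and degenerate-input choices

Polynomial fits use an orthonormalized basis on a [-1, 1]-scaled axis (QR of
the Vandermonde), so refits cost one projection and conditioning is
independent of the wavenumber range.  Zero-noise spectra: the noise
estimator returns 0, S2N returns +inf for positive signal (0 for none), and
the despiker is a no-op.  Zero-energy spectra cannot be RMS-normalized and
are rejected with a dedicated QC reason.  F scores with zero within-class
variance return +inf unless the between-class spread is also zero (then 0).
Undefined precision (no positive predictions) is reported as 0 with a
warning.  Top-k and grid-search ties have deterministic tie-breaks
(ascending shift; smaller model).

## Known limitations

* A degree-5 baseline cannot be distinguished from the smooth pedestal
  formed by overlapping Lorentzian tails: on the default profile ~59% of
  the clean signal's energy lies in the polynomial subspace, capping the
  correlation between baseline-subtracted and true clean spectra at ≈ 0.93
  for any order-5 method.  Against the baseline-identifiable component
  (clean minus its own polynomial projection) recovery exceeds 0.98.
* Under leave-one-patient-out with a class-balanced cohort, label
  permutation at the *patient* level is not a 0.5-accuracy null: the
  held-out patient's class is the training minority, biasing accuracy far
  below chance (the known anti-majority effect of leave-one-group-out).
  Chance-level null calibration uses spectrum-level permutation.
* The reported optimal random-forest depth (5) lies outside the stated RF
  search grid; the fixed-parameter defaults use the reported final values
  and the grids are kept verbatim for nested mode.
* Analyses and acceptance runs use the default cohort size (63 patients,
  ≈ 1600 spectra) and five seeds; these are the package's chosen problem
  sizes for all reported numbers.
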