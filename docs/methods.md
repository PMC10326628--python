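# Methods

`ramanomics` implements an end-to-end chemometric analysis of Raman
spectra of spent (discarded) embryo culture medium: the droplet a D3
cleavage-stage embryo was cultured in before transfer. The residual
metabolite composition of that droplet reflects embryo metabolism, and
the package asks two questions of it: *do amino-acid levels differ
between media of embryos that did and did not lead to pregnancy?* and
*can the outcome be predicted from the spectrum?* Because no raw spectra
from this assay are publicly deposited, the package ships a synthetic
cohort generator with known ground truth; every downstream claim the
test suite makes is a claim about recovery of planted structure.

## Synthetic cohorts

Each spectrum is simulated on a 50–2000 cm⁻¹ axis (1 cm⁻¹ step) as

    y(x) = Σ_b A_b · exp(−(x − x_b)² / 2σ_b²)  +  B(x)  +  ε(x)  +  spikes

* **Bands.** Gaussian lines at 24 fingerprint-region positions
  (aromatic amino-acid ring modes, amide bands, CH₂/CH₃ deformations,
  nucleic-acid phosphate modes, …), FWHM 10–16 cm⁻¹ — typical
  solution-phase Raman linewidths. The phenylalanine ring-breathing
  line at 1003 cm⁻¹ is the strongest band (base amplitude 1.0; all
  other amplitudes are relative to it), matching its dominance in real
  culture-medium spectra. Seven bands are the quantified amino acids:
  aspartic acid 941, glycine 900, tryptophan 758, tyrosine 853,
  taurine 1032, serine 1326 and proline 828 cm⁻¹.
* **Biological variability.** Band amplitudes are drawn per *sample*
  with a between-sample coefficient of variation of 0.15 (a realistic
  scale of inter-patient metabolite variability), then jittered
  per replicate acquisition by a multiplicative log-normal with
  σ = 0.05. Replicates of one sample are therefore correlated — a
  property the statistics below must respect.
* **Group effects.** An effect size d for an analyte shifts its mean
  sample-level amplitude in the non-pregnancy group by d between-sample
  standard deviations. The default planted pattern elevates tyrosine,
  tryptophan and serine, the amino acids reported elevated in media of
  embryos that fail to implant.
* **Baseline.** A broad exponential hump (decay constant ≈ 700 cm⁻¹)
  plus a gentle 4th-order polynomial, magnitude 5× the strongest band,
  so fluorescence dominates the raw signal as in real acquisitions.
  Coefficients are perturbed per spectrum.
* **Noise and artifacts.** White Gaussian noise (σ = 0.02 on the
  phenylalanine-amplitude scale) and Poisson-count cosmic-ray spikes
  (rate 0.3/spectrum, width 1–3 channels, 5–20× the local signal).
* **Platforms.** `p532` (crystallized droplet, high SNR) is the
  default; `p785` (liquid sample) scales amplitudes by 0.6, more than
  doubles the noise and halves planted effect sizes, mimicking the
  weaker group contrast of liquid-sample acquisition. Neither preset is
  fit to instrument data — absolute intensity scales and SNR for the
  real platforms are not published, so these are stated presets.

All randomness flows from one `numpy` generator seeded by the config;
identical configs reproduce identical cohorts bit for bit.

**What the generator does not emulate:** substrate enhancement physics,
instrument response and wavenumber miscalibration, correlated (pink)
noise, peak-position shifts between samples, and any metabolite
chemistry beyond independent per-band amplitudes. Passing recovery
tests therefore shows the algorithms are correct under the stated model,
not that the real assay reaches any particular performance.

## Preprocessing

Applied per spectrum, in order:

1. **Despiking.** Residual against a rolling median (window
   2·`spike_max_width`+1 = 9 channels); channels with modified z-score
   (0.6745·residual/MAD) above `spike_mad_k` = 8 are spike candidates.
   Because cosmic events are additive and positive, only positive
   residuals qualify, and the residual must also exceed 0.5× the local
   median level — without this prominence guard the apex of a genuine
   sharp band (phenylalanine 1003) clears a pure MAD threshold at high
   SNR and would be flattened. Contiguous runs wider than
   `spike_max_width` = 4 channels are genuine bands and are left alone;
   accepted runs are replaced by linear interpolation of the flanking
   channels. Detection iterates (≤3 passes) because clustered spikes
   can hide each other inside the median window.
2. **Band clipping** to the 600–1800 cm⁻¹ biological fingerprint
   region (1201 channels at 1 cm⁻¹).
3. **Savitzky–Golay smoothing**, window 11, order 3 — wide enough to
   suppress white noise, short enough not to erode ~10 cm⁻¹ bands
   (the filter reproduces polynomials up to order 3 exactly; edges are
   handled by refitting on the truncated window).
4. **SNIP baseline subtraction.** Intensities are compressed with the
   LLS transform v = ln(ln(√(y+1)+1)+1), clipped iteratively by
   v_i ← min(v_i, (v_{i−m}+v_{i+m})/2) with the window m *decreasing*
   from 60 to 1 (decreasing windows reduce peak erosion), then
   decompressed. By construction the baseline never exceeds the signal
   and baseline + corrected reconstructs the input exactly.
5. **Min–max normalization** of each spectrum onto [0, 1] over the
   clipped band, so every spectrum attains both bounds.

**Outlier screening** runs after preprocessing: spectra are projected
onto the batch's first 3 principal components and rejected when their
squared Mahalanobis distance exceeds the χ²₃ quantile at 0.999. A
sample leaves the cohort only when all its replicates are rejected.
The 99.9% quantile rejects ≈0.3% of clean spectra by construction — a
conservative, reportable rule for "abnormal data"; the true rejection
rule used on the real cohort is not published.

## Internal-standard quantification

For each spectrum and analyte the peak intensity is the maximum within
±5 cm⁻¹ of the catalog position (the window accommodates published
position doublets such as 1339/1341 cm⁻¹), and the quantitative ratio
is

    r = log10( I_target / I_standard ),   I_standard = intensity at 1003 cm⁻¹

Log base 10 (one unit = a decade of relative intensity) is a
configurable choice. The ratio is invariant under any positive
rescaling of the spectrum, so the normalization choice cannot affect
it. Non-positive intensities flag the spectrum out of the table rather
than producing undefined logs.

Group comparison is per analyte with a two-sided Mann–Whitney U test by
default (robust on bounded normalized intensities; Welch's t-test is
available), tiered `**` p<0.01, `*` p<0.05, `ns` otherwise, with the
direction of the non-pregnancy − pregnancy median difference. No
multiple-testing correction is applied across the seven analytes by
default, matching how such panels are conventionally reported.

**Replicates and calibration.** By default observations are individual
spectra. Replicates of one sample share its amplitude draw, so
per-spectrum tests treat correlated observations as independent and are
anticonservative under the null. The `per_sample` flag collapses
replicates to sample medians first. The package's own calibration
simulations therefore use one replicate per sample (where per-spectrum
and per-sample coincide and the nominal α is meaningful): over 200 null
cohorts of 40 samples the per-analyte rejection rate at α = 0.05 sits
within binomial bounds, while planted d = 1.0 effects on
tyrosine/tryptophan/serine in 200-sample cohorts are recovered with
correct sign in ≈100% of 50 seeds (`scripts/acceptance.py` recomputes
both rates).

## Feature extraction and classification

PCA is fitted on mean-centered (not variance-scaled — channels share
units after normalization) training spectra only; the first 3
components feed per-group histogram/KDE summaries (Silverman
bandwidth), the first 100 feed the classifiers. Component signs follow
a fixed convention (largest-magnitude loading positive).

Splitting is stratified 4:1 at the *sample* level: replicate spectra
never straddle the train/test boundary, because the label is a clinical
property of the sample and replicate leakage would inflate accuracy.
Cross-validation folds are likewise grouped by sample (5-fold default).

Four classifier families run on the PCA scores, each tuned by
exhaustive grid search over the tunables that matter for its family
(CV ties broken by listing order, refit on the full training set):

| family | implementation | default grid |
|---|---|---|
| 1D-CNN | NumPy (this package) | conv layers {1,2} × kernels {8,16,32} |
| SVM | scikit-learn SVC | kernel {rbf,linear} × C {0.1,1,10} × γ {scale,0.01,0.001} |
| random forest | scikit-learn | trees {100,300} × depth {None,10,20} × min-split {2,5} |
| XGBoost | xgboost | rounds {100,300} × depth {3,6} × η {0.1,0.3} × subsample {0.8,1.0} |

The 1D-CNN is a small, fully deterministic NumPy network: one or two
convolution blocks (width-7 kernels, 'same' padding, ReLU, max-pool 2;
the second block doubles the channels), a dense-64 ReLU layer and a
softmax pair, trained with Adam (lr 10⁻², batch 32, ≤60 epochs, early
stopping on the CV-fold loss with patience 10). Inputs are standardized
internally because PCA scores span orders of magnitude in variance.
Backpropagation is verified against finite differences in the test
suite.

Prediction outputs calibrated-sum probability pairs; the hard label is
the argmax with exact ties resolved to non-pregnancy. An optional
per-sample majority vote over a sample's replicates is provided;
per-spectrum evaluation is the default (blind-test counts in this
design are spectra).

## Evaluation

Confusion matrix (rows true, columns predicted), per-class precision /
recall / F1, per-class accuracy (class recall as a percentage — the
convention of clinical chemometrics tables), overall accuracy as
correct/total, and ROC by threshold sweep with trapezoid AUC (positive
class pregnancy, switchable). With tied scores the trapezoid area
equals the half-credit Mann–Whitney pair-count statistic, which the
tests verify by brute-force pair counting. Reports round to two
decimals for presentation and keep full precision in the fields.

## Numerical and degenerate-input choices

* SNIP guard `baseline = min(baseline, y)` absorbs the LLS transform's
  floating-point round-trip; reconstruction is then exact.
* Constant spectra make min–max normalization undefined → explicit
  degenerate-input error.
* Identical batch spectra make the outlier covariance degenerate →
  zero-variance components are dropped and nothing is rejected.
* `n_components` above the data rank is clipped with a warning.
* Requested CV folds above the number of samples are clipped; a fold
  whose training half is single-class is an error, not a silent skip.
* Seeds: every stochastic component (generator, split, RF/XGBoost/CNN
  initialization, batch shuffling) is driven by explicit integer seeds;
  fixed seeds reproduce whole runs bit for bit.

## Problem sizes

The default study-scale configuration is 107 samples × 5 replicates
(535 spectra, ~1:1 outcome balance). The package's own benchmark run
(`scripts/acceptance.py`) uses that scale with planted d = 1.0 effects
and reduced hyperparameter grids; its Monte-Carlo calibrations use 50
planted cohorts of 200 samples and 200 null cohorts of 40 samples, one
replicate each. These sizes are the package's chosen defaults for a
reproducible desk-scale analysis; all of them are configurable.

## Known limitations

* The generator's independence assumptions (bands, samples, channels)
  are idealized; real spectra have correlated backgrounds, shared
  matrix effects and peak shifts.
* Peak quantification uses in-window maxima, not fitted areas; heavily
  overlapped bands bleed into each other's windows (band positions and
  widths here were chosen so bleed stays below the quantification
  tolerance, which real spectra do not guarantee).
* Classifier accuracies on synthetic cohorts characterize the
  pipeline, not the clinical assay; no claim about real-cohort
  performance is made or testable here.
* The 1D-CNN is intentionally small and CPU-bound; it is not a
  general-purpose deep-learning stack.
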