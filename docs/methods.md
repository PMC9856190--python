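# Methods

## The measurement model

A detection point on a tissue sample yields 13 spectra on a shared
uniform grid (default 500-2000 cm⁻¹, 1780 channels, ~0.84 cm⁻¹ spacing):
one at each linear polarization angle 0°, 30°, ..., 330° and one
conventional (non-polarized) spectrum. The acquisition description
("every 30° from 0° to 360°") double-counts the coincident 0°/360°
orientation; we store 12 distinct angles.

Each synthetic spectrum is a sum of pseudo-Voigt bands (default pure
Gaussian), a broad fluorescence background, and i.i.d. Gaussian channel
noise, truncated so intensities are non-negative:

    I(w, θ) = Σ_b A_b(θ) · L(w; center_b, fwhm_b) + baseline(w) + ε(w)

with the Malus-type anisotropy law

    A_b(θ) = a_iso,b + a_aniso,b · cos²(θ − φ_b),

which is 180°-periodic and satisfies A(θ) + A(θ+90°) = 2a_iso + a_aniso
for every θ. The conventional spectrum uses the circular mean
a_iso + a_aniso/2 — exactly the average of the 12 polarized amplitudes.
How a real spectrometer's unpolarized acquisition relates to the
polarized ones is not specified by the acquisition protocol; the
circular mean is the simplest consistent choice, and it makes the
conventional spectrum identically the angular mean of the stack when
noise is off (a tested invariant).

Per detection point, band amplitudes receive a lognormal multiplicative
jitter (mean 1) and the background a lognormal scale factor; both are
shared by the 13 spectra of the point, since they model tissue
heterogeneity between points, not shot noise. Channel noise is drawn per
spectrum with a *class-independent* sigma (1% of the tallest band
amplitude over all profiles): detector noise is an instrument property,
and a per-class sigma would bias the trough-baseline areas differently
per class (observed empirically) and corrupt the between-class tests.

## Tissue profiles and calibration

Six profiles (protein/lipid × normal/paracancerous/cancerous) carry the
marker bands of breast tissue: protein 875, 921, 1003, 1032, 1247, 1269,
1302, 1318, 1450, and amide I at 1660 cm⁻¹ (red-shifted to 1656 in
cancer); lipid 871, 971, 1032, 1084, 1269, 1302, 1442, 1652, 1745 cm⁻¹.
Protein spectra alone carry 1003/1247; lipid spectra alone carry
1084/1745 — which is exactly what the component classifier keys on.
Band widths default to 8-14 cm⁻¹ for sharp modes, ~20 cm⁻¹ for the broad
amide III envelope, and 34-48 cm⁻¹ for the amide I and CH₂/CH₃
deformation envelopes.

Band intensities are parameterized by *measured-area targets*: the mean
trough-baseline areas per class that the published tables report for
parallel-polarized (0°) and conventional spectra. The pair
(parallel, conventional) determines (a_iso, a_aniso, φ ∈ {0°, 90°})
uniquely under the cos² law. Targets are converted to generator
amplitudes via per-band calibration factors obtained by iterating the
*full* measurement pipeline (synthesis → fluorescence removal →
normalization → trough-baseline integration) on synthetic points at the
default noise level until measured means match the targets
(`scripts/calibrate_profiles.py`; constants frozen in
`polraman/profiles.py`). Calibrating against noisy rather than
noise-free spectra matters because positive-part trough-chord
integration carries an additive noise-floor bias (about 0.2-0.4 area
units at the default noise level).

Known, deliberate deviations from the published mean tables:

* **Effect-size nudges within the ±25% calibration band.** A few
  published class means are too close together to reproduce their own
  reported significance at this cohort size (e.g. protein 1032: means
  2.66 vs 2.72, yet p = 0.034). The generator widens such gaps while
  keeping every nudged mean within ±25% of its published value
  (protein 875/921/1032, lipid 871, lipid 1652 conventional).
* **Noise-floor saturation.** Published means below ~0.5 area units
  (lipid 871 cancerous parallel 0.24; protein 1302 normal 0.13; protein
  1318 cancerous 0.18) sit below the integration noise floor and come
  out high regardless of amplitude. Their class *differences* are still
  realized and significant; only the absolute means saturate.
* **Amide III doublet compromise.** The published area pattern for
  1247/1269 in cancerous tissue (conventional above parallel for 1247,
  below for 1269) is jointly infeasible with the flat, always-below-1
  height-ratio curve that the same study reports for cancer, under any
  cos²-type response. The ratio behaviour is the study's headline
  observation, so it wins: the cancerous doublet is isotropic, its
  1247 areas land ~−20% of the published means (inside the band) and its
  1269 conventional area ~+40% (outside; the one uncorrectable cell).
  The doublet is therefore parameterized directly by per-class 0°/90°
  amplitudes rather than by area targets.

The fluorescence background is a degree-5 polynomial in the normalized
wavenumber with non-negative coefficients, peaking at 5-10× the tallest
band so that baseline removal is genuinely exercised.

## Preprocessing

* **Fluorescence removal** is iterative modified polynomial fitting:
  fit a degree-5 polynomial (least squares on a rescaled domain),
  replace the signal above the fit by the fit, repeat until the working
  signal changes by less than `tol` (relative to the input maximum,
  default 1e-3) or 100 iterations. The final polynomial is the
  background. A batch variant shares the factorized projection across
  spectra.
* **Component classification** compares trough-corrected peak heights
  at 1003+1247 cm⁻¹ (protein) vs 1084+1745 cm⁻¹ (lipid), on the
  corrected conventional spectrum; the call applies to all 13 spectra
  of the point.
* **Normalization** divides by the maximum corrected intensity within
  ±8 cm⁻¹ of the reference band (1450 protein / 1442 lipid). Height
  rather than area normalization is used; a consequence worth knowing is
  that the reference band's own normalized area is fixed by its width
  and cannot express class differences.
* **Trough-baseline band quantities.** The peak is the maximum within
  center ± halfwidth (default 20 cm⁻¹; narrower windows for crowded
  regions: 7 cm⁻¹ for the 1302/1318 pair, 12 cm⁻¹ for the amide III
  doublet, 10 cm⁻¹ for lipid 871). If the window maximum is pinned to a
  window edge with a rising neighbour it is a foreign band's flank, and
  the strongest interior local maximum is used instead. Troughs are
  found on a 5-channel moving-average copy by walking outward and
  tracking the running minimum; the walk stops when the signal rises
  more than 5% of the descent so far plus twice a robust noise estimate
  (from the median absolute second difference) — a literal
  first-local-minimum rule stops at noise wiggles on gentle flanks. The
  chord endpoints are local medians (±3 channels) of the raw signal
  around the trough indices, because the raw value at a selected
  minimum is itself a running minimum of noise and biased low.
  Negative excursions are clipped before trapezoidal integration
  (x in cm⁻¹); the peak height is the maximum of the chord-subtracted
  signal.

## Statistics

Band-area tables report per-class mean ± std over all qualifying
spectra, pooled per spectrum (not averaged per patient first). Group
comparisons use the Welch (unequal-variance) two-sided t-test; no
multiple-testing correction is applied, matching per-band reporting
practice. The bimodal ratio I₁₂₄₇/I₁₂₆₉ uses trough-corrected peak
heights per angle; the cohort-level curve uses the ratio of class-mean
heights (the average-spectrum statistic — per-point ratio means are
heavy-tailed because an occasional noisy denominator explodes a single
ratio). The hydroxyproline/proline table I₈₇₅/I₉₂₁ likewise uses ratios
of class-mean areas.

## Image encoding

The 12×1780 matrix (rows ascending by angle, preprocessed spectra) is
clipped to its 1st-99th percentile range, linearly quantized to 64
levels, mapped through a fixed 256-entry jet-style RGB lookup table, and
resized to 100×100 by exact area interpolation (interval-overlap
operators applied left and right). All choices are recorded in the image
metadata. PNG export applies the single 8-bit quantization; the model
consumes floats in [0, 1]. Percentile clipping makes the encoding
invariant to constant offsets and positive scaling of the matrix.

## Augmentation and splits

Training folds are balanced to an exact per-class count (5000 in the
full profile) by keeping every original and cycling seeded draws from
eight operations: horizontal/vertical flips, 90°/180°/270° rotations,
and Gaussian noise with means 0.1/0.2/0.3 (sigma 0.05, pixels clipped
to [0, 1]) — the nonzero-mean reading is taken literally. Expansion
happens per fold, strictly after the train/test split; provenance
(source index, operation) is recorded and the leakage check is an
executable assertion. The expanded set is then split 7:3 into train and
validation, stratified by label. The 1D branch balances conventional
spectra with the noise family only; flips and rotations have no
physical meaning for a single spectrum.

## Models and training

Both CNNs share depth and ordering: Conv → BN → LeakyReLU(0.01) →
MaxPool(2, stride 2) → Conv → BN → LeakyReLU → MaxPool → Flatten → FC
→ Dropout(0.5) → FC(1) → sigmoid, with 3×3 kernels and (16, 32)
channels in 2-D (100×100 → 25×25 features; 2 565 441 parameters) and
length-7 kernels in 1-D (1780 → 445 features). Loss is binary
cross-entropy on logits; the optimizer is Adam. Channel counts, kernel
sizes, FC width, dropout rate and batch size are exposed in the config.
Early stopping: every `eval_every` iterations the validation loss is
checked; if it fails to improve by more than 1e-4 for `patience`
consecutive checks training stops and the best-validation weights are
restored. The training trace records the minibatch loss/accuracy and
the full validation loss/accuracy at each check.

The engine is hand-written NumPy (float32, channels-last): convolutions
run as shift-and-matmul over the k² spatial offsets, pooling as staged
pairwise maxima, with analytically verified backpropagation (checked
against finite differences in double precision) and a single seeded
generator for initialization, shuffling and dropout — training is
bit-reproducible on one device.

The KNN baseline flattens pixels and votes over Euclidean neighbours
(scikit-learn, brute force); label ties resolve to the smaller label.

## Cross-validation and reporting

The discrimination experiment uses only cancerous (label 0) and normal
(label 1) samples. Ten folds each hold 2 cancerous + 1 normal sample;
a patient who contributed both sample types has them placed in the same
fold, so no patient ever spans a train/test boundary (a validated plan
invariant). Per fold, confusion matrices are row-normalized; across
folds the cells are averaged and their mean squared deviation (MSE)
reported; the overall accuracy is the mean of the two diagonal means
(classes equally weighted, not pooled predictions).

## Execution profiles and problem sizes

* `full` — the study layout end to end: 10 folds, 5000 images/class,
  dropout 0.5, constant learning rate 5e-5 with up to 6000 iterations
  per fold.
* `fast` — the same cohort and architecture at desk scale: 2 of the 10
  folds, 500 images/class, 200 iterations (150 for the 1D model) with a
  cosine learning-rate decay 2e-3 to 1e-4 and dropout disabled.  The
  regularization is scaled down together with the run: at a few hundred
  iterations the models underfit rather than overfit, and a constant
  5e-5 would need thousands of iterations to move at all.  This is the
  profile the test suite and the acceptance script run.
* `micro` — a smoke-test cohort (4+2 samples, 2 folds) exercising every
  stage in seconds.

A scale caveat that matters for interpreting fast-profile numbers: on
one CPU the NumPy engine spends about half a second per optimizer step
at the 100x100x3 input size, so the fast profile affords only a few
hundred steps per fold.  There the 2D-CNN's cross-validated test
accuracy sits in the high 0.8s, with the 1D-CNN consistently below it;
the same model trained ten times longer on the same fold data separates
the held-out points essentially perfectly (and a linear probe on the
encoded images already does), so the gap to the full-profile regime is
an optimization-budget effect, not a ceiling of the data or the
architecture.

## What the synthetic cohort does and does not show

The generator reproduces the study's *structure*: band positions and
widths, per-class mean areas (within the calibration tolerances above),
the anisotropy patterns including the amide III ratio curves, the
amide I red shift, lognormal between-point variability, fluorescence
background and detector noise. It does not model spatial tissue
heterogeneity beyond the protein/lipid point dichotomy, Raman tensors or
depolarization physics, instrument response, cosmic rays, or
patient-level correlation beyond sample bookkeeping (points are i.i.d.
given the class). Passing tests therefore demonstrate that the pipeline
recovers the designed effects at realistic noise — not that it would
reach the same accuracies on real tissue, where class overlap is
larger. In particular the near-perfect synthetic test accuracies of both
CNNs reflect the generator's clean class structure; the comparison
between polarized-image 2D-CNN and conventional-spectrum 1D-CNN is the
meaningful readout, not the absolute numbers.
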