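# Methods

## Signal model

A pixel of a deep-UV attenuation time series is modeled as

    x(t) = a + e(t),      I(f) = |DFT(x - x̄)|(f) ∝ f^(-β)

where `a` is the static attenuation of the underlying structure and `e(t)`
a zero-mean fluctuation whose *magnitude* spectrum decays as a power law.
β ≈ 1 corresponds to diffuse (Brownian) transport, β ≈ 2 to advective
motion; intracellular activity in live cells falls between the two.
"Spectrum" throughout means the magnitude (not power) of the DFT of the
mean-subtracted trace; the synthesizer and the fitter share this one
definition, so exponent recovery is exactly self-consistent and the choice
is testable.  Frequencies below `f_min = 0.1 Hz` are excluded from every
fit and phasor: at the default acquisition (500 frames at 8 Hz,
Δf = 0.016 Hz) the retained grid starts at 0.112 Hz and ends at the 4 Hz
Nyquist frequency.

The fit is ordinary least squares of `log10 I` on `log10 f` over the
retained bins, with zero-magnitude bins dropped; β is reported as the
positive decay exponent (−slope) together with the fit r².  An all-zero
retained spectrum (a constant pixel) leaves β undefined (NaN).

## Phasor convention

The phasor is the first harmonic of the normalized spectral *decay curve*
over the retained axis, FLIM-style:

    x(f) = (f - f_min) / (f_Nyq - f_min) ∈ [0, 1]
    g = Σ I(f) cos(2πx) / Σ I(f),   s = Σ I(f) sin(2πx) / Σ I(f)

This convention was chosen over a time-domain first-harmonic because it
(a) sends temporally constant pixels to exactly (0, 0) (total spectral
energy below 1e−12 short-circuits to the origin), (b) is sign-stable so
cellwise means separate cleanly, and (c) makes distance from the origin a
strictly increasing function of β for exact power-law spectra on a fixed
grid — all three behaviors the analysis relies on.  The product g·s is
used as the scalar activity measure for phasor pseudo-colorization.

## Synthetic scenes and stacks

The generator emulates the statistical structure the analysis assumes,
with full ground truth (label mask, nucleus mask, per-cell parameter
table).

*Geometry.*  Cells are discs with a concentric, higher-attenuation nucleus
(255 nm targets nucleic acids), placed by rejection sampling with a
3-pixel clearance; placement failure after 200 tries per cell raises an
explicit density error.  Dead cells get a radially perturbed boundary
(6 sinusoidal modes, amplitude sd 0.10·R — strong enough to look blebby,
weak enough that the boundary stays a simple closed curve; larger values
produce starburst shapes no segmentation should be expected to recover).

*Static phenotypes* (attenuation in [0, 1], background 0.02):

| class | radius (px) | nucleus att. | cytoplasm att. | texture |
| --- | --- | --- | --- | --- |
| activated | 16 ± 1.5 | 0.75 | 0.45 | 0.35 |
| quiescent | 9 ± 0.8 | 0.65 | 0.35 | 0.08 |
| dead | 11 ± 1.5 | 0.50 | 0.15 | 0.15 |
| CD4-/CD8-like | 14 ± 1.2 | 0.72 | 0.42 | 0.25 |

Activated cells are larger with stronger internal texture (higher
entropy); dead cells have a distinctly lower mean attenuation and an
irregular boundary; the two dynamic subtypes are statically identical by
construction, mirroring the finding that static features do not subtype.

*Dynamics.*  Each compartment pixel receives an independent synthetic
trace with exact power-law DFT magnitudes and uniform random phases,
scaled to the compartment's fluctuation amplitude.  Defaults: CD4-like
cytoplasm β = 1.7, amplitude 0.0375; CD8-like cytoplasm β = 1.3,
amplitude 0.025 (CD4 = 1.5× CD8); both nuclei β = 1.15, amplitude 0.015.
These place both subtypes inside the displayed [1, 2] slope range with the
CD4-like cytoplasm more active and the nuclei matched; absolute values are
stand-ins (no absolute amplitudes or per-subtype exponents are published)
and are exposed in `synth.DYNAMIC_PARAMS`.  Per-pixel exponents are
jittered around the compartment mean (sd 0.08, clipped to [0, 3]) so that
pixelwise slope histograms have realistic spread.

*Detector noise.*  White Gaussian noise is added to every stack pixel.
Its default is sd 2e−5 in attenuation units, set by a temporal-SNR
requirement: white noise contributes a flat DFT floor of ≈ sd·√n per bin,
while an f^−β magnitude spectrum with a bounded fluctuation amplitude
spans ~3 decades across the fitted band — at n = 500 the floor must stay
below ~1e−3 of full scale or it flattens the high-frequency tail and
biases β toward 0.  (At sd 2e−5 recovery is unbiased to <0.001; at 1e−3
the β = 1.7 channel collapses below 1.)  Equivalently: the method itself
presumes the cellular signal dominates the detector floor across the
fitted band, as it evidently does in the real instrument.

*What the generator does not emulate:* optical point-spread-function and
coherence effects, photon (shot) noise, cell motility/drift (the protocol
lets cells settle), spatial correlation of fluctuations between
neighboring pixels, and real biological variability in morphology.
Passing tests therefore demonstrate that the *analysis* is correct and
self-consistent on data with the assumed structure — not that real-donor
accuracy figures are reproduced; those data are unreleased, and all
classification results here are synthetic analogs.

## Segmentation

Background correction shifts the histogram mode to 0, clips negatives and
rescales by the maximum — a monotone transform exactly invariant to a
constant intensity offset.  Cells: hysteresis thresholding around the
global Otsu cut (weak threshold 0.3×Otsu) so that dim dead-cell cytoplasm
stays attached to its bright nucleus; then opening (disk radius 2), hole
filling, removal of objects under 30 px, and a watershed on the smoothed
(σ = 2) distance transform seeded by its depth-2 h-maxima — shallow lobes
of one irregular cell merge, the deep saddle between touching cells still
splits.  Labels are renumbered in raster order of centroids (row-major,
0-based, origin top-left).  Nuclei: Otsu binarization within the cell,
opening + closing (disk radius 1), largest component, hole filling; the
higher-attenuation class is the nucleus and cytoplasm is the exact
complement within the cell.  Cells with fewer than two intensity levels
return an empty nucleus with a degenerate flag.

Known limitation: Otsu nucleus masks carry a 5–15 % boundary ring of
cytoplasm pixels.  Because cytoplasmic β differs between subtypes, this
contamination leaks a ~0.02 shift into nuclear β means, which the nearly
noise-free synthetic fits resolve as a spurious subtype difference; the
compartment contrast contract is therefore validated against ground-truth
compartment masks, while the Otsu path remains the pipeline default for
feature extraction and classification (where it is harmless).

## Features and ranking

Fractal features binarize the background-corrected cell at eight equal
intensity bins `[(k−1)/8, k/8)` (bin 8 closed at 1) and summarize each
binary mask by its box-counting dimension: occupied-box counts at grid
sizes {2, 4, 8, 16, 32} px, least-squares slope of log count vs
log(1/size), 0 for an empty mask.  The estimate approaches 2 from below
for filled regions (perimeter and grid-saturation corrections decay like
1/size of the object); it is a texture descriptor, not a precision
dimension estimate.  Entropy uses a 64-bin histogram over [0, 1] (stable
at cell areas of ~10³ px).  Chi-square ranking discretizes each feature
into 10 quantile bins and scores the bin-by-class contingency table with
Pearson's statistic; constant features score 0.  Clustergram-style
summaries report the mean per-class z-score per feature.  UMAP embeddings
use n_neighbors = 15, min_dist = 0.1, a fixed seed, and z-scored features.

## Classification

Two estimators share one metric surface (confusion matrix, accuracy,
per-class precision/recall, 2-class sensitivity/specificity):

* **ResidualNetClassifier** — a compact numpy conv-net: stem 3×3
  convolution, three residual blocks (16/32/64 channels, stride-2
  projections between), global average pooling, linear softmax head;
  cross-entropy, Adam (lr 1e−3), ~30 epochs by default, translation
  (±8 px at crop scale) and reflection augmentation, all seeded.  Inputs
  larger than the 32-px network side are average-pooled down; channels are
  standardized with training-set statistics.  One channel for the 3-class
  task, four (attenuation, g, s, β) for subtyping.
* **LinearBaselineClassifier** — LDA on standardized features with a
  shrinkage fallback for singular covariances; deterministic, used for the
  composition study and as a wiring guard (it must agree with the conv-net
  within 10 points on cleanly separated synthetic data).

Training uses a stratified 80/20 split; subtyping additionally reports
stratified 5-fold cross-validation pooled over folds.  Sample composition
is viability % = 100·(1 − dead/total) and activation % =
100·activated/(activated + quiescent) among live cells, compared to the
known mix by OLS (slope, intercept, r²).

## Numerical choices and degenerate inputs

Zero-energy phasors short-circuit to (0, 0) below Σ I < 1e−12; log-log
fits drop zero bins and return NaN below two usable bins; constant frames
background-correct to zero with a warning; empty masks yield empty maps
(not errors); stacks are float32, analysis in float64.  Truncating a
synthesized stack (frame-sweep utility) introduces genuine spectral
leakage — the inverse-FFT construction guarantees the target spectrum only
on the full window — so the sweep reports the resulting fit bias rather
than hiding it; at the generator defaults classification stays at ceiling
well below 300 frames because amplitude differences survive truncation.
Resolution degradation (Gaussian blur σ = factor/2, then subsampling)
measurably shrinks the between-subtype cytoplasmic-β separation while the
baseline classifier remains at ceiling, so tests assert the separation
effect rather than an accuracy drop.

## Default problem sizes

Test and demo runs use a few hundred synthetic cells (scenes of 6–14
cells at 192–320 px, stacks of 200–500 frames), chosen as the smallest
sizes at which every statistical contract (≥50 cells per subtype for the
compartment tests, 20 samples for the composition fit) is comfortably
satisfied on a single CPU.
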