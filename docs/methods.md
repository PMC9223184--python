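# Methods

This note documents the models, numerical choices and limitations behind
`moldscan`. It is the package's own account; every number quoted here is
computed by the test suite or the acceptance script.

## Problem and grading reference

Kernels are graded into four mold levels — healthy, mild, moderate, severe —
using catalase (CAT) activity as the biochemical reference. CAT activity is
the permanganate titration volume consumed per gram per hour,
`(V1 − V2)/(M·T)` in mL/(h·g). Healthy (sterilized) kernels show exactly 0;
the three moldy levels are modeled as Gaussians with means 1.57 / 1.91 / 2.24
and SDs 0.13 / 0.09 / 0.12.

Grading thresholds are not part of the published statistics, so the package
uses the midpoints between adjacent class means (1.74 and 2.075) with a
numerical-zero band (ε₀ = 10⁻⁶) for healthy, and assigns a value exactly on a
cut point to the **higher** level — the conservative choice for food safety.
With these cuts the distributions overlap: the cut points sit 1.31–1.89 SD
from the class means, so the exact expected agreement between the generating
level and the CAT-assigned level is 93.9% (normal CDF arithmetic), not higher.
This overlap is a property of the measured class statistics, and it
effectively caps end-to-end classification accuracy on synthetic data in the
low-to-mid 90s — the pipeline is trained and scored against CAT-assigned
labels, as the experiment design prescribes.

## Synthetic scenes: what is emulated

`generate_scene` renders, per sample and sensor, a raw cube plus white/black
references satisfying `raw = black + (white − black)·R`, with the true
reflectance `R` built as:

* an elliptical kernel ROI on a dark background (reflectance 0.05);
* a smooth analytic base curve per sensor. Vis-SWNIR: an asymmetric Gaussian
  peaking at exactly 820 nm (rise width 230 nm, fall width 900 nm, so the
  descent is slow), spanning 0.12–0.80. LWNIR: a 0.45 baseline plus Gaussian
  peaks at 1100/1300 nm and troughs at 1192/1445 nm. Only the landmark
  positions are documented for the real material; the analytic shapes are
  this package's choice;
* a level reflectance scale (1.00, 0.85, 0.72, 0.60) — mold depresses overall
  reflectance monotonically;
* a whole-kernel multiplicative amplitude drawn once per scene with SD equal
  to the level's speckle SD, emulating between-sample scatter;
* an embryo patch (15% of ROI area, offset toward one end) whose reflectance
  dips *smoothly* from the body value at its rim to a level-dependent factor
  (0.60, 0.55, 0.50, 0.45) at its center — mold concentrates in the embryo —
  and which carries multiplicative per-pixel, per-band speckle with SD
  (0.01, 0.03, 0.05, 0.07) per level; the rest of the ROI gets one third of
  that SD;
* clipping to [0, 1.05]; white ≈ 0.99 and black ≈ 0.02 with small sensor
  noise.

The smooth embryo profile matters for texture. GLCM quantization uses
per-band ROI min–max; a sharp embryo step would place most pixels in the two
extreme gray levels, and the rare boundary pairs (with their large (i−j)²)
would then dominate contrast and *shrink* as speckle spreads the clusters —
a non-monotone artifact. With a gradient, neighbors along the profile differ
by at most a bin, and contrast is driven by the noise-to-bin-width ratio:
the additive sensor-noise floor in the corrected image is level-independent
while the quantization range scales with the level's reflectance, so that
ratio — and with it contrast — grows monotonically with mold severity, and
energy falls. The test suite verifies this ordering on class means for both
sensors at the default design.

Not emulated: radiometric response of the actual cameras, geometric/spectral
smile, multi-kernel dish layouts, spatially correlated mold blobs, and any
aflatoxin chemistry. Passing tests therefore demonstrate the pipeline's
correctness and its behavior under the assumed statistical structure, not
instrument-level realism.

### Two fidelities

Full 240-sample image sets would exceed a gigabyte for the Vis-SWNIR sensor
alone, so two paths exist:

* **image** (`render_feature_tables`): renders every scene and pushes it
  through calibration → Otsu masking → mean-spectrum → per-band GLCM →
  band trimming. Intended for small scene counts.
* **table** (`generate_feature_tables`, default): synthesizes the feature
  tables directly. Spectra rows are base curve × level scale × per-sample
  amplitude plus per-band noise (both proportional to the level's speckle
  SD), so with noise off the class means equal base × scale exactly. Texture
  class-mean curves are *calibrated* by rendering one scene per (level,
  sensor) and extracting real GLCM rows on a coarse 24-band grid,
  interpolated to the full axis; samples jitter around these curves (15%
  between-sample, 5% per-band relative noise).

The round-trip test renders a small image-path dataset and checks the fast
path against it: class-mean spectra agree within 10% relative (the image
path's ROI mean includes the darker embryo patch, a 6–8% bias the fast path
deliberately omits to keep its noise-off identity exact) and the texture
level-ordering matches.

## Texture

The GLCM is the ordered (non-symmetric) pair count at distance 1 along each
of 0°/45°/90°/135°, normalized per direction; the four parameters are
computed per direction and averaged — averaging parameter values, not
matrices. Pixels outside the ROI are excluded from pairs rather than
zero-filled. Quantization is per-band ROI min–max into 8 equal-width bins
(levels 1..8, background 0); a constant band maps to a single level and is
flagged. Undefined correlation (zero marginal SD) maps to 0 and is logged.
A band where some direction has no valid pair yields NaN in that sample's
row and is logged. Correctness is pinned by a brute-force double-loop oracle
(800 matrix/parameter comparisons at 10⁻¹² relative) and by scikit-image's
`graycomatrix` on unmasked rectangles.

## Preprocessing

All treatments are row- or column-wise linear maps given fitted context:

* **smooth** — centered moving average, default window 9, with symmetric
  shrinking windows at the edges (a linear spectrum is reproduced exactly
  everywhere, and the matrix keeps its width);
* **msc** — per-row regression on a reference spectrum (calibration mean by
  default), output `(x − a)/b`; slopes below 10⁻⁸ pass through, logged;
* **detrend** — subtract the least-squares line of reflectance on wavelength;
* **center** — column centering, the chemometric norm among the
  column/row/overall options.

MSC references and centering means are fitted on the calibration split and
frozen for prediction rows — the leakage-safe default. The pipeline's
default recipe is smooth-detrend; texture blocks are left untreated
(spectra-only preprocessing is what the recipe labels describe).

## Selector fitness: PLS-DA

All selectors minimize a stratified 5-fold CV misclassification rate of a
PLS-DA model on the candidate columns. The SIMPLS fit (verified prediction-
identical to `sklearn.cross_decomposition.PLSRegression`) produces
predictions for every component count 1..min(10, n_vars, n−1) in a single
pass; the reported error is the minimum over component counts — the standard
chemometric component choice at no extra model fits, in place of a nested CV
that would be prohibitive inside selectors making 10⁴–10⁵ fitness calls.
Class assignment uses nearest-training-class-centroid decoding in the
predicted-score space rather than argmax: severity grades are ordered and
their class means nearly collinear, a geometry where a linear model cannot
raise a middle class's indicator above both neighbors, while centroid
distance along the shared latent direction separates all four levels. The
whole evaluator is numba-compiled; selector determinism is exact for a fixed
seed.

## Selectors

* **VCPA** — defaults: 50 EDF iterations, K = 500 binary-matrix-sampling
  runs per iteration (inclusion 0.5, at least 2 variables per run), elite
  fraction σ = 0.1, final pool L = 14. The pool at iteration *i* is
  `round(p·exp(−i·ln(p/L)/n_iter))`, reaching L at the last iteration;
  variables are kept by inclusion frequency among the elite runs (ties favor
  the lower column index). The returned subset is always the argmin of the
  exhaustive 2¹⁴−1 evaluation over the final pool, ties broken toward
  smaller subsets — so the selection never exceeds L variables.
* **IRIV** — defaults: K = 500 rows, inclusion 0.5, α = 0.05, at most 20
  rounds. Per round, each variable's paired pseudo-population is built by
  flipping its column in the inclusion matrix; variables whose inclusion
  does not lower mean CV error (DMEAN ≤ 0) are dropped, whether weakly or
  significantly (two-sided Mann–Whitney); strongly and weakly informative
  variables are kept. Backward elimination then removes variables while a
  removal strictly lowers CV error, so the returned subset never scores
  worse than its starting subset. If everything is dropped, the best single
  variable is returned and flagged.
* **mVCPA-IRIV** — VCPA's frequency-ranking phase shrinks to an intermediate
  pool of 50, then IRIV runs on the pool. Blocks no wider than the pool
  bypass the VCPA phase and reduce to IRIV exactly (same seed, same output).

Reduced budgets for desk-scale runs (`VcpaParams.reduced()`,
`IrivParams.reduced()`): K = 100 and 15 EDF iterations; all other values
unchanged. The pipeline uses the reduced budgets by default
(`budgets="reduced"`).

The planted-recovery benchmark plants 10 informative columns among 200 at
n = 240 with per-variable adjacent-class shifts uniform in 0.6–1.0
within-class SD. The shift range matters: above ~1.5 SD a 5-variable subset
already reaches zero CV error, so a parsimonious selector is *correct* to
return fewer than 8 planted variables; 0.6–1.0 SD makes every planted
variable contribute. VCPA and IRIV recover medians of 8 and 9 of 10 over
seeds 1–5 under reduced budgets.

## Fusion and modeling

Pixel-level fusion concatenates full blocks; feature-level fusion
concatenates selected columns; every column carries (sensor, block, band,
wavelength) provenance. Cross-sensor feature fusion uses the Vis-SWNIR
smooth-detrend spectra + energy block and the LWNIR smooth-detrend spectra +
contrast block. Fused matrices are min–max scaled to [0,1] per column on
calibration rows (raw reflectance ~0–1 next to contrast ~0–3 would otherwise
dominate an RBF kernel); prediction rows may exceed the range and are not
clamped; constant columns map to 0 and are logged.

Splitting is per-class 3:1 (60 per level → 45 calibration / 15 prediction;
classes not divisible by 4 floor the prediction count). SVM-RBF searches
C, γ ∈ 2⁻⁸..2⁸ in factor-2 steps with 5-fold stratified CV; RF uses 50
trees; KNN searches odd k ∈ 1..15 over Euclidean/cityblock. Every report
carries the calibration/prediction gap (the overfitting criterion), the
confusion matrix in healthy→severe order and the moldy-graded-healthy count.

On the default synthetic design (five seeds), cross-sensor feature-level
VCPA fusion reaches a median prediction accuracy above 90%, never grades a
moldy kernel healthy, and matches or beats the spectra-only SVM baseline
(taken on the Vis-SWNIR sensor, the stronger of the two single-sensor
models). These numbers are recomputed by
`tests/test_acceptance.py::test_end_to_end_fusion_benchmark`.

## Problem sizes and runtime

The benchmarks run at the full experimental design (240 samples; 389 + 112
bands) with reduced selector budgets; image-path tests use 48×48-pixel
scenes with shortened band axes, and fast-path texture calibration renders
one scene per level and sensor on a 24-band grid. With the compiled fitness
core, a full feature-level cross-sensor run takes well under a minute per
seed on one CPU.

## Known limitations

* The generator's class structure is essentially one multiplicative latent
  dimension plus level-dependent speckle; real mold adds spatially
  structured, spectrally localized absorption changes the generator does not
  model, so selected wavelengths carry no biochemical meaning here.
* ROI means in the image path include the embryo bias that the fast path
  omits (see round-trip note above).
* Otsu's threshold stands in for the original unpublished mask thresholds.
* The exhaustive VCPA phase fixes L = 14; wider final pools would be
  exponentially more expensive.
* ENVI I/O covers the header fields this package writes (BSQ/BIL/BIP,
  numeric types 1–5 and 12), not the full ENVI dialect.
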