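# Methods

This note documents the models, numerical conventions and design choices
behind `afmtexture`, in the order the pipeline runs them.

## Surface-texture parameters

Every channel raster (or sliding window) is mean-leveled and reduced to the
31-parameter registry below. The registry order is fixed; `min_window_px`
is the smallest square window on which the parameter is defined (4 px for
amplitude/hybrid, 8 px for spatial/functional/volume).

| family | parameters | notes / units |
|---|---|---|
| amplitude | Sa, Sq, Ssk, Sku, Sp, Sv, Sz, S10z | height units; Ssk/Sku dimensionless |
| hybrid | Sdq, Sdr, Ssc, Sds | slope (–), developed area (%), summit curvature (1/nm), summit density (1/µm²) |
| spatial | Sal, Str, Std, Srw, Stdi | decay length (nm), aspect ratio (–), lay angle (°), dominant wavelength (nm), direction index (–) |
| functional | Sbi, Sci, Svi, Sk, Spk, Svk, Smr1, Smr2, Sxp, Sdc | bearing-curve (Abbott–Firestone) family; heights in channel units, Smr in % |
| volume | Vmp, Vmc, Vvc, Vvv | material/void volume per area at the 10 %/80 % material ratios |

Conventions that needed fixing because the standard definitions leave them
open (all are implemented identically in the windowed and whole-image
paths, and an independent naive implementation in the test suite must agree
to a relative 1e-9):

* **Leveling** is mean subtraction only. Plane fitting inside windows
  would let local tilt leak class signal inconsistently between training
  (whole image) and application (window); whole-image plane leveling is
  the user's pre-processing step.
* **Gradients/curvatures** use central differences with one-sided stencils
  at edges; no padding is invented.
* **S10z** averages the five highest 8-neighbourhood summits and five
  deepest pits; a small window with fewer extrema uses what exists, and a
  window with none falls back to Sp/Sv.
* **Sds** divides the summit count by the *interior* area (the pixels
  where an 8-neighbourhood exists), making the density comparable between
  a 32 px window and a full image. Ssc is 0 when a window has no summit.
* **Autocorrelation** (Sal, Str) is the periodic FFT autocorrelation.
  Decay lengths are found by marching 360 rays (1° apart) from zero lag in
  0.5 px steps with bilinear interpolation, refining the 0.2-crossing
  linearly; Sal is the shortest decay length × pitch, Str the
  shortest/longest ratio. Rays that never decay within the centred map
  take the maximal radius.
* **Spectrum** (Std, Srw, Stdi): half-plane power spectrum without DC.
  Std is the angle of the single strongest component (ties to smaller
  frequency indices); Srw converts the strongest radial ring (rings of
  width one fundamental frequency) to a wavelength; Stdi is mean/max of
  power summed in 5° angle bins.
* **Bearing curve**: heights sorted descending, linearly interpolated on a
  0–100 % material-ratio axis (fixed interpolation formula, index
  t = p·(N−1)/100). Sk uses the minimal-slope 40 %-wide secant searched on
  a 0.1 % grid of left endpoints (ties to the smallest ratio); Smr1/Smr2
  are the curve's crossings of the secant's 0 %/100 % levels on a 0.05 %
  grid with linear refinement; Spk/Svk are 2·area/width of the regions
  outside those levels. Degenerate cases (crossing at 0 % or 100 %) give
  Spk/Svk = 0.
* **Zero-variance surfaces**: Sa = Sq = 0 are valid; moment ratios
  (Ssk, Sku), Sq-normalised indices (Sbi, Sci, Svi) and the spatial family
  raise an undefined-moment error rather than returning NaN.

The field's commercial tools report "~40" parameters without an
enumerated list; this 31-entry registry covers every family they report
and is configurable (`ParameterRegistry.subset`), so users can restrict to
any subset. The workflow is agnostic to the exact list.

## Feature ranking and selection

Features are (channel, parameter) pairs; combining channels widens the
table. Gini importance is the mean decrease in Gini impurity over a
bagged ensemble of 500 decision trees with √(n_features) random feature
subsets per split — enough trees for importances stable to two figures.
Ties break by registry order for determinism. Ranking runs on the pooled
labelled table *before* the train/test split (parameter reduction is part
of dataset construction in this workflow); k defaults to 10 for one
channel and 20 for a combination.

## Gaussian-process classifier

Binary GP classification with a constant×RBF kernel (isotropic by default
— the fewest hyperparameters for tens of training cells; one length scale
per feature optionally via `ard=True`), Laplace approximation, kernel
hyperparameters by marginal-likelihood maximisation, Newton iteration cap
1000. Features are z-scored with training mean/sd — they mix nm, nN, %
and dimensionless quantities, and an RBF on raw values would be dominated
by whichever unit happens to be largest. The same statistics are applied
at heatmap time. The decision threshold is P(high) ≥ 0.5, ties to high.
Laplace-approximated probabilities are conservative: even perfectly
separated training rows score ~0.75–0.9, not 1.0.

Model bundles serialise to JSON (features, standardisation, kernel
hyperparameters, standardised training data); loading refits the Laplace
latent state deterministically, so reloaded models reproduce probabilities
to 1e-9.

## Blur scan and zoom selection

`blur_average` replaces each pixel by the mean of the k×k block anchored
at the pixel's top-left corner, truncated at the bottom/right edges
(shape-preserving, parameter-free; kernel 1 is the identity). The scan
re-runs the *entire* step-1 pipeline per kernel with identical seeds. The
zoom rule takes the largest kernel with accuracy ≥ X (default 80 %)
*relative to the unblurred baseline* — whether the published rule meant
relative or absolute accuracy is ambiguous, so both modes exist
(`relative=False` for absolute) — floored at 32 px, the scale below which
too few pixels remain for the parameter registry.

## Heatmaps

Windows of 32×32 px, stride 1; P(high) is stored at the window's centre
pixel (even windows: the top-left pixel of the central 2×2 block — an
arbitrary but documented convention). The border where no full window
fits is masked, never padded: padding would fabricate texture. Stride > 1
computes every stride-th position and fills intermediate valid pixels with
the nearest computed value. The raster path must agree with an
independent single-window evaluation to 1e-10 (tested at random
positions); any future accelerated path must preserve that.

The classifier is trained on whole images and applied to windows, as the
workflow prescribes. This is a real scale mismatch: parameters whose
expectation depends on the evaluation area (extreme heights Sp/Sv/Sz/S10z
grow with log-area; spatial decay lengths are bounded by the window) shift
between training and application. The registry definitions above minimise
the avoidable part (intensive Sds, mean-leveling), and the heatmap should
be read as a *relative* map of class evidence, not calibrated per-window
probability. A window-trained mode (sample labelled windows, then train)
is available as `AggressivenessGP` on a window-built table, but is not the
default workflow.

Regions are 8-connected components of {P < 0.5} / {P ≥ 0.5} within the
valid mask, filtered by a minimum area, with sub-pixel boundaries traced
in physical nm (pixel centre at (index + 0.5)·pitch).

## Synthetic study conditions

The generator emulates what the method needs from its data — two cell
classes whose surface texture differs at specific scales across
co-registered channels — not cell biophysics. Default geometry: 512×512 px
over 10×10 µm (pitch 19.53 ≈ 20 nm), channels height (nm) + three
Ringing-mode channels (nN), cross-channel latent correlation 0.5. Each
cell is a sum of:

* a **large-scale field** (Gaussian random field, 1/e correlation length
  1 µm) identical between classes — residual cell-body undulation after
  flattening. Its amplitude is deliberately small relative to the fine
  texture: a field-dominated image would make variance-normalised moments
  shift between whole-image and window scales and break the
  train-on-image/apply-to-window transfer that the method presumes.
* **microvilli-like bumps** (Gaussian profile, FWHM 250 nm, Poisson
  positions shared across channels): the low class has twice the surface
  density (8 vs 4 µm⁻²) at heights matched so the bump RMS is equal
  (height ∝ 1/√density). The ~0.4 µm class signal is therefore
  *sparsity*, not power.
* **nano-granularity** (~30 nm): equal RMS and spectrum in both classes,
  but Gaussian texture in the low class versus a mixture with sparse
  shot-noise spikes (half the variance, spike density set for excess
  kurtosis ~20) in the high class. The ~20–40 nm class signal is again
  structural (skew/kurtosis), not amplitude.
* per-cell lognormal amplitude jitter (sd 0.15) on each component —
  cell-to-cell biological variability.

Two properties of these conditions are load-bearing. First, matched
second-order statistics make the blur scan meaningful: an amplitude ratio
would survive *any* linear filter (a box filter's sidelobes keep
gradient-feature contrast large at every kernel), whereas sparsity
contrast genuinely dies once averaging Gaussianizes the texture — which is
the mechanism the accuracy-collapse reading of step 2 presumes. Second,
without per-cell jitter every cell of a class would be a near-copy and
any surviving post-blur RMS difference, however tiny, would stay
perfectly separable.

`nano_contrast_config` confines the contrast to the ~40 nm scale only
(identical fields and bumps; Gaussian vs spiky granularity at equal RMS):
the conditions for studying blur collapse in isolation. With them the
blur curve falls from ~1.0 at kernel 1 to near chance at kernels ≥ 16,
and the zoom rule returns the 32 px floor.

What the generator does **not** emulate: Ringing-mode signal formation,
instrument noise and scan artefacts, membrane mechanics, and the true
(unknown) cross-channel correlation structure of real cells — the 0.5
default is a placeholder. Passing tests show the *workflow* recovers
planted multi-scale class structure under realistic variability; they are
not evidence about real cell lines.

## Problem sizes and determinism

Tests and the acceptance script run the study conditions at desk scale:
step-1 recovery on 256×256 rasters (the windowed variant of the full
512×512 geometry; 40 cells/class, 4 channels), blur scans and heatmaps on
128×128 single-cell crops (97×97 valid window positions). All randomness
flows through explicit integer seeds (numpy `SeedSequence` spawning for
the generator; fixed `random_state` for the forest and GP), and identical
configuration reproduces feature tables, rankings, probabilities and
heatmap matrices bit for bit on one platform.

## Known limitations

* The registry is one reasonable instantiation of "~40 SPIP parameters";
  results depend on the feature space, and users with a preferred subset
  should pass their own registry.
* Whole-image-trained heatmaps are uncalibrated at window scale (above).
* The GP is binary; multi-class aggressiveness grading is out of scope.
* Sal/Str assume a centred autocorrelation map at least 8 px across;
  anisotropic textures with decay lengths beyond half the window are
  truncated at the map radius.
* The blur scan re-trains the feature ranking per kernel, so its curves
  measure the pipeline's behaviour, not a fixed feature set's.
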