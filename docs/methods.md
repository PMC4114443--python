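# Methods

This note documents the models, parameter choices and numerical conventions
behind `phasetex`, and what the synthetic experiments do and do not show.

## Physical model

X-ray optics uses the complex refractive index n = 1 − δ − iβ. The package
relates δ to electron density (δ = ρ_e r_e λ²/2π), β to linear attenuation
(μ = 4πβ/λ) and δ to phase shift per length (P = 2πδ/λ). The beamline
defaults emulate the experiment the pipeline is modelled on: 13 keV
(λ ≈ 0.954 Å), 85 cm specimen-to-detector propagation, 9 µm detector
pixels. The source is an ideal monochromatic plane wave; with a ~60 m
source distance the magnification and partial-coherence corrections are
below the pixel scale and are neglected (config-level extensions).

The expected photon count per unattenuated pixel defaults to 10⁴
(Poisson noise σ = 1 %), a plausible value for a synchrotron radiograph at
tens of milliseconds exposure. Detector blur and readout noise are out of
scope.

**Tissue constants** are order-of-magnitude soft-tissue values and are
deliberately labelled nominal: water-like electron density
ρ_e = 3.34 × 10²⁹ m⁻³ (δ ≈ 1.36 × 10⁻⁶ at 13 keV) and μ = 250 m⁻¹
(β ≈ 1.9 × 10⁻⁹). No measured δ/β for mouse gastric wall or implanted tumor
tissue exists; the resulting δ/β ≈ 700 preserves the phase-dominant regime
of light-element tissue. Both live in the configuration, not in code.

## Synthetic specimen generator

A specimen is a quasi-3-D tube (stack of annular cross-sections): gastric
wall around an air-filled lumen, because the emulated specimens were imaged
air-filled. Per stage (normal, d3 … d11) the generator controls

| parameter | normal → d11 | rationale |
|---|---|---|
| wall thickness | 250 → 470 µm | ~2× thickening, plausible for a mouse stomach wall at 9 µm pixels |
| texture amplitude (σ of δ fluctuation) | 5 % → 35 % of tissue δ | monotone textural irregularity |
| texture correlation length | 30 µm (fixed) | coarseness expressed through amplitude and nodules; a growing correlation length would *suppress* the distance-1 co-occurrence contrast it is meant to raise |
| boundary roughness (radial σ) | 9 → 81 µm | surface unevenness |
| hyperplasic nodules | 0 → 4 | focal inner-wall thickenings from d5 on |

The intra-wall texture is a stationary Gaussian random field (3-D Gaussian
filter of white noise, exactly normalized to the specified σ inside the
wall) applied multiplicatively to both δ and β, i.e. density fluctuations.
Boundary perturbations are low-order Fourier series in angle whose
coefficients drift smoothly along the tube axis. The wall occupancy uses a
one-pixel partial-volume ramp at each boundary: a binary voxel mask would
put multi-radian phase steps at single-pixel scale and flood the projection
with artificial speckle that saturates fringe contrast at every stage.

Amplitude spacing between adjacent stages was set so that the projected
texture response separates beyond single-specimen realization variability;
this was verified on four independent seed families. With one specimen per
stage (as in the emulated study), occasional adjacent-stage inversions of a
single feature remain possible at unlucky seeds — a faithful property of
single-specimen designs, not a pipeline defect.

Everything is a pure function of (stage, size, spec, physics); all
randomness flows from the per-stage seed plus the run-level seed offsets.

## Forward imaging and CT

Line integrals use parallel-beam geometry, rotation about the grid center,
bilinear interpolation — the same convention as `skimage.transform.radon`,
so simulated sinograms round-trip exactly through the FBP module. Free-space
propagation is a band-limited angular-spectrum kernel (exact for free
space; the classical sampling bound z ≤ N·dx²/λ is enforced with an
advisory error). z = 0 returns the input bit-for-bit; negative z applies
the exact inverse kernel.

Detection: intensity × photon count → Poisson draw → linear 8-bit
quantization. Two quantization modes exist. Per-image min–max scaling (the
256-gray convention of the emulated images) is self-normalizing but injects
a random per-image gain set by the extreme fringe pixels, which scrambles
cross-image comparability of gray levels. The pipeline therefore defaults
to a **fixed reference range** (0 … 2.2 × photon count, chosen to contain
the boundary-fringe overshoot) with **radiographic display polarity**
(attenuating structure bright, as in the clinical-film convention in which
the emulated study's absorption CT shows the wall as a white ring). Both
the mode and the applied scale are recorded in the image metadata because
texture features depend on them.

CT reconstruction is filtered back projection (`skimage.transform.iradon`)
of −log(I/I₀) sinograms, Ram-Lak by default with Shepp-Logan/Hann
apodization options, bilinear back-projection, and the region outside the
inscribed circle masked to zero (it is not covered by every projection and
collects circular artifacts). Values are rescaled to attenuation per meter.
Zero-intensity bins are floored to one quantization level (I₀/255) with a
logged count. Whether the emulated study reconstructed from raw or
phase-retrieved intensities is unknown; the pipeline follows its text
literally (intensity in, FBP out), so reconstructions of strongly
phase-contrast sinograms are edge maps rather than μ maps — the acknowledged
artifact of single-distance in-line CT without phase retrieval.

## Texture analysis

ROIs: 20 per image, 50 × 50 pixels, top-left corners drawn uniformly
without replacement among placements fully inside the analysis mask
(overlap allowed, duplicate corners forbidden; 0-based, half-open spans).
The pipeline's mask is the projected specimen silhouette eroded by 16
pixels, so ROIs sample wall texture rather than the steep intensity band at
the organ border, whose stage-independent gradients would mask the stage
signal. Masks are also accepted as explicit inputs.

GLCM: gray levels quantized by linear binning of the 8-bit range into
K = 16 levels (a 50 × 50 ROI yields ~2500 pairs — K = 256 would leave the
65536-cell matrix almost empty); offsets are explicit (Δrow, Δcol)
displacements, default distance 1 pooled over the four standard directions
with symmetrization, then normalized. The nine statistics use base-2
logarithms, 0·log 0 := 0, and the difference distribution is indexed by
|i−j|. A constant ROI has σ_x σ_y = 0; its correlation is reported as 0
with a logged warning rather than an error, so random ROI sampling cannot
abort a run.

## PCA discriminant

Per specimen, the 20 × 9 matrix is standardized column-wise (n−1
denominator); the 9 × 9 Pearson correlation matrix across ROI rows is
eigendecomposed (`numpy.linalg.eigh`); components are kept up to the first
CCR > 80 %; scores are F_i = l_i · t.

Two genuinely open design points and the choices made:

* **Score basis.** Standardized per-specimen scores are identically
  mean-zero (the columns of Z are centered), which would make a
  mean-score threshold vacuous. The per-specimen reports therefore score
  the *raw* feature rows (eigenvectors still come from the correlation
  matrix of standardized features, so standardization is not inert); the
  standardized path exists as `score_mode="standardized"`.
* **Eigenvector sign.** The sign of l_i is arbitrary but flips F_i and the
  meaning of any fixed threshold. Signs are anchored on the two
  marginal-appearance features in priority order — angular second moment
  (uniformity, the hallmark of normal tissue) first, sum average (overall
  gray level) second, requiring |loading| > 0.2, with loading-sum and
  largest-|loading| fallbacks — so that higher scores mean more
  normal-like, the polarity a "normal iff score > threshold" rule
  requires. The plain loading-sum convention is available but, on GLCM
  features, orients the first component along texture *contrast* and
  inverts the discriminant.

Because each specimen gets its own eigenbasis, per-specimen mean scores
are not comparable across specimens; their eigenvector composition swings
mean (F1+F2) by several units between realizations. Cross-stage statements
are therefore made in a **pooled basis**: all 120 ROI rows standardized and
eigendecomposed together, every ROI scored in that common basis
(`pooled_component_sums`, written as `stage_comparison.json`). In that
basis mean (F1+F2) decreases monotonically with stage and the normal
specimen scores highest. The 8.5 threshold of the original study is tied to
the scale of its (unavailable) data; it is shipped as the default
configuration value, and the direction of the separation — not the absolute
threshold — is the property the synthetic experiments test.

## Stage classification

The 120 × 9 dataset (six stages × 20 ROIs) is evaluated with a linear-kernel
SVM (`sklearn.svm.SVC`, C = 1, one-vs-one voting) under plain (not
stratified) seeded 10-fold cross-validation; features are standardized with
training-fold statistics only. ROI rows — not specimens — are the
cross-validation unit, exactly as the 120/12/108 arithmetic of the emulated
protocol implies; since ROIs from one image are statistically dependent,
the resulting accuracy is optimistic relative to a per-specimen split and
should be read as a within-design figure, not a clinical estimate. At the
shipped seeds the mean accuracy is 83.3 % (observed 79–89 % across seed
families; chance 16.7 %), with confusions almost entirely between adjacent
stages.

## Problem sizes and determinism

The default run uses 256 × 256 × 256 phantom volumes (2.3 mm field of view
at 9 µm), one projective image per stage, 180-angle sinograms of the
central slice (the 0.1°/1800-angle protocol grid is available as
`paper_angles()`), and completes in about a minute on one CPU; the oracle
checks use 512 detector bins (FBP disk) and 256² fields (Fresnel limits).
Every random stage has an explicit seed recorded in the run manifest, and
identical configurations reproduce feature tables byte for byte.

## What passing tests show — and what they do not

The synthetic family demonstrates that the implemented chain transduces a
monotone structural progression into monotone texture statistics, a
directionally correct PCA discriminant and an above-chance stage
classifier. It does not validate the biology: phantom texture is a
Gaussian random field, not histology; tissue optics are nominal; display
scaling is chosen, not measured; and the original study's absolute numbers
(its F values, 8.5 threshold and 83.3 % accuracy) depend on images that
were never deposited and are not reproducible from first principles.
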