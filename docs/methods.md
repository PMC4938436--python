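# Methods

## Model

An observed spectrum is modeled as a non-negative linear mixture of known
reference spectra plus a constant stray-light background:

    y = F x + b + noise

`y` is the length-`m` vector of intensities on the *concatenated* channel
axis: emission spectra recorded under `p` excitation wavelengths, joined
end-to-end with excitations ordered ascending and emission channels
ascending within each block. `F` is `m x n`, one peak-normalized column per
fluorophore, measured from pure singly-labeled populations under identical
acquisition settings. Peak normalization is global across the concatenated
axis (the single brightest excitation/emission channel of each fluorophore
is unit intensity), so abundances are in units of that fluorophore's peak
signal, not photophysical concentrations. No sum-to-one constraint is
imposed.

The binary label constraint replaces the `n`-fluorophore fit with an
exhaustive search over all `C(n, 2)` two-fluorophore submodels

    y = f_i x_i + f_j x_j + b,    x_i, x_j >= 0,

each solved by non-negative least squares after subtracting the fixed
background `b`; the pair with the minimal sum of squared residuals (SSR) is
selected. The search is exhaustive and deterministic: ties (measure zero in
the presence of noise) resolve to the lexicographically first pair.

### Solvers and numerical choices

* The 2-variable NNLS inside each pair fit is solved in closed form by
  active-set reasoning: the unconstrained 2×2 normal-equation solution is
  accepted if feasible; otherwise the optimum lies on a face and is the
  better of the two clipped single-variable fits. This is exactly optimal
  for two variables, and is vectorized over all pairs (the per-particle
  search over 120 pairs is a handful of array operations on the
  precomputed Gram matrix `FᵀF` and correlation vector `Fᵀ(y − b)`).
  `scipy.optimize.nnls` provides the general `n`-variable constrained
  solver and serves as an independent cross-check of the closed form in the
  test suite.
* The two-stage policy for plain unmixing — ordinary least squares first,
  NNLS only if some abundance is negative — reflects that the unconstrained
  solve is cheap and usually feasible; `method_used` records which branch
  ran.
* Pairs of reference columns whose 2×2 Gram matrix has condition number
  above 1e8 are flagged as degenerate (near-parallel spectra) but still
  fitted; the returned fit is the best feasible one.
* Background `b` is a known fixed vector (per-channel mean over a
  user-chosen cell-free ROI), subtracted from `y`, not a fitted amplitude;
  it is assumed identical for all objects in a field.
* Confidence is the sample Pearson correlation between the observed
  spectrum `y` and the reconstructed model `f_i x_i + f_j x_j + b`
  (background-inclusive on both sides); undefined (zero-variance) cases are
  reported as missing rather than clamped.

### Segmentation

Thresholding uses Otsu's between-class variance criterion on the per-pixel
sum over a configurable channel subset (default: all channels; real
acquisitions typically select a high-SNR subset spanning the data set,
which is image-specific and therefore configuration). Foreground components
are 8-connected; components under 4 pixels (configurable) are dropped. No
pixels inside a retained particle are excluded from the spectral average.
Touching cells are not split: the method assumes well-dispersed objects,
and one segmented feature is assumed to be one binary-labeled object.
Coordinates are 0-based `(row, col)`; boxes and ROIs are half-open.

## Synthetic data generator

The generator emulates the acquisition the pipeline consumes:

* **Fluorophores** have Gaussian excitation and emission curves in
  wavelength. Within each excitation block, emission channels sample the
  emission Gaussian at the channel centers scaled by the excitation
  Gaussian evaluated at the block's laser line — so blocks share the
  emission shape but differ in amplitude, which is exactly the information
  concatenation exploits. Channels at or below the laser wavelength are
  zeroed (no anti-Stokes emission). The default 16-dye palette uses common
  commercial dye names with catalog-plausible peak positions
  (405–702 nm excitation) and uniform 25 nm Gaussian widths; it is a
  synthetic stand-in, not measured spectra.
* **Layout** defaults to six lasers (405–633 nm) with 10 nm emission bands
  up to 750 nm (120 concatenated channels, at most 32 per laser). The
  per-excitation channel split is configuration, not a constant.
* **SNR** follows the shot-noise convention: target `snr` maps to a peak
  expected photon count of `snr²`, and every channel of every pixel is an
  independent Poisson draw. A constant `background_level` (default 2
  expected photons/channel) is added everywhere.
* **Cells** are ellipses (semi-axes 3.5 × 1.6 px, random orientation,
  uniform expected interior intensity) placed on a jittered grid that
  guarantees non-overlap; per-cell abundance ratios jitter log-normally
  (σ = 0.25) around 1:1. Shape does not enter the unmixing math; rods vs
  ellipses is cosmetic.

What the generator does *not* emulate: skewed real dye spectra, detector
read noise and gain, optical blur, photobleaching across sequential
excitations, and touching/overlapping cells. Passing tests therefore
demonstrate the correctness and noise behavior of the *algorithm*, not
instrument-level performance on real specimens.

## In-silico experiments

* **SNR benchmark.** Particles carry a 1:1 mixture of two heavily
  overlapping green dyes (AF488- and BODIPY-FL-like, emission peaks 7 nm
  apart) under a single 488 nm excitation with 16 × 10 nm channels, no
  background, and are unmixed against four candidate dyes. Each noisy
  spectrum is classified by (a) the binary-constrained search and (b)
  standard unconstrained unmixing followed by a top-two-abundance rule;
  both see identical noise realizations (common random numbers, a
  variance-reduction choice). The SNR grid is log-spaced, 3–300, 1000
  particles per level. The constrained algorithm dominates at every level,
  most strongly at low SNR, and both saturate at 100 % at the top of the
  grid.
* **Restricted-mixture error rate.** A mixture containing only the 15
  label types that share one fixed dye is unmixed while all 120 types are
  allowed; any assignment outside the generating set is an *impossible*
  label type, a direct error estimate. Default conditions: 1000 cells,
  SNR 20 (peak ≈ 400 expected photons per pixel before per-object
  averaging).
* **Linear-ramp mixture.** All 120 label types at proportions ramping
  linearly from 0.12 % to 1.5 %, 2400 cells; detected proportions are
  correlated against input proportions.

Problem sizes (particles per level, cell counts, image sizes) are chosen so
the full validation suite runs in seconds on one CPU while keeping
Monte-Carlo error well below the effect sizes being asserted.

## Known limitations

* Unweighted least squares is used throughout (as is standard); under
  Poisson noise a variance-weighted fit would be statistically more
  efficient, especially at low counts.
* Reference spectra are assumed exact; bleaching between sequential
  excitations and instrument drift are not corrected.
* The assignment is hard (single best pair); the per-pair residual vector
  is available (`keep_all_residuals`) for downstream soft analyses, but no
  posterior over pairs is computed.
* Segmentation merges touching objects, which violates the
  one-object-one-pair assumption; axial overlap is likewise out of scope.
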