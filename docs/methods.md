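# Methods

This note documents the models behind `camulm`, the parameters that
matter, what the synthetic data does and does not emulate, and the
numerical choices a maintainer would want stated.

## Synthetic scenes

**Vessel networks.** A tumor's feeding vasculature is modeled as a
branching tree rooted at the membrane (deepest) edge of the field.
Segments are polylines grown with per-step heading jitter; three presets
span the morphology regimes of interest: `chaotic` (tortuous, tumor-like;
heading jitter 0.25 rad/step), `columnar` (near-straight columns rising
from the membrane, jitter 0.02), and `pruned` (a chaotic tree whose
subtrees entering a fixed avascular disc are removed — the structural
signature of anti-angiogenic vascular disruption).  Radii and flow speeds
decay geometrically per generation (defaults: 60 µm root radius × 0.7,
4 mm/s root speed × 0.8), in the arteriole-to-capillary range of the CAM.
Growth is rejected as infeasible when the leaf count cannot fit the field
width at four root radii per leaf.

**Microbubbles.** Each bubble follows a random root-to-leaf path at the
local segment speed, offset from the centerline by a fixed perpendicular
fraction (≤ 0.9) of the local radius, and re-enters at the root on exit,
so the circulating count is constant — matching a CAM bolus, which stays
in circulation far longer than one acquisition.  Echo amplitudes are
log-normal across bubbles (σ_ln = 0.5) and constant along a track.

**IQ rendering.** The default geometry reproduces the emulated
acquisition: 2.93 mm × 8.82 mm field, λ/2 = 38.5 µm native pitch at
20 MHz, 1000 Hz effective frame rate, 1600 frames per acquisition
(analysis scripts scale the field and frame count down; all rates and
ratios are kept).  Each bubble renders as a separable complex Gaussian
PSF (σ_ax 40 µm, σ_lat 50 µm — diffraction-scale at 20 MHz) with a
constant random phase.  Tissue clutter is an *exactly* rank-`r`
spatiotemporal process: `r` orthonormalized smooth random spatial fields
paired with orthonormalized slow complex sinusoids (0.5–15 Hz) and
geometrically decaying weights (0.8^j), scaled 30 dB above the bubble
power.  Default rank 15: an SVD filter on in vivo CAM-tumor ensembles
typically removes the first 10–20 singular values, so the emulated tissue
occupies that range.  Noise is complex Gaussian with variance
∝ exp(depth/τ), τ = 1 mm, emulating depth-dependent gain.

What this does **not** emulate: nonlinear bubble oscillation, speckle
statistics of real tissue (the low-rank clutter model is an assumption —
real CAM clutter statistics are uncharacterized), beamforming artifacts,
out-of-plane motion, and 3-D geometry.  Tests passing on these scenes
show the *processing* is correct under its stated model, not that the
model captures every property of in vivo data.

## Clutter filtering

Casorati orientation is fixed: space along rows (C-order flattening),
time along columns.  The adaptive cutoff is the index of maximum discrete
curvature of log₁₀ of the singular values, clamped to a configurable
window (default [2, 40]); a flat spectrum falls back to the lower bound
with a warning.  The knee statistic is this package's concrete choice for
the "adaptive threshold" of the literature, which is cited without
formulas elsewhere; a fixed-cutoff override is exposed.  Index-based
low-order removal is deliberately *not* idempotent (a second pass removes
the next k components); the invariant that holds, and is tested, is
composition: two passes at cutoff k equal one pass at 2k.

Noise equalization estimates per-depth-row noise power from an identically
filtered noise reference, averages laterally (the dominant gradient is
axial), smooths with a 9-row moving average, and applies
gain = power^(−1/2).

## Localization

Upsampling uses a per-frame 2-D cubic interpolating spline (original
nodes preserved exactly).  Correlation operates on the envelope
(magnitude) of the upsampled IQ — the phase of interpolated IQ carries
speckle structure the Gaussian PSF model does not represent.  The
normalized cross-correlation map is cleaned of the fast-NCC instability
(near-constant windows produce |scores| ≫ 1; those pixels are
invalidated via a local-variance floor and scores clamped to [−1, 1]),
thresholded at 0.6 (midrange; validated on the synthetic detection/false
positive trade-off in the suite), and regional maxima (8-connected,
plateau centroids) become centroids with a minimum separation of half the
PSF FWHM.  PSF widths default to the scene values; `fit_psf_sigma`
provides an objective least-squares fit to the brightest blob when the
widths are unknown.

The conical Fourier separation assigns each 3-D spectral voxel the
apparent axial speed |f_t|/|k_z| (a bubble moving axially at v puts its
energy on the plane f_t = −v·k_z, where this ratio equals v at every
lateral frequency); the k_z = 0 plane goes to the slow cone.  The three
cones partition the spectrum, so the subsets sum to the input exactly.
The temporal window must be long enough that v·k_z exceeds a frequency
bin over the PSF's axial band, or slow-moving energy quantizes into the
f_t = 0 bin.

On 20 dB SNR single-bubble frames the centroid RMSE is ≤ 5 µm (one
super-pixel); most of it is grid quantization (≈ 2 µm RMSE).

## Tracking

Frame-to-frame linking is a global optimal assignment on squared
displacement with a hard gate; no gap closing, merging, or splitting —
a deliberately simple linker whose cost is verified against exhaustive
enumeration, and whose no-gaps property is exactly what the 10-frame
persistence rule (10 ms at 1 kHz) assumes.  The default gate is
1.5 × (root speed / frame rate) + 2 super-pixels: at 1 kHz a 4 mm/s
bubble moves only 4 µm per frame, below the localization jitter, so a
purely physiological gate fragments every track — the floor covers the
jitter.  Velocities difference positions after a 3-point moving average
(odd-reflection padding, so constant-velocity tracks keep exact end
speeds).  Maps accumulate *tracked* points (post-persistence), not raw
centroids, matching the pipeline order (tracking precedes map
quantification); the alternative raw-centroid count is one flag away.

## Vascular metrics

The ROI is a closed Hobby spline through ordered control points (the
curvature-minimizing interpolating spline of METAFONT), discretized to
≥ 200 boundary points; rasterization is even-odd pixel-center inclusion
on a canonically oriented polygon, so tracing direction cannot change the
mask.  Intervessel distance binarizes the density map at count ≥ 1 (any
localized bubble marks vasculature; threshold configurable), takes the
exact Euclidean distance transform, and reports the mean over avascular
ROI pixels as the headline (median alongside).  DM and SOAM run on
skeleton centerline paths (branch-point decomposition, ≥ 50 µm), which
are deterministic given the map, rather than on noisy individual tracks;
SOAM here is the 2-D in-plane restriction — the 3-D formulation's torsion
term does not exist in the plane.

**Box counting.** Dyadic box sizes on a grid anchored at the raster
origin; dimension = −slope of the least-squares line through
(log s, log N(s)), R² reported as a quality flag.  The default fit range
keeps the mesoscale: boxes tiling the raster between 4 and 32 per side
(min_side/32 ≤ s ≤ min_side/4).  Small boxes probe below the inner
cutoff of any thin structure — on a 20k-particle DLA cluster the local
slope rises from 1.07 at s = 2 to 1.71 at s = 32 while the mass–radius
dimension of the same cluster is already 1.715 — and the largest boxes
are too few to carry statistics.  Defining the range relative to the
raster also makes the estimate invariant under upsampling.  With this
default: filled plane 2.00, line 1.00, Sierpinski triangle 1.57
(log3/log2 ≈ 1.585), DLA ≈ 1.65–1.70.

**DLA.** Standard 2-D lattice aggregation: single seed, walkers launched
on a birth circle of radius r_max + 5, uniform 4-neighbor steps, sticking
on 4-adjacency, killed at 3× the birth radius.  The walker loop is
numba-compiled with an explicit xorshift64 RNG (seed passed through a
splitmix64 finalizer so adjacent integer seeds decorrelate), making
clusters bit-reproducible per seed.

## Histology

Stain math is done in true base-10 optical density (OD = −log₁₀(I/255),
intensities floored at one count) with the standard published
hematoxylin/DAB/residual vectors; concentrations solve OD = C·M exactly,
so the synthetic section generator (blob-wise DAB deposits over a uniform
hematoxylin background, optional darkening away from the membrane edge)
round-trips to within 8-bit quantization.  H-scores are **pixel**-based
(bins 0/1+/2+/3+ at OD 0.2/0.4/0.6, configurable), not nucleus-based:
no cell segmentation is performed, a deliberate, documented divergence
from pathologist practice in exchange for determinism and testability.
No thresholds are published for the emulated study; the defaults are
stated, not fitted.

## Statistics

Endpoint-only quantities: one-way ANOVA with Tukey HSD pairwise
correction (verified against an independent implementation to 1e-6).
Longitudinal quantities: ANCOVA `post ~ pre + C(arm)` with a type-II
group F-test and adjusted means at the grand-mean covariate; coefficients
match the normal equations to 1e-8.  When the covariate explains
everything (post an exact affine function of pre), the group F is 0/0
float noise and the implementation returns F = 0, p = 1.  Under the null
the ANOVA's empirical type-I error at α = 0.05 is calibrated to
[0.03, 0.07] (1000 replicates); ANCOVA power for a +2σ arm shift at
n = 8/arm exceeds 0.8 (500 replicates).  Stratification per cell line is
the intended use (run the tests per stratum); no correction is applied
across different metrics.  Tumors missing an endpoint are simply absent
from the longitudinal table — `ancova_longitudinal` refuses incomplete
pairs rather than imputing.

## Problem sizes

The analysis scripts and test suite run scaled-down scenes — 1.5 × 2.0 mm
fields, 400–800 frames, 10–20 bubbles, and 20,000–40,000-particle DLA
clusters — chosen so the full chain reproduces every qualitative regime
(10–20 cutoff range, sub-diffraction ridge separation, persistence
behavior) of the full-scale geometry it emulates.

## Known limitations

- The linker has no gap closing: a single missed detection splits a
  track; persistence filtering then discards short fragments, so density
  maps undercount in low-SNR regions.
- DM/SOAM depend on the skeleton, which can wobble at junctions of
  thick rasterized vessels.
- Pixel H-scores weight by area, not by cell, and will diverge from
  pathologist H-scores on sections with variable cellularity.
- The adaptive SVD cutoff assumes a visible knee; spectra without a
  clutter cliff (very low clutter, or clutter rank above the bound
  window) fall back to the configured minimum.
- 2-D only, by design: out-of-plane flow is invisible and velocities are
  in-plane projections.
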