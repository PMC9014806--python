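# camulm — super-resolution ULM analysis of tumor microvasculature

`camulm` implements a complete analysis chain for **ultrasound localization
microscopy (ULM)** studies of tumor microvasculature in the chicken-embryo
chorioallantoic-membrane (CAM) xenograft model: from contrast-enhanced
complex IQ frame stacks to super-resolved vascular maps to morphological
and functional treatment-response metrics and cohort statistics.  It is
aimed at ultrasound researchers who want a tested, reproducible, pure-Python
counterpart of the usual MATLAB ULM processing chain — and at anyone who
needs its individual pieces (SVD clutter filtering, sub-diffraction
localization, vessel tortuosity and fractal metrics, H-score
quantification) with oracle-verified behavior.

Because no in vivo acquisitions ship with the package, a first-class
synthetic-scene module generates ground-truth vessel networks, microbubble
trajectories, and realistic IQ ensembles (low-rank moving tissue clutter,
depth-dependent noise), so every stage is testable against known answers.

## The processing chain

1. **Clutter filtering** — the frame stack `s(z, x, t)` is reshaped into a
   Casorati matrix `S ∈ C^(n_z·n_x × n_t)` and decomposed as
   `S = U Σ Vᴴ`.  Slow, spatially coherent tissue concentrates in the
   leading singular components; the first `k` singular values are zeroed,
   with `k` chosen adaptively at the knee (maximum curvature) of
   `log σ_i`.  A noise reference acquisition yields a per-depth gain
   `g(z) = 1/√(E|n(z)|²)` that equalizes depth-dependent noise.
2. **Localization** — filtered IQ is spline-interpolated to a 5 µm grid,
   optionally split into three apparent-axial-speed populations by a
   conical Fourier filter (`|f_t|/|k_z|` against two thresholds, an exact
   partition of the spectrum), and bubble centroids are the regional
   maxima of the normalized cross-correlation of the envelope with a
   Gaussian PSF, thresholded at a correlation score of 0.6.
3. **Tracking** — frame-to-frame optimal assignment (Hungarian algorithm,
   squared displacement, hard distance gate), a 10-frame minimum
   persistence rule, 3-point smoothed velocities, and accumulation into
   count-density and mean-velocity rasters at 5 µm.
4. **Vascular metrics** — inside a Hobby-spline tumor ROI: RECIST-style
   long-axis diameter, contrast power, blood volume (centroid count),
   intervessel distance (Euclidean distance transform of avascular
   pixels), tortuosity `DM = L_path/L_chord` and
   `SOAM = Σ turning angles / L_path` on skeleton centerlines, and the
   box-counting fractal dimension `D = −d log N(s) / d log s`.
5. **Histology** — DAB extraction by optical-density stain unmixing
   (`OD = −log₁₀(I/255)`, Ruifrok H/DAB vectors) and pixel-based H-scores
   `H = 100·(p₁ + 2p₂ + 3p₃) ∈ [0, 300]`.
6. **Statistics** — endpoint contrasts by one-way ANOVA + Tukey HSD;
   longitudinal response by ANCOVA (`post ~ pre + arm`), α = 0.05.

The synthetic DLA generator provides the fractal limit case: 2-D lattice
diffusion-limited aggregation, whose dimension ≈ 1.7 is the reference
value for diffusion-limited vascular growth.

## Worked example

The numbered scripts under `analysis/` run the whole study at desk scale
(a 1.5 × 2.0 mm field, 800 frames, with every physical rate of the full
acquisition kept):

```bash
python analysis/01_simulate_scene.py     # scene + IQ synthesis
python analysis/02_clutter_filter.py     # SVD filter + noise equalization
python analysis/03_localize_and_track.py # 5 µm reconstruction
python analysis/04_vascular_metrics.py   # per-tumor metrics + resolution demo
python analysis/05_histology_quant.py    # synthetic sections + H-scores
python analysis/06_cohort_stats.py       # ANOVA/Tukey + ANCOVA
```

Selected output (what it means):

```
adaptive cutoff: 15 singular values zeroed (in vivo acquisitions typically need 10-20)
```
the knee detector lands inside the range tissue clutter occupies in vivo;

```
8223 centroids over 800 frames (10.3 per frame)
136 tracks survive the 10-frame persistence filter
density: 4246 accumulated track points; count-weighted mean velocity 3.25 mm/s
```
the reconstruction recovers flow speeds of the simulated 2.6–4 mm/s
vessel tree;

```
resolution benchmark (true separation 50 um, wavelength 77 um):
  ULM density ridges: 50 um apart, valley empty: True
  power-Doppler lateral peaks: 1 (unresolved blob)
```
two vessels 50 µm apart — well below the 77 µm wavelength at 20 MHz — are
two clean ridges in the ULM map but a single blob in the
diffraction-limited power image of the same scene: the super-resolution
claim in one picture;

```
ANCOVA arm effect on intervessel distance: F = 4.04, p = 2.22e-02
ANOVA on H-scores: F = 342.04, p = 2.39e-17
```
on the synthetic cohort, arms whose endpoint networks are pruned
(anti-angiogenic treatment) show a significant intervessel-distance
response, and the lighter hypoxia staining of those arms is recovered by
the H-score pipeline.

A `camulm` CLI exposes the same stages (`simulate`, `filter`, `localize`,
`track`, `metrics`, `histology`, `stats`, `all`) over the package's disk
formats (HDF5 IQ containers, CSV tables, 32-bit TIFF rasters).

## Layout

```
src/camulm/      library: scene, dla, iq, svdfilter, localize, tracking,
                 roi, metrics, histology, stats, pipeline, cli
analysis/        numbered study drivers (write results/)
tests/           pytest suite incl. end-to-end acceptance checks
scripts/         acceptance.py
docs/methods.md  models, parameter choices, limitations
```
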