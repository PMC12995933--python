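# Methods

This note documents the models, estimators and numerical choices behind
`pavactin`, what the synthetic-data generator does and does not emulate, and
the known limitations of the pipeline.

## 1. Synthetic cortical-filament movies

The movie simulator is built around one modelling commitment: **all temporal
signal change comes from filament turnover** (plus the camera model), so
that the frame-correlation decay read out downstream has a single known
cause.

- **Geometry.** Each filament is a 2D persistent random walk: unit pixel
  steps whose heading is perturbed per step by a von Mises deviate with
  concentration `persistence_px` (per-step angular s.d. ≈
  1/√persistence_px, so the heading decorrelates over roughly
  `persistence_px` pixels of arc length). Contour length is uniform in
  `length_range_px` (default 15–45 px). An optional global von Mises bias
  on initial headings (`orientation_kappa`, default 0 = isotropic) creates
  aligned fields for testing the anisotropy metric.
- **Turnover.** Each of `n_filaments` slots holds a chain of generations:
  lifetime ~ Exp(`turnover_rate_per_s`); on death a freshly sampled
  filament replaces it immediately. The expected filament count is thus
  stationary, and the exact exponential draws are kept in the ground truth
  (they are what the lifetime-recovery tests check against; draws censored
  by the movie end are retained uncensored).
- **Bundling.** A fraction `bundled_fraction` (default 0.3) of filaments
  carries the intensity multiplier `bundling_factor` (≥ 1). This makes the
  masked-intensity skewness and CV increase with the bundling factor by
  construction, which is the property the architecture metrics are meant to
  report.
- **Camera model.** Filaments are deposited as line integrals and blurred
  with a Gaussian PSF (`psf_sigma_px`, default 1.5 px); the deposit density
  is normalized so an isolated filament peaks at 0.25 on the canonical
  [0, 1] scale. The clean canvas is clipped to [0, 1] **before** the
  bleaching multiplier exp(−`bleach_rate_per_frame`·t) is applied; Gaussian
  noise (`noise_sd`) is added afterwards and the result clipped to [0, 1]
  again. Clipping the clean signal first makes the noise-free mean decay
  *exactly* geometric even where overlapping bundles would saturate — a
  property the tests rely on.
- **Noise level.** `noise_sd` defaults to 0.01, i.e. a peak-signal-to-noise
  ratio of 25 for a single filament. This is a mid-range value for
  spinning-disc confocal imaging of a bright live-cell filament marker at
  sub-second exposures; doubling it produces movies a microscopist would
  call poor.
- **Reproducibility.** One root `SeedSequence` is split per slot (and a
  separate child drives the noise), so identical parameters and seed give
  bit-identical movies, and adding slots does not reshuffle existing
  filaments.

What the generator does **not** emulate: 3D geometry and defocus, filament
elongation/severing/sliding (filaments are static between birth and death),
motor-driven buckling, shot-noise statistics (noise is additive Gaussian),
uneven illumination, and drift. Consequently, passing recovery tests show
that the estimators read out turnover, bundling and orientation correctly
under an idealized camera — not that they are robust to every artefact of
real acquisitions.

## 2. Synthetic lobed-cell mosaics

Cell boundaries follow r(θ) = R·(1 + a·sin(mθ + φ)) with random phase φ per
cell, lobe count m and relative amplitude a < 1 (self-intersection is
impossible below 1; the constructor enforces a ≤ 0.9). Radii are jittered
by ±8% by default so replicate mosaics have realistic size variance —
without it, per-plant mean shape metrics would be essentially degenerate
and group tests ill-posed. Cells are placed on a grid with pitch
2·R_max + 4 px, so rasterized labels can never overlap. The exact boundary
polygon (≥ 720 vertices) is stored per cell; these sinusoidal "flowers" are
a caricature of pavement-cell lobing (real cells have irregular,
non-harmonic lobes), sufficient to order shapes by lobing degree but not to
mimic real shape distributions.

## 3. Preprocessing

Order fixed: **background subtraction → contrast enhancement → bleach
correction** (changing the order would let per-frame operations absorb the
bleaching signal before it can be corrected).

- **Rolling ball.** The background is the grayscale opening of each frame
  with a ball structuring element (default radius 50 px). The ball's
  height is measured in grey levels of the original integer data; on the
  package's [0, 1] scale the spherical cap is therefore effectively flat at
  any practical radius, and the opening is computed with the flat disc
  footprint of the contact patch. This has three consequences the tests
  exploit: flat or smoothly ramping backgrounds are removed exactly,
  impulses and filaments narrower than the disc are preserved exactly, and
  the subtraction is exactly idempotent on background-free images. The
  opening itself is computed by decomposing the disc into horizontal chords
  (a 1D min/max filter per row offset), which is O(N·r) rather than
  O(N·r²). ImageJ's shrunken-paraboloid implementation is deliberately not
  replicated bit for bit.
- **Contrast.** One affine map from the *global* stack minimum/maximum to
  [0, 1]. Per-frame stretching would itself remove bleaching and confound
  the next step.
- **Bleach correction.** Monotone quantile (histogram) matching of every
  frame to the reference frame (default frame 0, which carries the least
  accumulated bleach). Matching preserves within-frame rank order and is
  exact under pure multiplicative decay.
- **ROI grid.** Pitch `spacing_um` (default 20 µm), integer pixel pitch,
  origin uniform on [0, pitch)² from the seed; square ROIs (side defaults
  to the pitch, i.e. tiling) centred per grid cell, border-crossing ROIs
  discarded. Only origin jitter is randomized — grid orientation is axis
  aligned. The protocol's manual curation of unusable regions is modelled
  objectively by `flag_low_signal_rois`: an ROI is dropped when its
  time-mean intensity is below 0.6× the global mean. Without curation,
  background-only ROIs contribute near-zero lag-1 Fisher z values whose
  normalized traces are numerically explosive.

## 4. Correlation-decay dynamics

For each ROI, Pearson r between the pixel vectors of every frame pair; the
lag-k trace value is the mean of the k-th superdiagonal (lag 0 is excluded
as trivially 1). The trace is transformed z = atanh(r̄) **after** averaging
r within a lag (transform-the-mean; the alternative mean-of-z is a
one-line change and gave indistinguishable results in development), and
normalized by z at the smallest lag, so z_norm(Δt₁) ≡ 1. Correlations are
clamped to |r| ≤ 1 − 1e−7 before atanh, with a logged count.

Group comparison: per-lag two-tailed Welch t tests on z_norm across ROIs,
BH step-up correction **across all lags of one comparison** (the family
could also span comparisons; one family per comparison is the choice
documented here), significance flags at 0.05 and 0.01, and group mean ±
95% CI mapped through tanh for plotting on the correlation scale. Because
ROIs within one recording share the same filament field, their traces are
correlated; the sampling design must therefore pool ROIs across several
recordings per group, or the per-lag test is pseudo-replicated and
anticonservative (measured: with one recording per group, 2/20 null
replicates produced dozens of false-positive lags; with ROIs drawn from
five recordings per group, 20/20 null replicates were clean). Plant- or
recording-level random effects beyond this pooling (full mixed models) are
out of scope; trace tables carry ROI identifiers so such models can be fit
externally.

## 5. Architecture metrics

- **Enhancement.** Multiscale Hessian-eigenvalue lineness (Sato tubeness,
  bright ridges), maximum over scales {1, 2, 4} px by default. The exact
  enhancement recipe is an open design point; Hessian ridges + Otsu +
  thinning is the documented stand-in, with every step's parameter exposed
  in `StructureConfig`.
- **Segmentation.** Global Otsu threshold computed in the **logarithm** of
  the positive ridge response (values below 10⁻³ of the maximum are
  excluded from the threshold computation, since the ridge filter's
  vanishing halo spans many decades). The log domain makes the
  background/filament class separation invariant to parts of the network
  brightening — with a linear-domain Otsu, a 3× bundle pulls the threshold
  above the faint-filament class, halving occupancy and *reversing* the
  skewness–bundling relation. Linear-domain Otsu is available via
  `log_space_threshold=False`. Components below `min_object_px` (20) are
  removed; skeletons come from morphological thinning, split into branches
  at junction pixels, with path length counting diagonal steps as √2.
- **Metrics.** Occupancy = masked-pixel fraction. Anisotropy = structure
  tensor coherence (λ₁−λ₂)/(λ₁+λ₂+ε), ε = 1e−12, evaluated at skeleton
  pixels after Gaussian pre-smoothing (σ = 1 px) with tensor window σ =
  `window_px` (8 px default); per-branch means are combined with
  branch-length weights. The normalized coherence, not the raw eigenvalue
  difference, is used so the score is bounded in [0, 1] by construction.
  Skewness is the Fisher–Pearson g₁ and CV the sample sd/mean of masked
  intensities; a constant distribution is defined as skewness 0 / CV 0
  (flagged), masks under 3 px yield NaN (flagged). Frame-wise values are
  averaged over time per ROI; frames with empty masks are excluded and
  counted in `n_frames_used`.
- The tensor `window_px` must be large relative to the inter-filament
  spacing for the isotropic limit to read near 0; with a window smaller
  than the spacing the coherence measures single-filament straightness
  instead.

## 6. Shape morphometrics

Area = pixel count × pixel area. Perimeter = 4-direction Crofton estimate,
a deliberate dialect choice matching common practice in interactive image
analysis. Crofton converges well on smooth boundaries (mean |circularity
error| vs the exact polygon oracle on synthetic lobed cells: 0.0078 →
0.0031 → 0.0011 as the pixel size halves from 1.0 to 0.25 µm) but carries
an irreducible bias on long axis-aligned straight edges (an upright
100-px square reads circularity ≈ 0.88 instead of π/4 ≈ 0.785); the
weighted-boundary alternative behaves oppositely (good on squares,
divergent on smooth lobes) and was rejected because cells are smooth.
Circularity is clamped to ≤ 1 (the raw value is kept in
`circularity_raw`; clamping affects < 1% of cells at default resolution,
essentially only near-perfect discs). Border-touching labels are flagged
and excluded from statistics; labels under 10 px are dropped with a log
entry. Segmentation of stained images into label masks is out of scope —
the module consumes masks from the generator or any external segmenter.

Group comparison aggregates cells to per-plant means first (the plant is
the experimental unit), then runs pairwise Welch t tests with BH
adjustment and summarizes with a compact letter display (insert-and-absorb
algorithm). A group with a single plant forces a logged fallback to
per-cell units for all tests, with the pseudo-replication caveat attached.
The full GLMM/beta-regression machinery appropriate for bounded responses
is intentionally not reimplemented; the tidy output carries plant IDs so it
can be fit externally.

## 7. Problem sizes used in tests and the acceptance script

Simulated movies use the default acquisition geometry (149 frames, 0.4 s)
at 128–192 px fields with 30–80 filaments, ROI grids of 6.4 µm pitch, and
4–5 recordings per trace group; architecture runs use 8-frame movies.
These sizes were chosen so the full verification suite completes in a few
minutes while every statistical check keeps comfortable margins; all of
them are package defaults or explicit arguments, and scale up unchanged.

## 8. Known limitations

- **Bleach correction under noise.** Histogram matching restores per-frame
  intensity *distributions* exactly under pure multiplicative decay (the
  noise-free check recovers frame-0 means to machine precision). It cannot
  restore lost information: with 1%-per-frame bleaching over 149 frames
  (77% signal loss) and camera noise, the corrected movie's late frames
  carry ~4× amplified noise, which depresses the lag-1 correlation and
  shifts the normalized decay curve. Measured on matched seeds, the max
  |Δz_norm| between a corrected-bleached and a bleach-free run is ≈ 0.10
  at the default noise (σ = 0.01), ≈ 0.05 at σ = 0.005, and 0 at σ = 0.
  Decay-curve comparisons across movies with very different bleaching
  should therefore be treated with caution regardless of correction.
- The per-lag Welch/BH comparison treats ROIs as exchangeable units after
  cross-recording pooling; it is not a substitute for hierarchical models
  when recordings are few and heterogeneous.
- Anisotropy depends on the tensor window relative to filament spacing
  (see §5); absolute values are comparable only at fixed settings.
- Crofton circularity values are estimator-specific; compare only within
  one estimator dialect.
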