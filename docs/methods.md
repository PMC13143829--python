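# Methods

`collmot` quantifies collective cell dynamics in three settings: epithelial
monolayers imaged by time-lapse microscopy, spheroids spreading ("wetting")
on an ECM-coated substrate, and multiplexed tissue-microarray (TMA) cohorts
with survival follow-up. A synthetic-data module generates seeded inputs
with known ground truth for every stage, so each estimator can be validated
end to end.

## Monolayer PIV

Velocity fields are estimated by single-pass windowed cross-correlation.
Each frame pair (separated by `frame_lag`, default 1 frame) is divided into
interrogation windows of `window_size_px` = 80 px — slightly larger than a
typical cell (~50 px) — laid out from the image origin with 50% overlap;
a partial window at the far edge is discarded. Windows are mean-subtracted
and correlated by FFT; the integer correlation peak is refined per axis by
3-point Gaussian interpolation (standard PIV practice), giving the
displacement Δr and the local velocity v_t(x) = Δr/Δt in px/frame,
converted exactly to µm/h by `pixel_size_um · 60 / frame_interval_min`
(defaults 0.65 µm/px and 10 min). A window with zero intensity variance
yields a flagged invalid vector, not an exception. The signal-to-noise
ratio is the primary peak over the highest peak outside the primary's 3×3
neighbourhood. Vectors failing a normalized-median test against their
8-neighbourhood (threshold 2.0, noise floor 0.1 px) are replaced by the
local median (policy `nmed`; `mask` and `none` are available). Per-pair
fields are averaged over chunks of 20 fields advancing by 10 (50% temporal
overlap); a chunk node is valid only where at least half its members are.
No cell-free-region masking is applied by default.

Coordinates are 0-based pixel indices, origin top-left, y increasing
downward; vectors are stored (vx, vy).

## Motility metrics

For each chunk-averaged field:

* total r.m.s. velocity `v_RMS^tot = sqrt(<|v_t(x)|²>_x)`;
* drift-corrected velocity `v^d.c._t(x) = v_t(x) − <v_t(x)>_x` and its
  r.m.s., isolating disordered motion from coherent drift. The Pythagorean
  identity `(v_RMS^tot)² = (v_RMS^d.c.)² + |<v>|²` holds to numerical
  precision and is enforced by tests;
* the radial velocity–velocity correlation
  `C_vv(δx) = <v^d.c.(x+δx)·v^d.c.(x)>_x / <|v^d.c.|²>_x`, accumulated
  over all node pairs into radial bins of width equal to the grid spacing
  (40 px by default). Each bin is labelled by the mean separation of the
  pairs it contains rather than the nominal bin centre: on a square grid
  the first bin also collects diagonal pairs (1.41·spacing), and the
  nominal label would bias every subsequent fit low by ~20%. The self-pair
  bin equals 1 exactly. A field that is uniform after drift correction has
  zero variance and raises a degenerate-field error;
* the correlation length ξ from a nonlinear least-squares fit of
  `C_vv(δx) = exp(−δx/ξ)` over bins from the first off-origin bin to the
  first bin with C_vv ≤ 0.05 (fits use C_vv directly, not its log, so
  near-zero bins are kept). ξ is fitted per chunk; an optional flag fits
  one curve averaged over chunks instead. Fit failure is flagged, never
  raised; a fitted ξ at or beyond the grid extent (the flocking limit,
  where the curve stays near 1) is reported with a `pegged` flag;
* the alignment index a_t(x): cosine between the field's mean vector and
  each local vector, in [−1, 1]; nodes with zero-magnitude vectors, or the
  whole map when the mean vector vanishes, are masked.

### Correcting the interrogation-window response in the ξ fit

A PIV vector is effectively an average of the underlying velocity over its
80 px window. For ξ below or near the window size this smoothing dominates
the measured correlation: fitted with the plain exponential, a field with
ξ = 20 px appears to have ξ ≈ 50 px. When the window size is known (the
pipeline always knows it), `fit_correlation_length(..., window_um=...)`
therefore fits the *window-smoothed* exponential: exp(−r/ξ) convolved with
the window's spatial autocorrelation (a separable triangle of half-width
equal to the window side), normalized to 1 at r = 0, evaluated by FFT on a
fine auxiliary grid. A second, smaller correction accounts for
mean-subtraction on a finite grid: the drift-corrected empirical
correlation is depressed by the pair-count-weighted mean model correlation
over the whole grid (`c̄`), so the fitted model is `(C_w(r) − c̄)/(1 − c̄)`.
With both corrections the full pipeline recovers ξ_true ∈ {20, 40, 80} px
to within ~25% (median over 5 realizations) on the default synthetic
movies; the plain exponential remains the default for user-supplied curves.

## Spheroid wetting

From a series of binary footprint masks with time stamps, the module
reports pixel-count areas (µm²), areas normalized to t = 0 (exactly 1 at
t = 0 by construction), the equivalent-circle radius r(t) = sqrt(A/π), and
the average wetting speed in µm/h. "Average wetting speed" is defined
operationally as the least-squares slope of r(t) versus time: it is
area-based (matching the measured quantity) and robust to irregular
fronts; an endpoint (r_T − r_0)/T alternative sits behind
`method="endpoint"`. The sign is preserved, so a retracting spheroid gives
a negative speed. Doubling the pixel size doubles the speed exactly.
Segmentation of raw movies is out of scope: the module consumes masks.

## TMA scoring and survival

The cell table is long-format: one row per cell per marker with
`patient_id, core_id, compartment (epithelial|stromal), cell_id, marker,
nuclear_mean, extranuclear_mean`. The pipeline:

1. excludes patients with fewer than 100 quantified cells in the stromal
   *or* epithelial compartment (boundary inclusive: exactly 100 is kept);
2. aggregates to patient level, pooling all cores of a patient: the
   *median* stromal extranuclear intensity for each of fibronectin,
   collagen I, SMA, laminin and vinculin, and the *mean* nuclear YAP over
   tumour-epithelial cells (extranuclear β-catenin in the epithelium is
   carried optionally, with no survival claim attached);
3. scores each patient one point per ECM marker *strictly above* the
   across-patient median of patient-level values (a value exactly at the
   median scores 0 — with continuous intensities ties have measure zero);
   scores 0–2 are "ECM-low", 3–5 "ECM-high". The dataset medians are
   computed after the exclusion filter, matching the processing order of
   the assay. YAP-high/low is the analogous single-marker median split;
4. compares groups with the Kaplan–Meier product-limit estimator
   (right-censoring, ties processed events-before-censorings, S(0) = 1)
   and the two-group log-rank test (observed-minus-expected with the
   hypergeometric tie-corrected variance, 1 df, no continuity
   correction). Both are implemented here and cross-checked against
   lifelines in the test suite.

## Synthetic data

The generators emulate the *structure* of the real inputs, not their
biology; flows are imposed, not emergent, and no nuclei or membranes are
rendered.

**Speckle movies.** The texture superposes two band-limited noise fields:
cell-scale blobs (Gaussian-filtered white noise, σ = feature_size/4 with
feature_size = 50 px) and a fine σ = 1 px component emulating the
intracellular detail of phase-contrast images. The fine component is what
makes window cross-correlation well-posed — with 50 px blobs alone the
correlation peak of an 80 px window is too broad to localize. Spatially
uniform (possibly decaying) drift advects the base texture by exact
Fourier shifting, so subpixel ground truth is exact; spatially varying
flows advect frame-to-frame by backward warping with cubic-spline
interpolation on a periodic domain (cubic rather than bilinear to limit
numerical diffusion over 20-frame chunks). Flow kinds: `uniform`,
`decaying-uniform`, `correlated` (see below), `vortex` (solid-body
rotation); any kind accepts a temporal half-life applied as
2^(−t/half_life), so a decaying correlated flow emulates a monolayer
relaxing toward dynamic arrest with measurable ξ throughout. True
per-frame Eulerian fields are stored alongside the frames. Defaults:
800×800 px, 21 frames (one 20-pair chunk), 0.65 µm/px, 10 min/frame —
sized so that the largest benchmark correlation length (80 px) still fits
~10 times into the field of view; at half that size the single-realization
correlation estimate becomes unusable. Bit depth and magnification of the
emulated microscope are free parameters.

**Correlated fields.** Zero-mean two-component Gaussian random fields with
isotropic exponential-like correlation are synthesized spectrally: white
noise filtered with the square root of S(k) ∝ (k² + ξ⁻²)^(−3/2) (the 2D
spectrum of exp(−r/ξ)), mean-subtracted and rescaled so the r.m.s. speed
is exact. Exactness of the exponential is not required — recovery
tolerances are percentage-based — and an independent full-resolution
autocorrelation oracle in the test suite confirms ξ within 15%.

**Spheroid masks.** Rasterized disks of radius r0 + v·t on a pixel grid
sized to the final radius.

**TMA cohorts.** Patients forced below the cell-count threshold are chosen
first; among the remaining patients each ECM marker is split exactly
half/half between a "low" intensity cluster (patient level ~U(0.5, 0.9))
and a "high" cluster (~U(1.1, 1.5)), so the post-exclusion dataset median
falls in the gap and the constructed score is recovered exactly — the
recovery test is therefore sharp, not statistical. Per-cell intensities
multiply the patient level by lognormal noise (σ = 0.08); nuclear YAP
rises with the true ECM score to mirror the observed ECM–YAP correlation.
Survival times are exponential with the ECM-high hazard multiplied by the
spec's hazard ratio (default 3), with independent exponential censoring
calibrated to the requested censoring fraction (default 0.3); the default
cohort is 198 patients with 5 forced below threshold. What the generator
does *not* emulate: staining batch effects, spatial intensity gradients,
core drop-out, correlated marker noise within cells, and non-proportional
hazards — passing tests show estimator correctness under the constructed
model, not robustness to those artifacts.

## Numerical choices and degenerate inputs

* Gaussian subpixel interpolation falls back to parabolic when a
  neighbouring correlation value is non-positive; displacement magnitudes
  are bounded by half the window by the circular-correlation convention.
* ξ fits require ≥3 usable bins with some positive C_vv; otherwise the
  fit is flagged failed. Fit initialisation is the middle fit-range bin.
* The exclusion filter's cell counts use distinct (core, cell) pairs when
  a `cell_id` column is present, falling back to row counts divided by the
  number of markers.
* All generators draw from `numpy.random.default_rng(seed)` per call; no
  global random state. The pipeline derives per-stage seeds from one
  global seed via a SeedSequence keyed on a CRC32 of the stage name.

## Benchmark problem sizes

The reproduction script (`scripts/acceptance.py`) uses: uniform-drift
accuracy on four 400×400 px, 4-frame movies (drifts 0.5–4 px/frame);
ξ recovery on five 800×800 px, 21-frame movies per ξ ∈ {20, 40, 80} px;
wetting on a 48 h disk series at 2 µm/px; a 198-patient cohort for the
exclusion filter; 500 null and 100 alternative survival simulations at
n = 200 for log-rank calibration and power. These sizes were chosen so
each estimate is statistically meaningful while the whole script completes
in minutes on one CPU.

## Known limitations

* Single-pass PIV only: no multi-pass window deformation, no optical
  flow; displacements approaching half the window size will wrap.
* The window-response correction assumes the ideal box-average response;
  real interrogation windows weight texture by local gradient content.
* ξ estimates from a single field realization carry large sampling
  variance whenever the field of view is < ~10ξ; medians over several
  movies (or time chunks with temporally evolving flows) are reported in
  the benchmarks for that reason.
* The survival module implements two-group comparisons only — no Cox
  modelling, no multiplicity correction across marker panels.
* Classification into "jammed" vs "flocking solid" states is left to the
  reported metrics (v_RMS, ξ, alignment); no automated labelling.
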