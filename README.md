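# collmot

Collective cell motility analysis for epithelial monolayers, spreading
spheroids, and multiplexed tissue-microarray (TMA) cohorts.

Squamous epithelia can sit on either side of a jamming transition: a dense,
kinetically arrested state with short velocity correlations, or an
unjammed/flocking state in which cells move coherently over long distances
— a mode associated with collective cancer invasion. `collmot` provides the
standard quantitative toolkit for telling these states apart from
time-lapse microscopy, together with the downstream tissue-level readouts
(spheroid wetting, stromal ECM scoring, survival stratification) used to
connect monolayer mechanics to patient outcome. It is a library first
(importable API plus `examples/`), with a thin `collmot` CLI over the
end-to-end pipeline.

## What it computes

**Monolayer PIV** (`collmot.piv`). Velocity fields v_t(x) = Δr/Δt by
windowed cross-correlation of frame pairs (80×80 px interrogation windows,
50% overlap, subpixel Gaussian peak fit, normalized-median vector
validation), temporally averaged over 20-frame chunks with 50% overlap.

**Motility metrics** (`collmot.metrics`). Per chunk:

- total r.m.s. velocity v_RMS^tot(t) = √⟨|v_t(x)|²⟩ₓ,
- drift-corrected velocity v_t^d.c.(x) = v_t(x) − ⟨v_t(x)⟩ₓ and its r.m.s.,
- the radial velocity–velocity correlation
  C_vv(δx, t) = ⟨v^d.c.(x+δx)·v^d.c.(x)⟩ₓ / ⟨|v^d.c.|²⟩ₓ, fitted with
  exp(−δx/ξ) to extract the correlation length ξ — the size of a cluster
  of cells moving together (optionally deconvolving the known
  interrogation-window response; see `docs/methods.md`),
- the alignment index a_t(x): cosine between each vector and the field
  mean (≈1 everywhere indicates flocking),
- the (v_RMS^d.c., ξ) phase trajectory used in jamming-phase plots.

**Spheroid wetting** (`collmot.wetting`). From binary footprint masks:
area normalized to t = 0, equivalent-circle radius r(t) = √(A/π), and the
average wetting speed (µm/h) as the least-squares slope of r(t).

**TMA scoring and survival** (`collmot.tma`). Per-cell marker intensities →
patient-level summaries (patients with <100 cells in the stromal or
epithelial compartment are excluded; cores pooled), an ECM score counting
how many of {fibronectin, collagen I, SMA, laminin, vinculin} exceed the
cohort median (0–2 = ECM-low, 3–5 = ECM-high), a median-split nuclear-YAP
class, and Kaplan–Meier / log-rank group comparison (both implemented
in-package).

**Synthetic data** (`collmot.synthetic`). Seeded generators with exact
ground truth for every stage: speckle movies advected by flows of known
drift, r.m.s. speed, correlation length ξ_true and temporal decay;
expanding-disk mask series of known front speed; TMA cohorts with known
per-patient ECM scores and a prescribed hazard ratio between ECM groups.

## Worked example

```bash
python examples/01_monolayer_motility.py
```

```
flocking (uniform drift 2 px/frame)
  v_RMS^tot   =   7.58 um/h   (total r.m.s. velocity)
  v_RMS^d.c.  =   0.08 um/h   (after drift removal)
  |drift|     =   7.58 um/h
  xi          : residual fluctuations are at PIV noise level; the motion is fully coherent drift
  <alignment> =   1.00        (cosine to the mean direction; ~1 means flocking)

correlated motion (xi_true = 40 px)
  v_RMS^tot   =   2.80 um/h   (total r.m.s. velocity)
  v_RMS^d.c.  =   2.80 um/h   (after drift removal)
  xi          =   29.0 um     (45 px; cluster size of coherently moving cells)
  <alignment> =  -0.01        (cosine to the mean direction; ~1 means flocking)
```

The first movie moves as one coherent block: all of v_RMS^tot is drift,
the alignment index is 1 and nothing but measurement noise survives drift
correction — the flocking signature. The second has no net drift but
spatially correlated swirls; the pipeline recovers a correlation length of
45 px against a constructed truth of 40 px.

`examples/02_spheroid_wetting.py` recovers a constructed 10 µm/h spheroid
front speed as `10.00 ± 0.00 µm/h` from rasterized masks, and
`examples/03_tma_survival.py` scores a 198-patient synthetic cohort
(5 patients excluded by the <100-cell rule, 193 analysed), splits it into
ECM-high/low, and finds the built-in survival difference
(log-rank χ² = 34.9, p = 3.5×10⁻⁹; median survival 27 vs 81 months).

The same stages run from the shell:

```bash
collmot all --config examples/demo_config.yaml --out out/
```

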