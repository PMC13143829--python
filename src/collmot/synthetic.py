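"""Seeded synthetic inputs with known ground truth.

Every generator here emulates one class of input consumed downstream:

* speckle-textured time-lapse "movies" advected by flow fields of known
  drift, spatial correlation length and temporal decay (for the PIV and
  motility-metrics stages);
* expanding-disk binary mask series of known radial speed (for the
  spheroid-wetting stage);
* multiplexed tissue-microarray cell tables and survival records in which
  each patient's ECM score and hazard group are known by construction (for
  the scoring/survival stage).

All randomness flows from the explicit seed carried by each spec; no global
random state is touched, and identical specs reproduce outputs bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import disk as draw_disk

ECM_MARKERS = ("fibronectin", "collagen_I", "SMA", "laminin", "vinculin")
YAP_MARKER = "YAP"

FLOW_KINDS = ("uniform", "correlated", "decaying-uniform", "vortex")


# --------------------------------------------------------------------------
# flow fields and speckle movies
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class FlowSpec:
    """Prescribed flow advecting a synthetic monolayer movie.

    ``drift`` is the spatially uniform component in px/frame (vx, vy);
    ``vrms`` the target root-mean-square speed of the zero-mean fluctuating
    component; ``xi_true_px`` its spatial correlation length (required for
    ``kind='correlated'``); ``decay_half_life`` an optional temporal
    half-life in frames applied multiplicatively to the whole field,
    emulating a monolayer relaxing towards dynamic arrest.
    """

    kind: str = "uniform"
    drift: tuple[float, float] = (0.0, 0.0)
    vrms: float = 0.0
    xi_true_px: float | None = None
    decay_half_life: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in FLOW_KINDS:
            raise ValueError(f"unknown flow kind {self.kind!r}; expected one of {FLOW_KINDS}")
        if self.vrms < 0:
            raise ValueError("vrms must be >= 0")
        if self.kind == "correlated":
            if self.xi_true_px is None or self.xi_true_px <= 0:
                raise ValueError("kind='correlated' requires xi_true_px > 0")
        if self.decay_half_life is not None and self.decay_half_life <= 0:
            raise ValueError("decay_half_life must be positive")

    def decay_factor(self, t: int) -> float:
        """Amplitude factor 2**(-t / half_life) for frame-pair index t."""
        if self.decay_half_life is None:
            return 1.0
        return float(2.0 ** (-t / self.decay_half_life))


@dataclass
class SyntheticMovie:
    """A synthetic grayscale movie plus its per-frame true velocity fields.

    ``true_fields[t]`` is the (2, H, W) Eulerian velocity (vx, vy) in
    px/frame that maps frame t onto frame t+1.
    """

    frames: np.ndarray  # (T, H, W) float32
    pixel_size_um: float
    frame_interval_min: float
    flow_spec: FlowSpec
    true_fields: np.ndarray  # (T-1, 2, H, W) float32

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def true_field_at(self, t: int, y_px: np.ndarray, x_px: np.ndarray) -> np.ndarray:
        """Sample the true field of frame-pair t at (row, col) positions.

        Returns an array of shape (2,) + y_px.shape with (vx, vy).
        """
        yy = np.round(np.asarray(y_px)).astype(int)
        xx = np.round(np.asarray(x_px)).astype(int)
        return self.true_fields[t][:, yy, xx]


def make_correlated_field(
    shape: tuple[int, int],
    xi_true: float,
    vrms: float,
    seed: int,
) -> np.ndarray:
    """Zero-mean 2-component Gaussian random field with exponential-like
    isotropic autocorrelation of decay length ``xi_true`` (px).

    The field is synthesized spectrally: in 2D the power spectrum of an
    exponential correlation exp(-r/xi) is proportional to
    (k^2 + xi^-2)^(-3/2), so filtering white noise with the square root of
    that spectrum yields the requested correlation up to periodic-domain
    truncation.  Each component is mean-subtracted and the pair rescaled so
    the total r.m.s. speed equals ``vrms`` exactly.

    Returns an array of shape (2, H, W) holding (vx, vy).
    """
    if xi_true <= 0:
        raise ValueError("xi_true must be > 0")
    h, w = shape
    rng = np.random.default_rng(seed)
    ky = np.fft.fftfreq(h)[:, None] * 2 * np.pi
    kx = np.fft.fftfreq(w)[None, :] * 2 * np.pi
    k2 = kx**2 + ky**2
    amp = (k2 + (1.0 / xi_true) ** 2) ** (-0.75)
    comps = []
    for _ in range(2):
        white = rng.standard_normal((h, w))
        f = np.real(np.fft.ifft2(np.fft.fft2(white) * amp))
        comps.append(f - f.mean())
    v = np.stack(comps)
    if vrms > 0:
        cur = np.sqrt(np.mean(v[0] ** 2 + v[1] ** 2))
        v *= vrms / cur
    else:
        v[:] = 0.0
    return v


def _speckle_texture(shape: tuple[int, int], feature_size_px: float, rng: np.random.Generator) -> np.ndarray:
    """Band-limited speckle emulating a phase-contrast monolayer: cell-scale
    blobs (~``feature_size_px``) superposed with fine intracellular texture
    that carries the cross-correlation signal, normalized to mean 0.5 /
    s.d. 0.15.  Without the fine component the correlation peak of an 80 px
    window would be too broad to localize."""
    coarse = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=feature_size_px / 4.0, mode="wrap")
    fine = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=1.0, mode="wrap")
    tex = coarse / coarse.std() + fine / fine.std()
    tex = (tex - tex.mean()) / tex.std()
    return (0.5 + 0.15 * tex).astype(np.float64)


def _base_flow(flow: FlowSpec, shape: tuple[int, int]) -> np.ndarray:
    """Time-independent (2, H, W) flow before drift and temporal decay."""
    h, w = shape
    if flow.kind in ("uniform", "decaying-uniform"):
        return np.zeros((2, h, w))
    if flow.kind == "correlated":
        return make_correlated_field(shape, flow.xi_true_px, flow.vrms, flow.seed)
    # vortex: solid-body rotation about the image centre, scaled to vrms
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    vx, vy = -(yy - cy), (xx - cx)
    v = np.stack([vx, vy])
    cur = np.sqrt(np.mean(v[0] ** 2 + v[1] ** 2))
    if cur > 0 and flow.vrms > 0:
        v *= flow.vrms / cur
    else:
        v[:] = 0.0
    return v


def make_speckle_movie(
    flow: FlowSpec,
    shape: tuple[int, int] = (400, 400),
    n_frames: int = 21,
    pixel_size_um: float = 0.65,
    frame_interval_min: float = 10.0,
    feature_size_px: float = 50.0,
) -> SyntheticMovie:
    """Generate a speckle movie advected by ``flow`` with stored ground truth.

    Uniform (possibly decaying) drift is applied by exact Fourier shifting of
    the base texture, so subpixel displacements are exact.  Spatially varying
    flows advect frame-to-frame by backward warping with cubic-spline
    interpolation on a periodic domain.
    """
    if min(shape) < 160:
        raise ValueError(
            f"shape {shape} too small: at least 160 px per side is needed to fit "
            "one 80 px interrogation window with 50% overlap"
        )
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    rng = np.random.default_rng(flow.seed)
    base = _speckle_texture(shape, feature_size_px, rng)
    fluct = _base_flow(flow, shape)
    drift = np.asarray(flow.drift, dtype=float)

    h, w = shape
    n_pairs = n_frames - 1
    frames = np.empty((n_frames,) + shape, dtype=np.float32)
    true_fields = np.empty((n_pairs, 2, h, w), dtype=np.float32)

    spatially_uniform = not np.any(fluct)
    frames[0] = base
    if spatially_uniform:
        cum = np.zeros(2)
        for t in range(n_pairs):
            v = drift * flow.decay_factor(t)
            true_fields[t, 0] = v[0]
            true_fields[t, 1] = v[1]
            cum = cum + v
            shifted = np.fft.ifftn(
                ndimage.fourier_shift(np.fft.fftn(base), shift=(cum[1], cum[0]))
            ).real
            frames[t + 1] = shifted
    else:
        yy, xx = np.mgrid[0:h, 0:w].astype(float)
        cur = base
        for t in range(n_pairs):
            g = flow.decay_factor(t)
            vx = fluct[0] * g + drift[0] * g
            vy = fluct[1] * g + drift[1] * g
            true_fields[t, 0] = vx
            true_fields[t, 1] = vy
            cur = ndimage.map_coordinates(
                cur, [yy - vy, xx - vx], order=3, mode="grid-wrap"
            )
            frames[t + 1] = cur
    return SyntheticMovie(
        frames=frames,
        pixel_size_um=pixel_size_um,
        frame_interval_min=frame_interval_min,
        flow_spec=flow,
        true_fields=true_fields,
    )


# --------------------------------------------------------------------------
# spheroid mask series
# --------------------------------------------------------------------------


@dataclass
class SpheroidMaskSeries:
    """Time-stamped binary masks of a spreading spheroid footprint."""

    masks: np.ndarray  # (T, H, W) bool
    times_h: np.ndarray  # (T,) strictly increasing
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        if self.masks.shape[0] != self.times_h.shape[0]:
            raise ValueError("masks and times must have the same length")
        if self.masks.shape[0] < 2:
            raise ValueError("need at least two time points")
        if np.any(np.diff(self.times_h) <= 0):
            raise ValueError("times must be strictly increasing")


def make_spheroid_series(
    r0_um: float,
    radial_speed_um_per_h: float,
    times_h: Sequence[float],
    pixel_size_um: float = 2.0,
) -> SpheroidMaskSeries:
    """Rasterized disk masks with radius r0 + speed * t."""
    if r0_um <= 0:
        raise ValueError("r0_um must be > 0")
    times = np.asarray(times_h, dtype=float)
    radii_um = r0_um + radial_speed_um_per_h * times
    if np.any(radii_um < 0):
        raise ValueError("radius becomes negative within the requested time range")
    rmax_px = int(np.ceil(radii_um.max() / pixel_size_um)) + 4
    side = 2 * rmax_px + 1
    centre = (rmax_px, rmax_px)
    masks = np.zeros((len(times), side, side), dtype=bool)
    for i, r_um in enumerate(radii_um):
        rr, cc = draw_disk(centre, r_um / pixel_size_um, shape=(side, side))
        masks[i, rr, cc] = True
    return SpheroidMaskSeries(masks=masks, times_h=times, pixel_size_um=pixel_size_um)


# --------------------------------------------------------------------------
# TMA cohort
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticCohortSpec:
    """Parameters of a synthetic multiplexed-TMA cohort.

    Marker intensities are drawn so that each patient's per-marker
    patient-level value falls either in a "low" cluster (below the cohort
    median) or a "high" cluster (above it), making the true ECM score exact
    by construction.  Survival times are exponential, with the hazard of
    ECM-high patients multiplied by ``hazard_ratio``; censoring is an
    independent exponential achieving roughly ``censoring_rate``.
    """

    n_patients: int = 198
    fraction_below_threshold: float = 5 / 198
    hazard_ratio: float = 3.0
    censoring_rate: float = 0.3
    median_survival_low_months: float = 80.0
    cells_per_compartment: tuple[int, int] = (150, 400)  # inclusive range
    low_cell_range: tuple[int, int] = (20, 99)
    n_cores: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if self.hazard_ratio <= 0:
            raise ValueError("hazard_ratio must be > 0")
        for frac in (self.fraction_below_threshold, self.censoring_rate):
            if not 0 <= frac <= 1:
                raise ValueError("fractions must lie in [0, 1]")


@dataclass
class SyntheticCohort:
    """Cell table, survival table and per-patient ground truth."""

    cells: pd.DataFrame
    survival: pd.DataFrame
    truth: pd.DataFrame  # patient_id, true marker highs, true_ecm_score, true groups


def make_survival_table(
    n: int,
    hazard_ratio: float,
    seed: int,
    frac_high: float = 0.5,
    censoring_rate: float = 0.3,
    median_low_months: float = 80.0,
    group_labels: tuple[str, str] = ("low", "high"),
) -> pd.DataFrame:
    """Two-group exponential survival data with independent censoring.

    Group 'high' has its hazard multiplied by ``hazard_ratio``.  Returns
    columns (patient_id, group, time_months, event).
    """
    rng = np.random.default_rng(seed)
    n_high = int(round(frac_high * n))
    groups = np.array([group_labels[1]] * n_high + [group_labels[0]] * (n - n_high))
    rng.shuffle(groups)
    lam_low = np.log(2) / median_low_months
    lam = np.where(groups == group_labels[1], lam_low * hazard_ratio, lam_low)
    t_event = rng.exponential(1.0 / lam)
    if censoring_rate > 0:
        lam_c = lam * censoring_rate / (1 - censoring_rate)
        t_cens = rng.exponential(1.0 / lam_c)
    else:
        t_cens = np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return pd.DataFrame(
        {
            "patient_id": [f"P{i:04d}" for i in range(n)],
            "group": groups,
            "time_months": time,
            "event": event,
        }
    )


def _assign_marker_highs(n: int, n_markers: int, rng: np.random.Generator) -> np.ndarray:
    """Boolean (n, n_markers): per marker, exactly floor(n/2) patients high.

    With floor(n/2) high and ceil(n/2) low, the across-patient median of the
    patient-level values always lies at or below the top of the low cluster,
    so 'strictly above the median' identifies exactly the high patients.
    """
    highs = np.zeros((n, n_markers), dtype=bool)
    n_high = n // 2
    for j in range(n_markers):
        order = rng.permutation(n)
        highs[order[:n_high], j] = True
    return highs


def make_tma_cohort(spec: SyntheticCohortSpec) -> SyntheticCohort:
    """Generate (cell table, survival table, truth) for a synthetic cohort.

    The cell table is long-format with columns (patient_id, core_id,
    compartment, cell_id, marker, nuclear_mean, extranuclear_mean).  Stromal
    extranuclear intensities of the five ECM markers and epithelial nuclear
    YAP encode the constructed patient levels; all other channel/compartment
    combinations are uninformative noise near 1.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    patient_ids = np.array([f"P{i:04d}" for i in range(n)])
    markers = list(ECM_MARKERS) + [YAP_MARKER]
    n_ecm = len(ECM_MARKERS)

    # patients forced below the cell-count threshold are chosen first: the
    # marker high/low split is balanced over the *retained* patients so the
    # post-exclusion dataset median falls in the gap between clusters and
    # the constructed ECM score is recovered exactly downstream
    k_low = int(round(spec.fraction_below_threshold * n))
    low_ids = rng.choice(n, size=k_low, replace=False)
    retained = np.setdiff1d(np.arange(n), low_ids)
    highs = np.zeros((n, n_ecm), dtype=bool)
    highs[retained] = _assign_marker_highs(len(retained), n_ecm, rng)
    highs[low_ids] = rng.integers(0, 2, (k_low, n_ecm)).astype(bool)
    true_score = highs.sum(axis=1)
    true_ecm_group = np.where(true_score >= 3, "high", "low")

    # patient-level marker values: low cluster U(0.5, 0.9), high U(1.1, 1.5)
    levels = np.where(
        highs,
        rng.uniform(1.1, 1.5, size=highs.shape),
        rng.uniform(0.5, 0.9, size=highs.shape),
    )
    # nuclear YAP level rises with the true ECM score (mirrors the observed
    # ECM-YAP correlation) but is dichotomized downstream at its own median
    yap_level = 0.8 + 0.08 * true_score + rng.normal(0, 0.03, n)

    # cell counts; the chosen patients are forced below the 100-cell rule
    counts = {
        comp: rng.integers(spec.cells_per_compartment[0], spec.cells_per_compartment[1] + 1, n)
        for comp in ("stromal", "epithelial")
    }
    forced = rng.integers(spec.low_cell_range[0], spec.low_cell_range[1] + 1, k_low)
    which_comp = rng.integers(0, 2, k_low)  # which compartment is under-sampled
    for idx, cnt, w in zip(low_ids, forced, which_comp):
        counts["stromal" if w == 0 else "epithelial"][idx] = cnt

    frames = []
    for i, pid in enumerate(patient_ids):
        for comp in ("stromal", "epithelial"):
            n_cells = int(counts[comp][i])
            core = rng.integers(0, spec.n_cores, n_cells)
            cell_id = np.arange(n_cells)
            for j, marker in enumerate(markers):
                nuc = rng.normal(1.0, 0.1, n_cells)
                extra = rng.normal(1.0, 0.1, n_cells)
                if comp == "stromal" and j < n_ecm:
                    extra = levels[i, j] * rng.lognormal(0.0, 0.08, n_cells)
                if comp == "epithelial" and marker == YAP_MARKER:
                    nuc = yap_level[i] * rng.lognormal(0.0, 0.08, n_cells)
                frames.append(
                    pd.DataFrame(
                        {
                            "patient_id": pid,
                            "core_id": np.char.add(f"{pid}_core", core.astype(str)),
                            "compartment": comp,
                            "cell_id": cell_id,
                            "marker": marker,
                            "nuclear_mean": np.abs(nuc),
                            "extranuclear_mean": np.abs(extra),
                        }
                    )
                )
    cells = pd.concat(frames, ignore_index=True)

    lam_low = np.log(2) / spec.median_survival_low_months
    lam = np.where(true_ecm_group == "high", lam_low * spec.hazard_ratio, lam_low)
    t_event = rng.exponential(1.0 / lam)
    if spec.censoring_rate > 0:
        lam_c = lam * spec.censoring_rate / (1 - spec.censoring_rate)
        t_cens = rng.exponential(1.0 / lam_c)
    else:
        t_cens = np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    t_status = np.clip(1 + true_score // 2 + rng.integers(0, 2, n), 1, 4)
    survival = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "time_months": time,
            "event": event,
            "t_status": np.char.add("T", t_status.astype(str)),
        }
    )
    truth = pd.DataFrame(
        {
            "patient_id": patient_ids,
            "true_ecm_score": true_score,
            "true_ecm_group": true_ecm_group,
            "stromal_cells": counts["stromal"],
            "epithelial_cells": counts["epithelial"],
        }
    )
    for j, m in enumerate(ECM_MARKERS):
        truth[f"true_high_{m}"] = highs[:, j]
    return SyntheticCohort(cells=cells, survival=survival, truth=truth)
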