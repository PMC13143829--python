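"""Motility statistics of chunk-averaged velocity fields.

Implements the standard jamming/flocking observables of collective cell
migration:

* total r.m.s. velocity  v_RMS^tot(t) = sqrt(<|v_t(x)|^2>_x);
* drift-corrected velocity v^dc_t(x) = v_t(x) - <v_t(x)>_x and its r.m.s.,
  isolating the disordered component from coherent monolayer drift;
* the radial velocity-velocity correlation function
  C_vv(dx, t) = <v^dc(x+dx) . v^dc(x)>_x / <|v^dc(x)|^2>_x,
  fitted with exp(-dx/xi) to extract the correlation length xi, the size of
  a cluster of cells moving together;
* the alignment index a_t(x): cosine of the angle between the field's mean
  velocity and each local vector (near 1 everywhere indicates flocking).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.spatial.distance import pdist, squareform

from collmot.piv import VelocityField


class DegenerateFieldError(ValueError):
    """Raised when the drift-corrected field has zero variance so the
    correlation function is undefined."""


def _valid_vectors(field: VelocityField, units: str) -> tuple[np.ndarray, np.ndarray]:
    """(n, 2) positions in um (or px) and (n, 2) vectors over valid nodes."""
    yy, xx = np.meshgrid(field.y_px, field.x_px, indexing="ij")
    m = field.valid
    if units == "um_per_h":
        vec = np.column_stack([field.vx_umh[m], field.vy_umh[m]])
        pos = np.column_stack([xx[m], yy[m]]) * field.pixel_size_um
    elif units == "px_per_frame":
        vec = np.column_stack([field.vx[m], field.vy[m]])
        pos = np.column_stack([xx[m], yy[m]])
    else:
        raise ValueError(f"unknown units {units!r}")
    return pos, vec


def rms_velocity(field: VelocityField, units: str = "um_per_h") -> float:
    """Root of the spatial mean of squared vector magnitudes over valid
    nodes; NaN if no node is valid."""
    _, vec = _valid_vectors(field, units)
    if len(vec) == 0:
        return float("nan")
    return float(np.sqrt(np.mean(np.sum(vec**2, axis=1))))


def mean_drift(field: VelocityField, units: str = "um_per_h") -> np.ndarray:
    """Spatial mean vector <v_t(x)>_x over valid nodes."""
    _, vec = _valid_vectors(field, units)
    if len(vec) == 0:
        return np.array([np.nan, np.nan])
    return vec.mean(axis=0)


def drift_correct(field: VelocityField) -> VelocityField:
    """Subtract the spatial mean vector from every valid node."""
    if field.n_valid == 0:
        raise ValueError("cannot drift-correct a field with no valid vectors")
    out = field.copy()
    out.vx[out.valid] -= out.vx[out.valid].mean()
    out.vy[out.valid] -= out.vy[out.valid].mean()
    return out


@dataclass
class CorrelationCurve:
    """Radially binned velocity-velocity correlation."""

    r_um: np.ndarray  # bin centres (separation)
    c: np.ndarray  # C_vv per bin
    n_pairs: np.ndarray
    bin_width_um: float
    max_extent_um: float  # largest pairwise separation on the grid


@dataclass
class CorrelationFit:
    """Exponential-decay fit of a correlation curve."""

    xi_um: float
    ok: bool
    pegged: bool  # xi at or beyond the field extent (flocking limit)
    fit_r: np.ndarray = dc_field(default_factory=lambda: np.empty(0))
    fit_c: np.ndarray = dc_field(default_factory=lambda: np.empty(0))
    residual_norm: float = float("nan")


def velocity_correlation(
    field: VelocityField,
    bin_width_um: float | None = None,
) -> CorrelationCurve:
    """Radial C_vv of a drift-corrected field by pair accumulation.

    Dot products of vector pairs are binned by separation |dx| (bin index =
    round(|dx| / bin_width)) and normalized by the spatial mean squared
    magnitude, so the self-pair bin at dx = 0 equals 1 exactly.  The default
    bin width is the velocity-grid spacing.
    """
    pos, vec = _valid_vectors(field, "um_per_h")
    if len(vec) < 2:
        raise ValueError("need at least two valid nodes")
    denom = np.mean(np.sum(vec**2, axis=1))
    if denom <= 1e-30:
        raise DegenerateFieldError(
            "drift-corrected field has zero variance; C_vv is undefined"
        )
    if bin_width_um is None:
        dx = np.diff(field.x_px)
        bin_width_um = float(dx[0] * field.pixel_size_um) if len(dx) else 1.0
    dists = squareform(pdist(pos))
    dots = vec @ vec.T
    idx = np.round(dists / bin_width_um).astype(int)
    nb = idx.max() + 1
    sums = np.bincount(idx.ravel(), weights=dots.ravel(), minlength=nb)
    counts = np.bincount(idx.ravel(), minlength=nb)
    dist_sums = np.bincount(idx.ravel(), weights=dists.ravel(), minlength=nb)
    with np.errstate(invalid="ignore"):
        c = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan) / denom
        # label each bin by the mean separation of the pairs it holds (a
        # grid bin also collects diagonal pairs, so the nominal centre
        # would understate the true separation)
        r = dist_sums / np.maximum(counts, 1)
    keep = counts > 0
    return CorrelationCurve(
        r_um=r[keep],
        c=c[keep],
        n_pairs=counts[keep],
        bin_width_um=bin_width_um,
        max_extent_um=float(dists.max()),
    )


def windowed_exponential_curve(
    r_um: np.ndarray,
    xi_um: float,
    window_um: float,
    step_um: float | None = None,
) -> np.ndarray:
    """Exponential correlation exp(-r/xi) convolved with the spatial
    response of a square interrogation window of side ``window_um`` (the
    window's autocorrelation, a separable triangle), normalized to 1 at
    r = 0.

    This is the two-point correlation a PIV grid actually measures when the
    underlying velocity field has an exponential correlation: each vector
    is an average over its interrogation window, which broadens the
    apparent correlation, most severely when xi is smaller than the window.
    """
    r_um = np.asarray(r_um, dtype=float)
    # span covers the requested radii and the kernel; beyond that the
    # periodic-domain alias of the exponential tail is negligible after
    # normalization.  The grid is capped at 2048^2 to bound memory.
    span = max(r_um.max() * 1.25 if r_um.size else 0.0, 3 * window_um, 3 * xi_um)
    if step_um is None:
        step_um = min(window_um, max(xi_um, window_um / 8.0)) / 8.0
    step_um = max(step_um, 4 * span / 2048.0)
    n = int(2 ** np.ceil(np.log2(max(4 * span / step_um, 64))))
    ax = (np.arange(n) - n // 2) * step_um
    rr = np.hypot(ax[:, None], ax[None, :])
    corr = np.exp(-rr / xi_um)
    tri = np.clip(1.0 - np.abs(ax) / window_um, 0.0, None)
    kern = np.outer(tri, tri)
    kern /= kern.sum()
    sm = np.fft.fftshift(
        np.real(
            np.fft.ifft2(
                np.fft.fft2(np.fft.ifftshift(corr)) * np.fft.fft2(np.fft.ifftshift(kern))
            )
        )
    )
    centre = sm[n // 2, n // 2]
    prof = sm[n // 2, n // 2 :] / centre  # isotropic: radial profile along +x
    return np.interp(r_um, ax[n // 2 :], prof)


def _model_curve(
    r_eval: np.ndarray,
    xi: float,
    curve: CorrelationCurve,
    window_um: float | None,
) -> np.ndarray:
    """Model C_vv at separations ``r_eval``: plain exponential, or the
    window-smoothed exponential with the small finite-grid correction
    c_bar (pair-count-weighted mean model correlation over the whole grid,
    which spatial-mean subtraction removes from every bin)."""
    if window_um is None:
        return np.exp(-r_eval / xi)
    model_all = windowed_exponential_curve(curve.r_um, xi, window_um)
    cbar = float(np.sum(curve.n_pairs * model_all) / np.sum(curve.n_pairs))
    model = np.interp(r_eval, curve.r_um, model_all)
    return (model - cbar) / (1.0 - cbar)


def fit_correlation_length(
    curve: CorrelationCurve,
    fit_range: tuple[float, float] | None = None,
    c_floor: float = 0.05,
    window_um: float | None = None,
) -> CorrelationFit:
    """Nonlinear least-squares fit of the correlation length xi.

    The model is C_vv(dx) = exp(-dx / xi); when ``window_um`` is given (the
    interrogation-window side in um) the model is the window-smoothed
    exponential of :func:`windowed_exponential_curve` with a finite-grid
    mean-subtraction correction, which removes the bias the window response
    would otherwise impose on xi below the window size.

    The default fit range runs from the first off-origin bin to the first
    bin where C_vv <= ``c_floor`` (inclusive), or the last bin.  The fit is
    done on C_vv directly (not log-transformed) so near-zero bins are kept.
    Failure (fewer than 3 usable bins, or C_vv non-positive throughout) is
    flagged, not raised; a fitted xi at or beyond the grid extent is
    reported with ``pegged=True``.
    """
    r, c = curve.r_um, curve.c
    off = r > 0
    if fit_range is not None:
        sel = off & (r >= fit_range[0]) & (r <= fit_range[1])
    else:
        sel = off.copy()
        below = np.flatnonzero(off & (c <= c_floor))
        if below.size:
            sel &= r <= r[below[0]]
    r_fit, c_fit = r[sel], c[sel]
    if len(r_fit) < 3 or not np.any(c_fit > 0):
        return CorrelationFit(xi_um=float("nan"), ok=False, pegged=False)
    p0 = max(curve.bin_width_um, r_fit[min(len(r_fit) // 2, len(r_fit) - 1)])
    try:
        popt, _ = curve_fit(
            lambda x, xi: _model_curve(x, xi, curve, window_um),
            r_fit,
            c_fit,
            p0=[p0],
            bounds=(1e-9, np.inf),
            maxfev=10000,
        )
    except RuntimeError:
        return CorrelationFit(xi_um=float("nan"), ok=False, pegged=False)
    xi = float(popt[0])
    resid = float(np.linalg.norm(_model_curve(r_fit, xi, curve, window_um) - c_fit))
    pegged = xi >= curve.max_extent_um
    return CorrelationFit(
        xi_um=xi, ok=True, pegged=pegged, fit_r=r_fit, fit_c=c_fit,
        residual_norm=resid,
    )


@dataclass
class AlignmentMap:
    """Per-node cosine between the field mean velocity and each vector."""

    a: np.ndarray  # (ny, nx), NaN where masked
    valid: np.ndarray
    t_min: float
    degenerate: bool = False  # mean vector was zero; all nodes masked


def alignment_index(field: VelocityField, zero_tol: float = 1e-12) -> AlignmentMap:
    """Alignment index a_t(x) in [-1, 1]; nodes whose vector (or the field
    mean) has zero magnitude are masked."""
    mean = mean_drift(field, "px_per_frame")
    a = np.full(field.vx.shape, np.nan)
    mnorm = np.linalg.norm(mean)
    if not np.isfinite(mnorm) or mnorm <= zero_tol:
        return AlignmentMap(a=a, valid=np.zeros_like(field.valid), t_min=field.t_min,
                            degenerate=True)
    mags = np.hypot(field.vx, field.vy)
    ok = field.valid & (mags > zero_tol)
    a[ok] = (field.vx[ok] * mean[0] + field.vy[ok] * mean[1]) / (mags[ok] * mnorm)
    np.clip(a, -1.0, 1.0, out=a)
    return AlignmentMap(a=a, valid=ok, t_min=field.t_min)


def compute_motility_series(
    chunk_fields: Sequence[VelocityField],
    bin_width_um: float | None = None,
    fit_range: tuple[float, float] | None = None,
    average_curves: bool = False,
    window_um: float | None = None,
) -> pd.DataFrame:
    """Per-chunk motility time series.

    Columns: t_min, vrms_tot, vrms_dc (um/h), drift_x, drift_y (um/h),
    xi_um, fit_ok, xi_pegged, mean_alignment.  With ``average_curves`` the
    correlation curves of all chunks are averaged before a single fit whose
    xi is then reported for every chunk.
    """
    rows = []
    curves = []
    for f in chunk_fields:
        drift = mean_drift(f, "um_per_h")
        tot = rms_velocity(f, "um_per_h")
        try:
            dc = drift_correct(f)
            vdc = rms_velocity(dc, "um_per_h")
        except ValueError:
            dc, vdc = None, float("nan")
        xi, ok, pegged = float("nan"), False, False
        if dc is not None:
            try:
                curve = velocity_correlation(dc, bin_width_um)
                curves.append(curve)
                fit = fit_correlation_length(curve, fit_range, window_um=window_um)
                xi, ok, pegged = fit.xi_um, fit.ok, fit.pegged
            except (DegenerateFieldError, ValueError):
                pass
        amap = alignment_index(f)
        mean_a = float(np.nanmean(amap.a)) if amap.valid.any() else float("nan")
        rows.append(
            dict(
                t_min=f.t_min,
                vrms_tot=tot,
                vrms_dc=vdc,
                drift_x=drift[0],
                drift_y=drift[1],
                xi_um=xi,
                fit_ok=ok,
                xi_pegged=pegged,
                mean_alignment=mean_a,
            )
        )
    df = pd.DataFrame(rows)
    if average_curves and curves:
        r0 = curves[0].r_um
        usable = [cv for cv in curves if len(cv.r_um) == len(r0)]
        mean_curve = CorrelationCurve(
            r_um=r0,
            c=np.mean([cv.c for cv in usable], axis=0),
            n_pairs=np.sum([cv.n_pairs for cv in usable], axis=0),
            bin_width_um=curves[0].bin_width_um,
            max_extent_um=curves[0].max_extent_um,
        )
        fit = fit_correlation_length(mean_curve, fit_range, window_um=window_um)
        df["xi_um"] = fit.xi_um
        df["fit_ok"] = fit.ok
        df["xi_pegged"] = fit.pegged
    return df


def phase_trajectory(series: pd.DataFrame) -> np.ndarray:
    """Time-ordered (v_RMS^dc, xi) points for jamming-phase plots.

    Accepts the output of :func:`compute_motility_series`; returns an
    (n, 2) array (empty for an empty series).
    """
    if len(series) == 0:
        return np.empty((0, 2))
    s = series.sort_values("t_min")
    return np.column_stack([s["vrms_dc"].to_numpy(), s["xi_um"].to_numpy()])
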