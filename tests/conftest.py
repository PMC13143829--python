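"""Shared fixtures and independent oracle helpers.

The oracles here deliberately avoid the production code paths: the radial
autocorrelation oracle works on the full-resolution field via
Wiener-Khinchin before any PIV, and the pair-enumeration oracle computes
C_vv with explicit Python loops.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import curve_fit

from collmot.piv import VelocityField


def make_field(
    vx,
    vy,
    spacing_px: float = 40.0,
    pixel_size_um: float = 1.0,
    frame_interval_min: float = 60.0,
    valid=None,
    t_min: float = 0.0,
) -> VelocityField:
    """Hand-built velocity field on a regular grid (px/frame vectors).

    With pixel_size 1 um and 60-min frames, px/frame and um/h coincide.
    """
    vx = np.atleast_2d(np.asarray(vx, dtype=float))
    vy = np.atleast_2d(np.asarray(vy, dtype=float))
    ny, nx = vx.shape
    return VelocityField(
        x_px=np.arange(nx) * spacing_px,
        y_px=np.arange(ny) * spacing_px,
        vx=vx,
        vy=vy,
        valid=np.ones_like(vx, dtype=bool) if valid is None else np.asarray(valid, bool),
        t_min=t_min,
        pixel_size_um=pixel_size_um,
        frame_interval_min=frame_interval_min,
    )


def oracle_radial_autocorr_xi(field: np.ndarray, max_r: int, bin_px: int = 4) -> float:
    """Correlation length of a (2, H, W) field by direct full-resolution
    isotropic autocorrelation (Wiener-Khinchin) and an exponential fit."""
    h, w = field.shape[1:]
    S = np.zeros((h, w))
    for comp in field:
        F = np.fft.fft2(comp)
        S += np.real(np.fft.ifft2(F * np.conj(F)))
    S /= S[0, 0]
    yy = np.minimum(np.arange(h), h - np.arange(h))[:, None]
    xx = np.minimum(np.arange(w), w - np.arange(w))[None, :]
    rr = np.hypot(yy, xx)
    bins = np.arange(0, max_r + 1, bin_px)
    idx = np.digitize(rr.ravel(), bins)
    c = np.array([S.ravel()[idx == i].mean() for i in range(1, len(bins))])
    r = 0.5 * (bins[:-1] + bins[1:])
    sel = c > 0.05
    popt, _ = curve_fit(lambda x, xi: np.exp(-x / xi), r[sel], c[sel], p0=[max_r / 3])
    return float(popt[0])


def oracle_cvv_direct(pos: np.ndarray, vec: np.ndarray, bin_width: float):
    """Radial C_vv by explicit pair enumeration (plain Python loops).

    Returns (mean separation per bin, C_vv per bin, counts), binned by
    round(|dx| / bin_width), normalized by the mean squared magnitude.
    """
    n = len(pos)
    denom = sum(float(v @ v) for v in vec) / n
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    dist_sums: dict[int, float] = {}
    for i in range(n):
        for j in range(n):
            d = float(np.hypot(*(pos[i] - pos[j])))
            b = int(round(d / bin_width))
            sums[b] = sums.get(b, 0.0) + float(vec[i] @ vec[j])
            counts[b] = counts.get(b, 0) + 1
            dist_sums[b] = dist_sums.get(b, 0.0) + d
    bs = sorted(counts)
    r = np.array([dist_sums[b] / counts[b] for b in bs])
    c = np.array([sums[b] / counts[b] / denom for b in bs])
    return r, c, np.array([counts[b] for b in bs])


def box_average_truth(true_field: np.ndarray, window: int, step: int) -> tuple[np.ndarray, np.ndarray]:
    """Window-averaged ground-truth field on the PIV grid (what an ideal
    interrogation window measures), via an integral image."""
    h, w = true_field.shape[1:]
    ys = np.arange(0, h - window + 1, step)
    xs = np.arange(0, w - window + 1, step)
    padded = np.pad(true_field, ((0, 0), (1, 0), (1, 0)))
    cs = np.cumsum(np.cumsum(padded, axis=1), axis=2)

    def avg(c):
        return (
            c[ys[:, None] + window, xs[None, :] + window]
            - c[ys[:, None] + window, xs[None, :]]
            - c[ys[:, None], xs[None, :] + window]
            + c[ys[:, None], xs[None, :]]
        ) / window**2

    return avg(cs[0]), avg(cs[1])


@pytest.fixture(scope="session")
def uniform_movie():
    from collmot.synthetic import FlowSpec, make_speckle_movie

    return make_speckle_movie(
        FlowSpec(kind="uniform", drift=(3.0, 0.0), seed=11), shape=(240, 240), n_frames=4
    )


@pytest.fixture(scope="session")
def small_cohort():
    from collmot.synthetic import SyntheticCohortSpec, make_tma_cohort

    return make_tma_cohort(
        SyntheticCohortSpec(
            n_patients=30,
            fraction_below_threshold=0.1,
            cells_per_compartment=(120, 200),
            seed=5,
        )
    )
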