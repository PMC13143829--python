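"""Windowed cross-correlation particle image velocimetry for monolayers.

Velocity fields are estimated by dividing each image into interrogation
windows (default 80x80 px, slightly larger than a typical cell, with 50%
spatial overlap), cross-correlating the intensity of each window between
the two frames of a pair separated by ``frame_lag``, and locating the
correlation peak with subpixel (3-point Gaussian) refinement.  The local
velocity is v_t(x) = dr / dt in px/frame, convertible exactly to um/h via
the pixel size and frame interval.  Per-pair fields are then temporally
averaged over chunks (default 20 frames, 50% overlap) to smooth the maps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class PIVConfig:
    """PIV parameters; defaults match standard monolayer practice
    (80 px windows at 50% overlap, 20-frame chunks at 50% overlap,
    frame pairs one frame apart)."""

    window_size_px: int = 80
    spatial_overlap: float = 0.5
    frame_lag: int = 1
    chunk_length: int = 20
    chunk_overlap: float = 0.5
    subpixel_method: str = "gaussian"  # "gaussian" | "parabolic" | "none"
    outlier_policy: str = "nmed"  # "nmed" (replace by local median) | "mask" | "none"
    pixel_size_um: float = 0.65
    frame_interval_min: float = 10.0

    def __post_init__(self) -> None:
        if self.window_size_px < 16:
            raise ValueError("window_size_px must be >= 16")
        if not (0 <= self.spatial_overlap < 1) or not (0 <= self.chunk_overlap < 1):
            raise ValueError("overlaps must lie in [0, 1)")
        if self.chunk_length < 1 or self.frame_lag < 1:
            raise ValueError("chunk_length and frame_lag must be >= 1")
        if self.pixel_size_um <= 0 or self.frame_interval_min <= 0:
            raise ValueError("pixel_size_um and frame_interval_min must be positive")

    @property
    def grid_step_px(self) -> int:
        return max(1, int(round(self.window_size_px * (1 - self.spatial_overlap))))

    @property
    def unit_factor_umh(self) -> float:
        """Multiply px/frame by this to obtain um/h."""
        return self.pixel_size_um * 60.0 / self.frame_interval_min


@dataclass
class DisplacementEstimate:
    """Subpixel displacement from one window pair."""

    dr: np.ndarray  # (dx, dy) in px
    peak_height: float
    snr: float
    valid: bool = True


@dataclass
class VelocityField:
    """Gridded velocity vectors for one frame pair or chunk.

    ``vx``/``vy`` are in px/frame on a rectangular grid whose node (i, j)
    sits at image coordinates (row ``y_px[i]``, column ``x_px[j]``),
    0-based, origin top-left, y increasing downward.
    """

    x_px: np.ndarray  # (nx,) window-centre columns
    y_px: np.ndarray  # (ny,) window-centre rows
    vx: np.ndarray  # (ny, nx) px/frame
    vy: np.ndarray  # (ny, nx) px/frame
    valid: np.ndarray  # (ny, nx) bool
    t_min: float
    pixel_size_um: float
    frame_interval_min: float

    @property
    def unit_factor_umh(self) -> float:
        return self.pixel_size_um * 60.0 / self.frame_interval_min

    @property
    def vx_umh(self) -> np.ndarray:
        return self.vx * self.unit_factor_umh

    @property
    def vy_umh(self) -> np.ndarray:
        return self.vy * self.unit_factor_umh

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def copy(self) -> "VelocityField":
        return VelocityField(
            x_px=self.x_px.copy(),
            y_px=self.y_px.copy(),
            vx=self.vx.copy(),
            vy=self.vy.copy(),
            valid=self.valid.copy(),
            t_min=self.t_min,
            pixel_size_um=self.pixel_size_um,
            frame_interval_min=self.frame_interval_min,
        )


def _wrap_index(idx: int, n: int) -> int:
    return idx - n if idx > n // 2 else idx


def _subpixel_offset(cm: float, c0: float, cp: float, method: str) -> float:
    """Offset of the true peak from the integer peak along one axis."""
    if method == "none":
        return 0.0
    if method == "gaussian" and cm > 0 and c0 > 0 and cp > 0:
        lm, l0, lp = np.log(cm), np.log(c0), np.log(cp)
        denom = lm + lp - 2 * l0
        if denom < 0:
            return float(0.5 * (lm - lp) / denom)
    denom = cm + cp - 2 * c0
    if denom < 0:  # parabolic fallback, also used when logs are unusable
        return float(0.5 * (cm - cp) / denom)
    return 0.0


def cross_correlate_window(
    roi_a: np.ndarray,
    roi_b: np.ndarray,
    subpixel_method: str = "gaussian",
) -> DisplacementEstimate:
    """Displacement of roi_b relative to roi_a by normalized FFT
    cross-correlation with subpixel peak refinement.

    A constant (zero-variance) ROI yields a flagged invalid estimate rather
    than an exception.  The signal-to-noise ratio is the primary peak height
    over the highest peak outside the 3x3 neighbourhood of the primary.
    """
    a = np.asarray(roi_a, dtype=float)
    b = np.asarray(roi_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("ROIs must have the same shape")
    if min(a.shape) < 16:
        raise ValueError("ROIs must be at least 16x16")
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return DisplacementEstimate(
            dr=np.array([np.nan, np.nan]), peak_height=0.0, snr=0.0, valid=False
        )
    corr = np.real(np.fft.ifft2(np.conj(np.fft.fft2(a)) * np.fft.fft2(b))) / (na * nb)
    h, w = corr.shape
    iy, ix = np.unravel_index(np.argmax(corr), corr.shape)
    peak = float(corr[iy, ix])

    def at(dy: int, dx: int) -> float:
        return float(corr[(iy + dy) % h, (ix + dx) % w])

    sub_y = _subpixel_offset(at(-1, 0), peak, at(1, 0), subpixel_method)
    sub_x = _subpixel_offset(at(0, -1), peak, at(0, 1), subpixel_method)
    dy = _wrap_index(iy, h) + sub_y
    dx = _wrap_index(ix, w) + sub_x

    masked = corr.copy()
    for oy in (-1, 0, 1):
        for ox in (-1, 0, 1):
            masked[(iy + oy) % h, (ix + ox) % w] = -np.inf
    second = float(masked.max())
    snr = peak / max(second, 1e-12) if second > 0 else np.inf
    return DisplacementEstimate(
        dr=np.array([dx, dy]), peak_height=peak, snr=snr, valid=True
    )


def _window_starts(extent: int, window: int, step: int) -> np.ndarray:
    """Window start offsets; a partial window at the far edge is dropped."""
    return np.arange(0, extent - window + 1, step)


def _validate_field(vx: np.ndarray, vy: np.ndarray, valid: np.ndarray, policy: str,
                    threshold: float = 2.0, eps: float = 0.1) -> None:
    """Normalized-median outlier test against the 8-neighbourhood
    (in place).  Outliers are replaced by the local median ('nmed') or
    masked ('mask')."""
    if policy == "none":
        return
    ny, nx = vx.shape
    med_x = np.full_like(vx, np.nan)
    med_y = np.full_like(vy, np.nan)
    resid = np.zeros_like(vx)
    for i in range(ny):
        for j in range(nx):
            if not valid[i, j]:
                continue
            nb_x, nb_y = [], []
            for oi in (-1, 0, 1):
                for oj in (-1, 0, 1):
                    if oi == 0 and oj == 0:
                        continue
                    ii, jj = i + oi, j + oj
                    if 0 <= ii < ny and 0 <= jj < nx and valid[ii, jj]:
                        nb_x.append(vx[ii, jj])
                        nb_y.append(vy[ii, jj])
            if not nb_x:
                continue
            mx, my = np.median(nb_x), np.median(nb_y)
            med_x[i, j], med_y[i, j] = mx, my
            rm = np.median(np.hypot(np.array(nb_x) - mx, np.array(nb_y) - my))
            resid[i, j] = np.hypot(vx[i, j] - mx, vy[i, j] - my) / (rm + eps)
    outlier = valid & (resid > threshold) & ~np.isnan(med_x)
    if policy == "nmed":
        vx[outlier] = med_x[outlier]
        vy[outlier] = med_y[outlier]
    elif policy == "mask":
        valid[outlier] = False
    else:
        raise ValueError(f"unknown outlier_policy {policy!r}")


def compute_velocity_fields(movie, config: PIVConfig = PIVConfig()) -> list[VelocityField]:
    """One VelocityField per frame pair (t, t + frame_lag).

    ``movie`` is either a ``synthetic.SyntheticMovie`` or a (T, H, W) array;
    in the latter case the config's pixel size and frame interval apply.
    """
    if hasattr(movie, "frames"):
        frames = np.asarray(movie.frames, dtype=float)
        pixel_size = movie.pixel_size_um
        interval = movie.frame_interval_min
    else:
        frames = np.asarray(movie, dtype=float)
        pixel_size = config.pixel_size_um
        interval = config.frame_interval_min
    if frames.ndim != 3:
        raise ValueError("movie must be a (T, H, W) stack")
    n_frames, h, w = frames.shape
    lag = config.frame_lag
    if n_frames < lag + 1:
        raise ValueError(f"need at least {lag + 1} frames, got {n_frames}")
    win = config.window_size_px
    step = config.grid_step_px
    ys = _window_starts(h, win, step)
    xs = _window_starts(w, win, step)
    if len(ys) < 2 or len(xs) < 2:
        raise ValueError("image too small for a 2x2 grid of interrogation windows")
    y_c = ys + (win - 1) / 2.0
    x_c = xs + (win - 1) / 2.0

    fields: list[VelocityField] = []
    for t in range(n_frames - lag):
        fa, fb = frames[t], frames[t + lag]
        vx = np.full((len(ys), len(xs)), np.nan)
        vy = np.full((len(ys), len(xs)), np.nan)
        valid = np.zeros((len(ys), len(xs)), dtype=bool)
        for i, y0 in enumerate(ys):
            for j, x0 in enumerate(xs):
                est = cross_correlate_window(
                    fa[y0 : y0 + win, x0 : x0 + win],
                    fb[y0 : y0 + win, x0 : x0 + win],
                    config.subpixel_method,
                )
                if est.valid:
                    vx[i, j] = est.dr[0] / lag
                    vy[i, j] = est.dr[1] / lag
                    valid[i, j] = True
        _validate_field(vx, vy, valid, config.outlier_policy)
        fields.append(
            VelocityField(
                x_px=x_c,
                y_px=y_c,
                vx=vx,
                vy=vy,
                valid=valid,
                t_min=(t + lag / 2.0) * interval,
                pixel_size_um=pixel_size,
                frame_interval_min=interval,
            )
        )
    return fields


def temporal_average(
    fields: Sequence[VelocityField],
    chunk_length: int = 20,
    chunk_overlap: float = 0.5,
) -> list[VelocityField]:
    """Average per-pair fields over chunks of ``chunk_length`` fields
    advancing by ``chunk_length * (1 - chunk_overlap)``.

    A grid node of the averaged field is valid only where at least half the
    chunk's member fields are valid; the chunk time is the mean of member
    times (the chunk centre).
    """
    if len(fields) < chunk_length:
        raise ValueError(
            f"need at least {chunk_length} fields for one chunk, got {len(fields)}"
        )
    step = max(1, int(round(chunk_length * (1 - chunk_overlap))))
    out: list[VelocityField] = []
    for start in range(0, len(fields) - chunk_length + 1, step):
        members = fields[start : start + chunk_length]
        vx = np.stack([f.vx for f in members])
        vy = np.stack([f.vy for f in members])
        ok = np.stack([f.valid for f in members])
        n_ok = ok.sum(axis=0)
        with np.errstate(invalid="ignore"):
            mean_vx = np.nansum(np.where(ok, vx, 0.0), axis=0) / np.maximum(n_ok, 1)
            mean_vy = np.nansum(np.where(ok, vy, 0.0), axis=0) / np.maximum(n_ok, 1)
        valid = n_ok >= chunk_length / 2.0
        mean_vx[~valid] = np.nan
        mean_vy[~valid] = np.nan
        f0 = members[0]
        out.append(
            VelocityField(
                x_px=f0.x_px.copy(),
                y_px=f0.y_px.copy(),
                vx=mean_vx,
                vy=mean_vy,
                valid=valid,
                t_min=float(np.mean([f.t_min for f in members])),
                pixel_size_um=f0.pixel_size_um,
                frame_interval_min=f0.frame_interval_min,
            )
        )
    return out
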