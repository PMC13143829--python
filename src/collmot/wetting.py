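"""Spheroid wetting quantification.

A 3D spheroid seeded on an ECM-coated substrate spreads ("wets") over
time.  From a series of binary footprint masks this module computes the
spreading area normalized to t = 0, the equivalent-circle radius
r(t) = sqrt(A(t) / pi), and the average wetting speed in um/h as the
least-squares slope of r(t) versus time (an endpoint Dr/Dt alternative is
available behind a flag).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from collmot.synthetic import SpheroidMaskSeries


@dataclass
class WettingResult:
    times_h: np.ndarray
    area_um2: np.ndarray
    norm_area: np.ndarray
    radius_um: np.ndarray
    speed_um_per_h: float
    speed_method: str
    speed_stderr: float  # standard error of the fitted slope (NaN for endpoint)


def _areas_um2(series: SpheroidMaskSeries) -> np.ndarray:
    return series.masks.reshape(series.masks.shape[0], -1).sum(axis=1) * series.pixel_size_um**2


def normalized_area(series: SpheroidMaskSeries) -> np.ndarray:
    """A(t) / A(0); exactly 1 at t = 0."""
    areas = _areas_um2(series)
    if areas[0] == 0:
        raise ValueError("mask at t=0 is empty")
    return areas / areas[0]


def equivalent_radius(series: SpheroidMaskSeries) -> np.ndarray:
    """Equivalent-circle radius sqrt(A/pi) in um."""
    return np.sqrt(_areas_um2(series) / np.pi)


def average_wetting_speed(series: SpheroidMaskSeries, method: str = "fit") -> float:
    """Average front speed in um/h.

    ``method='fit'``: least-squares slope of equivalent radius vs time
    (robust to irregular fronts); ``method='endpoint'``: (r_T - r_0) / T.
    Sign is preserved, so a shrinking spheroid gives a negative speed.
    """
    t = series.times_h
    if len(t) < 3 and method == "fit":
        raise ValueError("need at least 3 time points for a slope fit")
    if np.ptp(t) == 0:
        raise ValueError("degenerate time axis")
    r = equivalent_radius(series)
    if method == "endpoint":
        return float((r[-1] - r[0]) / (t[-1] - t[0]))
    if method != "fit":
        raise ValueError(f"unknown method {method!r}")
    slope, _ = np.polyfit(t, r, 1)
    return float(slope)


def analyze_wetting(series: SpheroidMaskSeries, speed_method: str = "fit") -> WettingResult:
    """Full wetting quantification of one mask series."""
    areas = _areas_um2(series)
    if areas[0] == 0:
        raise ValueError("mask at t=0 is empty")
    r = np.sqrt(areas / np.pi)
    speed = average_wetting_speed(series, speed_method)
    stderr = float("nan")
    if speed_method == "fit" and len(series.times_h) > 2:
        resid = r - (speed * series.times_h + np.polyfit(series.times_h, r, 1)[1])
        dof = len(r) - 2
        sxx = np.sum((series.times_h - series.times_h.mean()) ** 2)
        stderr = float(np.sqrt(np.sum(resid**2) / dof / sxx)) if dof > 0 else float("nan")
    return WettingResult(
        times_h=series.times_h,
        area_um2=areas,
        norm_area=areas / areas[0],
        radius_um=r,
        speed_um_per_h=speed,
        speed_method=speed_method,
        speed_stderr=stderr,
    )
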