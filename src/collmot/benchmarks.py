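"""Self-contained benchmark routines that exercise the full pipeline on
synthetic inputs with known ground truth.

Each function generates its own data from an explicit seed, runs the
production code path and returns the measured quantity, so results are
reproducible end to end.  These are the routines behind the repository's
reproduction script and the heavier validation tests.
"""

from __future__ import annotations

import numpy as np

from collmot.metrics import drift_correct, fit_correlation_length, velocity_correlation
from collmot.piv import PIVConfig, compute_velocity_fields, cross_correlate_window, temporal_average
from collmot.synthetic import (
    FlowSpec,
    SyntheticCohortSpec,
    _speckle_texture,
    make_speckle_movie,
    make_spheroid_series,
    make_tma_cohort,
    make_survival_table,
)
from collmot.tma import exclude_low_cell_patients, logrank_test
from collmot.wetting import average_wetting_speed, normalized_area
from scipy import ndimage


def _sub_seed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([int(seed), int(k)]).generate_state(1)[0] % (2**31))


def piv_drift_accuracy(
    seed: int,
    drifts: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0),
    shape: tuple[int, int] = (400, 400),
    n_frames: int = 4,
) -> dict:
    """Mean absolute velocity error (px/frame) of PIV on uniform-drift
    speckle movies, per drift magnitude and overall."""
    per_drift = {}
    n_vec = 0
    for i, d in enumerate(drifts):
        mov = make_speckle_movie(
            FlowSpec(kind="uniform", drift=(d, 0.0), seed=_sub_seed(seed, i)),
            shape=shape,
            n_frames=n_frames,
        )
        fields = compute_velocity_fields(mov)
        errs = np.concatenate(
            [np.hypot(f.vx[f.valid] - d, f.vy[f.valid]) for f in fields]
        )
        per_drift[d] = float(errs.mean())
        n_vec += errs.size
    return {"per_drift": per_drift, "mae": float(np.mean(list(per_drift.values()))), "n_vectors": n_vec}


def subpixel_accuracy(
    seed: int,
    shifts: tuple[tuple[float, float], ...] = ((2.5, -1.25), (0.3, 0.7), (-1.1, 3.6)),
    size: int = 80,
) -> dict:
    """Largest error (px) in recovering known Fourier-applied subpixel
    shifts of a speckle ROI by windowed cross-correlation."""
    rng = np.random.default_rng(seed)
    tex = _speckle_texture((size, size), 50.0, rng)
    errs = []
    for dx, dy in shifts:
        shifted = np.real(
            np.fft.ifftn(ndimage.fourier_shift(np.fft.fftn(tex), shift=(dy, dx)))
        )
        est = cross_correlate_window(tex, shifted)
        errs.append(np.max(np.abs(est.dr - np.array([dx, dy]))))
    return {"max_error_px": float(np.max(errs)), "n_shifts": len(shifts)}


def xi_recovery(
    seed: int,
    xi_true_px: tuple[float, ...] = (20.0, 40.0, 80.0),
    n_seeds: int = 5,
    shape: tuple[int, int] = (800, 800),
    n_frames: int = 21,
    vrms: float = 2.0,
    pixel_size_um: float = 0.65,
) -> dict:
    """Full-pipeline correlation-length recovery: movie -> PIV -> chunk
    average -> drift-corrected C_vv -> window-corrected exponential fit.

    Returns per xi_true the median recovered xi (px) over ``n_seeds``
    movie realizations and the relative error of that median.
    """
    cfg = PIVConfig(pixel_size_um=pixel_size_um, frame_interval_min=10.0)
    out = {}
    for j, xi in enumerate(xi_true_px):
        fits = []
        for s in range(n_seeds):
            mov = make_speckle_movie(
                FlowSpec(kind="correlated", xi_true_px=xi, vrms=vrms,
                         seed=_sub_seed(seed, 1000 * (j + 1) + s)),
                shape=shape,
                n_frames=n_frames,
                pixel_size_um=pixel_size_um,
            )
            fields = compute_velocity_fields(mov, cfg)
            chunk = temporal_average(fields, cfg.chunk_length, cfg.chunk_overlap)[0]
            curve = velocity_correlation(drift_correct(chunk))
            fit = fit_correlation_length(
                curve, window_um=cfg.window_size_px * pixel_size_um
            )
            if fit.ok:
                fits.append(fit.xi_um / pixel_size_um)
        med = float(np.median(fits))
        out[xi] = {
            "median_xi_px": med,
            "rel_error": float(abs(med - xi) / xi),
            "n_seeds": len(fits),
        }
    return out


def wetting_benchmark(
    seed: int,
    speed_um_per_h: float = 10.0,
    r0_um: float = 100.0,
    t_max_h: float = 48.0,
    dt_h: float = 2.0,
) -> dict:
    """Recover a known radial expansion speed from rasterized disk masks."""
    times = np.arange(0.0, t_max_h + dt_h / 2, dt_h)
    series = make_spheroid_series(r0_um, speed_um_per_h, times, pixel_size_um=2.0)
    na = normalized_area(series)
    return {
        "speed_um_per_h": float(average_wetting_speed(series)),
        "norm_area_t0": float(na[0]),
        "n_timepoints": len(times),
    }


def exclusion_benchmark(seed: int, n_patients: int = 198, n_below: int = 5) -> dict:
    """Cell-count exclusion on a synthetic cohort with a known number of
    under-sampled patients."""
    cohort = make_tma_cohort(
        SyntheticCohortSpec(
            n_patients=n_patients,
            fraction_below_threshold=n_below / n_patients,
            seed=seed,
        )
    )
    _, report = exclude_low_cell_patients(cohort.cells, min_cells=100)
    return {
        "n_patients": n_patients,
        "n_excluded": len(report.excluded_ids),
        "n_retained": report.n_retained,
    }


def logrank_type1(seed: int, n_sim: int = 500, n: int = 200, alpha: float = 0.05) -> dict:
    """Rejection rate of the log-rank test under the null (hazard ratio 1)."""
    rejections = 0
    for s in range(n_sim):
        tbl = make_survival_table(n, hazard_ratio=1.0, seed=_sub_seed(seed, 7_000_000 + s))
        res = logrank_test(tbl["time_months"], tbl["event"], tbl["group"])
        rejections += res.p_value < alpha
    return {"rate": rejections / n_sim, "n_sim": n_sim, "n": n}


def logrank_power(
    seed: int, n_sim: int = 100, n: int = 200, hazard_ratio: float = 3.0,
    alpha: float = 0.05,
) -> dict:
    """Power of the log-rank test at the given hazard ratio."""
    rejections = 0
    for s in range(n_sim):
        tbl = make_survival_table(
            n, hazard_ratio=hazard_ratio, seed=_sub_seed(seed, 9_000_000 + s)
        )
        res = logrank_test(tbl["time_months"], tbl["event"], tbl["group"])
        rejections += res.p_value < alpha
    return {"power": rejections / n_sim, "n_sim": n_sim, "n": n}
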