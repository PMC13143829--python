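"""Readers and writers for the on-disk formats the pipeline exchanges:
multi-page grayscale TIFF movies with YAML sidecars, mask-series TIFFs,
velocity-field CSVs and cohort CSV tables."""

from __future__ import annotations

import os
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from collmot.piv import VelocityField
from collmot.synthetic import SpheroidMaskSeries, SyntheticMovie


def write_movie(movie: SyntheticMovie, tiff_path: str, ground_truth: bool = True) -> None:
    """Write a movie as multi-page TIFF plus a YAML sidecar with pixel
    size, frame interval and (optionally) the flow ground truth."""
    tifffile.imwrite(tiff_path, np.asarray(movie.frames, dtype=np.float32), photometric="minisblack")
    spec = movie.flow_spec
    meta = {
        "pixel_size_um": float(movie.pixel_size_um),
        "frame_interval_min": float(movie.frame_interval_min),
        "n_frames": int(movie.n_frames),
    }
    if ground_truth:
        meta["flow"] = {
            "kind": spec.kind,
            "drift_px_per_frame": [float(v) for v in spec.drift],
            "vrms_px_per_frame": float(spec.vrms),
            "xi_true_px": None if spec.xi_true_px is None else float(spec.xi_true_px),
            "decay_half_life_frames": (
                None if spec.decay_half_life is None else float(spec.decay_half_life)
            ),
            "seed": int(spec.seed),
        }
    with open(_sidecar(tiff_path), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def _sidecar(tiff_path: str) -> str:
    return os.path.splitext(tiff_path)[0] + ".yaml"


def read_movie(tiff_path: str) -> tuple[np.ndarray, dict]:
    """Read a multi-page TIFF movie and its YAML sidecar (empty metadata
    dict if no sidecar exists)."""
    frames = tifffile.imread(tiff_path)
    if frames.ndim == 2:
        frames = frames[None]
    meta: dict = {}
    if os.path.exists(_sidecar(tiff_path)):
        with open(_sidecar(tiff_path)) as fh:
            meta = yaml.safe_load(fh) or {}
    return frames, meta


def write_mask_series(series: SpheroidMaskSeries, tiff_path: str) -> None:
    tifffile.imwrite(tiff_path, series.masks.astype(np.uint8), photometric="minisblack")
    with open(_sidecar(tiff_path), "w") as fh:
        yaml.safe_dump(
            {
                "pixel_size_um": float(series.pixel_size_um),
                "times_h": [float(t) for t in series.times_h],
            },
            fh,
            sort_keys=False,
        )


def read_mask_series(tiff_path: str) -> SpheroidMaskSeries:
    masks = tifffile.imread(tiff_path).astype(bool)
    with open(_sidecar(tiff_path)) as fh:
        meta = yaml.safe_load(fh)
    return SpheroidMaskSeries(
        masks=masks,
        times_h=np.asarray(meta["times_h"], dtype=float),
        pixel_size_um=float(meta["pixel_size_um"]),
    )


def fields_to_frame(fields: Sequence[VelocityField]) -> pd.DataFrame:
    """Tidy per-node table (t_min, x_px, y_px, vx_umh, vy_umh, valid)."""
    rows = []
    for f in fields:
        yy, xx = np.meshgrid(f.y_px, f.x_px, indexing="ij")
        rows.append(
            pd.DataFrame(
                {
                    "t_min": f.t_min,
                    "x_px": xx.ravel(),
                    "y_px": yy.ravel(),
                    "vx_umh": f.vx_umh.ravel(),
                    "vy_umh": f.vy_umh.ravel(),
                    "valid": f.valid.ravel(),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def write_fields(fields: Sequence[VelocityField], csv_path: str) -> None:
    fields_to_frame(fields).to_csv(csv_path, index=False)


def read_fields(csv_path: str, pixel_size_um: float, frame_interval_min: float) -> list[VelocityField]:
    """Rebuild VelocityField objects from a tidy field CSV."""
    df = pd.read_csv(csv_path)
    factor = pixel_size_um * 60.0 / frame_interval_min
    out = []
    for t, sub in df.groupby("t_min", sort=True):
        x = np.unique(sub["x_px"])
        y = np.unique(sub["y_px"])
        piv_sub = sub.sort_values(["y_px", "x_px"])
        shape = (len(y), len(x))
        out.append(
            VelocityField(
                x_px=x,
                y_px=y,
                vx=piv_sub["vx_umh"].to_numpy().reshape(shape) / factor,
                vy=piv_sub["vy_umh"].to_numpy().reshape(shape) / factor,
                valid=piv_sub["valid"].to_numpy().reshape(shape).astype(bool),
                t_min=float(t),
                pixel_size_um=pixel_size_um,
                frame_interval_min=frame_interval_min,
            )
        )
    return out
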