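"""End-to-end pipeline wiring: generate -> piv -> motility -> wetting -> tma.

A :class:`PipelineConfig` (typically loaded from YAML) selects stages and
parameters; :func:`run_pipeline` materializes every artifact into an output
directory and writes a machine-readable run report (versions, config hash,
per-stage outputs).  One global seed fans out to per-stage seeds through
``stage_seed`` (a CRC32 of the stage name mixed into a SeedSequence), so
stages are reproducible independently of each other.
"""

from __future__ import annotations

import hashlib
import json
import os
import zlib
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

import collmot
from collmot import io as cio
from collmot.metrics import compute_motility_series
from collmot.piv import PIVConfig, compute_velocity_fields, temporal_average
from collmot.synthetic import (
    FlowSpec,
    SyntheticCohortSpec,
    make_speckle_movie,
    make_spheroid_series,
    make_tma_cohort,
)
from collmot.tma import compare_survival, score_cohort
from collmot.wetting import analyze_wetting


class ConfigError(ValueError):
    """Invalid pipeline configuration; the message names the offending keys."""


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31 derived from the global
    seed and the stage name."""
    ss = np.random.SeedSequence([int(seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


_KNOWN_TOP = {"seed", "stages", "piv", "metrics", "scoring", "generate", "paths"}
_DEFAULT_GENERATE = {
    "movie": {
        "kind": "correlated",
        "drift": [0.0, 0.0],
        "vrms": 2.0,
        "xi_true_px": 40.0,
        "decay_half_life": None,
        "shape": [400, 400],
        "n_frames": 21,
        "pixel_size_um": 0.65,
        "frame_interval_min": 10.0,
    },
    "wetting": {"r0_um": 100.0, "radial_speed_um_per_h": 10.0,
                "t_max_h": 48.0, "dt_h": 2.0, "pixel_size_um": 2.0},
    "cohort": {"n_patients": 198, "hazard_ratio": 3.0,
               "fraction_below_threshold": 5 / 198, "censoring_rate": 0.3},
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration with study-standard defaults
    (80 px windows, 50% overlaps, 20-frame chunks, min_cells = 100)."""

    seed: int = 0
    stages: tuple[str, ...] = ("generate", "piv", "motility", "wetting", "tma")
    piv: PIVConfig = field(default_factory=PIVConfig)
    metrics: dict = field(default_factory=lambda: {"bin_width_um": None, "fit_range": None})
    scoring: dict = field(default_factory=lambda: {"min_cells": 100})
    generate: dict = field(default_factory=lambda: json.loads(json.dumps(_DEFAULT_GENERATE)))
    paths: dict = field(default_factory=dict)  # optional pre-existing inputs

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        unknown = set(raw) - _KNOWN_TOP
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        piv_kwargs = raw.get("piv", {})
        bad = set(piv_kwargs) - set(PIVConfig.__dataclass_fields__)
        if bad:
            raise ConfigError(f"unknown piv keys: {sorted(bad)}")
        gen = json.loads(json.dumps(_DEFAULT_GENERATE))
        for section, vals in raw.get("generate", {}).items():
            if section not in gen:
                raise ConfigError(f"unknown generate section: {section!r}")
            gen[section].update(vals)
        cfg = cls(
            seed=int(raw.get("seed", 0)),
            stages=tuple(raw.get("stages", cls.stages)),
            piv=PIVConfig(**piv_kwargs),
            metrics={**{"bin_width_um": None, "fit_range": None}, **raw.get("metrics", {})},
            scoring={**{"min_cells": 100}, **raw.get("scoring", {})},
            generate=gen,
            paths=dict(raw.get("paths", {})),
        )
        for key, path in cfg.paths.items():
            if not os.path.exists(path):
                raise ConfigError(f"paths.{key}: no such file {path!r}")
        return cfg

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "seed": self.seed,
                "stages": list(self.stages),
                "piv": asdict(self.piv),
                "metrics": self.metrics,
                "scoring": self.scoring,
                "generate": self.generate,
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, out_dir: str) -> dict:
    """Run the selected stages, writing artifacts under ``out_dir``.

    Returns the run report (also written to run_report.json).
    """
    os.makedirs(out_dir, exist_ok=True)
    report: dict = {
        "collmot_version": collmot.__version__,
        "numpy_version": np.__version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }
    movie = None
    series = None
    cohort = None

    if "generate" in config.stages:
        m = config.generate["movie"]
        flow = FlowSpec(
            kind=m["kind"],
            drift=tuple(m["drift"]),
            vrms=m["vrms"],
            xi_true_px=m["xi_true_px"],
            decay_half_life=m["decay_half_life"],
            seed=stage_seed(config.seed, "movie"),
        )
        movie = make_speckle_movie(
            flow,
            shape=tuple(m["shape"]),
            n_frames=m["n_frames"],
            pixel_size_um=m["pixel_size_um"],
            frame_interval_min=m["frame_interval_min"],
        )
        cio.write_movie(movie, os.path.join(out_dir, "movie.tif"))
        wcfg = config.generate["wetting"]
        times = np.arange(0.0, wcfg["t_max_h"] + wcfg["dt_h"] / 2, wcfg["dt_h"])
        series = make_spheroid_series(
            wcfg["r0_um"], wcfg["radial_speed_um_per_h"], times, wcfg["pixel_size_um"]
        )
        cio.write_mask_series(series, os.path.join(out_dir, "spheroid_masks.tif"))
        ccfg = config.generate["cohort"]
        cohort = make_tma_cohort(
            SyntheticCohortSpec(
                n_patients=ccfg["n_patients"],
                hazard_ratio=ccfg["hazard_ratio"],
                fraction_below_threshold=ccfg["fraction_below_threshold"],
                censoring_rate=ccfg["censoring_rate"],
                seed=stage_seed(config.seed, "cohort"),
            )
        )
        cohort.cells.to_csv(os.path.join(out_dir, "cells.csv"), index=False)
        cohort.survival.to_csv(os.path.join(out_dir, "survival.csv"), index=False)
        cohort.truth.to_csv(os.path.join(out_dir, "cohort_truth.csv"), index=False)
        report["stages"]["generate"] = {
            "movie": "movie.tif",
            "masks": "spheroid_masks.tif",
            "cells": "cells.csv",
            "survival": "survival.csv",
        }

    chunk_fields = None
    if "piv" in config.stages:
        piv_cfg = config.piv
        if movie is None:
            if "movie" not in config.paths:
                raise ConfigError("piv stage needs generate stage or paths.movie")
            frames, meta = cio.read_movie(config.paths["movie"])
            movie = frames
            if meta:  # sidecar calibration wins over config defaults
                piv_cfg = replace(
                    piv_cfg,
                    pixel_size_um=meta.get("pixel_size_um", piv_cfg.pixel_size_um),
                    frame_interval_min=meta.get(
                        "frame_interval_min", piv_cfg.frame_interval_min
                    ),
                )
        fields = compute_velocity_fields(movie, piv_cfg)
        if len(fields) >= config.piv.chunk_length:
            chunk_fields = temporal_average(
                fields, config.piv.chunk_length, config.piv.chunk_overlap
            )
        else:
            chunk_fields = fields
        cio.write_fields(chunk_fields, os.path.join(out_dir, "velocity_fields.csv"))
        report["stages"]["piv"] = {
            "n_pair_fields": len(fields),
            "n_chunks": len(chunk_fields),
            "fields": "velocity_fields.csv",
        }

    if "motility" in config.stages:
        if chunk_fields is None:
            raise ConfigError("motility stage needs the piv stage")
        series_df = compute_motility_series(
            chunk_fields,
            bin_width_um=config.metrics["bin_width_um"],
            fit_range=config.metrics["fit_range"],
            window_um=config.piv.window_size_px * chunk_fields[0].pixel_size_um,
        )
        series_df.to_csv(os.path.join(out_dir, "motility_metrics.csv"), index=False)
        import tifffile

        from collmot.metrics import alignment_index

        amaps = np.stack(
            [alignment_index(f).a.astype(np.float32) for f in chunk_fields]
        )
        tifffile.imwrite(os.path.join(out_dir, "alignment_maps.tif"), amaps, photometric="minisblack")
        report["stages"]["motility"] = {
            "metrics": "motility_metrics.csv",
            "alignment_maps": "alignment_maps.tif",
            "n_chunks": len(series_df),
        }

    if "wetting" in config.stages:
        if series is None:
            if "masks" not in config.paths:
                raise ConfigError("wetting stage needs generate stage or paths.masks")
            series = cio.read_mask_series(config.paths["masks"])
        res = analyze_wetting(series)
        pd.DataFrame(
            {
                "t_h": res.times_h,
                "area_um2": res.area_um2,
                "norm_area": res.norm_area,
                "radius_um": res.radius_um,
            }
        ).to_csv(os.path.join(out_dir, "wetting.csv"), index=False)
        report["stages"]["wetting"] = {
            "speed_um_per_h": res.speed_um_per_h,
            "table": "wetting.csv",
        }

    if "tma" in config.stages:
        if cohort is None:
            if "cells" not in config.paths or "survival" not in config.paths:
                raise ConfigError("tma stage needs generate stage or paths.cells + paths.survival")
            cells = pd.read_csv(config.paths["cells"])
            survival = pd.read_csv(config.paths["survival"])
        else:
            cells, survival = cohort.cells, cohort.survival
        scored, excl = score_cohort(cells, min_cells=config.scoring["min_cells"])
        scored.reset_index().to_csv(os.path.join(out_dir, "scored_cohort.csv"), index=False)
        curves, lr = compare_survival(scored, survival, by="ecm_group")
        for label, curve in curves.items():
            pd.DataFrame(
                {
                    "time_months": curve.time,
                    "survival": curve.survival,
                    "at_risk": curve.at_risk,
                    "events": curve.events,
                }
            ).to_csv(os.path.join(out_dir, f"km_ecm_{label}.csv"), index=False)
        report["stages"]["tma"] = {
            "n_retained": excl.n_retained,
            "n_excluded": len(excl.excluded_ids),
            "logrank_statistic": lr.statistic,
            "logrank_p": lr.p_value,
            "scored": "scored_cohort.csv",
        }

    with open(os.path.join(out_dir, "run_report.json"), "w") as fh:
        json.dump(report, fh, indent=2)
    return report
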