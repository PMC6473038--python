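"""Run configuration for the command-line pipeline.

A run is described by a flat YAML file; CLI flags override file values.
Every random stage draws from the single ``seed`` recorded here, and each
stage writes a JSON manifest (inputs, parameters, seeds, version) next to
its artifacts so a run can be reproduced from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import FociMetaError


class ConfigError(FociMetaError):
    """Invalid run configuration; the message names the offending field."""


@dataclass
class RunConfig:
    # inputs / outputs
    foci: str | None = None
    out_dir: str = "focimeta_out"
    # clustering
    resolution_mm: float = 5.0
    cut_criterion: str = "mean"
    # composition
    alpha: float = 0.05
    correction: str = "none"
    # ALE
    fwhm_mm: float = 10.0
    n_iter: int = 200
    uncorr_p: float = 0.05
    fdr_q: float = 0.05
    extent_mm3: float = 300.0
    conjunction_order: str = "threshold_first"
    voxel_size_mm: float = 4.0
    grid_lo: tuple[float, float, float] = (-90.0, -126.0, -72.0)
    grid_hi: tuple[float, float, float] = (90.0, 90.0, 108.0)
    labels: tuple[str, str] = ("intention", "self_agency")
    validate_radius_mm: float = 5.0
    # connectivity
    voxel_p: float = 0.001
    cluster_fwe: float = 0.05
    n_perm: int = 500
    n_subjects: int = 32
    t_volumes: int = 212
    rho: float = 0.6
    # randomness
    seed: int = 0

    def validate(self) -> None:
        checks = {
            "resolution_mm": self.resolution_mm > 0,
            "alpha": 0 < self.alpha < 1,
            "fwhm_mm": self.fwhm_mm > 0,
            "n_iter": self.n_iter >= 100,
            "uncorr_p": 0 < self.uncorr_p <= 1,
            "fdr_q": 0 < self.fdr_q < 1,
            "extent_mm3": self.extent_mm3 >= 0,
            "voxel_size_mm": self.voxel_size_mm > 0,
            "voxel_p": 0 < self.voxel_p < 1,
            "cluster_fwe": 0 < self.cluster_fwe < 1,
            "n_perm": self.n_perm >= 100,
            "n_subjects": self.n_subjects >= 6,
            "t_volumes": self.t_volumes >= 20,
            "rho": -1 < self.rho < 1,
            "seed": self.seed >= 0,
            "cut_criterion": self.cut_criterion in ("mean", "max"),
            "correction": self.correction in ("none", "bh"),
            "conjunction_order": self.conjunction_order in ("threshold_first", "min_first"),
        }
        for name, ok in checks.items():
            if not ok:
                raise ConfigError(f"invalid value for config field {name!r}")


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load YAML config (if any), apply keyword overrides, validate."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise ConfigError("config file must contain a mapping")
        data.update(loaded)
    data.update({k: v for k, v in overrides.items() if v is not None})
    names = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown config field(s): {sorted(unknown)}")
    for key in ("grid_lo", "grid_hi", "labels"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    cfg = RunConfig(**data)
    cfg.validate()
    return cfg


def write_manifest(out_dir: str | Path, stage: str, cfg: RunConfig, extra: dict | None = None) -> Path:
    from . import __version__

    payload = {
        "stage": stage,
        "version": __version__,
        "config": dataclasses.asdict(cfg),
    }
    if extra:
        payload.update(extra)
    path = Path(out_dir) / f"{stage}_manifest.json"
    path.write_text(json.dumps(payload, indent=2, default=str))
    return path
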