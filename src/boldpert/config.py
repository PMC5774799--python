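"""Pipeline configuration: defaults registry, YAML loading, validation.

Every numeric default of every stage lives here, in :data:`DEFAULT_CONFIG`;
stage functions take explicit arguments and the pipeline resolves them from
the merged config.  A run always echoes its fully resolved config into the
output manifest.
"""

from __future__ import annotations

import copy
from pathlib import Path
from typing import Any

import yaml

from .forward import GAMMA_PROTON, AcquisitionParams
from .grid import VoxelGrid
from .inversion import InversionConfig
from .phantom import (
    BlobKind,
    BlobSpec,
    HRFParams,
    TaskParadigm,
    default_background_specs,
    default_bold_blobs,
    make_task_paradigm,
)

__all__ = [
    "DEFAULT_CONFIG",
    "PARADIGM_PRESETS",
    "load_config",
    "resolve_config",
    "validate_config",
    "build_grid",
    "build_acquisition",
    "build_paradigm",
    "build_hrf_params",
    "build_inversion_config",
    "build_background_specs",
    "build_bold_blobs",
]

#: Block-paradigm presets from the two standard protocols:
#: 7T: 5 cycles of {5 ON, 5 OFF} = 50 volumes; 3T: 5 cycles of
#: {15 OFF, 15 ON} plus a trailing 15 OFF = 165 volumes.
PARADIGM_PRESETS: dict[str, list[tuple[str, int]]] = {
    "7t": [("ON", 5), ("OFF", 5)] * 5,
    "3t": [("OFF", 15), ("ON", 15)] * 5 + [("OFF", 15)],
}

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "output_dir": "boldpert_out",
    "grid": {
        "shape": [64, 64, 64],
        "voxel_size_mm": [1.0, 1.0, 1.0],
        "b0_direction": [0.0, 0.0, 1.0],
    },
    "phantom": {
        "chi0": {"specs": "default", "envelope_fraction": 0.8},
        "blobs": {"specs": "default", "amplitude_ppm": 0.02},
        "noise_sd_ppm": 0.0,
    },
    "paradigm": {"preset": "7t", "pattern": None, "tr_s": 3.0},
    "hrf": {
        "peak_delay_s": 6.0,
        "undershoot_delay_s": 16.0,
        "peak_dispersion_s": 1.0,
        "undershoot_dispersion_s": 1.0,
        "peak_undershoot_ratio": 6.0,
        "kernel_length_s": 32.0,
    },
    "acquisition": {
        "b0_tesla": 7.0,
        "te_s": 0.029,
        "tr_s": 3.0,
        "gamma_rad_per_s_per_tesla": GAMMA_PROTON,
        "supersample": 4,
        "noise_sd": 0.0,
        "zero_pad": True,
    },
    "inversion": {
        "method": "tvb",
        "tkd_threshold": 0.1,
        "tv_weight": 2e-3,
        "bregman_penalty": 2e-2,
        "max_iters": 100,
        "rel_tol": 1e-4,
        "zero_pad": True,
    },
    "fmap": {
        "ref_index": 0,
        "on_threshold": 0.5,
        "z_threshold": 3.0,
        "roi_size": [5, 5, 3],
        "exclude_ref_from_metrics": True,
    },
}

_REQUIRED_SECTIONS = (
    "grid",
    "phantom",
    "paradigm",
    "hrf",
    "acquisition",
    "inversion",
    "fmap",
)


def _deep_merge(base: dict, override: dict) -> dict:
    out = copy.deepcopy(base)
    for key, value in override.items():
        if key in out and isinstance(out[key], dict) and isinstance(value, dict):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = copy.deepcopy(value)
    return out


def resolve_config(user: dict | None = None) -> dict:
    """Merge a user config over the defaults and validate the result."""
    merged = _deep_merge(DEFAULT_CONFIG, user or {})
    validate_config(merged)
    return merged


def load_config(path: str | Path) -> dict:
    """Load a YAML config file and resolve it against the defaults."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return resolve_config(user)


def validate_config(cfg: dict) -> None:
    """Schema check run before any stage: sections, types, value ranges."""
    missing = [s for s in _REQUIRED_SECTIONS if s not in cfg]
    if missing:
        raise ValueError(f"config missing sections: {missing}")
    if not isinstance(cfg.get("seed"), int):
        raise ValueError("config seed must be an integer")
    # constructing the typed objects enforces the numeric invariants
    build_grid(cfg)
    build_acquisition(cfg)
    build_paradigm(cfg)
    build_hrf_params(cfg)
    build_inversion_config(cfg)
    fmap = cfg["fmap"]
    if fmap["z_threshold"] <= 0:
        raise ValueError("fmap z_threshold must be positive")
    if not (0.0 < fmap["on_threshold"] <= 1.0):
        raise ValueError("fmap on_threshold must lie in (0, 1]")


def build_grid(cfg: dict) -> VoxelGrid:
    g = cfg["grid"]
    return VoxelGrid(
        shape=tuple(g["shape"]),
        voxel_size_mm=tuple(g["voxel_size_mm"]),
        b0_direction=tuple(g["b0_direction"]),
    )


def build_acquisition(cfg: dict) -> AcquisitionParams:
    a = cfg["acquisition"]
    return AcquisitionParams(
        b0_tesla=a["b0_tesla"],
        te_s=a["te_s"],
        tr_s=a["tr_s"],
        gamma_rad_per_s_per_tesla=a["gamma_rad_per_s_per_tesla"],
        supersample=a["supersample"],
    )


def build_paradigm(cfg: dict) -> TaskParadigm:
    p = cfg["paradigm"]
    if p.get("pattern"):
        pattern = [(str(s).upper(), int(n)) for s, n in p["pattern"]]
    else:
        preset = str(p.get("preset", "7t")).lower()
        if preset not in PARADIGM_PRESETS:
            raise ValueError(
                f"unknown paradigm preset {preset!r}; options: {sorted(PARADIGM_PRESETS)}"
            )
        pattern = PARADIGM_PRESETS[preset]
    return make_task_paradigm(pattern, tr_s=p["tr_s"])


def build_hrf_params(cfg: dict) -> HRFParams:
    return HRFParams(**cfg["hrf"])


def build_inversion_config(cfg: dict) -> InversionConfig:
    return InversionConfig(**cfg["inversion"])


def build_background_specs(cfg: dict, grid: VoxelGrid) -> list[BlobSpec]:
    spec = cfg["phantom"]["chi0"]["specs"]
    if spec == "default":
        return default_background_specs(grid)
    return [
        BlobSpec(
            center_mm=tuple(s["center_mm"]),
            radius_mm=s["radius_mm"],
            amplitude_ppm=s["amplitude_ppm"],
            kind=BlobKind.STATIC,
        )
        for s in spec
    ]


def build_bold_blobs(cfg: dict, grid: VoxelGrid) -> list[BlobSpec]:
    section = cfg["phantom"]["blobs"]
    spec = section["specs"]
    if spec == "default":
        return default_bold_blobs(grid, amplitude_ppm=section["amplitude_ppm"])
    return [
        BlobSpec(
            center_mm=tuple(s["center_mm"]),
            radius_mm=s["radius_mm"],
            amplitude_ppm=s["amplitude_ppm"],
            kind=BlobKind.TASK_LOCKED,
        )
        for s in spec
    ]
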