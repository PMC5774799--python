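"""NIfTI I/O, sidecar metadata and run manifests.

Complex T2* data is stored as a magnitude/phase NIfTI pair (the format raw
GRE-EPI exports ship in) rather than a complex-valued NIfTI, for
interoperability.  Voxel size is carried in the NIfTI affine; acquisition
parameters and wrapped/unwrapped state travel in a JSON sidecar.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import nibabel as nib
import numpy as np

from .forward import AcquisitionParams, ComplexT2Series
from .grid import VoxelGrid

__all__ = [
    "read_nifti_volume",
    "write_nifti_volume",
    "write_complex_series",
    "read_complex_series",
    "write_regressor",
    "read_regressor",
    "RunManifest",
    "file_sha256",
]


def write_nifti_volume(
    path: str | Path,
    data: np.ndarray,
    grid: VoxelGrid,
    sidecar: dict | None = None,
) -> Path:
    """Write a 3D/4D array as NIfTI-1 with voxel size in the affine.

    An optional JSON sidecar (``<stem>.json``) records stage metadata such
    as acquisition parameters or the wrapped flag.
    """
    path = Path(path)
    arr = np.asarray(data)
    if arr.shape[:3] != grid.shape:
        raise ValueError(
            f"data shape {arr.shape} does not match grid {grid.shape}"
        )
    affine = np.diag(list(grid.voxel_size_mm) + [1.0])
    img = nib.Nifti1Image(arr.astype(np.float64), affine)
    img.header.set_zooms(grid.voxel_size_mm + ((1.0,) if arr.ndim == 4 else ()))
    nib.save(img, str(path))
    if sidecar is not None:
        sidecar_path = path.with_suffix("").with_suffix(".json") \
            if path.name.endswith(".nii.gz") else path.with_suffix(".json")
        with open(sidecar_path, "w") as fh:
            json.dump(sidecar, fh, indent=2, sort_keys=True)
    return path


def read_nifti_volume(
    path: str | Path, expected_grid: VoxelGrid | None = None
) -> tuple[np.ndarray, VoxelGrid, dict]:
    """Read a NIfTI volume; returns (data, grid, sidecar).

    If ``expected_grid`` is given, a header/grid mismatch raises an error
    naming both shapes.  For phase data, a ``wrapped`` flag is inferred when
    absent from the sidecar: wrapped iff all values lie in [-pi, pi).
    """
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    zooms = img.header.get_zooms()[:3]
    grid = VoxelGrid(shape=data.shape[:3], voxel_size_mm=tuple(float(z) for z in zooms))
    if expected_grid is not None and not expected_grid.same_geometry(grid):
        raise ValueError(
            f"NIfTI grid {grid.shape}@{grid.voxel_size_mm} does not match "
            f"expected {expected_grid.shape}@{expected_grid.voxel_size_mm}"
        )
    sidecar_path = path.with_suffix("").with_suffix(".json") \
        if path.name.endswith(".nii.gz") else path.with_suffix(".json")
    sidecar: dict = {}
    if sidecar_path.exists():
        with open(sidecar_path) as fh:
            sidecar = json.load(fh)
    if "wrapped" not in sidecar:
        sidecar["wrapped"] = bool(data.min() >= -np.pi and data.max() < np.pi)
    return data, grid, sidecar


def write_complex_series(
    stem: str | Path, series: ComplexT2Series
) -> tuple[Path, Path]:
    """Write a complex T2* series as ``<stem>_mag.nii.gz`` / ``<stem>_phs.nii.gz``."""
    stem = Path(stem)
    acq = series.acq
    sidecar = {
        "b0_tesla": acq.b0_tesla,
        "te_s": acq.te_s,
        "tr_s": acq.tr_s,
        "gamma_rad_per_s_per_tesla": acq.gamma_rad_per_s_per_tesla,
        "supersample": acq.supersample,
    }
    mag_path = stem.parent / (stem.name + "_mag.nii.gz")
    phs_path = stem.parent / (stem.name + "_phs.nii.gz")
    write_nifti_volume(mag_path, series.magnitude, series.grid, sidecar)
    write_nifti_volume(
        phs_path, series.phase, series.grid, {**sidecar, "wrapped": True}
    )
    return mag_path, phs_path


def read_complex_series(
    mag_path: str | Path, phs_path: str | Path
) -> ComplexT2Series:
    """Rebuild a complex series from a magnitude/phase NIfTI pair."""
    mag, grid_m, sidecar = read_nifti_volume(mag_path)
    phs, grid_p, _ = read_nifti_volume(phs_path)
    if mag.shape != phs.shape:
        raise ValueError(
            f"magnitude shape {mag.shape} does not match phase shape {phs.shape}"
        )
    acq = AcquisitionParams(
        b0_tesla=sidecar.get("b0_tesla", 7.0),
        te_s=sidecar.get("te_s", 0.029),
        tr_s=sidecar.get("tr_s", 3.0),
        gamma_rad_per_s_per_tesla=sidecar.get(
            "gamma_rad_per_s_per_tesla", 2.6752218744e8
        ),
        supersample=sidecar.get("supersample", 1),
    )
    return ComplexT2Series(grid_m, mag * np.exp(1j * phs), acq)


def write_regressor(path: str | Path, values: np.ndarray) -> Path:
    """Plain-text two-column (index, value) regressor/paradigm file."""
    path = Path(path)
    with open(path, "w") as fh:
        for i, v in enumerate(np.asarray(values, dtype=float)):
            fh.write(f"{i}\t{v:.12g}\n")
    return path


def read_regressor(path: str | Path) -> np.ndarray:
    values = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if len(parts) >= 2:
                values.append(float(parts[1]))
    return np.asarray(values)


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Record of a pipeline run: stages, output hashes, parameter echoes.

    ``timestamps`` are informational only; determinism comparisons between
    reruns are made on ``stages``, ``files`` and ``config``.
    """

    config: dict = dc_field(default_factory=dict)
    stages: dict = dc_field(default_factory=dict)
    files: dict = dc_field(default_factory=dict)
    timestamps: dict = dc_field(default_factory=dict)

    def record_stage(self, name: str, **info) -> None:
        self.stages[name] = info
        self.timestamps[name] = time.time()

    def record_file(self, name: str, path: str | Path) -> None:
        self.files[name] = {"path": str(path), "sha256": file_sha256(path)}

    def deterministic_view(self) -> dict:
        """The portion of the manifest that must be identical across reruns
        with equal config and seed: stage records and content hashes (output
        locations and timestamps may differ)."""
        hashes = {name: info["sha256"] for name, info in self.files.items()}
        cfg = {k: v for k, v in self.config.items() if k != "output_dir"}
        return {"config": cfg, "stages": self.stages, "files": hashes}

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "config": self.config,
            "stages": self.stages,
            "files": self.files,
            "timestamps": self.timestamps,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            config=payload.get("config", {}),
            stages=payload.get("stages", {}),
            files=payload.get("files", {}),
            timestamps=payload.get("timestamps", {}),
        )
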