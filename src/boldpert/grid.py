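"""Voxel-grid geometry shared by every volume in the pipeline.

A :class:`VoxelGrid` fixes the array shape, the physical voxel size and the
direction of the main field B0.  All Fourier-space operators (dipole kernel,
Laplacian) derive their discrete frequency grids from it, so that forward and
inverse stages are guaranteed to share one convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VoxelGrid"]

_MIN_DIM = 8  # FFT-based operators need a few samples per axis to be meaningful


@dataclass(frozen=True)
class VoxelGrid:
    """Geometry contract for all volumes.

    Parameters
    ----------
    shape :
        Array shape ``(nx, ny, nz)``; every entry must be >= 8.
    voxel_size_mm :
        Physical edge lengths of one voxel in millimetres.
    b0_direction :
        Unit vector of the main field in array coordinates.  Defaults to the
        third array axis (+z), matching an axial acquisition with no slice
        obliquity.
    """

    shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    b0_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        shape = tuple(int(n) for n in self.shape)
        vox = tuple(float(v) for v in self.voxel_size_mm)
        b0 = np.asarray(self.b0_direction, dtype=float)
        if len(shape) != 3 or any(n < _MIN_DIM for n in shape):
            raise ValueError(
                f"grid shape must be 3 entries, each >= {_MIN_DIM}; got {shape}"
            )
        if len(vox) != 3 or any(v <= 0 for v in vox):
            raise ValueError(f"voxel sizes must be positive; got {vox}")
        norm = float(np.linalg.norm(b0))
        if abs(norm - 1.0) > 1e-12:
            if norm == 0:
                raise ValueError("b0_direction must be a nonzero vector")
            b0 = b0 / norm
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "voxel_size_mm", vox)
        object.__setattr__(self, "b0_direction", tuple(float(c) for c in b0))

    # -- derived geometry ---------------------------------------------------

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        return tuple(n * v for n, v in zip(self.shape, self.voxel_size_mm))

    def coordinate_arrays_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-centre coordinates in mm, origin at the grid centre."""
        axes = [
            (np.arange(n) - (n - 1) / 2.0) * v
            for n, v in zip(self.shape, self.voxel_size_mm)
        ]
        return tuple(np.meshgrid(*axes, indexing="ij"))

    def frequency_arrays(
        self, shape: tuple[int, int, int] | None = None
    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Discrete spatial-frequency grids (cycles/mm) for ``numpy.fft``.

        ``shape`` overrides the grid shape (used by zero-padded transforms);
        voxel size is kept so padded and unpadded operators agree on physical
        frequency.
        """
        shape = self.shape if shape is None else shape
        axes = [
            np.fft.fftfreq(n, d=v) for n, v in zip(shape, self.voxel_size_mm)
        ]
        return tuple(np.meshgrid(*axes, indexing="ij"))

    def supersampled(self, factor: int) -> "VoxelGrid":
        """Grid refined by an integer factor per axis (same physical extent)."""
        if int(factor) < 1:
            raise ValueError("supersampling factor must be >= 1")
        f = int(factor)
        return VoxelGrid(
            shape=tuple(n * f for n in self.shape),
            voxel_size_mm=tuple(v / f for v in self.voxel_size_mm),
            b0_direction=self.b0_direction,
        )

    def same_geometry(self, other: "VoxelGrid") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.voxel_size_mm, other.voxel_size_mm)
            and np.allclose(self.b0_direction, other.b0_direction)
        )
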