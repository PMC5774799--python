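"""Phase-domain processing of the complex T2* timeseries.

Three operations connect the measured wrapped phase to field estimates:

* **Complex division** extracts the dynamic phase perturbation
  ``dP[r,t] = Arg(exp(i P[r,t]) / exp(i P_ref[r]))`` — exact whenever the
  true perturbation magnitude stays below pi, regardless of how severely
  the static background phase is wrapped.  It removes the static phase
  background entirely and needs no spatial unwrapping.
* **Laplacian unwrapping** recovers a smooth unwrapped phase from a wrapped
  3D volume via ``P_unwrap = IFT{ FT{cos P * IFT(k^2 FT sin P) -
  sin P * IFT(k^2 FT cos P)} / k^2 }`` and, as a side effect, annihilates
  harmonic (Laplacian-free) background components such as linear ramps.
* **Field from phase** is the linear inverse of the first-order phase
  imaging model: ``b = P / (gamma T_E)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .forward import AcquisitionParams, FieldMap, FieldSeries, wrap_phase
from .grid import VoxelGrid

__all__ = [
    "PhaseVolume",
    "DeltaPhaseSeries",
    "complex_divide_phase",
    "laplacian_unwrap",
    "unwrap_series",
    "phase_to_field",
]


@dataclass(frozen=True)
class PhaseVolume:
    """A 3D phase image in radians, wrapped into [-pi, pi) or unwrapped."""

    grid: VoxelGrid
    values_rad: np.ndarray
    wrapped: bool

    def __post_init__(self) -> None:
        arr = np.asarray(self.values_rad, dtype=float)
        if arr.shape != self.grid.shape:
            raise ValueError(
                f"phase shape {arr.shape} does not match grid {self.grid.shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValueError("phase values must be finite")
        if self.wrapped and (arr.min() < -np.pi or arr.max() >= np.pi):
            raise ValueError("wrapped phase must lie in [-pi, pi)")
        object.__setattr__(self, "values_rad", arr)


@dataclass(frozen=True)
class DeltaPhaseSeries:
    """4D BOLD phase perturbation dP[r, t] relative to a reference frame."""

    grid: VoxelGrid
    values_rad: np.ndarray
    ref_index: int
    tr_s: float = 1.0

    def __post_init__(self) -> None:
        arr = np.asarray(self.values_rad, dtype=float)
        if arr.ndim != 4 or arr.shape[:3] != self.grid.shape:
            raise ValueError(
                f"series shape {arr.shape} does not match grid {self.grid.shape}"
            )
        if not (0 <= self.ref_index < arr.shape[3]):
            raise ValueError(
                f"ref_index {self.ref_index} outside [0, {arr.shape[3]})"
            )
        if arr.min() < -np.pi or arr.max() >= np.pi:
            raise ValueError("phase differences must lie in [-pi, pi)")
        if np.max(np.abs(arr[..., self.ref_index])) != 0.0:
            raise ValueError("reference frame must be identically zero")
        object.__setattr__(self, "values_rad", arr)

    @property
    def n_t(self) -> int:
        return self.values_rad.shape[3]


def complex_divide_phase(
    phase_series: np.ndarray,
    ref_index: int = 0,
    tr_s: float = 1.0,
    grid: VoxelGrid | None = None,
) -> DeltaPhaseSeries:
    """Extract dP[r, t] = Arg(exp(iP[r, t]) / exp(iP_ref[r])).

    The phasor ratio subtracts phases modulo 2 pi, so the static (possibly
    severely wrapped) background cancels exactly; the result is correct
    whenever the true perturbation lies in (-pi, pi).  The reference frame
    maps to exactly zero.
    """
    arr = np.asarray(phase_series, dtype=float)
    if arr.ndim != 4:
        raise ValueError("phase series must be 4D (x, y, z, t)")
    n_t = arr.shape[3]
    if not (0 <= ref_index < n_t):
        raise ValueError(f"ref_index {ref_index} outside [0, {n_t})")
    delta = wrap_phase(arr - arr[..., ref_index][..., None])
    delta[..., ref_index] = 0.0
    if grid is None:
        grid = VoxelGrid(shape=arr.shape[:3])
    elif grid.shape != arr.shape[:3]:
        raise ValueError(
            f"grid shape {grid.shape} does not match series {arr.shape[:3]}"
        )
    return DeltaPhaseSeries(grid, delta, ref_index=ref_index, tr_s=tr_s)


def _k2_grid(grid: VoxelGrid) -> np.ndarray:
    kx, ky, kz = grid.frequency_arrays()
    return kx**2 + ky**2 + kz**2


def laplacian_unwrap(wrapped: PhaseVolume) -> PhaseVolume:
    """Laplacian phase unwrapping of a wrapped 3D volume.

    Computes the Laplacian of the true phase from sin/cos of the wrapped
    phase (both continuous across wraps), then inverts the Laplacian in
    Fourier space with the zero-frequency coefficient set to 0 — the output
    is therefore mean-free.  Harmonic input components (for which the true
    Laplacian vanishes) are removed.
    """
    if not wrapped.wrapped:
        raise ValueError("laplacian_unwrap expects a wrapped phase volume")
    p = wrapped.values_rad
    k2 = _k2_grid(wrapped.grid)
    sin_p, cos_p = np.sin(p), np.cos(p)
    lap_sin = np.fft.ifftn(k2 * np.fft.fftn(sin_p)).real
    lap_cos = np.fft.ifftn(k2 * np.fft.fftn(cos_p)).real
    numerator = np.fft.fftn(cos_p * lap_sin - sin_p * lap_cos)
    with np.errstate(divide="ignore", invalid="ignore"):
        quotient = np.where(k2 > 0, numerator / np.where(k2 > 0, k2, 1.0), 0.0)
    unwrapped = np.fft.ifftn(quotient).real
    return PhaseVolume(wrapped.grid, unwrapped, wrapped=False)


def unwrap_series(phase_series: np.ndarray, grid: VoxelGrid) -> np.ndarray:
    """Frame-wise Laplacian unwrapping of a 4D wrapped phase series."""
    arr = np.asarray(phase_series, dtype=float)
    if arr.ndim != 4:
        raise ValueError("phase series must be 4D (x, y, z, t)")
    out = np.empty_like(arr)
    for t in range(arr.shape[3]):
        frame = PhaseVolume(grid, arr[..., t], wrapped=True)
        out[..., t] = laplacian_unwrap(frame).values_rad
    return out


def phase_to_field(
    phase: PhaseVolume | DeltaPhaseSeries | np.ndarray,
    acq: AcquisitionParams,
    grid: VoxelGrid | None = None,
    tr_s: float | None = None,
) -> FieldMap | FieldSeries:
    """Linear field estimate b = P / (gamma T_E).

    Accepts an unwrapped :class:`PhaseVolume` (3D), a
    :class:`DeltaPhaseSeries` (4D, needs no unwrapping by construction), or
    a bare array with an explicit ``grid``.
    """
    if acq.te_s <= 0:
        raise ValueError("TE must be positive")
    scale = 1.0 / acq.gamma_te
    if isinstance(phase, PhaseVolume):
        if phase.wrapped:
            raise ValueError("phase must be unwrapped before field conversion")
        return FieldMap(phase.grid, scale * phase.values_rad)
    if isinstance(phase, DeltaPhaseSeries):
        return FieldSeries(
            phase.grid, scale * phase.values_rad, tr_s=phase.tr_s
        )
    arr = np.asarray(phase, dtype=float)
    if grid is None:
        raise ValueError("a grid is required when passing a bare array")
    if arr.ndim == 3:
        return FieldMap(grid, scale * arr)
    if arr.ndim == 4:
        return FieldSeries(grid, scale * arr, tr_s=tr_s or 1.0)
    raise ValueError("phase array must be 3D or 4D")
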