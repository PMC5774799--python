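"""Forward model: susceptibility -> fieldmap -> complex T2* timeseries.

Two physical stages:

1. **Magnetization / dipole convolution.**  Under linear magnetization the
   z-component of the induced field is ``b = B0 * (chi * 1e-6) (*) h`` with
   the point-dipole kernel ``h(r) = (3 z^2 - r^2) / (4 pi r^5)``.  The
   convolution is evaluated in Fourier space with the kernel
   ``D(k) = 1/3 - k_z^2 / |k|^2`` (``D(0) = 0``: the field is mean-free, a
   uniform susceptibility offset being unobservable in phase).

2. **Intravoxel dephasing.**  A gradient-echo voxel signal is the normalized
   average of unit spin phasors over the voxel volume,
   ``C[r] = (1/|Omega|) sum_{r' in Omega(r)} exp(i gamma T_E b(r'))``,
   so ``C[T_E = 0] = 1`` and ``|C| <= 1`` always.  The continuous voxel
   interior is approximated by an integer supersampling of the grid.

The first-order Taylor diagnostics of magnitude and phase are provided as
separate operations; note the printed first-order magnitude approximation
``A ~ 1 + (gamma T_E)^2 <b^2> / 2`` exceeds 1 while exact dephasing always
attenuates (|C| <= 1) — it is a diagnostic of the quadratic nonlinearity,
not a usable forward model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import VoxelGrid
from .phantom import SusceptibilitySeries, SusceptibilityVolume

__all__ = [
    "GAMMA_PROTON",
    "AcquisitionParams",
    "FieldMap",
    "FieldSeries",
    "DipoleKernelK",
    "ComplexT2Series",
    "wrap_phase",
    "dipole_kernel_spatial",
    "dipole_kernel_kspace",
    "chi_to_field",
    "chi_series_to_field",
    "sphere_field_analytic",
    "dephase_to_complex",
    "simulate_t2star_series",
    "magnitude_first_order",
    "phase_taylor",
]

#: Proton gyromagnetic ratio, rad s^-1 T^-1.
GAMMA_PROTON = 2.6752218744e8

PPM = 1e-6  # chi is stored in ppm; SI dimensionless value = ppm * 1e-6


@dataclass(frozen=True)
class AcquisitionParams:
    """Gradient-echo acquisition parameters (7T protocol defaults)."""

    b0_tesla: float = 7.0
    te_s: float = 0.029
    tr_s: float = 3.0
    gamma_rad_per_s_per_tesla: float = GAMMA_PROTON
    supersample: int = 4

    def __post_init__(self) -> None:
        if self.b0_tesla <= 0 or self.te_s <= 0 or self.tr_s <= 0:
            raise ValueError("B0, TE and TR must be positive")
        if self.te_s >= self.tr_s:
            raise ValueError("TE must be smaller than TR")
        if self.gamma_rad_per_s_per_tesla <= 0:
            raise ValueError("gamma must be positive")
        if int(self.supersample) < 1:
            raise ValueError("supersample must be >= 1")

    @property
    def gamma_te(self) -> float:
        """Phase accrued per tesla at the echo time: gamma * T_E (rad/T)."""
        return self.gamma_rad_per_s_per_tesla * self.te_s


@dataclass(frozen=True)
class FieldMap:
    """z-component field perturbation (tesla), mean-free by convention."""

    grid: VoxelGrid
    values_tesla: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values_tesla, dtype=float)
        if arr.shape != self.grid.shape:
            raise ValueError(
                f"field shape {arr.shape} does not match grid {self.grid.shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValueError("field values must be finite")
        peak = np.max(np.abs(arr))
        if peak > 0 and abs(arr.mean()) > 1e-9 * peak:
            raise ValueError("fieldmap must be mean-free (D(0)=0 convention)")
        object.__setattr__(self, "values_tesla", arr)


@dataclass(frozen=True)
class FieldSeries:
    """4D (x, y, z, t) field perturbation series in tesla."""

    grid: VoxelGrid
    values_tesla: np.ndarray
    tr_s: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.values_tesla, dtype=float)
        if arr.ndim != 4 or arr.shape[:3] != self.grid.shape:
            raise ValueError(
                f"field series shape {arr.shape} does not match grid {self.grid.shape}"
            )
        object.__setattr__(self, "values_tesla", arr)

    @property
    def n_t(self) -> int:
        return self.values_tesla.shape[3]

    def frame(self, t: int) -> FieldMap:
        return FieldMap(self.grid, self.values_tesla[..., t])


@dataclass(frozen=True)
class DipoleKernelK:
    """Fourier-domain dipole kernel D(k) = 1/3 - k_z^2/|k|^2 on a grid."""

    grid: VoxelGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.min() < -2.0 / 3.0 - 1e-12 or arr.max() > 1.0 / 3.0 + 1e-12:
            raise ValueError("dipole kernel values must lie in [-2/3, 1/3]")
        object.__setattr__(self, "values", arr)


@dataclass(frozen=True)
class ComplexT2Series:
    """4D complex T2* data C[r, t] with magnitude and wrapped-phase views."""

    grid: VoxelGrid
    complex_values: np.ndarray
    acq: AcquisitionParams

    def __post_init__(self) -> None:
        arr = np.asarray(self.complex_values, dtype=complex)
        if arr.ndim != 4 or arr.shape[:3] != self.grid.shape:
            raise ValueError(
                f"T2* series shape {arr.shape} does not match grid {self.grid.shape}"
            )
        object.__setattr__(self, "complex_values", arr)

    @property
    def n_t(self) -> int:
        return self.complex_values.shape[3]

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.complex_values)

    @property
    def phase(self) -> np.ndarray:
        """Wrapped phase P[r, t] in [-pi, pi)."""
        return wrap_phase(np.angle(self.complex_values))


def wrap_phase(phase: np.ndarray) -> np.ndarray:
    """Fold phase into the half-open interval [-pi, pi)."""
    w = np.mod(np.asarray(phase, dtype=float) + np.pi, 2.0 * np.pi) - np.pi
    # floating-point remainders can round up to exactly +pi; fold them back
    return np.where(w >= np.pi, w - 2.0 * np.pi, w)


# ---------------------------------------------------------------------------
# dipole kernel
# ---------------------------------------------------------------------------


def dipole_kernel_spatial(
    offset_mm: np.ndarray | tuple[float, float, float],
    b0_direction: tuple[float, float, float] = (0.0, 0.0, 1.0),
) -> float | np.ndarray:
    """Point-dipole spatial kernel h(r) = (3 z^2 - r^2) / (4 pi r^5).

    ``z`` is the offset component along the B0 direction.  Accepts a single
    offset or an (..., 3) array; the offset must be nonzero (the kernel is
    singular at the origin).
    """
    off = np.asarray(offset_mm, dtype=float)
    single = off.ndim == 1
    off = np.atleast_2d(off)
    r = np.linalg.norm(off, axis=-1)
    if np.any(r == 0):
        raise ValueError("dipole kernel is singular at zero offset")
    z = off @ np.asarray(b0_direction, dtype=float)
    values = (3.0 * z**2 - r**2) / (4.0 * np.pi * r**5)
    return float(values[0]) if single else values


def dipole_kernel_kspace(
    grid: VoxelGrid, shape: tuple[int, int, int] | None = None
) -> DipoleKernelK:
    """Fourier dipole kernel D(k) = 1/3 - k_z^2/|k|^2 with D(0) = 0.

    ``k_z`` is the projection of k onto the B0 direction, so oblique fields
    are supported.  ``shape`` overrides the grid shape for zero-padded
    transforms.
    """
    kx, ky, kz = grid.frequency_arrays(shape)
    bx, by, bz = grid.b0_direction
    k_par = kx * bx + ky * by + kz * bz
    k2 = kx**2 + ky**2 + kz**2
    with np.errstate(divide="ignore", invalid="ignore"):
        d = 1.0 / 3.0 - np.where(k2 > 0, k_par**2 / np.where(k2 > 0, k2, 1.0), 0.0)
    d.flat[0] = 0.0  # zero-frequency convention: mean-free field
    return DipoleKernelK(grid, d)


# ---------------------------------------------------------------------------
# susceptibility -> field
# ---------------------------------------------------------------------------


def _padded_shape(shape: tuple[int, int, int]) -> tuple[int, int, int]:
    return tuple(2 * n for n in shape)


def _field_from_chi_array(
    chi_ppm: np.ndarray, grid: VoxelGrid, b0_tesla: float, zero_pad: bool
) -> np.ndarray:
    if not np.all(np.isfinite(chi_ppm)):
        raise ValueError("susceptibility must be finite")
    shape = grid.shape
    work_shape = _padded_shape(shape) if zero_pad else shape
    kernel = dipole_kernel_kspace(grid, work_shape).values
    if zero_pad:
        work = np.zeros(work_shape, dtype=float)
        work[: shape[0], : shape[1], : shape[2]] = chi_ppm
    else:
        work = chi_ppm
    field = np.fft.ifftn(kernel * np.fft.fftn(work)).real
    field = field[: shape[0], : shape[1], : shape[2]]
    field = b0_tesla * PPM * field
    return field - field.mean()  # restore the mean-free convention after cropping


def chi_to_field(
    chi: SusceptibilityVolume,
    acq: AcquisitionParams,
    zero_pad: bool = True,
) -> FieldMap:
    """Induced z-field b = B0 * (chi*1e-6) (*) h via Fourier multiplication.

    Zero padding to twice the grid (default on) suppresses the circular
    wrap-around of the FFT convolution; the result is cropped back and
    re-centred to mean zero.
    """
    field = _field_from_chi_array(chi.values_ppm, chi.grid, acq.b0_tesla, zero_pad)
    return FieldMap(chi.grid, field)


def chi_series_to_field(
    chi: SusceptibilitySeries, acq: AcquisitionParams, zero_pad: bool = True
) -> FieldSeries:
    """Frame-by-frame dipole convolution of a 4D susceptibility series."""
    out = np.empty_like(chi.values_ppm)
    for t in range(chi.n_t):
        out[..., t] = _field_from_chi_array(
            chi.values_ppm[..., t], chi.grid, acq.b0_tesla, zero_pad
        )
    return FieldSeries(chi.grid, out, tr_s=chi.tr_s)


def sphere_field_analytic(
    grid: VoxelGrid,
    center_mm: tuple[float, float, float],
    radius_mm: float,
    dchi_ppm: float,
    acq: AcquisitionParams,
) -> FieldMap:
    """Closed-form exterior field of a uniformly magnetized sphere.

    Exterior: ``B0 * (dchi/3) (a/r)^3 (3 cos^2 theta - 1)`` with theta the
    polar angle from the B0 axis; interior: 0, matching the mean-free
    Fourier-kernel convention.  Serves as the independent analytic oracle
    for :func:`chi_to_field`.
    """
    if radius_mm <= 0:
        raise ValueError("sphere radius must be positive")
    xx, yy, zz = grid.coordinate_arrays_mm()
    cx, cy, cz = center_mm
    dx, dy, dz = xx - cx, yy - cy, zz - cz
    r = np.sqrt(dx**2 + dy**2 + dz**2)
    bx, by, bz = grid.b0_direction
    z_par = dx * bx + dy * by + dz * bz
    exterior = r > radius_mm
    field = np.zeros(grid.shape, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        cos2 = np.where(r > 0, (z_par / np.where(r > 0, r, 1.0)) ** 2, 0.0)
        ext = (
            acq.b0_tesla
            * (dchi_ppm * PPM / 3.0)
            * (radius_mm / np.where(r > 0, r, 1.0)) ** 3
            * (3.0 * cos2 - 1.0)
        )
    field[exterior] = ext[exterior]
    # no mean subtraction: the analytic exterior field integrates to ~0 already
    return FieldMap(grid, field - field.mean())


# ---------------------------------------------------------------------------
# field -> complex T2* signal
# ---------------------------------------------------------------------------


def _block_mean(fine: np.ndarray, factor: int) -> np.ndarray:
    """Average a fine array over non-overlapping factor^3 blocks."""
    nx, ny, nz = (n // factor for n in fine.shape)
    return (
        fine.reshape(nx, factor, ny, factor, nz, factor)
        .mean(axis=(1, 3, 5))
    )


def dephase_to_complex(
    field_fine: FieldMap, acq: AcquisitionParams, coarse_grid: VoxelGrid
) -> np.ndarray:
    """Intravoxel dephasing: average unit phasors over each voxel's block.

    ``field_fine`` lives on ``coarse_grid.supersampled(f)`` for an integer
    ``f``; the returned complex frame is on the coarse grid with
    ``C = <exp(i gamma T_E b)>_Omega``, so ``|C| <= 1`` and ``C = 1`` at
    ``T_E = 0``.
    """
    fine_shape = field_fine.grid.shape
    coarse_shape = coarse_grid.shape
    factors = set(f // c for f, c in zip(fine_shape, coarse_shape))
    if len(factors) != 1 or any(
        f != c * next(iter(factors)) for f, c in zip(fine_shape, coarse_shape)
    ):
        raise ValueError(
            f"fine shape {fine_shape} is not an integer multiple of {coarse_shape}"
        )
    factor = next(iter(factors))
    phasors = np.exp(1j * acq.gamma_te * field_fine.values_tesla)
    return _block_mean(phasors, factor)


def _upsample_nearest(arr: np.ndarray, factor: int) -> np.ndarray:
    if factor == 1:
        return arr
    return np.repeat(np.repeat(np.repeat(arr, factor, 0), factor, 1), factor, 2)


def simulate_t2star_series(
    chi_series: SusceptibilitySeries,
    acq: AcquisitionParams,
    noise_sd: float = 0.0,
    seed: int | None = None,
    zero_pad: bool = True,
) -> ComplexT2Series:
    """Simulate the complex T2* timeseries from a dynamic susceptibility source.

    Per frame: nearest-neighbour upsampling of chi to the supersampled grid
    (exact for piecewise-constant phantoms), dipole convolution on the fine
    grid, intravoxel phasor averaging back to the acquisition grid, and
    optional additive complex Gaussian noise (sd per real/imag channel).
    """
    if noise_sd < 0:
        raise ValueError("noise standard deviation must be nonnegative")
    grid = chi_series.grid
    factor = int(acq.supersample)
    fine_grid = grid.supersampled(factor)
    n_t = chi_series.n_t
    out = np.empty(grid.shape + (n_t,), dtype=complex)
    for t in range(n_t):
        chi_fine = _upsample_nearest(chi_series.values_ppm[..., t], factor)
        field_fine = _field_from_chi_array(chi_fine, fine_grid, acq.b0_tesla, zero_pad)
        out[..., t] = dephase_to_complex(FieldMap(fine_grid, field_fine), acq, grid)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        out = out + rng.normal(0.0, noise_sd, out.shape) + 1j * rng.normal(
            0.0, noise_sd, out.shape
        )
    return ComplexT2Series(grid, out, acq)


# ---------------------------------------------------------------------------
# Taylor diagnostics
# ---------------------------------------------------------------------------


def magnitude_first_order(
    field_fine: FieldMap, acq: AcquisitionParams, coarse_grid: VoxelGrid
) -> np.ndarray:
    """First-order magnitude approximation A ~ 1 + (gamma T_E)^2 <b^2> / 2.

    Implemented exactly as printed.  Note it yields A >= 1, whereas exact
    intravoxel dephasing gives |C| <= 1: the approximation captures the
    quadratic (irreversible) nonlinearity of the magnitude channel, and its
    sign disagrees with the exact attenuation — a documented diagnostic.
    """
    fine_shape = field_fine.grid.shape
    factor = fine_shape[0] // coarse_grid.shape[0]
    b2 = _block_mean(field_fine.values_tesla**2, factor)
    return 1.0 + 0.5 * acq.gamma_te**2 * b2


def phase_taylor(
    field_fine: FieldMap,
    acq: AcquisitionParams,
    coarse_grid: VoxelGrid,
    order: int = 1,
) -> np.ndarray:
    """Taylor phase approximations of the voxel signal.

    order 1: ``gamma T_E <b>`` (the linear phase-imaging model);
    order 2: ``arctan(gamma T_E <b> / (1 - (gamma T_E)^2 <b^2> / 2))``.
    """
    if order not in (1, 2):
        raise ValueError(f"order must be 1 or 2, got {order}")
    fine_shape = field_fine.grid.shape
    factor = fine_shape[0] // coarse_grid.shape[0]
    b_mean = _block_mean(field_fine.values_tesla, factor)
    if order == 1:
        return acq.gamma_te * b_mean
    b2_mean = _block_mean(field_fine.values_tesla**2, factor)
    return np.arctan2(
        acq.gamma_te * b_mean, 1.0 - 0.5 * acq.gamma_te**2 * b2_mean
    )
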