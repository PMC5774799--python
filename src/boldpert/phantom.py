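"""Synthetic susceptibility phantom, task paradigm and hemodynamic regressor.

The phantom emulates the structure of a task GRE-EPI experiment: a static
bipolar susceptibility background chi0 (tissue-like, within roughly
[-0.5, 0.5] ppm), plus a weak task-locked dynamic perturbation dchi (within
roughly [-0.03, 0.03] ppm) whose timecourse follows the HRF-convolved block
paradigm.  The perturbation model is additive,

    chi(r, t) = chi0(r) + dchi(r, t),   |dchi| << |chi0|,

which is the premise the whole forward/inverse pipeline rests on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .grid import VoxelGrid

__all__ = [
    "BlobKind",
    "BlobSpec",
    "TaskParadigm",
    "HRFParams",
    "Regressor",
    "SusceptibilityVolume",
    "SusceptibilitySeries",
    "make_background_chi",
    "make_task_paradigm",
    "canonical_hrf",
    "effective_regressor",
    "classify_states",
    "make_bold_perturbation",
    "compose_chi_series",
    "default_background_specs",
    "default_bold_blobs",
]


class BlobKind(str, Enum):
    STATIC = "static"
    TASK_LOCKED = "task_locked"


@dataclass(frozen=True)
class BlobSpec:
    """A spherical susceptibility inclusion.

    ``center_mm`` is measured from the grid centre; ``amplitude_ppm`` is
    signed (positive for ferritin/deoxyhaemoglobin-like inclusions, negative
    for water/oxyhaemoglobin-like ones).
    """

    center_mm: tuple[float, float, float]
    radius_mm: float
    amplitude_ppm: float
    kind: BlobKind = BlobKind.STATIC

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError(f"blob radius must be positive, got {self.radius_mm}")
        if not np.isfinite(self.amplitude_ppm):
            raise ValueError("blob amplitude must be finite")

    def fits_inside(self, grid: VoxelGrid) -> bool:
        half = np.asarray(grid.extent_mm) / 2.0
        c = np.asarray(self.center_mm, dtype=float)
        return bool(np.all(np.abs(c) + self.radius_mm <= half))

    def support(self, grid: VoxelGrid) -> np.ndarray:
        """Boolean mask of voxel centres inside the sphere."""
        xx, yy, zz = grid.coordinate_arrays_mm()
        cx, cy, cz = self.center_mm
        r2 = (xx - cx) ** 2 + (yy - cy) ** 2 + (zz - cz) ** 2
        return r2 <= self.radius_mm**2


@dataclass(frozen=True)
class TaskParadigm:
    """Block-design stimulus timecourse: task[t] = 1 during ON, 0 during OFF."""

    block_pattern: tuple[tuple[str, int], ...]
    tr_s: float

    def __post_init__(self) -> None:
        if not self.block_pattern:
            raise ValueError("block pattern must be nonempty")
        for state, n in self.block_pattern:
            if state not in ("ON", "OFF"):
                raise ValueError(f"block state must be 'ON' or 'OFF', got {state!r}")
            if int(n) < 1:
                raise ValueError(f"block length must be >= 1, got {n}")
        if self.tr_s <= 0:
            raise ValueError("TR must be positive")

    @property
    def n_volumes_total(self) -> int:
        return sum(int(n) for _, n in self.block_pattern)

    def task_series(self) -> np.ndarray:
        parts = [
            np.full(int(n), 1.0 if state == "ON" else 0.0)
            for state, n in self.block_pattern
        ]
        return np.concatenate(parts)


@dataclass(frozen=True)
class HRFParams:
    """Double-gamma canonical hemodynamic response parameters (seconds)."""

    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_dispersion_s: float = 1.0
    undershoot_dispersion_s: float = 1.0
    peak_undershoot_ratio: float = 6.0
    kernel_length_s: float = 32.0

    def __post_init__(self) -> None:
        for name in (
            "peak_delay_s",
            "undershoot_delay_s",
            "peak_dispersion_s",
            "undershoot_dispersion_s",
            "peak_undershoot_ratio",
            "kernel_length_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.kernel_length_s < self.undershoot_delay_s:
            raise ValueError("kernel must be long enough to contain the undershoot")


@dataclass(frozen=True)
class Regressor:
    """Effective task regressor task*[t] = (task (*) hrf)[t], peak-normalized."""

    values: np.ndarray
    tr_s: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class SusceptibilityVolume:
    """A static 3D susceptibility map in ppm."""

    grid: VoxelGrid
    values_ppm: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.values_ppm, dtype=float)
        if arr.shape != self.grid.shape:
            raise ValueError(
                f"volume shape {arr.shape} does not match grid {self.grid.shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValueError("susceptibility values must be finite")
        object.__setattr__(self, "values_ppm", arr)


@dataclass(frozen=True)
class SusceptibilitySeries:
    """A dynamic 4D (x, y, z, t) susceptibility series in ppm."""

    grid: VoxelGrid
    values_ppm: np.ndarray
    tr_s: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.values_ppm, dtype=float)
        if arr.ndim != 4 or arr.shape[:3] != self.grid.shape:
            raise ValueError(
                f"series shape {arr.shape} does not match grid {self.grid.shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValueError("susceptibility values must be finite")
        object.__setattr__(self, "values_ppm", arr)

    @property
    def n_t(self) -> int:
        return self.values_ppm.shape[3]

    def frame(self, t: int) -> SusceptibilityVolume:
        return SusceptibilityVolume(self.grid, self.values_ppm[..., t])


# ---------------------------------------------------------------------------
# construction operations
# ---------------------------------------------------------------------------


def make_background_chi(
    grid: VoxelGrid,
    tissue_spec: list[BlobSpec] | tuple[BlobSpec, ...] = (),
    envelope_semiaxes_mm: tuple[float, float, float] | None = None,
) -> SusceptibilityVolume:
    """Build the static bipolar background chi0.

    An ellipsoidal "brain" envelope (zero susceptibility outside) encloses the
    listed spherical inclusions.  Inclusions are piecewise constant: each
    voxel centre inside a blob takes the blob amplitude (later blobs
    overwrite earlier ones where they overlap).

    ``envelope_semiaxes_mm`` defaults to 80% of the half-extent per axis;
    pass explicit semi-axes to control the envelope, or ``None`` entries are
    not supported.  With an empty spec list the volume is identically zero.
    """
    vol = np.zeros(grid.shape, dtype=float)
    if not tissue_spec:
        return SusceptibilityVolume(grid, vol)

    for blob in tissue_spec:
        if not blob.fits_inside(grid):
            raise ValueError(
                f"blob at {blob.center_mm} (radius {blob.radius_mm} mm) "
                f"does not fit inside grid extent {grid.extent_mm}"
            )

    if envelope_semiaxes_mm is None:
        envelope_semiaxes_mm = tuple(0.8 * e / 2.0 for e in grid.extent_mm)
    xx, yy, zz = grid.coordinate_arrays_mm()
    ax, ay, az = envelope_semiaxes_mm
    envelope = (xx / ax) ** 2 + (yy / ay) ** 2 + (zz / az) ** 2 <= 1.0

    for blob in tissue_spec:
        vol[blob.support(grid)] = blob.amplitude_ppm
    vol[~envelope] = 0.0
    return SusceptibilityVolume(grid, vol)


def make_task_paradigm(
    pattern: list[tuple[str, int]] | tuple[tuple[str, int], ...],
    tr_s: float,
) -> TaskParadigm:
    """Build a block paradigm from an ordered (state, n_volumes) list."""
    return TaskParadigm(block_pattern=tuple((s, int(n)) for s, n in pattern), tr_s=tr_s)


def canonical_hrf(params: HRFParams | None = None, tr_s: float = 1.0) -> np.ndarray:
    """Sample the canonical double-gamma HRF at the repetition time.

    The kernel is causal (first sample at lag 0), peak-normalized to 1, and
    modelled as the difference of two gamma densities: a positive response
    peaking near ``peak_delay_s`` minus an undershoot scaled by
    ``1/peak_undershoot_ratio``.
    """
    if tr_s <= 0:
        raise ValueError("TR must be positive")
    p = params or HRFParams()
    t = np.arange(0.0, p.kernel_length_s + 0.5 * tr_s, tr_s)

    def gamma_density(t: np.ndarray, delay: float, dispersion: float) -> np.ndarray:
        # mode-parametrized: the lobe peaks at exactly `delay` seconds
        shape = 1.0 + delay / dispersion
        scale = dispersion
        from scipy.stats import gamma

        return gamma.pdf(t, a=shape, scale=scale)

    kernel = gamma_density(t, p.peak_delay_s, p.peak_dispersion_s) - gamma_density(
        t, p.undershoot_delay_s, p.undershoot_dispersion_s
    ) / p.peak_undershoot_ratio
    peak = kernel.max()
    if not np.isfinite(peak) or peak <= 0:
        raise ValueError("HRF kernel must have a positive peak")
    return kernel / peak


def effective_regressor(paradigm: TaskParadigm, hrf_kernel: np.ndarray) -> Regressor:
    """Convolve the block timecourse with the HRF: task*[t] = task (*) hrf.

    The causal discrete convolution is truncated to the paradigm length and
    the result peak-normalized to 1 (an all-OFF paradigm stays identically
    zero).  Post-stimulus undershoot excursions below zero are floored at 0
    so the regressor is a [0, 1]-valued activation weight compatible with
    the ON-state threshold convention.
    """
    task = paradigm.task_series()
    kernel = np.asarray(hrf_kernel, dtype=float)
    if kernel.ndim != 1 or kernel.size == 0:
        raise ValueError("HRF kernel must be a nonempty 1D array")
    full = np.convolve(task, kernel)[: paradigm.n_volumes_total]
    peak = full.max()
    if peak > 0:
        full = full / peak
    full = np.maximum(full, 0.0)
    return Regressor(values=full, tr_s=paradigm.tr_s)


def classify_states(regressor: Regressor, threshold: float = 0.5) -> np.ndarray:
    """Binary ON/OFF labels: ON where task*[t] >= threshold (default 0.5)."""
    return np.asarray(regressor.values) >= threshold


def make_bold_perturbation(
    grid: VoxelGrid,
    blobs: list[BlobSpec] | tuple[BlobSpec, ...],
    regressor: Regressor,
    noise_sd_ppm: float = 0.0,
    seed: int | None = None,
) -> SusceptibilitySeries:
    """Build the dynamic BOLD perturbation dchi[r, t].

    Each task-locked blob contributes ``amplitude * support(r) * task*[t]``
    (a linear neurovascular response); optional i.i.d. Gaussian noise is
    added per voxel and timepoint.  Reproducible given ``seed``.
    """
    if noise_sd_ppm < 0:
        raise ValueError("noise standard deviation must be nonnegative")
    for blob in blobs:
        if blob.kind is not BlobKind.TASK_LOCKED:
            raise ValueError("BOLD perturbation blobs must be kind=task_locked")
        if not blob.fits_inside(grid):
            raise ValueError(
                f"blob at {blob.center_mm} does not fit inside the grid"
            )

    n_t = len(regressor)
    spatial = np.zeros(grid.shape, dtype=float)
    for blob in blobs:
        spatial[blob.support(grid)] += blob.amplitude_ppm

    series = spatial[..., None] * np.asarray(regressor.values)[None, None, None, :]
    if noise_sd_ppm > 0:
        rng = np.random.default_rng(seed)
        series = series + rng.normal(0.0, noise_sd_ppm, size=series.shape)
    return SusceptibilitySeries(grid, series, tr_s=regressor.tr_s)


def compose_chi_series(
    chi0: SusceptibilityVolume, dchi: SusceptibilitySeries
) -> SusceptibilitySeries:
    """chi(r, t) = chi0(r) + dchi(r, t), broadcast over time."""
    if not chi0.grid.same_geometry(dchi.grid):
        raise ValueError("chi0 and dchi must share the same grid")
    return SusceptibilitySeries(
        dchi.grid, chi0.values_ppm[..., None] + dchi.values_ppm, tr_s=dchi.tr_s
    )


# ---------------------------------------------------------------------------
# demo phantom presets
# ---------------------------------------------------------------------------


def default_background_specs(grid: VoxelGrid) -> list[BlobSpec]:
    """Bipolar background inclusions for the demo phantom.

    Amplitudes span the tissue-like +/-0.5 ppm range: two paramagnetic
    (ferritin/deoxyhaemoglobin-like) and two diamagnetic (water-like)
    spheres placed off-centre inside the envelope.
    """
    ex, ey, ez = grid.extent_mm
    s = min(ex, ey, ez)
    r = 0.08 * s
    return [
        BlobSpec((-0.18 * ex, -0.10 * ey, 0.0), r, +0.5, BlobKind.STATIC),
        BlobSpec((+0.18 * ex, -0.10 * ey, 0.0), r, -0.5, BlobKind.STATIC),
        BlobSpec((0.0, +0.15 * ey, +0.10 * ez), 0.6 * r, +0.25, BlobKind.STATIC),
        BlobSpec((0.0, -0.22 * ey, -0.10 * ez), 0.6 * r, -0.25, BlobKind.STATIC),
    ]


def default_bold_blobs(grid: VoxelGrid, amplitude_ppm: float = 0.02) -> list[BlobSpec]:
    """One positive and one negative task-locked blob (bidirectional response)."""
    ex, ey, ez = grid.extent_mm
    r = 0.06 * min(ex, ey, ez)
    return [
        BlobSpec((-0.12 * ex, +0.12 * ey, 0.0), r, +amplitude_ppm, BlobKind.TASK_LOCKED),
        BlobSpec((+0.12 * ex, -0.12 * ey, 0.0), r, -amplitude_ppm, BlobKind.TASK_LOCKED),
    ]
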