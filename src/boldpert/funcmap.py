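"""Task-correlation functional mapping and SNR/CNR characterization.

A 4D dataset (T2* magnitude A, reconstructed chi, or reconstructed dchi) is
reduced to a 3D functional map by voxel-wise Pearson correlation against the
HRF-convolved task regressor task*[t].  Positive correlation marks a
task-driven response, negative an anti-correlated (inhibitory) one — the
bidirectional response signature.  Significance is summarized per voxel by
the t-transform p-value and the Fisher z-score.

SNR/CNR traces characterize signal strength per timepoint:
``SNR[t] = |mean(ROI_act[t])| / std(ROI_inact[t])`` and
``CNR[t] = |mean(ROI_act[t]) - mean(ROI_inact[t])| / std(ROI_inact[t])``,
time-averaged with the reference frame optionally excluded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .grid import VoxelGrid
from .phantom import Regressor

__all__ = [
    "CorrelationMap",
    "ROISpec",
    "MetricsSeries",
    "BlobStats",
    "tcorr_map",
    "tcorr_significance",
    "snr_cnr",
    "threshold_blobs",
]

_TINY = np.finfo(float).tiny


@dataclass(frozen=True)
class CorrelationMap:
    """Voxel-wise task correlation with significance maps."""

    grid: VoxelGrid
    r_values: np.ndarray
    p_values: np.ndarray
    z_values: np.ndarray
    n_t: int

    def __post_init__(self) -> None:
        r = np.asarray(self.r_values, dtype=float)
        if np.max(np.abs(r)) > 1.0 + 1e-12:
            raise ValueError("correlation values must lie in [-1, 1]")
        object.__setattr__(self, "r_values", r)


@dataclass(frozen=True)
class ROISpec:
    """Activation / inactivation ROI boxes as half-open voxel index ranges."""

    act_box: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]
    inact_box: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]

    def __post_init__(self) -> None:
        for box in (self.act_box, self.inact_box):
            for lo, hi in box:
                if hi <= lo:
                    raise ValueError(f"empty ROI range ({lo}, {hi})")

    @staticmethod
    def _slices(box) -> tuple[slice, slice, slice]:
        return tuple(slice(lo, hi) for lo, hi in box)

    def act_slices(self) -> tuple[slice, slice, slice]:
        return self._slices(self.act_box)

    def inact_slices(self) -> tuple[slice, slice, slice]:
        return self._slices(self.inact_box)

    def validate_against(self, shape: tuple[int, int, int]) -> None:
        for box in (self.act_box, self.inact_box):
            for (lo, hi), n in zip(box, shape):
                if lo < 0 or hi > n:
                    raise ValueError(f"ROI box {box} outside grid shape {shape}")
        # disjointness: overlapping ranges on all three axes means overlap
        overlap = all(
            max(a[0], b[0]) < min(a[1], b[1])
            for a, b in zip(self.act_box, self.inact_box)
        )
        if overlap:
            raise ValueError("ROI_act and ROI_inact must be disjoint")

    @classmethod
    def centered(
        cls,
        act_center: tuple[int, int, int],
        inact_center: tuple[int, int, int],
        size: tuple[int, int, int] = (5, 5, 3),
    ) -> "ROISpec":
        """Boxes of the conventional 5 x 5 x 3 voxel size around two centres."""

        def box(center):
            return tuple(
                (c - s // 2, c - s // 2 + s) for c, s in zip(center, size)
            )

        return cls(act_box=box(act_center), inact_box=box(inact_center))


@dataclass(frozen=True)
class MetricsSeries:
    """Per-timepoint SNR/CNR traces and their time averages."""

    snr_t: np.ndarray
    cnr_t: np.ndarray
    snr_mean: float
    cnr_mean: float
    excluded_ref_index: int | None = None
    flagged_frames: tuple[int, ...] = ()


@dataclass(frozen=True)
class BlobStats:
    """One connected suprathreshold component of a z-map."""

    label: int
    sign: int
    n_voxels: int
    peak_abs_z: float
    peak_index: tuple[int, int, int]


def tcorr_map(series: np.ndarray, regressor: Regressor | np.ndarray) -> CorrelationMap:
    """Voxel-wise Pearson correlation of a 4D series against task*[t].

    Constant-timecourse voxels (air/background) get r = 0 by convention.
    Includes t-transform p-values and Fisher z-scores (see
    :func:`tcorr_significance`).
    """
    data = np.asarray(series, dtype=float)
    reg = np.asarray(
        regressor.values if isinstance(regressor, Regressor) else regressor,
        dtype=float,
    )
    if data.ndim != 4:
        raise ValueError("series must be 4D (x, y, z, t)")
    n_t = data.shape[3]
    if reg.shape != (n_t,):
        raise ValueError(
            f"regressor length {reg.shape} does not match series length {n_t}"
        )
    if n_t < 3:
        raise ValueError("need at least 3 timepoints for correlation")

    reg_c = reg - reg.mean()
    reg_ss = float(np.sqrt(np.sum(reg_c**2)))
    data_c = data - data.mean(axis=3, keepdims=True)
    data_ss = np.sqrt(np.sum(data_c**2, axis=3))
    denom = data_ss * reg_ss
    num = data_c @ reg_c
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    r = np.clip(r, -1.0, 1.0)
    grid = VoxelGrid(shape=data.shape[:3])
    p, z = _significance_from_r(r, n_t)
    return CorrelationMap(grid, r, p, z, n_t=n_t)


def _significance_from_r(r: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        t_stat = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, _TINY))
    p = 2.0 * stats.t.sf(np.abs(t_stat), df=n - 2)
    p = np.clip(p, _TINY, 1.0)  # |r| = 1 underflows to the smallest positive float
    if n > 3:
        z = np.arctanh(np.clip(r, -1 + 1e-16, 1 - 1e-16)) * np.sqrt(n - 3)
    else:
        z = np.zeros_like(r)
    return p, z


def tcorr_significance(cmap: CorrelationMap) -> CorrelationMap:
    """Recompute p/z from the stored r-map.

    Two-sided p from ``t = r sqrt((n-2)/(1-r^2))`` on n-2 degrees of
    freedom; Fisher z-score ``z = atanh(r) sqrt(n-3)``.
    """
    if cmap.n_t < 4:
        raise ValueError("need at least 4 timepoints for significance")
    p, z = _significance_from_r(cmap.r_values, cmap.n_t)
    return CorrelationMap(cmap.grid, cmap.r_values, p, z, n_t=cmap.n_t)


def snr_cnr(
    series: np.ndarray,
    roi: ROISpec,
    exclude_index: int | None = None,
) -> MetricsSeries:
    """Dynamic SNR/CNR of a 4D series over activation/inactivation ROIs.

    Frames whose inactive-ROI standard deviation is zero are flagged and
    excluded from the time averages (as is ``exclude_index``, conventionally
    the complex-division reference frame).
    """
    data = np.asarray(series, dtype=float)
    if data.ndim != 4:
        raise ValueError("series must be 4D (x, y, z, t)")
    roi.validate_against(data.shape[:3])
    n_t = data.shape[3]
    act = data[roi.act_slices()].reshape(-1, n_t)
    inact = data[roi.inact_slices()].reshape(-1, n_t)
    if inact.shape[0] < 2:
        raise ValueError("inactive ROI must contain at least 2 voxels")

    act_mean = act.mean(axis=0)
    inact_mean = inact.mean(axis=0)
    inact_std = inact.std(axis=0, ddof=0)

    flagged = np.where(inact_std == 0)[0]
    safe_std = np.where(inact_std > 0, inact_std, 1.0)
    snr_t = np.where(inact_std > 0, np.abs(act_mean) / safe_std, 0.0)
    cnr_t = np.where(
        inact_std > 0, np.abs(act_mean - inact_mean) / safe_std, 0.0
    )

    include = np.ones(n_t, dtype=bool)
    include[flagged] = False
    if exclude_index is not None:
        if not (0 <= exclude_index < n_t):
            raise ValueError(f"exclude_index {exclude_index} outside [0, {n_t})")
        include[exclude_index] = False
    if not include.any():
        raise ValueError("no timepoints left to average")
    return MetricsSeries(
        snr_t=snr_t,
        cnr_t=cnr_t,
        snr_mean=float(snr_t[include].mean()),
        cnr_mean=float(cnr_t[include].mean()),
        excluded_ref_index=exclude_index,
        flagged_frames=tuple(int(i) for i in flagged),
    )


def threshold_blobs(
    cmap: CorrelationMap, z_threshold: float
) -> tuple[np.ndarray, list[BlobStats]]:
    """Label connected suprathreshold components of the |z| map.

    26-connectivity; each component carries its response sign (sign of z at
    its peak) and the location/magnitude of its |z| peak.  Returns the
    integer label volume and per-blob stats sorted by descending peak |z|.
    """
    if z_threshold <= 0:
        raise ValueError("z threshold must be positive")
    z = np.asarray(cmap.z_values, dtype=float)
    mask = np.abs(z) >= z_threshold
    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    labels, n_labels = ndimage.label(mask, structure=structure)
    blobs: list[BlobStats] = []
    for lab in range(1, n_labels + 1):
        idx = np.argwhere(labels == lab)
        zvals = z[labels == lab]
        peak_pos = int(np.argmax(np.abs(zvals)))
        peak_index = tuple(int(c) for c in idx[peak_pos])
        peak_z = float(zvals[peak_pos])
        blobs.append(
            BlobStats(
                label=lab,
                sign=int(np.sign(peak_z)),
                n_voxels=int(idx.shape[0]),
                peak_abs_z=abs(peak_z),
                peak_index=peak_index,
            )
        )
    blobs.sort(key=lambda b: -b.peak_abs_z)
    return labels, blobs
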