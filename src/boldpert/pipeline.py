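"""Pipeline orchestration: the forward and inverse dataflows.

Forward: phantom (chi0, dchi, paradigm, regressor) -> dipole field ->
intravoxel dephasing -> magnitude/phase NIfTI pair.

Inverse: complex division (dP, no unwrapping needed) -> field -> dipole
inversion -> dchi series; in parallel, Laplacian unwrapping -> field ->
inversion -> full chi series; then task-correlation maps and SNR/CNR
metrics.  Every run writes a manifest with parameter echoes and output
hashes; reruns with equal config and seed hash identically.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path

import numpy as np

from . import config as cfgmod
from . import funcmap as fm
from . import io as bio
from . import phantom as ph
from .forward import simulate_t2star_series
from .inversion import reconstruct_chi_series, reconstruct_dchi_series
from .io import RunManifest
from .phaseproc import complex_divide_phase

__all__ = ["run_forward", "run_inverse", "run_all"]

logger = logging.getLogger(__name__)


def _summary(arr: np.ndarray) -> dict:
    arr = np.asarray(arr)
    return {
        "min": float(arr.min()),
        "max": float(arr.max()),
        "p05": float(np.percentile(arr, 5)),
        "p95": float(np.percentile(arr, 95)),
    }


def run_forward(cfg: dict, output_dir: str | Path | None = None) -> dict:
    """Phantom + forward simulation; writes the dataset bundle and manifest.

    Returns a dict of the in-memory objects and output paths.
    """
    cfg = cfgmod.resolve_config(cfg)
    out = Path(output_dir or cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg)
    seed = int(cfg["seed"])

    grid = cfgmod.build_grid(cfg)
    acq = cfgmod.build_acquisition(cfg)
    paradigm = cfgmod.build_paradigm(cfg)
    hrf_kernel = ph.canonical_hrf(cfgmod.build_hrf_params(cfg), tr_s=paradigm.tr_s)
    regressor = ph.effective_regressor(paradigm, hrf_kernel)

    chi0 = ph.make_background_chi(grid, cfgmod.build_background_specs(cfg, grid))
    dchi = ph.make_bold_perturbation(
        grid,
        cfgmod.build_bold_blobs(cfg, grid),
        regressor,
        noise_sd_ppm=cfg["phantom"]["noise_sd_ppm"],
        seed=seed,
    )
    chi = ph.compose_chi_series(chi0, dchi)
    manifest.record_stage(
        "phantom",
        seed=seed,
        n_volumes=paradigm.n_volumes_total,
        chi0=_summary(chi0.values_ppm),
        dchi=_summary(dchi.values_ppm),
    )

    t2s = simulate_t2star_series(
        chi,
        acq,
        noise_sd=cfg["acquisition"]["noise_sd"],
        seed=seed + 1,
        zero_pad=cfg["acquisition"]["zero_pad"],
    )
    manifest.record_stage(
        "forward",
        b0_tesla=acq.b0_tesla,
        te_s=acq.te_s,
        supersample=acq.supersample,
        magnitude=_summary(t2s.magnitude),
        phase=_summary(t2s.phase),
    )

    paths = {}
    paths["chi0"] = bio.write_nifti_volume(out / "chi0.nii", chi0.values_ppm, grid)
    paths["dchi"] = bio.write_nifti_volume(out / "dchi.nii", dchi.values_ppm, grid)
    paths["chi"] = bio.write_nifti_volume(out / "chi.nii", chi.values_ppm, grid)
    mag_path, phs_path = bio.write_complex_series(out / "t2star", t2s)
    paths["mag"], paths["phs"] = mag_path, phs_path
    paths["regressor"] = bio.write_regressor(out / "regressor.txt", regressor.values)
    paths["paradigm"] = bio.write_regressor(out / "paradigm.txt", paradigm.task_series())
    for name, p in paths.items():
        manifest.record_file(name, p)
    paths["manifest"] = manifest.save(out / "manifest_forward.json")

    return {
        "grid": grid,
        "acq": acq,
        "paradigm": paradigm,
        "regressor": regressor,
        "chi0": chi0,
        "dchi": dchi,
        "chi": chi,
        "t2star": t2s,
        "paths": paths,
        "manifest": manifest,
    }


def run_inverse(
    cfg: dict,
    mag_path: str | Path,
    phs_path: str | Path,
    regressor_path: str | Path | None = None,
    output_dir: str | Path | None = None,
    reconstruct_full_chi: bool = True,
) -> dict:
    """Inverse pipeline on a magnitude/phase 4D pair.

    The dchi pathway runs complex division -> field -> inversion (no
    unwrapping); the full-chi pathway runs Laplacian unwrapping per frame
    before inversion.  Functional maps and SNR/CNR metrics are computed on
    the reconstructed dchi series.
    """
    cfg = cfgmod.resolve_config(cfg)
    out = Path(output_dir or cfg["output_dir"])
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=cfg)

    t2s = bio.read_complex_series(mag_path, phs_path)
    grid = t2s.grid
    acq = t2s.acq
    inv_cfg = cfgmod.build_inversion_config(cfg)
    ref_index = int(cfg["fmap"]["ref_index"])

    dphase = complex_divide_phase(
        t2s.phase, ref_index=ref_index, tr_s=acq.tr_s, grid=grid
    )
    manifest.record_stage(
        "complex_division", ref_index=ref_index, dphase=_summary(dphase.values_rad)
    )

    dchi_recon = reconstruct_dchi_series(dphase, acq, inv_cfg)
    manifest.record_stage(
        "dchi_reconstruction",
        method=inv_cfg.method,
        dchi=_summary(dchi_recon.values_ppm),
    )

    paths = {}
    paths["dphase"] = bio.write_nifti_volume(
        out / "dphase.nii", dphase.values_rad, grid, {"wrapped": True}
    )
    paths["dchi_recon"] = bio.write_nifti_volume(
        out / "dchi_recon.nii", dchi_recon.values_ppm, grid
    )

    chi_recon = None
    if reconstruct_full_chi:
        chi_recon = reconstruct_chi_series(
            t2s.phase, acq, inv_cfg, grid=grid, tr_s=acq.tr_s
        )
        manifest.record_stage(
            "chi_reconstruction",
            method=inv_cfg.method,
            chi=_summary(chi_recon.values_ppm),
        )
        paths["chi_recon"] = bio.write_nifti_volume(
            out / "chi_recon.nii", chi_recon.values_ppm, grid
        )

    # functional mapping on the reconstructed dchi series
    if regressor_path is not None:
        reg_values = bio.read_regressor(regressor_path)
    else:
        paradigm = cfgmod.build_paradigm(cfg)
        hrf_kernel = ph.canonical_hrf(
            cfgmod.build_hrf_params(cfg), tr_s=paradigm.tr_s
        )
        reg_values = ph.effective_regressor(paradigm, hrf_kernel).values
    if len(reg_values) != t2s.n_t:
        raise ValueError(
            f"regressor length {len(reg_values)} does not match series {t2s.n_t}"
        )
    cmap = fm.tcorr_map(dchi_recon.values_ppm, reg_values)
    manifest.record_stage(
        "fmap",
        r=_summary(cmap.r_values),
        z_threshold=cfg["fmap"]["z_threshold"],
    )
    paths["tcorr_r"] = bio.write_nifti_volume(out / "tcorr_r.nii", cmap.r_values, grid)
    paths["tcorr_p"] = bio.write_nifti_volume(out / "tcorr_p.nii", cmap.p_values, grid)
    paths["tcorr_z"] = bio.write_nifti_volume(out / "tcorr_z.nii", cmap.z_values, grid)

    # SNR/CNR around the strongest blob vs. a task-irrelevant corner region
    labels, blobs = fm.threshold_blobs(cmap, cfg["fmap"]["z_threshold"])
    metrics = None
    if blobs:
        size = tuple(cfg["fmap"]["roi_size"])

        def clamp(center):
            return tuple(
                int(np.clip(c, s // 2, n - (s - s // 2)))
                for c, s, n in zip(center, size, grid.shape)
            )

        act_center = clamp(blobs[0].peak_index)
        try:
            roi = None
            for frac in ((1, 1, 1), (3, 1, 1), (1, 3, 1), (3, 3, 3)):
                cand = clamp(tuple(f * s // 4 for f, s in zip(frac, grid.shape)))
                trial = fm.ROISpec.centered(act_center, cand, size)
                try:
                    trial.validate_against(grid.shape)
                except ValueError:
                    continue
                roi = trial
                break
            if roi is None:
                raise ValueError("no task-irrelevant ROI disjoint from the blob")
            exclude = ref_index if cfg["fmap"]["exclude_ref_from_metrics"] else None
            metrics = fm.snr_cnr(dchi_recon.values_ppm, roi, exclude_index=exclude)
            manifest.record_stage(
                "metrics",
                snr_mean=metrics.snr_mean,
                cnr_mean=metrics.cnr_mean,
                excluded_ref_index=metrics.excluded_ref_index,
            )
            paths["metrics"] = _write_metrics_csv(out / "metrics.csv", metrics)
        except ValueError as exc:  # ROI construction can fail near edges
            logger.warning("skipping SNR/CNR metrics: %s", exc)

    for name, p in paths.items():
        manifest.record_file(name, p)
    paths["manifest"] = manifest.save(out / "manifest_inverse.json")
    return {
        "t2star": t2s,
        "dphase": dphase,
        "dchi_recon": dchi_recon,
        "chi_recon": chi_recon,
        "cmap": cmap,
        "blobs": blobs,
        "blob_labels": labels,
        "metrics": metrics,
        "paths": paths,
        "manifest": manifest,
    }


def _write_metrics_csv(path: Path, metrics: fm.MetricsSeries) -> Path:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["t", "snr", "cnr"])
        for t, (s, c) in enumerate(zip(metrics.snr_t, metrics.cnr_t)):
            writer.writerow([t, f"{s:.12g}", f"{c:.12g}"])
        writer.writerow(["mean", f"{metrics.snr_mean:.12g}", f"{metrics.cnr_mean:.12g}"])
    return path


def run_all(cfg: dict, output_dir: str | Path | None = None) -> dict:
    """Forward simulation followed by the inverse pipeline on its outputs."""
    cfg = cfgmod.resolve_config(cfg)
    out = Path(output_dir or cfg["output_dir"])
    fwd = run_forward(cfg, out / "forward")
    inv = run_inverse(
        cfg,
        fwd["paths"]["mag"],
        fwd["paths"]["phs"],
        regressor_path=fwd["paths"]["regressor"],
        output_dir=out / "inverse",
    )
    return {"forward": fwd, "inverse": inv}
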