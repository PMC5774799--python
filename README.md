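# boldpert

Forward and inverse modelling of BOLD fMRI as a **dynamic magnetic
susceptibility perturbation**.

In a gradient-echo EPI experiment the measured complex T2\* signal is an
indirect, nonlinear view of the brain's magnetic susceptibility χ. `boldpert`
treats a task-evoked BOLD response as a small additive perturbation of a
static tissue background,

    χ(r, t) = χ₀(r) + δχ(r, t),        |δχ| ≪ |χ₀|,

and implements the full closed loop around that model:

**Forward** — the susceptibility source induces a field through dipole
convolution, `b = B₀ (χ·10⁻⁶) ∗ h` with `h(r) = (3z² − r²)/(4πr⁵)`
(Fourier kernel `D(k) = 1/3 − k_z²/|k|²`, `D(0) = 0`), and each voxel's
complex signal is the intravoxel average of unit spin phasors,
`C[r] = ⟨exp(iγ T_E b)⟩_Ω`, yielding 4D magnitude `A[r,t]` and wrapped phase
`P[r,t]` volumes.

**Inverse** — complex division of each phase frame against a reference frame
extracts the BOLD phase perturbation
`δP[r,t] = Arg(e^{iP[r,t]} / e^{iP_ref[r]})` exactly (for |δP| < π), with the
severely wrapped static background cancelling identically and no spatial
unwrapping needed; the field estimate `δb = δP/(γT_E)` is then deconvolved by
regularized dipole inversion — truncated k-space division (TKD) or
total-variation split-Bregman iteration (TVB) — to recover `δχ[r,t]` in ppm.
The full-χ pathway additionally Laplacian-unwraps each phase frame (a
per-frame QSM reconstruction).

**Functional mapping** — voxel-wise Pearson correlation of any 4D dataspace
(A, χ or δχ) against the HRF-convolved task regressor
`task*[t] = (task ∗ hrf)[t]` gives r/p/z maps; SNR/CNR traces
(`SNR[t] = |mean(ROI_act)|/std(ROI_inact)`, CNR subtracting the inactive
mean) characterize signal strength per stage. A synthetic phantom module
generates the study conditions — bipolar χ₀ in ±0.5 ppm, task-locked δχ blobs
in ±0.03 ppm, block paradigms (e.g. 50 volumes of 5 × {5 ON, 5 OFF} at
TR = 3 s) — so every stage can be validated against known ground truth.

Intended for researchers studying phase-based fMRI analysis, functional QSM,
and susceptibility-domain BOLD modelling.

## Worked example

A 48³ phantom with a bipolar ±0.5 ppm background and one +0.02 ppm
task-locked blob, simulated at 7 T / T_E = 29 ms, then recovered through the
inverse loop:

```python
import numpy as np
from boldpert import *
from boldpert.phantom import BlobSpec, BlobKind, Regressor

grid = VoxelGrid((48, 48, 48), voxel_size_mm=(1.0, 1.0, 1.0))
acq = AcquisitionParams(b0_tesla=7.0, te_s=0.029, supersample=1)

chi0 = make_background_chi(
    grid,
    [BlobSpec((-8, 0, 0), 5.0, +0.5), BlobSpec((8, 0, 0), 5.0, -0.5)],
)
blob = BlobSpec((0, 10, 0), 3.0, 0.02, BlobKind.TASK_LOCKED)
reg = Regressor(np.array([0.0, 1.0]), tr_s=3.0)   # OFF then ON
dchi = make_bold_perturbation(grid, [blob], reg, noise_sd_ppm=0.0, seed=0)
chi = compose_chi_series(chi0, dchi)

t2s = simulate_t2star_series(chi, acq)            # forward: chi -> C[r,t]
print(f"wrapped phase range: [{t2s.phase.min():+.2f}, {t2s.phase.max():+.2f}] rad")

dP = complex_divide_phase(t2s.phase, ref_index=0, grid=grid)
print(f"max |dP|: {np.abs(dP.values_rad).max():.3f} rad")
rec = reconstruct_dchi_series(dP, acq, InversionConfig(method="tvb"))
recovered = rec.values_ppm[blob.support(grid), 1].mean()
print(f"recovered blob amplitude: {recovered:.4f} ppm (true 0.0200)")
```

Output:

```
wrapped phase range: [-3.14, +3.14] rad
max |dP|: 0.434 rad
recovered blob amplitude: 0.0198 ppm (true 0.0200)
```

The ±0.5 ppm background wraps the raw 7 T phase through the full [−π, π)
interval, yet the complex-division perturbation stays far below π (0.43 rad),
so the δχ pathway needs no unwrapping — and the TV-regularized inversion
returns the planted 0.02 ppm amplitude to 1%.

## Command line

```bash
boldpert simulate config.yaml --out fwd/        # phantom + forward model
boldpert extract-dphase fwd/t2star_phs.nii.gz   # complex division
boldpert qsm fwd/t2star_phs.nii.gz              # full-chi QSM pathway
boldpert recon-dchi dphase.nii --method tvb     # BOLD dchi pathway
boldpert fmap dchi_recon.nii fwd/regressor.txt  # r/p/z correlation maps
boldpert metrics dchi_recon.nii --act 24 30 24 --inact 10 10 10
boldpert run-all config.yaml --out out/         # the whole loop
```

Configuration is YAML over a complete defaults registry
(`boldpert.config.DEFAULT_CONFIG`); every run writes a manifest with
parameter echoes and output hashes, and reruns with the same seed are
bit-identical.

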