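# Methods

## The perturbation model

`boldpert` models a task-evoked BOLD response as an additive perturbation of
the brain's static magnetic susceptibility distribution:

    chi(r, t) = chi0(r) + dchi(r, t),   |dchi| << |chi0|.

chi is stored in ppm throughout (1 ppm = 1e-6 dimensionless SI); the 1e-6
factor is applied only inside the field computation and removed again by the
inversion, so forward and inverse are exactly symmetric in units.  The
background chi0 is bipolar — diamagnetic (water-like, negative) and
paramagnetic (ferritin/deoxyhaemoglobin-like, positive) tissue coexist — and
the BOLD perturbation dchi is likewise signed: a stimulus can raise
deoxyhaemoglobin content in one region (positive dchi) while lowering it in
another (negative dchi), the bidirectional response the delta-chi functional
maps are designed to reveal.

## Forward model

**Magnetization.**  Tissue is weakly magnetic, so magnetization is linear
and the z-component of the induced field is a convolution with the unit
point-dipole response:

    b(r) = B0 * (chi * 1e-6) (*) h,   h(r) = (3 z^2 - r^2) / (4 pi |r|^5),

computed in Fourier space with the kernel D(k) = 1/3 - k_par^2/|k|^2, where
k_par is the projection on the B0 axis (oblique B0 supported).  D(0) = 0 by
convention: a uniform susceptibility offset is unobservable in phase, so
every fieldmap is mean-free.  FFT convolution is periodic; the forward model
zero-pads to twice the grid by default to suppress wrap-around (validated
against the closed-form exterior field of a uniform sphere: 1.1% relative
RMSE outside 1.5 radii on a 64^3 grid, interior leakage ~1.5% of the peak
exterior field).

**Intravoxel dephasing.**  Each acquired voxel averages unit phasors over
its volume, C[r] = <exp(i gamma T_E b)>_Omega, approximated by an integer
supersampling of the grid (default 4 per axis; |C| converges to <0.5%
between 4 and 8 on the demo phantom).  Piecewise-constant phantoms are
upsampled by nearest neighbour, which is exact for them.  gamma is the
proton gyromagnetic ratio 2.6752218744e8 rad/s/T.  |C| <= 1 always and
C = 1 at T_E = 0.

**Taylor diagnostics.**  The first-order magnitude expansion
A ~ 1 + (gamma T_E)^2 <b^2>/2 is implemented verbatim as a diagnostic of the
quadratic magnitude nonlinearity.  Note its sign: it exceeds 1, while exact
intravoxel dephasing always attenuates (|C| <= 1).  The two agree only in
the trivial b = 0 case; the package reports the discrepancy rather than
using the expansion as a forward model.  The phase expansions (order 1:
gamma T_E <b>; order 2: the arctan form) are exact in the small-phase regime
— with supersample 1 and max |gamma T_E b| < 0.1 rad the simulated phase
equals gamma T_E b to machine precision, which is the linearity the inverse
pipeline relies on.

## Inverse pipeline

**Phase perturbation by complex division.**  dP[r,t] =
Arg(exp(iP[r,t]) / exp(iP_ref[r])) removes the static phase background
exactly — even when P is wrapped through many cycles (a 7 T, 29 ms
acquisition over a +/-0.5 ppm background spans the full [-pi, pi) interval)
— and is exact whenever the true perturbation magnitude is below pi.  For
the phantom's +/-0.02 ppm perturbations, |dP| ~ 0.4 rad at 7 T, far inside
that bound.  The reference frame is configurable (default index 0) and maps
to exactly zero.

**Laplacian unwrapping** (full-chi pathway only).  The Laplacian of the true
phase is computed from sin/cos of the wrapped phase — both continuous across
wraps — and inverted in Fourier space with the k = 0 coefficient set to zero
(forced by the formula; output mean-free).  Harmonic components (linear
ramps, external-source backgrounds) have zero Laplacian and are annihilated,
which doubles as background-field removal; no additional SHARP/PDF-style
step is applied.  Measured fidelity on 64^3: a wrapped 8-rad Gaussian bump
is recovered to 4e-9 rad RMSE; an integer-cycle linear ramp is annihilated
to 8e-16 rad; constants map to exactly zero at the operator level.  The k^2
grid is the squared magnitude of the same frequency grid the dipole kernel
uses; any global rescaling of k^2 cancels between numerator and denominator
(asserted by a scale-invariance test).

**Field from phase.**  b = P/(gamma T_E), the linear inverse of the
first-order imaging model.  Combined with the inversion's symmetric 1e-6
handling, the pair (B0, T_E) cancels end to end: reconstructed chi is
invariant to the acquisition constants used consistently in both directions
(tested to 1e-10).

**Dipole inversion.**  D(k) vanishes on the magic-angle cone, so direct
division is ill-posed.  Two regularized solvers:

* *TKD* — spectral division restricted to |D| >= threshold (default 0.1),
  zero elsewhere.  Linear and fast; exact for passband-limited sources.  Its
  known amplitude bias equals the excluded passband fraction: a 1-ppm sphere
  recovers 0.82 at threshold 0.1, 0.90 at 0.05.  The threshold trades this
  bias against noise amplification (gain <= 1/threshold in the passband).
* *TVB* — split-Bregman minimization of ||D chi_hat - f_hat||^2 +
  lambda TV(chi) with isotropic TV, forward differences and periodic
  boundary.  The quadratic subproblem is solved exactly in Fourier space by
  multiplication with D (never division), the shrinkage step soft-thresholds
  the gradient magnitude at lambda/nu, and the Bregman variables accumulate
  the constraint error.  The field is normalized to unit peak before solving
  so lambda is scale-free; defaults lambda = 2e-3, nu = 10 lambda,
  max_iters = 100, rel_tol = 1e-4, warm-started from TKD.  On the noiseless
  sphere the data residual decreases monotonically and the interior mean
  recovers to 1%; hitting max_iters returns the iterate with
  converged=False (logged), never an exception.

The delta-chi pathway (complex division -> field -> inversion) involves no
unwrapping; the full-chi pathway (unwrap -> field -> inversion) is a
per-frame QSM reconstruction.  Reconstructed chi is mean-free (relative
susceptibility); no tissue baseline referencing is attempted.

On smoothness: dipole inversion removes the dipole fringing patterns of the
fieldmap, but because the passband gain 1/|D| is >= 1 everywhere it does not
reduce total variation — the reconstructed source is sharper than the field
it came from (the true piecewise-constant source is too).  What holds, and
is tested, is that TV regularization suppresses the truncation ringing of
TKD: TV(chi_TVB) < TV(chi_TKD) on the same input.

## Functional mapping and metrics

Voxel-wise Pearson correlation against the HRF-convolved regressor
task*[t] = (task (*) hrf)[t].  The HRF is the conventional double-gamma
difference: a positive lobe peaking at 6 s minus an undershoot at 16 s
scaled by 1/6, dispersions 1 s, kernel length 32 s, sampled at TR and
peak-normalized; each gamma lobe is mode-parametrized so the nominal delays
are the actual peak locations.  After convolution the regressor is
peak-normalized to 1 and its post-undershoot negative excursions are floored
at 0, making task* a [0, 1] activation weight consistent with the ON-state
rule task* >= 0.5 (the threshold is inclusive).  Constant-timecourse voxels
(air, background) get r = 0, p = 1 by convention.

Significance: two-sided p from t = r sqrt((n-2)/(1-r^2)) on n-2 degrees of
freedom, and z = atanh(r) sqrt(n-3) (Fisher).  |r| = 1 underflows p to the
smallest positive double, documented rather than special-cased.  No
multiple-comparison correction is applied — maps are raw voxel-wise
p-values; users performing inference over many voxels should correct
downstream.

SNR[t] = |mean(ROI_act[t])| / std(ROI_inact[t]) and CNR[t] additionally
subtracts the inactive mean; ROIs default to 5 x 5 x 3 voxel boxes.  Time
averages exclude the complex-division reference frame when configured (the
N_t - 1 convention) and any frame with zero inactive-ROI variance (flagged
and logged).  CNR is invariant to global offsets; both are invariant to
positive global scaling.

Thresholded blob extraction labels 26-connected components of |z| above a
threshold, with per-component sign and peak location — the representation
used for detection statistics and overlay rendering.

## The synthetic phantom: what it emulates, what it does not

The generator reproduces the structure of the study conditions: a static
bipolar chi0 within [-0.5, 0.5] ppm inside an ellipsoidal envelope,
task-locked spherical dchi blobs within +/-0.03 ppm (default +/-0.02, one
positive, one negative), block paradigms of 50 volumes (5 cycles {5 ON,
5 OFF}, TR 3 s) or 165 volumes (5 cycles {15 OFF, 15 ON} + 15 OFF), and the
7 T / T_E 29 ms acquisition constants.  The dchi timecourse is
amplitude x task*[t] — a linear neurovascular response chosen because it
makes correlation recovery analytically predictable; the model itself is
agnostic to the source waveform.  Noise, when enabled, is i.i.d. Gaussian in
the dchi source (sd in ppm; the detection studies use 0.004 ppm against
0.02 ppm blobs, source-domain CNR 5) and/or i.i.d. complex Gaussian added to
C[r,t]; both default off and are seeded.

Not emulated: vascular trees or anatomical geometry, physiological
(cardiac/respiratory) fluctuations, T1/T2 relaxation weighting, k-space
sampling, EPI distortion or coil combination.  Passing tests therefore
demonstrate the correctness of the computational loop — not robustness to
physiological noise, motion, or coil-phase errors in real acquisitions.

## Problem sizes and numerical choices

Validation runs use 64^3 grids for the sphere oracle and the noiseless
round trip, 48^3 for the 50-frame detection study, and supersample 1 where
dephasing fidelity is not the property under test (the supersampling
machinery is exercised separately by the small-phase and dephasing tests).
The per-frame inversion in the 50-frame study is TKD; TVB is used for the
amplitude-recovery comparison, where it beats TKD by an order of magnitude
(0.8% vs 18% blob-mean error).  Detection is scored by scanning |z|
thresholds for the lowest one at which every suprathreshold 26-connected
component intersects the planted support (zero false-positive components),
then measuring blob-voxel sensitivity there; across seeds this yields
sensitivity >= 0.99 at thresholds near z = 6.

Degenerate inputs: empty blob lists give zero volumes; all-OFF paradigms
give identically zero regressors (no normalization blow-up); zero fields
invert to zero in one iteration; constant phase unwraps to exactly zero;
zero-variance ROIs are flagged rather than propagating infinities.

## Known limitations

* TKD amplitude bias is not corrected (the operation is the verbatim
  truncated division); users needing unbiased amplitudes should use TVB or
  apply a point-spread correction downstream.
* TVB hyperparameters are engineering defaults, not reproductions of any
  published protocol; they are exposed in the config and echoed in run
  manifests.
* The inversion assumes the field estimate is mean-free and periodic (with
  optional zero padding); strong field sources just outside the imaging box
  violate this and are not modelled.
* Group-level/multi-subject analysis, DICOM/BIDS ingestion and raw-archive
  conversion are out of scope; inputs are NIfTI magnitude/phase pairs.
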