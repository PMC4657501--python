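# Methods

## The experiment being simulated

A FAIR pulsed-ASL experiment at 7 T with QUIPSS2 bolus truncation: TR 4 s,
TE 18 ms, TI₁ = 0.7 s, six ascending axial slices of a 64² matrix
(3×3×5 mm³, 2 mm gap), TI₂ search window 0.8–2.55 s.  Ten blocks of eight
control/tag pairs are acquired per scan (160 images, 640 s ≈ 11 min); the
TI₂ schedule of every block after the first is regenerated from the data
accumulated so far under a tissue mask (full WM, GM, or WM-minus-GM), so
the sampling adapts to the tissue of interest.  An unprepared TR 20 s scan
supplies the M0 calibration volume.

## Kinetic model

Single-compartment pulsed-ASL difference signal with a fixed bolus width
τ = TI₁ (the QUIPSS2 assumption); see README for the closed form.  Both
piece boundaries are continuous; the k → 0 degeneracy (blood and apparent
tissue relaxation equal) is handled through a series expansion of
(e^z − 1)/z rather than a hard threshold, so the model is smooth in its
parameters and complex-step differentiable.  Parameter gradients used by
the design criterion and the fitters are computed by complex-step
differentiation (machine-precision away from the piece boundaries;
verified against central differences).  The closed form is verified
against direct integration of the delivery–clearance ODE to 10⁻⁶ relative
tolerance.

Defaults, configurable in `FitConfig` / `KineticParams`:

| parameter | default | unit | why |
|---|---|---|---|
| T1 blood (7 T) | 2.1 | s | representative 7 T arterial blood value |
| T1 tissue | 1.4 WM / 1.9 GM | s | 7 T tissue values used in fitting |
| α (labelling efficiency) | 0.95 | – | adiabatic pulses ≥95% efficient |
| λ (partition coefficient) | 0.9 | mL/g | standard whole-brain value |
| τ (bolus width) | 0.7 | s | QUIPSS2 cutoff at TI₁; not estimated |
| T2* CSF (7 T) | 0.1 | s | ventricle CSF at long TE, order-of-magnitude value |

The full exchange correction q(t) is the default; `q_correction=False`
selects the simpler q ≡ 1 approximation.

A note on "where the curve peaks": with the truncated bolus the signal is
maximal exactly at Δt + τ (1.4 s for GM-like parameters, 1.59 s for
WM-like) and decays monotonically with the apparent T1′ afterwards.  The
often-quoted theoretical optimum near 1.8 s ≈ T1 corresponds to an
*untruncated* bolus, for which the arrival/decay balance point is
Δt + ln(T1′/T1b)/k ≈ 1.95–2.0 s at these relaxation times.  `peak_ti2`
reports the truncated-bolus maximum, i.e. the model actually fitted.

## Digital head phantom

Concentric in-plane compartments per slice — CSF ventricle core, WM
annulus, GM ribbon, air background — with radii proportional to the matrix
size and scaled per slice (0.85–1.0) so the middle slices carry the most
WM; the slice with the largest WM count is the designated slice for
transit-time reporting (ties break to the lower index).

Ground-truth maps: per-tissue CBF, ATT, T1, M0, mixed by partial-volume
fraction in interface voxels.  Defaults: ATT 0.70 s GM / 0.89 s WM (a
0.19 s offset, within the plausible adult range), M0 100 GM / 70 WM
(arbitrary units), M0-blood 110.  The cohort generator assigns per-subject
GM and WM CBF values spanning a realistic adult range (GM 33.6–69.3, mean
50.7; WM 14.7–19.6, mean 16.3 mL/100 g/min).

**Partial volume.**  The GM/WM interface is a one-voxel shell with an
exact 50:50 tissue mix.  Thresholding fraction maps at 0.5 therefore puts
interface voxels in *both* tissue masks, so the (WM−GM) subtraction mask
excludes them — the same mechanism a dual-mask ROI exclusion implements on
real data — while the full WM mask keeps them and is measurably inflated
by GM contamination (interface truth ≈ mean of the two tissue CBFs).  A
continuous-fraction ramp would instead leave partially contaminated voxels
inside the "cleaned" ROI, which defeats the point of the subtraction; the
idealised 50:50 shell is a deliberate simplification.

**Signal model.**  Static tissue is saturation-recovery steady state,
identical in control and tag; the tag additionally carries −ΔM at the
slice-corrected effective TI₂ (nominal + slice × 45 ms; the per-slice
readout delay is a chosen value, not a measured one).  Noise is iid
Gaussian per image (difference noise SD σ√2).  The ventricle CSF value of
the M0 scan is constructed so that the M0-blood calibration inverts
exactly in the noiseless case (T2* decay, partition coefficient and the
long-TR saturation factor all cancel by construction).

**Noise level.**  The default σ = 0.05 (tissue M0 ≈ 100) is calibrated so
that the voxelwise least-squares estimator operates in its asymptotic
regime for WM: ≈2% CBF bias after the full 80-pair acquisition, WM z ≈ 13,
essentially all WM voxels passing the z > 2 filter.  This matters because
an unregularised maximum-likelihood fit of this model develops a strong
positive CBF/ATT bias at low CNR: the (f, Δt) likelihood has a curved
ridge (later arrival trades off against higher perfusion) and the model is
non-smooth in Δt at the arrival point, so at noise levels where a sizable
minority of WM voxels fall below z = 2 the ROI mean is inflated by
15–40%.  Bayesian fitters with informative priors tolerate that regime;
a frequentist ROI-mean analysis does not.  The phantom default therefore
represents a cleaner acquisition than typical in-vivo data; the
boundary-noise regime (σ ≈ 0.2, where the z-filter discards ~25% of WM
voxels, comparable to in-vivo retention rates) is exercised explicitly in
the test suite.  What passing tests at default noise do **not** show:
robustness to motion, B1 inhomogeneity, physiological noise, or
macrovascular signal — none of which the phantom contains.

GM:WM peak difference-signal ratio implied by the defaults is ≈3.6:1
(CBF ratio 3.1 modulated by the shorter WM T1 and later arrival),
within the 2.5–5:1 range reported across the literature.

## Schedule optimisation

D-optimality on the (f, Δt) Fisher information at the pooled estimate,
`I = Σᵢ J(tᵢ)ᵀJ(tᵢ)` (the common noise variance does not affect the
argmax), maximised by coordinate exchange over a 10 ms grid with
deterministic starts (previous schedule, evenly spaced, replicated best
single point) and lowest-TI tie-breaking; A-optimality is available via
`FitConfig.design_criterion`.  Information is averaged over slice-delay
offsets weighted by the mask's voxel count per slice.  Duplicate TI₂
values are allowed (exact optimal designs replicate support points).  The
pooled fit uses the mask-mean ΔM curve (weighted by voxel count); by
default it refits all accumulated blocks, `refit_all_blocks=False`
restricts it to the latest block.  An empty mask or failed pooled fit
falls back to the previous schedule.  Feedback latency is collapsed to
zero — the schedule computed from blocks 1..k is used for block k+1.

Known limitation: a locally D-optimal design concentrates samples just
above the estimated arrival time, where the Δt-derivative is largest but
the model's regularity conditions fail (the derivative is discontinuous
across arrival).  Such designs are asymptotically optimal yet finite-noise
fragile; they are kept because they are what the criterion prescribes, and
their behaviour is characterised in the tests.

## Voxelwise fitting

Bounded nonlinear least squares over f ∈ [0, 300] mL/100 g/min,
Δt ∈ [0, 2.5] s.  Two equivalent paths: a per-voxel multi-start scipy
`least_squares` fit (starts Δt ∈ {0.2, 0.6, 1.0, 1.4}, perfusion profiled
linearly at each start), and a vectorised projected Levenberg–Marquardt
over all voxels of a slice at once, initialised by profiling f on a dense
Δt grid.  Both end with an exact linear-perfusion polish at the final Δt
(the optimiser can stall marginally short at the arrival-point kink); they
agree to <0.1% and the batch path is ~100× faster.  Standard errors are
curvature-based, `cov = σ̂² (JᵀJ)⁻¹` with σ̂² the residual variance
(n − 2 dof); z = f̂/SE(f̂), with the SE floored at 10⁻¹² so noise-free
fits stay significant rather than degenerate.  GM-mask voxels are fitted
with the GM tissue T1, all other in-brain voxels with the WM value;
negative ΔM observations are retained (clipping would bias low-CNR WM
fits).  Because z is in effect maximised over the transit-time search, its
null false-positive rate is slightly above nominal (~5.5% vs 5% at the
default design) — measured, and asserted as such in the tests.

## ROI analysis

GM-only and (WM−GM) ROIs drop voxels present in both thresholded masks;
the full WM ROI keeps them.  Significance filtering is strict (z > 2).
Subject means pool all slices (per-slice-first averaging is a config
option); across-subject statistics are unweighted mean ± SD.  The
GM-to-WM ratio divides the GM-only mean by the significant-(WM−GM) mean.
Transit-time statistics use the designated single slice.  Schedule
distributions are compared by a paired two-tailed t-test on per-subject
final-block mean TI₂, with zero-variance differences resolved analytically
(identical → P = 1; constant shift → P = 0).  An optional min/max-subject
exclusion reports a trimmed GM mean.  The GM-ATT source for the
transit-time difference is the GM-weighted run and the WM side comes from
the (WM−GM)-weighted run — tissue-matched, mirroring per-scan fitting of
each tissue-weighted acquisition.

## Numerical and design choices

- All randomness flows from one master seed through `SeedSequence` spawns
  (per subject, per mask variant, per block); identical config + seed
  reproduces outputs bit-for-bit.
- Coordinate-exchange ties and grid snapping resolve to the lowest TI₂,
  making schedules deterministic.
- The acceptance script runs the GM- and (WM−GM)-weighted variants (the
  two that feed its reported quantities); the study command runs all
  three.  Problem sizes are the full study protocol: 8 subjects, 64²×6,
  10 blocks × 8 pairs.
- Scan-time accounting in the manifest is computed from TR × images, not
  wall clock.

## Known limitations

- No motion, EPI distortion, coil sensitivity, B0/B1 effects or
  physiological noise; no macrovascular compartment (flow crushers are
  assumed perfect).
- Tissue masks come from partial-volume fractions, not from simulated
  dual-inversion-recovery contrast.
- The transit-time difference recovered at default noise carries a small
  positive residual bias (~+0.005 s) from the estimator's finite-noise
  curvature; it shrinks with noise but so does its Monte-Carlo
  uncertainty, so it remains detectable in a cohort sharing identical
  ground-truth ATT.
- At boundary-level noise the z > 2 filter removes both poorly determined
  low-perfusion fits and inflated ridge fits; its net effect on the ROI
  mean is then near-neutral rather than upward.
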