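# ossasl

In-silico optimal-sampling-strategy (OSS) arterial spin labeling at 7 T:
simulate FAIR-QUIPSS2 multi-TI perfusion acquisitions on a digital head
phantom, run the tissue-masked real-time feedback loop that adapts the
inversion-time schedule, fit the single-compartment kinetic model voxel by
voxel for cerebral blood flow (CBF) and arterial transit time (ATT), and
reproduce white-matter perfusion ROI statistics.

## Who this is for

Measuring white-matter (WM) CBF with ASL is hard: the WM control-tag
difference signal ΔM is several times weaker than gray matter's (GM) and
labelled blood arrives later, so generic acquisition timings waste samples.
This package is for perfusion-MRI methodologists who want a fully
controlled, ground-truth testbed for tissue-adaptive sampling: every stage
of the experiment — phantom, acquisition, schedule feedback, quantification,
ROI statistics — is simulated, deterministic per seed, and inspectable.

## The model and the method

**Kinetic model.** The pulsed-ASL difference signal with a QUIPSS2
saturation that truncates the bolus to width τ (= TI₁) is, for acquisition
time *t* (TI₂), transit time Δt, perfusion *f*:

```
ΔM(t) = 0                                          t < Δt
ΔM(t) = 2 α M0b f (t−Δt) e^(−t/T1b) q(t)           Δt ≤ t < Δt+τ
ΔM(t) = 2 α M0b f τ e^(−t/T1b) q(t)                t ≥ Δt+τ
```

with `1/T1' = 1/T1_tissue + f/λ`, `k = 1/T1b − 1/T1'`, and the exchange
correction `q(t)` equal to `(e^(ku) − 1)/(ku)` during arrival (u = t−Δt)
and `e^(ku)(1 − e^(−kτ))/(kτ)` during clearance.  *f* is mL/100 g/min on
every public interface (internally divided by 6000).

**Optimal sampling.**  Each block acquires N control/tag pairs at N TI₂
values in the 0.8–2.55 s window.  After a block, the model is fitted to the
mask-pooled ΔM curve from all data so far, and the next schedule maximises
the D-optimality criterion `det Σᵢ J(tᵢ)ᵀJ(tᵢ)` for (f, Δt) at the pooled
estimate (coordinate exchange on a 10 ms grid, slice-delay aware).  Block 1
is always evenly spaced (0.25 s steps).

**Quantification.**  Pairwise subtraction, per-slice effective TI₂
(`nominal + slice × 45 ms`), M0-blood calibrated from ventricle CSF
(`M0b = mean(M0_csf) · e^(TE/T2*csf) / λ`), then bounded multi-start
nonlinear least squares per voxel with curvature standard errors; the
goodness-of-fit statistic is `z = f̂ / SE(f̂)` and ROI analysis keeps
voxels with z > 2 (≈95% confidence of nonzero perfusion).

## Worked example

```python
from ossasl import StudyConfig, build_rois, filter_significant
from ossasl.pipeline import run_subject

config = StudyConfig()
config.mask_variants = ("gm", "wm-gm")
subject = run_subject(config, 0, seed=42)
rois = build_rois(subject["masks"]["wm"], subject["masks"]["gm"])
wmg = subject["fits"]["wm-gm"]
sig, frac = filter_significant(rois["wm_minus_gm"], wmg.z, 2.0)
print(frac, wmg.cbf[sig].mean())
```

Running `python examples/04_voxelwise_fitting.py` (the same computation)
prints:

```
M0-blood calibration: 110.00
significant (z>2) fraction of (WM-GM) voxels: 1.00
fitted CBF, (WM-GM) z>2 ROI: 16.68 mL/100 g/min (truth 16.3)
fitted CBF, GM-only ROI:     43.31 mL/100 g/min (truth 43.3)
ATT on slice 2: WM 0.898 s, GM 0.700 s, difference 0.198 s (truth 0.190 s)
```

The phantom's WM ground truth for this subject is 16.3 mL/100 g/min; the
full pipeline (adaptive schedule → 80 noisy pairs → voxel fits → ROI mean)
recovers it to ~2%, and the 0.19 s GM-to-WM transit-time offset to ~4%.
The other scripts in `examples/` walk through the kinetic curves, the
phantom, the feedback loop and a multi-subject cohort; `ossasl --help`
exposes the same pipeline as a command line (`simulate`, `run-study`,
`fit`, `report`).

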