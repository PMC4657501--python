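"""Digital head phantom and simulated FAIR control/tag acquisitions.

The phantom is the study's synthetic stand-in for a subject's head: six
axial 64x64 slices of concentric tissue compartments (CSF ventricle core,
white-matter annulus, gray-matter ribbon, background), with per-slice radii
tapered so the middle slices carry the most white matter.  Voxels on the
GM/WM interface carry an exact 50:50 partial-volume mix one voxel wide, so
that fraction-threshold masks put them in *both* tissue masks — this is the
mechanism by which the (WM-GM) mask subtraction removes partial-volumed
voxels downstream.

Simulated acquisitions produce control/tag pairs whose difference equals
the closed-form kinetic curve at each voxel's ground-truth parameters (at
the slice-corrected effective TI2) plus iid Gaussian image noise; the
static tissue signal is identical in both conditions.  An unprepared
calibration volume emulates the long-TR M0 scan, with ventricle CSF values
constructed to invert the M0-blood calibration formula exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .config import AcquisitionConfig, FitConfig, PhantomSpec
from .kinetic import _delta_m_core, CBF_PER_SI

__all__ = [
    "PhantomVolume", "AcquisitionSeries",
    "make_phantom", "simulate_masks", "simulate_acquisition", "simulate_m0",
    "slice_scales", "calibrate_noise_sigma",
]

# in-plane compartment radii as fractions of the matrix size
_R_CSF = 0.078
_R_WM = 0.234
_R_GM = 0.344


def slice_scales(n_slices: int) -> np.ndarray:
    """Per-slice radius scale, tapering towards the extremal slices."""
    z = np.arange(n_slices)
    return 0.85 + 0.15 * np.sin(np.pi * (z + 0.5) / n_slices)


@dataclass
class PhantomVolume:
    """Partial-volume fraction maps plus voxelwise ground-truth maps."""
    pv: dict                   # tissue -> (X, Y, Z) fraction map
    truth: dict                # 'cbf', 'att', 't1', 'm0' -> (X, Y, Z)
    spec: PhantomSpec
    affine: np.ndarray

    @property
    def shape(self):
        return self.truth["cbf"].shape


@dataclass
class AcquisitionSeries:
    """Ordered control/tag volumes with per-image metadata.

    ``meta`` has one row per volume: volume index, block, nominal TI2 (s)
    and condition ('control' | 'tag').  The effective TI2 of slice ``z`` is
    ``nominal + z * slice_delay`` (ascending acquisition).
    """
    images: np.ndarray         # (X, Y, Z, n_volumes)
    meta: pd.DataFrame
    slice_delay: float
    affine: np.ndarray
    m0_volume: Optional[np.ndarray] = None
    csf_roi: Optional[np.ndarray] = None   # boolean mask

    @property
    def n_slices(self) -> int:
        return self.images.shape[2]

    def effective_ti2(self) -> np.ndarray:
        """(n_volumes, n_slices) effective TI2 per image and slice."""
        nominal = self.meta["ti2"].to_numpy()[:, None]
        return nominal + np.arange(self.n_slices)[None, :] * self.slice_delay

    @staticmethod
    def concat(parts: list) -> "AcquisitionSeries":
        first = parts[0]
        meta = pd.concat([p.meta for p in parts], ignore_index=True)
        meta["volume"] = np.arange(len(meta))
        return AcquisitionSeries(
            images=np.concatenate([p.images for p in parts], axis=3),
            meta=meta, slice_delay=first.slice_delay, affine=first.affine,
            m0_volume=first.m0_volume, csf_roi=first.csf_roi)


def _affine(spec: PhantomSpec) -> np.ndarray:
    dx, dy, dz = spec.voxel_dims
    return np.diag([dx, dy, dz + spec.slice_gap, 1.0])


def make_phantom(spec: PhantomSpec,
                 acquisition: AcquisitionConfig | None = None,
                 fit: FitConfig | None = None) -> PhantomVolume:
    """Build the phantom volume for ``spec`` (deterministic).

    ``acquisition``/``fit`` supply the echo time, CSF T2* and partition
    coefficient used to derive the ventricle-CSF equilibrium signal when the
    spec leaves it at the derive-me sentinel value 0.
    """
    acq = acquisition or AcquisitionConfig()
    fitc = fit or FitConfig()
    m = spec.matrix
    rv, rw, rg = _R_CSF * m, _R_WM * m, _R_GM * m
    if rg >= m / 2:
        raise ValueError("geometry impossible: outer radius exceeds grid")
    w = spec.pv_boundary_width / 2.0

    centre = (m - 1) / 2.0
    x, y = np.meshgrid(np.arange(m), np.arange(m), indexing="ij")
    r_xy = np.hypot(x - centre, y - centre)

    shape = (m, m, spec.n_slices)
    pv = {t: np.zeros(shape) for t in ("gm", "wm", "csf")}
    scales = slice_scales(spec.n_slices)
    for z, s in enumerate(scales):
        r = r_xy / s
        csf = r < rv
        wm = (r >= rv) & (r < rw - w)
        mix = (r >= rw - w) & (r < rw + w) if spec.pv_boundary_width else \
            np.zeros_like(csf)
        gm = (r >= rw + w) & (r < rg) & ~mix
        pv["csf"][:, :, z] = csf
        pv["wm"][:, :, z] = wm + 0.5 * mix
        pv["gm"][:, :, z] = gm + 0.5 * mix

    tp = spec.tissue_params
    csf_m0 = tp["csf"].m0
    if csf_m0 == 0.0:
        # invert the M0-blood calibration so that a noiseless round trip
        # recovers m0_blood exactly (T2* decay, partition coefficient and
        # the long-TR saturation factor all cancel)
        sat = 1.0 - np.exp(-acq.m0_tr / tp["csf"].t1)
        csf_m0 = spec.m0_blood * fitc.lam * np.exp(-acq.te / fitc.t2star_csf) / sat
    values = {
        "cbf": {"gm": tp["gm"].cbf, "wm": tp["wm"].cbf, "csf": tp["csf"].cbf},
        "att": {"gm": tp["gm"].att, "wm": tp["wm"].att, "csf": tp["csf"].att},
        "t1": {"gm": tp["gm"].t1, "wm": tp["wm"].t1, "csf": tp["csf"].t1},
        "m0": {"gm": tp["gm"].m0, "wm": tp["wm"].m0, "csf": csf_m0},
    }
    truth = {}
    for name, per_tissue in values.items():
        vol = np.zeros(shape)
        for t in ("gm", "wm", "csf"):
            vol += pv[t] * per_tissue[t]
        if name == "t1":
            vol[vol == 0] = tp["wm"].t1  # harmless filler outside the head
        truth[name] = vol
    return PhantomVolume(pv=pv, truth=truth, spec=spec, affine=_affine(spec))


def simulate_masks(phantom: PhantomVolume, threshold: float = 0.5) -> dict:
    """Binary tissue masks by partial-volume thresholding.

    ``mask[t] = pv[t] >= threshold``; additionally ``wm-gm`` is the WM mask
    minus voxels also present in the GM mask (the partial-volume exclusion).
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    masks = {t: phantom.pv[t] >= threshold for t in ("gm", "wm", "csf")}
    masks["wm-gm"] = masks["wm"] & ~masks["gm"]
    return masks


def _truth_delta_m(phantom: PhantomVolume, eff_ti2_per_slice: np.ndarray,
                   acq: AcquisitionConfig, fit: FitConfig) -> np.ndarray:
    """Noiseless ΔM volume for one nominal TI2 (eff TI2 given per slice)."""
    t = np.broadcast_to(eff_ti2_per_slice[None, None, :], phantom.shape)
    return _delta_m_core(
        t, phantom.truth["cbf"] / CBF_PER_SI, phantom.truth["att"],
        acq.ti1, fit.t1_blood, phantom.truth["t1"], fit.alpha,
        phantom.spec.m0_blood, fit.lam, q_correction=True)


def _static_signal(phantom: PhantomVolume, tr: float) -> np.ndarray:
    """Saturation-recovery steady-state static tissue signal at repetition
    time ``tr``."""
    return phantom.truth["m0"] * (1.0 - np.exp(-tr / phantom.truth["t1"]))


def simulate_acquisition(phantom: PhantomVolume, schedule,
                         acq: AcquisitionConfig, fit: FitConfig | None = None,
                         seed=None) -> AcquisitionSeries:
    """Simulate N control/tag pairs for one TI2 schedule (one block).

    ``seed`` may be an int, a Generator, or None (noise-free if the spec's
    noise_sigma is zero).  Control and tag get independent N(0, sigma) image
    noise, so the pairwise difference carries noise of SD sigma * sqrt(2).
    """
    fit = fit or FitConfig()
    lo, hi = acq.window
    ti2s = np.asarray(schedule.ti2_values, dtype=float)
    if np.any(ti2s < lo - 1e-9) or np.any(ti2s > hi + 1e-9):
        raise ValueError("schedule outside the TI2 search window")
    rng = seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(seed)
    sigma = phantom.spec.noise_sigma
    static = _static_signal(phantom, acq.tr)
    z_idx = np.arange(phantom.shape[2])

    vols, rows = [], []
    for i, ti2 in enumerate(ti2s):
        eff = ti2 + z_idx * acq.slice_delay
        dm = _truth_delta_m(phantom, eff, acq, fit)
        control = static + (rng.normal(0.0, sigma, phantom.shape)
                            if sigma > 0 else 0.0)
        tag = static - dm + (rng.normal(0.0, sigma, phantom.shape)
                             if sigma > 0 else 0.0)
        for cond, vol in (("control", control), ("tag", tag)):
            rows.append({"volume": len(vols), "block": schedule.block_index,
                         "ti2": ti2, "condition": cond})
            vols.append(vol)
    return AcquisitionSeries(
        images=np.stack(vols, axis=3), meta=pd.DataFrame(rows),
        slice_delay=acq.slice_delay, affine=phantom.affine)


def simulate_m0(phantom: PhantomVolume, acq: AcquisitionConfig,
                fit: FitConfig | None = None, seed=None):
    """Unprepared long-TR calibration volume and the ventricle CSF ROI.

    Returns ``(m0_volume, csf_roi)``.  The CSF values are constructed (in
    :func:`make_phantom`) such that the downstream M0-blood calibration is
    exact in the noiseless case.
    """
    fit = fit or FitConfig()
    volume = _static_signal(phantom, acq.m0_tr)
    if seed is not None:
        rng = seed if isinstance(seed, np.random.Generator) else \
            np.random.default_rng(seed)
        if phantom.spec.noise_sigma > 0:
            volume = volume + rng.normal(0.0, phantom.spec.noise_sigma,
                                         volume.shape)
    csf_roi = phantom.pv["csf"] >= 1.0
    return volume, csf_roi


def calibrate_noise_sigma(target_z: float = 3.5,
                          acq: AcquisitionConfig | None = None,
                          fit: FitConfig | None = None,
                          spec: PhantomSpec | None = None,
                          slice_index: int = 2) -> float:
    """Image-noise SD placing the mean WM voxel at CBF z ~ ``target_z``.

    Runs the idealised (noise-free) feedback loop for a WM voxel — one
    evenly spaced block followed by optimal blocks designed at the true
    parameters — accumulates the Fisher information of the resulting
    effective-TI2 design, and solves for the sigma at which the CBF
    standard error gives ``z = cbf / se = target_z``.  The design itself is
    independent of sigma, so this is a fixed point, not an iteration.
    """
    from .scheduler import initial_schedule, optimal_schedule
    from .kinetic import KineticParams, sensitivity

    acq = acq or AcquisitionConfig()
    fit = fit or FitConfig()
    spec = spec or PhantomSpec()
    wm = spec.tissue_params["wm"]
    params = KineticParams(
        f=wm.cbf, delta_t=wm.att, tau=acq.ti1, t1_blood=fit.t1_blood,
        t1_tissue=wm.t1, alpha=fit.alpha, m0_blood=spec.m0_blood,
        lam=fit.lam, q_correction=fit.q_correction)
    even = initial_schedule(acq.n_ti, acq.window).ti2_values
    opt = optimal_schedule(params, acq.window, acq.n_ti,
                           slice_offsets=np.array([slice_index * acq.slice_delay]),
                           criterion=fit.design_criterion).ti2_values
    design = np.concatenate([even] + [opt] * (acq.n_blocks - 1))
    J = sensitivity(design + slice_index * acq.slice_delay, params)
    info = J.T @ J
    se_unit = np.sqrt(np.linalg.inv(info)[0, 0])  # SE of f per unit noise SD
    return float(wm.cbf / (target_z * np.sqrt(2.0) * se_unit))
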