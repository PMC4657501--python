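"""End-to-end simulated study: phantom -> masks -> M0 -> OSS runs -> fits -> ROI report.

One subject's protocol mirrors the scanned experiment: tissue masks are
derived from the phantom, an unprepared long-TR M0 scan calibrates the
arterial-blood magnetization from ventricle CSF, and one OSS feedback loop
is run per mask weighting (full WM, GM, and the partial-volume-cleaned
WM-GM), each followed by voxelwise kinetic fitting.  A cohort run repeats
this per subject with per-subject ground-truth CBF values and summarises
ROI statistics across subjects.
"""

from __future__ import annotations

import copy
import dataclasses
import json
import logging
from pathlib import Path

import numpy as np

from . import io as ossio
from .config import StudyConfig, dump_config
from .fitting import calibrate_m0_blood, fit_volume, pairwise_subtract
from .phantom import make_phantom, simulate_acquisition, simulate_m0, \
    simulate_masks
from .roi import ROIReport, cohort_summary
from .scheduler import run_feedback_loop

__all__ = ["subject_phantom_spec", "run_subject", "run_study", "StudyResult"]

log = logging.getLogger(__name__)

_MASK_TISSUE_T1 = {"gm": "t1_gm", "wm": "t1_wm", "wm-gm": "t1_wm"}


def subject_phantom_spec(config: StudyConfig, subject: int):
    """Phantom spec for one subject: cohort ground truths substituted."""
    spec = copy.deepcopy(config.phantom)
    cohort = config.cohort
    spec.tissue_params["gm"].cbf = cohort.gm_cbf[subject]
    spec.tissue_params["wm"].cbf = cohort.wm_cbf[subject]
    spec.tissue_params["gm"].att = cohort.gm_att
    spec.tissue_params["wm"].att = cohort.wm_att
    return spec


def run_subject(config: StudyConfig, subject: int, seed) -> dict:
    """Simulate and quantify one subject; returns masks/fits/histories."""
    acq, fit = config.acquisition, config.fit
    spec = subject_phantom_spec(config, subject)
    phantom = make_phantom(spec, acq, fit)
    masks = simulate_masks(phantom, config.analysis.mask_threshold)
    ss = seed if isinstance(seed, np.random.SeedSequence) else \
        np.random.SeedSequence(seed)
    children = ss.spawn(len(config.mask_variants) + 1)
    m0_volume, csf_roi = simulate_m0(
        phantom, acq, fit, seed=np.random.default_rng(children[-1]))
    m0_blood = calibrate_m0_blood(m0_volume, csf_roi, acq.te,
                                  fit.t2star_csf, fit.lam)
    fits, histories, series_by_variant = {}, {}, {}
    for variant, child in zip(config.mask_variants, children):
        t1_tissue = getattr(fit, _MASK_TISSUE_T1[variant])
        series, history = run_feedback_loop(
            phantom, masks[variant], acq, fit, t1_tissue=t1_tissue,
            m0_blood=m0_blood, n_blocks=acq.n_blocks,
            seed=np.random.default_rng(child))
        series.m0_volume, series.csf_roi = m0_volume, csf_roi
        fits[variant] = fit_volume(series, masks, m0_blood, fit, tau=acq.ti1)
        histories[variant] = history
        series_by_variant[variant] = series
    return {"phantom": phantom, "masks": masks, "m0_blood": m0_blood,
            "fits": fits, "histories": histories,
            "series": series_by_variant}


@dataclasses.dataclass
class StudyResult:
    report: ROIReport
    subjects: list
    manifest: dict


def _manifest(config: StudyConfig) -> dict:
    acq = config.acquisition
    n_images = acq.n_blocks * acq.n_ti * 2
    asl_seconds = n_images * acq.tr
    return {
        "n_subjects": config.cohort.n_subjects,
        "mask_variants": list(config.mask_variants),
        "images_per_asl_scan": n_images,
        "asl_scan_seconds": asl_seconds,
        "asl_scan_minutes_rounded": round(asl_seconds / 60),
        "m0_scan_seconds": acq.m0_tr,
        "subject_seconds": asl_seconds * len(config.mask_variants) + acq.m0_tr,
    }


def run_study(config: StudyConfig, outdir=None, seed=None) -> StudyResult:
    """Run the full simulated cohort study.

    ``seed`` overrides ``config.seed``.  If ``outdir`` is given, the
    resolved config, per-subject maps and schedules, the ROI report (CSV
    and JSON) and a manifest are written there.
    """
    seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    subject_seeds = ss.spawn(config.cohort.n_subjects)
    subjects = []
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
        dump_config(config, outdir / "config_resolved.yaml")
    manifest = _manifest(config)
    try:
        for i in range(config.cohort.n_subjects):
            log.info("subject %d/%d", i + 1, config.cohort.n_subjects)
            subj = run_subject(config, i, subject_seeds[i])
            subjects.append(subj)
            if outdir is not None:
                sdir = outdir / f"subject_{i + 1:02d}"
                for variant in config.mask_variants:
                    tag = variant.replace("-", "_")
                    ossio.write_fit_maps(subj["fits"][variant],
                                         subj["phantom"].affine, sdir,
                                         prefix=f"{tag}_")
                    ossio.write_schedule_history(
                        subj["histories"][variant],
                        sdir / f"{tag}_schedule.tsv")
                    if config.analysis.save_figures:
                        ossio.write_map_figures(subj["fits"][variant],
                                                sdir, prefix=f"{tag}_")
    finally:
        if outdir is not None:
            manifest["subjects_completed"] = len(subjects)
            (outdir / "manifest.json").write_text(
                json.dumps(manifest, indent=2))
    report = cohort_summary(
        subjects, z_threshold=config.analysis.z_threshold,
        per_slice=config.analysis.per_slice_averaging,
        exclude_outlier_subjects=config.analysis.exclude_outlier_subjects)
    if outdir is not None:
        report.to_csv(outdir / "roi_report.csv")
        (outdir / "roi_report.json").write_text(
            json.dumps(report.to_json(), indent=2, default=float))
    return StudyResult(report=report, subjects=subjects, manifest=manifest)


def simulate_to_disk(config: StudyConfig, outdir, seed=None) -> None:
    """Phantom, masks and M0 calibration volume for subject 0, on disk."""
    seed = config.seed if seed is None else seed
    acq, fit = config.acquisition, config.fit
    spec = subject_phantom_spec(config, 0)
    spec.seed = seed
    phantom = make_phantom(spec, acq, fit)
    masks = simulate_masks(phantom, config.analysis.mask_threshold)
    m0_volume, csf_roi = simulate_m0(phantom, acq, fit)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ossio.write_phantom(phantom, outdir)
    for name, mask in masks.items():
        tag = name.replace("-", "_")
        ossio.write_nifti(mask.astype(float), phantom.affine,
                          outdir / f"mask_{tag}.nii")
    ossio.write_nifti(m0_volume, phantom.affine, outdir / "m0.nii")
    ossio.write_nifti(csf_roi.astype(float), phantom.affine,
                      outdir / "csf_roi.nii")
    dump_config(config, outdir / "config_resolved.yaml")
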