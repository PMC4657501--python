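"""ROI statistics: mask algebra, significance filtering, cohort summaries.

Reproduces the study-style analysis: per-subject ROI means of fitted CBF
and ATT for gray matter, the partial-volume-cleaned (WM-GM) mask (all and
z > 2 voxels), and the full WM mask; across-subject mean +/- SD; the
GM:(WM-GM) CBF ratio; the GM-to-WM transit-time difference on a designated
single slice; and paired t-tests (partial-volume effect, schedule
comparison).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ROIReport", "build_rois", "filter_significant", "designated_slice",
    "cohort_summary", "compare_schedules",
]

log = logging.getLogger(__name__)


def build_rois(wm_mask: np.ndarray, gm_mask: np.ndarray) -> dict:
    """ROIs from thresholded tissue masks.

    ``gm_only`` and ``wm_minus_gm`` drop voxels present in both masks (the
    partial-volume exclusion); ``wm`` is the full WM mask.
    """
    wm_mask = np.asarray(wm_mask, dtype=bool)
    gm_mask = np.asarray(gm_mask, dtype=bool)
    if wm_mask.shape != gm_mask.shape:
        raise ValueError("mask grids do not match")
    overlap = wm_mask & gm_mask
    return {"gm_only": gm_mask & ~overlap,
            "wm_minus_gm": wm_mask & ~overlap,
            "wm": wm_mask}


def filter_significant(roi: np.ndarray, z_map: np.ndarray,
                       threshold: float = 2.0):
    """Voxels of ``roi`` with fitted-CBF z strictly above ``threshold``.

    Returns ``(mask, fraction)``; the retained fraction is NaN (flagged)
    for an empty ROI.
    """
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != np.shape(z_map):
        raise ValueError("z map does not align with the ROI grid")
    kept = roi & (z_map > threshold)
    n = roi.sum()
    fraction = kept.sum() / n if n else float("nan")
    return kept, float(fraction)


def designated_slice(wm_mask: np.ndarray) -> int:
    """Slice with the most WM voxels (ties -> lower index)."""
    counts = np.asarray(wm_mask, dtype=bool).sum(axis=(0, 1))
    return int(np.argmax(counts))


def _roi_mean(values: np.ndarray, roi: np.ndarray,
              per_slice: bool = False) -> float:
    if not roi.any():
        return float("nan")
    if per_slice:
        means = [values[:, :, z][roi[:, :, z]].mean()
                 for z in range(roi.shape[2]) if roi[:, :, z].any()]
        return float(np.mean(means))
    return float(values[roi].mean())


def _final_block_mean(history) -> float:
    return float(np.mean(history[-1].ti2_values))


def compare_schedules(histories_a: list, histories_b: list):
    """Paired two-tailed t-test on per-subject mean final-block TI2.

    ``histories_*`` are per-subject schedule histories, paired by index.
    Returns ``(t, df, p)``.  Degenerate zero-variance differences are
    resolved analytically: identical schedules give (0, n-1, 1); a constant
    nonzero shift gives (+/-inf, n-1, 0).
    """
    if len(histories_a) != len(histories_b):
        raise ValueError("paired comparison requires equal subject counts")
    n = len(histories_a)
    if n < 2:
        raise ValueError("need >= 2 subjects for a paired test")
    a = np.array([_final_block_mean(h) for h in histories_a])
    b = np.array([_final_block_mean(h) for h in histories_b])
    d = a - b
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d.mean(), 0.0):
            return 0.0, n - 1, 1.0
        return float(np.sign(d.mean()) * np.inf), n - 1, 0.0
    t, p = stats.ttest_rel(a, b)
    return float(t), n - 1, float(p)


@dataclass
class ROIReport:
    """Per-subject ROI table plus across-subject summary statistics."""
    per_subject: pd.DataFrame
    summary: dict

    def to_csv(self, path) -> None:
        table = self.per_subject.copy()
        mean_row = {"subject": "mean"}
        sd_row = {"subject": "sd"}
        for col in table.columns:
            if col == "subject":
                continue
            vals = table[col].to_numpy(dtype=float)
            mean_row[col] = np.nanmean(vals)
            sd_row[col] = np.nanstd(vals, ddof=1) \
                if np.sum(~np.isnan(vals)) > 1 else np.nan
        full = pd.concat([table, pd.DataFrame([mean_row, sd_row])],
                         ignore_index=True)
        full.to_csv(path, index=False)

    def to_json(self) -> dict:
        return {"per_subject": self.per_subject.to_dict(orient="records"),
                "summary": self.summary}


def cohort_summary(subjects: list, z_threshold: float = 2.0,
                   per_slice: bool = False,
                   exclude_outlier_subjects: bool = False) -> ROIReport:
    """Across-subject ROI statistics for a fitted cohort.

    Each element of ``subjects`` is a dict with keys ``masks`` (tissue
    masks), ``fits`` (mask-variant name -> FitMaps) and optionally
    ``histories`` (mask-variant name -> schedule history).  ROI CBF/ATT
    means use the fit of the matching tissue-weighted run: GM statistics
    from the 'gm' run, (WM-GM) from 'wm-gm', full-WM from 'wm'.

    Voxel means are taken per subject over all slices pooled (optionally
    per slice first), then averaged unweighted across subjects.  A subject
    with an empty ROI is excluded from that cell with a logged warning.
    """
    if not subjects:
        raise ValueError("need at least one subject")
    rows = []
    for i, subj in enumerate(subjects):
        masks = subj["masks"]
        fits = subj["fits"]
        rois = build_rois(masks["wm"], masks["gm"])
        row = {"subject": i + 1}
        gm_fit = fits.get("gm")
        wmg_fit = fits.get("wm-gm")
        wm_fit = fits.get("wm")
        if gm_fit is not None:
            row["gm_cbf"] = _roi_mean(gm_fit.cbf, rois["gm_only"], per_slice)
        if wmg_fit is not None:
            row["wmg_cbf"] = _roi_mean(wmg_fit.cbf, rois["wm_minus_gm"],
                                       per_slice)
            sig, frac = filter_significant(rois["wm_minus_gm"], wmg_fit.z,
                                           z_threshold)
            row["wmg_sig_cbf"] = _roi_mean(wmg_fit.cbf, sig, per_slice)
            row["sig_fraction"] = frac
        if wm_fit is not None:
            wm_sig, _ = filter_significant(rois["wm"], wm_fit.z, z_threshold)
            row["wm_sig_cbf"] = _roi_mean(wm_fit.cbf, wm_sig, per_slice)
        # transit times on the designated single slice
        z_slice = designated_slice(masks["wm"])
        slice_sel = np.zeros_like(masks["wm"], dtype=bool)
        slice_sel[:, :, z_slice] = True
        if gm_fit is not None:
            row["gm_att"] = _roi_mean(gm_fit.att, rois["gm_only"] & slice_sel)
        if wmg_fit is not None:
            sig, _ = filter_significant(rois["wm_minus_gm"] & slice_sel,
                                        wmg_fit.z, z_threshold)
            row["wmg_sig_att"] = _roi_mean(wmg_fit.att, sig)
        if "gm_att" in row and "wmg_sig_att" in row:
            row["att_diff"] = row["wmg_sig_att"] - row["gm_att"]
        for key, value in row.items():
            if key != "subject" and isinstance(value, float) and np.isnan(value):
                log.warning("subject %d: empty ROI for %s; excluded", i + 1, key)
        rows.append(row)
    table = pd.DataFrame(rows)

    summary = {}
    for col in table.columns:
        if col == "subject":
            continue
        vals = table[col].to_numpy(dtype=float)
        summary[f"{col}_mean"] = float(np.nanmean(vals))
        summary[f"{col}_sd"] = float(np.nanstd(vals, ddof=1)) \
            if np.sum(~np.isnan(vals)) > 1 else float("nan")
    if {"gm_cbf_mean", "wmg_sig_cbf_mean"} <= summary.keys():
        summary["gm_to_wm_ratio"] = (summary["gm_cbf_mean"]
                                     / summary["wmg_sig_cbf_mean"])
    if exclude_outlier_subjects and "gm_cbf" in table:
        vals = table["gm_cbf"].dropna().to_numpy()
        if len(vals) > 2:
            trimmed = np.sort(vals)[1:-1]
            summary["gm_cbf_trimmed_mean"] = float(trimmed.mean())
            summary["gm_cbf_trimmed_sd"] = float(trimmed.std(ddof=1))
    # partial-volume effect: full-WM z>2 mean vs (WM-GM) z>2 mean, paired
    if {"wm_sig_cbf", "wmg_sig_cbf"} <= set(table.columns) and len(table) >= 2:
        a = table["wm_sig_cbf"].to_numpy(dtype=float)
        b = table["wmg_sig_cbf"].to_numpy(dtype=float)
        keep = ~(np.isnan(a) | np.isnan(b))
        if keep.sum() >= 2:
            t, p = stats.ttest_rel(a[keep], b[keep])
            summary["pv_ttest_t"] = float(t)
            summary["pv_ttest_p"] = float(p)
    # schedule comparison: (WM-GM)-weighted vs GM-weighted final TI2s
    hists = [s.get("histories", {}) for s in subjects]
    if all({"wm-gm", "gm"} <= set(h.keys()) for h in hists) and len(hists) >= 2:
        t, df, p = compare_schedules([h["wm-gm"] for h in hists],
                                     [h["gm"] for h in hists])
        summary["schedule_ttest_t"] = t
        summary["schedule_ttest_df"] = df
        summary["schedule_ttest_p"] = p
    return ROIReport(per_subject=table, summary=summary)
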