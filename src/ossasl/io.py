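"""NIfTI / TSV / CSV persistence for phantoms, series, schedules and maps."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .fitting import DeltaMSeries, FitMaps
from .phantom import AcquisitionSeries, PhantomVolume

__all__ = [
    "write_nifti", "read_nifti", "write_phantom", "write_series",
    "read_delta_m_series", "write_fit_maps", "write_schedule_history",
]


def write_nifti(data: np.ndarray, affine: np.ndarray, path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine),
             str(path))


def read_nifti(path):
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), img.affine


def write_phantom(phantom: PhantomVolume, outdir) -> None:
    """Truth and partial-volume maps as NIfTI-1."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, vol in phantom.truth.items():
        write_nifti(vol, phantom.affine, outdir / f"truth_{name}.nii")
    for tissue, vol in phantom.pv.items():
        write_nifti(vol, phantom.affine, outdir / f"pv_{tissue}.nii")


def write_series(series: AcquisitionSeries, prefix) -> None:
    """4D volume plus a TSV sidecar (volume, block, ti2, condition)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    write_nifti(series.images, series.affine, f"{prefix}.nii")
    series.meta.to_csv(f"{prefix}.tsv", sep="\t", index=False)
    if series.m0_volume is not None:
        write_nifti(series.m0_volume, series.affine, f"{prefix}_m0.nii")


def read_delta_m_series(nifti_path, sidecar_path,
                        slice_delay: float = 0.045) -> DeltaMSeries:
    """External multi-TI ΔM data: 4D NIfTI + TSV with a ``ti2`` column."""
    data, _ = read_nifti(nifti_path)
    meta = pd.read_csv(sidecar_path, sep="\t")
    if "ti2" not in meta.columns:
        raise ValueError("sidecar is missing the required 'ti2' column")
    if len(meta) != data.shape[3]:
        raise ValueError("sidecar rows do not match the number of volumes")
    block = meta["block"].to_numpy() if "block" in meta.columns else None
    return DeltaMSeries(dm=data, ti2=meta["ti2"].to_numpy(dtype=float),
                        slice_delay=slice_delay, block=block)


def write_fit_maps(maps: FitMaps, affine: np.ndarray, outdir,
                   prefix: str = "") -> None:
    """CBF/ATT/z/convergence maps as NIfTI plus a per-voxel TSV table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, vol in (("cbf", maps.cbf), ("att", maps.att), ("z", maps.z),
                      ("converged", maps.converged.astype(np.float32))):
        write_nifti(vol, affine, outdir / f"{prefix}{name}.nii")
    idx = np.argwhere(maps.fitted)
    table = pd.DataFrame({
        "x": idx[:, 0], "y": idx[:, 1], "z_slice": idx[:, 2],
        "cbf": maps.cbf[maps.fitted], "att": maps.att[maps.fitted],
        "se_f": maps.se_f[maps.fitted], "se_att": maps.se_att[maps.fitted],
        "z_stat": maps.z[maps.fitted],
        "converged": maps.converged[maps.fitted],
    })
    table.to_csv(outdir / f"{prefix}voxels.tsv", sep="\t", index=False)


def write_map_figures(maps: FitMaps, outdir, prefix: str = "") -> None:
    """Optional PNG previews of the fitted maps.

    Display ranges follow perfusion-imaging convention: CBF on a GM-scaled
    0-120 and a WM-scaled 0-35 mL/100 g/min window, ATT on 0-1.2 s.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    panels = [("cbf_gm_range", maps.cbf, 0, 120),
              ("cbf_wm_range", maps.cbf, 0, 35),
              ("att", maps.att, 0, 1.2)]
    n_slices = maps.cbf.shape[2]
    for name, vol, lo, hi in panels:
        fig, axes = plt.subplots(1, n_slices, figsize=(2.2 * n_slices, 2.4))
        for z, ax in enumerate(np.atleast_1d(axes)):
            im = ax.imshow(vol[:, :, z].T, vmin=lo, vmax=hi, cmap="inferno",
                           origin="lower")
            ax.set_axis_off()
        fig.colorbar(im, ax=axes, shrink=0.8)
        fig.savefig(outdir / f"{prefix}{name}.png", dpi=100)
        plt.close(fig)


def write_schedule_history(history, path) -> None:
    """Schedule history as TSV: block, index, ti2 (seconds)."""
    rows = [{"block": s.block_index, "index": i, "ti2": float(v)}
            for s in history for i, v in enumerate(s.ti2_values)]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
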