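"""Optimal sampling strategy: feedback-driven TI2 schedule generation.

Each acquisition block delivers N control/tag pairs at N TI2 values.  After
a block, the kinetic model is fitted to the mask-pooled ΔM curve from all
data so far, and the next block's TI2 schedule is chosen to maximise the
information that N new samples carry about (CBF, ATT) at the pooled
estimate.  The information criterion is D-optimality — maximise
``det I`` with ``I = sum_i J(t_i)^T J(t_i)`` and ``J`` the model gradient
with respect to (f, delta_t) — optimised by coordinate exchange over a
10 ms grid on the search window (A-optimality available as an option).
Slice-timing is folded in: the information of a nominal TI2 is averaged
over the slice-delay offsets of the slices that contain masked voxels.

The first block is always the evenly spaced schedule, emulating a scanner
that starts with no subject-specific knowledge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import AcquisitionConfig, FitConfig
from .kinetic import KineticParams, sensitivity
from .phantom import AcquisitionSeries, PhantomVolume, simulate_acquisition

__all__ = [
    "TISchedule", "OSSState", "initial_schedule", "pooled_fit",
    "optimal_schedule", "update_schedule", "run_feedback_loop",
]


@dataclass(frozen=True)
class TISchedule:
    """Ordered TI2 values for one block, inside the search window."""
    ti2_values: np.ndarray
    block_index: int = 0
    window: tuple = (0.8, 2.55)

    def __post_init__(self):
        vals = np.sort(np.asarray(self.ti2_values, dtype=float))
        object.__setattr__(self, "ti2_values", vals)
        lo, hi = self.window
        if vals.size and (vals[0] < lo - 1e-9 or vals[-1] > hi + 1e-9):
            raise ValueError("schedule values outside the search window")

    @property
    def n(self) -> int:
        return len(self.ti2_values)


@dataclass
class OSSState:
    """Accumulated observations and estimates of one feedback loop."""
    mask: np.ndarray
    parts: list = field(default_factory=list)        # AcquisitionSeries per block
    history: list = field(default_factory=list)      # TISchedule per block
    estimate: tuple | None = None                    # (f_hat, att_hat)
    noise_variance: float | None = None

    @property
    def blocks_completed(self) -> int:
        return len(self.parts)

    def slice_weights(self) -> np.ndarray:
        counts = self.mask.sum(axis=(0, 1)).astype(float)
        total = counts.sum()
        return counts / total if total else counts


def initial_schedule(n: int, window=(0.8, 2.55)) -> TISchedule:
    """Evenly spaced schedule spanning the window (first block)."""
    if n < 2:
        raise ValueError("need at least 2 TI2 values")
    lo, hi = float(window[0]), float(window[1])
    if not hi > lo:
        raise ValueError("window must satisfy lo < hi")
    return TISchedule(np.linspace(lo, hi, n), block_index=0, window=(lo, hi))


def _pooled_curve(state: OSSState) -> pd.DataFrame:
    """Mask-mean ΔM per (image pair, slice): columns ti2, dm, weight."""
    from .fitting import pairwise_subtract  # local import, no cycle

    rows = []
    counts = state.mask.sum(axis=(0, 1))
    for part in state.parts:
        series = pairwise_subtract(part)
        for z in np.flatnonzero(counts):
            sel = state.mask[:, :, z]
            dm_mean = series.dm[:, :, z, :][sel].mean(axis=0)
            eff = series.ti2 + z * series.slice_delay
            for t, d in zip(eff, dm_mean):
                rows.append({"ti2": t, "dm": d, "weight": float(counts[z])})
    return pd.DataFrame(rows)


def pooled_fit(state: OSSState, fit: FitConfig, t1_tissue: float,
               m0_blood: float):
    """Fit the kinetic model to the mask-averaged ΔM curve.

    Returns ``(f_hat, att_hat, noise_variance)`` where the noise variance is
    the implied per-voxel ΔM variance (the mask mean at a slice has variance
    ``var / n_voxels``).  Raises ``ValueError`` on an empty mask or too few
    observations; the caller treats that as the fallback signal.
    """
    from .fitting import fit_voxel  # local import, no cycle

    if state.blocks_completed < 1:
        raise ValueError("pooled_fit requires at least one completed block")
    if not state.mask.any():
        raise ValueError("empty mask")
    curve = _pooled_curve(state)
    w = np.sqrt(curve["weight"].to_numpy())
    res = fit_voxel(curve["ti2"].to_numpy(), curve["dm"].to_numpy(),
                    t1_tissue=t1_tissue, m0_blood=m0_blood, fit=fit,
                    weights=w)
    # residual variance of the weighted problem estimates the per-voxel
    # pair-difference variance directly (weights are sqrt(n_voxels))
    return res.f_hat, res.att_hat, res.residual_variance


def _information_tables(params: KineticParams, window, grid_step,
                        slice_offsets, slice_weights):
    """Per-grid-point 2x2 information contributions (m11, m12, m22)."""
    lo, hi = window
    grid = np.round(np.arange(lo, hi + 1e-9, grid_step), 10)
    m11 = np.zeros(len(grid))
    m12 = np.zeros(len(grid))
    m22 = np.zeros(len(grid))
    for off, wgt in zip(slice_offsets, slice_weights):
        if wgt == 0:
            continue
        J = sensitivity(grid + off, params)
        m11 += wgt * J[:, 0] ** 2
        m12 += wgt * J[:, 0] * J[:, 1]
        m22 += wgt * J[:, 1] ** 2
    return grid, m11, m12, m22


def _score(i11, i12, i22, criterion):
    det = i11 * i22 - i12 ** 2
    if criterion == "D":
        return det
    if criterion == "A":  # minimise trace of the inverse
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(det > 0, -(i11 + i22) / det, -np.inf)
    raise ValueError(f"unknown design criterion {criterion!r}")


def _exchange(idx0, grid, m11, m12, m22, criterion, max_sweeps=60):
    """Coordinate exchange from a starting index vector; deterministic."""
    idx = np.array(idx0, dtype=int)
    i11, i12, i22 = m11[idx].sum(), m12[idx].sum(), m22[idx].sum()
    best = _score(np.array([i11]), np.array([i12]), np.array([i22]),
                  criterion)[0]
    for _ in range(max_sweeps):
        changed = False
        for pos in range(len(idx)):
            b11 = i11 - m11[idx[pos]]
            b12 = i12 - m12[idx[pos]]
            b22 = i22 - m22[idx[pos]]
            scores = _score(b11 + m11, b12 + m12, b22 + m22, criterion)
            j = int(np.argmax(scores))
            if scores[j] > best * (1 + 1e-12) + 1e-300:
                idx[pos] = j
                i11, i12, i22 = b11 + m11[j], b12 + m12[j], b22 + m22[j]
                best = scores[j]
                changed = True
        if not changed:
            break
    return idx, best


def optimal_schedule(params: KineticParams, window, n: int,
                     slice_offsets=None, slice_weights=None,
                     criterion: str = "D", grid_step: float = 0.01,
                     start: np.ndarray | None = None,
                     block_index: int = 0) -> TISchedule:
    """Information-optimal n-point TI2 schedule at the given parameters.

    Coordinate exchange over a ``grid_step`` grid, run from a small set of
    deterministic starts (the supplied ``start`` schedule, the evenly
    spaced schedule, and the replicated best single point); the best result
    is returned, ties resolved towards lower TI2 values.
    """
    if slice_offsets is None:
        slice_offsets = np.array([0.0])
    slice_offsets = np.asarray(slice_offsets, dtype=float)
    if slice_weights is None:
        slice_weights = np.full(len(slice_offsets), 1.0 / len(slice_offsets))
    grid, m11, m12, m22 = _information_tables(
        params, window, grid_step, slice_offsets, slice_weights)

    def snap(values):
        return np.clip(np.round((np.asarray(values) - grid[0]) / grid_step),
                       0, len(grid) - 1).astype(int)

    starts = []
    if start is not None:
        starts.append(snap(start))
    starts.append(snap(np.linspace(window[0], window[1], n)))
    starts.append(np.full(n, int(np.argmax(m11)), dtype=int))
    best_idx, best_score = None, -np.inf
    for s in starts:
        idx, score = _exchange(s, grid, m11, m12, m22, criterion)
        if score > best_score + 1e-300:
            best_idx, best_score = idx, score
    return TISchedule(grid[np.sort(best_idx)], block_index=block_index,
                      window=tuple(window))


def update_schedule(state: OSSState, fit: FitConfig, t1_tissue: float,
                    m0_blood: float, acq: AcquisitionConfig,
                    n: int | None = None) -> TISchedule:
    """Next block's schedule from the accumulated state.

    Falls back to the previous block's schedule when the mask is empty or
    the pooled fit fails.
    """
    previous = state.history[-1]
    n = n or previous.n
    try:
        f_hat, att_hat, noise_var = pooled_fit(state, fit, t1_tissue, m0_blood)
    except ValueError:
        return TISchedule(previous.ti2_values,
                          block_index=previous.block_index + 1,
                          window=previous.window)
    state.estimate = (f_hat, att_hat)
    state.noise_variance = noise_var
    params = KineticParams(
        f=max(f_hat, 1e-3), delta_t=att_hat, tau=acq.ti1,
        t1_blood=fit.t1_blood, t1_tissue=t1_tissue, alpha=fit.alpha,
        m0_blood=m0_blood, lam=fit.lam, q_correction=fit.q_correction)
    weights = state.slice_weights()
    offsets = np.arange(len(weights)) * acq.slice_delay
    return optimal_schedule(
        params, acq.window, n, slice_offsets=offsets, slice_weights=weights,
        criterion=fit.design_criterion, start=previous.ti2_values,
        block_index=previous.block_index + 1)


def run_feedback_loop(phantom: PhantomVolume, mask: np.ndarray,
                      acq: AcquisitionConfig, fit: FitConfig,
                      t1_tissue: float, m0_blood: float,
                      n_blocks: int | None = None, seed=None):
    """Simulate the full OSS acquisition for one tissue mask.

    Returns ``(series, history)``: the concatenated AcquisitionSeries of
    ``n_blocks * n_ti * 2`` images and the list of per-block schedules.
    """
    n_blocks = n_blocks or acq.n_blocks
    rng = seed if isinstance(seed, np.random.Generator) else \
        np.random.default_rng(seed)
    state = OSSState(mask=mask.astype(bool))
    schedule = initial_schedule(acq.n_ti, acq.window)
    for block in range(n_blocks):
        part = simulate_acquisition(phantom, schedule, acq, fit, seed=rng)
        state.parts.append(part)
        state.history.append(schedule)
        if block + 1 < n_blocks:
            refit_state = state if fit.refit_all_blocks else OSSState(
                mask=state.mask, parts=state.parts[-1:],
                history=state.history[-1:])
            schedule = update_schedule(refit_state, fit, t1_tissue,
                                       m0_blood, acq)
            if not fit.refit_all_blocks:
                schedule = TISchedule(schedule.ti2_values,
                                      block_index=block + 1,
                                      window=schedule.window)
            state.estimate = refit_state.estimate
            state.noise_variance = refit_state.noise_variance
    return AcquisitionSeries.concat(state.parts), state.history
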