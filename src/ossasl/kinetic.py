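"""Single-compartment pulsed-ASL kinetic model with QUIPSS2 bolus truncation.

The control-minus-tag difference signal :math:`\\Delta M(t)` of a pulsed ASL
experiment with a saturation pulse that truncates the labelled bolus to a
fixed temporal width ``tau`` is piecewise in the acquisition time ``t``
(the post-label inversion time TI2):

* ``t < delta_t`` — no labelled blood has arrived, the signal is zero;
* ``delta_t <= t < delta_t + tau`` — the bolus is arriving,
  ``dM = 2 a M0b f (t - dt) exp(-t/T1b) q(t)``;
* ``t >= delta_t + tau`` — the full (truncated) bolus has arrived and the
  signal clears with the apparent tissue relaxation time T1',
  ``dM = 2 a M0b f tau exp(-t/T1b) q(t)``.

The correction factor ``q(t)`` accounts for labelled water exchanging into
the tissue compartment (relaxing with T1' instead of T1b).  With
``k = 1/T1b - 1/T1'`` and ``1/T1' = 1/T1_tissue + f/lambda`` it reduces to

* arrival phase:  ``q = (exp(k u) - 1) / (k u)`` with ``u = t - delta_t``;
* clearance phase: ``q = exp(k u) (1 - exp(-k tau)) / (k tau)``.

Both forms are smooth in ``k`` (the ``k -> 0`` limit is handled by a series
expansion of ``(exp(z)-1)/z``), so the model is continuous across the piece
boundaries and well behaved when tissue and blood T1 are equal.

Perfusion ``f`` is expressed in the conventional mL/100 g/min on all public
interfaces and converted to mL g^-1 s^-1 once, internally (tissue density
1 g/mL assumed).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "CBF_PER_SI",
    "KineticParams",
    "ParameterDomainError",
    "delta_m",
    "sensitivity",
    "peak_ti2",
]

#: conversion from mL/100 g/min to mL g^-1 s^-1 (density 1 g/mL)
CBF_PER_SI = 6000.0


class ParameterDomainError(ValueError):
    """A kinetic parameter is outside its physical domain."""

    def __init__(self, field: str, value: float, constraint: str):
        self.field = field
        super().__init__(f"parameter {field!r} = {value!r} violates {constraint}")


@dataclass(frozen=True)
class KineticParams:
    """Parameters of the single-compartment QUIPSS2 model.

    f : perfusion (CBF), mL/100 g/min
    delta_t : arterial transit time, s
    tau : bolus temporal width (= TI1 under QUIPSS2), s
    t1_blood : longitudinal relaxation of arterial blood, s
    t1_tissue : longitudinal relaxation of tissue, s (1.4 WM, 1.9 GM at 7T)
    alpha : inversion (labelling) efficiency, 0-1
    m0_blood : equilibrium magnetization of arterial blood, signal units
    lam : blood:water partition coefficient, mL/g
    q_correction : apply the full exchange correction q(t); if False the
        T1'-only approximation q = 1 is used
    """

    f: float
    delta_t: float
    tau: float = 0.7
    t1_blood: float = 2.1
    t1_tissue: float = 1.4
    alpha: float = 0.95
    m0_blood: float = 1.0
    lam: float = 0.9
    q_correction: bool = True

    def __post_init__(self):
        checks = [
            ("f", self.f, self.f >= 0, ">= 0"),
            ("delta_t", self.delta_t, self.delta_t >= 0, ">= 0"),
            ("tau", self.tau, self.tau > 0, "> 0"),
            ("t1_blood", self.t1_blood, self.t1_blood > 0, "> 0"),
            ("t1_tissue", self.t1_tissue, self.t1_tissue > 0, "> 0"),
            ("alpha", self.alpha, 0 < self.alpha <= 1, "0 < alpha <= 1"),
            ("lam", self.lam, self.lam > 0, "> 0"),
        ]
        for name, value, ok, constraint in checks:
            if not ok:
                raise ParameterDomainError(name, value, constraint)

    def with_(self, **kw) -> "KineticParams":
        return replace(self, **kw)


def _e1(z):
    """(exp(z) - 1) / z, stable near z = 0 and safe for complex input."""
    z = np.asarray(z)
    small = np.abs(z) < 1e-6
    zs = np.where(small, 1.0, z)  # avoid 0/0 in the generic branch
    out = np.where(small, 1.0 + z / 2.0 + z * z / 6.0, np.expm1(zs) / zs
                   if not np.iscomplexobj(z) else (np.exp(zs) - 1.0) / zs)
    return out


def _delta_m_core(t, f_si, delta_t, tau, t1b, t1t, alpha, m0b, lam,
                  q_correction=True):
    """Vectorised piecewise model; ``f_si`` in mL g^-1 s^-1.

    All arguments broadcast.  Complex-safe (piece selection uses real parts)
    so derivatives can be taken by complex step.
    """
    t = np.asarray(t)
    one_over_t1p = 1.0 / t1t + f_si / lam
    k = 1.0 / t1b - one_over_t1p
    u = t - delta_t
    amp = 2.0 * alpha * m0b * f_si * np.exp(-t / t1b)
    if q_correction:
        q_rise = _e1(k * u)
        q_clear = np.exp(k * u) * _e1(-k * tau)
    else:
        q_rise = 1.0
        q_clear = 1.0
    rise = amp * u * q_rise
    clear = amp * tau * q_clear
    tr, dtr, taur = np.real(t), np.real(delta_t), np.real(tau)
    out = np.where(tr < dtr, 0.0, np.where(tr < dtr + taur, rise, clear))
    return out


def delta_m(ti2, params: KineticParams):
    """Difference signal ΔM at acquisition time(s) ``ti2`` (seconds).

    Returns an array of the broadcast shape of ``ti2`` (scalar in, scalar
    out), in the units of ``params.m0_blood``.
    """
    ti2 = np.asarray(ti2, dtype=float)
    if np.any(ti2 < 0):
        raise ValueError("ti2 must be non-negative")
    out = _delta_m_core(
        ti2, params.f / CBF_PER_SI, params.delta_t, params.tau,
        params.t1_blood, params.t1_tissue, params.alpha, params.m0_blood,
        params.lam, params.q_correction,
    )
    return out if out.shape else float(out)


_CS_STEP = 1e-30  # complex-step size; derivative = Im(f(x + ih)) / h


def sensitivity(ti2, params: KineticParams):
    """Gradient of ΔM with respect to (f, delta_t).

    Computed by complex-step differentiation of the closed form, which is
    exact to machine precision away from the piece boundaries.  ``f`` is in
    mL/100 g/min so the first component has units signal per (mL/100 g/min).
    Returns an array of shape ``ti2.shape + (2,)``.
    """
    ti2 = np.asarray(ti2, dtype=float)
    common = dict(tau=params.tau, t1b=params.t1_blood, t1t=params.t1_tissue,
                  alpha=params.alpha, m0b=params.m0_blood, lam=params.lam,
                  q_correction=params.q_correction)
    f_si = params.f / CBF_PER_SI
    d_f = np.imag(_delta_m_core(
        ti2, f_si + 1j * _CS_STEP, params.delta_t, **common)) / _CS_STEP
    d_dt = np.imag(_delta_m_core(
        ti2, f_si, params.delta_t + 1j * _CS_STEP, **common)) / _CS_STEP
    return np.stack([d_f / CBF_PER_SI, d_dt], axis=-1)


def peak_ti2(params: KineticParams, window=(0.8, 2.55)):
    """TI2 maximizing ΔM over ``window = (lo, hi)``.

    The maximum of the truncated-bolus model is either the interior balance
    point of the arrival phase, the end of bolus arrival ``delta_t + tau``,
    or a window bound; the candidates are evaluated exactly.  If the window
    lies entirely before label arrival (zero signal everywhere) the lower
    bound is returned with a warning.
    """
    lo, hi = float(window[0]), float(window[1])
    if not hi >= lo:
        raise ValueError("window must satisfy lo <= hi")
    candidates = [lo, hi]
    end_of_bolus = params.delta_t + params.tau
    if lo < end_of_bolus < hi:
        # approach from below: the arrival piece attains its sup there
        candidates.append(np.nextafter(end_of_bolus, lo))
        candidates.append(end_of_bolus)
    if params.q_correction and params.f > 0:
        one_over_t1p = 1.0 / params.t1_tissue + params.f / CBF_PER_SI / params.lam
        k = 1.0 / params.t1_blood - one_over_t1p
        if abs(k) > 1e-12:
            t1p = 1.0 / one_over_t1p
            t_star = params.delta_t + np.log(t1p / params.t1_blood) / k
            if lo < t_star < hi:
                candidates.append(float(t_star))
    else:
        # without the exchange correction the arrival piece u*exp(-t/T1b)
        # peaks at delta_t + T1b
        t_star = params.delta_t + params.t1_blood
        if lo < t_star < hi:
            candidates.append(t_star)
    cand = np.array(sorted(set(candidates)))
    vals = delta_m(cand, params)
    if np.max(vals) <= 0.0:
        warnings.warn("window lies outside model support (zero signal); "
                      "returning the lower window bound", RuntimeWarning)
        return lo
    return float(cand[int(np.argmax(vals))])
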