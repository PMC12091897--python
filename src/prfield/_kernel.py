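"""Compiled inner loop: derivative evaluation and the fixed-step RK4 sweep.

Mirrors :mod:`prfield.model` exactly (the test suite cross-checks the two on
random states).  Parameter layout, matching ``ModelParams.to_array`` plus a
trailing ``Ve`` slot appended by the integrator:

    0:p 1:Cm 2:gc 3:gL 4:gNa 5:gKDR 6:gCa 7:gKAHP 8:gKC
    9:VNa 10:VCa 11:VK 12:VL 13:Is 14:Id 15:Ve
"""

from __future__ import annotations

import numpy as np
from numba import njit

_EPS = 1e-7  # removable-singularity guard, mV


@njit(cache=True)
def deriv_nb(y, prm, out):  # pragma: no cover - exercised via wrappers
    p = prm[0]
    Cm = prm[1]
    gc = prm[2]
    gL = prm[3]
    gNa = prm[4]
    gKDR = prm[5]
    gCa = prm[6]
    gKAHP = prm[7]
    gKC = prm[8]
    VNa = prm[9]
    VCa = prm[10]
    VK = prm[11]
    VL = prm[12]
    Is = prm[13]
    Id = prm[14]
    Ve = prm[15]

    Vs = y[0]
    Vd = y[1]
    h = y[2]
    n = y[3]
    s = y[4]
    c = y[5]
    q = y[6]
    Ca = y[7]

    # field-shifted voltages seen by the ionic driving forces
    vs = Vs + Ve
    vd = Vd + Ve

    # instantaneous sodium activation at the bare somatic potential
    u = 13.1 - Vs
    am = 0.32 * 4.0 if abs(u) < _EPS else 0.32 * u / (np.exp(u / 4.0) - 1.0)
    u = Vs - 40.1
    bm = 0.28 * 5.0 if abs(u) < _EPS else 0.28 * u / (np.exp(u / 5.0) - 1.0)
    minf = am / (am + bm)

    # gate kinetics at the bare membrane potentials
    ah = 0.128 * np.exp((17.0 - Vs) / 18.0)
    bh = 4.0 / (1.0 + np.exp((40.0 - Vs) / 5.0))
    u = 35.1 - Vs
    an = 0.016 * 5.0 if abs(u) < _EPS else 0.016 * u / (np.exp(u / 5.0) - 1.0)
    bn = 0.25 * np.exp(0.5 - 0.025 * Vs)
    as_ = 1.6 / (1.0 + np.exp(-0.072 * (Vd - 65.0)))
    u = Vd - 51.1
    bs = 0.02 * 5.0 if abs(u) < _EPS else 0.02 * u / (np.exp(u / 5.0) - 1.0)
    if Vd <= 50.0:
        ac = np.exp((Vd - 10.0) / 11.0 - (Vd - 6.5) / 27.0) / 18.975
        bc = 2.0 * np.exp((6.5 - Vd) / 27.0) - ac
    else:
        ac = 2.0 * np.exp((6.5 - Vd) / 27.0)
        bc = 0.0
    aq = min(0.00002 * Ca, 0.01)
    bq = 0.001

    chi = min(Ca / 250.0, 1.0)

    IsLeak = gL * (vs - VL)
    INa = gNa * minf * minf * h * (vs - VNa)
    IKDR = gKDR * n * (vs - VK)
    IdLeak = gL * (vd - VL)
    ICa = gCa * s * s * (vd - VCa)
    IKAHP = gKAHP * q * (vd - VK)
    IKC = gKC * c * chi * (vd - VK)
    IDS = gc * (Vd - Vs)

    out[0] = (-IsLeak - INa - IKDR + IDS / p + Is / p) / Cm
    out[1] = (-IdLeak - ICa - IKAHP - IKC - IDS / (1.0 - p) + Id / (1.0 - p)) / Cm
    out[2] = ah * (1.0 - h) - bh * h
    out[3] = an * (1.0 - n) - bn * n
    out[4] = as_ * (1.0 - s) - bs * s
    out[5] = ac * (1.0 - c) - bc * c
    out[6] = aq * (1.0 - q) - bq * q
    out[7] = -0.13 * ICa - 0.075 * Ca


@njit(cache=True)
def rk4_run(y0, prm, dt, n_steps, stride):  # pragma: no cover
    """Integrate ``n_steps`` RK4 steps, recording every ``stride``-th state.

    Returns ``(states, n_recorded, diverged_step)``; ``diverged_step`` is -1
    for a clean run, otherwise the 1-based step index at which the state
    first became non-finite (recording stops just before it).
    """
    n_rec = n_steps // stride + 1
    out = np.empty((n_rec, 8))
    y = y0.copy()
    out[0] = y
    k1 = np.empty(8)
    k2 = np.empty(8)
    k3 = np.empty(8)
    k4 = np.empty(8)
    tmp = np.empty(8)
    rec = 1
    for i in range(n_steps):
        deriv_nb(y, prm, k1)
        for j in range(8):
            tmp[j] = y[j] + 0.5 * dt * k1[j]
        deriv_nb(tmp, prm, k2)
        for j in range(8):
            tmp[j] = y[j] + 0.5 * dt * k2[j]
        deriv_nb(tmp, prm, k3)
        for j in range(8):
            tmp[j] = y[j] + dt * k3[j]
        deriv_nb(tmp, prm, k4)
        ok = True
        for j in range(8):
            y[j] = y[j] + dt * (k1[j] / 6.0 + k2[j] / 3.0 + k3[j] / 3.0 + k4[j] / 6.0)
            if not np.isfinite(y[j]):
                ok = False
        if not ok:
            return out, rec, i + 1
        if (i + 1) % stride == 0:
            out[rec] = y
            rec += 1
    return out, rec, -1
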