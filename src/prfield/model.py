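"""Two-compartment Pinsky-Rinzel CA3 pyramidal neuron with a DC induced field.

The model splits the neuron into a somatic compartment (fast Na+ spikes,
delayed-rectifier K+) and a dendritic compartment (Ca2+ spikes and two
Ca-dependent K+ currents), electrotonically coupled through a conductance
``gc`` weighted by the somatic area fraction ``p``.  Voltages are expressed
in the original shifted convention of Pinsky & Rinzel: the leak reversal is
0 mV and rest sits a few mV below it, so sodium reverses at +120 mV and
potassium near -15 mV.

A DC induced electric field of amplitude ``Ve`` (mV) adds a constant
polarization to the membrane potential *as seen by the ionic driving
forces*: every ionic current is evaluated at ``V + Ve`` while the gating
kinetics (including the instantaneous sodium activation ``m_inf``) follow
the bare membrane potential, and the compartment coupling depends only on
the voltage difference.  This is the coupling that gives the field a real
dynamical effect; shifting the gating kinetics as well would make the
change of variables exact and the field invisible.

Units form a consistent set: mV, ms, uA/cm^2, mS/cm^2, uF/cm^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ModelParams",
    "NeuronState",
    "FieldConfig",
    "CurrentSet",
    "INITIAL_STATE",
    "rate_constants",
    "gate_kinetics",
    "chi",
    "m_inf",
    "ionic_currents",
    "derivatives",
    "derivatives_array",
    "GATE_NAMES",
]

#: Voltage window (mV) around a removable singularity inside which the rate
#: function is replaced by its analytic limit, avoiding 0/0 on grid-aligned
#: voltages.
SINGULARITY_EPS = 1e-7

GATE_NAMES = ("m", "h", "n", "s", "c", "q")


@dataclass(frozen=True)
class ModelParams:
    """Biophysical constants of the two-compartment model.

    Defaults follow the published parameter table with one correction:
    ``gCa`` uses the classic Pinsky-Rinzel value 10 mS/cm^2.  The table's
    printed 2.1 (identical to ``gc``) abolishes dendritic bursting entirely
    and is inconsistent with every firing pattern the model is known for.

    ``Vsyn`` is stored for completeness but enters no equation here
    (synaptic input is out of scope).
    """

    p: float = 0.5          # somatic area fraction (dimensionless)
    Cm: float = 3.0         # membrane capacitance, uF/cm^2
    gc: float = 2.1         # soma-dendrite coupling conductance, mS/cm^2
    gL: float = 0.1         # leak conductance, mS/cm^2
    gNa: float = 30.0       # fast sodium, mS/cm^2
    gKDR: float = 15.0      # delayed-rectifier potassium, mS/cm^2
    gCa: float = 10.0       # dendritic calcium, mS/cm^2
    gKAHP: float = 0.8      # slow afterhyperpolarization K+, mS/cm^2
    gKC: float = 15.0       # fast Ca-dependent K+, mS/cm^2
    VNa: float = 120.0      # sodium reversal, mV
    VCa: float = 140.0      # calcium reversal, mV
    VK: float = -15.0       # potassium reversal, mV
    VL: float = 0.0         # leak reversal, mV
    Vsyn: float = 60.0      # synaptic reversal, mV (unused)
    Is: float = 0.0         # somatic injected current, uA/cm^2
    Id: float = 0.7         # dendritic injected current, uA/cm^2

    def __post_init__(self) -> None:
        if not 0.0 < self.p < 1.0:
            raise ValueError(f"area fraction p must lie in (0, 1), got {self.p}")
        if self.Cm <= 0.0:
            raise ValueError(f"Cm must be positive, got {self.Cm}")
        for name in ("gc", "gL", "gNa", "gKDR", "gCa", "gKAHP", "gKC"):
            if getattr(self, name) < 0.0:
                raise ValueError(f"conductance {name} must be >= 0, got {getattr(self, name)}")

    def replace(self, **changes) -> "ModelParams":
        return replace(self, **changes)

    def to_array(self) -> np.ndarray:
        """Pack into the flat layout consumed by the numba kernel."""
        return np.array(
            [self.p, self.Cm, self.gc, self.gL, self.gNa, self.gKDR, self.gCa,
             self.gKAHP, self.gKC, self.VNa, self.VCa, self.VK, self.VL,
             self.Is, self.Id],
            dtype=np.float64,
        )


@dataclass(frozen=True)
class FieldConfig:
    """A DC induced electric field.

    For a DC field the membrane polarization equals the field amplitude
    (``delta_V = Ve = A``) and the capacitive current it would inject is
    identically zero (``Ie = Cm * d(delta_V)/dt = 0``).  ``tau`` (charge
    accumulation time constant, s) and ``lam`` (polarization length) are
    kept for documentation; they drop out of the DC limit.
    """

    Ve: float = 0.0
    Ie: float = 0.0
    tau: float = 1e-10
    lam: float = 1.0

    def __post_init__(self) -> None:
        if self.Ie != 0.0:
            raise ValueError("DC induced fields carry no capacitive current: Ie must be 0")


@dataclass(frozen=True)
class NeuronState:
    """The 8-dimensional model state.

    ``m`` is not a state variable: sodium activation is instantaneous
    (``m_inf(Vs)^2`` enters INa directly), which is why the printed initial
    condition has exactly eight entries.
    """

    Vs: float
    Vd: float
    h: float
    n: float
    s: float
    c: float
    q: float
    Ca: float

    def to_array(self) -> np.ndarray:
        return np.array(
            [self.Vs, self.Vd, self.h, self.n, self.s, self.c, self.q, self.Ca],
            dtype=np.float64,
        )

    @classmethod
    def from_array(cls, y: np.ndarray) -> "NeuronState":
        return cls(*map(float, y))

    def validate(self) -> None:
        for g in ("h", "n", "s", "c", "q"):
            v = getattr(self, g)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"gate {g}={v} outside [0, 1]")
        if self.Ca < 0.0:
            raise ValueError(f"Ca={self.Ca} must be >= 0")


#: Printed initial condition: a point on (or very near) the firing attractor
#: of the unperturbed model, used for every simulation unless overridden.
INITIAL_STATE = NeuronState(
    Vs=8.22594127701169,
    Vd=11.2873513664516,
    h=0.657103951268693,
    n=0.0575840069166615,
    s=0.0586561971436294,
    c=0.0328693668351334,
    q=0.461747452058436,
    Ca=46.9558464653944,
)


def _exprel_rate(scale: float, u: float, divisor: float) -> float:
    """Evaluate ``scale * u / (exp(u / divisor) - 1)``.

    At u = 0 the expression has a removable singularity with limit
    ``scale * divisor``; within SINGULARITY_EPS of it the limit is returned.
    """
    if abs(u) < SINGULARITY_EPS:
        return scale * divisor
    return scale * u / (math.exp(u / divisor) - 1.0)


def rate_constants(gate: str, value: float) -> tuple[float, float]:
    """Forward/backward rates (1/ms) for one gating variable.

    ``m``, ``h``, ``n`` take the somatic voltage (mV); ``s`` and ``c`` take
    the dendritic voltage (mV); ``q`` takes the calcium variable.  The
    removable singularities (alpha_m at 13.1 mV, beta_m at 40.1 mV, alpha_n
    at 35.1 mV, beta_s at 51.1 mV) evaluate to their analytic limits; the
    ``c`` rates are piecewise at Vd = 50 mV.
    """
    if not isinstance(value, (int, float)) or not math.isfinite(value):
        raise ValueError(f"rate_constants needs a finite input, got {value!r}")
    v = float(value)
    if gate == "m":
        alpha = _exprel_rate(0.32, 13.1 - v, 4.0)
        beta = _exprel_rate(0.28, v - 40.1, 5.0)
    elif gate == "h":
        alpha = 0.128 * math.exp((17.0 - v) / 18.0)
        beta = 4.0 / (1.0 + math.exp((40.0 - v) / 5.0))
    elif gate == "n":
        alpha = _exprel_rate(0.016, 35.1 - v, 5.0)
        beta = 0.25 * math.exp(0.5 - 0.025 * v)
    elif gate == "s":
        alpha = 1.6 / (1.0 + math.exp(-0.072 * (v - 65.0)))
        beta = _exprel_rate(0.02, v - 51.1, 5.0)
    elif gate == "c":
        if v <= 50.0:
            alpha = math.exp((v - 10.0) / 11.0 - (v - 6.5) / 27.0) / 18.975
            beta = 2.0 * math.exp((6.5 - v) / 27.0) - alpha
        else:
            alpha = 2.0 * math.exp((6.5 - v) / 27.0)
            beta = 0.0
    elif gate == "q":
        if v < 0.0:
            raise ValueError(f"calcium must be >= 0, got {v}")
        alpha = min(0.00002 * v, 0.01)
        beta = 0.001
    else:
        raise ValueError(f"unknown gate {gate!r}; expected one of {GATE_NAMES}")
    return alpha, beta


def gate_kinetics(alpha: float, beta: float, x: float) -> float:
    """First-order gate derivative ``(x_inf - x) / tau = alpha(1-x) - beta x``."""
    if alpha < 0.0 or beta < 0.0:
        raise ValueError("rates must be nonnegative")
    if alpha + beta == 0.0:
        raise ValueError("singular kinetics: alpha + beta must be positive")
    return alpha * (1.0 - x) - beta * x


def chi(Ca: float) -> float:
    """Calcium saturation factor ``min(Ca/250, 1)`` gating the IKC current."""
    if Ca < 0.0:
        raise ValueError(f"calcium must be >= 0, got {Ca}")
    return min(Ca / 250.0, 1.0)


def m_inf(v: float) -> float:
    """Instantaneous sodium activation at membrane potential ``v`` (mV)."""
    am, bm = rate_constants("m", v)
    return am / (am + bm)


@dataclass(frozen=True)
class CurrentSet:
    """Ionic and coupling currents (uA/cm^2) at one instant.

    ``IDS`` is the raw coupling current gc*(Vd - Vs); the voltage equations
    scale it by 1/p on the soma side and -1/(1-p) on the dendrite side so
    the coupling charge is conserved.
    """

    IsLeak: float
    INa: float
    IKDR: float
    IdLeak: float
    ICa: float
    IKAHP: float
    IKC: float
    IDS: float


def ionic_currents(state: NeuronState, params: ModelParams, Ve: float = 0.0) -> CurrentSet:
    """Evaluate all membrane currents with the field shift ``Ve`` applied.

    The shift enters every ionic driving-force argument (``Vs+Ve`` on the
    soma, ``Vd+Ve`` on the dendrite); gating variables and ``m_inf`` follow
    the bare membrane potential, and the coupling current depends only on
    the voltage difference, so it is unshifted.  With Ve=0 this is exactly
    the standard Pinsky-Rinzel current set.
    """
    vs = state.Vs + Ve
    vd = state.Vd + Ve
    minf = m_inf(state.Vs)
    return CurrentSet(
        IsLeak=params.gL * (vs - params.VL),
        INa=params.gNa * minf * minf * state.h * (vs - params.VNa),
        IKDR=params.gKDR * state.n * (vs - params.VK),
        IdLeak=params.gL * (vd - params.VL),
        ICa=params.gCa * state.s * state.s * (vd - params.VCa),
        IKAHP=params.gKAHP * state.q * (vd - params.VK),
        IKC=params.gKC * state.c * chi(state.Ca) * (vd - params.VK),
        IDS=params.gc * (state.Vd - state.Vs),
    )


def derivatives(state: NeuronState, params: ModelParams,
                field: FieldConfig | None = None) -> NeuronState:
    """Time derivative of the full state under an optional DC field."""
    y = derivatives_array(state.to_array(), params, 0.0 if field is None else field.Ve)
    return NeuronState.from_array(y)


def derivatives_array(y: np.ndarray, params: ModelParams, Ve: float = 0.0) -> np.ndarray:
    """Reference (pure-Python) derivative on a packed state vector.

    This is the readable twin of the compiled kernel in ``_kernel``; the
    test suite asserts the two agree to machine precision on random states.
    """
    Vs, Vd, h, n, s, c, q, Ca = map(float, y)
    cur = ionic_currents(NeuronState(Vs, Vd, h, n, s, c, q, Ca), params, Ve)

    p, Cm = params.p, params.Cm
    dVs = (-cur.IsLeak - cur.INa - cur.IKDR + cur.IDS / p + params.Is / p) / Cm
    dVd = (-cur.IdLeak - cur.ICa - cur.IKAHP - cur.IKC
           - cur.IDS / (1.0 - p) + params.Id / (1.0 - p)) / Cm

    ah, bh = rate_constants("h", Vs)
    an, bn = rate_constants("n", Vs)
    as_, bs = rate_constants("s", Vd)
    ac, bc = rate_constants("c", Vd)
    aq, bq = rate_constants("q", Ca)

    return np.array([
        dVs,
        dVd,
        gate_kinetics(ah, bh, h),
        gate_kinetics(an, bn, n),
        gate_kinetics(as_, bs, s),
        gate_kinetics(ac, bc, c),
        gate_kinetics(aq, bq, q),
        -0.13 * cur.ICa - 0.075 * Ca,
    ])
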