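"""Rate functions, gating kinetics, ionic currents and the derivative field."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from prfield import (FieldConfig, ModelParams, NeuronState, chi, derivatives,
                     derivatives_array, gate_kinetics, ionic_currents, m_inf,
                     rate_constants)
from prfield._kernel import deriv_nb

# Frozen against a 30-digit mpmath evaluation of the closed forms.
RATE_CASES = [
    ("h", 17.0, 0, 0.128),                       # exponent vanishes
    ("h", 40.0, 1, 2.0),                         # beta_h = 4/(1+e^0)
    ("q", 1000.0, 0, 0.01),                      # alpha_q capped at 0.01
    ("q", 1000.0, 1, 0.001),                     # beta_q constant
    ("q", 100.0, 0, 0.002),                      # linear branch 2e-5 * Ca
    ("m", 0.0, 0, 0.164758984791549),
    ("m", 0.0, 1, 11.2316932056161),
    ("n", 0.0, 0, 5.02421473905470e-4),
    ("n", 35.1, 0, 0.08),                        # removable singularity limit
    ("s", 0.0, 1, 1.02203723720831),
    ("c", 0.0, 0, 0.0270120425611585),
    ("c", 0.0, 1, 2.51737028785886),
    ("c", 60.0, 1, 0.0),                         # beta_c vanishes above 50 mV
]


@pytest.mark.parametrize("gate,v,which,expected", RATE_CASES)
def test_rate_constants_match_closed_forms(gate, v, which, expected):
    assert rate_constants(gate, v)[which] == pytest.approx(expected, rel=1e-12)


@pytest.mark.parametrize("gate,v_sing", [("m", 13.1), ("n", 35.1)])
def test_rates_continuous_at_removable_singularities_alpha(gate, v_sing):
    limit = rate_constants(gate, v_sing)[0]
    for off in (-1e-6, 1e-6):
        assert rate_constants(gate, v_sing + off)[0] == pytest.approx(limit, rel=1e-5)


@pytest.mark.parametrize("gate,v_sing", [("m", 40.1), ("s", 51.1)])
def test_rates_continuous_at_removable_singularities_beta(gate, v_sing):
    limit = rate_constants(gate, v_sing)[1]
    for off in (-1e-6, 1e-6):
        assert rate_constants(gate, v_sing + off)[1] == pytest.approx(limit, rel=1e-5)


def test_rate_constants_rejects_bad_input():
    with pytest.raises(ValueError):
        rate_constants("x", 0.0)
    with pytest.raises(ValueError):
        rate_constants("m", float("nan"))
    with pytest.raises(ValueError):
        rate_constants("q", -1.0)


@given(st.sampled_from(["m", "h", "n", "s", "c"]),
       st.floats(min_value=-100.0, max_value=150.0))
def test_rates_are_nonnegative(gate, v):
    alpha, beta = rate_constants(gate, v)
    assert alpha >= 0.0
    if gate == "c":
        # the printed c-rates leave beta_c marginally negative (~ -3e-4)
        # just below the 50 mV branch point; kept as published
        assert beta >= -5e-4
    else:
        assert beta >= -1e-12


@pytest.mark.parametrize("alpha,beta,x,expected", [
    (1.0, 1.0, 0.5, 0.0),    # steady state
    (1.0, 0.0, 0.0, 1.0),    # pure activation
    (0.3, 0.7, 0.1, 0.2),    # alpha(1-x) - beta*x
])
def test_gate_kinetics_examples(alpha, beta, x, expected):
    assert gate_kinetics(alpha, beta, x) == pytest.approx(expected, abs=1e-15)


def test_gate_kinetics_errors():
    with pytest.raises(ValueError):
        gate_kinetics(0.0, 0.0, 0.5)
    with pytest.raises(ValueError):
        gate_kinetics(-0.1, 1.0, 0.5)


@given(st.floats(min_value=0.001, max_value=10.0),
       st.floats(min_value=0.001, max_value=10.0))
def test_gate_kinetics_pushes_toward_steady_state(alpha, beta):
    x_inf = alpha / (alpha + beta)
    assert gate_kinetics(alpha, beta, x_inf) == pytest.approx(0.0, abs=1e-12)
    assert gate_kinetics(alpha, beta, 0.0) > 0.0
    assert gate_kinetics(alpha, beta, 1.0) < 0.0


@pytest.mark.parametrize("ca,expected", [(0.0, 0.0), (125.0, 0.5), (250.0, 1.0), (500.0, 1.0)])
def test_chi_examples(ca, expected):
    assert chi(ca) == expected


def test_chi_monotone_and_bounded():
    grid = np.linspace(0.0, 600.0, 200)
    vals = [chi(c) for c in grid]
    assert all(0.0 <= v <= 1.0 for v in vals)
    assert all(b >= a for a, b in zip(vals, vals[1:]))
    with pytest.raises(ValueError):
        chi(-1.0)


def _state(**kw) -> NeuronState:
    base = dict(Vs=-4.0, Vd=-4.0, h=0.9, n=0.1, s=0.05, c=0.03, q=0.4, Ca=50.0)
    base.update(kw)
    return NeuronState(**base)


def test_currents_vanish_without_driving_force_or_gate():
    p = ModelParams()
    assert ionic_currents(_state(Vs=0.0), p).IsLeak == 0.0         # Vs = VL
    assert ionic_currents(_state(n=0.0), p).IKDR == 0.0            # closed gate
    assert ionic_currents(_state(Vd=140.0), p).ICa == 0.0          # at reversal
    assert ionic_currents(_state(Ca=0.0), p).IKC == 0.0            # chi(0) = 0
    assert ionic_currents(_state(Vd=-4.0, Vs=-4.0), p).IDS == 0.0  # no gradient


def test_calcium_current_is_inward_below_reversal():
    p = ModelParams()
    cur = ionic_currents(_state(Vd=20.0, s=0.3), p, Ve=5.0)
    assert cur.ICa < 0.0  # so -0.13*ICa sources calcium


def test_field_shift_moves_driving_forces_not_gating():
    p = ModelParams()
    s = _state()
    shifted = ionic_currents(s, p, Ve=10.0)
    base = ionic_currents(s, p, Ve=0.0)
    # leak picks up exactly gL * Ve
    assert shifted.IsLeak - base.IsLeak == pytest.approx(p.gL * 10.0)
    # coupling is unshifted: depends only on the voltage difference
    assert shifted.IDS == base.IDS
    # sodium activation follows the bare potential: same m_inf in both
    ratio = shifted.INa / base.INa
    assert ratio == pytest.approx((s.Vs + 10.0 - p.VNa) / (s.Vs - p.VNa))


def test_calcium_derivative_vanishes_when_sources_do():
    d = derivatives(_state(Ca=0.0, s=0.0), ModelParams(), FieldConfig(0.0))
    assert d.Ca == 0.0


def test_derivative_finite_at_printed_initial_state():
    from prfield import INITIAL_STATE
    d = derivatives(INITIAL_STATE, ModelParams(Is=0.0, Id=1.0), FieldConfig(0.0))
    assert all(math.isfinite(v) for v in d.to_array())


def test_kernel_matches_reference_derivative(rng):
    """The compiled kernel and the readable reference implementation agree."""
    p = ModelParams(Is=0.3, Id=1.0)
    for _ in range(50):
        y = np.array([
            rng.uniform(-40.0, 120.0), rng.uniform(-40.0, 120.0),
            *rng.uniform(0.0, 1.0, 5), rng.uniform(0.0, 400.0),
        ])
        ve = rng.uniform(-40.0, 40.0)
        ref = derivatives_array(y, p, ve)
        out = np.empty(8)
        deriv_nb(y, np.append(p.to_array(), ve), out)
        np.testing.assert_allclose(out, ref, rtol=1e-13, atol=1e-13)


def test_params_validation():
    with pytest.raises(ValueError):
        ModelParams(p=0.0)
    with pytest.raises(ValueError):
        ModelParams(Cm=-1.0)
    with pytest.raises(ValueError):
        ModelParams(gNa=-5.0)
    with pytest.raises(ValueError):
        FieldConfig(Ve=5.0, Ie=1.0)  # DC fields inject no capacitive current
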