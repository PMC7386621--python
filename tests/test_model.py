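"""Gate kinetics, ionic currents, GHK flux and the assembled membrane RHS."""

import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from condassim.errors import InvalidParameterError, OutOfRangeError
from condassim.model import (
    GateParams,
    ParameterSet,
    PhysicalConstants,
    gate_rhs,
    gate_steady_state,
    gate_time_constant,
    ghk_current_density,
    ionic_current_density,
    membrane_rhs,
    model_from_json,
    model_to_json,
    rvlm_model,
)
from condassim.model import _ghk_voltage_factor


class TestGateKinetics:
    @pytest.mark.parametrize(
        "g,V,expected",
        [
            # at the half-activation voltage the gate is half open
            (GateParams(-40.0, 10.0, 20.0, 1.0, 2.0), -40.0, 0.5),
            # one width above threshold: (1 + tanh 1)/2
            (GateParams(-40.0, 10.0, 20.0, 1.0, 2.0), -30.0, 0.8807970779778823),
            # the published NaT activation gate evaluated at -60 mV
            (GateParams(-39.92, 10.0, 23.39, 0.143, 1.099), -60.0, 0.017705775418333),
        ],
    )
    def test_steady_state_examples(self, g, V, expected):
        assert gate_steady_state(V, g) == pytest.approx(expected, rel=1e-12)

    def test_zero_width_rejected(self):
        with pytest.raises(InvalidParameterError):
            GateParams(-40.0, 0.0, 20.0, 1.0, 2.0)

    @given(
        Vt=st.floats(-90, -20),
        dV=st.floats(min_value=1.0, max_value=30.0),
        sign=st.sampled_from([1.0, -1.0]),
    )
    @settings(deadline=None, max_examples=50)
    def test_steady_state_monotone_with_direction_set_by_width_sign(self, Vt, dV, sign):
        g = GateParams(Vt, sign * dV, 20.0, 1.0, 2.0)
        V = np.linspace(-120, 60, 200)
        x = gate_steady_state(V, g)
        assert np.all((x >= 0) & (x <= 1))
        d = np.diff(x)
        assert np.all(sign * d >= 0)

    def test_time_constant_peak_and_floor(self):
        g = GateParams(-65.37, -17.65, 27.22, 0.701, 12.9)
        # at threshold the recovery time is t0 + eps
        assert gate_time_constant(g.V_t, g) == pytest.approx(g.t0 + g.eps)
        # far from threshold it falls back to t0
        assert gate_time_constant(g.V_t + 50 * g.dV_tau, g) == pytest.approx(g.t0, rel=1e-9)
        # the published h gate, one tau-width above threshold
        assert gate_time_constant(g.V_t + g.dV_tau, g) == pytest.approx(6.118669006, rel=1e-9)

    def test_time_constant_bounded(self):
        g = GateParams(-40.0, 10.0, 15.0, 0.5, 3.0)
        V = np.linspace(-120, 60, 300)
        tau = gate_time_constant(V, g)
        assert np.all(tau >= g.t0 - 1e-15)
        assert np.all(tau <= g.t0 + g.eps + 1e-15)

    def test_gate_rhs_fixed_point_sign_and_closed_form(self):
        g = GateParams(-40.0, 10.0, 20.0, 1.0, 2.0)
        V = -55.0
        xinf = gate_steady_state(V, g)
        assert gate_rhs(xinf, V, g) == pytest.approx(0.0, abs=1e-15)
        assert gate_rhs(xinf - 0.1, V, g) > 0
        # frozen-V relaxation matches the closed-form exponential
        tau = gate_time_constant(V, g)
        x0, t = 0.9, np.linspace(0, 5, 40)
        exact = xinf + (x0 - xinf) * np.exp(-t / tau)
        from scipy.integrate import solve_ivp

        sol = solve_ivp(
            lambda tt, x: gate_rhs(x, V, g), (0, 5), [x0], t_eval=t, rtol=1e-10, atol=1e-12
        )
        assert np.allclose(sol.y[0], exact, atol=1e-8)


class TestCurrents:
    def test_reversal_and_closed_gate(self, rvlm):
        model, table = rvlm
        p = table.p_true
        nat = next(c for c in model.channels if c.id == "NaT")
        gates = {"m": 0.5, "h": 0.5}
        assert ionic_current_density(nat, p["E_Na"], gates, p) == pytest.approx(0.0)
        assert ionic_current_density(nat, -50.0, {"m": 0.0, "h": 0.5}, p) == 0.0

    def test_leak_table_value(self, rvlm):
        model, table = rvlm
        leak = next(c for c in model.channels if c.id == "Leak")
        # g_L = 0.465, E_L = -65, V = -75 -> J = 0.465 * 10 = 4.65 uA/cm^2
        assert ionic_current_density(leak, -75.0, {}, table.p_true) == pytest.approx(4.65)

    def test_ghk_rejected_by_ohmic_path(self, rvlm):
        model, _ = rvlm
        cat = next(c for c in model.channels if c.id == "CaT")
        with pytest.raises(InvalidParameterError):
            ionic_current_density(cat, -50.0, {"q": 0.1, "r": 0.1}, {})


class TestGhk:
    def test_closed_gate_gives_zero(self):
        k = PhysicalConstants()
        assert ghk_current_density(-50.0, 0.0, 0.5, 1e-4, k) == 0.0

    def test_zero_voltage_limit(self):
        # L'Hopital: J(0) = p_bar act^2 inact z F ([Ca]_i - [Ca]_o)
        k = PhysicalConstants()
        act, inact, p_bar = 0.3, 0.6, 1.035e-4
        lim = (
            p_bar * act**2 * inact * k.z_valence * k.F_faraday
            * (k.Ca_in_mM - k.Ca_out_mM) * 1e-6 * 1e6
        )
        assert ghk_current_density(1e-12, act, inact, p_bar, k) == pytest.approx(lim, rel=1e-9)

    def test_zero_at_nernst_equilibrium(self):
        k = PhysicalConstants()
        # V where [Ca]_i = [Ca]_o exp(-zFV/RT): the flux reverses
        V_eq = -np.log(k.Ca_in_mM / k.Ca_out_mM) / k.zF_over_RT * 1e3
        assert ghk_current_density(V_eq, 0.5, 0.5, 1e-4, k) == pytest.approx(0.0, abs=1e-12)

    def test_horner_fidelity_sweep(self, rvlm):
        model, _ = rvlm
        h = model.ghk_horner()
        V = np.arange(-100.0, 45.0 + 1e-9, 1.0)
        exact = _ghk_voltage_factor(V, model.constants)
        approx = h.factor(V)
        assert np.max(np.abs(approx - exact) / np.abs(exact)) < 1e-6

    def test_horner_out_of_range(self, rvlm):
        model, _ = rvlm
        with pytest.raises(OutOfRangeError):
            model.ghk_horner().factor(-130.0)

    def test_horner_matches_power_sum(self, rvlm):
        model, _ = rvlm
        h = model.ghk_horner()
        V = np.linspace(-95, 40, 7)
        s = h.scaled(V)
        naive = sum(c * s**k for k, c in enumerate(h.coeffs))
        assert np.allclose(h.factor(V), naive, rtol=1e-12)


class TestMembraneRhs:
    def test_dimensions_and_purity(self, rvlm):
        model, table = rvlm
        x = np.array([-65.0, 0.1, 0.5, 0.2, 0.1, 0.05, 0.02])
        out1 = membrane_rhs(x, model, table.p_true, 100.0)
        out2 = membrane_rhs(x, model, table.p_true, 100.0)
        assert out1.shape == (7,)
        assert np.array_equal(out1, out2)

    def test_leak_only_equilibrium(self, leak):
        model, table = leak
        p = table.p_true
        I = 500.0
        V_eq = p["E_Leak"] + 0.01 * I / (p["A"] * p["g_L"])
        out = membrane_rhs(np.array([V_eq]), model, p, I)
        assert out[0] == pytest.approx(0.0, abs=1e-12)

    def test_nudging_term(self, rvlm):
        model, table = rvlm
        x = np.array([-60.0, 0.1, 0.5, 0.2, 0.1, 0.05, 0.02])
        base = membrane_rhs(x, model, table.p_true, 0.0)
        nudged_same = membrane_rhs(x, model, table.p_true, 0.0, u=0.7, V_exp=-60.0)
        assert np.allclose(nudged_same, base)
        nudged = membrane_rhs(x, model, table.p_true, 0.0, u=0.5, V_exp=-50.0)
        assert nudged[0] == pytest.approx(base[0] + 0.5 * 10.0)
        with pytest.raises(InvalidParameterError):
            membrane_rhs(x, model, table.p_true, 0.0, u=0.5)


class TestRvlmAssembly:
    def test_dimensions(self, rvlm):
        model, table = rvlm
        assert model.n_states == 7
        assert model.n_params == 41
        assert len(table.p_true) == 41

    def test_bounds_sets(self, rvlm):
        _, table = rvlm
        lo, hi = table.bounds_vectors("table2_widened")
        p = table.p_true.to_vector(table.model)
        assert np.all(p >= lo) and np.all(p <= hi)
        # the printed intervals exclude several true values
        lo_p, hi_p = table.bounds_vectors("table2_as_printed")
        assert np.any((p < lo_p) | (p > hi_p))

    def test_json_round_trip(self, rvlm):
        model, table = rvlm
        text = model_to_json(model, table)
        model2, table2 = model_from_json(text)
        assert model2.param_names == model.param_names
        assert dict(table2.p_true) == dict(table.p_true)
        assert table2.bounds_widened == table.bounds_widened
        x = np.array([-55.0, 0.2, 0.4, 0.3, 0.1, 0.02, 0.05])
        assert np.allclose(
            membrane_rhs(x, model2, table2.p_true, 250.0),
            membrane_rhs(x, model, table.p_true, 250.0),
        )

    def test_parameter_set_vector_round_trip(self, rvlm):
        model, table = rvlm
        vec = table.p_true.to_vector(model)
        assert ParameterSet.from_vector(model, vec) == table.p_true
        with pytest.raises(InvalidParameterError):
            ParameterSet.from_vector(model, vec[:-1])
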