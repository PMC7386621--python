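"""Protocols, forward integration, seeded noise and collocation meshes."""

import numpy as np
import pytest

from condassim.errors import InvalidParameterError
from condassim.twin import (
    MeshPlan,
    adaptive_mesh,
    build_step_protocol,
    default_protocol,
    integrate_forward,
    make_twin_dataset,
    sample_noise,
    settle_initial_state,
    uniform_mesh,
)


class TestProtocol:
    def test_step_lookup_left_closed(self):
        proto = build_step_protocol([(100, 0), (100, 250)])
        assert proto.total_duration == 200
        assert proto.amplitude_at(150.0) == 250
        assert proto.amplitude_at(100.0) == 250  # left-closed at the edge
        assert proto.amplitude_at(99.999) == 0

    def test_single_step_constant(self):
        proto = build_step_protocol([(50, 123.0)])
        t = np.linspace(0, 50, 11)
        assert np.all(proto.amplitude_at(t) == 123.0)

    def test_invalid_specs(self):
        with pytest.raises(InvalidParameterError):
            build_step_protocol([])
        with pytest.raises(InvalidParameterError):
            build_step_protocol([(0.0, 10.0)])

    def test_default_fixture_shape(self):
        proto = default_protocol()
        assert proto.total_duration == 200
        amps = [a for _, a in proto.steps]
        assert max(amps) > 0 and min(amps) < 0  # mixed de- and hyperpolarizing
        durs = {d for d, _ in proto.steps}
        assert len(durs) > 1  # multiple durations probing different kinetics


class TestNoise:
    def test_zero_amplitude(self):
        assert np.all(sample_noise(0.0, 7, 100) == 0.0)

    def test_sign_antisymmetry_and_determinism(self):
        a = sample_noise(0.3, 42, 1000)
        b = sample_noise(-0.3, 42, 1000)
        assert np.array_equal(a, -b)
        assert np.array_equal(a, sample_noise(0.3, 42, 1000))
        assert not np.array_equal(a, sample_noise(0.3, 43, 1000))

    def test_sample_std_matches_sigma(self):
        # chi-square bound: sd(sigma_hat) ~ sigma / sqrt(2 n)
        n, sigma = 10_000, 0.5
        eps = sample_noise(sigma, 5, n)
        assert abs(np.std(eps, ddof=1) - sigma) < 3 * sigma / np.sqrt(2 * n)


class TestIntegration:
    def test_leak_matches_analytic_relaxation(self, leak):
        model, table = leak
        p = table.p_true
        proto = build_step_protocol([(30.0, 800.0)])
        V0 = p["E_Leak"]
        x0 = np.array([V0])
        t = np.linspace(0, 30, 301)
        out = integrate_forward(model, p, x0, proto, t)
        tau = p["C"] / p["g_L"]
        V_inf = p["E_Leak"] + 0.01 * 800.0 / (p["A"] * p["g_L"])
        exact = V_inf + (V0 - V_inf) * np.exp(-t / tau)
        assert np.max(np.abs(out[:, 0] - exact)) < 1e-7

    def test_self_convergence_under_tolerance_refinement(self, rvlm):
        model, table = rvlm
        proto = build_step_protocol([(5, 0), (10, 3000)])
        x0 = settle_initial_state(model, table.p_true, rtol=1e-8, atol=1e-10)
        t = np.linspace(0, 15, 151)
        coarse = integrate_forward(model, table.p_true, x0, proto, t, rtol=1e-6, atol=1e-8)
        fine = integrate_forward(model, table.p_true, x0, proto, t, rtol=1e-9, atol=1e-11)
        assert np.max(np.abs(coarse[:, 0] - fine[:, 0])) < 1e-2

    def test_gates_stay_in_unit_interval(self, rvlm):
        model, table = rvlm
        proto = build_step_protocol([(5, 0), (10, 4000), (10, -4000)])
        x0 = settle_initial_state(model, table.p_true, rtol=1e-8, atol=1e-10)
        t = np.linspace(0, 25, 501)
        out = integrate_forward(model, table.p_true, x0, proto, t)
        assert np.all(out[:, 1:] >= -1e-9)
        assert np.all(out[:, 1:] <= 1 + 1e-9)

    def test_nudging_inputs_rejected(self, leak):
        model, table = leak
        proto = build_step_protocol([(10, 0)])
        with pytest.raises(InvalidParameterError):
            integrate_forward(
                model, table.p_true, np.array([-65.0]), proto,
                np.linspace(0, 10, 11), u_trace=0.5,
            )


class TestTwinDataset:
    def test_zero_noise_and_grid(self, leak):
        model, table = leak
        proto = build_step_protocol([(10, 0), (10, 1000)])
        ds = make_twin_dataset(model, table.p_true, proto, sigma=0.0, zeta=1, dt_base=0.01)
        assert ds.n_samples == 2001  # 20 ms at 100 kHz: n = 2000 intervals
        assert np.array_equal(ds.V_exp, ds.V_use)
        assert ds.t[-1] == pytest.approx(20.0)

    def test_bit_identical_under_same_seed(self, leak):
        model, table = leak
        proto = build_step_protocol([(10, 500)])
        a = make_twin_dataset(model, table.p_true, proto, sigma=0.4, zeta=9, dt_base=0.05)
        b = make_twin_dataset(model, table.p_true, proto, sigma=0.4, zeta=9, dt_base=0.05)
        assert np.array_equal(a.V_exp, b.V_exp)
        assert np.array_equal(a.V_use, b.V_use)

    def test_with_noise_reuses_clean_trace(self, leak_dataset):
        noisy = leak_dataset.with_noise(0.25, 11)
        assert np.array_equal(noisy.V_use, leak_dataset.V_use)
        eps = noisy.V_exp - noisy.V_use
        assert np.std(eps) == pytest.approx(0.25, rel=0.1)

    def test_csv_round_trip(self, tmp_path, leak_dataset):
        path = tmp_path / "twin.csv"
        leak_dataset.to_csv(path)
        back = type(leak_dataset).from_csv(path)
        assert np.allclose(back.t, leak_dataset.t)
        assert np.allclose(back.V_exp, leak_dataset.V_exp)
        assert back.zeta == leak_dataset.zeta
        assert back.protocol.steps == leak_dataset.protocol.steps


class TestMesh:
    def test_uniform_groups(self):
        plan = uniform_mesh(10_000, 0.02)
        plan.validate()
        assert plan.n_groups == 2500  # n/4 groups for n = 10,000 intervals
        assert plan.n_retained == 10_001

    def test_adaptive_all_supra_equals_base_grid(self):
        trace = np.full(41, -20.0)
        plan = adaptive_mesh(trace, threshold=-65.0, m=2, dt_base=0.1)
        assert np.array_equal(plan.retained, np.arange(41))
        assert np.all(plan.group_dt == 0.1)

    def test_adaptive_all_sub_keeps_every_mth(self):
        trace = np.full(81, -80.0)
        plan = adaptive_mesh(trace, threshold=-65.0, m=4, dt_base=0.1)
        # every 4th sample kept; trailing groups trimmed so the retained
        # interval count is a multiple of 4 m
        assert np.array_equal(plan.retained, np.arange(0, 65, 4))
        assert (plan.n_retained - 1) % 16 == 0
        assert np.all(plan.group_dt == pytest.approx(0.4))

    def test_divisibility_invariant_mixed_trace(self):
        rng = np.random.default_rng(0)
        for m in (1, 2, 4):
            trace = -80.0 + 40.0 * (rng.uniform(size=1201) > 0.7)
            plan = adaptive_mesh(trace, threshold=-65.0, m=m, dt_base=0.05)
            plan.validate()
            assert (plan.n_retained - 1) % (4 * m) == 0

    def test_longer_window_at_fixed_size(self):
        # sub-threshold thinning covers more time with the same point count
        t = np.arange(20_001) * 0.01
        trace = np.where((t % 50) < 10, -30.0, -80.0)
        p1 = adaptive_mesh(trace, -65.0, 1, 0.01)
        p4 = adaptive_mesh(trace, -65.0, 4, 0.01)
        n = min(p1.n_retained, p4.n_retained)
        assert p4.achieved_duration > p1.achieved_duration * 0.9
        # per retained sample, m=4 spans more time
        assert p4.achieved_duration / p4.n_retained > p1.achieved_duration / p1.n_retained

    def test_json_round_trip(self):
        plan = uniform_mesh(80, 0.05, stride=2)
        back = MeshPlan.from_json(plan.to_json())
        assert np.array_equal(back.retained, plan.retained)
        assert np.array_equal(back.groups, plan.groups)
        assert back.m == plan.m

    def test_too_short_trace(self):
        with pytest.raises(InvalidParameterError):
            adaptive_mesh(np.full(3, -80.0), -65.0, 1, 0.1)
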