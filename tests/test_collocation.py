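"""Collocation residual kernels, NLP assembly and small-problem recovery."""

import numpy as np
import pytest

from condassim.collocation import (
    InitPolicy,
    SolverOptions,
    assemble_nlp,
    boole_residual,
    classify_solution,
    hermite_residuals,
    solve_nlp,
)
from condassim.errors import InvalidParameterError
from condassim.model import RVLM_P0_LOCAL, ParameterSet
from condassim.twin import uniform_mesh


class TestBooleRule:
    def test_constant_dynamics(self):
        # weights sum to 2: x4 = x0 + 4 dt c closes the residual exactly
        dt, c = 0.1, 3.0
        x = np.linspace(0, 4 * dt * c, 5).reshape(5, 1)
        f = np.full((5, 1), c)
        assert boole_residual(x, f, dt) == pytest.approx(0.0, abs=1e-15)

    def test_degree5_polynomial_exactness(self):
        # Boole's rule integrates polynomials of degree 5 exactly
        rng = np.random.default_rng(3)
        dt = 0.07
        t = dt * np.arange(5)
        for _ in range(5):
            coeffs = rng.normal(size=6)  # f(t) of degree 5
            f = np.polyval(coeffs, t).reshape(5, 1)
            anti = np.polyint(coeffs)
            x = np.polyval(anti, t).reshape(5, 1)
            r = boole_residual(x, f, dt)
            assert abs(r[0]) < 1e-13 * max(1.0, np.abs(x).max())

    def test_degree6_not_exact(self):
        dt = 0.3
        t = dt * np.arange(5)
        coeffs = np.zeros(7)
        coeffs[0] = 1.0  # f = t^6
        f = np.polyval(coeffs, t).reshape(5, 1)
        x = np.polyval(np.polyint(coeffs), t).reshape(5, 1)
        assert abs(boole_residual(x, f, dt)[0]) > 1e-9

    def test_shape_validation(self):
        with pytest.raises(InvalidParameterError):
            boole_residual(np.zeros((4, 1)), np.zeros((4, 1)), 0.1)


class TestHermiteConditions:
    def test_linear_state_constant_dynamics(self):
        dt, a, b = 0.05, 1.3, -0.7
        t = dt * np.arange(5)
        x = (a + b * t).reshape(5, 1)
        f = np.full((5, 1), b)
        assert np.allclose(hermite_residuals(x, f, dt), 0.0, atol=1e-15)

    def test_cubic_exactness(self):
        # the midpoint interpolation is exact for cubics on each half-group
        rng = np.random.default_rng(5)
        dt = 0.11
        t = dt * np.arange(5)
        for _ in range(5):
            coeffs = rng.normal(size=4)  # cubic x(t)
            x = np.polyval(coeffs, t).reshape(5, 1)
            f = np.polyval(np.polyder(coeffs), t).reshape(5, 1)
            r = hermite_residuals(x, f, dt)
            assert np.max(np.abs(r)) < 1e-13 * max(1.0, np.abs(x).max())

    def test_quartic_not_exact(self):
        dt = 0.4
        t = dt * np.arange(5)
        coeffs = np.array([1.0, 0, 0, 0, 0])  # t^4
        x = np.polyval(coeffs, t).reshape(5, 1)
        f = np.polyval(np.polyder(coeffs), t).reshape(5, 1)
        assert np.max(np.abs(hermite_residuals(x, f, dt))) > 1e-6

    def test_constant_state_zero_dynamics(self):
        x = np.full((5, 2), 0.42)
        f = np.zeros((5, 2))
        assert np.allclose(hermite_residuals(x, f, 0.2), 0.0)


class TestAssembly:
    def test_constraint_and_decision_counts(self, leak_k, leak_k_dataset):
        model, table = leak_k
        L = model.n_states
        mesh = uniform_mesh(len(leak_k_dataset.t) - 1, leak_k_dataset.dt_base, stride=5)
        G = mesh.n_groups
        # published counting: L*G Boole + 2(L+1)*G Hermite with 2 retained
        # midpoint conditions per state
        prob2 = assemble_nlp(
            leak_k_dataset, mesh, model, table, SolverOptions(n_hermite=2)
        )
        assert prob2.n_constraints == L * G + 2 * (L + 1) * G
        # the default transcription adds the third state condition
        prob3 = assemble_nlp(leak_k_dataset, mesh, model, table, SolverOptions())
        assert prob3.n_constraints == L * G + 3 * L * G + 2 * G
        assert prob3.n_decision == (L + 1) * prob3.N + model.n_params

    def test_rvlm_full_problem_counts(self, rvlm):
        # L = 7, n = 10,000 intervals, m = 1: G = 2,500 groups;
        # 17,500 Boole and 40,000 Hermite constraints in the published counting
        L, n = 7, 10_000
        G = n // 4
        assert G == 2500
        assert L * G == 17_500
        assert 2 * (L + 1) * G == 40_000

    def test_bounds_wired_from_table(self, leak_problem, leak):
        model, table = leak
        prob = leak_problem
        pb = prob.param_slice()
        lo, hi = table.bounds_vectors()
        assert np.array_equal(prob.z_lo[pb], lo)
        assert np.array_equal(prob.z_hi[pb], hi)

    def test_bad_bounds_rejected(self, leak, leak_dataset):
        model, table = leak
        mesh = uniform_mesh(len(leak_dataset.t) - 1, leak_dataset.dt_base, stride=4)
        bad = table.bounds()
        bad["g_L"] = (2.0, 1.0)
        with pytest.raises(InvalidParameterError):
            assemble_nlp(leak_dataset, mesh, leak[0], bad, SolverOptions())

    def test_cost_assembly(self, leak_problem):
        prob = leak_problem
        z = prob.initial_point(InitPolicy(gates="steady_state_pointwise"))
        X, U, p = prob.unpack(z)
        # perfect fit with zero control costs nothing
        X[:, 0] = prob.V_exp
        U[:] = 0.0
        assert prob.cost(prob.pack(X, U, p)) == 0.0
        # a single delta mismatch costs delta^2/2
        X[3, 0] = prob.V_exp[3] + 0.5
        assert prob.cost(prob.pack(X, U, p)) == pytest.approx(0.125)


class TestRecovery:
    def test_leak_parameters_recovered(self, leak, leak_problem):
        model, table = leak
        rec = solve_nlp(leak_problem, InitPolicy(gates="steady_state_pointwise"))
        assert rec.converged
        for k in ("E_Leak", "g_L"):
            assert abs(rec.p_est[k] - table.p_true[k]) / abs(table.p_true[k]) < 1e-4
        assert rec.cost < 1e-6
        assert rec.feasibility <= 1e-8

    def test_leak_k_parameters_recovered(self, leak_k, leak_k_dataset):
        model, table = leak_k
        mesh = uniform_mesh(len(leak_k_dataset.t) - 1, leak_k_dataset.dt_base, stride=1)
        opt = SolverOptions(
            mu_schedule=(1e2, 1e4, 1e6, 1e8), alm_max_outer=14, stage0=False,
            trf_ftol=1e-14,
        )
        prob = assemble_nlp(leak_k_dataset, mesh, model, table, opt)
        rec = solve_nlp(prob, InitPolicy(nudge_gain=0.5))
        p_true = table.p_true
        rel = {
            k: abs(rec.p_est[k] - p_true[k]) / abs(p_true[k])
            for k in model.param_names
        }
        assert max(rel.values()) < 1e-4, rel

    def test_warm_start_at_solution_stays(self, leak, leak_problem):
        model, table = leak
        rec = solve_nlp(leak_problem, InitPolicy(gates="steady_state_pointwise"))
        z = leak_problem.pack(rec.states, rec.control, rec.p_est.to_vector(model))
        rec2 = solve_nlp(leak_problem, warm_start=z)
        assert abs(rec2.cost - rec.cost) < 1e-8 + 0.1 * rec.cost
        for k in model.param_names:
            assert rec2.p_est[k] == pytest.approx(rec.p_est[k], rel=1e-6, abs=1e-9)


class TestClassify:
    def test_identical_is_optimal(self, rvlm):
        _, table = rvlm
        p = table.p_true
        assert classify_solution(p, p, 0.01, table.bounds()) == "optimal"

    def test_published_local_minimum_is_suboptimal(self, rvlm):
        _, table = rvlm
        label = classify_solution(
            RVLM_P0_LOCAL, table.p_true, 0.01, table.bounds()
        )
        assert label == "suboptimal"

    def test_boundary_tolerance_inclusive(self):
        bounds = {"a": (0.0, 10.0)}
        p_ref = ParameterSet({"a": 5.0})
        p = ParameterSet({"a": 5.1})  # exactly 1% of the interval
        assert classify_solution(p, p_ref, 0.01, bounds) == "optimal"
        assert classify_solution(p, p_ref, 0.0099, bounds) == "suboptimal"

    def test_name_mismatch(self):
        with pytest.raises(InvalidParameterError):
            classify_solution({"a": 1.0}, {"b": 1.0}, 0.01, {"a": (0, 1)})
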