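"""Noise-ramp regularization: fold detection against a closed-form oracle.

The analytic fixture is the tilted double well
c(p; sigma) = (p^2-1)^2 + (b + sigma) p with base tilt b = 0.3, so the well
near p = -1 is the strict global minimum at sigma = 0 and the well near
p = +1 is local.  Stationary points satisfy 4p^3 - 4p + (b + sigma) = 0;
the local minimum merges with the saddle when the cubic has a double root,
i.e. at b + sigma_crit = 8/(3 sqrt 3), giving sigma_crit ~ 1.2396 on the
positive leg.  Ramping sigma with warm-started local minimizations must
detect the fold within one grid step.
"""

import numpy as np
import pytest
from scipy.optimize import minimize

from condassim.errors import SolverError
from condassim.regularize import (
    RampPoint,
    anneal_to_zero,
    default_sigma_grid,
    ramp_and_detect,
    regularized_search,
)

BASE_TILT = 0.3
SIGMA_CRIT = 8.0 / (3.0 * np.sqrt(3.0)) - BASE_TILT


class QuarticWellSolver:
    """Warm-started local minimization of the tilted double well."""

    widths = np.array([2.0])

    def __init__(self):
        self.model = None

    @staticmethod
    def cost(p, sigma):
        return (p * p - 1.0) ** 2 + (BASE_TILT + sigma) * p

    def solve(self, sigma, warm) -> RampPoint:
        p0 = float(np.ravel(warm)[0]) if not np.isscalar(warm) else float(warm)
        res = minimize(
            lambda p: self.cost(p[0], sigma),
            [p0],
            jac=lambda p: np.array([4.0 * p[0] * (p[0] ** 2 - 1.0) + BASE_TILT + sigma]),
            method="BFGS",
            options={"gtol": 1e-12},
        )
        p = float(res.x[0])
        return RampPoint(sigma=float(sigma), params=np.array([p]),
                         cost=float(res.fun), warm=p)


@pytest.fixture
def local_start():
    solver = QuarticWellSolver()
    # the well at p = +1 becomes metastable for sigma > 0: start there
    return solver, solver.solve(0.0, +1.0)


class TestFoldDetection:
    def test_sigma_crit_within_one_grid_step(self, local_start):
        solver, start = local_start
        grid = default_sigma_grid(sigma_max=2.0, step=0.02)
        trace = ramp_and_detect(solver, start, grid, both_legs=True)
        assert trace.sigma_crit is not None
        # positive sigma tilts the p=+1 well upward -> fold on the + leg
        assert trace.sigma_crit > 0
        assert abs(trace.sigma_crit - SIGMA_CRIT) <= 0.02 + 1e-12

    def test_global_start_never_jumps(self):
        solver = QuarticWellSolver()
        # starting in the well favored by the tilt: no bifurcation on a
        # modest ramp range
        start = solver.solve(0.0, -1.0)
        grid = default_sigma_grid(sigma_max=1.0, step=0.02)
        trace = ramp_and_detect(solver, start, grid, both_legs=False)
        assert trace.sigma_crit is None

    def test_trace_is_reproducible(self, local_start):
        solver, start = local_start
        grid = default_sigma_grid(sigma_max=2.0, step=0.05)
        t1 = ramp_and_detect(solver, start, grid)
        t2 = ramp_and_detect(solver, start, grid)
        assert t1.sigma_crit == t2.sigma_crit
        assert [p.cost for p in t1.points] == [p.cost for p in t2.points]


class TestAnneal:
    def test_zero_sigma_is_identity(self, local_start):
        solver, start = local_start
        out = anneal_to_zero(solver, start)
        assert out is start

    def test_anneal_reaches_global_minimum(self, local_start):
        solver, start = local_start
        grid = default_sigma_grid(sigma_max=2.0, step=0.02)
        trace = ramp_and_detect(solver, start, grid)
        final = anneal_to_zero(solver, trace.points[trace.jump_index], grid)
        assert final.sigma == 0.0
        assert final.params[0] == pytest.approx(-1.037, abs=5e-3)
        assert final.cost < solver.solve(0.0, +1.0).cost


class TestRegularizedSearch:
    def test_escapes_local_minimum(self, local_start):
        solver, _ = local_start
        grid = default_sigma_grid(sigma_max=2.0, step=0.02)
        final, diag = regularized_search(solver, +1.0, grid)
        assert diag["status"] == "regularized"
        assert final.params[0] == pytest.approx(-1.037, abs=5e-3)
        # the regularized result is never worse than the plain solve
        assert final.cost <= diag["plain"].cost + 1e-12

    def test_noop_from_global_basin(self):
        solver = QuarticWellSolver()
        grid = default_sigma_grid(sigma_max=1.0, step=0.05)
        final, diag = regularized_search(solver, -1.0, grid)
        assert diag["status"] == "no-bifurcation"
        assert final.params[0] == pytest.approx(-1.037, abs=5e-3)

    def test_grid_tail_invariance(self, local_start):
        solver, _ = local_start
        # the ramp stops at the jump, so extending the grid beyond the fold
        # does not change the outcome
        g1 = default_sigma_grid(sigma_max=1.8, step=0.02)
        g2 = default_sigma_grid(sigma_max=3.0, step=0.02)
        f1, d1 = regularized_search(solver, +1.0, g1)
        f2, d2 = regularized_search(solver, +1.0, g2)
        assert d1["ramp_trace"].sigma_crit == d2["ramp_trace"].sigma_crit
        assert f1.params[0] == pytest.approx(f2.params[0], abs=1e-10)
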