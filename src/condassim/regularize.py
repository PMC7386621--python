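"""Noise-ramp regularization toward the global cost minimum.

Additive observation noise shifts the local and global minima of the data
misfit relative to one another by an amount that depends on the noise
amplitude sigma and realization zeta.  Ramping the amplitude of one fixed
realization therefore deforms the cost surface continuously; at a critical
amplitude sigma_crit the tracked local minimum merges with a saddle
(a saddle-node bifurcation) and the solution jumps into the neighboring —
deeper — basin.  Annealing sigma back to zero then lands in the global
minimum.  The algorithm:

  (i)   solve the inverse problem on the clean data (possibly sub-optimal);
  (ii)  ramp sigma over a fixed realization, warm-starting each solve from
        the previous one, until an abrupt jump in both the parameters and
        the cost is detected;
  (iii) anneal sigma back to zero, warm-starting along the way.

A negative sigma means the sign-flipped realization of the same noise.

The machinery is generic over a ``solver``: any object with a
``solve(sigma, warm_start) -> RampPoint`` method and a ``widths`` vector
for interval-scaled parameter distances.  ``AssimilationRampSolver`` adapts
the collocation estimator; a cheap analytic double-well fixture can use the
same ramp/detection code, which is how the detector is validated against a
closed-form fold point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .collocation import (
    InitPolicy,
    SolutionRecord,
    SolverOptions,
    assemble_nlp,
    classify_solution,
    solve_nlp,
)
from .errors import InvalidParameterError, SolverError
from .model import ModelSpec, ParameterSet, ParameterTable
from .twin import MeshPlan, TwinDataset

__all__ = [
    "RampPoint",
    "SigmaRampTrace",
    "AssimilationRampSolver",
    "ramp_and_detect",
    "anneal_to_zero",
    "regularized_search",
    "success_rate_experiment",
    "default_sigma_grid",
]


@dataclass
class RampPoint:
    """One solve along the sigma ramp."""

    sigma: float
    params: np.ndarray
    cost: float
    warm: object = None  # solver-specific warm-start payload
    record: object = None


@dataclass
class SigmaRampTrace:
    """Ordered ramp solves, per-step jump metrics, and the detected fold."""

    points: list[RampPoint] = field(default_factory=list)
    dp_steps: list[float] = field(default_factory=list)  # interval-scaled ||dp||
    dc_steps: list[float] = field(default_factory=list)
    sigma_crit: float | None = None
    jump_index: int | None = None

    def to_jsonable(self) -> dict:
        return {
            "sigma": [p.sigma for p in self.points],
            "cost": [p.cost for p in self.points],
            "dp_steps": self.dp_steps,
            "dc_steps": self.dc_steps,
            "sigma_crit": self.sigma_crit,
        }


class AssimilationRampSolver:
    """Adapter presenting the collocation estimator to the ramp machinery.

    One fixed noise realization ``zeta``; ``solve(sigma, warm)`` assimilates
    V_use + sigma * eta_zeta warm-started from the previous decision vector.
    """

    def __init__(
        self,
        dataset_clean: TwinDataset,
        mesh: MeshPlan,
        model: ModelSpec,
        table: ParameterTable,
        zeta: int,
        options: SolverOptions | None = None,
    ):
        self.model = model
        self.table = table
        self.zeta = int(zeta)
        self.dataset_clean = dataset_clean
        self.options = options or SolverOptions(
            mu_schedule=(1e4,), alm_max_outer=6, lm_max_iter=30, stage0=False
        )
        self.problem = assemble_nlp(dataset_clean, mesh, model, table, self.options)
        lo, hi = table.bounds_vectors(self.options.bounds_set)
        w = hi - lo
        self.widths = np.where(w > 0, w, np.maximum(np.abs(hi), 1.0))

    def solve(self, sigma: float, warm) -> RampPoint:
        ds = self.dataset_clean.with_noise(sigma, self.zeta)
        self.problem.update_observations(ds)
        if isinstance(warm, np.ndarray):
            rec = solve_nlp(self.problem, warm_start=warm)
        else:
            rec = solve_nlp(self.problem, init=warm)
        z = self.problem.pack(rec.states, rec.control, rec.p_est.to_vector(self.model))
        return RampPoint(
            sigma=float(sigma),
            params=rec.p_est.to_vector(self.model),
            cost=rec.cost,
            warm=z,
            record=rec,
        )


def default_sigma_grid(sigma_max: float = 0.5, step: float = 0.01) -> np.ndarray:
    """Positive amplitudes of one ramp leg: step, 2*step, ..., sigma_max (mV)."""
    n = int(round(sigma_max / step))
    return step * np.arange(1, n + 1)


def _scaled_jump(p_new: np.ndarray, p_old: np.ndarray, widths: np.ndarray) -> float:
    return float(np.linalg.norm((p_new - p_old) / widths))


def ramp_and_detect(
    solver,
    start: RampPoint,
    sigma_grid: np.ndarray | None = None,
    jump_factor: float = 10.0,
    min_steps_before_detect: int = 3,
    both_legs: bool = True,
) -> SigmaRampTrace:
    """Ramp |sigma| along both signed legs until a saddle-node jump is seen.

    Each solve is warm-started from the previous ramp point.  A jump is
    flagged at the first step whose interval-scaled parameter displacement
    exceeds ``jump_factor`` times the running median of earlier steps on the
    same leg AND whose cost change does so as well — a scale-free detector
    for the simultaneous discontinuity in p and c at the fold.
    """
    grid = default_sigma_grid() if sigma_grid is None else np.asarray(sigma_grid)
    grid = np.sort(np.abs(np.unique(grid[grid != 0])))
    trace = SigmaRampTrace(points=[start])
    legs = [-1.0, +1.0] if both_legs else [+1.0]
    for sign in legs:
        prev = start
        dp_hist: list[float] = []
        dc_hist: list[float] = []
        for s in grid:
            sigma = sign * s
            point = solver.solve(sigma, prev.warm)
            dp = _scaled_jump(point.params, prev.params, solver.widths)
            dc = abs(point.cost - prev.cost)
            trace.points.append(point)
            trace.dp_steps.append(dp)
            trace.dc_steps.append(dc)
            if len(dp_hist) >= min_steps_before_detect:
                med_dp = float(np.median(dp_hist)) + 1e-300
                med_dc = float(np.median(dc_hist)) + 1e-300
                if dp > jump_factor * med_dp and dc > jump_factor * med_dc:
                    trace.sigma_crit = sigma
                    trace.jump_index = len(trace.points) - 1
                    return trace
            dp_hist.append(dp)
            dc_hist.append(dc)
            prev = point
    return trace


def anneal_to_zero(
    solver,
    point_from: RampPoint,
    sigma_grid: np.ndarray | None = None,
    jump_factor: float = 10.0,
) -> RampPoint:
    """Step sigma monotonically back to zero, warm-starting each solve.

    The trajectory must stay continuous (no further bifurcations): a jump
    during annealing indicates a mis-detected basin and raises
    :class:`SolverError`.
    """
    sigma_from = point_from.sigma
    if sigma_from == 0.0:
        return point_from
    grid = default_sigma_grid() if sigma_grid is None else np.asarray(sigma_grid)
    grid = np.sort(np.abs(np.unique(grid[grid != 0])))
    down = grid[grid < abs(sigma_from)][::-1]
    sigmas = np.concatenate([np.sign(sigma_from) * down, [0.0]])
    prev = point_from
    dp_hist: list[float] = []
    for sigma in sigmas:
        point = solver.solve(float(sigma), prev.warm)
        dp = _scaled_jump(point.params, prev.params, solver.widths)
        if len(dp_hist) >= 3 and dp > jump_factor * (np.median(dp_hist) + 1e-300):
            raise SolverError(
                f"jump during annealing at sigma={sigma:.4g}; basin mis-detected"
            )
        dp_hist.append(dp)
        prev = point
    return prev


def regularized_search(
    solver,
    init,
    sigma_grid: np.ndarray | None = None,
    jump_factor: float = 10.0,
) -> tuple[RampPoint, dict]:
    """The full regularization pipeline: plain solve, sigma ramp, anneal.

    Returns the final sigma = 0 solution and diagnostics (the ramp trace and
    a status flag).  The final cost never exceeds the plain solve's cost: if
    no jump is found, or the annealed solution is worse, the plain solution
    is returned ('no-bifurcation' / 'anneal-not-better').
    """
    plain = solver.solve(0.0, init)
    trace = ramp_and_detect(solver, plain, sigma_grid, jump_factor)
    diagnostics = {"ramp_trace": trace, "status": "no-bifurcation", "plain": plain}
    if trace.sigma_crit is None:
        return plain, diagnostics
    try:
        annealed = anneal_to_zero(
            solver, trace.points[trace.jump_index], sigma_grid, jump_factor
        )
    except SolverError as e:
        diagnostics["status"] = f"anneal-failed: {e}"
        return plain, diagnostics
    if annealed.cost <= plain.cost:
        diagnostics["status"] = "regularized"
        return annealed, diagnostics
    diagnostics["status"] = "anneal-not-better"
    return plain, diagnostics


def success_rate_experiment(
    solver_factory,
    p_true,
    bounds: dict,
    n_runs: int,
    master_seed: int,
    with_regularization: bool,
    tol_rel: float = 0.01,
    sigma_grid: np.ndarray | None = None,
) -> dict:
    """Fraction of random initializations converging to the true parameters.

    ``solver_factory(zeta)`` returns a ramp solver whose noise realization
    is ``zeta`` (a fresh realization per run); each run starts from a
    uniform-in-bounds random parameter draw (seeded from ``master_seed``)
    and is scored by interval-scaled classification against ``p_true``.
    """
    if n_runs < 1:
        raise InvalidParameterError("n_runs must be >= 1")
    rng = np.random.Generator(np.random.Philox(key=int(master_seed)))
    seeds = rng.integers(0, 2**31 - 1, size=n_runs)
    runs = []
    n_opt = 0
    for run, zeta_r in enumerate(seeds):
        solver = solver_factory(int(zeta_r))
        init = InitPolicy(params="random", seed=int(zeta_r))
        if with_regularization:
            final, diag = regularized_search(solver, init, sigma_grid)
            status = diag["status"]
        else:
            final = solver.solve(0.0, init)
            status = "plain"
        p_est = ParameterSet.from_vector(solver.model, final.params)
        label = classify_solution(p_est, ParameterSet(p_true), tol_rel, bounds)
        n_opt += label == "optimal"
        runs.append(
            {
                "zeta": int(zeta_r),
                "classification": label,
                "cost": final.cost,
                "status": status,
                "params": dict(p_est),
            }
        )
    return {
        "fraction_optimal": n_opt / n_runs,
        "n_runs": n_runs,
        "runs": runs,
        "with_regularization": with_regularization,
    }
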