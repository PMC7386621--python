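"""Posterior characterization and misfit-surface geometry.

Two complementary views of parameter uncertainty are implemented:

* **Monte-Carlo posteriors** — re-assimilating many noisy realizations of
  the same clean trace yields an ensemble of estimates whose sample
  covariance Sigma (unbiased, over R realizations) approximates the inverse
  Hessian of the data-misfit surface; its eigenvalues lambda_k^2 are the
  squared principal semi-axes of the constant-misfit ellipsoid, and their
  spread measures parameter sloppiness.

* **Analytic misfit geometry** — expanding the cost perturbation about a
  converged zero-noise solution p*:

      delta_c = F + (p - p*)^T G + 1/2 (p - p*)^T H (p - p*)

  with F = 1/2 sum eps^2 + sum eps*eps_mod (the noise-entropy offset),
  G_k = sum eps * dV/dp_k, and H_kk' = sum [dV/dp_k dV/dp_k' +
  d2V/dp_k dp_k' (eps + eps_mod)].  The noise-induced parameter offset is
  the minimizer delta_p = -H^{-1} G, reported in the parameter basis and in
  the eigenbasis of H.

The expected noise energy E[1/2 sum eps^2] = (n+1) sigma^2 / 2 maps to a
noise-equivalent temperature through the Johnson-Nyquist relation
sigma^2 = 4 k_B T R df.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .collocation import (
    SolutionRecord,
    SolverOptions,
    assemble_nlp,
    solve_nlp,
)
from .errors import InvalidParameterError
from .model import ModelSpec, ParameterSet, ParameterTable
from ._symbolic import compiled_rhs
from .twin import MeshPlan, TwinDataset, adaptive_mesh

__all__ = [
    "EnsembleEstimates",
    "MisfitGeometry",
    "LinearForwardModel",
    "ODEForwardModel",
    "ensemble_estimates",
    "covariance_and_spectrum",
    "misfit_terms",
    "parameter_offset",
    "noise_energy_and_temperature",
    "pdf_summary",
    "window_length_experiment",
]

_BOLTZMANN = 1.380649e-23  # J/K


# ---------------------------------------------------------------------------
# ensembles
# ---------------------------------------------------------------------------


@dataclass
class EnsembleEstimates:
    """Matrix of parameter estimates over noise realizations (R x K)."""

    params: np.ndarray  # (R, K)
    param_names: tuple[str, ...]
    sigma: float
    seeds: np.ndarray  # realization seeds, one per row
    n_failed: int = 0
    records: list = field(default_factory=list)

    @property
    def R(self) -> int:
        return self.params.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.params[:, self.param_names.index(name)]

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.params, columns=list(self.param_names))
        df.insert(0, "zeta", self.seeds)
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, sigma: float = np.nan) -> "EnsembleEstimates":
        df = pd.read_csv(path)
        seeds = df.pop("zeta").to_numpy()
        return cls(
            params=df.to_numpy(),
            param_names=tuple(df.columns),
            sigma=float(sigma),
            seeds=seeds,
        )


def ensemble_estimates(
    dataset_clean: TwinDataset,
    mesh: MeshPlan,
    model: ModelSpec,
    table: ParameterTable,
    base_record: SolutionRecord,
    sigma: float,
    R: int,
    master_seed: int,
    options: SolverOptions | None = None,
    keep_records: bool = False,
) -> EnsembleEstimates:
    """Assimilate R fresh noise realizations, warm-started from the sigma=0 fit.

    Each realization seed is drawn from ``master_seed``; every solve starts
    from the zero-noise solution's full decision vector (the published
    recipe: initializing the search at the optimum secures convergence).
    Failed solves are excluded and counted.
    """
    if R < 1:
        raise InvalidParameterError("R must be >= 1")
    opt = options or SolverOptions(
        mu_schedule=(1e4,), alm_max_outer=6, lm_max_iter=30, stage0=False
    )
    problem = assemble_nlp(dataset_clean, mesh, model, table, opt)
    z_base = problem.pack(
        base_record.states, base_record.control, base_record.p_est.to_vector(model)
    )
    rng = np.random.Generator(np.random.Philox(key=int(master_seed)))
    seeds = rng.integers(0, 2**31 - 1, size=R)
    rows, kept_seeds, records = [], [], []
    n_failed = 0
    for zeta_r in seeds:
        ds_r = dataset_clean.with_noise(sigma, int(zeta_r))
        problem.update_observations(ds_r)
        rec = solve_nlp(problem, warm_start=z_base)
        if not np.all(np.isfinite(rec.p_est.to_vector(model))):
            n_failed += 1
            continue
        rows.append(rec.p_est.to_vector(model))
        kept_seeds.append(zeta_r)
        if keep_records:
            records.append(rec)
    return EnsembleEstimates(
        params=np.array(rows),
        param_names=tuple(model.param_names),
        sigma=float(sigma),
        seeds=np.array(kept_seeds),
        n_failed=n_failed,
        records=records,
    )


def covariance_and_spectrum(ens: EnsembleEstimates | np.ndarray):
    """Unbiased sample covariance of the ensemble and its sorted eigenvalues.

    Returns (Sigma, lambda2) with lambda2 descending; Sigma is symmetric
    positive semidefinite and relates to the misfit Hessian by H = Sigma^-1.
    """
    P = ens.params if isinstance(ens, EnsembleEstimates) else np.asarray(ens)
    if P.shape[0] < 2:
        raise InvalidParameterError("covariance needs at least two realizations")
    Sigma = np.cov(P, rowvar=False, ddof=1)
    Sigma = np.atleast_2d(Sigma)
    lam2 = np.linalg.eigvalsh(Sigma)[::-1]
    return Sigma, lam2


# ---------------------------------------------------------------------------
# forward maps with exact sensitivities
# ---------------------------------------------------------------------------


class LinearForwardModel:
    """V_mod(p) = X p + offset — the linear-Gaussian reference model.

    Its least-squares estimate and covariance are known in closed form
    (p_hat = (X^T X)^{-1} X^T V, cov = sigma^2 (X^T X)^{-1}), which makes it
    the oracle for the misfit-geometry machinery.
    """

    def __init__(self, X: np.ndarray, offset: np.ndarray | float = 0.0):
        self.X = np.asarray(X, dtype=float)
        self.offset = offset

    def values(self, p: np.ndarray) -> np.ndarray:
        return self.X @ np.asarray(p, dtype=float) + self.offset

    def jacobian(self, p: np.ndarray) -> np.ndarray:
        return self.X

    def hessian(self, p: np.ndarray) -> np.ndarray:
        n, K = self.X.shape
        return np.zeros((n, K, K))

    def fit(self, V: np.ndarray) -> np.ndarray:
        return np.linalg.lstsq(self.X, V - self.offset, rcond=None)[0]


class ODEForwardModel:
    """Voltage trace of the conductance model as a function of parameters.

    First derivatives dV/dp come from the forward sensitivity system
    integrated alongside the ODE (exact symbolic dF/dx and dF/dp); second
    derivatives are obtained by central differences of the exact first-order
    sensitivities.  ``free_names`` restricts differentiation to a parameter
    subset.
    """

    def __init__(
        self,
        model: ModelSpec,
        protocol,
        t_grid: np.ndarray,
        base_params,
        free_names=None,
        x0: np.ndarray | None = None,
        rtol: float = 1e-8,
        atol: float = 1e-10,
    ):
        self.model = model
        self.protocol = protocol
        self.t_grid = np.asarray(t_grid, dtype=float)
        self.base = ParameterSet(base_params)
        self.free_names = tuple(free_names or model.param_names)
        self.x0 = x0
        self.rtol, self.atol = rtol, atol
        self.rhs = compiled_rhs(model, assimilation=False)
        self._free_idx = [model.param_names.index(k) for k in self.free_names]

    def _full_vec(self, p: np.ndarray) -> np.ndarray:
        full = self.base.to_vector(self.model)
        full[self._free_idx] = p
        return full

    def _x0(self, pmap) -> np.ndarray:
        # the initial state is held fixed (settled once at the base
        # parameters) so that the map p -> V(t) and its sensitivities are
        # consistent: S(0) = dx0/dp = 0
        from .twin import settle_initial_state

        if self.x0 is None:
            self.x0 = settle_initial_state(
                self.model, self.base, I_hold=self.protocol.steps[0][1]
            )
        return np.asarray(self.x0, dtype=float)

    def states(self, p: np.ndarray) -> np.ndarray:
        from .twin import integrate_forward

        full = self._full_vec(np.asarray(p, dtype=float))
        pmap = ParameterSet.from_vector(self.model, full)
        return integrate_forward(
            self.model, pmap, self._x0(pmap), self.protocol, self.t_grid,
            rtol=self.rtol, atol=self.atol,
        )

    def values(self, p: np.ndarray) -> np.ndarray:
        return self.states(p)[:, 0]

    def jacobian(self, p: np.ndarray) -> np.ndarray:
        """dV/dp on the time grid, (n, K_free), by forward sensitivities."""
        from scipy.integrate import solve_ivp

        model = self.model
        L = model.n_states
        full = self._full_vec(np.asarray(p, dtype=float))
        pmap = ParameterSet.from_vector(model, full)
        Kf = len(self._free_idx)
        n_local = self.rhs.n_local  # == L in prediction mode
        jac_entries = self.rhs.jac_entries

        def rhs_aug(t, y, amp):
            x = y[:L]
            S = y[L:].reshape(L, Kf)
            F, Jvals = self.rhs.rhs_and_jac(
                x[None, :], None, None, np.array([amp]), full
            )
            A = np.zeros((L, L))
            B = np.zeros((L, Kf))
            for (l, j), val in zip(jac_entries, Jvals):
                if j < n_local:
                    A[l, j] = val[0]
                else:
                    kp = j - n_local
                    if kp in self._free_idx:
                        B[l, self._free_idx.index(kp)] = val[0]
            dS = A @ S + B
            return np.concatenate([F[0], dS.ravel()])

        y = np.concatenate([self._x0(pmap), np.zeros(L * Kf)])
        out = np.empty((len(self.t_grid), Kf))
        edges = self.protocol.edges
        for seg, (_, amp) in enumerate(self.protocol.steps):
            a, b = edges[seg], edges[seg + 1]
            sel = (self.t_grid >= a - 1e-12) & (self.t_grid <= b + 1e-12)
            sol = solve_ivp(
                rhs_aug, (a, b), y, args=(amp,), method="LSODA",
                rtol=self.rtol, atol=self.atol, dense_output=True,
            )
            if np.any(sel):
                ys = sol.sol(self.t_grid[sel]).T
                out[sel] = ys[:, L:].reshape(-1, L, Kf)[:, 0, :]
            y = sol.y[:, -1]
        return out

    def hessian(self, p: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
        """d2V/dp dp' (n, K, K) by central differences of exact sensitivities."""
        p = np.asarray(p, dtype=float)
        Kf = len(p)
        n = len(self.t_grid)
        H = np.empty((n, Kf, Kf))
        for k in range(Kf):
            h = rel_step * max(abs(p[k]), 1e-3)
            pp, pm = p.copy(), p.copy()
            pp[k] += h
            pm[k] -= h
            H[:, k, :] = (self.jacobian(pp) - self.jacobian(pm)) / (2 * h)
        return 0.5 * (H + np.transpose(H, (0, 2, 1)))


# ---------------------------------------------------------------------------
# misfit geometry
# ---------------------------------------------------------------------------


@dataclass
class MisfitGeometry:
    """Local expansion of the data misfit about a zero-noise optimum."""

    F: float
    G: np.ndarray  # (K,)
    H: np.ndarray  # (K, K), symmetric
    eigenvalues: np.ndarray  # of H, ascending
    eigenvectors: np.ndarray  # columns
    semi_axes: np.ndarray  # lambda_k = eigenvalue^{-1/2} where positive

    @property
    def offset(self) -> np.ndarray:
        return parameter_offset(self)

    def offset_in_eigenbasis(self) -> np.ndarray:
        return self.eigenvectors.T @ parameter_offset(self)


def misfit_terms(
    forward_model,
    p_star: np.ndarray,
    V_exp: np.ndarray,
    V_use: np.ndarray | None = None,
    include_second_order: bool = True,
) -> MisfitGeometry:
    """Offset F, gradient G and Hessian H of the misfit expansion at p_star.

    ``eps = V_exp - V_use`` is the experimental error and
    ``eps_mod = V_mod(p_star) - V_use`` the model error (zero in a perfect
    twin experiment).  With ``include_second_order`` the Hessian carries the
    error-weighted second-derivative term; otherwise it is the Gauss-Newton
    part only.
    """
    p_star = np.asarray(p_star, dtype=float)
    V_mod = forward_model.values(p_star)
    if V_use is None:
        V_use = V_mod
    eps = np.asarray(V_exp, dtype=float) - np.asarray(V_use, dtype=float)
    eps_mod = V_mod - np.asarray(V_use, dtype=float)
    J = forward_model.jacobian(p_star)
    F = 0.5 * float(eps @ eps) + float(eps @ eps_mod)
    G = J.T @ eps
    H = J.T @ J
    if include_second_order:
        H2 = forward_model.hessian(p_star)
        H = H + np.einsum("i,ikl->kl", eps + eps_mod, H2)
    H = 0.5 * (H + H.T)
    w, V = np.linalg.eigh(H)
    with np.errstate(divide="ignore", invalid="ignore"):
        semi = np.where(w > 0, 1.0 / np.sqrt(np.abs(w)), np.inf)
    return MisfitGeometry(F=F, G=G, H=H, eigenvalues=w, eigenvectors=V, semi_axes=semi)


def parameter_offset(geom: MisfitGeometry) -> np.ndarray:
    """Noise-induced parameter offset delta_p = H^{-1} G.

    With G = sum eps dV/dp (the explicit noise-weighted sensitivity sum),
    the noisy cost expands as delta_c = F - delta_p.G + 1/2 delta_p.H.delta_p,
    whose minimizer — and the actual shift of the re-solved minimum — is
    +H^{-1} G.  Falls back to the pseudo-inverse (with a warning) when H is
    singular.
    """
    try:
        return np.linalg.solve(geom.H, geom.G)
    except np.linalg.LinAlgError:
        warnings.warn("misfit Hessian is singular; using pseudo-inverse", RuntimeWarning)
        return np.linalg.pinv(geom.H) @ geom.G


def noise_energy_and_temperature(
    sigma: float, n: int, R_membrane: float, bandwidth: float
):
    """Expected noise energy (n+1) sigma^2 / 2 and the equivalent temperature.

    ``sigma`` in mV, ``R_membrane`` in ohm, ``bandwidth`` in Hz; the
    temperature follows from the Johnson-Nyquist relation
    sigma^2 = 4 k_B T R df (sigma converted to volts).
    """
    if R_membrane <= 0 or bandwidth <= 0:
        raise InvalidParameterError("membrane resistance and bandwidth must be positive")
    energy = 0.5 * (n + 1) * sigma**2  # mV^2
    T_sigma = (sigma * 1e-3) ** 2 / (4.0 * _BOLTZMANN * R_membrane * bandwidth)
    return energy, T_sigma


def pdf_summary(samples: np.ndarray, skew_threshold: float = 0.5) -> dict:
    """Mode (MLE), spread and Gaussianity summary of one parameter's posterior.

    The MLE is the mode of a Gaussian-kernel density (Silverman bandwidth);
    sigma_p is the unbiased sample standard deviation; the moment-matched
    Gaussian fit and a skewness flag describe departure from normality.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 30:
        raise InvalidParameterError("pdf_summary needs at least 30 samples")
    sigma_p = float(np.std(x, ddof=1))
    mean = float(np.mean(x))
    if sigma_p == 0.0:
        return {
            "mle": mean, "sigma_p": 0.0, "gaussian_fit": (mean, 0.0),
            "skewness": 0.0, "non_gaussian": False,
        }
    kde = stats.gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(x.min(), x.max(), 512)
    mle = float(grid[np.argmax(kde(grid))])
    skew = float(stats.skew(x, bias=False))
    return {
        "mle": mle,
        "sigma_p": sigma_p,
        "gaussian_fit": (mean, sigma_p),
        "skewness": skew,
        "non_gaussian": bool(abs(skew) > skew_threshold),
    }


# ---------------------------------------------------------------------------
# window-length (adaptive-mesh) identifiability experiment
# ---------------------------------------------------------------------------


def window_length_experiment(
    dataset_long: TwinDataset,
    model: ModelSpec,
    table: ParameterTable,
    base_solver,
    sigma: float,
    R: int,
    master_seed: int,
    m_values=(1, 2, 4),
    n_target: int | None = None,
    threshold: float = -65.0,
    options: SolverOptions | None = None,
):
    """Covariance spectra at fixed problem size but growing window duration.

    For each sub-threshold multiplier m, an adaptive mesh retains full
    resolution around action potentials and every m-th sample elsewhere;
    trailing groups are trimmed so every mesh keeps the same retained
    interval count ``n_target``.  ``base_solver(dataset, mesh)`` must return
    the sigma = 0 SolutionRecord used to warm-start the ensembles.  Returns
    ``{m: {"eigenvalues", "sigma_matrix", "achieved_T", "ensemble"}}``.
    """
    import dataclasses as _dc

    results = {}
    for m in m_values:
        mesh = adaptive_mesh(dataset_long.V_exp, threshold, m, dataset_long.dt_base)
        if n_target is not None:
            G_keep = n_target // 4
            G_keep -= G_keep % m
            if mesh.n_groups < G_keep:
                raise InvalidParameterError(
                    f"long trace supports only {4*mesh.n_groups} intervals at m={m}"
                )
            retained = mesh.retained[: 4 * G_keep + 1]
            mesh = _dc.replace(
                mesh,
                retained=retained,
                groups=mesh.groups[:G_keep],
                group_dt=mesh.group_dt[:G_keep],
            )
            mesh.validate()
        base = base_solver(dataset_long, mesh)
        ens = ensemble_estimates(
            dataset_long, mesh, model, table, base, sigma, R, master_seed,
            options=options,
        )
        Sigma, lam2 = covariance_and_spectrum(ens)
        results[m] = {
            "eigenvalues": lam2,
            "sigma_matrix": Sigma,
            "achieved_T": mesh.achieved_duration,
            "ensemble": ens,
        }
    return results
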