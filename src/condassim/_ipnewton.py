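"""Structured interior-point Newton solver for the ALM collocation subproblem.

The subproblem at one penalty level is

    min_z  1/2 ||r_d(z)||^2 + 1/2 ||S_mu c(z) + S_mu^{-1} lam||^2 - eta * B(z)

with r_d the data residuals, c the (row-scaled) collocation constraints,
S_mu = diag(sqrt(mu_row)), and B the log-barrier for the box bounds.  The
Newton step is computed from the exact KKT (augmented) system rather than
the squared normal equations, which keeps the linear algebra well
conditioned at large penalties:

    [ H_uu  H_up  J_u^T ] [s_u]   [-g_u]
    [ H_pu  H_pp  J_p^T ] [s_p] = [-g_p]
    [ J_u   J_p  -D_1/mu ] [ w ]   [  a0 ]

H_uu (states and control) is block diagonal with (L+1)x(L+1) blocks per
mesh point, so it is eliminated first by batched Cholesky; the resulting
constraint-space Schur complement J_u H_uu^{-1} J_u^T + D_1/mu is banded in
time and solved by banded Cholesky; the final dense Schur complement over
the model parameters is K x K.  Total cost per step is O(n) with small
constants.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as spa
from scipy.linalg import LinAlgError, cho_solve_banded, cholesky_banded

__all__ = ["ipx_minimize", "IPXResult"]


@dataclass
class IPXResult:
    x: np.ndarray
    cost: float  # 1/2 ||full residual stack||^2 at the solution (no barrier)
    optimality: float  # projected true gradient, infinity norm
    nfev: int
    njev: int
    status: int
    message: str


class _StructuredStep:
    """One factorization/solve of the structured KKT system."""

    def __init__(self, problem, n_blk: int):
        self.problem = problem
        self.L1 = problem.L + 1
        self.n_xu = self.L1 * problem.N
        self.n_par = problem.n_free - self.n_xu
        self.N = problem.N

    def solve(self, Jc, Hc, extra_diag, inv_mu_row, g_tot):
        """Return the Newton step s (length n_free); raises LinAlgError if
        the primal block is not positive definite at this damping."""
        L1, n_xu, n_par, N = self.L1, self.n_xu, self.n_par, self.N
        # --- split H into point blocks / border / corner
        Hcoo = Hc.tocoo()
        r, c, v = Hcoo.row, Hcoo.col, Hcoo.data
        in_uu = (r < n_xu) & (c < n_xu)
        blocks = np.zeros((N, L1, L1))
        ru, cu = r[in_uu], c[in_uu]
        np.add.at(blocks, (ru // L1, ru % L1, cu % L1), v[in_uu])
        blocks[:, np.arange(L1), np.arange(L1)] += extra_diag[:n_xu].reshape(N, L1)
        in_up = (r < n_xu) & (c >= n_xu)
        H_up = np.zeros((n_xu, n_par))
        np.add.at(H_up, (r[in_up], c[in_up] - n_xu), v[in_up])
        in_pp = (r >= n_xu) & (c >= n_xu)
        H_pp = np.zeros((n_par, n_par))
        np.add.at(H_pp, (r[in_pp] - n_xu, c[in_pp] - n_xu), v[in_pp])
        H_pp[np.arange(n_par), np.arange(n_par)] += extra_diag[n_xu:]
        # --- batched inversion of the point blocks (PD required)
        chol = np.linalg.cholesky(blocks)  # raises LinAlgError when not PD
        eye = np.broadcast_to(np.eye(L1), (N, L1, L1))
        inv_blocks = np.linalg.solve(
            np.transpose(chol, (0, 2, 1)), np.linalg.solve(chol, eye)
        )
        Hinv = spa.bsr_matrix(
            (inv_blocks, np.arange(N), np.arange(N + 1)), shape=(n_xu, n_xu)
        ).tocsr()
        # --- constraint-space Schur complement (banded SPD)
        Jc_u = Jc[:, :n_xu]
        Jc_p = Jc[:, n_xu:].toarray()
        W = (Jc_u @ Hinv).tocsr()
        M = (W @ Jc_u.T).tocoo()
        n_c = Jc.shape[0]
        off = M.col - M.row
        upper = off >= 0
        bw = int(off[upper].max()) if np.any(upper) else 0
        ab = np.zeros((bw + 1, n_c))
        np.add.at(ab, (bw - off[upper], M.col[upper]), M.data[upper])
        ab[bw, :] += inv_mu_row
        cb = cholesky_banded(ab)
        # --- assemble right-hand sides
        g_u, g_p = g_tot[:n_xu], g_tot[n_xu:]
        hu = Hinv @ g_u
        a_vec = Jc_u @ hu
        Bc = Jc_p - W @ H_up
        b_p = -g_p + H_up.T @ hu
        X = cho_solve_banded((cb, False), np.column_stack([a_vec, Bc]))
        X_a, X_B = X[:, 0], X[:, 1:]
        Cpp = H_pp - H_up.T @ (Hinv @ H_up)
        S = Cpp + Bc.T @ X_B
        rhs_p = b_p + Bc.T @ X_a
        s_p = np.linalg.solve(S, rhs_p)
        w = X_B @ s_p - X_a
        s_u = -(hu + Hinv @ (H_up @ s_p) + Hinv @ (Jc_u.T @ w))
        return np.concatenate([s_u, s_p])


def ipx_minimize(
    problem,
    zeta0: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
    smu_row: np.ndarray,
    lam: np.ndarray,
    eta: float,
    max_iter: int = 60,
    gtol: float = 1e-9,
    ftol: float = 1e-12,
    xtol: float = 1e-12,
    lam0: float = 1e-5,
    lam_min: float = 1e-11,
    lam_max: float = 1e12,
    max_step: float = np.inf,
    barrier_mask: np.ndarray | None = None,
    verbose: int = 0,
) -> IPXResult:
    """Minimize the ALM subproblem with structured interior-point Newton steps.

    ``problem`` is an AssimilationProblem; ``smu_row`` the per-row penalty
    square roots; ``lam`` the current multipliers; ``eta`` the barrier
    weight.  The barrier acts only on ``barrier_mask`` variables (default:
    the model parameters) — state variables such as gate occupancies live
    legitimately hard against their box and must not feel a barrier force.
    Variables with lo == hi are held fixed.
    """
    Jd = problem.data_jacobian()
    data_h = np.asarray((Jd.T @ Jd).todia().diagonal(0)).ravel()
    mu_row = smu_row**2
    inv_mu = np.where(mu_row > 0, 1.0 / np.maximum(mu_row, 1e-300), 1e300)
    lam_over = np.where(smu_row > 0, lam / np.maximum(smu_row, 1e-300), 0.0)
    stepper = _StructuredStep(problem, problem.L + 1)

    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    width = hi - lo
    fixed = width <= 0
    if barrier_mask is None:
        barrier_mask = np.zeros_like(fixed)
        barrier_mask[(problem.L + 1) * problem.N :] = True
    free = ~fixed & np.asarray(barrier_mask, dtype=bool)
    margin = 1e-4 * np.where(free, width, 1.0)
    x = np.clip(zeta0, lo + np.where(free, margin, 0.0), hi - np.where(free, margin, 0.0))
    x[fixed] = lo[fixed]

    def full_z(xx):
        full = np.zeros(problem.n_z)
        full[problem.solver_cols] = xx
        return problem.z_off + full * problem.z_scale

    def residuals(xx):
        z = full_z(xx)
        rd = problem.data_residuals(z)
        c = problem.constraint_values(z)
        return z, rd, c, np.concatenate([rd, smu_row * c + lam_over])

    def barrier_val(xx):
        a = np.maximum(xx[free] - lo[free], 1e-300)
        b = np.maximum(hi[free] - xx[free], 1e-300)
        return -float(np.sum(np.log(a)) + np.sum(np.log(b)))

    z, rd, c, r = residuals(x)
    cost = 0.5 * float(r @ r)
    phi = cost + eta * barrier_val(x)
    nfev = njev = 0
    tr = lam0
    status, msg = 0, "max iterations reached"
    g_true = np.zeros_like(x)
    for it in range(max_iter):
        Jc = problem.constraint_jacobian(z)
        njev += 1
        y = mu_row * c + lam  # constraint weights in the Lagrangian Hessian
        Hc = problem.constraint_hessian(z, y)
        g_true = Jd.T @ rd + Jc.T @ y
        a = np.where(free, x - lo, 1.0)
        b = np.where(free, hi - x, 1.0)
        bgrad = np.where(free, -1.0 / a + 1.0 / b, 0.0)
        bdiag = np.where(free, 1.0 / a**2 + 1.0 / b**2, 0.0)
        g_tot = g_true + eta * bgrad
        gp = g_true.copy()
        tol_b = 1e-10 * np.maximum(1.0, width)
        gp[(x <= lo + tol_b) & (gp > 0)] = 0.0
        gp[(x >= hi - tol_b) & (gp < 0)] = 0.0
        gp[fixed] = 0.0
        if float(np.max(np.abs(gp)) if len(gp) else 0.0) <= gtol:
            status, msg = 1, "projected gradient below gtol"
            break
        # diagonal scale for trust damping
        d_ref = np.asarray(abs(Hc).sum(axis=1)).ravel() + data_h + 1.0
        accepted = False
        for _ in range(30):
            extra = tr * d_ref + eta * bdiag + np.where(fixed, 1e16, 0.0) + data_h
            try:
                step = stepper.solve(Jc, Hc, extra, inv_mu, g_tot)
            except (LinAlgError, np.linalg.LinAlgError):
                tr = max(tr, 1e-8) * 10.0
                if tr > lam_max:
                    break
                continue
            step[fixed] = 0.0
            snorm = float(np.max(np.abs(step))) if len(step) else 0.0
            if snorm > max_step:
                step = step * (max_step / snorm)
            # fraction-to-boundary only for barrier variables (parameters);
            # state/control variables are simply projected into the box
            with np.errstate(divide="ignore", invalid="ignore"):
                alpha_lo = np.where(free & (step < 0), (lo - x) / step, np.inf)
                alpha_hi = np.where(free & (step > 0), (hi - x) / step, np.inf)
            alpha = min(1.0, 0.995 * float(np.min(np.minimum(alpha_lo, alpha_hi))))
            x_new = np.clip(x + alpha * step, lo, hi)
            x_new[fixed] = lo[fixed]
            s = x_new - x
            z_new, rd_new, c_new, r_new = residuals(x_new)
            nfev += 1
            cost_new = 0.5 * float(r_new @ r_new)
            phi_new = cost_new + eta * barrier_val(x_new)
            # model decrease of the Newton quadratic
            Jcs = Jc @ s
            quad = (
                float(s @ (Hc @ s))
                + float((data_h + eta * bdiag + tr * d_ref) @ (s * s))
                + float(mu_row @ (Jcs * Jcs))
            )
            pred = -float(g_tot @ s) - 0.5 * quad
            rho = (phi - phi_new) / pred if pred > 0 else -1.0
            if phi_new < phi and (rho > 1e-4 or phi_new < phi * (1 - 1e-12)):
                if rho > 0.9:
                    tr = max(tr * 0.1, lam_min)
                elif rho > 0.75:
                    tr = max(tr / 3.0, lam_min)
                elif rho < 0.25:
                    tr = min(tr * 2.0, lam_max)
                step_norm = float(np.max(np.abs(s) / np.maximum(1.0, np.abs(x))))
                dphi = phi - phi_new
                x, z, rd, c, r = x_new, z_new, rd_new, c_new, r_new
                cost, phi = cost_new, phi_new
                accepted = True
                if verbose > 1:
                    print(
                        f"    ipx it={it} phi={phi:.6e} tr={tr:.1e} "
                        f"rho={rho:.2f} alpha={alpha:.2f}"
                    )
                if dphi <= ftol * max(1.0, abs(phi)):
                    status, msg = 2, "merit decrease below ftol"
                if step_norm <= xtol:
                    status, msg = 3, "step below xtol"
                break
            tr = min(max(tr, 1e-10) * 5.0, lam_max)
            if tr >= lam_max:
                break
        if not accepted:
            status, msg = 3, "no acceptable step (trust region collapsed)"
            break
        if status in (2, 3):
            break
    gp = g_true.copy()
    tol_b = 1e-10 * np.maximum(1.0, width)
    gp[(x <= lo + tol_b) & (gp > 0)] = 0.0
    gp[(x >= hi - tol_b) & (gp < 0)] = 0.0
    gp[fixed] = 0.0
    return IPXResult(
        x=x,
        cost=cost,
        optimality=float(np.max(np.abs(gp)) if len(gp) else 0.0),
        nfev=nfev,
        njev=njev,
        status=status,
        message=msg,
    )
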