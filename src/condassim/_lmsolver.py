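"""Bound-constrained sparse Levenberg-Marquardt with direct normal-equation solves.

Inner solver for the augmented-Lagrangian loop.  Each iteration factorizes
the damped normal matrix J^T J + lam * D (SuperLU) — the collocation
Jacobian is block-banded in time with a narrow dense parameter border, so
the factorization is cheap and the steps are far stronger than truncated
iterative solves.  Simple bounds are handled by an active-set rule: at a
bound, coordinates whose negative gradient points outward are frozen for
the step (large diagonal penalty), and trial points are projected back into
the box.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as spa
from scipy.linalg import LinAlgError, cho_solve_banded, cholesky_banded
from scipy.sparse.linalg import splu

__all__ = ["LMResult", "lm_bounded", "banded_border_solver"]


def banded_border_solver(n_band: int):
    """Normal-equation solver for banded-plus-dense-border structure.

    The leading ``n_band`` variables (states and control, point-major) have a
    banded coupling graph; the trailing variables (model parameters) couple
    densely to everything.  Solves via banded Cholesky of the leading block
    and a Schur complement on the border.  Raises ``LinAlgError`` when the
    damped matrix is not positive definite (caller increases damping).
    """

    def solve(JtJ: spa.spmatrix, diag_add: np.ndarray, rhs: np.ndarray) -> np.ndarray:
        A = (JtJ + spa.diags(diag_add)).tocsr()
        n = A.shape[0]
        B = A[:n_band, :n_band].tocoo()
        off = B.col - B.row
        upper = off >= 0
        u = int(off[upper].max()) if np.any(upper) else 0
        ab = np.zeros((u + 1, n_band))
        ab[u - off[upper], B.col[upper]] = B.data[upper]
        cb = cholesky_banded(ab)  # raises LinAlgError if not PD
        rhs1, rhs2 = rhs[:n_band], rhs[n_band:]
        if n == n_band:
            return cho_solve_banded((cb, False), rhs1)
        C = A[:n_band, n_band:].toarray()
        P = A[n_band:, n_band:].toarray()
        Y = cho_solve_banded((cb, False), np.column_stack([rhs1, C]))
        y0, BiC = Y[:, 0], Y[:, 1:]
        S = P - C.T @ BiC
        x2 = np.linalg.solve(S, rhs2 - C.T @ y0)
        x1 = y0 - BiC @ x2
        return np.concatenate([x1, x2])

    return solve


def _splu_solver(JtJ: spa.spmatrix, diag_add: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    A = (JtJ + spa.diags(diag_add)).tocsc()
    return splu(A).solve(rhs)


@dataclass
class LMResult:
    x: np.ndarray
    cost: float
    optimality: float  # projected gradient, infinity norm
    nfev: int
    njev: int
    status: int  # 1 gtol, 2 ftol, 3 xtol, 0 max iterations
    message: str


def _projected_grad(g: np.ndarray, x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    tol = 1e-10 * np.maximum(1.0, hi - lo)
    g = np.where((x <= lo + tol) & (g > 0), 0.0, g)
    g = np.where((x >= hi - tol) & (g < 0), 0.0, g)
    return g


def lm_bounded(
    fun,
    jac,
    x0: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
    max_iter: int = 100,
    gtol: float = 1e-8,
    ftol: float = 1e-12,
    xtol: float = 1e-12,
    lam0: float = 1e-5,
    lam_min: float = 1e-11,
    lam_max: float = 1e12,
    max_step: float = np.inf,
    solve_normal=None,
    hess=None,
    verbose: int = 0,
) -> LMResult:
    """Minimize 1/2 ||fun(x)||^2 subject to lo <= x <= hi.

    ``jac`` returns a scipy sparse matrix.  ``solve_normal(JtJ, diag_add,
    rhs)`` solves the damped normal equations (default: SuperLU).  When
    ``hess(x, r)`` is given it returns the residual-weighted second-order
    term sum_i r_i * Hess r_i, upgrading the Gauss-Newton model to a damped
    Newton model (the trust region copes with indefiniteness).
    Deterministic.
    """
    if solve_normal is None:
        solve_normal = _splu_solver
    x = np.clip(np.asarray(x0, dtype=float), lo, hi)
    r = fun(x)
    cost = 0.5 * float(r @ r)
    nfev, njev = 1, 0
    lam = lam0
    status, msg = 0, "max iterations reached"
    J = None
    for it in range(max_iter):
        J = jac(x)
        njev += 1
        g = J.T @ r
        gp = _projected_grad(g, x, lo, hi)
        gnorm = float(np.max(np.abs(gp))) if len(gp) else 0.0
        if gnorm <= gtol:
            status, msg = 1, "projected gradient below gtol"
            break
        JtJ = (J.T @ J).tocsc()
        if hess is not None:
            JtJ = (JtJ + hess(x, r)).tocsc()
        d = JtJ.diagonal()
        d = np.maximum(np.abs(d), 1e-12 * max(1.0, np.abs(d).max()))
        # freeze outward-pointing coordinates at active bounds
        tol_b = 1e-10 * np.maximum(1.0, hi - lo)
        frozen = ((x <= lo + tol_b) & (g > 0)) | ((x >= hi - tol_b) & (g < 0))
        accepted = False
        for _ in range(25):
            diag_add = lam * d + np.where(frozen, 1e12 * d, 0.0)
            try:
                step = solve_normal(JtJ, diag_add, -g)
            except (RuntimeError, LinAlgError):
                lam = min(lam * 10.0, lam_max)
                continue
            # cap the step length: unchecked moves along near-flat (sloppy)
            # directions would otherwise fly to the bounds and stick there
            snorm = float(np.max(np.abs(step)))
            if snorm > max_step:
                step = step * (max_step / snorm)
            x_new = np.clip(x + step, lo, hi)
            s = x_new - x
            r_new = fun(x_new)
            nfev += 1
            cost_new = 0.5 * float(r_new @ r_new)
            pred = -float(g @ s) - 0.5 * float(s @ (JtJ @ s))
            rho = (cost - cost_new) / pred if pred > 0 else -1.0
            if cost_new < cost and (rho > 1e-4 or cost_new < cost * (1 - 1e-12)):
                # accept
                if rho > 0.9:
                    lam = max(lam * 0.1, lam_min)
                elif rho > 0.75:
                    lam = max(lam / 3.0, lam_min)
                elif rho < 0.25:
                    lam = min(lam * 2.0, lam_max)
                step_norm = float(np.max(np.abs(s) / np.maximum(1.0, np.abs(x))))
                df = cost - cost_new
                x, r, cost_prev, cost = x_new, r_new, cost, cost_new
                accepted = True
                if verbose > 1:
                    print(f"    lm it={it} cost={cost:.6e} lam={lam:.1e} rho={rho:.2f}")
                if df <= ftol * max(1.0, cost):
                    status, msg = 2, "cost decrease below ftol"
                if step_norm <= xtol:
                    status, msg = 3, "step below xtol"
                break
            lam = min(lam * 5.0, lam_max)
            if lam >= lam_max:
                break
        if not accepted:
            status, msg = 3, "no acceptable step (trust region collapsed)"
            break
        if status in (2, 3):
            break
    g = J.T @ r if J is not None else np.zeros_like(x)
    gp = _projected_grad(g, x, lo, hi)
    return LMResult(
        x=x,
        cost=cost,
        optimality=float(np.max(np.abs(gp))) if len(gp) else 0.0,
        nfev=nfev,
        njev=njev,
        status=status,
        message=msg,
    )


def lm_interior(
    fun,
    jac,
    x0: np.ndarray,
    lo: np.ndarray,
    hi: np.ndarray,
    eta: float,
    max_iter: int = 60,
    gtol: float = 1e-9,
    ftol: float = 1e-12,
    xtol: float = 1e-12,
    lam0: float = 1e-5,
    lam_min: float = 1e-11,
    lam_max: float = 1e12,
    max_step: float = np.inf,
    solve_normal=None,
    hess=None,
    verbose: int = 0,
) -> LMResult:
    """Interior-point damped-Newton least squares: min 1/2||fun||^2 - eta*log barriers.

    Iterates stay strictly inside the box (fraction-to-boundary rule), so
    sloppy directions cannot pin variables at their bounds mid-run — the
    pathology of projection-type methods on ill-conditioned problems.
    Variables with ``lo == hi`` are held fixed.  ``eta`` is the barrier
    weight; the caller anneals it across outer iterations.
    """
    if solve_normal is None:
        solve_normal = _splu_solver
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    width = hi - lo
    fixed = width <= 0
    free = ~fixed
    margin = 1e-4 * np.where(free, width, 1.0)
    x = np.clip(np.asarray(x0, dtype=float), lo + np.where(free, margin, 0.0),
                hi - np.where(free, margin, 0.0))
    x[fixed] = lo[fixed]

    def barrier_val(xx):
        a = xx[free] - lo[free]
        b = hi[free] - xx[free]
        return -float(np.sum(np.log(a)) + np.sum(np.log(b)))

    r = fun(x)
    cost = 0.5 * float(r @ r)
    phi = cost + eta * barrier_val(x)
    nfev, njev = 1, 0
    lam = lam0
    status, msg = 0, "max iterations reached"
    J = None
    g_true = np.zeros_like(x)
    for it in range(max_iter):
        J = jac(x)
        njev += 1
        g_true = J.T @ r
        H = (J.T @ J).tocsc()
        if hess is not None:
            H = (H + hess(x, r)).tocsc()
        a = np.where(free, x - lo, 1.0)
        b = np.where(free, hi - x, 1.0)
        bgrad = np.where(free, -1.0 / a + 1.0 / b, 0.0)
        bdiag = np.where(free, 1.0 / a**2 + 1.0 / b**2, 0.0)
        g_tot = g_true + eta * bgrad
        gp = _projected_grad(g_true, x, lo, hi)
        if float(np.max(np.abs(gp)) if len(gp) else 0.0) <= gtol:
            status, msg = 1, "projected gradient below gtol"
            break
        d = np.maximum(np.abs(H.diagonal()), 1e-12)
        accepted = False
        for _ in range(30):
            diag_add = lam * d + eta * bdiag + np.where(fixed, 1e14 * np.maximum(d, 1.0), 0.0)
            try:
                step = solve_normal(H, diag_add, -g_tot)
            except (RuntimeError, LinAlgError):
                lam = max(lam, 1e-8)
                lam = min(lam * 10.0, lam_max)
                continue
            step[fixed] = 0.0
            snorm = float(np.max(np.abs(step))) if len(step) else 0.0
            if snorm > max_step:
                step = step * (max_step / snorm)
            # fraction-to-boundary
            with np.errstate(divide="ignore", invalid="ignore"):
                alpha_lo = np.where(step < 0, (lo - x) / step, np.inf)
                alpha_hi = np.where(step > 0, (hi - x) / step, np.inf)
            alpha = min(1.0, 0.995 * float(np.min(np.minimum(alpha_lo, alpha_hi))))
            s = alpha * step
            x_new = x + s
            r_new = fun(x_new)
            nfev += 1
            cost_new = 0.5 * float(r_new @ r_new)
            phi_new = cost_new + eta * barrier_val(x_new)
            Hd = H @ s
            pred = -float(g_tot @ s) - 0.5 * float(s @ Hd) - 0.5 * eta * float(
                s @ (bdiag * s)
            )
            rho = (phi - phi_new) / pred if pred > 0 else -1.0
            if phi_new < phi and (rho > 1e-4 or phi_new < phi * (1 - 1e-12)):
                if rho > 0.9:
                    lam = max(lam * 0.1, lam_min)
                elif rho > 0.75:
                    lam = max(lam / 3.0, lam_min)
                elif rho < 0.25:
                    lam = min(lam * 2.0, lam_max)
                step_norm = float(np.max(np.abs(s) / np.maximum(1.0, np.abs(x))))
                dphi = phi - phi_new
                x, r, cost, phi = x_new, r_new, cost_new, phi_new
                accepted = True
                if verbose > 1:
                    print(f"    ip it={it} phi={phi:.6e} cost={cost:.6e} lam={lam:.1e} rho={rho:.2f} alpha={alpha:.2f}")
                if dphi <= ftol * max(1.0, abs(phi)):
                    status, msg = 2, "merit decrease below ftol"
                if step_norm <= xtol:
                    status, msg = 3, "step below xtol"
                break
            lam = min(lam * 5.0, lam_max)
            if lam >= lam_max:
                break
        if not accepted:
            status, msg = 3, "no acceptable step (trust region collapsed)"
            break
        if status in (2, 3):
            break
    gp = _projected_grad(g_true, x, lo, hi)
    return LMResult(
        x=x,
        cost=cost,
        optimality=float(np.max(np.abs(gp))) if len(gp) else 0.0,
        nfev=nfev,
        njev=njev,
        status=status,
        message=msg,
    )
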