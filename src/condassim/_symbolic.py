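"""Symbolic construction of the model right-hand side and its exact derivatives.

The collocation transcription and the sensitivity machinery need
machine-precision first (and optionally second) derivatives of the vector
field F(x, u, p) with respect to the local variables (states + nudging
control) and the parameters.  These are generated once per model with sympy
and compiled to vectorized numpy callables (common-subexpression
elimination keeps evaluation cheap); results are cached per model instance.

The GHK calcium flux enters through its degree-25 Horner polynomial
surrogate so that the expression tree stays polynomial-smooth in V.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import sympy as sp

from .model import ModelSpec

__all__ = ["CompiledRhs", "compiled_rhs"]


def _horner_expr(coeffs: np.ndarray, s: sp.Expr) -> sp.Expr:
    """Nested Horner evaluation of ascending power coefficients at s."""
    acc: sp.Expr = sp.Float(coeffs[-1])
    for c in coeffs[-2::-1]:
        acc = acc * s + sp.Float(c)
    return acc


def build_rhs_exprs(model: ModelSpec, assimilation: bool):
    """Return (state_syms, u, vexp, iinj, param_syms, F_exprs)."""
    xs = sp.symbols([f"x{i}" for i in range(model.n_states)], real=True)
    u, vexp, iinj = sp.symbols("u vexp iinj", real=True)
    psyms = {name: sp.Symbol(f"p_{name}", real=True) for name in model.param_names}
    V = xs[0]
    gates = {g: xs[i + 1] for i, g in enumerate(model.gates)}
    J: sp.Expr = sp.Integer(0)
    for ch in model.channels:
        if ch.is_ghk:
            h = model.ghk_horner()
            lo, hi = h.v_range
            s = (2 * V - (lo + hi)) / (hi - lo)
            factor = _horner_expr(h.coeffs, s)
            names = [g for g, pw in ch.gate_powers.items() if pw]
            act = gates[names[0]]
            inact = gates[names[1]] if len(names) > 1 else sp.Integer(1)
            J = J - psyms[ch.conductance] * sp.Float(1e-4) * act**2 * inact * factor
        else:
            term = psyms[ch.conductance] * (psyms[ch.reversal] - V)
            for gname, pw in ch.gate_powers.items():
                if pw:
                    term *= gates[gname] ** pw
            J = J + term
    dV = (J + sp.Float(0.01) * iinj / psyms["A"]) / psyms["C"]
    if assimilation:
        dV = dV + u * (vexp - V)
    F = [dV]
    for g in model.gates:
        xg = gates[g]
        arg_inf = (V - psyms[f"V_{g}"]) / psyms[f"dV_{g}"]
        arg_tau = (V - psyms[f"V_{g}"]) / psyms[f"dV_tau_{g}"]
        x_inf = (1 + sp.tanh(arg_inf)) / 2
        tau = psyms[f"t_{g}"] + psyms[f"eps_{g}"] * (1 - sp.tanh(arg_tau) ** 2)
        F.append((x_inf - xg) / tau)
    return xs, u, vexp, iinj, psyms, F


def _broadcast(vals, n: int) -> list[np.ndarray]:
    out = []
    for v in vals:
        a = np.asarray(v, dtype=float)
        if a.ndim == 0:
            a = np.full(n, float(a))
        out.append(a)
    return out


@dataclass
class _HessFuncs:
    entries: list[tuple[int, int]]  # (a, b) with a <= b, in local+param indexing
    fun: object  # lambdified callable


class CompiledRhs:
    """Vectorized F and sparse dF for one model, in one mode.

    Local variable ordering: states (L) then the control u (assimilation
    mode only), giving ``n_local = L + 1`` (or L in prediction mode).
    Column indices in the derivative patterns run over
    ``[locals..., params...]`` with params in the model's canonical order.
    """

    def __init__(self, model: ModelSpec, assimilation: bool = True):
        self.model = model
        self.assimilation = assimilation
        xs, u, vexp, iinj, psyms, F = build_rhs_exprs(model, assimilation)
        L = model.n_states
        self.n_local = L + 1 if assimilation else L
        self.n_params = model.n_params
        local_syms = list(xs) + ([u] if assimilation else [])
        wsyms = local_syms + [psyms[name] for name in model.param_names]
        self._wsyms = wsyms
        self._data_syms = [vexp, iinj] if assimilation else [iinj]
        # sparse first-derivative pattern
        jac_entries: list[tuple[int, int]] = []
        jac_exprs: list[sp.Expr] = []
        for l, f in enumerate(F):
            free = f.free_symbols
            for j, wsym in enumerate(wsyms):
                if wsym in free:
                    d = sp.diff(f, wsym)
                    if d != 0:
                        jac_entries.append((l, j))
                        jac_exprs.append(d)
        self.jac_entries = jac_entries
        args = list(xs) + ([u] if assimilation else []) + self._data_syms + [
            psyms[name] for name in model.param_names
        ]
        self._args = args
        self._fun = sp.lambdify(args, list(F) + jac_exprs, modules="numpy", cse=True)
        self._F_exprs = F
        self._psyms = psyms
        self._xs = xs
        self._u_sym = u if assimilation else None
        self._hess: _HessFuncs | None = None

    # -- evaluation -------------------------------------------------------
    def _call_args(self, X: np.ndarray, U, Vexp, Iinj, pvec: np.ndarray):
        cols = [X[:, i] for i in range(self.model.n_states)]
        if self.assimilation:
            cols.append(np.asarray(U, dtype=float))
            cols.append(np.asarray(Vexp, dtype=float))
        cols.append(np.asarray(Iinj, dtype=float))
        cols.extend(float(v) for v in pvec)
        return cols

    def rhs_and_jac(self, X: np.ndarray, U, Vexp, Iinj, pvec: np.ndarray):
        """Evaluate F (n, L) and the nonzero dF entries (list of (n,) arrays)."""
        n = X.shape[0]
        vals = _broadcast(self._fun(*self._call_args(X, U, Vexp, Iinj, pvec)), n)
        L = self.model.n_states
        F = np.column_stack(vals[:L])
        return F, vals[L:]

    def rhs(self, X: np.ndarray, U, Vexp, Iinj, pvec: np.ndarray) -> np.ndarray:
        return self.rhs_and_jac(X, U, Vexp, Iinj, pvec)[0]

    # -- multiplier-weighted second derivatives ---------------------------
    def _build_hess(self) -> _HessFuncs:
        L = self.model.n_states
        lams = sp.symbols(" ".join(f"lam{l}" for l in range(L)), real=True)
        if L == 1:
            lams = (lams,)
        g = sum(lams[l] * self._F_exprs[l] for l in range(L))
        entries: list[tuple[int, int]] = []
        exprs: list[sp.Expr] = []
        firsts = {}
        for a, wa in enumerate(self._wsyms):
            if wa in g.free_symbols:
                firsts[a] = sp.diff(g, wa)
        for a in sorted(firsts):
            da = firsts[a]
            for b, wb in enumerate(self._wsyms):
                if b < a or wb not in da.free_symbols:
                    continue
                d2 = sp.diff(da, wb)
                if d2 != 0:
                    entries.append((a, b))
                    exprs.append(d2)
        fun = sp.lambdify(list(self._args) + list(lams), exprs, modules="numpy", cse=True)
        return _HessFuncs(entries=entries, fun=fun)

    def weighted_hess(self, X, U, Vexp, Iinj, pvec, gamma: np.ndarray):
        """Entries of Hess_w(sum_l gamma[:, l] * F_l) per point.

        ``gamma`` has shape (n, L).  Returns (entries, values) where values
        is a list of (n,) arrays aligned with the (a, b) upper-triangle
        entry list.
        """
        if self._hess is None:
            self._hess = self._build_hess()
        n = X.shape[0]
        args = self._call_args(X, U, Vexp, Iinj, pvec)
        args += [gamma[:, l] for l in range(self.model.n_states)]
        vals = _broadcast(self._hess.fun(*args), n)
        return self._hess.entries, vals


_CACHE: dict[tuple[int, bool], CompiledRhs] = {}


def compiled_rhs(model: ModelSpec, assimilation: bool = True) -> CompiledRhs:
    """Cached compiled RHS/derivatives for a model."""
    key = (id(model), assimilation)
    if key not in _CACHE:
        _CACHE[key] = CompiledRhs(model, assimilation)
    return _CACHE[key]
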