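"""Twin-experiment data synthesis: protocols, forward integration, noise, meshes.

A twin experiment generates "observations" from a model with known
parameters, then tests whether the estimator recovers them.  The clean trace
V_use is obtained by stiff forward integration (LSODA) of the conductance
model on a uniform base grid (100 kHz by default); the "experimental" trace
adds seed-controlled i.i.d. Gaussian noise, V_exp = V_use + sigma * eta_zeta.
A negative sigma flips the sign of the same realization, which is the
convention used by the noise-ramp regularizer.

The adaptive mesh thins sub-threshold stretches of the trace by an integer
multiplier m while keeping full resolution around action potentials, and
regroups the retained samples into the 5-point groups consumed by the
collocation transcription.
"""

from __future__ import annotations

import json
import pathlib
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .errors import IntegrationError, InvalidParameterError
from .model import ModelSpec, ParameterSet, gate_steady_state, membrane_rhs

__all__ = [
    "CurrentProtocol",
    "TwinDataset",
    "MeshPlan",
    "build_step_protocol",
    "default_protocol",
    "integrate_forward",
    "settle_initial_state",
    "sample_noise",
    "make_twin_dataset",
    "adaptive_mesh",
    "uniform_mesh",
]


@dataclass(frozen=True)
class CurrentProtocol:
    """Piecewise-constant current injection: ordered (duration ms, amplitude pA) steps."""

    steps: tuple[tuple[float, float], ...]

    @property
    def total_duration(self) -> float:
        return float(sum(d for d, _ in self.steps))

    @property
    def edges(self) -> np.ndarray:
        return np.concatenate([[0.0], np.cumsum([d for d, _ in self.steps])])

    def amplitude_at(self, t):
        """Current amplitude (pA) at time(s) t; intervals are left-closed."""
        t = np.asarray(t, dtype=float)
        amps = np.array([a for _, a in self.steps])
        idx = np.clip(np.searchsorted(self.edges, t, side="right") - 1, 0, len(amps) - 1)
        out = amps[idx]
        return float(out) if out.ndim == 0 else out

    def to_jsonable(self) -> list[list[float]]:
        return [[d, a] for d, a in self.steps]


def build_step_protocol(spec: Sequence[tuple[float, float]]) -> CurrentProtocol:
    """Build a piecewise-constant protocol from (duration ms, amplitude pA) pairs."""
    if not spec:
        raise InvalidParameterError("protocol spec must be nonempty")
    for d, _ in spec:
        if not d > 0:
            raise InvalidParameterError("step durations must be positive")
    return CurrentProtocol(tuple((float(d), float(a)) for d, a in spec))


# Versioned default protocol fixtures.  Amplitudes are calibrated for the
# RVLM model: >~1.5 nA depolarizing steps elicit spikes, ~-3 nA steps
# hyperpolarize into the HCN/CaT recovery range, and the mixed durations
# (10-30 ms) probe gate kinetics from sub-millisecond to tens of ms.
# All durations are multiples of 10 ms so that protocol edges coincide with
# collocation group boundaries for mesh steps whose 4*dt span divides 10 ms
# (e.g. 20 and 50 us).
_PROTOCOLS = {
    "mixed_steps_200ms_v1": (
        (10, 0), (20, 3000), (10, 0), (10, 1200), (30, -3000), (20, 0),
        (10, 4000), (10, -1500), (10, 2000), (20, 500), (20, -4000), (30, 1800),
    ),
    # the same structure stretched with longer steps (slow-kinetics probing)
    "mixed_steps_500ms_v1": (
        (20, 0), (40, 3000), (20, 0), (30, 1200), (80, -3000), (40, 0),
        (30, 4000), (40, -1500), (30, 2000), (40, 500), (80, -4000), (50, 1800),
    ),
    # sparse depolarizations separated by long sub-threshold stretches: the
    # regime where adaptive sub-threshold thinning buys window duration
    "sparse_bursts_500ms_v1": (
        (20, 0), (10, 3000), (50, 0), (30, -2000), (10, 2800), (60, 0),
        (40, -3500), (10, 3000), (60, 0), (20, -1500), (10, 2800), (60, 0),
        (40, -3000), (10, 3000), (120, 0),
    ),
    # hold-out protocol for prediction experiments (never used in training)
    "holdout_200ms_v1": (
        (10, 0), (20, 2500), (10, -2000), (20, 3500), (20, 0), (30, -3500),
        (10, 1500), (20, 4500), (20, -1000), (40, 2000),
    ),
    # a deliberately poor, simple protocol (long plain rectangles)
    "simple_steps_200ms_v1": ((50, 0), (100, 3000), (50, 0)),
}


def default_protocol(name: str = "mixed_steps_200ms_v1") -> CurrentProtocol:
    """Return a versioned default protocol fixture by name."""
    try:
        return build_step_protocol(_PROTOCOLS[name])
    except KeyError:
        raise InvalidParameterError(
            f"unknown protocol {name!r}; available: {sorted(_PROTOCOLS)}"
        ) from None


def settle_initial_state(
    model: ModelSpec,
    params,
    I_hold: float = 0.0,
    V_guess: float = -65.0,
    t_settle: float = 500.0,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> np.ndarray:
    """Relax the model to its (possibly oscillating) steady state at holding current.

    Starting from V_guess with gates at steady state, integrates for
    ``t_settle`` ms and returns the final state.  Deterministic.
    """
    x0 = np.array(
        [V_guess]
        + [float(gate_steady_state(V_guess, model.gate_params(params, g))) for g in model.gates]
    )
    sol = solve_ivp(
        lambda t, x: membrane_rhs(x, model, params, I_hold),
        (0.0, t_settle),
        x0,
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"settling integration failed: {sol.message}")
    return sol.y[:, -1]


def integrate_forward(
    model: ModelSpec,
    params,
    x0: np.ndarray,
    protocol: CurrentProtocol,
    t_grid: np.ndarray,
    rtol: float = 1e-10,
    atol: float = 1e-12,
    u_trace=None,
    V_exp_trace=None,
) -> np.ndarray:
    """Integrate the model ODE over a step protocol; sample states on t_grid.

    Integration proceeds segment-by-segment between protocol edges with the
    stiff-capable LSODA solver so that current discontinuities never cross an
    integrator step.  Returns an array of shape (len(t_grid), L).  Integrator
    failures and non-finite output raise :class:`IntegrationError`.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    T = protocol.total_duration
    if t_grid[0] < -1e-12 or t_grid[-1] > T + 1e-9:
        raise InvalidParameterError("t_grid must lie within the protocol duration")
    if u_trace is not None or V_exp_trace is not None:
        raise InvalidParameterError(
            "forward integration is nudging-free; u/V_exp are not accepted"
        )
    edges = protocol.edges
    out = np.empty((len(t_grid), model.n_states))
    x = np.asarray(x0, dtype=float).copy()
    for j, (_, amp) in enumerate(protocol.steps):
        a, b = edges[j], edges[j + 1]
        sel = (t_grid >= a - 1e-12) & (t_grid <= b + 1e-12)
        sol = solve_ivp(
            lambda t, xx: membrane_rhs(xx, model, params, amp),
            (a, b),
            x,
            method="LSODA",
            rtol=rtol,
            atol=atol,
            dense_output=True,
        )
        if not sol.success:
            raise IntegrationError(
                f"LSODA failed on segment [{a}, {b}] ms: {sol.message}"
            )
        if np.any(sel):
            out[sel] = sol.sol(t_grid[sel]).T
        x = sol.y[:, -1]
    if not np.all(np.isfinite(out)):
        raise IntegrationError("forward integration produced non-finite states")
    return out


def sample_noise(sigma: float, zeta: int, n_samples: int) -> np.ndarray:
    """Seed-controlled additive noise: eps_i = sigma * eta_i, eta ~ N(0,1).

    The unit realization eta is fully determined by the seed ``zeta``
    (Philox counter-based generator, versioned as the package's RNG), so
    ``sample_noise(-s, z, n) == -sample_noise(s, z, n)`` exactly.
    """
    if n_samples <= 0:
        raise InvalidParameterError("n_samples must be positive")
    eta = np.random.Generator(np.random.Philox(key=int(zeta))).standard_normal(n_samples)
    return float(sigma) * eta


@dataclass(frozen=True)
class TwinDataset:
    """One synthetic recording: protocol, clean and noisy voltage, provenance.

    ``t`` are the sample times (ms) on the uniform base grid, ``V_use`` the
    clean voltage, ``V_exp = V_use + sigma*eta_zeta`` the noisy observation.
    ``states_use`` optionally carries the full clean state trajectory.
    """

    t: np.ndarray
    I_inj: np.ndarray
    V_use: np.ndarray
    V_exp: np.ndarray
    sigma: float
    zeta: int
    dt_base: float
    protocol: CurrentProtocol
    states_use: np.ndarray | None = None
    x0: np.ndarray | None = None

    @property
    def n_samples(self) -> int:
        return len(self.t)

    def with_noise(self, sigma: float, zeta: int | None = None) -> "TwinDataset":
        """Same clean trace, different noise amplitude and/or realization."""
        z = self.zeta if zeta is None else int(zeta)
        eps = sample_noise(sigma, z, self.n_samples) if sigma != 0.0 else 0.0
        return replace(self, V_exp=self.V_use + eps, sigma=float(sigma), zeta=z)

    # ---- serialization (CSV + JSON sidecar) ----
    def to_csv(self, path) -> None:
        path = pathlib.Path(path)
        header = "time_ms,I_inj_pA,V_use_mV,V_exp_mV"
        np.savetxt(
            path,
            np.column_stack([self.t, self.I_inj, self.V_use, self.V_exp]),
            delimiter=",",
            header=header,
            comments="",
            fmt="%.17g",
        )
        side = {
            "sigma": self.sigma,
            "zeta": self.zeta,
            "dt_base": self.dt_base,
            "protocol": self.protocol.to_jsonable(),
            "x0": None if self.x0 is None else list(self.x0),
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(side, indent=1))

    @classmethod
    def from_csv(cls, path) -> "TwinDataset":
        path = pathlib.Path(path)
        arr = np.loadtxt(path, delimiter=",", skiprows=1)
        side = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(
            t=arr[:, 0],
            I_inj=arr[:, 1],
            V_use=arr[:, 2],
            V_exp=arr[:, 3],
            sigma=float(side["sigma"]),
            zeta=int(side["zeta"]),
            dt_base=float(side["dt_base"]),
            protocol=build_step_protocol(side["protocol"]),
            x0=None if side.get("x0") is None else np.array(side["x0"]),
        )


def make_twin_dataset(
    model: ModelSpec,
    p_true,
    protocol: CurrentProtocol,
    sigma: float = 0.0,
    zeta: int = 0,
    dt_base: float = 0.01,
    T: float | None = None,
    rtol: float = 1e-10,
    atol: float = 1e-12,
    keep_states: bool = True,
) -> TwinDataset:
    """Synthesize a twin dataset on the uniform base grid (default 100 kHz).

    The initial state is the deterministic settled state at the protocol's
    first amplitude.  ``T`` truncates the window (defaults to the protocol
    duration); the number of intervals n = T/dt_base.
    """
    T = protocol.total_duration if T is None else float(T)
    n = int(round(T / dt_base))
    t = np.arange(n + 1) * dt_base
    x0 = settle_initial_state(model, p_true, I_hold=protocol.steps[0][1])
    states = integrate_forward(model, p_true, x0, protocol, t, rtol=rtol, atol=atol)
    V_use = states[:, 0]
    eps = sample_noise(sigma, zeta, n + 1) if sigma != 0.0 else np.zeros(n + 1)
    return TwinDataset(
        t=t,
        I_inj=np.asarray(protocol.amplitude_at(t), dtype=float),
        V_use=V_use,
        V_exp=V_use + eps,
        sigma=float(sigma),
        zeta=int(zeta),
        dt_base=float(dt_base),
        protocol=protocol,
        states_use=states if keep_states else None,
        x0=x0,
    )


# --------------------------------------------------------------------------
# collocation meshes
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class MeshPlan:
    """Retained samples and their 5-point grouping for collocation.

    ``retained`` holds indices into the base grid; ``groups`` is a (G, 5)
    array of indices *into the retained list* with uniform spacing
    ``group_dt[g]`` inside each group; the last point of a group is the first
    point of the next.
    """

    retained: np.ndarray
    groups: np.ndarray
    group_dt: np.ndarray
    threshold: float
    m: int
    dt_base: float

    @property
    def n_retained(self) -> int:
        return len(self.retained)

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def achieved_duration(self) -> float:
        """Window duration actually covered by the retained samples (ms)."""
        return float(4.0 * np.sum(self.group_dt))

    def validate(self) -> None:
        g = self.groups
        assert g.shape[1] == 5
        assert np.all(g[1:, 0] == g[:-1, 4]), "groups must chain end-to-start"
        n_intervals = self.n_retained - 1
        assert n_intervals == 4 * self.n_groups
        assert n_intervals % (4 * self.m) == 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "retained": self.retained.tolist(),
                "groups": self.groups.tolist(),
                "group_dt": self.group_dt.tolist(),
                "threshold": self.threshold,
                "m": self.m,
                "dt_base": self.dt_base,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "MeshPlan":
        d = json.loads(text)
        return cls(
            retained=np.array(d["retained"], dtype=int),
            groups=np.array(d["groups"], dtype=int),
            group_dt=np.array(d["group_dt"], dtype=float),
            threshold=float(d["threshold"]),
            m=int(d["m"]),
            dt_base=float(d["dt_base"]),
        )


def uniform_mesh(n_base: int, dt_base: float, stride: int = 1) -> MeshPlan:
    """Uniform mesh over a base grid of n_base+1 samples, optional stride.

    The number of retained intervals is trimmed to a multiple of 4.
    """
    idx = np.arange(0, n_base + 1, stride)
    n_int = (len(idx) - 1) // 4 * 4
    idx = idx[: n_int + 1]
    G = n_int // 4
    groups = np.arange(G)[:, None] * 4 + np.arange(5)[None, :]
    return MeshPlan(
        retained=idx,
        groups=groups,
        group_dt=np.full(G, dt_base * stride),
        threshold=np.inf,
        m=1,
        dt_base=dt_base,
    )


def adaptive_mesh(trace: np.ndarray, threshold: float, m: int, dt_base: float) -> MeshPlan:
    """Two-rate mesh: base step where the trace is supra-threshold, m x elsewhere.

    ``trace`` is V_exp on the uniform base grid.  Groups of 5 points span 4
    base steps (supra-threshold: any sample in the span above ``threshold``)
    or 4*m base steps (sub-threshold, retaining every m-th sample).  Trailing
    groups are trimmed so the retained interval count is a multiple of 4*m.
    """
    if m not in (1, 2, 4):
        raise InvalidParameterError("sub-threshold multiplier m must be 1, 2 or 4")
    trace = np.asarray(trace, dtype=float)
    n_base = len(trace) - 1
    if n_base < 4 * m:
        raise InvalidParameterError("trace shorter than one mesh group")
    groups_base: list[np.ndarray] = []
    dts: list[float] = []
    i = 0
    while True:
        if i + 4 > n_base:
            break
        coarse_ok = i + 4 * m <= n_base and not np.any(trace[i : i + 4 * m + 1] > threshold)
        if coarse_ok:
            groups_base.append(np.arange(i, i + 4 * m + 1, m))
            dts.append(dt_base * m)
            i += 4 * m
        else:
            groups_base.append(np.arange(i, i + 5))
            dts.append(dt_base)
            i += 4
    # trim so retained interval count is a multiple of 4m
    def n_intervals(k: int) -> int:
        return 4 * k
    G = len(groups_base)
    while G > 0 and n_intervals(G) % (4 * m) != 0:
        G -= 1
    if G == 0:
        raise InvalidParameterError("no complete mesh groups after trimming")
    groups_base = groups_base[:G]
    dts = dts[:G]
    retained = np.unique(np.concatenate(groups_base))
    pos = {b: i for i, b in enumerate(retained.tolist())}
    groups = np.array([[pos[b] for b in g] for g in groups_base], dtype=int)
    plan = MeshPlan(
        retained=retained,
        groups=groups,
        group_dt=np.array(dts),
        threshold=float(threshold),
        m=int(m),
        dt_base=float(dt_base),
    )
    plan.validate()
    return plan
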