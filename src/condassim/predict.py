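"""Prediction and validation: drive a fitted model on held-out protocols.

A parameter set is validated by forward-integrating the model (no nudging)
under a protocol it was not trained on and comparing the predicted voltage
against a reference trace: pointwise error, RMS error, and spike-event
matching (missed and spurious action potentials).  Sub-optimal parameter
sets produce visible spike mismatches even when their training cost was
low, which is what makes prediction a sharper test than the fit itself.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .errors import InvalidParameterError
from .model import ModelSpec, ParameterSet
from .twin import CurrentProtocol, integrate_forward, settle_initial_state

__all__ = [
    "predict",
    "detect_spikes",
    "compare_traces",
    "parameter_distance",
    "PredictionReport",
]


def predict(
    p_set,
    model: ModelSpec,
    protocol: CurrentProtocol,
    x0: np.ndarray | None = None,
    t_grid: np.ndarray | None = None,
    dt: float = 0.01,
    rtol: float = 1e-10,
    atol: float = 1e-12,
) -> np.ndarray:
    """Forward-integrate the model under a protocol; returns states on t_grid.

    Nudging-free and deterministic: the result depends only on the
    parameters, the protocol and the initial state (settled at the first
    step amplitude when ``x0`` is omitted).
    """
    if t_grid is None:
        n = int(round(protocol.total_duration / dt))
        t_grid = np.arange(n + 1) * dt
    if x0 is None:
        x0 = settle_initial_state(model, p_set, I_hold=protocol.steps[0][1])
    return integrate_forward(model, p_set, x0, protocol, t_grid, rtol=rtol, atol=atol)


def detect_spikes(
    t: np.ndarray, V: np.ndarray, threshold: float = -20.0, refractory: float = 2.0
) -> np.ndarray:
    """Spike times as upward threshold crossings with a refractory gap (ms)."""
    up = np.nonzero((V[:-1] <= threshold) & (V[1:] > threshold))[0]
    times = []
    last = -np.inf
    for i in up:
        if t[i] - last >= refractory:
            times.append(t[i])
            last = t[i]
    return np.asarray(times)


@dataclass
class PredictionReport:
    """Comparison of a predicted voltage trace against a reference trace."""

    t: np.ndarray
    predicted: np.ndarray
    reference: np.ndarray
    error: np.ndarray  # predicted - reference, elementwise
    rms_error: float  # mV
    spikes_reference: np.ndarray
    spikes_predicted: np.ndarray
    missed_spikes: int
    spurious_spikes: int
    parameter_distance: float | None = None
    parameter_distance_normalized: float | None = None

    def to_json(self) -> str:
        return json.dumps(
            {
                "rms_error_mV": self.rms_error,
                "n_spikes_reference": int(len(self.spikes_reference)),
                "n_spikes_predicted": int(len(self.spikes_predicted)),
                "missed_spikes": self.missed_spikes,
                "spurious_spikes": self.spurious_spikes,
                "parameter_distance": self.parameter_distance,
                "parameter_distance_normalized": self.parameter_distance_normalized,
            },
            indent=1,
        )


def compare_traces(
    t: np.ndarray,
    predicted: np.ndarray,
    reference: np.ndarray,
    spike_threshold: float = -20.0,
    refractory: float = 2.0,
    match_window: float = 2.0,
) -> PredictionReport:
    """Error trace, RMS, and greedy spike matching within a tolerance window.

    Spikes are upward crossings of ``spike_threshold``; each reference spike
    is matched greedily to the nearest unmatched predicted spike within
    ``match_window`` ms.  Unmatched reference spikes count as missed,
    unmatched predicted spikes as spurious.
    """
    predicted = np.asarray(predicted, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if predicted.shape != reference.shape or predicted.shape != np.shape(t):
        raise InvalidParameterError("traces must share one common time grid")
    err = predicted - reference
    rms = float(np.sqrt(np.mean(err**2)))
    sp_ref = detect_spikes(t, reference, spike_threshold, refractory)
    sp_pred = detect_spikes(t, predicted, spike_threshold, refractory)
    used = np.zeros(len(sp_pred), dtype=bool)
    matched = 0
    for ts in sp_ref:
        if len(sp_pred) == 0:
            break
        d = np.abs(sp_pred - ts)
        d[used] = np.inf
        j = int(np.argmin(d))
        if d[j] <= match_window:
            used[j] = True
            matched += 1
    return PredictionReport(
        t=np.asarray(t),
        predicted=predicted,
        reference=reference,
        error=err,
        rms_error=rms,
        spikes_reference=sp_ref,
        spikes_predicted=sp_pred,
        missed_spikes=int(len(sp_ref) - matched),
        spurious_spikes=int(len(sp_pred) - matched),
    )


def parameter_distance(
    p,
    p_ref,
    bounds=None,
) -> dict[str, float]:
    """Euclidean distance in parameter space, raw and interval-normalized.

    Raw: ||p - p_ref||_2 over the shared parameter names.  Normalized:
    each coordinate divided by its search-interval width first (requires
    ``bounds``); both are returned because the parameter units are
    heterogeneous.
    """
    p = ParameterSet(p)
    p_ref = ParameterSet(p_ref)
    if set(p) != set(p_ref):
        raise InvalidParameterError("parameter name mismatch")
    keys = sorted(p)
    d = np.array([p[k] - p_ref[k] for k in keys])
    out = {"euclidean": float(np.linalg.norm(d))}
    if bounds is not None:
        w = np.array(
            [max(bounds[k][1] - bounds[k][0], abs(p_ref[k]), 1e-12) for k in keys]
        )
        out["normalized"] = float(np.linalg.norm(d / w))
    return out
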