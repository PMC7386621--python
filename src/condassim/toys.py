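"""Reduced conductance models with closed-form or easily verified behaviour.

These small models (a passive leak membrane, and leak + delayed-rectifier
potassium) share the full model machinery — symbolic derivatives,
collocation, twin data — but are cheap enough for exhaustive regression
oracles: the leak membrane relaxes analytically as
V(t) = V_inf + (V0 - V_inf) e^{-t g_L/C} with V_inf = E_L + 0.01 I/(A g_L).
"""

from __future__ import annotations

from .model import ChannelSpec, ModelSpec, ParameterSet, ParameterTable, PhysicalConstants

__all__ = ["leak_model", "leak_k_model"]


def leak_model() -> tuple[ModelSpec, ParameterTable]:
    """Single-state passive membrane: C dV/dt = g_L (E_L - V) + 0.01 I/A."""
    model = ModelSpec(
        name="leak",
        gates=(),
        channels=(ChannelSpec("Leak", "g_L", "E_Leak", {}),),
        param_names=("C", "E_Leak", "A", "g_L"),
        constants=PhysicalConstants(),
    )
    p_true = ParameterSet({"C": 1.0, "E_Leak": -65.0, "A": 2.9, "g_L": 0.465})
    bounds = {
        "C": (1.0, 1.0),
        "E_Leak": (-90.0, -40.0),
        "A": (2.9, 2.9),  # degenerate with g_L otherwise (only g_L/C/A ratio enters)
        "g_L": (0.05, 2.0),
    }
    return model, ParameterTable(model, p_true, dict(bounds), dict(bounds))


def leak_k_model() -> tuple[ModelSpec, ParameterTable]:
    """Two-state model: leak plus a delayed-rectifier K current g_K n^4 (E_K - V)."""
    model = ModelSpec(
        name="leak_k",
        gates=("n",),
        channels=(
            ChannelSpec("Leak", "g_L", "E_Leak", {}),
            ChannelSpec("K", "g_K", "E_K", {"n": 4}),
        ),
        param_names=(
            "C", "E_Leak", "E_K", "A", "g_L", "g_K",
            "V_n", "dV_n", "dV_tau_n", "t_n", "eps_n",
        ),
        constants=PhysicalConstants(),
    )
    p_true = ParameterSet(
        {
            "C": 1.0, "E_Leak": -65.0, "E_K": -100.0, "A": 2.9,
            "g_L": 0.465, "g_K": 6.9,
            "V_n": -34.58, "dV_n": 22.17, "dV_tau_n": 23.58, "t_n": 1.291, "eps_n": 4.314,
        }
    )
    bounds = {
        "C": (1.0, 1.0),
        "E_Leak": (-90.0, -40.0),
        "E_K": (-115.0, -80.0),
        "A": (2.9, 2.9),
        "g_L": (0.05, 2.0),
        "g_K": (0.5, 20.0),
        "V_n": (-69.0, -21.0),
        "dV_n": (5.0, 34.0),
        "dV_tau_n": (5.0, 34.0),
        "t_n": (0.01, 5.4),
        "eps_n": (0.002, 23.0),
    }
    return model, ParameterTable(model, p_true, dict(bounds), dict(bounds))
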