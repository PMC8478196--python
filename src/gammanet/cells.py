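"""Adaptive exponential integrate-and-fire (Adex) cell parameters.

Three cortical cell classes are provided as presets:

* ``RS`` — regular-spiking excitatory cells (spike-frequency adapting),
* ``FS`` — fast-spiking inhibitory cells (non-adapting, a = b = 0),
* ``CH`` — chattering excitatory cells (strong subthreshold adaptation,
  short refractory period, burst-like firing).

Units follow the conventions of the field: capacitance in pF, conductances
in nS, voltages in mV, times in ms, currents in pA (external drives are
usually quoted in nA and converted at the interface).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import yaml

__all__ = [
    "AdexParams",
    "SynapseKinetics",
    "NeuronState",
    "CELL_PRESETS",
    "cell_params",
    "load_cell_presets",
]


@dataclass(frozen=True)
class AdexParams:
    """Constants of the Adex membrane equation for one cell class.

    The membrane potential V obeys

        C dV/dt = -g_L (V - E_L) + g_L * delta * exp((V - V_th)/delta)
                  - w - g_E (V - E_E) - g_I (V - E_I) + I_ext

    and the adaptation current w obeys

        tau_w dw/dt = a (V - E_L) - w,   w -> w + b at each spike.

    A spike is registered when V reaches ``v_cut``. The default follows
    standard Adex practice, ``v_th + 5 * delta``, letting the exponential
    upswing express itself before detection; detection at the effective
    threshold itself (``with_cut(v_th)``) is also supported. The choice
    matters in recurrent networks: threshold-touch detection lets a volley
    recruit neurons that a later-arriving IPSP would have rescued.
    """

    c_m: float  # membrane capacitance, pF
    g_l: float  # leak conductance, nS
    e_l: float  # leak reversal, mV
    v_th: float  # effective threshold, mV
    delta: float  # threshold slope factor, mV
    t_ref: float  # refractory period, ms
    tau_w: float  # adaptation time constant, ms
    a: float  # subthreshold adaptation, nS
    b: float  # spike-triggered adaptation increment, pA
    v_reset: float  # post-spike reset potential, mV
    e_e: float = 0.0  # excitatory synaptic reversal, mV
    e_i: float = -80.0  # inhibitory synaptic reversal, mV
    cell_type: str = "RS"
    v_cut: Optional[float] = None  # spike-detection voltage; None -> v_th + 5*delta

    def __post_init__(self) -> None:
        if self.delta <= 0 or self.c_m <= 0 or self.g_l <= 0:
            raise ValueError("delta, c_m and g_l must be positive")
        if self.tau_w <= 0 or self.t_ref < 0:
            raise ValueError("tau_w must be > 0 and t_ref >= 0")
        if not (self.e_i < self.e_l < self.e_e):
            raise ValueError("expected E_I < E_L < E_E")

    @property
    def cut_voltage(self) -> float:
        return self.v_th + 5.0 * self.delta if self.v_cut is None else self.v_cut

    def with_cut(self, v_cut: float) -> "AdexParams":
        """Return a copy detecting spikes at ``v_cut`` instead of v_th."""
        return replace(self, v_cut=v_cut)


@dataclass(frozen=True)
class SynapseKinetics:
    """Conductance-based synapse kinetics on the postsynaptic side.

    Each presynaptic spike increments the target conductance by ``q`` (nS);
    between events the conductance decays exponentially with time constant
    ``tau_e`` / ``tau_i`` (ms).
    """

    tau_e: float
    tau_i: float
    q: float = 0.0

    def __post_init__(self) -> None:
        if self.tau_e <= 0 or self.tau_i <= 0:
            raise ValueError("synaptic time constants must be positive")
        if self.q < 0:
            raise ValueError("synaptic increment q must be >= 0")


@dataclass
class NeuronState:
    """Dynamical variables of a single Adex neuron."""

    v: float  # membrane potential, mV
    w: float = 0.0  # adaptation current, pA
    g_e: float = 0.0  # excitatory conductance, nS
    g_i: float = 0.0  # inhibitory conductance, nS
    refractory_until: float = -1.0  # absolute time (ms) until which V, w are frozen


# Cell-class presets (RS / FS / CH cortical neurons).
#
# Threshold convention: the exponential (rheobase) threshold V_T is -50 mV
# for every cell class — the canonical value for this Adex family — while
# the conventionally quoted per-class "threshold" is the spike-DETECTION
# voltage V_T + 5*delta (RS: -40 mV, FS/CH: -47.5 mV), which the default
# ``cut_voltage`` rule reproduces. Reading the quoted values as V_T itself
# leaves the excitatory population ~4 SD below threshold in every balanced
# network state, silencing it and destroying all reference network
# behaviour; see docs/methods.md for the full analysis.
CELL_PRESETS: dict[str, AdexParams] = {
    "RS": AdexParams(
        c_m=150.0, g_l=10.0, e_l=-65.0, v_th=-50.0, delta=2.0, t_ref=5.0,
        tau_w=500.0, a=4.0, b=20.0, v_reset=-65.0, cell_type="RS",
    ),
    "FS": AdexParams(
        c_m=150.0, g_l=10.0, e_l=-65.0, v_th=-50.0, delta=0.5, t_ref=5.0,
        tau_w=500.0, a=0.0, b=0.0, v_reset=-65.0, cell_type="FS",
    ),
    "CH": AdexParams(
        c_m=150.0, g_l=10.0, e_l=-58.0, v_th=-50.0, delta=0.5, t_ref=1.0,
        tau_w=50.0, a=80.0, b=150.0, v_reset=-65.0, cell_type="CH",
    ),
}
# FS2 cells (the highly interconnected inhibitory subpopulation of the ING
# network) share all FS parameters; only their wiring differs.
CELL_PRESETS["FS2"] = replace(CELL_PRESETS["FS"], cell_type="FS2")


def cell_params(name: str) -> AdexParams:
    """Look up a cell preset by name (RS, FS, FS2, CH)."""
    key = name.upper()
    if key not in CELL_PRESETS:
        raise KeyError(f"unknown cell type {name!r}; known: {sorted(CELL_PRESETS)}")
    return CELL_PRESETS[key]


_FIELD_ALIASES = {
    "C": "c_m", "g_L": "g_l", "E_L": "e_l", "V_th": "v_th", "Delta": "delta",
    "T_ref": "t_ref", "tau_w": "tau_w", "a": "a", "b": "b",
    "V_reset": "v_reset", "E_E": "e_e", "E_I": "e_i",
}


def load_cell_presets(path) -> dict[str, AdexParams]:
    """Load cell presets from a YAML file.

    The file maps cell-type names to parameter dictionaries; keys may use
    either the dataclass field names or the conventional symbols
    (C, g_L, E_L, V_th, Delta, T_ref, tau_w, a, b, V_reset, E_E, E_I).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    out = {}
    for name, entry in raw.items():
        kwargs = {}
        for key, value in entry.items():
            kwargs[_FIELD_ALIASES.get(key, key)] = float(value)
        kwargs.setdefault("e_e", 0.0)
        kwargs.setdefault("e_i", -80.0)
        out[name.upper()] = AdexParams(cell_type=name.upper(), **kwargs)
    return out
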