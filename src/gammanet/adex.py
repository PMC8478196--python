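"""Single-neuron Adex dynamics: forward-Euler stepping with conductance
synapses, spike/reset handling and refractoriness.

This module is the scalar reference implementation; the network engine
(:mod:`gammanet._engine`) vectorises the identical update rule.

Integration scheme
------------------
* V and w advance by forward Euler (reference dt = 0.1 ms).
* Synaptic conductances decay by the exact exponential factor
  ``exp(-dt/tau)`` between events ("exact" scheme, the default) or by
  forward Euler (``scheme="euler"``) for parity experiments, and jump by
  Q per incoming presynaptic spike.
* A spike is detected when V reaches the cut voltage (default
  V_th + 5*delta); V is then reset, w incremented by b, and both V and w
  are held frozen for the refractory period while conductances keep
  decaying and accumulating input.
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from .cells import AdexParams, NeuronState, SynapseKinetics

__all__ = ["step_neuron", "simulate_single_neuron", "ramp_plateau_current"]


def _check_finite(state: NeuronState) -> None:
    if not (math.isfinite(state.v) and math.isfinite(state.w)
            and math.isfinite(state.g_e) and math.isfinite(state.g_i)):
        raise FloatingPointError(
            f"non-finite neuron state: V={state.v}, w={state.w}, "
            f"gE={state.g_e}, gI={state.g_i}"
        )


def step_neuron(
    state: NeuronState,
    params: AdexParams,
    kinetics: SynapseKinetics,
    n_exc_spikes: int = 0,
    n_inh_spikes: int = 0,
    q_e: float | None = None,
    q_i: float | None = None,
    i_ext: float = 0.0,
    dt: float = 0.1,
    t: float = 0.0,
    scheme: str = "exact",
) -> tuple[NeuronState, bool]:
    """Advance one neuron by one time step of duration ``dt`` (ms).

    Parameters
    ----------
    n_exc_spikes, n_inh_spikes
        Number of presynaptic spikes arriving at this step.
    q_e, q_i
        Conductance increment per arriving spike (nS). Default: ``kinetics.q``.
    i_ext
        External current in nA.
    t
        Absolute time at the start of the step (ms); used for the
        refractory clock.

    Returns the new state and a flag that is True if the neuron spiked
    during this step.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    _check_finite(state)
    qe = kinetics.q if q_e is None else q_e
    qi = kinetics.q if q_i is None else q_i

    # Conductance update: decay then accumulate arrivals.
    if scheme == "exact":
        g_e = state.g_e * math.exp(-dt / kinetics.tau_e)
        g_i = state.g_i * math.exp(-dt / kinetics.tau_i)
    elif scheme == "euler":
        g_e = state.g_e * (1.0 - dt / kinetics.tau_e)
        g_i = state.g_i * (1.0 - dt / kinetics.tau_i)
    else:
        raise ValueError(f"unknown conductance scheme {scheme!r}")
    g_e += qe * n_exc_spikes
    g_i += qi * n_inh_spikes

    refractory = t < state.refractory_until
    v, w = state.v, state.w
    spiked = False
    if not refractory:
        # Currents in pA: conductances nS * mV = pA; i_ext nA -> pA.
        i_syn = g_e * (v - params.e_e) + g_i * (v - params.e_i)
        exp_term = params.g_l * params.delta * math.exp((v - params.v_th) / params.delta)
        dv = (-params.g_l * (v - params.e_l) + exp_term - w - i_syn
              + i_ext * 1e3) / params.c_m
        dw = (params.a * (v - params.e_l) - w) / params.tau_w
        v = v + dt * dv
        w = w + dt * dw
        if v >= params.cut_voltage:
            spiked = True
            v = params.v_reset
            w = w + params.b
    new = NeuronState(
        v=v, w=w, g_e=g_e, g_i=g_i,
        refractory_until=(t + dt + params.t_ref) if spiked else state.refractory_until,
    )
    return new, spiked


def simulate_single_neuron(
    params: AdexParams,
    current_trace: Sequence[float] | np.ndarray,
    dt: float = 0.1,
    kinetics: SynapseKinetics | None = None,
    v0: float | None = None,
    scheme: str = "exact",
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate an isolated neuron driven by an external current trace.

    Parameters
    ----------
    current_trace
        External current in nA, sampled at ``dt``.
    v0
        Initial membrane potential (default: the leak reversal E_L).

    Returns
    -------
    spike_times : ndarray of ms (spike registered at the end of its step)
    v_trace : ndarray of mV, one entry per input sample (potential at the
        end of each step; reset value on spike steps)
    """
    current = np.asarray(current_trace, dtype=float)
    if current.ndim != 1:
        raise ValueError("current_trace must be one-dimensional")
    n = current.size
    if n == 0:
        return np.empty(0), np.empty(0)
    kin = kinetics or SynapseKinetics(tau_e=5.0, tau_i=5.0, q=0.0)
    state = NeuronState(v=params.e_l if v0 is None else v0)
    v_trace = np.empty(n)
    spikes: list[float] = []
    t = 0.0
    for k in range(n):
        state, spiked = step_neuron(
            state, params, kin, i_ext=current[k], dt=dt, t=t, scheme=scheme
        )
        t += dt
        v_trace[k] = state.v
        if spiked:
            spikes.append(t)
    return np.asarray(spikes), v_trace


def ramp_plateau_current(
    amplitude: float = 0.5,
    ramp_ms: float = 250.0,
    plateau_ms: float = 500.0,
    dt: float = 0.1,
    pad_ms: float = 50.0,
) -> np.ndarray:
    """Ramp-up / plateau / ramp-down current protocol (nA).

    The drive rises linearly from 0 to ``amplitude`` over ``ramp_ms``, holds
    for ``plateau_ms``, and descends linearly back to 0, with silent padding
    at both ends — the standard step-like protocol used to expose spike-
    frequency adaptation in RS cells and tonic firing in FS cells.
    """
    n_pad = int(round(pad_ms / dt))
    n_ramp = int(round(ramp_ms / dt))
    n_plat = int(round(plateau_ms / dt))
    up = np.linspace(0.0, amplitude, n_ramp, endpoint=False)
    down = np.linspace(amplitude, 0.0, n_ramp, endpoint=False)
    return np.concatenate([
        np.zeros(n_pad), up, np.full(n_plat, amplitude), down, np.zeros(n_pad)
    ])
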