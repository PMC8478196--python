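"""Vectorised Adex network integration kernel.

The kernel advances all neurons with forward-Euler membrane/adaptation
updates and exact-exponential conductance decay, identical in semantics to
the scalar reference in :mod:`gammanet.adex`:

* conductances decay each step and jump by the synaptic strength when a
  presynaptic spike (delayed by an integer number of steps) arrives;
* refractory neurons have V and w frozen while their conductances keep
  integrating input;
* spike detection at the per-neuron cut voltage, reset to v_reset, w += b.

Recurrent connectivity is CSR by source neuron; delayed deliveries use a
ring buffer of conductance increments. The external Poissonian drive is
passed as a per-step list of source-train events plus a train->target CSR
map, so that the (event x target) expansion never has to be materialised.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["run_network"]


@njit(cache=True)
def _run(
    n_steps, dt,
    c_m, g_l, e_l, v_th, delta, a, b, tau_w, v_reset, v_cut, e_e, e_i,
    t_ref_steps,
    decay_e, decay_i,
    V, w, gE, gI, ref_left,
    indptr, targets, weights, is_inh, delay_steps,
    ev_indptr, ev_src, drv_indptr, drv_targets, qext,
    i_ext, i_ext_gain,
    rec_idx, rec_stride, recV, recGE, recGI,
    spike_step, spike_id,
):
    N = V.shape[0]
    D = delay_steps + 1
    incE = np.zeros((D, N))
    incI = np.zeros((D, N))
    n_sp = 0
    cap = spike_step.shape[0]
    rec_row = 0
    for s in range(n_steps):
        slot = s % D
        for i in range(N):
            gE[i] = gE[i] * decay_e[i] + incE[slot, i]
            gI[i] = gI[i] * decay_i[i] + incI[slot, i]
            incE[slot, i] = 0.0
            incI[slot, i] = 0.0
        # external drive arrivals (delivered without delay)
        for k in range(ev_indptr[s], ev_indptr[s + 1]):
            src = ev_src[k]
            for m in range(drv_indptr[src], drv_indptr[src + 1]):
                tgt = drv_targets[m]
                gE[tgt] += qext[tgt]
        ie = i_ext[s]
        dslot = (s + delay_steps) % D
        for i in range(N):
            if ref_left[i] > 0:
                ref_left[i] -= 1
                continue
            v = V[i]
            i_syn = gE[i] * (v - e_e[i]) + gI[i] * (v - e_i[i])
            dv = (
                -g_l[i] * (v - e_l[i])
                + g_l[i] * delta[i] * np.exp((v - v_th[i]) / delta[i])
                - w[i] - i_syn + ie * i_ext_gain[i]
            ) / c_m[i]
            w[i] += dt * (a[i] * (v - e_l[i]) - w[i]) / tau_w[i]
            v = v + dt * dv
            if v >= v_cut[i]:
                if n_sp >= cap:
                    return -1
                spike_step[n_sp] = s
                spike_id[n_sp] = i
                n_sp += 1
                v = v_reset[i]
                w[i] += b[i]
                ref_left[i] = t_ref_steps[i]
                for e in range(indptr[i], indptr[i + 1]):
                    if is_inh[e]:
                        incI[dslot, targets[e]] += weights[e]
                    else:
                        incE[dslot, targets[e]] += weights[e]
            V[i] = v
        if rec_stride > 0 and s % rec_stride == 0:
            for j in range(rec_idx.shape[0]):
                recV[rec_row, j] = V[rec_idx[j]]
                recGE[rec_row, j] = gE[rec_idx[j]]
                recGI[rec_row, j] = gI[rec_idx[j]]
            rec_row += 1
    return n_sp


def run_network(
    n_steps: int,
    dt: float,
    neuron_arrays: dict,
    state: dict,
    conn: tuple,
    delay_steps: int,
    drive: tuple,
    qext: np.ndarray,
    i_ext: np.ndarray,
    i_ext_gain: np.ndarray,
    rec_idx: np.ndarray,
    rec_stride: int,
    spike_capacity: int,
):
    """Driver around the jitted kernel; grows the spike buffer on overflow.

    Returns (spike_step, spike_id, recorded V/gE/gI arrays).
    """
    indptr, targets, weights, is_inh = conn
    ev_indptr, ev_src, drv_indptr, drv_targets = drive
    n_rec_rows = (n_steps + rec_stride - 1) // rec_stride if rec_stride > 0 else 0
    recV = np.empty((n_rec_rows, rec_idx.size))
    recGE = np.empty_like(recV)
    recGI = np.empty_like(recV)
    cap = int(spike_capacity)
    while True:
        spike_step = np.empty(cap, dtype=np.int64)
        spike_id = np.empty(cap, dtype=np.int64)
        st = {k: v.copy() for k, v in state.items()}
        n_sp = _run(
            n_steps, dt,
            neuron_arrays["c_m"], neuron_arrays["g_l"], neuron_arrays["e_l"],
            neuron_arrays["v_th"], neuron_arrays["delta"], neuron_arrays["a"],
            neuron_arrays["b"], neuron_arrays["tau_w"], neuron_arrays["v_reset"],
            neuron_arrays["v_cut"], neuron_arrays["e_e"], neuron_arrays["e_i"],
            neuron_arrays["t_ref_steps"],
            neuron_arrays["decay_e"], neuron_arrays["decay_i"],
            st["V"], st["w"], st["gE"], st["gI"], st["ref_left"],
            indptr, targets, weights, is_inh, delay_steps,
            ev_indptr, ev_src, drv_indptr, drv_targets, qext,
            i_ext, i_ext_gain,
            rec_idx, rec_stride, recV, recGE, recGI,
            spike_step, spike_id,
        )
        if n_sp >= 0:
            return spike_step[:n_sp], spike_id[:n_sp], recV, recGE, recGI, st
        cap *= 2
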