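"""Synthetic fixtures for the burst-detection / unit-statistics chain.

`generate_fixture` emulates the structure of a multielectrode resting
recording: per segment, a noisy LFP with embedded gamma bursts
(amplitude-modulated 40 Hz tone) and spike trains of a cohort of neurons
whose gamma participation is controlled exactly:

* phase-locking — inside bursts, a neuron's spikes are drawn as an
  inhomogeneous Poisson process whose intensity follows a von Mises
  density of concentration ``kappa`` around a preferred phase ``mu``;
* rate change — inside-burst rate ``f_gamma`` versus outside rate
  ``f_out``.

The returned truth table carries the intended labels, so calibration and
power of the statistical chain can be measured against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import ConfigError

__all__ = ["FixtureSpec", "SegmentData", "generate_fixture", "von_mises_spikes"]


@dataclass(frozen=True)
class FixtureSpec:
    n_neurons: int = 20
    n_segments: int = 5
    segment_s: float = 60.0  # duration of one segment
    gamma_s: float = 13.0  # total burst time per segment
    burst_s: float = 0.5  # duration of one burst
    f_gamma_hz: float = 40.0  # tone frequency
    burst_amplitude: float = 4.0  # tone amplitude in noise-SD units
    # ground truth (arrays of length n_neurons, or scalars broadcast)
    kappa: float | np.ndarray = 0.0
    mu: float | np.ndarray = 0.0
    f_out: float | np.ndarray = 2.0  # Hz outside bursts
    f_in: float | np.ndarray = 2.0  # Hz inside bursts
    fs: float = 1000.0  # LFP sampling rate

    def __post_init__(self):
        if self.n_neurons < 0 or self.n_segments <= 0:
            raise ConfigError("invalid fixture shape")
        if self.gamma_s > self.segment_s:
            raise ConfigError("gamma time exceeds segment duration")
        if self.gamma_s > 0 and self.burst_s <= 0:
            raise ConfigError("gamma requested with zero burst length")


@dataclass
class SegmentData:
    t_ms: np.ndarray
    lfp: np.ndarray
    spike_times: np.ndarray  # ms
    spike_ids: np.ndarray
    burst_intervals: list[tuple[float, float]]  # ms


def von_mises_spikes(rng, t0: float, t1: float, rate_hz: float,
                     f_tone_hz: float, kappa: float, mu: float,
                     phase0: float = 0.0) -> np.ndarray:
    """Inhomogeneous Poisson spikes (ms) on [t0, t1) whose intensity is a
    von Mises density of the tone phase, with mean rate ``rate_hz``.

    The tone phase at time t is phase0 + 2 pi f t; ``kappa = 0`` reduces
    to a homogeneous Poisson process.
    """
    if rate_hz <= 0 or t1 <= t0:
        return np.empty(0)
    from scipy.special import i0
    peak = np.exp(kappa) / i0(kappa)  # max density / mean density
    lam_max = rate_hz * peak * 1e-3  # events per ms
    n_cand = rng.poisson(lam_max * (t1 - t0))
    cand = np.sort(rng.uniform(t0, t1, n_cand))
    ph = phase0 + 2 * np.pi * f_tone_hz * cand * 1e-3
    accept = rng.random(n_cand) < np.exp(kappa * (np.cos(ph - mu) - 1.0))
    return cand[accept]


def generate_fixture(spec: FixtureSpec, seed: int = 0
                     ) -> tuple[list[SegmentData], pd.DataFrame]:
    """Generate ``n_segments`` synthetic segments plus the truth table.

    Burst placement: bursts of ``burst_s`` seconds are spaced evenly
    through each segment until ``gamma_s`` seconds are placed. The LFP is
    unit-variance white noise plus the windowed tone; spike phases inside
    bursts are defined against the tone (phase convention of the analytic
    signal of a cosine: phase 0 at the tone peak).
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xF1]))
    n = spec.n_neurons
    kappa = np.broadcast_to(np.asarray(spec.kappa, float), (n,))
    mu = np.broadcast_to(np.asarray(spec.mu, float), (n,))
    f_out = np.broadcast_to(np.asarray(spec.f_out, float), (n,))
    f_in = np.broadcast_to(np.asarray(spec.f_in, float), (n,))

    seg_ms = spec.segment_s * 1e3
    dt = 1e3 / spec.fs
    n_samp = int(round(seg_ms / dt))
    t_ms = np.arange(n_samp) * dt

    n_bursts = int(round(spec.gamma_s / spec.burst_s)) if spec.gamma_s > 0 else 0
    segments = []
    for _ in range(spec.n_segments):
        lfp = rng.standard_normal(n_samp)
        intervals = []
        if n_bursts:
            gap = seg_ms / n_bursts
            for k in range(n_bursts):
                start = k * gap + 0.25 * gap
                end = start + spec.burst_s * 1e3
                intervals.append((start, min(end, seg_ms)))
                m = (t_ms >= start) & (t_ms < end)
                # cosine tone: analytic-signal phase is 0 at each peak
                lfp[m] += spec.burst_amplitude * np.cos(
                    2 * np.pi * spec.f_gamma_hz * (t_ms[m]) * 1e-3)
        st_all, id_all = [], []
        for i in range(n):
            # outside bursts: homogeneous Poisson at f_out
            n_out = rng.poisson(f_out[i] * spec.segment_s)
            t_out = rng.uniform(0.0, seg_ms, n_out)
            keep = np.ones(n_out, dtype=bool)
            for (a, b) in intervals:
                keep &= ~((t_out >= a) & (t_out < b))
            spikes = [t_out[keep]]
            for (a, b) in intervals:
                spikes.append(von_mises_spikes(
                    rng, a, b, f_in[i], spec.f_gamma_hz, kappa[i], mu[i]))
            st = np.sort(np.concatenate(spikes))
            st_all.append(st)
            id_all.append(np.full(st.size, i, dtype=np.int64))
        segments.append(SegmentData(
            t_ms=t_ms, lfp=lfp,
            spike_times=np.concatenate(st_all) if st_all else np.empty(0),
            spike_ids=np.concatenate(id_all) if id_all else np.empty(0, np.int64),
            burst_intervals=intervals,
        ))
    truth = pd.DataFrame({
        "neuron_id": np.arange(n),
        "kappa": kappa, "mu": mu, "f_out": f_out, "f_in": f_in,
        "locked": kappa > 0,
        "rate_change": np.where(f_in > f_out, "increase",
                                np.where(f_in < f_out, "decrease", "no_change")),
    })
    return segments, truth
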