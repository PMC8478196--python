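"""Construction and simulation of the five gamma-oscillation network
architectures: PING, AI, GAMMA, ING and CHING.

All five are random (Erdos-Renyi-style) networks of conductance-based Adex
neurons with a uniform 1.5 ms synaptic delay and an external drive of
independent excitatory Poissonian spike trains:

* **PING** — 20000 RS + 5000 FS at p = 2%; fast excitation (tau_E = 1 ms,
  Q_E = 5 nS) against slow inhibition (tau_I = 7.5 ms, Q_I = 3.34 nS)
  produces a pyramidal-interneuron gamma near 40 Hz.
* **AI** — same populations, Q_E = 1 nS, Q_I = 5 nS, tau_E = tau_I = 5 ms:
  an asynchronous-irregular control that cannot oscillate at any drive.
* **GAMMA** — 1000 FS neurons, densely coupled (p = 60%, Q_I = 5 nS):
  a purely inhibitory oscillator near 70 Hz.
* **ING** — the AI core (20000 RS + 4000 FS) plus the 1000-neuron GAMMA
  subnetwork ("FS2") coupled to it; oscillates near 55 Hz.
* **CHING** — the AI network with 5% of the RS cells replaced by chattering
  (CH) pacemakers and stronger FS inhibition onto excitatory cells;
  oscillates near 40 Hz.

Each architecture has a "gamma" and an "ai" drive level (the same wiring;
only the Poisson-rate differs), matching the burst/asynchronous states the
models are studied in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence, Union

import numpy as np

from . import adex  # noqa: F401  (scalar reference semantics)
from .cells import AdexParams, cell_params
from ._engine import run_network

__all__ = [
    "ConfigError",
    "PopulationSpec",
    "SynapseGroup",
    "DriveSpec",
    "NetworkSpec",
    "SimResult",
    "RealizedNetwork",
    "RateProfile",
    "constant_profile",
    "gaussian_bump",
    "sinusoid_profile",
    "trapezoid_profile",
    "build_network",
    "scale_network",
    "realize_network",
    "generate_drive",
    "events_per_target",
    "simulate_network",
    "NETWORK_NAMES",
]

NETWORK_NAMES = ("PING", "AI", "GAMMA", "ING", "CHING")


class ConfigError(ValueError):
    """Invalid network/protocol configuration."""


# ---------------------------------------------------------------------------
# Rate profiles for the external drive (Hz per source train, clipped at 0)
# ---------------------------------------------------------------------------

RateProfile = Callable[[np.ndarray], np.ndarray]


def constant_profile(rate: float) -> RateProfile:
    if rate < 0:
        raise ConfigError("drive rate must be >= 0")
    return lambda t: np.full_like(t, float(rate))


def gaussian_bump(amplitude: float, sd_ms: float, center_ms: float) -> RateProfile:
    """Additive Gaussian fluctuation of the drive rate (Hz)."""
    if sd_ms <= 0:
        raise ConfigError("gaussian bump sd must be > 0")
    return lambda t: amplitude * np.exp(-((t - center_ms) ** 2) / (2.0 * sd_ms**2))


def sinusoid_profile(mu: float, delta: float, freq_hz: float) -> RateProfile:
    """mu + delta * sin(2 pi f t); negative excursions are clipped at 0."""
    if mu < 0:
        raise ConfigError("mean drive rate must be >= 0")
    if mu - delta < 0:
        warnings.warn("sinusoidal drive dips below 0 Hz; clipping", stacklevel=2)
    return lambda t: mu + delta * np.sin(2.0 * np.pi * freq_hz * t * 1e-3)


def trapezoid_profile(base: float, top: float, t_on: float, t_off: float,
                      ramp_ms: float = 100.0) -> RateProfile:
    """Drive schedule stepping from ``base`` to ``top`` Hz with linear ramps.

    Used to induce a predictable gamma burst inside an otherwise AI-like
    run: the rate ramps up over ``ramp_ms`` before ``t_on``, holds at
    ``top`` until ``t_off``, then ramps back down.
    """
    def f(t: np.ndarray) -> np.ndarray:
        up = np.clip((t - (t_on - ramp_ms)) / ramp_ms, 0.0, 1.0)
        down = np.clip(((t_off + ramp_ms) - t) / ramp_ms, 0.0, 1.0)
        return base + (top - base) * np.minimum(up, down)
    return f


def _sum_profiles(*profiles: RateProfile) -> RateProfile:
    return lambda t: sum(p(t) for p in profiles)


# ---------------------------------------------------------------------------
# Specifications
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationSpec:
    name: str  # RS, FS, FS2 or CH
    size: int
    params: AdexParams

    def __post_init__(self):
        if self.size <= 0:
            raise ConfigError(f"population {self.name} must have size > 0")


@dataclass(frozen=True)
class SynapseGroup:
    source: str
    target: str
    p_connect: float
    q: float  # nS
    sign: str  # "E" or "I"
    delay: float = 1.5  # ms

    def __post_init__(self):
        if not (0.0 <= self.p_connect <= 1.0):
            raise ConfigError("p_connect must lie in [0, 1]")
        if self.sign not in ("E", "I"):
            raise ConfigError("synapse sign must be 'E' or 'I'")
        if self.q < 0 or self.delay < 0:
            raise ConfigError("q and delay must be >= 0")


@dataclass(frozen=True)
class DriveSpec:
    """External drive of iid excitatory Poissonian spike trains.

    ``shared`` mode: ``n_sources`` trains, each wired to every neuron with
    probability ``p_connect`` (neurons share trains, adding weak input
    correlation). ``independent`` mode: every neuron receives its own
    superposition of ``n_per_neuron`` iid trains (equivalently one Poisson
    train at ``n_per_neuron * rate``), with no shared-input correlation.
    """

    rate: float = 2.0  # Hz per source train
    q: Union[float, dict] = 1.0  # nS; scalar or {population: nS}
    n_sources: int = 20000
    p_connect: float = 0.02
    mode: str = "shared"
    n_per_neuron: int = 400  # independent mode only
    profile: Optional[RateProfile] = None  # overrides constant `rate`

    def __post_init__(self):
        if self.rate < 0:
            raise ConfigError("drive rate must be >= 0")
        if self.mode not in ("shared", "independent"):
            raise ConfigError("drive mode must be 'shared' or 'independent'")
        if not (0.0 <= self.p_connect <= 1.0):
            raise ConfigError("drive p_connect must lie in [0, 1]")

    def rate_profile(self) -> RateProfile:
        return self.profile if self.profile is not None else constant_profile(self.rate)


@dataclass(frozen=True)
class NetworkSpec:
    name: str
    populations: tuple  # of PopulationSpec
    groups: tuple  # of SynapseGroup
    tau_e: float  # ms, network-wide excitatory decay (incl. drive)
    tau_i: float  # ms
    drive: DriveSpec
    state: str = "gamma"
    scale: float = 1.0

    @property
    def n_neurons(self) -> int:
        return sum(p.size for p in self.populations)

    def population_slices(self) -> dict:
        out, start = {}, 0
        for p in self.populations:
            out[p.name] = slice(start, start + p.size)
            start += p.size
        return out


# ---------------------------------------------------------------------------
# Architecture catalogue
# ---------------------------------------------------------------------------

def _all_pairs(pops: Sequence[str], p: float, q_of, sign_of) -> list:
    groups = []
    for src in pops:
        for tgt in pops:
            groups.append(SynapseGroup(src, tgt, p, q_of(src, tgt), sign_of(src)))
    return groups


_STATE_DRIVE = {
    # network -> state -> per-train Poisson rate (Hz)
    "PING": {"gamma": 3.0, "ai": 2.0},
    "ING": {"gamma": 3.0, "ai": 2.0},
    "CHING": {"gamma": 2.0, "ai": 1.0},
    # The AI network cannot oscillate; "gamma"/"ai" just select the drive
    # level used in the corresponding protocol comparisons.
    "AI": {"gamma": 3.0, "ai": 2.0},
    "GAMMA": {"gamma": 5.0, "ai": 5.0},
}


def build_network(name: str, state: str = "gamma") -> NetworkSpec:
    """Build one of the five architectures at full reference size.

    ``state`` selects the external-drive level ("gamma" induces the
    oscillatory regime, "ai" the asynchronous/AI-like regime).
    """
    key = name.upper()
    if key not in NETWORK_NAMES:
        raise ConfigError(f"unknown network {name!r}; known: {NETWORK_NAMES}")
    if state not in ("gamma", "ai"):
        raise ConfigError("state must be 'gamma' or 'ai'")
    mu = _STATE_DRIVE[key][state]
    sign = lambda src: "I" if src.startswith("FS") else "E"  # noqa: E731

    if key == "PING":
        pops = (
            PopulationSpec("RS", 20000, cell_params("RS")),
            PopulationSpec("FS", 5000, cell_params("FS")),
        )
        groups = _all_pairs(
            ["RS", "FS"], 0.02,
            q_of=lambda s, t: 5.0 if s == "RS" else 3.34, sign_of=sign,
        )
        drive = DriveSpec(rate=mu, q=4.0)
        # tau_E = 1.0 ms: the value consistent with the synaptic-gain
        # normalisation Q_E * tau_E = Q_ref * tau_ref (5 nS x 1 ms = 1 nS x 5 ms).
        return NetworkSpec(key, pops, tuple(groups), 1.0, 7.5, drive, state)

    if key == "AI":
        pops = (
            PopulationSpec("RS", 20000, cell_params("RS")),
            PopulationSpec("FS", 5000, cell_params("FS")),
        )
        groups = _all_pairs(
            ["RS", "FS"], 0.02,
            q_of=lambda s, t: 1.0 if s == "RS" else 5.0, sign_of=sign,
        )
        drive = DriveSpec(rate=mu, q=1.0)
        return NetworkSpec(key, pops, tuple(groups), 5.0, 5.0, drive, state)

    if key == "GAMMA":
        pops = (PopulationSpec("FS", 1000, cell_params("FS")),)
        groups = (SynapseGroup("FS", "FS", 0.60, 5.0, "I"),)
        drive = DriveSpec(rate=mu, q=1.0, mode="independent", n_per_neuron=400)
        return NetworkSpec(key, pops, tuple(groups), 5.0, 5.0, drive, state)

    if key == "ING":
        pops = (
            PopulationSpec("RS", 20000, cell_params("RS")),
            PopulationSpec("FS", 4000, cell_params("FS")),
            PopulationSpec("FS2", 1000, cell_params("FS2")),
        )
        qq = lambda s, t: 1.0 if s == "RS" else 5.0  # noqa: E731
        groups = _all_pairs(["RS", "FS"], 0.02, q_of=qq, sign_of=sign)
        groups += [
            SynapseGroup("FS2", "RS", 0.15, 5.0, "I"),
            SynapseGroup("RS", "FS2", 0.15, 1.0, "E"),
            SynapseGroup("FS2", "FS", 0.15, 5.0, "I"),
            SynapseGroup("FS", "FS2", 0.03, 5.0, "I"),
            SynapseGroup("FS2", "FS2", 0.60, 5.0, "I"),
        ]
        drive = DriveSpec(rate=mu, q=0.9)
        return NetworkSpec(key, pops, tuple(groups), 5.0, 5.0, drive, state)

    # CHING
    pops = (
        PopulationSpec("RS", 19000, cell_params("RS")),
        PopulationSpec("CH", 1000, cell_params("CH")),
        PopulationSpec("FS", 5000, cell_params("FS")),
    )

    def q_ching(src, tgt):
        if src in ("RS", "CH"):
            return 1.0
        return 5.0 if tgt == "FS" else 7.0  # FS inhibition: 7 nS on RS/CH

    groups = _all_pairs(["RS", "CH", "FS"], 0.02, q_of=q_ching, sign_of=sign)
    drive = DriveSpec(rate=mu, q={"RS": 1.0, "CH": 1.0, "FS": 0.75})
    return NetworkSpec("CHING", pops, tuple(groups), 5.0, 5.0, drive, state)


def scale_network(spec: NetworkSpec, factor: float) -> NetworkSpec:
    """Shrink a network by ``factor`` while preserving mean synaptic drive.

    Population sizes are multiplied by ``factor`` and connection
    probabilities by ``1/factor`` so that expected in-degrees (hence the
    mean recurrent conductance) are unchanged. When the boosted
    probability would exceed 1 it is capped and the synaptic strength Q is
    raised to preserve the product (in-degree x Q), i.e. the total
    synaptic gain of the pathway, with a warning (densely coupled pathways
    such as the 60% FS2-FS2 block cannot keep their in-degree at small
    sizes). The external drive is scaled identically.
    """
    if not (0.0 < factor <= 1.0):
        raise ConfigError("scale factor must lie in (0, 1]")
    if factor == 1.0:
        return spec
    pops = []
    for p in spec.populations:
        new_size = int(round(p.size * factor))
        if new_size <= 0:
            raise ConfigError(f"scaling by {factor} empties population {p.name}")
        pops.append(replace(p, size=new_size))
    groups = []
    for g in spec.groups:
        p_new = g.p_connect / factor
        q_new = g.q
        if p_new > 1.0:
            q_new = g.q * p_new  # preserve in-degree x Q
            warnings.warn(
                f"{g.source}->{g.target}: p={g.p_connect:.2f}/{factor} caps at 1; "
                f"boosting Q {g.q:.3g} -> {q_new:.3g} nS to preserve synaptic gain",
                stacklevel=2,
            )
            p_new = 1.0
        groups.append(replace(g, p_connect=p_new, q=q_new))
    drv = spec.drive
    if drv.mode == "shared":
        p_new = drv.p_connect / factor
        q_scale = 1.0
        if p_new > 1.0:
            q_scale = p_new
            warnings.warn("drive p_connect caps at 1; boosting Q_Ext", stacklevel=2)
            p_new = 1.0
        q_new = (
            {k: v * q_scale for k, v in drv.q.items()}
            if isinstance(drv.q, dict) else drv.q * q_scale
        )
        drv = replace(
            drv, n_sources=max(1, int(round(drv.n_sources * factor))),
            p_connect=p_new, q=q_new,
        )
    return replace(
        spec, populations=tuple(pops), groups=tuple(groups), drive=drv,
        scale=spec.scale * factor,
    )


# ---------------------------------------------------------------------------
# Realization: sampled wiring + per-neuron parameter arrays
# ---------------------------------------------------------------------------

def _sample_bipartite(rng, n_src, tgt_ids, p, forbid_diagonal_offset=None,
                      chunk_budget=20_000_000):
    """Sample Bernoulli(p) edges from n_src sources onto the id array
    ``tgt_ids``; returns (src_idx, tgt_global) arrays.

    ``forbid_diagonal_offset``: when source k corresponds to global neuron
    ``offset + k`` inside the target population, autapses are excluded.
    """
    n_tgt = tgt_ids.size
    if p <= 0.0 or n_tgt == 0 or n_src == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    srcs, tgts = [], []
    chunk = max(1, chunk_budget // max(1, n_tgt))
    for start in range(0, n_src, chunk):
        stop = min(n_src, start + chunk)
        mask = rng.random((stop - start, n_tgt)) < p
        if forbid_diagonal_offset is not None:
            rows = np.arange(start, stop) - forbid_diagonal_offset
            ok = (rows >= 0) & (rows < n_tgt)
            mask[np.nonzero(ok)[0], rows[ok]] = False
        s, t = np.nonzero(mask)
        srcs.append(s + start)
        tgts.append(tgt_ids[t])
    return np.concatenate(srcs), np.concatenate(tgts)


@dataclass
class RealizedNetwork:
    """A NetworkSpec with sampled wiring and flattened parameter arrays."""

    spec: NetworkSpec
    n_neurons: int
    pop_slices: dict
    neuron_arrays: dict  # per-neuron f8 arrays for the kernel (dt-free part)
    conn_indptr: np.ndarray
    conn_targets: np.ndarray
    conn_weights: np.ndarray
    conn_is_inh: np.ndarray
    drv_indptr: np.ndarray  # train -> target CSR (shared) or identity (independent)
    drv_targets: np.ndarray
    qext: np.ndarray  # nS per target neuron
    seed: int

    def in_degree(self, source: str, target: str) -> np.ndarray:
        """Per-neuron count of connections from ``source`` onto ``target``."""
        ssl, tsl = self.pop_slices[source], self.pop_slices[target]
        counts = np.zeros(self.n_neurons, dtype=int)
        for i in range(ssl.start, ssl.stop):
            e0, e1 = self.conn_indptr[i], self.conn_indptr[i + 1]
            tg = self.conn_targets[e0:e1]
            sel = tg[(tg >= tsl.start) & (tg < tsl.stop)]
            np.add.at(counts, sel, 1)
        return counts[tsl]


def realize_network(spec: NetworkSpec, seed: int = 0) -> RealizedNetwork:
    """Sample the random wiring of ``spec`` (independent Bernoulli per
    directed pair, no autapses) and flatten the cell parameters."""
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC0]))
    slices = spec.population_slices()
    n = spec.n_neurons

    # per-neuron parameter arrays
    fields = ["c_m", "g_l", "e_l", "v_th", "delta", "a", "b", "tau_w",
              "v_reset", "e_e", "e_i"]
    arrays = {f: np.empty(n) for f in fields}
    arrays["v_cut"] = np.empty(n)
    arrays["t_ref"] = np.empty(n)
    for p in spec.populations:
        sl = slices[p.name]
        for f in fields:
            arrays[f][sl] = getattr(p.params, f)
        arrays["v_cut"][sl] = p.params.cut_voltage
        arrays["t_ref"][sl] = p.params.t_ref

    # recurrent wiring
    all_src, all_tgt, all_w, all_inh = [], [], [], []
    for g in spec.groups:
        ssl, tsl = slices[g.source], slices[g.target]
        tgt_ids = np.arange(tsl.start, tsl.stop, dtype=np.int64)
        diag = (tsl.start - ssl.start) if g.source == g.target else None
        s, t = _sample_bipartite(
            rng, ssl.stop - ssl.start, tgt_ids, g.p_connect,
            forbid_diagonal_offset=0 if diag == 0 else None,
        )
        all_src.append(s + ssl.start)
        all_tgt.append(t)
        all_w.append(np.full(s.size, g.q))
        all_inh.append(np.full(s.size, g.sign == "I", dtype=np.bool_))
    src = np.concatenate(all_src) if all_src else np.empty(0, np.int64)
    tgt = np.concatenate(all_tgt) if all_tgt else np.empty(0, np.int64)
    wts = np.concatenate(all_w) if all_w else np.empty(0)
    inh = np.concatenate(all_inh) if all_inh else np.empty(0, np.bool_)
    order = np.argsort(src, kind="stable")
    src, tgt, wts, inh = src[order], tgt[order], wts[order], inh[order]
    indptr = np.zeros(n + 1, dtype=np.int64)
    np.add.at(indptr, src + 1, 1)
    indptr = np.cumsum(indptr)

    # drive wiring and per-target strength
    qext = np.empty(n)
    q = spec.drive.q
    for p in spec.populations:
        qext[slices[p.name]] = q[p.name] if isinstance(q, dict) else q
    if spec.drive.mode == "shared":
        tgt_ids = np.arange(n, dtype=np.int64)
        dsrc, dtgt = _sample_bipartite(
            rng, spec.drive.n_sources, tgt_ids, spec.drive.p_connect
        )
        dorder = np.argsort(dsrc, kind="stable")
        dsrc, dtgt = dsrc[dorder], dtgt[dorder]
        dindptr = np.zeros(spec.drive.n_sources + 1, dtype=np.int64)
        np.add.at(dindptr, dsrc + 1, 1)
        dindptr = np.cumsum(dindptr)
    else:  # independent: source k targets exactly neuron k
        dindptr = np.arange(n + 1, dtype=np.int64)
        dtgt = np.arange(n, dtype=np.int64)

    return RealizedNetwork(
        spec=spec, n_neurons=n, pop_slices=slices, neuron_arrays=arrays,
        conn_indptr=indptr, conn_targets=tgt, conn_weights=wts,
        conn_is_inh=inh, drv_indptr=dindptr, drv_targets=dtgt, qext=qext,
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# External drive event sampling
# ---------------------------------------------------------------------------

@dataclass
class DriveEvents:
    """Source-train spike events on the simulation step grid."""

    steps: np.ndarray  # sorted step indices (int64)
    sources: np.ndarray  # train ids (int64)
    n_steps: int

    def step_indptr(self) -> np.ndarray:
        counts = np.bincount(self.steps, minlength=self.n_steps)
        return np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)

    def merged_with(self, other: "DriveEvents") -> "DriveEvents":
        steps = np.concatenate([self.steps, other.steps])
        sources = np.concatenate([self.sources, other.sources])
        order = np.argsort(steps, kind="stable")
        return DriveEvents(steps[order], sources[order], self.n_steps)


def generate_drive(
    net: RealizedNetwork,
    duration: float,
    dt: float = 0.1,
    seed: int = 0,
    profile: Optional[RateProfile] = None,
) -> DriveEvents:
    """Sample the external Poissonian drive over ``duration`` ms.

    The profile gives the per-train rate in Hz (clipped at 0); in shared
    mode the superposed event stream across the ``n_sources`` iid trains is
    sampled per step and events are attributed to trains uniformly (exact
    for iid trains). In independent mode each neuron is its own source with
    rate ``n_per_neuron`` times the profile.
    """
    if duration <= 0:
        raise ConfigError("duration must be positive")
    drv = net.spec.drive
    prof = profile if profile is not None else drv.rate_profile()
    n_steps = int(round(duration / dt))
    t = (np.arange(n_steps) + 0.5) * dt
    rates = np.clip(np.asarray(prof(t), dtype=float), 0.0, None)  # Hz per train
    if drv.mode == "shared":
        n_src = drv.n_sources
        lam = n_src * rates * dt * 1e-3
    else:
        n_src = net.n_neurons
        lam = n_src * drv.n_per_neuron * rates * dt * 1e-3
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xD1]))
    counts = rng.poisson(lam)
    total = int(counts.sum())
    steps = np.repeat(np.arange(n_steps, dtype=np.int64), counts)
    sources = rng.integers(0, n_src, size=total, dtype=np.int64)
    return DriveEvents(steps=steps, sources=sources, n_steps=n_steps)


def events_per_target(net: RealizedNetwork, events: DriveEvents,
                      dt: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
    """Expand drive events through the wiring: (times_ms, target_ids).

    Intended for inspection/testing at small scale — the simulation kernel
    performs this expansion on the fly.
    """
    deg = np.diff(net.drv_indptr)
    ev_deg = deg[events.sources]
    total = int(ev_deg.sum())
    if total == 0:
        return np.empty(0), np.empty(0, np.int64)
    out_ptr = np.concatenate([[0], np.cumsum(ev_deg)])
    pos = (np.arange(total) - np.repeat(out_ptr[:-1], ev_deg)
           + np.repeat(net.drv_indptr[events.sources], ev_deg))
    targets = net.drv_targets[pos]
    times = np.repeat(events.steps, ev_deg) * dt
    return times, targets


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

@dataclass
class SimResult:
    """Spike output (plus optional recorded traces) of one network run."""

    spike_times: np.ndarray  # ms, sorted
    spike_ids: np.ndarray
    n_neurons: int
    duration: float  # ms
    dt: float
    populations: dict  # name -> slice of global ids
    recorded: Optional[dict] = None  # {'t','ids','v','g_e','g_i'}
    meta: dict = field(default_factory=dict)

    def spike_trains(self) -> list[np.ndarray]:
        """Per-neuron sorted spike-time arrays (ms)."""
        order = np.argsort(self.spike_ids, kind="stable")
        ids, times = self.spike_ids[order], self.spike_times[order]
        bounds = np.searchsorted(ids, np.arange(self.n_neurons + 1))
        return [times[bounds[i]:bounds[i + 1]] for i in range(self.n_neurons)]

    def population_rate(self, bin_ms: float = 1.0, pop: Optional[str] = None,
                        t_start: float = 0.0, t_stop: Optional[float] = None
                        ) -> tuple[np.ndarray, np.ndarray]:
        """Population rate: total spike count per time bin / bin duration.

        Returns (bin centers ms, rate in spikes/s summed over the selected
        population).
        """
        t_stop = self.duration if t_stop is None else t_stop
        times, ids = self.spike_times, self.spike_ids
        if pop is not None:
            sl = self.populations[pop]
            m = (ids >= sl.start) & (ids < sl.stop)
            times = times[m]
        edges = np.arange(t_start, t_stop + bin_ms, bin_ms)
        counts, _ = np.histogram(times, bins=edges)
        centers = 0.5 * (edges[:-1] + edges[1:])
        return centers, counts / (bin_ms * 1e-3)

    def mean_rates(self, t_start: float = 0.0) -> np.ndarray:
        """Per-neuron mean firing rate in Hz over [t_start, duration]."""
        m = self.spike_times >= t_start
        counts = np.bincount(self.spike_ids[m], minlength=self.n_neurons)
        return counts / ((self.duration - t_start) * 1e-3)

    def currents(self) -> tuple[np.ndarray, np.ndarray]:
        """Recorded synaptic currents (I_exc, I_inh) in pA per trace.

        I_exc = g_E (V - E_E) is negative (inward), I_inh = g_I (V - E_I)
        positive at typical potentials.
        """
        if self.recorded is None:
            raise ValueError("no traces recorded; pass record=... to simulate")
        r = self.recorded
        return (r["g_e"] * (r["v"] - r["e_e"]), r["g_i"] * (r["v"] - r["e_i"]))


def simulate_network(
    network: Union[NetworkSpec, RealizedNetwork],
    duration: float,
    dt: float = 0.1,
    seed: int = 0,
    record: Optional[Union[int, Sequence[int]]] = None,
    record_stride: int = 10,
    drive_events: Optional[DriveEvents] = None,
    drive_profile: Optional[RateProfile] = None,
    i_ext: Optional[np.ndarray] = None,
    i_ext_gain: Optional[np.ndarray] = None,
    init: str = "rest",
) -> SimResult:
    """Simulate a network for ``duration`` ms.

    Parameters
    ----------
    network
        A NetworkSpec (wiring sampled from ``seed``) or a pre-realized
        network (reused across paired runs).
    record
        Neuron ids (or an int: the first k ids) whose V/g_E/g_I traces are
        kept, decimated by ``record_stride`` steps.
    drive_events
        Pre-sampled drive (e.g. baseline + stimulus merged); defaults to
        sampling the spec's drive profile with a sub-seed of ``seed``.
    drive_profile
        Alternative rate profile used when sampling the drive here.
    i_ext
        Common external current trace in nA, one value per step (or a
        scalar), scaled per neuron by ``i_ext_gain`` (default 1).

    Determinism: identical arguments (and seeds) give identical spike
    rasters.
    """
    if duration <= 0:
        raise ConfigError("duration must be positive")
    if dt <= 0:
        raise ConfigError("dt must be positive")
    net = network if isinstance(network, RealizedNetwork) else realize_network(network, seed)
    spec = net.spec
    delay = spec.groups[0].delay if spec.groups else 1.5
    delay_steps_f = delay / dt
    if abs(delay_steps_f - round(delay_steps_f)) > 1e-9:
        raise ConfigError(
            f"synaptic delay {delay} ms is not an integer multiple of dt={dt} ms"
        )
    delay_steps = int(round(delay_steps_f))
    n_steps = int(round(duration / dt))
    n = net.n_neurons

    na = dict(net.neuron_arrays)
    na["t_ref_steps"] = np.round(na.pop("t_ref") / dt).astype(np.int64)
    na["decay_e"] = np.full(n, np.exp(-dt / spec.tau_e))
    na["decay_i"] = np.full(n, np.exp(-dt / spec.tau_i))

    if drive_events is None:
        drive_events = generate_drive(net, duration, dt, seed, drive_profile)
    ev_indptr = drive_events.step_indptr()
    if ev_indptr.size != n_steps + 1:
        raise ConfigError("drive events were sampled for a different duration/dt")

    if i_ext is None:
        iext_trace = np.zeros(n_steps)
    else:
        iext_trace = np.broadcast_to(np.asarray(i_ext, float), (n_steps,)).copy()
        iext_trace = iext_trace * 1e3  # nA -> pA
    gain = np.ones(n) if i_ext_gain is None else np.asarray(i_ext_gain, float)

    if record is None:
        rec_idx = np.empty(0, dtype=np.int64)
        rec_stride = 0
    else:
        rec_idx = (np.arange(int(record), dtype=np.int64)
                   if np.isscalar(record) else np.asarray(record, dtype=np.int64))
        rec_stride = int(record_stride)

    # "rest": V ~ E_L + U[0, 5) mV. "spread": V ~ U[E_L, V_th) — more initial
    # activity; in bistable regimes the two can select different attractors.
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xA3]))
    if init == "rest":
        v0 = na["e_l"] + rng.random(n) * 5.0
    elif init == "spread":
        v0 = na["e_l"] + rng.random(n) * (na["v_th"] - na["e_l"])
    else:
        raise ConfigError("init must be 'rest' or 'spread'")
    state = {
        "V": v0, "w": np.zeros(n), "gE": np.zeros(n), "gI": np.zeros(n),
        "ref_left": np.zeros(n, dtype=np.int64),
    }

    expected_rate_hz = 30.0  # head-room guess; buffer grows if exceeded
    cap = max(100_000, int(n * duration * 1e-3 * expected_rate_hz))
    spike_step, spike_id, recV, recGE, recGI, _ = run_network(
        n_steps, dt, na, state,
        (net.conn_indptr, net.conn_targets, net.conn_weights, net.conn_is_inh),
        delay_steps,
        (ev_indptr, drive_events.sources, net.drv_indptr, net.drv_targets),
        net.qext, iext_trace, gain, rec_idx, rec_stride, cap,
    )

    recorded = None
    if rec_idx.size:
        n_rows = recV.shape[0]
        recorded = {
            "t": (np.arange(n_rows) * rec_stride + 1) * dt,
            "ids": rec_idx,
            "v": recV, "g_e": recGE, "g_i": recGI,
            "e_e": na["e_e"][rec_idx], "e_i": na["e_i"][rec_idx],
        }
    return SimResult(
        spike_times=(spike_step + 1) * dt,
        spike_ids=spike_id,
        n_neurons=n,
        duration=duration,
        dt=dt,
        populations=net.pop_slices,
        recorded=recorded,
        meta={
            "network": spec.name, "state": spec.state, "scale": spec.scale,
            "seed": int(seed), "dt": dt, "duration": duration,
            "wiring_seed": net.seed,
        },
    )
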