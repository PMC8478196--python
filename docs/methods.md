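# Methods

## Neuron model

All units are adaptive exponential integrate-and-fire (Adex) neurons with
conductance-based synapses:

    C dV/dt   = -g_L (V - E_L) + g_L Δ exp((V - V_T)/Δ) - w
                - g_E (V - E_E) - g_I (V - E_I) + I_ext
    τ_w dw/dt = a (V - E_L) - w
    τ_x dg_x/dt = -g_x,   g_x → g_x + Q_x at each presynaptic spike (x ∈ {E, I})

A spike is registered when V reaches the detection voltage
V_cut = V_T + 5Δ; V is then reset to V_reset, w is incremented by b, and
both V and w are held for the refractory period T_ref while the
conductances keep decaying and accumulating input. Integration is forward
Euler at dt = 0.1 ms for V and w; conductances decay by the exact
exponential factor per step (a forward-Euler mode exists for parity
experiments).

Three cell classes are provided: regular-spiking excitatory cells (RS;
adapting, a = 4 nS, b = 20 pA), fast-spiking inhibitory cells (FS; a = b =
0) and chattering excitatory cells (CH; E_L = -58 mV, a = 80 nS, τ_w = 50
ms, T_ref = 1 ms). Shared constants: C = 150 pF, g_L = 10 nS, E_E = 0 mV,
E_I = -80 mV, V_reset = -65 mV, Δ = 2 mV (RS) or 0.5 mV (FS/CH).

### The threshold convention

This package takes the exponential threshold V_T = -50 mV for **every**
cell class, and reads the conventional per-class "threshold" figures (-40
mV for RS, -47.5 mV for FS and CH) as the spike-detection voltages — and
indeed each equals V_T + 5Δ exactly for its cell class, so the default
detection rule reproduces them with no extra parameter. This choice is
load-bearing and was settled by falsification rather than taste. Reading
-40 mV as the RS exponential threshold itself places the RS population
roughly 4 standard deviations of its membrane-potential distribution below
threshold in every balanced state of every network in this family: the
excitatory population goes silent (mean rates below 0.05 Hz), no RS cell
ever reaches the 5-spike minimum needed by the phase-locking statistics,
the interneuron-gamma pacemaker subpopulation is starved of its excitatory
feed (pushing that network's rhythm near 100 Hz), and all collective
rhythms become weak and spectrally unstable. With V_T = -50 mV the four
architectures reproduce their intended behaviour at full size (see the
frequencies below) with irregular, low-rate, fluctuation-driven firing in
all populations. Detection at V_T itself (threshold-touch spiking) is also
supported via `AdexParams.with_cut`, but is not the default: during a
synchronized volley it commits every neuron that grazes threshold before
the loop's 1.5 ms inhibitory feedback can arrive, which pushes the
excitatory-inhibitory network into a saturated spike-to-spike attractor.

## Network architectures

All five networks use independent-Bernoulli random connectivity (no
autapses), a uniform 1.5 ms synaptic delay, and an external drive of
independent excitatory Poissonian spike trains (20000 trains wired to each
neuron with probability 2%, i.e. 400 trains per neuron, except the GAMMA
network where each neuron receives its own 400-train superposition).

| network | populations | p | Q_E / Q_I (nS) | τ_E / τ_I (ms) | drive (gamma / AI) |
|---|---|---|---|---|---|
| PING | 20000 RS + 5000 FS | 2% | 5 / 3.34 | 1.0 / 7.5 | 3 / 2 Hz × 4 nS |
| AI | 20000 RS + 5000 FS | 2% | 1 / 5 | 5 / 5 | 3 / 2 Hz × 1 nS |
| GAMMA | 1000 FS | 60% | – / 5 | 5 / 5 | 400 × 5 Hz × 1 nS |
| ING | AI core (20000 RS + 4000 FS) + 1000 FS2 | 2% core; FS2↔RS 15%, FS2→FS 15%, FS→FS2 3%, FS2↔FS2 60% | 1 / 5 | 5 / 5 | 3 / 2 Hz × 0.9 nS |
| CHING | 19000 RS + 1000 CH + 5000 FS | 2% | 1 / 7 (FS→RS/CH), 5 (FS→FS) | 5 / 5 | 2 / 1 Hz × 1 nS (0.75 on FS) |

Two parameter choices deserve comment. First, the PING excitatory time
constant is 1.0 ms: with the synaptic-gain normalisation used for the
time-constant parameter sweeps (Q·τ held at the 1 nS × 5 ms reference),
Q_E = 5 nS corresponds to τ_E = 1.0 ms, and only this value yields a
~40 Hz pyramidal-interneuron rhythm. Second, the CH spike-triggered
adaptation is b = 150 pA (a sub-picoampere value would be
indistinguishable from zero and make the parameter pointless).

Initial conditions are V ~ E_L + U[0, 5) mV, w = g = 0; the first 200 ms
are discarded from analyses. A spread-to-threshold initialisation
(`init="spread"`) is available but not default: it synchronises the first
volley and can trap the excitatory-inhibitory loop in its saturated
attractor.

With these settings the dominant gamma-band population-rate frequencies
at full reference size (five-seed spectrum averages; see the measurement
convention below) are ≈74 Hz for the GAMMA network (reference ≈70; its
spectrum is a broad 70–100 Hz band, so single-realisation peaks scatter
over roughly 71–83 Hz), ≈53 Hz for ING (reference ≈55), ≈37 Hz for PING
(≈40) and ≈37–41 Hz for CHING (≈40), with mean rates of ~1–2 Hz (RS),
~3–8 Hz (FS/FS2) and ~4 Hz (CH): the fluctuation-driven, firing-rate
regime, with unit rates far below the population frequency.

### Down-scaling

`scale_network(spec, factor)` multiplies population sizes by the factor
and connection probabilities by its inverse, preserving expected
in-degrees. When the boosted probability exceeds 1 it is capped and Q is
raised to preserve in-degree × Q (total pathway gain) — unavoidable for
the 60%-coupled FS2 block below factor ~0.6. Scaled networks are used in
the cheap protocol tests; note that the correlated part of the shared
drive grows as 1/factor and the capped dense blocks change their quantal
structure, so scaled rhythm frequencies can sit 10–25% below the full-size
ones (the scaled ING reads ~42 Hz versus ~53–58 Hz at full size). The
headline frequencies are therefore always computed at full size, which the
compiled engine simulates at roughly 10 s of model time per wall-clock
minute for the 25000-neuron networks on one core.

## LFP model

Each spike adds a spatiotemporal Gaussian kernel to the electrode signal:
amplitude A0 exp(-d/λ) with distance d to the electrode, width σ, and
peak delay d0 + d/v_a; excitatory and inhibitory neurons carry separate
kernels of opposite polarity. Neurons are scattered uniformly on a square
sheet (default 0.4 mm side) with the electrode at the centre. The kernel
constants are configuration values with order-of-magnitude defaults
(|A0| 0.15–0.25 μV, λ = 0.2 mm, σ = 1.5–2 ms, v_a = 0.2 mm/ms); all
burst detection downstream thresholds the filtered-LFP envelope in SD
units and is insensitive to them. Kernels are rasterised over ±5σ
(truncation error < 4·10⁻⁶ of the peak).

## Rhythm detection and unit statistics

The LFP (1 kHz) is band-passed (default 30–50 Hz) with a Kaiser-window FIR
filter (60 dB stop-band, 5 Hz transition), group delay compensated by
shifting; the Hilbert analytic signal supplies envelope and phase. Gamma
bursts are maximal intervals with envelope above its global mean + k·SD
(k = 1 for simulated signals, 2 for recordings) lasting at least 3 cycles
of the band centre (75 ms for 30–50 Hz). Burst boundaries are the
threshold crossings themselves, not extended down to the mean.

Per neuron and segment: spikes inside bursts receive the instantaneous
phase; circular uniformity is tested with the Rayleigh statistic
Z = n R̄², p = exp(√(1+4n+4(n²−nZ)) − (1+2n)), Bonferroni-corrected at
family α = 0.01 over the neurons tested in the segment; the preferred
phase is the von Mises location (= circular mean, with the standard
R̄ → κ maximum-likelihood inversion for the concentration). The
firing-rate change test compares the observed burst-time spike count with
the 95% Poisson quantiles for λ = f_out·T_γ, where f_out is the
outside-burst rate; both an upper (increase) and symmetric lower
(decrease) tail are evaluated. Neurons with fewer than 5 burst spikes,
f_out < 0.1 Hz, or under 1 s of gamma on their electrode are labelled
inconclusive. Note the null rate is a plug-in estimate: its calibration to
the nominal 5% requires the outside-burst time to dominate the burst time,
which holds for recording-like proportions (minutes outside, ~13 s
inside) but not for short toy segments.

## Stimulation protocols

*Integration mode*: Gaussian fluctuations of the drive rate (SD 50 ms)
and responsiveness R = (N^S − N)/(T·N_n) over T = 0.5 s, from paired runs
sharing wiring and baseline drive events and differing only by the extra
stimulus events (superposition of Poisson processes — an exact paired
design). Gamma-state trials embed the window in a drive fluctuation
(100 ms linear ramps to the network's gamma drive). *Coincidence
detection*: 1 ms-SD Gaussian impulses at varying times; R over one gamma
cycle, binned by the phase at the impulse peak, read from the paired
baseline run's band-passed signal (gamma state), from the injected
sinusoidal current (AI + current control), or drawn uniformly (plain AI).
*Resonance*: sinusoidally modulated drive (5–100 Hz), spikes accumulated
in 25 equal phase bins of the drive cycle and normalised by the map's
grand mean (exactly 1 by construction).

Supporting metrics: the synchrony index is the zero-lag value of a damped
cosine A e^{−λt} cos(2πνt) fitted to the normalised population-rate
autocorrelation (1 ms bins, lags 1–200 ms); "no oscillation" is declared
when λ > 100 s⁻¹, when A is below the autocorrelation noise floor
(≈4/√n), or when the fitted ν is below 5 Hz (a zero-frequency "cosine" is
rate drift, not a rhythm). Membrane synchrony is
χ = √(Var_t V̄ / mean_i Var_t V_i). The excitation-inhibition balance is
⟨|⟨I_exc⟩_N| / |⟨I_inh⟩_N|⟩_t from recorded conductance traces.

## Synthetic fixtures

`generate_fixture` emulates the *structure* of a resting multielectrode
recording: segments of unit-variance white-noise LFP with embedded
amplitude-modulated 40 Hz tones (bursts), and spike trains with controlled
ground truth — outside bursts homogeneous Poisson at f_out; inside bursts
an inhomogeneous Poisson process whose intensity is a von Mises density of
the tone phase (concentration κ, location μ) with mean rate f_in. It does
**not** emulate spike waveforms, electrode noise spectra (1/f), burst
frequency jitter, or cross-neuron correlations; passing the calibration
and recovery tests therefore demonstrates the correctness and statistical
calibration of the analysis chain, not its robustness to real-data
artefacts.

## Numerical choices and degenerate inputs

dt = 0.1 ms reference (halving it changes a driven cell's 1 s spike count
by ≤ 1); synaptic delays must be integer multiples of dt (no silent
rounding); drive events are sampled per step as Poisson counts and
attributed to trains uniformly (exact for iid trains); spike buffers grow
geometrically on overflow; Rayleigh on an empty sample, zero-variance
membrane traces, vanishing inhibitory current, and bands outside Nyquist
all raise explicit errors; κ is capped at 10⁶ for degenerate all-equal
phase samples; sub-3-cycle envelope excursions are never bursts.

## Frequency measurement convention

The headline "dominant oscillation frequency" of a network is the maximum
of the Welch power spectrum of its population rate (1 ms bins, burn-in
discarded) within the gamma band, 30–90 Hz, with spectra averaged over a
few independent realisations before the peak is taken. The band
restriction matters for the PING network, whose adapting RS population
also sustains a slow (~25 Hz) rate fluctuation that competes with the
gamma bump in long unrestricted periodograms.

## Known limitations

* The GAMMA-network spectrum is a broad 70–100 Hz band: averaged peaks
  read ~2–18% above the reference ≈70 Hz depending on the realisations
  pooled; the other headline frequencies land within a few percent of
  their reference values.
* The phase ordering of cell classes within the gamma cycle reproduces
  the reference pattern for ING (FS-class firing earlier in the cycle
  than RS) but not for CHING (here CH pacemakers fire first, then RS,
  with FS last) or PING (here FS slightly precede RS); the discrepancy is
  deterministic across seeds and scales. In this implementation the
  excitatory and inhibitory populations of PING receive identical
  external drive, which by the standard conductance-network argument
  predicts inhibition-led cycles — the reference E-leads-I order would
  require an input asymmetry favouring the excitatory cells that the
  stated parameters do not encode.
* In the AI control the balance ratio ⟨I_exc⟩/⟨I_inh⟩ evaluates to ~1.3–1.4
  (the external drive enters the excitatory conductance); the state is
  nonetheless asynchronous by the synchrony-index criterion, which is the
  classifier used throughout.
* Scaled-down networks shift rhythm frequencies 10–25% downward (see
  Down-scaling); frequency claims should always be checked at full size.
* The phase-dependent responsiveness protocol at publication scale
  (120 positions × 100 seeds) is cluster-scale; the implementation is
  exact but the shipped defaults are desk-scale.
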