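"""Per-neuron statistics of gamma participation.

Two behaviours are tested per neuron, per data segment, always against the
gamma rhythm of the neuron's own electrode:

* **phase-locking** — circular non-uniformity of the spike-phase
  distribution inside gamma bursts, by a Bonferroni-corrected Rayleigh
  test at family level alpha = 0.01; the preferred phase comes from a von
  Mises fit (its location equals the circular mean);
* **firing-rate change** — whether the spike count observed inside bursts
  exceeds (falls below) the upper (lower) 95% Poisson quantile expected
  from the neuron's outside-burst rate.

Neurons with fewer than 5 spikes inside bursts (for phase-locking), an
outside rate below 0.1 Hz (for rate change), or less than 1 s of gamma on
their electrode are labelled *inconclusive* rather than tested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sst

__all__ = [
    "rayleigh_test", "fit_von_mises", "classify_phase_locking",
    "classify_rate_change", "consistency_analysis",
    "PhaseLockResult", "RateChangeResult",
]

MIN_SPIKES_IN_BURSTS = 5
MIN_GAMMA_SECONDS = 1.0
MIN_RATE_HZ = 0.1
KAPPA_MAX = 1e6


def rayleigh_test(phases: np.ndarray) -> tuple[float, float, float, float]:
    """Rayleigh test of circular uniformity.

    Returns (Z, p, mean_resultant_length, circular_mean) where
    Z = n * Rbar^2 and p uses the standard correction

        p = exp( sqrt(1 + 4 n + 4 (n^2 - n Z)) - (1 + 2 n) ),

    accurate for small samples and asymptotically exp(-Z).
    """
    phases = np.asarray(phases, dtype=float)
    n = phases.size
    if n == 0:
        raise ValueError("rayleigh_test needs at least one phase")
    c = np.exp(1j * phases).sum()
    rbar = np.abs(c) / n
    z = n * rbar**2
    arg = 1.0 + 4.0 * n + 4.0 * (n**2 - n * z)
    p = float(np.exp(np.sqrt(max(arg, 0.0)) - (1.0 + 2.0 * n)))
    return float(z), min(p, 1.0), float(rbar), float(np.angle(c))


def _kappa_from_rbar(rbar: float, n: int) -> float:
    # Best & Fisher maximum-likelihood inversion of A(kappa) = Rbar.
    if rbar >= 1.0:
        return KAPPA_MAX
    if rbar < 0.53:
        k = 2 * rbar + rbar**3 + 5 * rbar**5 / 6
    elif rbar < 0.85:
        k = -0.4 + 1.39 * rbar + 0.43 / (1 - rbar)
    else:
        k = 1.0 / (rbar**3 - 4 * rbar**2 + 3 * rbar)
    # small-sample bias correction
    if n < 16 and k > 0:
        k = max(k - 2.0 / (n * k), 0.0) if k < 2 else k * (n - 1) ** 3 / (n**3 + n)
    return float(min(k, KAPPA_MAX))


def fit_von_mises(phases: np.ndarray) -> tuple[float, float]:
    """Maximum-likelihood von Mises fit: (mu, kappa).

    mu is the circular mean; kappa from the standard Rbar inversion,
    capped at 1e6 for degenerate (all-identical) samples.
    """
    phases = np.asarray(phases, dtype=float)
    if phases.size < 2:
        raise ValueError("need at least two phases to fit")
    _, _, rbar, mu = rayleigh_test(phases)
    return mu, _kappa_from_rbar(rbar, phases.size)


@dataclass(frozen=True)
class PhaseLockResult:
    neuron_id: int
    n_spikes_in_bursts: int
    z: float
    p: float
    z_critical: float
    preferred_phase: float
    mean_resultant_length: float
    label: str  # locked | not_locked | inconclusive


def classify_phase_locking(
    phases_per_neuron: dict[int, np.ndarray],
    gamma_time_s: float,
    alpha: float = 0.01,
    n_tested: int | None = None,
) -> list[PhaseLockResult]:
    """Label each neuron locked / not_locked / inconclusive.

    ``gamma_time_s``: total burst time on the neuron's electrode (s); a
    scalar here because callers group neurons by electrode.
    ``n_tested``: Bonferroni family size; defaults to the number of
    neurons passing the inconclusive screens.
    """
    testable = [i for i, ph in phases_per_neuron.items()
                if len(ph) >= MIN_SPIKES_IN_BURSTS and gamma_time_s >= MIN_GAMMA_SECONDS]
    m = n_tested if n_tested is not None else max(len(testable), 1)
    alpha_corr = alpha / m
    out = []
    for i, ph in sorted(phases_per_neuron.items()):
        n = len(ph)
        if i not in testable:
            out.append(PhaseLockResult(i, n, np.nan, np.nan, np.nan, np.nan,
                                       np.nan, "inconclusive"))
            continue
        z, p, rbar, _ = rayleigh_test(ph)
        mu, _ = fit_von_mises(ph)
        # critical Z at the corrected level (asymptotic inversion)
        z_c = -np.log(alpha_corr)
        label = "locked" if p < alpha_corr else "not_locked"
        out.append(PhaseLockResult(i, n, z, p, z_c, mu, rbar, label))
    return out


@dataclass(frozen=True)
class RateChangeResult:
    neuron_id: int
    f_out: float  # Hz outside bursts
    f_gamma: float  # Hz inside bursts
    t_gamma_s: float
    n_observed: int
    n_critical: int
    label: str  # increase | decrease | no_change | inconclusive


def classify_rate_change(
    spike_times_ms: np.ndarray,
    bursts,
    segment_duration_s: float,
    neuron_id: int = 0,
    confidence: float = 0.95,
) -> RateChangeResult:
    """Poisson test of the firing-rate change inside gamma bursts.

    The outside-burst rate f_out sets the null expectation
    lambda = f_out * T_gamma for the burst-time spike count; the neuron
    increases its firing if the observed count exceeds the ``confidence``
    Poisson quantile and decreases if it falls below the symmetric
    lower-tail quantile.
    """
    spike_times_ms = np.asarray(spike_times_ms, float)
    t_gamma = sum(b.duration for b in bursts) * 1e-3  # s
    in_burst = np.zeros(spike_times_ms.size, dtype=bool)
    for b in bursts:
        in_burst |= (spike_times_ms >= b.start) & (spike_times_ms <= b.end)
    n_in = int(in_burst.sum())
    n_out = int(spike_times_ms.size - n_in)
    t_out = segment_duration_s - t_gamma
    f_out = n_out / t_out if t_out > 0 else np.nan
    f_gamma = n_in / t_gamma if t_gamma > 0 else np.nan
    if t_gamma < MIN_GAMMA_SECONDS or not np.isfinite(f_out) or f_out < MIN_RATE_HZ:
        return RateChangeResult(neuron_id, f_out, f_gamma, t_gamma, n_in, -1,
                                "inconclusive")
    lam = f_out * t_gamma
    n_c = int(sst.poisson.ppf(confidence, lam))
    n_lo = int(sst.poisson.ppf(1.0 - confidence, lam))
    if n_in > n_c:
        label = "increase"
    elif n_in < n_lo:
        label = "decrease"
    else:
        label = "no_change"
    return RateChangeResult(neuron_id, f_out, f_gamma, t_gamma, n_in, n_c, label)


def consistency_analysis(labels_by_segment: list[dict[int, str]],
                         positive: str = "locked") -> pd.DataFrame:
    """Cross-segment behaviour consistency per neuron.

    ``labels_by_segment``: one {neuron_id: label} mapping per segment (all
    segments must cover the same ids). Returns a tidy frame with one row
    per neuron: counts of the positive label, of inconclusive segments,
    and the per-segment labels. The distribution of ``n_positive`` over
    neurons is the stacked-bar consistency histogram.
    """
    if not labels_by_segment:
        raise ValueError("need at least one segment")
    ids = sorted(labels_by_segment[0])
    for seg in labels_by_segment[1:]:
        if sorted(seg) != ids:
            raise ValueError("segments cover different neuron ids")
    rows = []
    for i in ids:
        labels = [seg[i] for seg in labels_by_segment]
        rows.append({
            "neuron_id": i,
            "n_positive": sum(lb == positive for lb in labels),
            "n_inconclusive": sum(lb == "inconclusive" for lb in labels),
            "labels": labels,
        })
    return pd.DataFrame(rows)
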