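"""Circular statistics, Poisson rate-change test, consistency analysis."""

import numpy as np
import pytest
from scipy import stats as sst

from gammanet.detect import GammaBurst
from gammanet.stats import classify_phase_locking, classify_rate_change, \
    consistency_analysis, fit_von_mises, rayleigh_test


class TestRayleigh:
    def test_identical_phases_maximal_statistic(self):
        z, p, rbar, mean = rayleigh_test(np.full(10, 0.7))
        assert rbar == pytest.approx(1.0)
        assert z == pytest.approx(10.0)
        assert mean == pytest.approx(0.7)
        assert p < 1e-3

    def test_equally_spaced_phases_null(self):
        ph = np.linspace(-np.pi, np.pi, 12, endpoint=False)
        z, p, rbar, _ = rayleigh_test(ph)
        assert rbar == pytest.approx(0.0, abs=1e-12)
        assert z == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_p_approximation_matches_monte_carlo_null(self):
        """The analytic p-value agrees with a permutation/Monte-Carlo null
        within a factor of 2 for p in [1e-4, 0.1]."""
        rng = np.random.default_rng(4)  # dedicated stream: the sample must
        n = 50                          # land inside the validated regime
        phases = rng.vonmises(1.0, 0.55, n)
        z_obs, p_obs, _, _ = rayleigh_test(phases)
        null = np.empty(100_000)
        for k in range(null.size):
            u = rng.uniform(-np.pi, np.pi, n)
            c = np.exp(1j * u).sum()
            null[k] = np.abs(c) ** 2 / n
        p_mc = (null >= z_obs).mean()
        assert 1e-4 < p_obs < 0.1  # in the validated regime
        assert p_obs / p_mc < 2.0 and p_mc / p_obs < 2.0

    def test_concentrated_sample_significant(self, rng):
        phases = rng.vonmises(1.0, 2.0, 50)
        _, p, _, _ = rayleigh_test(phases)
        assert p < 0.01

    def test_p_monotone_in_n_at_fixed_rbar(self):
        """At fixed mean resultant length > 0 the evidence against
        uniformity grows with the sample size."""
        rbar = 0.3
        ps = []
        for n in (10, 30, 100, 300):
            z = n * rbar**2
            arg = 1 + 4 * n + 4 * (n**2 - n * z)
            ps.append(np.exp(np.sqrt(arg) - (1 + 2 * n)))
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            rayleigh_test(np.empty(0))


class TestVonMises:
    def test_uniform_gives_near_zero_kappa(self, rng):
        mu, kappa = fit_von_mises(rng.uniform(-np.pi, np.pi, 5000))
        assert kappa < 0.1

    def test_parameter_recovery(self, rng):
        mu, kappa = fit_von_mises(rng.vonmises(-2.0, 5.0, 10_000))
        assert mu == pytest.approx(-2.0, abs=0.05)
        assert kappa == pytest.approx(5.0, rel=0.10)

    def test_antipodal_pair_is_degenerate(self):
        mu, kappa = fit_von_mises(np.array([0.5, 0.5 - np.pi]))
        assert kappa == pytest.approx(0.0, abs=1e-9)


class TestPhaseLocking:
    def test_few_spikes_inconclusive_regardless_of_phases(self):
        res = classify_phase_locking({0: np.full(4, 1.0)}, gamma_time_s=10.0)
        assert res[0].label == "inconclusive"

    def test_short_gamma_time_inconclusive(self, rng):
        res = classify_phase_locking({0: rng.vonmises(0, 5, 100)},
                                     gamma_time_s=0.8)
        assert res[0].label == "inconclusive"

    def test_concentrated_neuron_locked_under_bonferroni(self, rng):
        phases = {i: rng.uniform(-np.pi, np.pi, 20) for i in range(99)}
        phases[99] = rng.vonmises(0.5, 3.0, 200)
        res = classify_phase_locking(phases, gamma_time_s=10.0)
        assert res[99].label == "locked"

    def test_type_one_error_controlled(self, rng):
        """Uniform phases over many replicate cohorts: the locked fraction
        stays at or below the Bonferroni family level."""
        n_locked = 0
        n_total = 0
        for _ in range(200):
            phases = {i: rng.uniform(-np.pi, np.pi, 30) for i in range(20)}
            res = classify_phase_locking(phases, gamma_time_s=5.0)
            n_locked += sum(r.label == "locked" for r in res)
            n_total += len(res)
        assert n_locked / n_total <= 0.01  # family alpha with margin

    def test_power_at_moderate_concentration(self, rng):
        """kappa = 2 with 100 spikes per neuron is detected essentially
        always (100 neurons tested)."""
        hits = 0
        for _ in range(50):
            phases = {i: rng.vonmises(0.0, 2.0, 100) for i in range(100)}
            res = classify_phase_locking(phases, gamma_time_s=10.0)
            hits += sum(r.label == "locked" for r in res) / len(res)
        assert hits / 50 > 0.95


class TestRateChange:
    BURSTS = [GammaBurst(start=1000.0 * k, end=1000.0 * k + 500.0)
              for k in range(20)]  # 10 s of gamma in a 20 s segment

    def test_critical_count_matches_enumerated_cdf(self):
        """With f_out = 1 Hz and 10 s of gamma (lambda = 10), n_c equals
        the smallest k with Poisson CDF(k; 10) >= 0.95, enumerated
        directly from the CDF."""
        k = 0
        while sst.poisson.cdf(k, 10.0) < 0.95:
            k += 1
        # 10 spikes placed outside bursts -> f_out = 10 / 10 s = 1 Hz
        spikes = 750.0 + 1000.0 * np.arange(10)
        res = classify_rate_change(spikes, self.BURSTS, segment_duration_s=20.0)
        assert res.f_out == pytest.approx(1.0)
        assert res.t_gamma_s == pytest.approx(10.0)
        assert res.n_critical == k

    def test_mean_count_is_no_change(self, rng):
        """Observing about the expected count never clears the 95%
        quantile (f_out = 4 Hz, lambda = 40, observed 40)."""
        out_times = rng.uniform(500.0, 1000.0, 40) + 1000.0 * rng.integers(0, 20, 40)
        in_times = rng.uniform(0.0, 500.0, 40) + 1000.0 * rng.integers(0, 20, 40)
        res = classify_rate_change(np.concatenate([out_times, in_times]),
                                   self.BURSTS, segment_duration_s=20.0)
        assert res.label == "no_change"

    def test_low_rate_inconclusive(self):
        res = classify_rate_change(np.array([100.0]), self.BURSTS, 20.0)
        assert res.label == "inconclusive"

    def test_zero_gamma_time_inconclusive(self):
        res = classify_rate_change(np.linspace(0, 19_000, 50), [], 20.0)
        assert res.label == "inconclusive"

    def test_strong_increase_detected(self, rng):
        out_times = rng.uniform(500.0, 1000.0, 20) + 1000.0 * rng.integers(0, 20, 20)
        in_times = rng.uniform(0.0, 500.0, 120) + 1000.0 * rng.integers(0, 20, 120)
        res = classify_rate_change(np.concatenate([out_times, in_times]),
                                   self.BURSTS, segment_duration_s=20.0)
        assert res.label == "increase"

    def test_false_increase_rate_calibrated(self, rng):
        """Equal in/out Poisson rates at recording-like proportions
        (long outside time, ~10 s of gamma): the one-sided increase rate
        is ~5%. The outside window must dominate because the null rate is
        a plug-in estimate; a short outside window would inflate the
        level."""
        bursts = [GammaBurst(start=60_000.0 * k, end=60_000.0 * k + 500.0)
                  for k in range(20)]  # 10 s of gamma in a 20 min segment
        n_rep, hits = 600, 0
        for _ in range(n_rep):
            t_all = rng.uniform(0.0, 1_200_000.0, rng.poisson(2.0 * 1200.0))
            res = classify_rate_change(t_all, bursts, 1200.0)
            hits += res.label == "increase"
        p_hat = hits / n_rep
        # exact level is <= 0.05 (Poisson discreteness); allow 3 sigma
        assert p_hat < 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_rep)


class TestConsistency:
    def test_counts_across_segments(self):
        segs = [{0: "locked", 1: "not_locked"},
                {0: "locked", 1: "inconclusive"},
                {0: "locked", 1: "not_locked"}]
        df = consistency_analysis(segs)
        assert df.loc[df.neuron_id == 0, "n_positive"].item() == 3
        assert df.loc[df.neuron_id == 1, "n_positive"].item() == 0
        assert df.loc[df.neuron_id == 1, "n_inconclusive"].item() == 1

    def test_bimodal_cohort_histogram(self, rng):
        """10% always-locked / 90% never-locked cohort: histogram mass
        only at 0 and K."""
        k_seg = 5
        segs = []
        for _ in range(k_seg):
            segs.append({i: ("locked" if i < 10 else "not_locked")
                         for i in range(100)})
        df = consistency_analysis(segs)
        counts = df.n_positive.value_counts()
        assert set(counts.index) == {0, k_seg}
        assert counts[k_seg] == 10

    def test_mismatched_ids_rejected(self):
        with pytest.raises(ValueError):
            consistency_analysis([{0: "locked"}, {1: "locked"}])


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.lists(st.floats(-np.pi, np.pi), min_size=2, max_size=60),
       st.floats(-np.pi, np.pi))
def test_rayleigh_rotation_invariance(phases, shift):
    """Rotating all phases leaves Z, p and the resultant length unchanged
    and rotates the circular mean equivariantly."""
    ph = np.asarray(phases)
    z1, p1, r1, m1 = rayleigh_test(ph)
    z2, p2, r2, m2 = rayleigh_test(np.angle(np.exp(1j * (ph + shift))))
    assert z2 == pytest.approx(z1, abs=1e-9)
    assert p2 == pytest.approx(p1, abs=1e-9)
    assert r2 == pytest.approx(r1, abs=1e-12)
    if r1 > 1e-9:
        assert np.angle(np.exp(1j * (m2 - m1 - shift))) == pytest.approx(0.0, abs=1e-6)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(1, 200), st.floats(0.01, 0.99))
def test_rayleigh_statistic_identity(n, rbar_target):
    """Z = n * Rbar^2 exactly, for constructed two-point samples of any
    resultant length."""
    # two antipodal clusters sized to produce the requested resultant
    theta = np.arccos(np.clip(rbar_target, -1, 1))
    ph = np.concatenate([np.full(n, theta), np.full(n, -theta)])
    z, _, rbar, _ = rayleigh_test(ph)
    assert rbar == pytest.approx(abs(np.cos(theta)), abs=1e-9)
    assert z == pytest.approx(2 * n * rbar**2, rel=1e-9)
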