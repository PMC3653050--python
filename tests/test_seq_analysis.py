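"""Rectified-increment sequential analysis: moments, MGF roots, Wald formulas."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.stats import norm

from robint.seq_analysis import (
    RectifiedGaussian,
    accuracy_fixed_N,
    accuracy_fixed_N_robust,
    calibrate_sampling_interval,
    mgf_root,
    rectified_mgf,
    rectified_moments,
    taylor_mean_deficit,
    wald_accuracy,
    wald_mean_dt,
    wald_solution,
)


def _moments_by_quadrature(d):
    lim = 12 * d.sigma + abs(d.mu)
    m1 = sum(quad(lambda z: z * norm.pdf(z, d.mu, d.sigma), a, b)[0]
             for a, b in [(-lim, -d.R), (d.R, lim)])
    m2 = sum(quad(lambda z: z * z * norm.pdf(z, d.mu, d.sigma), a, b)[0]
             for a, b in [(-lim, -d.R), (d.R, lim)])
    return m1, m2 - m1 * m1


class TestRectifiedMoments:
    def test_no_dead_zone_recovers_gaussian(self):
        m, v = rectified_moments(RectifiedGaussian(mu=0.3, sigma=2.0, R=0.0))
        assert m == pytest.approx(0.3)
        assert v == pytest.approx(4.0)

    def test_zero_mean_stays_zero_mean(self):
        m, _ = rectified_moments(RectifiedGaussian(mu=0.0, sigma=1.0, R=0.7))
        assert m == pytest.approx(0.0, abs=1e-15)

    def test_closed_form_matches_quadrature(self):
        d = RectifiedGaussian(mu=0.1, sigma=1.0, R=0.5)
        m, v = rectified_moments(d)
        mq, vq = _moments_by_quadrature(d)
        assert m == pytest.approx(mq, abs=1e-10)
        assert v == pytest.approx(vq, abs=1e-10)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(mu=st.floats(-1.0, 1.0), sigma=st.floats(0.3, 3.0), R=st.floats(0.0, 3.0))
    def test_moment_properties(self, mu, sigma, R):
        d = RectifiedGaussian(mu=mu, sigma=sigma, R=R)
        m, v = rectified_moments(d)
        mq, vq = _moments_by_quadrature(d)
        assert m == pytest.approx(mq, abs=1e-8)
        assert v == pytest.approx(vq, abs=1e-8)
        assert 0.0 <= d.p0 <= 1.0
        assert v >= 0.0


class TestTaylorDeficit:
    def test_cubic_scaling(self):
        """The mean deficit scales as R-hat^3 for small dead zones."""
        rs = np.array([0.01, 0.02, 0.05, 0.1])
        deficits = [0.1 - rectified_moments(RectifiedGaussian(0.1, 1.0, r))[0]
                    for r in rs]
        slope = np.polyfit(np.log(rs), np.log(deficits), 1)[0]
        assert slope == pytest.approx(3.0, abs=0.05)

    def test_zero_mean_zero_deficit(self):
        assert taylor_mean_deficit(0.0, 1.0, 0.4) == 0.0

    def test_leading_term_accurate_at_moderate_R(self):
        exact = 0.1 - rectified_moments(RectifiedGaussian(0.1, 1.0, 0.3))[0]
        assert taylor_mean_deficit(0.1, 1.0, 0.3) == pytest.approx(exact, rel=0.05)


class TestFixedN:
    def test_no_signal_is_chance(self):
        assert accuracy_fixed_N(0.0, 50) == 0.5

    def test_erf_evaluation(self):
        assert accuracy_fixed_N(0.1, 100) == pytest.approx(0.8413447, abs=1e-6)

    def test_monotone_in_N(self):
        accs = [accuracy_fixed_N(0.1, n) for n in (10, 100, 1000, 10_000)]
        assert all(b > a for a, b in zip(accs, accs[1:]))
        assert accs[-1] > 0.999

    def test_robust_equals_plain_at_zero_R(self):
        assert accuracy_fixed_N_robust(0.1, 100, 0.0) == accuracy_fixed_N(0.1, 100)

    def test_robust_accuracy_deficit_is_cubic(self):
        rs = np.array([0.01, 0.02, 0.05, 0.1])
        base = accuracy_fixed_N(0.1, 100)
        deficits = [base - accuracy_fixed_N_robust(0.1, 100, r) for r in rs]
        slope = np.polyfit(np.log(rs), np.log(deficits), 1)[0]
        assert slope == pytest.approx(3.0, abs=0.05)

    def test_clt_matches_direct_monte_carlo(self):
        """Sum of N rectified draws vs the CLT accuracy, across R-hat.

        Checked where the Gaussian approximation is valid (up to
        R-hat = 1.5 for N = 14); beyond that the point mass at zero
        dominates and the CLT degrades (see the companion test).
        """
        rng = np.random.default_rng(77)
        s, N, reps = 0.289, 14, 100_000
        for r_hat in (0.0, 0.5, 1.0, 1.5):
            d = RectifiedGaussian(mu=s, sigma=1.0, R=r_hat)
            draws = d.rvs((reps, N), rng).sum(axis=1)
            p_mc = float(np.mean(draws > 0) + 0.5 * np.mean(draws == 0))
            se = math.sqrt(p_mc * (1 - p_mc) / reps)
            assert accuracy_fixed_N_robust(s, N, r_hat) == pytest.approx(
                p_mc, abs=3 * se + 0.004), r_hat

    def test_clt_degrades_when_zero_atom_dominates(self):
        """At R-hat = 2 with N = 14 nearly half the trial sums are exactly
        zero (p0^N ~ 0.45) and score 0.5 by the tie rule, pulling the true
        accuracy toward chance; the continuous CLT approximation sits a few
        percentage points above it.  This deviation is a known property of
        the approximation, not an estimator defect."""
        rng = np.random.default_rng(78)
        s, N, reps = 0.289, 14, 100_000
        d = RectifiedGaussian(mu=s, sigma=1.0, R=2.0)
        assert d.p0 ** N > 0.4
        draws = d.rvs((reps, N), rng).sum(axis=1)
        p_mc = float(np.mean(draws > 0) + 0.5 * np.mean(draws == 0))
        clt = accuracy_fixed_N_robust(s, N, 2.0)
        assert clt > p_mc  # ties at zero pull the true accuracy toward 0.5
        assert abs(clt - p_mc) < 0.05


class TestMgfRoot:
    def test_gaussian_root(self):
        assert mgf_root(RectifiedGaussian(0.1, 1.0, 0.0)) == pytest.approx(-0.2, abs=1e-10)

    def test_root_survives_rectification(self):
        assert mgf_root(RectifiedGaussian(0.1, 1.0, 1.5)) == pytest.approx(-0.2, abs=1e-8)

    @pytest.mark.parametrize("s", [0.05, 0.1, 0.2])
    @pytest.mark.parametrize("r_hat", [0.0, 0.5, 1.0, 1.5, 2.0])
    def test_h0_invariance_grid(self, s, r_hat):
        """h0 = -2 mu/sigma^2 regardless of the dead-zone width."""
        h0 = mgf_root(RectifiedGaussian(mu=s, sigma=1.0, R=r_hat))
        assert abs(h0 + 2.0 * s) < 1e-8

    def test_zero_mean_degenerate(self):
        with pytest.raises(ValueError):
            mgf_root(RectifiedGaussian(0.0, 1.0, 0.5))

    def test_mgf_is_one_at_both_real_roots(self):
        d = RectifiedGaussian(0.15, 1.2, 0.8)
        assert rectified_mgf(d, 0.0) == pytest.approx(1.0)
        assert rectified_mgf(d, mgf_root(d)) == pytest.approx(1.0, abs=1e-10)

    def test_exponential_symmetry_identity(self):
        """f(z) = f(-z) e^{-h0 z} outside the dead zone, at h0 = -2mu/sigma^2."""
        d = RectifiedGaussian(mu=0.1, sigma=1.0, R=0.5)
        h0 = -2 * d.mu / d.sigma ** 2
        z = np.linspace(0.5, 5.0, 50)
        assert np.allclose(d.pdf(z), d.pdf(-z) * np.exp(-h0 * z), atol=1e-12)


class TestWald:
    def test_accuracy_at_vanishing_threshold(self):
        assert wald_accuracy(1e-12, -0.2) == pytest.approx(0.5)

    def test_accuracy_closed_form(self):
        assert wald_accuracy(10.0, -0.2) == pytest.approx(1.0 / (1.0 + math.exp(-2.0)))

    def test_mean_dt_closed_form(self):
        assert wald_mean_dt(10.0, -0.2, 0.1) == pytest.approx(100.0 * math.tanh(1.0))

    def test_mean_dt_vanishes_with_threshold(self):
        assert wald_mean_dt(0.0, -0.2, 0.1) == 0.0
        assert wald_mean_dt(1e-9, -0.2, 0.1) == pytest.approx(0.0, abs=1e-6)

    def test_rectification_slows_but_does_not_err(self):
        """Dead zones increase decision time at identical accuracy."""
        theta = 10.0
        sols = [wald_solution(RectifiedGaussian(0.1, 1.0, r), theta)
                for r in (0.0, 0.5, 1.0, 1.5)]
        accs = [s.accuracy for s in sols]
        steps = [s.mean_steps for s in sols]
        assert np.allclose(accs, accs[0], atol=1e-9)
        assert all(b >= a for a, b in zip(steps, steps[1:]))

    def test_nonpositive_mean_increment_rejected(self):
        with pytest.raises(ValueError):
            wald_mean_dt(10.0, -0.2, 0.0)


def _walk_to_bound_mc(d, theta, n_walks, rng, max_steps=100_000):
    """Brute-force random walks between symmetric bounds +/- theta."""
    E = np.zeros(n_walks)
    steps = np.zeros(n_walks)
    hit_top = np.zeros(n_walks, dtype=bool)
    active = np.arange(n_walks)
    for i in range(1, max_steps + 1):
        E += d.rvs(active.size, rng)
        done = np.abs(E) >= theta
        if done.any():
            idx = active[done]
            hit_top[idx] = E[done] >= theta
            steps[idx] = i
            keep = ~done
            active, E = active[keep], E[keep]
            if active.size == 0:
                break
    assert active.size == 0, "walks did not terminate"
    return hit_top, steps


class TestWaldAgainstBruteForce:
    def test_formulas_match_simulated_walks(self):
        """Wald accuracy and mean steps vs direct simulation, with and
        without a dead zone (small increments, so overshoot is negligible)."""
        rng = np.random.default_rng(99)
        theta, n_walks = 50.0, 20_000
        for R in (0.0, 1.0):
            d = RectifiedGaussian(mu=0.05, sigma=1.0, R=R)
            sol = wald_solution(d, theta)
            hit, steps = _walk_to_bound_mc(d, theta, n_walks, rng)
            p = hit.mean()
            se_p = math.sqrt(p * (1 - p) / n_walks)
            se_t = steps.std(ddof=1) / math.sqrt(n_walks)
            assert sol.accuracy == pytest.approx(p, abs=3 * se_p + 0.003)
            assert sol.mean_steps == pytest.approx(steps.mean(), abs=3 * se_t + 0.01 * steps.mean())


class TestSamplingInterval:
    def test_self_consistency(self):
        """Calibrating against the discrete model's own output recovers
        the generating interval."""
        s, interval = 0.289, 37.0
        d = RectifiedGaussian(mu=s, sigma=1.0, R=0.0)
        sol = wald_solution(d, theta=3.0)
        est = calibrate_sampling_interval(sol.accuracy, sol.mean_steps * interval, s)
        assert est == pytest.approx(interval, rel=1e-6)

    def test_interval_for_default_stream_is_tens_of_ms(self, cfg128, fits):
        """Against the calibrated continuous model the equivalent
        inter-sample time is a few tens of ms (about twice the input
        correlation time)."""
        from robint.decision_tasks import wald_predictions
        from robint.sensory_synth import stream_stats

        m, v, _ = stream_stats(cfg128, fits)
        acc, rt_ms = wald_predictions(cfg128, theta=20.0, fits=fits)
        est = calibrate_sampling_interval(acc, rt_ms - 350.0, m / math.sqrt(v))
        assert 37.0 * 0.5 <= est <= 37.0 * 1.5

    def test_no_solution_out_of_band_raises(self):
        with pytest.raises(ValueError):
            calibrate_sampling_interval(0.999999, 1.0, 0.01)
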