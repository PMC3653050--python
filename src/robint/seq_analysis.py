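"""Discrete-time sequential-sampling theory with a dead zone.

The robust integrator's dead zone has a discrete-time analog: i.i.d.
Gaussian evidence increments Z ~ N(mu, sigma^2) whose probability
mass inside (-R, R) is reassigned to an atom at zero.  This module
provides exact moments of that rectified increment, fixed-sample-size
(controlled-duration) accuracy via the CLT, and Wald's sequential
analysis of the race-to-threshold task:

    Accuracy = 1 / (1 + e^{theta h0}),
    E[steps] = (theta / E[Z]) tanh(-theta h0 / 2),

where h0 is the nontrivial real root of the increment moment
generating function equation M_Z(omega) = 1.  The central result is
that h0 = -2 mu / sigma^2 independent of the dead-zone width: the
dead zone slows decisions but leaves accuracy at fixed threshold
untouched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import erf
from scipy.stats import norm

__all__ = [
    "RectifiedGaussian",
    "WaldSolution",
    "rectified_moments",
    "taylor_mean_deficit",
    "accuracy_fixed_N",
    "accuracy_fixed_N_robust",
    "rectified_mgf",
    "mgf_root",
    "wald_accuracy",
    "wald_mean_dt",
    "wald_solution",
    "calibrate_sampling_interval",
]


@dataclass(frozen=True)
class RectifiedGaussian:
    """N(mu, sigma^2) increment with a symmetric dead zone of half-width R.

    Mass inside (-R, R) collapses onto a point mass p0 at zero; the
    density outside is untouched.
    """

    mu: float
    sigma: float
    R: float = 0.0
    p0: float = field(init=False)

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.R < 0:
            raise ValueError("R must be non-negative")
        object.__setattr__(
            self, "p0",
            float(norm.cdf((self.R - self.mu) / self.sigma)
                  - norm.cdf((-self.R - self.mu) / self.sigma)))

    @property
    def s(self) -> float:
        """Per-increment signal-to-noise ratio mu/sigma."""
        return self.mu / self.sigma

    @property
    def R_hat(self) -> float:
        return self.R / self.sigma

    def pdf(self, z):
        """Density of the continuous part (excludes the atom at 0)."""
        z = np.asarray(z, dtype=float)
        out = norm.pdf(z, loc=self.mu, scale=self.sigma)
        return np.where(np.abs(z) < self.R, 0.0, out)

    def rvs(self, size, rng: np.random.Generator):
        z = self.mu + self.sigma * rng.standard_normal(size)
        return np.where(np.abs(z) < self.R, 0.0, z)


@dataclass(frozen=True)
class WaldSolution:
    h0: float
    accuracy: float
    mean_steps: float


def _partial_m1(mu: float, sigma: float, a: float, b: float) -> float:
    """int_a^b z N(z; mu, sigma^2) dz via Gaussian partial moments."""
    al, be = (a - mu) / sigma, (b - mu) / sigma
    return mu * (norm.cdf(be) - norm.cdf(al)) - sigma * (norm.pdf(be) - norm.pdf(al))


def _partial_m2(mu: float, sigma: float, a: float, b: float) -> float:
    """int_a^b z^2 N(z; mu, sigma^2) dz."""
    al, be = (a - mu) / sigma, (b - mu) / sigma
    return ((mu * mu + sigma * sigma) * (norm.cdf(be) - norm.cdf(al))
            - sigma * ((b + mu) * norm.pdf(be) - (a + mu) * norm.pdf(al)))


def rectified_moments(d: RectifiedGaussian) -> tuple[float, float]:
    """Mean and variance of the dead-zone increment, in closed form.

    The atom at zero contributes nothing to either raw moment, so
    E[Z_R] = mu - int_{-R}^{R} z f(z) dz and similarly for E[Z_R^2].
    """
    lost_m1 = _partial_m1(d.mu, d.sigma, -d.R, d.R)
    lost_m2 = _partial_m2(d.mu, d.sigma, -d.R, d.R)
    mean = d.mu - lost_m1
    second = d.mu * d.mu + d.sigma * d.sigma - lost_m2
    return mean, second - mean * mean


def taylor_mean_deficit(mu: float, sigma: float, R_hat: float) -> float:
    """Leading-order (cubic) mean deficit E[Z] - E[Z_R-hat].

    Expanding the dead-zone partial moment around R = 0 gives
    deficit = mu * sqrt(2/(9 pi)) * exp(-s^2/2) * R-hat^3 + O(R-hat^5),
    with s = mu/sigma: the dead zone has no first- or second-order
    effect on the mean increment.
    """
    s = mu / sigma
    return mu * math.sqrt(2.0 / (9.0 * math.pi)) * math.exp(-0.5 * s * s) * R_hat ** 3


def accuracy_fixed_N(s: float, N: float) -> float:
    """Fixed-sample accuracy (1 + erf(sqrt(N/2) s)) / 2 of the Gaussian walk."""
    if N < 1:
        raise ValueError("N must be >= 1")
    return 0.5 * (1.0 + erf(math.sqrt(N / 2.0) * s))


def accuracy_fixed_N_robust(s: float, N: float, R_hat: float) -> float:
    """Fixed-sample accuracy with dead-zone increments, via the CLT.

    The sum of N rectified increments is approximately Gaussian with
    the rectified mean and variance; its deficit relative to
    ``accuracy_fixed_N`` scales as R-hat^3 for small R-hat.
    """
    if R_hat == 0.0:
        return accuracy_fixed_N(s, N)
    d = RectifiedGaussian(mu=s, sigma=1.0, R=R_hat)
    m, v = rectified_moments(d)
    return 0.5 * (1.0 + erf(math.sqrt(N / 2.0) * m / math.sqrt(v)))


def rectified_mgf(d: RectifiedGaussian, omega):
    """MGF of the dead-zone increment via Gaussian partial expectations.

    M(w) = p0 + e^{w mu + w^2 sigma^2/2} [1 - Phi(b_w) + Phi(a_w)] with
    the dead-zone limits shifted by w sigma^2.
    """
    omega = np.asarray(omega, dtype=float)
    mu, sg, R = d.mu, d.sigma, d.R
    shift = mu + omega * sg * sg
    expo = np.exp(omega * mu + 0.5 * omega * omega * sg * sg)
    inside = norm.cdf((R - shift) / sg) - norm.cdf((-R - shift) / sg)
    out = d.p0 + expo * (1.0 - inside)
    return out if out.shape else float(out)


def mgf_root(d: RectifiedGaussian, tol: float = 1e-12) -> float:
    """Nontrivial real root h0 of M_{Z_R}(omega) = 1.

    For Gaussian-class increments (any dead-zone width) the root is
    -2 mu / sigma^2; it is located here by bracketed search so the
    invariance is a computed result, not an assumption.
    """
    if d.mu == 0.0:
        raise ValueError("mu = 0 is degenerate: omega = 0 is the only real root")
    sgn = -math.copysign(1.0, d.mu)
    guess = 2.0 * abs(d.mu) / d.sigma ** 2

    def g(w):
        return rectified_mgf(d, w) - 1.0

    # M has a strict interior minimum between its two real roots; walk
    # outward from the trivial root at 0 until g changes sign again.
    inner = sgn * 1e-8 * guess
    outer = sgn * 2.0 * guess
    for _ in range(60):
        if g(outer) > 0:
            break
        outer *= 2.0
    else:
        raise RuntimeError("failed to bracket the nontrivial MGF root")
    return float(brentq(g, min(inner, outer), max(inner, outer), xtol=tol))


def wald_accuracy(theta: float, h0: float) -> float:
    """SPRT accuracy 1 / (1 + e^{theta h0}) at symmetric thresholds."""
    if theta <= 0:
        raise ValueError("theta must be positive")
    return 1.0 / (1.0 + math.exp(theta * h0))


def wald_mean_dt(theta: float, h0: float, mean_increment: float) -> float:
    """Mean number of steps to threshold, (theta/E[Z]) tanh(-theta h0/2).

    Valid when thresholds are crossed with negligible overshoot.  Under
    rectification h0 is fixed, so decision time lengthens exactly as
    the rectified mean increment E[Z_R] shrinks.
    """
    if mean_increment <= 0:
        raise ValueError("mean_increment must be positive")
    if theta < 0:
        raise ValueError("theta must be non-negative")
    return (theta / mean_increment) * math.tanh(-theta * h0 / 2.0)


def wald_solution(d: RectifiedGaussian, theta: float) -> WaldSolution:
    """Accuracy and mean decision steps of the race task for increments d."""
    h0 = mgf_root(d)
    m, _ = rectified_moments(d)
    return WaldSolution(h0=h0, accuracy=wald_accuracy(theta, h0),
                        mean_steps=wald_mean_dt(theta, h0, m))


def calibrate_sampling_interval(
    accuracy_ref: float,
    mean_dt_ref_ms: float,
    s: float,
    lo_ms: float = 1.0,
    hi_ms: float = 500.0,
) -> float:
    """Inter-sample interval (ms) matching the discrete model to a reference.

    Given a continuous-model reference operating point (accuracy and
    mean decision time, nondecision time excluded) at R-hat = 0, and
    the momentary SNR s = mu/S of the input, find the threshold of the
    unit-variance discrete walk reproducing the reference accuracy and
    assign each discrete sample the interval that reproduces the
    reference decision time.
    """
    if not 0.5 < accuracy_ref < 1.0:
        raise ValueError("reference accuracy must be in (0.5, 1)")
    if mean_dt_ref_ms <= 0:
        raise ValueError("reference decision time must be positive")
    d = RectifiedGaussian(mu=s, sigma=1.0, R=0.0)
    h0 = -2.0 * s  # exact for the unit-variance Gaussian
    theta = math.log(1.0 / accuracy_ref - 1.0) / h0
    steps = wald_mean_dt(theta, h0, s)
    interval = mean_dt_ref_ms / steps
    if not lo_ms <= interval <= hi_ms:
        raise ValueError(
            f"calibrated interval {interval:.1f} ms outside [{lo_ms}, {hi_ms}] ms")
    return interval
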