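"""Robust (dead-zone) neural integrator dynamics.

A pair of accumulators E_l(t), E_r(t) integrate the differenced
sensory streams under the piecewise dynamics

    tau_E dE/dt = 0                      if |beta E + kappa dI| <= kappa S R-hat
                  beta E + kappa dI      otherwise,

with reflecting boundaries at E = 0 so firing rates never go
negative.  beta is the feedback mistuning (beta > 0: runaway
excitation, beta < 0: leak), drawn per trial from N(beta_mean,
beta_sd^2); R-hat is the robustness limit in units of the stationary
SD S of the input difference.  R-hat = 0 and beta = 0 recover a
perfect integrator of kappa*dI/tau_E.

Because the four OU components of dI share one correlation time, the
Monte-Carlo engine simulates dI directly as a single OU process with
the differenced mean and summed variance (distributionally exact),
which keeps batched Euler-Maruyama simulation fast.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .sensory_synth import SensoryConfig, SignalPath, stream_stats

__all__ = [
    "IntegratorParams",
    "BetaGrid",
    "TrialResult",
    "SpeedAccuracyPoint",
    "sample_beta_grid",
    "step",
    "simulate_trial",
    "run_condition",
    "run_duration_curve",
    "NONDECISION_MS",
    "RACE_CAP_MS",
]

#: Nondecision time added to threshold-crossing times to form reaction times.
NONDECISION_MS = 350.0

#: Simulated-time cap for race trials that never reach threshold.
RACE_CAP_MS = 10_000.0


@dataclass(frozen=True)
class IntegratorParams:
    """Integrator circuit parameters.

    beta_mean/beta_sd parameterize the trial-to-trial mistuning
    distribution (1/unit-time, relative to the leak); robustness is
    the dead-zone half-width R-hat in SDs of dI; kappa weights the
    input; tau_E (ms) is the integrator time constant; floor is the
    reflecting boundary.
    """

    beta_mean: float = 0.0
    beta_sd: float = 0.0
    robustness: float = 0.0
    kappa: float = 1.0 / 9.0
    tau_E: float = 20.0
    floor: float = 0.0

    def __post_init__(self):
        if self.beta_sd < 0:
            raise ValueError("beta_sd must be non-negative")
        if self.robustness < 0:
            raise ValueError("robustness must be non-negative")
        if self.tau_E <= 0:
            raise ValueError("tau_E must be positive")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")


@dataclass(frozen=True)
class BetaGrid:
    """Discrete mistuning grid with normal-distribution weights."""

    values: np.ndarray
    weights: np.ndarray


@dataclass
class TrialResult:
    choice: str  # "left" or "right"
    decision_time: float  # ms; trial duration if no crossing
    crossed: bool
    E_final_left: float
    E_final_right: float


@dataclass
class SpeedAccuracyPoint:
    """One (accuracy, mean RT) point with Monte-Carlo standard errors."""

    accuracy: float
    mean_rt: float  # ms, includes nondecision time in race mode
    se_accuracy: float
    se_rt: float
    theta: float | None = None
    duration: float | None = None
    n_trials: int = 0


def sample_beta_grid(beta_mean: float, beta_sd: float, n_points: int = 19) -> BetaGrid:
    """Linearly spaced beta grid over +/- 3 SD with Gaussian weights.

    With beta_sd = 0 the grid collapses to the single point beta_mean.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    if beta_sd == 0.0:
        return BetaGrid(values=np.array([beta_mean]), weights=np.array([1.0]))
    if n_points < 19:
        raise ValueError("n_points must be >= 19 when beta_sd > 0")
    values = np.linspace(beta_mean - 3 * beta_sd, beta_mean + 3 * beta_sd, n_points)
    w = norm.pdf(values, loc=beta_mean, scale=beta_sd)
    return BetaGrid(values=values, weights=w / w.sum())


def step(
    E: float,
    delta_I: float,
    beta: float,
    params: IntegratorParams,
    S: float,
    dt: float,
) -> float:
    """One Euler-Maruyama step of the dead-zone dynamics (scalar).

    Order of operations: dead-zone test on the total drive, then the
    update, then the reflecting-floor clamp.
    """
    if S <= 0:
        raise ValueError("S must be positive")
    drive = beta * E + params.kappa * delta_I
    if abs(drive) > params.kappa * S * params.robustness:
        E = E + (dt / params.tau_E) * drive
    return max(E, params.floor)


def simulate_trial(
    streams: tuple[SignalPath, SignalPath, float],
    params: IntegratorParams,
    beta: float,
    mode: str = "race",
    theta: float | None = None,
    T: float | None = None,
    dt: float | None = None,
    rng: np.random.Generator | None = None,
) -> TrialResult:
    """Single-trial integration of explicit streams.

    race: first accumulator to reach theta wins; compare: argmax at
    time T (ties broken by fair coin); bounded: an accumulator
    reaching theta is frozen there and compared at T.
    """
    delta_l, delta_r, S = streams
    dt = dt or delta_l.dt
    rng = rng or np.random.default_rng()
    if mode == "race" and theta is None:
        raise ValueError("race mode requires theta")
    if mode in ("compare", "bounded") and T is None:
        raise ValueError(f"{mode} mode requires T")
    n_steps = delta_l.values.size if T is None else min(
        delta_l.values.size, int(round(T / dt)))
    E_l = E_r = max(0.0, params.floor)  # activity starts at zero
    lim = params.kappa * S * params.robustness
    c = dt / params.tau_E
    frozen_l = frozen_r = False
    for i in range(n_steps):
        dI = delta_l.values[i]
        drive_l = beta * E_l + params.kappa * dI
        drive_r = beta * E_r - params.kappa * dI
        if not frozen_l and abs(drive_l) > lim:
            E_l = max(E_l + c * drive_l, params.floor)
        if not frozen_r and abs(drive_r) > lim:
            E_r = max(E_r + c * drive_r, params.floor)
        if mode == "bounded" and theta is not None:
            if E_l >= theta:
                E_l, frozen_l = theta, True
            if E_r >= theta:
                E_r, frozen_r = theta, True
        if mode == "race" and (E_l >= theta or E_r >= theta):
            if E_l >= theta and E_r >= theta:
                choice = "left" if (E_l > E_r or (E_l == E_r and rng.random() < 0.5)) else "right"
            else:
                choice = "left" if E_l >= theta else "right"
            return TrialResult(choice, (i + 1) * dt, True, E_l, E_r)
    if mode == "race":
        return TrialResult("left" if rng.random() < 0.5 else "right",
                           n_steps * dt, False, E_l, E_r)
    if E_l == E_r:
        choice = "left" if rng.random() < 0.5 else "right"
    else:
        choice = "left" if E_l > E_r else "right"
    crossed = mode == "bounded" and theta is not None and (E_l >= theta or E_r >= theta)
    return TrialResult(choice, n_steps * dt, crossed, E_l, E_r)


# ---------------------------------------------------------------------------
# batched Monte-Carlo engine


def _batch_controlled(
    mean_dI: float,
    var_dI: float,
    tau_ms: float,
    params: IntegratorParams,
    betas: np.ndarray,
    S: float,
    durations_ms: np.ndarray,
    dt: float,
    rng: np.random.Generator,
    bound: float | None = None,
) -> np.ndarray:
    """Fraction of 'left' choices at each requested duration.

    Simulates n = len(betas) trials of the dead-zone dynamics driven
    by the single-OU reduction of dI; snapshots E_l, E_r at each
    duration.  With bound set, accumulators absorb at the bound
    (the bounded controlled-duration variant).  Returns an array of
    shape (len(durations), n) with +1 (left), -1 (right) and 0 (tie).
    """
    n = betas.size
    n_steps = int(round(durations_ms.max() / dt))
    checkpoints = np.round(durations_ms / dt).astype(int)
    a = math.exp(-dt / tau_ms)
    s_upd = math.sqrt(var_dI * (1.0 - a * a))
    dI = mean_dI + math.sqrt(var_dI) * rng.standard_normal(n)
    E0 = max(0.0, params.floor)  # activity starts at zero
    E_l = np.full(n, E0)
    E_r = np.full(n, E0)
    lim = params.kappa * S * params.robustness
    c = dt / params.tau_E
    kap = params.kappa
    out = np.zeros((durations_ms.size, n))
    cp_index = {int(cpt): j for j, cpt in enumerate(checkpoints)}
    if bound is not None:
        absorbed_l = np.zeros(n, dtype=bool)
        absorbed_r = np.zeros(n, dtype=bool)
        winner = np.zeros(n)  # +1 left absorbed first, -1 right, 0 undecided
    for i in range(1, n_steps + 1):
        drive_l = betas * E_l + kap * dI
        drive_r = betas * E_r - kap * dI
        if lim > 0:
            upd_l = np.abs(drive_l) > lim
            upd_r = np.abs(drive_r) > lim
        else:
            upd_l = upd_r = True
        E_l = np.where(upd_l, np.maximum(E_l + c * drive_l, params.floor), E_l)
        E_r = np.where(upd_r, np.maximum(E_r + c * drive_r, params.floor), E_r)
        if bound is not None:
            # an accumulator that reaches the bound is absorbed there; the
            # first to absorb determines the report
            new_l = (E_l >= bound) & ~absorbed_l
            new_r = (E_r >= bound) & ~absorbed_r
            undecided = winner == 0
            winner = np.where(undecided & new_l & ~new_r, 1.0, winner)
            winner = np.where(undecided & new_r & ~new_l, -1.0, winner)
            winner = np.where(undecided & new_l & new_r, np.sign(E_l - E_r), winner)
            absorbed_l |= new_l
            absorbed_r |= new_r
            E_l = np.where(absorbed_l, bound, E_l)
            E_r = np.where(absorbed_r, bound, E_r)
        if i in cp_index:
            snap = np.sign(E_l - E_r)
            if bound is not None:
                snap = np.where(winner != 0, winner, snap)
            out[cp_index[i]] = snap
        dI = mean_dI + (dI - mean_dI) * a + s_upd * rng.standard_normal(n)
    return out


def _batch_race(
    mean_dI: float,
    var_dI: float,
    tau_ms: float,
    params: IntegratorParams,
    betas: np.ndarray,
    S: float,
    theta: float,
    dt: float,
    rng: np.random.Generator,
    cap_ms: float = RACE_CAP_MS,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Race-to-threshold trials; returns (won_left, decision_time_ms, crossed)."""
    n = betas.size
    max_steps = int(round(cap_ms / dt))
    a = math.exp(-dt / tau_ms)
    s_upd = math.sqrt(var_dI * (1.0 - a * a))
    dI = mean_dI + math.sqrt(var_dI) * rng.standard_normal(n)
    E0 = max(0.0, params.floor)  # activity starts at zero
    E_l = np.full(n, E0)
    E_r = np.full(n, E0)
    lim = params.kappa * S * params.robustness
    c = dt / params.tau_E
    kap = params.kappa
    won_left = np.zeros(n, dtype=bool)
    dec_time = np.full(n, cap_ms)
    crossed = np.zeros(n, dtype=bool)
    active = np.arange(n)
    bet = betas.copy()
    for i in range(1, max_steps + 1):
        drive_l = bet * E_l + kap * dI
        drive_r = bet * E_r - kap * dI
        if lim > 0:
            np.putmask(E_l, np.abs(drive_l) > lim, np.maximum(E_l + c * drive_l, params.floor))
            np.putmask(E_r, np.abs(drive_r) > lim, np.maximum(E_r + c * drive_r, params.floor))
        else:
            E_l = np.maximum(E_l + c * drive_l, params.floor)
            E_r = np.maximum(E_r + c * drive_r, params.floor)
        hit_l = E_l >= theta
        hit_r = E_r >= theta
        hit = hit_l | hit_r
        if hit.any():
            idx = active[hit]
            # single crossings are decisive; simultaneous crossings go to
            # the higher accumulator, exact ties to a fair coin
            wl = np.where(hit_l[hit] & ~hit_r[hit], True,
                          np.where(hit_r[hit] & ~hit_l[hit], False, E_l[hit] > E_r[hit]))
            eq = hit_l[hit] & hit_r[hit] & (E_l[hit] == E_r[hit])
            if eq.any():
                wl[eq] = rng.random(int(eq.sum())) < 0.5
            won_left[idx] = wl
            dec_time[idx] = i * dt
            crossed[idx] = True
            keep = ~hit
            active, E_l, E_r, dI, bet = active[keep], E_l[keep], E_r[keep], dI[keep], bet[keep]
            if active.size == 0:
                break
        dI = mean_dI + (dI - mean_dI) * a + s_upd * rng.standard_normal(active.size)
    if active.size:
        won_left[active] = rng.random(active.size) < 0.5
    return won_left, dec_time, crossed


def _favored_is_left(config: SensoryConfig) -> bool:
    return config.favored_side == "left"


def run_duration_curve(
    config: SensoryConfig,
    params: IntegratorParams,
    durations_ms,
    n_trials: int,
    seed: int,
    dt: float = 0.5,
    n_beta: int = 19,
    bound: float | None = None,
    fits: dict | None = None,
) -> list[SpeedAccuracyPoint]:
    """Controlled-duration accuracy at each duration.

    Mistuning is handled in figure-reproduction mode: the beta grid is
    swept deterministically with n_trials trials per grid point and
    the outcomes averaged under the Gaussian grid weights.  One set of
    paths is simulated to the longest duration and snapshotted at each
    requested duration, so points share realizations across durations
    (each marginal estimate is unbiased).
    """
    durations_ms = np.asarray(sorted(durations_ms), dtype=float)
    # stream_stats already encodes the favored side through the rate law:
    # mean_dI < 0 when the rightward alternative is favored
    mean_dI, var_dI, tau = stream_stats(config, fits)
    S = math.sqrt(var_dI)
    grid = sample_beta_grid(params.beta_mean, params.beta_sd, n_beta)
    acc = np.zeros((grid.values.size, durations_ms.size))
    acc_var = np.zeros_like(acc)
    rng = np.random.default_rng(seed)
    for gi, beta in enumerate(grid.values):
        betas = np.full(n_trials, beta)
        signs = _batch_controlled(mean_dI, var_dI, tau, params, betas, S,
                                  durations_ms, dt, rng, bound=bound)
        fav = 1.0 if _favored_is_left(config) else -1.0
        correct = (signs * fav > 0) + 0.5 * (signs == 0)
        p = correct.mean(axis=1)
        acc[gi] = p
        acc_var[gi] = p * (1 - p) / n_trials
    w = grid.weights[:, None]
    accuracy = (w * acc).sum(axis=0)
    se = np.sqrt((w ** 2 * acc_var).sum(axis=0))
    return [
        SpeedAccuracyPoint(accuracy=float(accuracy[j]), mean_rt=float(durations_ms[j]),
                           se_accuracy=float(se[j]), se_rt=0.0,
                           duration=float(durations_ms[j]),
                           n_trials=n_trials * grid.values.size)
        for j in range(durations_ms.size)
    ]


def run_condition(
    config: SensoryConfig,
    params: IntegratorParams,
    mode: str,
    theta: float | None = None,
    T: float | None = None,
    n_trials: int = 10_000,
    seed: int = 0,
    dt: float = 0.5,
    n_beta: int = 19,
    beta_mode: str = "grid",
    fits: dict | None = None,
) -> SpeedAccuracyPoint:
    """Accuracy and mean RT for one task condition.

    beta_mode="grid" (default, as used for all figure-level runs)
    sweeps the beta grid deterministically and averages outcomes under
    the Gaussian weights, n_trials per grid point; beta_mode="sample"
    draws one beta per trial from the grid by weight.  Race-mode RT
    includes the 350-ms nondecision time.
    """
    if n_trials < 100:
        raise ValueError("n_trials must be >= 100")
    # stream_stats already encodes the favored side through the rate law:
    # mean_dI < 0 when the rightward alternative is favored
    mean_dI, var_dI, tau = stream_stats(config, fits)
    S = math.sqrt(var_dI)
    grid = sample_beta_grid(params.beta_mean, params.beta_sd, n_beta)
    rng = np.random.default_rng(seed)

    if mode in ("compare", "bounded"):
        if T is None:
            raise ValueError("controlled-duration modes require T")
        pts = run_duration_curve(config, params, [T], n_trials, seed, dt=dt,
                                 n_beta=n_beta, fits=fits,
                                 bound=theta if mode == "bounded" else None)
        return pts[0]

    if mode != "race":
        raise ValueError(f"unknown mode {mode!r}")
    if theta is None:
        raise ValueError("race mode requires theta")

    if beta_mode == "sample":
        betas = rng.choice(grid.values, size=n_trials, p=grid.weights)
        won_left, dec, _ = _batch_race(mean_dI, var_dI, tau, params, betas, S, theta, dt, rng)
        correct = won_left if _favored_is_left(config) else ~won_left
        p = correct.mean()
        rt = dec.mean() + NONDECISION_MS
        return SpeedAccuracyPoint(
            accuracy=float(p), mean_rt=float(rt),
            se_accuracy=float(math.sqrt(p * (1 - p) / n_trials)),
            se_rt=float(dec.std(ddof=1) / math.sqrt(n_trials)),
            theta=theta, n_trials=n_trials)

    accs = np.zeros(grid.values.size)
    rts = np.zeros(grid.values.size)
    acc_var = np.zeros(grid.values.size)
    rt_var = np.zeros(grid.values.size)
    for gi, beta in enumerate(grid.values):
        betas = np.full(n_trials, beta)
        won_left, dec, _ = _batch_race(mean_dI, var_dI, tau, params, betas, S, theta, dt, rng)
        correct = won_left if _favored_is_left(config) else ~won_left
        p = correct.mean()
        accs[gi], rts[gi] = p, dec.mean()
        acc_var[gi] = p * (1 - p) / n_trials
        rt_var[gi] = dec.var(ddof=1) / n_trials
    w = grid.weights
    accuracy = float((w * accs).sum())
    mean_rt = float((w * rts).sum() + NONDECISION_MS)
    return SpeedAccuracyPoint(
        accuracy=accuracy, mean_rt=mean_rt,
        se_accuracy=float(math.sqrt((w ** 2 * acc_var).sum())),
        se_rt=float(math.sqrt((w ** 2 * rt_var).sum())),
        theta=theta, n_trials=n_trials * grid.values.size)
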