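"""Task-level analysis: speed-accuracy curves, reward rate, fitting.

Speed-accuracy curves trace all (mean RT, accuracy) pairs attained by
sweeping the decision threshold theta in the race task.  Reward rate,

    RR = Accuracy / (<RT> + T_del),

collapses the two into correct responses per second, with T_del the
enforced inter-trial delay (default 3 s).  Threshold optimization
locates the reward-rate-maximizing theta by coarse-to-fine grid
search at a resolution of 0.1; the bias sweep repeats it across
mistuning biases beta-bar for several robustness limits.  The generic
behavioral-fitting routine recovers (theta, nu_gamma) from accuracy
and chronometric tables by least squares on a discrete grid.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .integrator_core import (
    NONDECISION_MS,
    IntegratorParams,
    SpeedAccuracyPoint,
    run_condition,
)
from .sensory_synth import SensoryConfig, stream_stats

__all__ = [
    "RewardRateResult",
    "speed_accuracy_curve",
    "reward_rate",
    "optimize_threshold",
    "bias_sweep",
    "fit_behavior",
    "wald_predictions",
    "behavior_tables",
    "accuracy_at_rt",
    "read_behavior_csv",
    "write_behavior_csv",
    "COHERENCE_GRID",
    "DURATION_GRID_MS",
]

#: Standard coherence levels (%) of the random-dot task family.
COHERENCE_GRID = (0.0, 3.2, 6.4, 12.8, 25.6, 51.2)

#: Viewing durations (ms) for controlled-duration curves.
DURATION_GRID_MS = (100.0, 200.0, 350.0, 500.0, 750.0, 1000.0, 1500.0, 2000.0)


@dataclass(frozen=True)
class RewardRateResult:
    rr: float  # correct responses per second
    theta_opt: float
    T_del: float  # s

    def __post_init__(self):
        if self.rr < 0:
            raise ValueError("reward rate must be non-negative")


def speed_accuracy_curve(
    config: SensoryConfig,
    params: IntegratorParams,
    theta_grid,
    n_trials: int,
    seed: int,
    dt: float = 0.5,
    n_beta: int = 19,
    fits: dict | None = None,
) -> list[SpeedAccuracyPoint]:
    """One (accuracy, mean RT) point per threshold in the race task."""
    theta_grid = list(theta_grid)
    if theta_grid != sorted(theta_grid):
        raise ValueError("theta_grid must be sorted ascending")
    pts = []
    for i, theta in enumerate(theta_grid):
        pts.append(run_condition(config, params, "race", theta=theta,
                                 n_trials=n_trials, seed=seed + 7919 * i,
                                 dt=dt, n_beta=n_beta, fits=fits))
    return pts


def reward_rate(accuracy: float, mean_rt: float, T_del: float) -> float:
    """Correct responses per second: accuracy / (mean RT + T_del), times in s."""
    if mean_rt < 0 or T_del < 0:
        raise ValueError("times must be non-negative")
    denom = mean_rt + T_del
    if denom == 0:
        raise ZeroDivisionError("mean_rt + T_del must be positive")
    return accuracy / denom


def _rr_of_point(p: SpeedAccuracyPoint, T_del: float) -> float:
    return reward_rate(p.accuracy, p.mean_rt / 1000.0, T_del)


def optimize_threshold(
    config: SensoryConfig,
    params: IntegratorParams,
    T_del: float,
    theta_range: tuple[float, float],
    seed: int,
    n_trials: int = 2000,
    resolution: float = 0.1,
    n_coarse: int = 9,
    dt: float = 0.5,
    n_beta: int = 19,
    fits: dict | None = None,
    performance_fn=None,
) -> RewardRateResult:
    """Reward-rate-maximizing threshold by coarse-to-fine grid search.

    The coarse pass brackets the maximum inside theta_range; the fine
    pass resolves theta to ``resolution``.  ``performance_fn(theta) ->
    (accuracy, mean_rt_ms)`` substitutes an analytic map for the
    Monte-Carlo evaluation (used for deterministic testing and quick
    theory runs).  A maximum on the range boundary triggers a warning
    suggesting range extension.
    """
    lo, hi = theta_range
    if not hi > lo > 0:
        raise ValueError("theta_range must satisfy 0 < lo < hi")

    def evaluate(theta: float) -> float:
        if performance_fn is not None:
            acc, rt_ms = performance_fn(theta)
            return reward_rate(acc, rt_ms / 1000.0, T_del)
        p = run_condition(config, params, "race", theta=theta,
                          n_trials=n_trials, seed=seed, dt=dt,
                          n_beta=n_beta, fits=fits)
        return _rr_of_point(p, T_del)

    coarse = np.linspace(lo, hi, n_coarse)
    rr_coarse = np.array([evaluate(t) for t in coarse])
    k = int(np.argmax(rr_coarse))
    if k in (0, n_coarse - 1):
        warnings.warn("reward-rate maximum at theta_range boundary; "
                      "extend the range to bracket the interior optimum")
    lo_f = coarse[max(k - 1, 0)]
    hi_f = coarse[min(k + 1, n_coarse - 1)]
    fine = np.arange(lo_f, hi_f + resolution / 2, resolution)
    rr_fine = np.array([evaluate(t) for t in fine])
    j = int(np.argmax(rr_fine))
    return RewardRateResult(rr=float(rr_fine[j]), theta_opt=float(round(fine[j], 10)),
                            T_del=T_del)


def bias_sweep(
    beta_means,
    config: SensoryConfig,
    params: IntegratorParams,
    R_hats=(0.0, 0.75, 1.25, 2.0),
    mode: str = "race",
    T_del: float = 3.0,
    theta_range: tuple[float, float] = (5.0, 60.0),
    duration: float = 1000.0,
    n_trials: int = 1000,
    seed: int = 0,
    dt: float = 0.5,
    fits: dict | None = None,
) -> pd.DataFrame:
    """Best performance per (beta-bar, R-hat): the mistuning-bias sweep.

    In race mode each cell reports the theta-optimized reward rate; in
    compare mode, accuracy at the given duration.  beta_sd is held at
    params.beta_sd (0.1 by default in the presets).
    """
    rows = []
    for i, bm in enumerate(beta_means):
        for j, rh in enumerate(R_hats):
            p = replace(params, beta_mean=float(bm), robustness=float(rh))
            cell_seed = seed + 104729 * i + 1299709 * j
            if mode == "race":
                res = optimize_threshold(config, p, T_del, theta_range,
                                         seed=cell_seed, n_trials=n_trials,
                                         resolution=0.5, dt=dt, fits=fits)
                rows.append({"beta_mean": bm, "R_hat": rh, "metric": "reward_rate",
                             "value": res.rr, "theta_opt": res.theta_opt})
            else:
                pt = run_condition(config, p, "compare", T=duration,
                                   n_trials=n_trials, seed=cell_seed, dt=dt,
                                   fits=fits)
                rows.append({"beta_mean": bm, "R_hat": rh, "metric": "accuracy",
                             "value": pt.accuracy, "theta_opt": float("nan")})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# analytic (diffusion-limit) behavioral predictions


def wald_predictions(
    config: SensoryConfig,
    theta: float,
    nu_gamma: float | None = None,
    fits: dict | None = None,
    kappa: float = 1.0 / 9.0,
    tau_E: float = 20.0,
) -> tuple[float, float]:
    """(accuracy, mean RT in ms) of the perfectly tuned, non-robust model.

    Diffusion-limit sequential analysis of the race task: the
    integrated input has drift kappa*m/tau_E and diffusion coefficient
    2 v tau (kappa/tau_E)^2, giving h0 = -m tau_E / (v tau kappa) in
    accumulator units.  Valid for the baseline model; mistuned or
    robust models require simulation.
    """
    if nu_gamma is not None:
        config = replace(config, nu_gamma=nu_gamma)
    m, v, tau = stream_stats(config, fits)
    a = kappa * m / tau_E  # drift per ms
    D = 2.0 * v * tau * (kappa / tau_E) ** 2  # diffusion per ms
    if m == 0.0:
        return 0.5, theta * theta / D + NONDECISION_MS
    h0 = -2.0 * a / D
    acc = 1.0 / (1.0 + math.exp(theta * h0))
    dt_ms = (theta / a) * math.tanh(-theta * h0 / 2.0)
    return acc, dt_ms + NONDECISION_MS


def behavior_tables(
    theta: float,
    nu_gamma: float,
    coherences=COHERENCE_GRID,
    favored_side: str = "left",
    fits: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Accuracy and chronometric tables predicted by the baseline theory."""
    rows = []
    for c in coherences:
        cfg = SensoryConfig(coherence=c, favored_side=favored_side, nu_gamma=nu_gamma)
        acc, rt = wald_predictions(cfg, theta, fits=fits)
        rows.append({"coherence_pct": c, "accuracy": acc, "mean_rt_ms": rt})
    df = pd.DataFrame(rows)
    return df[["coherence_pct", "accuracy"]], df[["coherence_pct", "mean_rt_ms"]]


def fit_behavior(
    acc_table: pd.DataFrame,
    rt_table: pd.DataFrame,
    params_base: IntegratorParams | None = None,
    grid_resolution: float = 0.1,
    theta_range: tuple[float, float] = (5.0, 40.0),
    nu_range: tuple[float, float] = (100.0, 1000.0),
    nu_resolution: float | None = None,
    model_fn=None,
    fits: dict | None = None,
) -> tuple[float, float, float]:
    """Joint grid search for (theta, nu_gamma) against behavioral tables.

    Tables carry columns coherence_pct plus accuracy / mean_rt_ms.
    The objective is the summed squared error of accuracy (fraction)
    and mean RT (seconds) across the shared coherence grid.
    ``model_fn(coherence, theta, nu_gamma) -> (accuracy, rt_ms)``
    defaults to the baseline diffusion-limit predictor.  Returns
    (theta_fit, nu_gamma_fit, sse).
    """
    if len(acc_table) == 0 or len(rt_table) == 0:
        raise ValueError("behavioral tables must be non-empty")
    cs = sorted(set(acc_table["coherence_pct"]) & set(rt_table["coherence_pct"]))
    if not cs:
        raise ValueError("accuracy and RT tables share no coherence values")
    acc_data = acc_table.set_index("coherence_pct")["accuracy"].loc[cs].to_numpy()
    rt_data = rt_table.set_index("coherence_pct")["mean_rt_ms"].loc[cs].to_numpy() / 1000.0

    if model_fn is None:
        kappa = params_base.kappa if params_base is not None else 1.0 / 9.0
        tau_E = params_base.tau_E if params_base is not None else 20.0

        def model_fn(c, theta, nu):
            cfg = SensoryConfig(coherence=c, nu_gamma=nu)
            return wald_predictions(cfg, theta, fits=fits, kappa=kappa, tau_E=tau_E)

    nu_resolution = nu_resolution or grid_resolution
    thetas = np.arange(theta_range[0], theta_range[1] + grid_resolution / 2,
                       grid_resolution)
    nus = np.arange(nu_range[0], nu_range[1] + nu_resolution / 2, nu_resolution)
    best = (float("nan"), float("nan"), float("inf"))
    for theta in thetas:
        for nu in nus:
            preds = [model_fn(c, theta, nu) for c in cs]
            acc_m = np.array([p[0] for p in preds])
            rt_m = np.array([p[1] for p in preds]) / 1000.0
            sse = float(((acc_m - acc_data) ** 2).sum() + ((rt_m - rt_data) ** 2).sum())
            if sse < best[2]:
                best = (float(theta), float(nu), sse)
    return best


# ---------------------------------------------------------------------------
# helpers


def accuracy_at_rt(points: list[SpeedAccuracyPoint], rt_ms: float) -> float:
    """Accuracy at a matched mean RT by piecewise-linear interpolation."""
    pts = sorted(points, key=lambda p: p.mean_rt)
    rts = np.array([p.mean_rt for p in pts])
    accs = np.array([p.accuracy for p in pts])
    if not rts[0] <= rt_ms <= rts[-1]:
        raise ValueError(f"rt {rt_ms} ms outside the attained range "
                         f"[{rts[0]:.0f}, {rts[-1]:.0f}] ms")
    return float(np.interp(rt_ms, rts, accs))


def write_behavior_csv(path, acc_table: pd.DataFrame, rt_table: pd.DataFrame) -> None:
    merged = acc_table.merge(rt_table, on="coherence_pct")
    merged.to_csv(path, index=False)


def read_behavior_csv(path) -> tuple[pd.DataFrame, pd.DataFrame]:
    df = pd.read_csv(path)
    return df[["coherence_pct", "accuracy"]], df[["coherence_pct", "mean_rt_ms"]]
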