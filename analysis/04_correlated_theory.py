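"""Why correlated evidence makes robustness cheap: the decorrelation story.

Compares controlled-duration accuracy of the continuous, temporally
correlated evidence model against the matched discrete/independent-
sample model as the dead zone widens, and traces the mechanism:

* the autocovariance of the dead-zoned OU stream decays faster with
  lag (shorter integral correlation time -> more effectively
  independent samples per unit time);
* the same thresholding, applied to a single correlated pair of
  samples, visibly lowers their Pearson correlation (0.5 -> ~0.41 at
  R-hat = 1 for the calibrated C = 12.8 stream).

    python analysis/04_correlated_theory.py [--n-samples-log2 22]
"""

import argparse
import math
import sys
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from robint.corr_theory import (
    accuracy_at_T,
    dead_zone_corr,
    integral_correlation_time,
    rectified_ou_autocov,
)
from robint.seq_analysis import accuracy_fixed_N, accuracy_fixed_N_robust
from robint.sensory_synth import OUParams, SensoryConfig, stream_stats

ROOT = Path(__file__).resolve().parents[1]


def main() -> int:
    ap = argparse.ArgumentParser()
    ap.add_argument("--n-samples-log2", type=int, default=22,
                    help="OU samples (power of two) for autocovariance estimates")
    ap.add_argument("--T", type=float, default=500.0)
    ap.add_argument("--seed", type=int, default=20130227)
    args = ap.parse_args()
    n_samples = 1 << args.n_samples_log2

    outdir = ROOT / "results"
    outdir.mkdir(exist_ok=True)

    m, v, tau = stream_stats(SensoryConfig(coherence=12.8))
    s = m / math.sqrt(v)
    params = OUParams(mean=m, variance=v, tau=tau)
    print(f"calibrated C=12.8 stream: momentary SNR {s:.3f}, tau {tau:.1f} ms")

    r_hats = (0.0, 0.25, 0.5, 0.75, 1.0, 1.25, 1.5, 2.0)
    cont = [accuracy_at_T(params, r, args.T, n_samples=n_samples, dt=0.1,
                          seed=args.seed) for r in r_hats]
    N = brentq(lambda n: accuracy_fixed_N(s, n) - cont[0], 1.0, 500.0)
    disc = [accuracy_fixed_N_robust(s, N, r) for r in r_hats]
    df = pd.DataFrame({"R_hat": r_hats, "continuous": cont, "discrete": disc})
    df.to_csv(outdir / "accuracy_vs_Rhat.csv", index=False)
    print(f"matched independent-sample model: N = {N:.1f} samples in "
          f"{args.T:.0f} ms (interval {args.T / N:.1f} ms)")
    print(df.round(4).to_string(index=False))
    print("-> the correlated stream tolerates roughly twice the dead zone")

    rows = []
    unit = OUParams(mean=0.0, variance=1.0, tau=tau)
    for r in (0.0, 0.5, 1.0, 1.5):
        acf = rectified_ou_autocov(unit, r, n_samples=n_samples, dt=0.1,
                                   seed=args.seed + 1, max_lag_ms=200.0)
        rows.append({"R_hat": r, "variance": acf.values[0],
                     "integral_corr_time_ms": integral_correlation_time(acf)})
        acf.to_csv(outdir / f"rectified_ou_autocov_Rhat{r:g}.csv")
    ct = pd.DataFrame(rows)
    ct.to_csv(outdir / "correlation_time_vs_Rhat.csv", index=False)
    print("\nintegral correlation time shrinks with the dead zone:")
    print(ct.round(2).to_string(index=False))

    pair = {r: dead_zone_corr(0.5, r, "quadrature", mu=s)
            for r in (0.0, 0.5, 1.0, 1.5)}
    print("\npairwise view (correlation 0.5 pair of signal samples):")
    for r, c in pair.items():
        print(f"  R-hat {r:g}: corr -> {c:.3f}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
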