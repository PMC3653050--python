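"""Discrete-time sequential analysis of the dead-zone increment model.

Three results, all closed-form or deterministic numerics:

1. the nontrivial MGF root h0 of the rectified-Gaussian increment is
   -2 mu / sigma^2 for every dead-zone width, so race-task accuracy at
   fixed threshold is untouched by robustness;
2. the mean increment E[Z_R] shrinks only at cubic order in R-hat, so
   the price of robustness (longer decisions) stays negligible until
   R-hat approaches ~1;
3. the resulting speed-accuracy predictions: decision time grows with
   R-hat while accuracy stays pinned.

    python analysis/03_sequential_theory.py
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from robint.seq_analysis import (
    RectifiedGaussian,
    rectified_moments,
    taylor_mean_deficit,
    wald_solution,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> int:
    outdir = ROOT / "results"
    outdir.mkdir(exist_ok=True)

    rows = []
    for s in (0.05, 0.1, 0.2):
        for r_hat in (0.0, 0.5, 1.0, 1.5, 2.0):
            d = RectifiedGaussian(mu=s, sigma=1.0, R=r_hat)
            m, v = rectified_moments(d)
            sol = wald_solution(d, theta=10.0)
            rows.append({"s": s, "R_hat": r_hat, "h0": sol.h0,
                         "h0_gaussian": -2 * s, "mean_increment": m,
                         "p0": d.p0, "accuracy_theta10": sol.accuracy,
                         "mean_steps_theta10": sol.mean_steps})
    df = pd.DataFrame(rows)
    df.to_csv(outdir / "wald_h0_table.csv", index=False)

    print("h0 invariance (max |h0 + 2s| over the grid):",
          f"{(df.h0 - df.h0_gaussian).abs().max():.2e}")
    for s, g in df.groupby("s"):
        acc_spread = g.accuracy_theta10.max() - g.accuracy_theta10.min()
        slow = g.mean_steps_theta10.max() / g.mean_steps_theta10.min()
        print(f"s={s}: accuracy spread across R-hat {acc_spread:.2e}; "
              f"decision time grows x{slow:.2f} from R-hat 0 to 2")

    rs = np.array([0.01, 0.02, 0.05, 0.1, 0.2, 0.3])
    exact = np.array([0.1 - rectified_moments(RectifiedGaussian(0.1, 1.0, r))[0]
                      for r in rs])
    taylor = np.array([taylor_mean_deficit(0.1, 1.0, r) for r in rs])
    slope = np.polyfit(np.log(rs[:4]), np.log(exact[:4]), 1)[0]
    print(f"\nmean-increment deficit: log-log slope {slope:.3f} (cubic law); "
          f"Taylor error at R-hat=0.3: {abs(taylor[-1] / exact[-1] - 1) * 100:.1f}%")
    pd.DataFrame({"R_hat": rs, "deficit_exact": exact,
                  "deficit_taylor": taylor}).to_csv(
        outdir / "mean_increment_deficit.csv", index=False)
    return 0


if __name__ == "__main__":
    sys.exit(main())
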