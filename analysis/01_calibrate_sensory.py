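"""Calibrate the synthetic sensory stage and build the pool-OU table.

For every pool firing rate implied by the standard coherence grid
(both the preferred and anti-preferred slopes of the linear rate
law), this script:

1. calibrates the spiking random-walk step SD so the simulated rate
   matches the rate law within 2%,
2. calibrates the common-input mixing weight so the 100-ms pairwise
   spike-count correlation matches the target 0.11,
3. simulates a long pooled, exponentially smoothed output and fits
   the OU surrogate (stationary variance and correlation time).

The fitted table is written to ``src/robint/data/ou_fits_default.json``
(the packaged default consumed by ``robint.sensory_synth``) and
echoed as a CSV under results/.  Run from the repository root:

    python analysis/01_calibrate_sensory.py [--quick]
"""

import argparse
import sys
import time
from pathlib import Path

import pandas as pd

from robint.decision_tasks import COHERENCE_GRID
from robint.sensory_synth import SensoryConfig, build_pool_fits

ROOT = Path(__file__).resolve().parents[1]


def main() -> int:
    ap = argparse.ArgumentParser()
    ap.add_argument("--quick", action="store_true",
                    help="shorter simulations (sanity check only; not written to the package)")
    ap.add_argument("--seed", type=int, default=20130227)
    args = ap.parse_args()

    cfg = SensoryConfig()
    rates = sorted({round(cfg.r0 + b * c, 4)
                    for c in COHERENCE_GRID for b in (cfg.b_pref, cfg.b_anti)})
    duration = 100_000.0 if args.quick else 500_000.0
    out_json = None if args.quick else ROOT / "src/robint/data/ou_fits_default.json"

    print(f"calibrating {len(rates)} pool rates (duration {duration/1000:.0f} s each)")
    t0 = time.time()
    table = build_pool_fits(rates, cfg, dt=0.5, duration=duration,
                            seed=args.seed, out_path=out_json)
    df = pd.DataFrame({k: table[k] for k in ("rate", "variance", "tau")})
    print(df.to_string(index=False, float_format=lambda x: f"{x:.3f}"))
    print(f"done in {time.time() - t0:.0f} s")
    if out_json:
        print(f"wrote {out_json}")
        outdir = ROOT / "results"
        outdir.mkdir(exist_ok=True)
        df.to_csv(outdir / "pool_ou_fits.csv", index=False)
    # sanity: variance should grow roughly linearly with rate (shot noise)
    slope = (df.variance / df.rate).describe()
    print("variance/rate ratio:\n", slope.to_string())
    return 0


if __name__ == "__main__":
    sys.exit(main())
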