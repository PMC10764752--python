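#!/usr/bin/env python
"""Build per-subject Fisher-z connectivity matrices from the cohort time
series and report the density-sweep edge counts.

Reads results/cohort (from 01_simulate_cohort.py); writes results/fc/.
"""

import argparse
from pathlib import Path

from fconn.config import RunConfig
from fconn.connectivity import density_grid
from fconn.pipeline import run_fc

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=ROOT / "results" / "cohort")
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    args = ap.parse_args()

    cfg = RunConfig(cohort_dir=str(args.cohort), out_dir=str(args.out))
    fcs = run_fc(cfg)
    n = fcs[0].n_nodes
    grid = density_grid(cfg.d_min, cfg.d_max, cfg.d_step)
    print(f"{len(fcs)} FC matrices written under {args.out}/fc ({n} nodes each)")
    print(
        f"density sweep: {len(grid)} thresholds from {grid[0]:.2f} to {grid[-1]:.2f}; "
        f"edge counts {round(grid[0] * n * (n - 1) / 2)}..{round(grid[-1] * n * (n - 1) / 2)}"
    )


if __name__ == "__main__":
    main()
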