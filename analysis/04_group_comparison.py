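#!/usr/bin/env python
"""Covariate-adjusted group comparison of AUC metrics and the clinical
correlation screen.

For each configured contrast, fits the GLM (age, sex, education, mean FD as
nuisance covariates) to every global AUC metric and every nodal AUC value
(FDR across nodes), then screens metrics with group differences against
clinical scores by partial correlation within each patient group.
"""

import argparse
from pathlib import Path

from fconn.config import RunConfig
from fconn.pipeline import run_compare

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=ROOT / "results" / "cohort")
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    args = ap.parse_args()

    cfg = RunConfig(cohort_dir=str(args.cohort), out_dir=str(args.out))
    results = run_compare(cfg)
    for contrast, res in results.items():
        if contrast == "correlation_screen":
            screen = res["screen"]
            n_sig = int(screen["significant"].sum()) if len(screen) else 0
            print(f"correlation screen: {len(screen)} tests, {n_sig} significant after FDR")
            continue
        g = res["global"]
        print(f"\n{contrast}: global AUC contrasts")
        print(g[["name", "t", "p", "cohens_d", "cohens_f2"]].round(4).to_string(index=False))
        n_sig = int(res["nodal"]["significant"].sum())
        print(f"nodal tests surviving FDR: {n_sig}")


if __name__ == "__main__":
    main()
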