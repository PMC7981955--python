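#!/usr/bin/env python
"""Logistic associations of predialysis plasma levels with PEW characteristics.

Fits the 4 predictors x 5 outcomes grid (sex-adjusted and multivariable)
plus the sensitivity variants, using the generated ground-truth outcome
columns, and reports the predialysis-plasma vs dialysate-loss Pearson
correlations.
"""

import argparse

import pandas as pd

from creapew import (
    build_analysis_frame,
    pearson_predialysis_vs_loss,
    phenotype_table,
    run_model_grid,
)
from creapew.io import read_cohort


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort-dir", default="results/cohort")
    ap.add_argument("--out", default="results")
    ap.add_argument("--no-sensitivity", action="store_true")
    args = ap.parse_args()

    from pathlib import Path
    Path(args.out).mkdir(parents=True, exist_ok=True)
    read = read_cohort(f"{args.cohort_dir}/patients.csv", f"{args.cohort_dir}/sessions.csv")
    outcomes = pd.read_csv(f"{args.cohort_dir}/outcomes.csv")
    ph = phenotype_table(read.patients, read.sessions)
    frame = build_analysis_frame(read.patients, read.sessions, ph)
    grid = run_model_grid(frame, outcomes, include_sensitivity=not args.no_sensitivity)
    grid.to_csv(f"{args.out}/associations.csv", index=False)

    ok = grid[grid["error"] == ""]
    print(f"association grid: {len(ok)}/{len(grid)} cells fitted -> {args.out}/associations.csv")
    print("sex-adjusted creatine odds ratios (per halving):")
    sub = ok.query("variant == 'sex_adjusted' and predictor == 'creatine'")
    for r in sub.itertuples():
        star = " *" if r.p_value < 0.05 else ""
        print(f"  {r.outcome:<16} OR {r.odds_ratio:5.2f} "
              f"[{r.ci_low:.2f}–{r.ci_high:.2f}]  p={r.p_value:.3f}{star}")

    print("predialysis plasma vs dialysate loss (Pearson):")
    for solute in ("arginine", "guanidinoacetate", "creatine", "creatinine"):
        sub = read.sessions[read.sessions["solute"] == solute]
        loss = sub["dialysate_volume_L"] * sub["dialysate_conc_umol_L"]
        r, p = pearson_predialysis_vs_loss(sub["plasma_pre_umol_L"], loss)
        print(f"  {solute:<18} r = {r:5.2f}  (p = {p:.2g})")


if __name__ == "__main__":
    main()
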