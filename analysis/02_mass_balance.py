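#!/usr/bin/env python
"""Intradialytic plasma changes and compartmental partition of dialysate losses.

Reads the cohort from results/cohort/, computes per-patient per-solute mass
balances (Abraham ECV), the sex-stratified cohort summary and the
extracellular/intracellular split, and writes them under results/.
"""

import argparse

import pandas as pd

from creapew import cohort_summary, compartment_shares, mass_balance_table
from creapew.io import read_cohort


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort-dir", default="results/cohort")
    ap.add_argument("--out", default="results")
    ap.add_argument("--ecv-formula", default="abraham", choices=["abraham", "bird"])
    args = ap.parse_args()

    from pathlib import Path
    Path(args.out).mkdir(parents=True, exist_ok=True)
    read = read_cohort(f"{args.cohort_dir}/patients.csv", f"{args.cohort_dir}/sessions.csv")
    mb = mass_balance_table(read.sessions, read.patients, args.ecv_formula)
    summ = cohort_summary(mb, read.patients)
    mb.to_csv(f"{args.out}/mass_balance.csv", index=False)
    summ.summary.to_csv(f"{args.out}/mass_balance_summary.csv", index=False)
    summ.tests.to_csv(f"{args.out}/mass_balance_tests.csv", index=False)

    print(f"mass balance for {mb['patient_id'].nunique()} patients "
          f"({args.ecv_formula} ECV) -> {args.out}/")
    for solute, sub in mb.groupby("solute"):
        ec, ic = sub["ec_loss_umol"].mean(), sub["ic_loss_umol"].mean()
        tot = sub["total_loss_umol"].mean()
        ec_s, ic_s = compartment_shares(tot, ec, rounded=True)
        print(f"  {solute:<18} plasma decrease {sub['prop_decrease_pct'].mean():5.1f} %   "
              f"total loss {tot:10.0f} μmol   EC {ec_s:3.0f} % / IC {ic_s:3.0f} %")
    p = summ.tests.query("contrast == 'ec_vs_ic' and stratum == 'all'")
    print("  EC-vs-IC paired test p-values:",
          {r.solute: f"{r.p_value:.2g}" for r in p.itertuples()})


if __name__ == "__main__":
    main()
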