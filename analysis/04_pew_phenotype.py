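#!/usr/bin/env python
"""Derive the protein-energy-wasting phenotype table.

Computes SMI (creatinine-equivalence), Maroni protein intake, Kt/V
(Daugirdas), BMI, albumin class and the CIS fatigue-severity score, then
applies the five classification thresholds.
"""

import argparse

from creapew import phenotype_table
from creapew.io import read_cohort

FLAGS = ("low_muscle", "low_protein", "hypoalbuminemia", "low_bmi", "severe_fatigue")


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort-dir", default="results/cohort")
    ap.add_argument("--out", default="results")
    args = ap.parse_args()

    from pathlib import Path
    Path(args.out).mkdir(parents=True, exist_ok=True)
    read = read_cohort(f"{args.cohort_dir}/patients.csv", f"{args.cohort_dir}/sessions.csv")
    ph = phenotype_table(read.patients, read.sessions)
    ph.to_csv(f"{args.out}/phenotype.csv", index=False)

    print(f"phenotype table for {len(ph)} patients -> {args.out}/phenotype.csv")
    print(f"  SMI (kg/m^2):        {ph['smi_kg_m2'].mean():.1f} ± {ph['smi_kg_m2'].std():.1f}")
    print(f"  protein (g/kg/24-h): {ph['protein_intake_g_kg_24h'].mean():.2f} ± "
          f"{ph['protein_intake_g_kg_24h'].std():.2f}")
    print(f"  Kt/V:                {ph['ktv'].mean():.2f} ± {ph['ktv'].std():.2f}")
    print("  PEW-characteristic prevalences:")
    for flag in FLAGS:
        print(f"    {flag:<16} {ph[flag].mean():.2f}")


if __name__ == "__main__":
    main()
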