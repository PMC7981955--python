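"""End-to-end pipeline: cohort tables -> mass balance, rates, phenotype, associations.

Stages are isolated: a failing stage is recorded in the bundle's
``errors`` mapping and stages that do not depend on it still run.  Given
identical inputs, configuration and seed the bundle is deterministic.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .anthropometry import bsa_du_bois
from .association import run_model_grid
from .config import PipelineConfig
from .excretion_rates import contribution_summary, excretion_table
from .io import write_cohort, write_truth
from .mass_balance import SOLUTES, cohort_summary, mass_balance_table
from .nutrition import phenotype_table
from .synthetic import generate_cohort

__all__ = ["build_analysis_frame", "run_pipeline"]

log = logging.getLogger(__name__)


def build_analysis_frame(
    patients: pd.DataFrame,
    sessions: pd.DataFrame,
    phenotype: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Per-patient frame with predictors and covariates for the logistic grid.

    Columns: ``plasma_<solute>_umol_L`` (predialysis), ``loss_<solute>_umol``
    (total dialysate loss), ``is_female``, ``age_years``, ``bsa_m2``
    (Du Bois on postdialysis weight), ``vintage_months``, ``hs_crp_mg_L``,
    access dummies, medication flags, ``residual_diuresis`` and ``ktv``
    (when a phenotype table is supplied).
    """
    wide_pre = sessions.pivot(index="patient_id", columns="solute",
                              values="plasma_pre_umol_L")
    loss = sessions.assign(
        loss=sessions["dialysate_volume_L"] * sessions["dialysate_conc_umol_L"]
    ).pivot(index="patient_id", columns="solute", values="loss")
    frame = patients.set_index("patient_id").copy()
    for s in SOLUTES:
        if s in wide_pre:
            frame[f"plasma_{s}_umol_L"] = wide_pre[s]
            frame[f"loss_{s}_umol"] = loss[s]
    frame["is_female"] = (frame["sex"] == "female").astype(float)
    frame["bsa_m2"] = bsa_du_bois(
        frame["weight_post_kg"].to_numpy(float), frame["height_m"].to_numpy(float)
    )
    for acc in ("upper_arm_fistula", "cvc", "graft"):  # lower_arm_fistula is reference
        frame[f"access_{acc}"] = (frame["access"] == acc).astype(float)
    for med in ("esa", "vitd", "steroid"):
        frame[med] = frame[med].astype(float)
    frame["residual_diuresis"] = frame["residual_diuresis"].astype(float)
    if phenotype is not None:
        frame["ktv"] = phenotype.set_index("patient_id")["ktv"]
    return frame.reset_index()


def run_pipeline(
    config: PipelineConfig,
    patients: Optional[pd.DataFrame] = None,
    sessions: Optional[pd.DataFrame] = None,
    outcomes: Optional[pd.DataFrame] = None,
    write: bool = True,
) -> dict:
    """Run all analysis stages; optionally write the result bundle to disk.

    With no input tables a synthetic cohort is generated from the config's
    seed and size (the generated outcome columns then drive the
    association grid; with real tables the phenotype flags do).
    """
    bundle: dict = {"errors": {}}
    truth = None
    if patients is None or sessions is None:
        cohort = generate_cohort(config.n_patients, config.seed, **config.simulator)
        patients, sessions, outcomes, truth = cohort
        bundle["truth"] = truth
    bundle["patients"], bundle["sessions"] = patients, sessions
    if outcomes is not None:
        bundle["outcomes"] = outcomes

    try:
        mb = mass_balance_table(sessions, patients, config.ecv_formula)
        bundle["mass_balance"] = mb
        summ = cohort_summary(mb, patients)
        bundle["summary"], bundle["tests"] = summ.summary, summ.tests
    except Exception as e:
        log.error("mass_balance stage failed: %s", e)
        bundle["errors"]["mass_balance"] = f"{type(e).__name__}: {e}"

    try:
        rates = excretion_table(sessions, patients)
        bundle["excretion"] = rates
        bundle["contribution"] = contribution_summary(rates)
    except Exception as e:
        log.error("excretion stage failed: %s", e)
        bundle["errors"]["excretion"] = f"{type(e).__name__}: {e}"

    phenotype = None
    try:
        phenotype = phenotype_table(
            patients, sessions, config.pew_thresholds(),
            config.cis_item_map, config.cis_reverse_items,
        )
        bundle["phenotype"] = phenotype
    except Exception as e:
        log.error("phenotype stage failed: %s", e)
        bundle["errors"]["phenotype"] = f"{type(e).__name__}: {e}"

    try:
        frame = build_analysis_frame(patients, sessions, phenotype)
        outcome_tbl = outcomes if outcomes is not None else phenotype
        if outcome_tbl is None:
            raise RuntimeError("no outcome table available (phenotype stage failed)")
        grid = run_model_grid(
            frame,
            outcome_tbl.set_index("patient_id").loc[frame["patient_id"]].reset_index(),
            include_sensitivity=config.sensitivity,
            firth=config.firth,
        )
        bundle["association"] = grid
    except Exception as e:
        log.error("association stage failed: %s", e)
        bundle["errors"]["association"] = f"{type(e).__name__}: {e}"

    if write:
        outdir = Path(config.output_dir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_cohort(patients, sessions, outdir, outcomes)
        if truth is not None:
            write_truth(truth, outdir)
        for key in ("mass_balance", "summary", "tests", "excretion", "contribution",
                    "phenotype", "association"):
            if key in bundle:
                bundle[key].to_csv(outdir / f"{key}.csv", index=False)
        (outdir / "report.txt").write_text(render_report(bundle))
    return bundle


def render_report(bundle: dict) -> str:
    """Plain-text report mirroring the cohort-summary and association layouts."""
    lines = ["Hemodialysis solute mass balance & PEW phenotype report", "=" * 56, ""]
    if "summary" in bundle:
        lines.append("Cohort summary (per solute, stratified by sex)")
        lines.append("-" * 46)
        s = bundle["summary"]
        for solute in s["solute"].unique():
            lines.append(f"\n{solute}")
            sub = s[s["solute"] == solute]
            for qty in sub["quantity"].unique():
                row = sub[sub["quantity"] == qty]
                cells = {r.stratum: r.display for r in row.itertuples()}
                lines.append(
                    f"  {qty:<24} all: {cells.get('all', '—'):<22}"
                    f" M: {cells.get('male', '—'):<22} F: {cells.get('female', '—')}"
                )
    if "contribution" in bundle and len(bundle["contribution"]):
        lines.append("\nUrinary contribution to combined daily excretion (residual diuresis)")
        lines.append("-" * 66)
        for r in bundle["contribution"].itertuples():
            lines.append(f"  {r.solute:<18} {r.urinary_contribution_pct:6.1f} %"
                         f"   (n={r.n_patients})")
    if "association" in bundle:
        lines.append("\nLogistic associations (OR [95% CI], p)")
        lines.append("-" * 40)
        grid = bundle["association"]
        for variant in ("sex_adjusted", "multivariable"):
            sub = grid[grid["variant"] == variant]
            if sub.empty:
                continue
            lines.append(f"\n{variant.replace('_', ' ')}:")
            for r in sub.itertuples():
                if r.error:
                    lines.append(f"  {r.predictor:<18} {r.outcome:<16} failed: {r.error}")
                else:
                    lines.append(
                        f"  {r.predictor:<18} {r.outcome:<16}"
                        f" {r.odds_ratio:5.2f} [{r.ci_low:.2f}–{r.ci_high:.2f}]"
                        f"  p={r.p_value:.3f}  ({r.unit_note})"
                    )
    if bundle.get("errors"):
        lines.append("\nStage failures:")
        for stage, msg in bundle["errors"].items():
            lines.append(f"  {stage}: {msg}")
    return "\n".join(lines) + "\n"
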