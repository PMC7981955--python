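"""Predictor scaling, logistic fits, the model grid and correlation analyses."""

import numpy as np
import pandas as pd
import pytest

from creapew import (
    DomainError,
    ModelSpec,
    RankDeficiencyError,
    SeparationError,
    build_analysis_frame,
    fit_association,
    fit_logistic,
    pearson_predialysis_vs_loss,
    run_model_grid,
    transform_predictor,
)


class TestTransformPredictor:
    def test_per_sd_decrease_maps_one_sd_below_mean_to_plus_one(self):
        x = np.array([10.0, 20.0, 30.0, 40.0, 50.0])
        t, note = transform_predictor(x, "per_sd_decrease")
        sd = np.std(x, ddof=1)
        below = np.mean(x) - sd
        t2, _ = transform_predictor(np.append(x, below), "per_sd_decrease")
        assert note == "per 1-SD decrease"
        assert t == pytest.approx(-(x - x.mean()) / sd)

    def test_per_halving_unit_is_one_halving(self):
        t, note = transform_predictor(np.array([32.0, 16.0]), "per_halving")
        assert note == "per halving"
        assert t[1] - t[0] == pytest.approx(1.0)

    def test_constant_predictor_rejected(self):
        with pytest.raises(DomainError, match="zero standard deviation"):
            transform_predictor(np.full(10, 3.0), "per_sd_decrease")

    def test_nonpositive_values_rejected_for_log2_with_row_listing(self):
        with pytest.raises(DomainError, match=r"\[1\]"):
            transform_predictor(np.array([5.0, 0.0, 2.0]), "per_halving")


def _bernoulli_data(n=400, beta=1.0, seed=3):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    p = 1 / (1 + np.exp(-(-0.3 + beta * x)))
    y = (rng.random(n) < p).astype(float)
    return y, pd.DataFrame({"x": x})


class TestFitLogistic:
    def test_or_equivariance_under_sign_flip(self):
        y, X = _bernoulli_data()
        params, _, _ = fit_logistic(y, X)
        params_neg, _, _ = fit_logistic(y, -X)
        assert params["x"] == pytest.approx(-params_neg["x"], rel=1e-6)

    def test_null_predictor_gives_or_near_one(self):
        rng = np.random.default_rng(11)
        y = (rng.random(600) < 0.4).astype(float)
        X = pd.DataFrame({"x": rng.normal(size=600)})
        params, bse, _ = fit_logistic(y, X)
        assert abs(params["x"]) < 2 * bse["x"] + 0.2

    def test_single_class_outcome_rejected(self):
        X = pd.DataFrame({"x": np.random.default_rng(0).normal(size=50)})
        with pytest.raises(DomainError):
            fit_logistic(np.zeros(50), X)

    def test_separation_raises_explicitly(self):
        x = np.concatenate([np.full(20, -3.0), np.full(20, 3.0)])
        y = (x > 0).astype(float)
        with pytest.raises(SeparationError):
            fit_logistic(y, pd.DataFrame({"x": x}))

    def test_firth_handles_separated_data(self):
        x = np.concatenate([np.full(20, -3.0), np.full(20, 3.0)])
        y = (x > 0).astype(float)
        params, bse, n = fit_logistic(y, pd.DataFrame({"x": x}), firth=True)
        assert np.isfinite(params["x"]) and np.isfinite(bse["x"]) and n == 40

    def test_duplicated_covariate_raises_rank_error(self):
        y, X = _bernoulli_data()
        X = X.assign(x_copy=X["x"])
        with pytest.raises(RankDeficiencyError):
            fit_logistic(y, X)


class TestFitAssociation:
    def test_ci_brackets_or_and_n_reported(self):
        rng = np.random.default_rng(5)
        n = 300
        creatine = rng.lognormal(np.log(26), 0.5, size=n)
        lp = -0.5 + np.log(2.0) * (-np.log2(creatine) - np.mean(-np.log2(creatine)))
        y = (rng.random(n) < 1 / (1 + np.exp(-lp))).astype(int)
        data = pd.DataFrame({"plasma_creatine_umol_L": creatine})
        out = pd.DataFrame({"severe_fatigue": y})
        spec = ModelSpec("severe_fatigue", "plasma_creatine_umol_L", "per_halving")
        res = fit_association(spec, data, out)
        assert res.ci_low <= res.odds_ratio <= res.ci_high
        assert res.n_used == n
        assert res.unit_note == "per halving"
        assert 1.2 < res.odds_ratio < 3.5  # true OR is 2 per halving

    def test_percentile_exclusion_reduces_n(self):
        rng = np.random.default_rng(6)
        n = 200
        data = pd.DataFrame({"plasma_creatine_umol_L": rng.lognormal(3, 0.5, n)})
        out = pd.DataFrame({"severe_fatigue": rng.integers(0, 2, n)})
        spec = ModelSpec(
            "severe_fatigue", "plasma_creatine_umol_L", "per_halving",
            exclude_above_percentile=95.0,
        )
        res = fit_association(spec, data, out)
        assert n - int(np.ceil(0.05 * n)) <= res.n_used < n


class TestModelGrid:
    def test_failing_outcome_isolated(self, cohort59):
        frame = build_analysis_frame(cohort59.patients, cohort59.sessions)
        outcomes = cohort59.outcomes.copy()
        outcomes["severe_fatigue"] = 1  # degenerate: single class
        grid = run_model_grid(frame, outcomes, include_sensitivity=False)
        bad = grid[grid["outcome"] == "severe_fatigue"]
        good = grid[grid["outcome"] != "severe_fatigue"]
        assert (bad["error"] != "").all()
        assert (good["error"] == "").any()

    def test_simulated_effects_detected_where_planted(self):
        # larger cohort: the planted creatine->fatigue effect must be
        # significant and the guanidinoacetate null must mostly stay null
        from creapew import generate_cohort

        cohort = generate_cohort(600, 19)
        frame = build_analysis_frame(cohort.patients, cohort.sessions)
        grid = run_model_grid(frame, cohort.outcomes, include_sensitivity=False)
        sexadj = grid[grid["variant"] == "sex_adjusted"].set_index(["predictor", "outcome"])
        assert sexadj.loc[("creatine", "severe_fatigue"), "p_value"] < 0.01
        assert sexadj.loc[("creatine", "severe_fatigue"), "odds_ratio"] > 1.5
        gaa = grid[(grid["predictor"] == "guanidinoacetate") & (grid["error"] == "")]
        assert (gaa["p_value"] > 0.05).mean() >= 0.8

    def test_unit_notes_follow_transform(self, cohort59):
        frame = build_analysis_frame(cohort59.patients, cohort59.sessions)
        grid = run_model_grid(frame, cohort59.outcomes, include_sensitivity=False)
        creatine = grid[grid["predictor"] == "creatine"]
        assert (creatine["unit_note"] == "per halving").all()
        others = grid[grid["predictor"] != "creatine"]
        assert (others["unit_note"] == "per 1-SD decrease").all()


class TestPearson:
    def test_collinear(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r, p = pearson_predialysis_vs_loss(x, 3 * x + 1)
        assert r == pytest.approx(1.0)
        r, _ = pearson_predialysis_vs_loss(x, -2 * x)
        assert r == pytest.approx(-1.0)

    def test_simulated_creatine_correlation_strong(self, mass_balance59):
        creat = mass_balance59.query("solute == 'creatine'")
        r, p = pearson_predialysis_vs_loss(
            creat["plasma_pre_umol_L"], creat["total_loss_umol"]
        )
        assert r > 0.8 and p < 0.001

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(DomainError):
            pearson_predialysis_vs_loss([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(DomainError):
            pearson_predialysis_vs_loss([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
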