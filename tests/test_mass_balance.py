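"""Plasma-change metrics and compartment partitioning of dialysate losses."""

import numpy as np
import pandas as pd
import pytest

from creapew import (
    DomainError,
    EcvEstimate,
    SoluteSession,
    absolute_decrease,
    cohort_summary,
    compartment_shares,
    extracellular_loss,
    intracellular_loss,
    mass_balance,
    proportional_decrease,
    total_loss,
)


@pytest.mark.parametrize(
    "pre,post,expected",
    [(689.0, 257.0, 432.0), (77.0, 60.0, 17.0), (42.0, 42.0, 0.0), (50.0, 60.0, -10.0)],
)
def test_absolute_decrease(pre, post, expected):
    assert absolute_decrease(pre, post) == pytest.approx(expected)


class TestProportionalDecrease:
    @pytest.mark.parametrize(
        "pre,post,expected",
        [(100.0, 50.0, 50.0), (77.0, 60.0, 100 * 17 / 77), (5.0, 5.0, 0.0)],
    )
    def test_values(self, pre, post, expected):
        assert proportional_decrease(pre, post) == pytest.approx(expected)

    def test_zero_predialysis_rejected(self):
        with pytest.raises(DomainError):
            proportional_decrease(0.0, 0.0)

    def test_mean_of_ratios_differs_from_ratio_of_means(self):
        # cohort-mean proportional decrease must be the mean of per-patient
        # ratios; the ratio of means is a different number on skewed data
        pre = np.array([100.0, 10.0])
        post = np.array([50.0, 9.0])
        mean_of_ratios = np.mean([proportional_decrease(a, b) for a, b in zip(pre, post)])
        ratio_of_means = proportional_decrease(pre.mean(), post.mean())
        assert mean_of_ratios == pytest.approx(30.0)
        assert abs(mean_of_ratios - ratio_of_means) > 10.0

    def test_mean_linearity_of_absolute_decrease(self):
        pre = np.array([100.0, 10.0, 55.0])
        post = np.array([50.0, 9.0, 31.0])
        assert np.mean(pre - post) == pytest.approx(
            absolute_decrease(pre.mean(), post.mean())
        )


class TestTotalLoss:
    @pytest.mark.parametrize(
        "v,c,expected",
        [(135.0, 5.33, 719.55), (135.0, 0.0, 0.0), (135.0, 114.8, 15498.0)],
    )
    def test_values(self, v, c, expected):
        assert total_loss(v, c) == pytest.approx(expected)

    def test_monotone_in_both_arguments(self):
        assert total_loss(140, 5.0) > total_loss(135, 5.0)
        assert total_loss(135, 6.0) > total_loss(135, 5.0)


class TestExtracellularLoss:
    def test_worked_example(self):
        ecv = EcvEstimate(15.9, 15.7, "abraham")
        # 689*15.9 - 257*15.7, evaluated independently
        assert extracellular_loss(689.0, 257.0, ecv) == pytest.approx(6920.2, abs=0.1)

    def test_zero_when_nothing_changes(self):
        ecv = EcvEstimate(15.0, 15.0, "abraham")
        assert extracellular_loss(100.0, 100.0, ecv) == 0.0

    def test_negative_value_returned_with_warning(self):
        ecv = EcvEstimate(15.0, 15.0, "abraham")
        with pytest.warns(UserWarning, match="negative"):
            v = extracellular_loss(50.0, 60.0, ecv)
        assert v < 0

    def test_accepts_session_object(self):
        ecv = EcvEstimate(15.9, 15.7, "abraham")
        s = SoluteSession("creatinine", 689.0, 257.0, 135.0, 114.8)
        assert extracellular_loss(s, ecv) == pytest.approx(6920.2, abs=0.1)


@pytest.mark.parametrize(
    "total,ec,expected",
    [(15500.0, 6800.0, 8700.0), (37.0, 12.0, 25.0), (7.0, 7.0, 0.0)],
)
def test_intracellular_loss(total, ec, expected):
    assert intracellular_loss(total, ec) == pytest.approx(expected)


class TestCompartmentShares:
    @pytest.mark.parametrize(
        "total,ec,shares",
        [
            (15.5, 6.8, (44, 56)),
            (37.0, 12.0, (32, 68)),
            (1939.0, 287.0, (15, 85)),
        ],
    )
    def test_rounded_shares_match_reported_splits(self, total, ec, shares):
        assert compartment_shares(total, ec, rounded=True) == shares

    def test_shares_sum_to_100_before_rounding(self):
        ec_s, ic_s = compartment_shares(37.0, 12.0)
        assert ec_s + ic_s == pytest.approx(100.0, rel=1e-12)

    def test_scale_invariance(self):
        assert compartment_shares(15.5, 6.8) == pytest.approx(
            compartment_shares(15500.0, 6800.0)
        )

    def test_zero_total_rejected(self):
        with pytest.raises(DomainError):
            compartment_shares(0.0, 0.0)


def test_partition_conserves_total(mass_balance59):
    mb = mass_balance59
    assert np.allclose(
        mb["total_loss_umol"], mb["ec_loss_umol"] + mb["ic_loss_umol"], rtol=1e-12
    )


def test_mass_balance_flags_negative_components():
    ecv = EcvEstimate(15.0, 15.0, "abraham")
    s = SoluteSession("creatine", 20.0, 30.0, 135.0, 1.0)
    res = mass_balance(s, ecv)
    assert res.flag_negative_ec and res.ec_loss < 0
    assert res.total_loss == pytest.approx(res.ec_loss + res.ic_loss)


def _tiny_mb_frame(pre, post, sex=("male", "male", "female", "female")):
    n = len(pre)
    return (
        pd.DataFrame(
            {
                "patient_id": [f"P{i}" for i in range(n)],
                "solute": "creatinine",
                "plasma_pre_umol_L": pre,
                "plasma_post_umol_L": post,
                "abs_decrease_umol_L": np.asarray(pre) - np.asarray(post),
                "prop_decrease_pct": 100 * (np.asarray(pre) - np.asarray(post)) / np.asarray(pre),
                "total_loss_umol": 1000.0,
                "ec_loss_umol": 400.0,
                "ic_loss_umol": 600.0,
            }
        ),
        pd.DataFrame({"patient_id": [f"P{i}" for i in range(n)], "sex": list(sex)[:n]}),
    )


class TestCohortSummary:
    def test_identical_pre_post_gives_null_paired_test(self):
        mb, pats = _tiny_mb_frame([600.0, 650.0, 700.0, 620.0], [600.0, 650.0, 700.0, 620.0])
        res = cohort_summary(mb, pats)
        row = res.tests.query("contrast == 'pre_vs_post' and stratum == 'all'")
        assert row["p_value"].iloc[0] == pytest.approx(1.0)
        dec = res.summary.query("quantity == 'abs_decrease_umol_L' and stratum == 'all'")
        assert dec["mean"].iloc[0] == pytest.approx(0.0)

    def test_constant_decrease_has_zero_sd(self):
        mb, pats = _tiny_mb_frame([600.0, 650.0, 700.0, 620.0], [550.0, 600.0, 650.0, 570.0])
        res = cohort_summary(mb, pats)
        dec = res.summary.query("quantity == 'abs_decrease_umol_L' and stratum == 'all'")
        assert dec["mean"].iloc[0] == pytest.approx(50.0)
        assert dec["sd"].iloc[0] == pytest.approx(0.0)

    def test_simulated_cohort_detects_intracellular_dominance(self, mass_balance59, cohort59):
        # creatine removal is overwhelmingly intracellular in the simulator;
        # the paired EC-vs-IC contrast must pick that up
        res = cohort_summary(mass_balance59, cohort59.patients)
        creat = mass_balance59.query("solute == 'creatine'")
        assert creat["ic_loss_umol"].mean() > creat["ec_loss_umol"].mean()
        p = res.tests.query(
            "solute == 'creatine' and contrast == 'ec_vs_ic' and stratum == 'all'"
        )["p_value"].iloc[0]
        assert p < 0.001

    def test_normality_override_switches_presentation(self, mass_balance59, cohort59):
        res = cohort_summary(
            mass_balance59, cohort59.patients, normality_override={"creatine": "median"}
        )
        rows = res.summary.query("solute == 'creatine' and stratum == 'all'")
        assert (~rows["normal"]).all()
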