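"""PEW phenotype variables: Kt/V, CER/CUER, SMI, Maroni intake, CIS fatigue, flags."""

import numpy as np
import pytest

from creapew import (
    DEFAULT_THRESHOLDS,
    DomainError,
    cer_combined,
    cis_fatigue,
    classify_pew,
    cuer,
    ktv_daugirdas,
    phenotype_table,
    protein_intake_maroni,
    smi,
)
from creapew.nutrition import CIS_FATIGUE_ITEMS, CIS_REVERSE_ITEMS


class TestKtv:
    def test_worked_example(self):
        # -ln(0.37 - 0.032) + (4 - 3.5*0.37) * 1.9/78, evaluated independently
        assert ktv_daugirdas(0.37, 4.0, 1.9, 78.0) == pytest.approx(1.1506, abs=1e-3)

    def test_zero_when_log_argument_is_one_and_no_uf(self):
        assert ktv_daugirdas(1.032, 4.0, 0.0, 78.0) == pytest.approx(0.0)

    def test_cohort_typical_scale(self):
        # typical session (R~0.35, 4 h, 2 L UF, 78 kg) lands near the usual 1.4
        v = ktv_daugirdas(0.35, 4.0, 2.0, 78.0)
        assert 1.0 < v < 1.8

    def test_monotonicity_grid(self):
        R = np.linspace(0.25, 0.6, 8)
        vals = [ktv_daugirdas(r, 4.0, 1.9, 78.0) for r in R]
        assert np.all(np.diff(vals) < 0)  # strictly decreasing in R
        t = np.linspace(3.0, 5.0, 6)
        vals = [ktv_daugirdas(0.37, tt, 1.9, 78.0) for tt in t]
        assert np.all(np.diff(vals) > 0)  # increasing in t
        uf = np.linspace(0.0, 4.0, 6)
        vals = [ktv_daugirdas(0.37, 4.0, u, 78.0) for u in uf]
        assert np.all(np.diff(vals) > 0)  # increasing in UF

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            ktv_daugirdas(0.02, 4.0, 1.9, 78.0)  # R - 0.008 t <= 0
        with pytest.raises(DomainError):
            ktv_daugirdas(0.37, 4.0, 1.9, 0.0)


class TestExcretionRateCombination:
    def test_cer_worked_example(self):
        assert cer_combined(135.0, 0.1148, 3, 0.0) == pytest.approx(6.642, abs=1e-3)

    def test_cer_urinary_additivity(self):
        assert cer_combined(135.0, 0.1148, 3, 2.0) == pytest.approx(8.642, abs=1e-3)

    def test_cer_zero_warns(self):
        with pytest.warns(UserWarning):
            assert cer_combined(135.0, 0.0, 3, 0.0) == 0.0

    def test_cuer_worked_example(self):
        assert cuer(135.0, 15.0, 3, 0.0) == pytest.approx(867.86, abs=0.01)

    def test_cuer_additivity_and_zero(self):
        assert cuer(135.0, 15.0, 3, 10.0) == pytest.approx(877.86, abs=0.01)
        assert cuer(135.0, 0.0, 3, 0.0) == 0.0


class TestSmi:
    def test_creatinine_equivalence(self):
        # 1 g creatinine/24-h (8.84 mmol) marks 22.73 kg of skeletal muscle
        assert smi(8.84, 1.0) == pytest.approx(22.73, rel=1e-12)

    def test_height_scaling(self):
        assert smi(8.84, 1.75) == pytest.approx(22.73 / 1.75**2, rel=1e-12)

    def test_linear_in_cer_inverse_quadratic_in_height(self):
        assert smi(2 * 8.84, 1.75) == pytest.approx(2 * smi(8.84, 1.75), rel=1e-12)
        assert smi(8.84, 2 * 1.75) == pytest.approx(smi(8.84, 1.75) / 4, rel=1e-12)

    def test_zero_and_errors(self):
        assert smi(0.0, 1.7) == 0.0
        with pytest.raises(DomainError):
            smi(8.84, 0.0)


class TestMaroni:
    def test_worked_example(self):
        # 6.25*(0.028*300 + 0.031*78)/78, evaluated independently
        assert protein_intake_maroni(300.0, 78.0, 0.0) == pytest.approx(0.8668, abs=1e-4)

    def test_urea_free_limit(self):
        # CUER -> 0 collapses to 6.25 * 0.031 regardless of body weight
        for bw in (50.0, 78.0, 110.0):
            assert protein_intake_maroni(0.0, bw, 0.0) == pytest.approx(0.19375, rel=1e-12)

    def test_upe_additivity(self):
        base = protein_intake_maroni(300.0, 78.0, 0.0)
        assert protein_intake_maroni(300.0, 78.0, 7.8) == pytest.approx(base + 0.1, rel=1e-9)

    def test_closed_form_on_grid(self):
        for c in (100.0, 300.0, 600.0):
            for bw in (50.0, 90.0):
                expected = (6.25 * (0.028 * c + 0.031 * bw) + 1.0) / bw
                assert protein_intake_maroni(c, bw, 1.0) == pytest.approx(expected, rel=1e-12)

    def test_non_positive_weight_rejected(self):
        with pytest.raises(DomainError):
            protein_intake_maroni(300.0, 0.0)


class TestCisFatigue:
    @staticmethod
    def _items_with_subscale_contribution(c: int) -> list[int]:
        """All 20 responses set so every fatigue-subscale item contributes c."""
        items = [4] * 20
        for idx in CIS_FATIGUE_ITEMS:
            items[idx - 1] = (8 - c) if idx in CIS_REVERSE_ITEMS else c
        return items

    def test_range_extremes(self):
        assert cis_fatigue(self._items_with_subscale_contribution(7)) == 56
        assert cis_fatigue(self._items_with_subscale_contribution(1)) == 8

    def test_reverse_scoring_applied(self):
        low = self._items_with_subscale_contribution(1)
        # a reversed item answered 1 contributes 7, not 1
        reversed_idx = CIS_REVERSE_ITEMS[0]
        assert low[reversed_idx - 1] == 7
        low[reversed_idx - 1] = 1
        assert cis_fatigue(low) == 8 + 6

    def test_boundary_score_flags_severe_fatigue(self):
        ph = classify_pew("male", 12.0, 1.0, 40.0, 25.0, 35.0)
        assert ph.severe_fatigue
        ph = classify_pew("male", 12.0, 1.0, 40.0, 25.0, 34.0)
        assert not ph.severe_fatigue

    def test_invalid_items_rejected(self):
        with pytest.raises(DomainError):
            cis_fatigue([4] * 19)
        with pytest.raises(DomainError):
            cis_fatigue([0] + [4] * 19)


class TestClassifyPew:
    def test_sex_specific_muscle_threshold(self):
        assert classify_pew("male", 10.0, 1.0, 40.0, 25.0, 10.0).low_muscle
        assert not classify_pew("female", 10.0, 1.0, 40.0, 25.0, 10.0).low_muscle

    def test_strict_boundaries(self):
        ph = classify_pew("male", 10.76, 0.8, 38.0, 23.0, 10.0)
        assert not (ph.low_muscle or ph.low_protein or ph.hypoalbuminemia or ph.low_bmi)
        ph = classify_pew("male", 10.75, 0.79, 37.99, 22.99, 10.0)
        assert ph.low_muscle and ph.low_protein and ph.hypoalbuminemia and ph.low_bmi

    def test_unknown_sex_rejected(self):
        with pytest.raises(DomainError):
            classify_pew("other", 10.0, 1.0, 40.0, 25.0, 10.0)

    def test_idempotent_pure_function(self):
        a = classify_pew("female", 6.0, 0.7, 36.0, 21.0, 40.0)
        b = classify_pew("female", 6.0, 0.7, 36.0, 21.0, 40.0)
        assert a == b


def test_phenotype_table_flags_reproducible(cohort59):
    ph = phenotype_table(cohort59.patients, cohort59.sessions)
    assert (ph["ktv"] > 0).all()
    th = DEFAULT_THRESHOLDS
    cut = np.where(ph["sex"] == "male", th.smi_male, th.smi_female)
    assert (ph["low_muscle"] == (ph["smi_kg_m2"] < cut)).all()
    assert (ph["low_protein"] == (ph["protein_intake_g_kg_24h"] < th.protein_intake)).all()
    assert (ph["hypoalbuminemia"] == (ph["albumin_g_L"] < th.albumin)).all()
    assert (ph["low_bmi"] == (ph["bmi_kg_m2"] < th.bmi)).all()
    assert (ph["severe_fatigue"] == (ph["cis_fatigue_score"] >= th.cis_fatigue)).all()
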