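"""Dose-response fitting, synergy surfaces and the scoring-category table."""

import numpy as np
import pandas as pd
import pytest

from pathsynergy import (
    DoseMatrix,
    bliss_surface,
    category_comparison,
    fit_hill,
    hsa_surface,
    loewe_surface,
    read_dose_matrix,
    summarize_synergy,
    write_dose_matrix,
)
from pathsynergy.combination import assign_categories, hill_curve

DOSES = np.array([0.0, 3.0, 10.0, 30.0, 100.0, 300.0, 1000.0, 3000.0])


def matrix_from_effect(effect, doses_a=DOSES, doses_b=DOSES):
    return DoseMatrix("A", "B", doses_a, doses_b, effect)


class TestHillFit:
    @pytest.mark.parametrize("ec50", [10.0, 100.0, 1000.0])
    @pytest.mark.parametrize("hill", [0.5, 1.0, 2.0])
    def test_noiseless_recovery(self, ec50, hill):
        doses = np.array([0.0, 1.0, 3.0, 10.0, 30.0, 100.0, 1000.0, 10000.0])
        effects = hill_curve(doses, 0.0, 1.0, ec50, hill)
        fit = fit_hill(doses, effects)
        assert fit.ec50 == pytest.approx(ec50, rel=0.01)
        assert fit.hill == pytest.approx(hill, rel=0.01)
        assert fit.gi50 == pytest.approx(ec50, rel=0.01)  # e0=0, emax=1 -> GI50=EC50

    def test_gi90_not_reached_when_plateau_below_target(self):
        # a drug plateauing at 46% inhibition has a GI50 but no GI90
        doses = np.array([0.0, 10.0, 30.0, 100.0, 300.0, 1000.0, 3000.0, 10000.0])
        effects = hill_curve(doses, 0.0, 0.46, 150.0, 1.0)
        fit = fit_hill(doses, effects)
        assert fit.gi50 is None and fit.gi90 is None
        assert fit.gi_label("gi90").startswith("> ")

    def test_gi50_beyond_tested_range_not_reached(self):
        doses = np.array([0.0, 1.0, 3.0, 10.0, 30.0, 100.0, 300.0, 1000.0])
        effects = hill_curve(doses, 0.0, 1.0, 5e4, 1.0)  # GI50 far above max dose
        fit = fit_hill(doses, effects)
        assert fit.gi50 is None

    def test_flat_zero_response_degenerates_without_error(self):
        fit = fit_hill(DOSES, np.zeros_like(DOSES))
        assert fit.degenerate and fit.gi50 is None and fit.gi90 is None

    def test_too_few_doses(self):
        with pytest.raises(ValueError, match="at least 4"):
            fit_hill([0.0, 1.0, 10.0], [0.0, 0.1, 0.5])


class TestBliss:
    def test_multiplicative_null_is_zero(self):
        ea = hill_curve(DOSES, 0.0, 0.8, 50.0, 1.0)
        eb = hill_curve(DOSES, 0.0, 0.6, 200.0, 1.5)
        effect = ea[:, None] + eb[None, :] - ea[:, None] * eb[None, :]
        res = bliss_surface(matrix_from_effect(effect))
        np.testing.assert_allclose(res.surface, 0.0, atol=1e-9)
        assert res.summary == pytest.approx(0.0, abs=1e-6)

    def test_single_cell_arithmetic(self):
        # Ea=0.5, Eb=0.5, observed 0.9 -> synergy 100*(0.9-0.75) = 15
        doses = np.array([0.0, 100.0])
        effect = np.array([[0.0, 0.5], [0.5, 0.9]])
        res = bliss_surface(matrix_from_effect(effect, doses, doses))
        assert res.surface[0, 0] == pytest.approx(15.0)


class TestLoewe:
    def test_sham_self_combination_is_zero(self):
        # a drug combined with itself: observed effect at the summed dose
        fit = fit_hill(DOSES, hill_curve(DOSES, 0.0, 0.9, 100.0, 1.2))
        total = DOSES[:, None] + DOSES[None, :]
        effect = fit.effect_at(total)
        res = loewe_surface(matrix_from_effect(effect), fit, fit)
        assert np.nanmax(np.abs(res.surface)) < 1e-4  # 1e-6 on the fraction scale

    def test_two_identical_curves_additive_construction(self):
        e0, emax, ec50, h = 0.0, 0.95, 80.0, 1.0
        doses = np.array([0.0, 10.0, 30.0, 100.0, 300.0, 1000.0])
        fit = fit_hill(doses, hill_curve(doses, e0, emax, ec50, h))
        effect = hill_curve(doses[:, None] + doses[None, :], e0, emax, ec50, h)
        res = loewe_surface(matrix_from_effect(effect, doses, doses), fit, fit)
        assert np.nanmax(np.abs(res.surface)) < 1e-4

    def test_super_additive_matrix_scores_positive(self):
        fit = fit_hill(DOSES, hill_curve(DOSES, 0.0, 0.9, 100.0, 1.2))
        total = DOSES[:, None] + DOSES[None, :]
        effect = fit.effect_at(total)
        boosted = effect.copy()
        boosted[1:, 1:] = np.clip(boosted[1:, 1:] + 0.08, 0.0, 1.0)
        null = loewe_surface(matrix_from_effect(effect), fit, fit)
        res = loewe_surface(matrix_from_effect(boosted), fit, fit)
        assert res.summary > null.summary
        assert res.summary > 0.0

    def test_degenerate_fit_rejected(self):
        flat = fit_hill(DOSES, np.zeros_like(DOSES))
        good = fit_hill(DOSES, hill_curve(DOSES, 0.0, 0.9, 100.0, 1.0))
        effect = np.zeros((len(DOSES), len(DOSES)))
        with pytest.raises(ValueError, match="invertible"):
            loewe_surface(matrix_from_effect(effect), flat, good)


class TestHsa:
    def test_max_of_monotherapies_is_zero(self):
        ea = hill_curve(DOSES, 0.0, 0.8, 50.0, 1.0)
        eb = hill_curve(DOSES, 0.0, 0.6, 200.0, 1.5)
        effect = np.maximum(ea[:, None], eb[None, :])
        res = hsa_surface(matrix_from_effect(effect))
        np.testing.assert_allclose(res.surface, 0.0, atol=1e-9)

    def test_bliss_observation_is_hsa_positive(self):
        ea = hill_curve(DOSES, 0.0, 0.8, 50.0, 1.0)
        eb = hill_curve(DOSES, 0.0, 0.6, 200.0, 1.5)
        effect = ea[:, None] + eb[None, :] - ea[:, None] * eb[None, :]
        res = hsa_surface(matrix_from_effect(effect))
        assert np.all(res.surface[1:, 1:] > 0.0)  # both effects in (0,1) there

    def test_hsa_synergy_dominates_bliss_cellwise(self):
        rng = np.random.default_rng(3)
        ea = hill_curve(DOSES, 0.0, 0.8, 50.0, 1.0)
        eb = hill_curve(DOSES, 0.0, 0.6, 200.0, 1.5)
        observed = np.clip(
            ea[:, None] + eb[None, :] - ea[:, None] * eb[None, :]
            + rng.normal(0, 0.03, (len(DOSES), len(DOSES))),
            0.0, 1.0,
        )
        observed[0, 0] = 0.0
        m = matrix_from_effect(observed)
        # Bliss-expected >= HSA-expected for effects in (0,1), so HSA synergy >= Bliss
        assert np.all(hsa_surface(m).surface >= bliss_surface(m).surface - 1e-9)


class TestSummary:
    def test_zero_surface_sums_to_zero(self):
        from pathsynergy.combination import SynergyResult

        res = SynergyResult("bliss", np.zeros((3, 3)), 0.0)
        assert summarize_synergy(res, "sum").summary == 0.0

    def test_single_cell_uniform_sum(self):
        from pathsynergy.combination import SynergyResult

        surface = np.zeros((3, 3))
        surface[1, 2] = 8.0
        res = SynergyResult("bliss", surface, 0.0)
        assert summarize_synergy(res, "sum").summary == pytest.approx(8.0)
        assert summarize_synergy(res, "mean").summary == pytest.approx(8.0 / 9)


class TestCategories:
    def test_score_type_parsing(self):
        assert assign_categories({"score_type": "Res", "single_or_comb": "S&C"}) == ["Res-score"]
        assert assign_categories({"score_type": "Res/Score1", "single_or_comb": "S&C"}) == [
            "Res-score", "Score1",
        ]
        assert assign_categories({"score_type": "Selected CM&FoM", "single_or_comb": "S&C"}) == [
            "Selected",
        ]
        assert assign_categories({"score_type": "PC", "single_or_comb": "C"}) == []
        assert assign_categories({"score_type": None, "single_or_comb": "S"}) == [
            "Single agents",
        ]
        assert assign_categories({"score_type": None, "single_or_comb": "C"}) == []

    def test_comparison_arithmetic_on_toy_table(self):
        table = pd.DataFrame(
            {
                "compound": ["a", "b", "c", "d", "e"],
                "single_or_comb": ["C", "C", "S", "S", "S"],
                "score_type": ["Score1", "Score1", None, None, None],
                "loewe_combenefit": [30.0, 20.0, 10.0, 5.0, 15.0],
                "bliss_combenefit": [6.0, 4.0, 2.0, 1.0, 3.0],
            }
        )
        result = category_comparison(table)
        assert result.loc["Score1", "avg_loewe_combenefit"] == pytest.approx(25.0)
        assert result.loc["Single agents", "avg_loewe_combenefit"] == pytest.approx(10.0)
        assert result.loc["Score1", "div_loewe_combenefit"] == pytest.approx(2.5)
        assert result.loc["Score1", "div_bliss_combenefit"] == pytest.approx(2.5)
        p = result.loc["Score1", "ttest_loewe_combenefit"]
        assert 0.0 < p < 0.5  # one-tailed: combinations exceed singles

    def test_missing_single_agent_reference_errors(self):
        table = pd.DataFrame(
            {"single_or_comb": ["C"], "score_type": ["Score1"],
             "loewe_combenefit": [10.0], "bliss_combenefit": [1.0]}
        )
        with pytest.raises(ValueError, match="single-agent"):
            category_comparison(table)


class TestDoseMatrixIO:
    def test_roundtrip(self, tmp_path):
        ea = hill_curve(DOSES, 0.0, 0.8, 50.0, 1.0)
        eb = hill_curve(DOSES, 0.0, 0.6, 200.0, 1.5)
        effect = ea[:, None] + eb[None, :] - ea[:, None] * eb[None, :]
        m = matrix_from_effect(effect)
        path = tmp_path / "m.csv"
        write_dose_matrix(m, path)
        back = read_dose_matrix(path)
        assert back.drug_a == "A" and back.drug_b == "B"
        np.testing.assert_allclose(back.effect, m.effect, atol=1e-6)
        np.testing.assert_allclose(back.doses_a, m.doses_a)

    def test_grid_validation(self):
        with pytest.raises(ValueError, match="dose 0"):
            DoseMatrix("A", "B", np.array([1.0, 2.0]), np.array([0.0, 1.0]),
                       np.zeros((2, 2)))
        with pytest.raises(ValueError, match="ascending"):
            DoseMatrix("A", "B", np.array([0.0, 2.0, 1.0]), np.array([0.0, 1.0]),
                       np.zeros((3, 2)))
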