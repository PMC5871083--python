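"""Quartile coding, predictive equation, OR grid and cut-off table."""

import numpy as np
import pandas as pd
import pytest

import coagcomp as cc
from coagcomp.biomarker import (
    C4_SCHEME,
    DDIMER_SCHEME,
    DEFAULT_EQUATION,
    RULE_ORDER,
    PredictiveEquation,
    estimate_quartiles,
    evaluate_rules,
    fit_equation,
    linear_predictor,
    or_grid,
    predict_probability,
    quartile_code,
)

#: The 16 cut-off probabilities of the built-in equation, in RULE_ORDER.
EXPECTED_CUTOFFS = [
    0.932, 0.868, 0.760, 0.604, 0.872, 0.773, 0.629, 0.783,
    0.655, 0.501, 0.664, 0.519, 0.533, 0.398, 0.406, 0.303,
]


class TestQuartileCode:
    @pytest.mark.parametrize(
        "value, expected",
        [(3.10, 4), (0.56, 1), (0.57, 2), (1.20, 2), (2.80, 3), (0.0, 1)],
    )
    def test_ddimer_coding(self, value, expected):
        assert quartile_code(value, DDIMER_SCHEME) == expected

    @pytest.mark.parametrize(
        "value, expected",
        [(0.04, 4), (0.05, 4), (0.051, 3), (0.12, 3), (0.20, 2), (0.25, 1)],
    )
    def test_c4_coding_is_reversed(self, value, expected):
        assert quartile_code(value, C4_SCHEME) == expected

    def test_vectorized_and_negative_rejected(self):
        codes = quartile_code([0.1, 0.9, 2.0, 5.0], DDIMER_SCHEME)
        assert codes.tolist() == [1, 2, 3, 4]
        with pytest.raises(ValueError):
            quartile_code(-0.1, DDIMER_SCHEME)


class TestEstimateQuartiles:
    def test_linear_interpolation_percentiles(self):
        scheme = estimate_quartiles(np.arange(1, 9), "x")
        assert scheme.cuts == pytest.approx((2.75, 4.5, 6.25))

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            estimate_quartiles(np.ones(10), "x")
        with pytest.raises(ValueError):
            estimate_quartiles(np.arange(5), "x")

    def test_round_trip_on_synthetic_cohort(self):
        """Codes are uniform over intervals bounded by the fixed cuts, so
        empirical quartiles of the simulated concentrations land on them."""
        df = cc.gen_cohort3(n_patients=20_000, seed=6, extra_markers=False)
        dd = estimate_quartiles(df["ddimer"], "D-dimer")
        np.testing.assert_allclose(dd.cuts, (0.56, 1.20, 2.80), rtol=0.05)
        c4 = estimate_quartiles(df["c4"], "C4", "lower_is_risk")
        np.testing.assert_allclose(c4.cuts, (0.05, 0.12, 0.20), rtol=0.05)


class TestEquation:
    def test_worked_example(self):
        assert linear_predictor(DEFAULT_EQUATION, 4, 4) == pytest.approx(2.620)
        assert predict_probability(DEFAULT_EQUATION, 4, 4) == pytest.approx(
            0.932, abs=5e-4
        )

    def test_low_risk_corner(self):
        assert linear_predictor(DEFAULT_EQUATION, 1, 1) == pytest.approx(-0.833)
        assert predict_probability(DEFAULT_EQUATION, 1, 1) == pytest.approx(
            0.303, abs=5e-4
        )

    def test_zero_equation(self):
        eq = PredictiveEquation(0, 0, 0, 0)
        assert linear_predictor(eq, 2, 3) == 0.0
        assert predict_probability(eq, 2, 3) == 0.5

    def test_all_16_cutoffs(self):
        probs = [
            round(predict_probability(DEFAULT_EQUATION, d, c), 3)
            for d, c in RULE_ORDER
        ]
        assert probs == EXPECTED_CUTOFFS

    def test_probability_strictly_increasing_in_each_code(self):
        """With all positive slopes the 16 probabilities are distinct and
        monotone along each code axis."""
        grid = {
            (d, c): predict_probability(DEFAULT_EQUATION, d, c)
            for d in range(1, 5)
            for c in range(1, 5)
        }
        assert len(set(grid.values())) == 16
        for d in range(1, 5):
            for c in range(1, 4):
                assert grid[(d, c + 1)] > grid[(d, c)]
                assert grid[(c + 1, d)] > grid[(c, d)]

    def test_out_of_range_codes_rejected(self):
        with pytest.raises(ValueError):
            linear_predictor(DEFAULT_EQUATION, 0, 2)
        with pytest.raises(ValueError):
            predict_probability(DEFAULT_EQUATION, 2, 5)


class TestFitEquation:
    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_equation(np.tile([1, 2, 3, 4], 10), np.tile([1, 2, 3, 4], 10),
                         np.ones(40))

    def test_null_labels_cover_zero(self):
        """With labels independent of the codes, each non-intercept 95% CI
        covers 0 in roughly 95% of seeds."""
        covered = np.zeros(3)
        n_seeds = 100
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            d = rng.integers(1, 5, 1000)
            c = rng.integers(1, 5, 1000)
            y = rng.random(1000) < 0.5
            fit = fit_equation(d, c, y)
            for j in range(3):
                lo, hi = fit.conf_int[j + 1]
                covered[j] += lo <= 0 <= hi
        # binomial 99.9% bounds around 0.95 at 100 seeds
        assert (covered / n_seeds > 0.87).all()


class TestORGrid:
    def test_analytic_odds_oracle(self):
        """ORs from data generated by the built-in equation converge to the
        analytic odds ratios odds(d,c)/odds(1,1) of that equation."""
        df = cc.gen_cohort3(n_patients=50_000, seed=17, extra_markers=False)
        grid = or_grid(df["code_d"], df["code_c"], df["active"])
        ref_odds = lambda d, c: np.exp(linear_predictor(DEFAULT_EQUATION, d, c))
        for d in range(1, 5):
            for c in range(1, 5):
                expected = ref_odds(d, c) / ref_odds(1, 1)
                est = grid.or_[d - 1, c - 1]
                # ~3000 patients per cell: log-OR sampling error well under 0.35
                assert abs(np.log(est) - np.log(expected)) < 0.35
                assert grid.ci_low[d - 1, c - 1] <= est <= grid.ci_high[d - 1, c - 1]
        assert grid.or_[0, 0] == 1.0
        assert grid.p_interaction < 0.05

    def test_monotone_generator_gives_monotone_grid(self):
        df = cc.gen_cohort3(n_patients=50_000, seed=23, extra_markers=False)
        grid = or_grid(df["code_d"], df["code_c"], df["active"])
        # allow small sampling wiggle on the log scale
        log_or = np.log(grid.or_)
        assert (np.diff(log_or, axis=0) > -0.15).all()
        assert (np.diff(log_or, axis=1) > -0.15).all()

    def test_empty_reference_cell_rejected(self):
        d = np.tile([2, 3, 4], 20)
        c = np.tile([2, 3, 4], 20)
        y = np.tile([0, 1, 1], 20)
        with pytest.raises(ValueError, match="reference"):
            or_grid(d, c, y)


class TestEvaluateRules:
    def test_all_inclusive_rule_structure(self, cohort3_small):
        table = evaluate_rules(
            cohort3_small["code_d"], cohort3_small["code_c"],
            cohort3_small["active"],
        )
        row = table[(table.rule_d == 1) & (table.rule_c == 1)].iloc[0]
        prevalence = cohort3_small["active"].mean()
        assert row.sensitivity == 1.0
        assert row.specificity == 0.0
        assert row.youden == 1.0
        assert row.npv == 0.0 and row.degenerate
        assert row.ppv == pytest.approx(prevalence)

    def test_hand_enumerated_toy_cohort(self):
        """8 patients with hand-assigned cells and labels; confusion counts
        for rule (3, 2) enumerated by hand."""
        code_d = np.array([4, 4, 3, 3, 2, 2, 1, 1])
        code_c = np.array([4, 1, 2, 3, 4, 1, 2, 1])
        active = np.array([1, 1, 0, 1, 1, 0, 0, 0])
        table = evaluate_rules(code_d, code_c, active)
        row = table[(table.rule_d == 3) & (table.rule_c == 2)].iloc[0]
        # positive under (3,2): patients 1 (4,4), 3 (3,2), 4 (3,3) -> TP {1,4}, FP {3}
        assert (row.tp, row.fp, row.fn, row.tn) == (2, 1, 2, 3)
        assert row.sensitivity == pytest.approx(2 / 4)
        assert row.specificity == pytest.approx(3 / 4)
        assert row.ppv == pytest.approx(2 / 3)
        assert row.npv == pytest.approx(3 / 5)

    def test_perfect_rule(self):
        rng = np.random.default_rng(3)
        code_d = rng.integers(1, 5, 200)
        code_c = rng.integers(1, 5, 200)
        active = (code_d == 4) & (code_c == 4)
        if not active.any():  # guard; with this seed both classes exist
            active[0] = True
        table = evaluate_rules(code_d, code_c, active.astype(int))
        row = table[(table.rule_d == 4) & (table.rule_c == 4)].iloc[0]
        assert row.sensitivity == 1.0 and row.specificity == 1.0

    def test_nested_rules_are_monotone(self, cohort3_small):
        """Stricter rectangles can only lose sensitivity and gain
        specificity."""
        table = evaluate_rules(
            cohort3_small["code_d"], cohort3_small["code_c"],
            cohort3_small["active"],
        ).set_index(["rule_d", "rule_c"])
        for d1 in range(1, 5):
            for c1 in range(1, 5):
                for d2 in range(1, d1 + 1):
                    for c2 in range(1, c1 + 1):
                        strict = table.loc[(d1, c1)]
                        loose = table.loc[(d2, c2)]
                        assert strict.sensitivity <= loose.sensitivity + 1e-12
                        assert strict.specificity >= loose.specificity - 1e-12

    def test_youden_identity(self, cohort3_small):
        table = evaluate_rules(
            cohort3_small["code_d"], cohort3_small["code_c"],
            cohort3_small["active"],
        )
        np.testing.assert_allclose(
            table["youden"], table["sensitivity"] + table["specificity"]
        )
        np.testing.assert_allclose(table["youden_j"], table["youden"] - 1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            evaluate_rules([1, 2], [3, 4], [1, 1])
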