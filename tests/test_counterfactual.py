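"""Intervention library, effect application, transitions and projections."""

import numpy as np
import pandas as pd
import pytest

from preventsim.counterfactual import (
    CounterfactualError,
    InterventionEffect,
    absolute_risk_reduction_pct,
    apply_all,
    apply_effect,
    project_reduction,
    recompute_scores,
    render_case_study,
    round_half_away,
    table4_intervention_library,
    transition_table,
)
from preventsim.derivation import cat_column, indicator_column
from preventsim.synthetic import default_bcs70_spec, generate_cohort
from preventsim.derivation import add_domain_scores, derive_domain_indicators

SPEC = default_bcs70_spec(1200)


def _derived_cohort(seed=1):
    df = generate_cohort(SPEC, seed)
    return add_domain_scores(
        derive_domain_indicators(df, SPEC.domain_specs), SPEC.domain_specs
    )


class TestLibrary:
    def test_eleven_effects(self):
        lib = table4_intervention_library()
        assert len(lib) == 11

    def test_birthweight_entry(self):
        lib = {e.target_variable: e for e in table4_intervention_library()}
        bw = lib["birthweight"]
        assert bw.effect_kind == "additive_shift"
        assert bw.magnitude == 324.0
        assert bw.eligibility == "all"

    def test_no_effect_for_maternal_age_or_parity(self):
        targets = {e.target_variable for e in table4_intervention_library()}
        assert "young_maternal_age" not in targets
        assert "high_parity" not in targets

    def test_reclassification_fractions(self):
        lib = {e.target_variable: e for e in table4_intervention_library()}
        expected = {
            "maternal_smoking": 0.08,
            "teenage_pregnancy": 0.62,
            "rutter_high_risk": 0.39,
            "behavioural_problems": 0.55,
            "temper": 0.026,
            "walking_backwards": 0.06,
            "hand_control": 0.06,
            "clumsy": 0.06,
            "balance_right": 0.06,
            "balance_left": 0.06,
        }
        for var, frac in expected.items():
            assert lib[var].effect_kind == "fraction_reclassified"
            assert lib[var].magnitude == frac


class TestApplyEffect:
    def test_birthweight_shift_updates_value_and_indicator(self):
        df = _derived_cohort()
        df.loc[df.index[0], "birthweight"] = 2300.0
        df.loc[df.index[0], indicator_column("birthweight")] = 1.0
        effect = InterventionEffect("birthweight", "additive_shift", 324.0, "all", "x")
        out = apply_effect(df, effect, seed=0, domain_specs=SPEC.domain_specs)
        assert out.loc[out.index[0], "birthweight"] == 2624.0
        # 2624 g is above the 2500 g cut-off, so no longer adverse
        assert out.loc[out.index[0], indicator_column("birthweight")] == 0.0

    def test_exact_fraction_count(self):
        df = _derived_cohort()
        col = indicator_column("maternal_smoking")
        idx = df.index[:100]
        df[col] = 0.0
        df.loc[idx, col] = 1.0  # exactly 100 smokers
        effect = InterventionEffect("maternal_smoking", "fraction_reclassified", 0.08, "adverse", "x")
        out = apply_effect(df, effect, seed=1, domain_specs=SPEC.domain_specs)
        assert (df[col].sum() - out[col].sum()) == 8

    def test_zero_fraction_leaves_cohort_unchanged(self):
        df = _derived_cohort()
        effect = InterventionEffect("temper", "fraction_reclassified", 0.0, "adverse", "x")
        out = apply_effect(df, effect, seed=2, domain_specs=SPEC.domain_specs)
        pd.testing.assert_frame_equal(df, out)

    def test_tiny_fraction_rounds_to_zero_participants(self):
        df = _derived_cohort()
        col = indicator_column("temper")
        df[col] = 0.0
        df.loc[df.index[:5], col] = 1.0  # 5 at risk, 2.6% of 5 = 0.13 -> 0
        effect = InterventionEffect("temper", "fraction_reclassified", 0.026, "adverse", "x")
        out = apply_effect(df, effect, seed=3, domain_specs=SPEC.domain_specs)
        assert out[col].sum() == 5

    def test_unknown_variable_rejected(self):
        df = _derived_cohort()
        effect = InterventionEffect("no_such_var", "fraction_reclassified", 0.1, "adverse", "x")
        with pytest.raises(CounterfactualError):
            apply_effect(df, effect, seed=0, domain_specs=SPEC.domain_specs)


class TestApplyAll:
    def test_empty_effect_list_is_identity(self):
        df = _derived_cohort()
        out = apply_all(df, [], seed=0, domain_specs=SPEC.domain_specs)
        pd.testing.assert_frame_equal(df, out)

    def test_order_invariance(self):
        df = _derived_cohort()
        lib = table4_intervention_library()
        a = apply_all(df, lib, seed=7, domain_specs=SPEC.domain_specs)
        b = apply_all(df, list(reversed(lib)), seed=7, domain_specs=SPEC.domain_specs)
        pd.testing.assert_frame_equal(a, b)

    def test_seeded_determinism(self):
        df = _derived_cohort()
        lib = table4_intervention_library()
        a = apply_all(df, lib, seed=8, domain_specs=SPEC.domain_specs)
        b = apply_all(df, lib, seed=8, domain_specs=SPEC.domain_specs)
        pd.testing.assert_frame_equal(a, b)

    def test_duplicate_targets_rejected(self):
        df = _derived_cohort()
        e = InterventionEffect("temper", "fraction_reclassified", 0.1, "adverse", "x")
        with pytest.raises(CounterfactualError, match="same variable"):
            apply_all(df, [e, e], seed=0, domain_specs=SPEC.domain_specs)

    def test_no_score_ever_increases(self):
        df = _derived_cohort()
        lib = table4_intervention_library()
        after = recompute_scores(
            apply_all(df, lib, seed=9, domain_specs=SPEC.domain_specs),
            SPEC.domain_specs,
        )
        for dom in SPEC.domain_specs:
            col = f"derived_score_{dom.name}"
            assert (after[col].to_numpy() <= df[col].to_numpy()).all()


class TestTransitions:
    def _cats(self, pairs):
        before = np.concatenate([[b] * n for (b, a), n in pairs])
        after = np.concatenate([[a] * n for (b, a), n in pairs])
        cases = np.ones(before.size, dtype=bool)
        return before, after, cases

    def test_no_intervention_gives_diagonal(self):
        before, after, cases = self._cats([(("3+", "3+"), 10), (("1", "1"), 5)])
        tr = transition_table(before, after, cases, "dom")
        assert tr.movers("3+", "3+") == 10
        assert tr.counts.to_numpy().sum() == tr.counts.to_numpy().trace()

    def test_worked_transition_counts_and_percentages(self):
        # 78 cases at 3+ of whom 42 end at 2; 272 cases at 1 of whom 53 end at 0
        before, after, cases = self._cats(
            [(("3+", "2"), 42), (("3+", "3+"), 36), (("1", "0"), 53), (("1", "1"), 219)]
        )
        tr = transition_table(before, after, cases, "prenatal_birth")
        assert tr.movers("3+", "2") == 42
        assert tr.group_sizes["3+"] == 78
        assert tr.percent("3+", "2") == 53.8
        assert tr.percent("1", "0") == 19.5

    def test_conservation_of_cases(self):
        before, after, cases = self._cats(
            [(("3+", "2"), 4), (("2", "0"), 3), (("0", "0"), 7)]
        )
        tr = transition_table(before, after, cases, "dom")
        assert tr.counts.to_numpy().sum() == cases.sum()

    def test_score_increase_rejected(self):
        with pytest.raises(CounterfactualError, match="increased"):
            transition_table(["1"], ["2"], [True], "dom")

    def test_single_mover_in_one_cell_only(self):
        tr = transition_table(["3+"], ["0"], [True], "dom")
        assert tr.movers("3+", "0") == 1
        assert tr.counts.to_numpy().sum() == 1


class TestProjection:
    def test_rounding_seven_of_53(self):
        # 13.0% of 53 movers = 6.89 -> 7 whole people
        r = project_reduction(53, 0.130, 272)
        assert r.removals_integer == 7
        assert r.removals_fractional == pytest.approx(6.89)

    def test_rounding_one_of_three(self):
        # 19.5% of 3 movers = 0.585 -> 1 whole person
        r = project_reduction(3, 0.195, 205)
        assert r.removals_integer == 1

    def test_zero_paf_zero_arr(self):
        r = project_reduction(10, 0.0, 100)
        assert r.arr_fractional_pct == 0.0 and r.arr_integer_pct == 0.0

    def test_zero_group_rejected(self):
        with pytest.raises(CounterfactualError):
            project_reduction(0, 0.1, 0)

    def test_conventions_bracket_each_other(self):
        for movers, paf, cases in ((42, 0.2, 78), (53, 0.13, 272), (3, 0.195, 205)):
            r = project_reduction(movers, paf, cases)
            assert abs(r.arr_integer_pct - r.arr_fractional_pct) <= 100.0 / cases

    @pytest.mark.parametrize("x, expected", [(8.5, 9), (8.4, 8), (0.5, 1), (0.49, 0), (6.89, 7)])
    def test_round_half_away(self, x, expected):
        assert round_half_away(x) == expected

    def test_arr_helper_one_decimal(self):
        assert absolute_risk_reduction_pct(9, 78) == 11.5

    def test_case_study_narrative_carries_numbers(self):
        r = project_reduction(42, 0.20, 78, domain="prenatal_birth",
                              from_category="3+", to_category="2")
        text = render_case_study(r)
        assert "42" in text and "78" in text
        # integer convention: round(0.20*42)=8 of 78 -> 10.3%; fractional 10.8%
        assert "10.3" in text and "10.8" in text
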