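"""Generator schema, determinism, calibration and missingness mechanism."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.special import logit

from conftest import complete_analysis_table, generating_model_design, null_spec
from preventsim.models import fit_logistic_mle
from preventsim.synthetic import (
    LTC_COLUMNS,
    SF36_EMOTIONAL,
    SF36_PHYSICAL,
    CohortSpec,
    SpecValidationError,
    default_bcs70_spec,
    export_cohort,
    generate_cohort,
    inject_missingness,
    load_cohort,
)


class TestDefaultSpec:
    def test_prenatal_domain_variables(self, default_spec):
        prenatal = default_spec.domain_specs[0]
        assert prenatal.name == "prenatal_birth"
        assert len(prenatal.variable_names) == 5
        for v in (
            "birthweight",
            "maternal_smoking",
            "teenage_pregnancy",
            "young_maternal_age",
            "high_parity",
        ):
            assert v in prenatal.variable_names

    def test_development_domain_has_eight_variables(self, default_spec):
        dev = default_spec.domain_specs[1]
        assert dev.name == "development_behaviour"
        assert len(dev.variable_names) == 8

    def test_all_domains_at_least_four_variables(self, default_spec):
        assert len(default_spec.domain_specs) == 5
        for dom in default_spec.domain_specs:
            assert len(dom.variable_names) >= 4

    def test_binary_prevalences_within_band(self, default_spec):
        for vdef in default_spec.variable_defs.values():
            if vdef.kind == "binary":
                assert 0.05 <= vdef.prevalence <= 0.30

    def test_yaml_round_trip(self, default_spec, tmp_path):
        p = tmp_path / "spec.yaml"
        default_spec.to_yaml(p)
        again = CohortSpec.from_yaml(p)
        assert again == default_spec

    @pytest.mark.parametrize(
        "mutation, field",
        [
            ({"outcome_coefficients": {"no_such_column": 1.0}}, "outcome_coefficients"),
            ({"missingness_rates": {"birthweight": 1.5}}, "missingness_rates"),
            ({"missingness_rates": {"sex": 0.1}}, "missingness_rates"),
            ({"n_participants": -1}, "n_participants"),
        ],
    )
    def test_validation_names_offending_field(self, default_spec, mutation, field):
        bad = dataclasses.replace(default_spec, **mutation)
        with pytest.raises(SpecValidationError) as err:
            bad.validate()
        assert err.value.field_name == field


class TestGeneration:
    def test_seeded_determinism(self):
        spec = default_bcs70_spec(1500)
        a = generate_cohort(spec, 1)
        b = generate_cohort(spec, 1)
        pd.testing.assert_frame_equal(a, b)

    def test_zero_participants_keeps_schema(self, default_spec):
        spec = dataclasses.replace(default_spec, n_participants=0)
        out = generate_cohort(spec, 1)
        assert len(out) == 0
        for col in ("participant_id", "birthweight", "sex", *LTC_COLUMNS):
            assert col in out.columns

    def test_complete_when_no_missingness_applied(self):
        spec = default_bcs70_spec(800)
        out = generate_cohort(spec, 3)
        assert not out.isna().any().any()
        assert out["participant_id"].is_unique
        assert (out["birthweight"] > 0).all()

    def test_binary_columns_are_binary(self):
        spec = default_bcs70_spec(800)
        out = generate_cohort(spec, 5)
        for col in LTC_COLUMNS + SF36_PHYSICAL + SF36_EMOTIONAL + ["maternal_smoking"]:
            assert set(np.unique(out[col])) <= {0.0, 1.0}

    def test_null_model_hits_declared_prevalence(self):
        # all coefficients zero, intercept logit(0.119): the case fraction in
        # the analytical sample is binomial around 0.119
        spec = null_spec(20000)
        kept = complete_analysis_table(spec, seed=7)
        prev = kept["derived_case"].mean()
        n = len(kept)
        assert abs(prev - 0.119) < 3 * np.sqrt(0.119 * 0.881 / n)

    def test_default_prevalence_calibration_band(self, default_spec):
        kept = complete_analysis_table(default_spec, seed=1)
        assert 0.10 <= kept["derived_case"].mean() <= 0.14

    def test_csv_round_trip_with_dictionary(self, tmp_path):
        spec = default_bcs70_spec(300)
        out = generate_cohort(spec, 2)
        csv, dd = tmp_path / "cohort.csv", tmp_path / "dict.json"
        export_cohort(out, csv, dd, spec)
        again = load_cohort(csv)
        pd.testing.assert_frame_equal(out, again, check_dtype=False)


class TestMissingness:
    def test_zero_rates_leave_table_unchanged(self, default_spec):
        spec = dataclasses.replace(default_spec, n_participants=500, missingness_rates={})
        table = generate_cohort(spec, 1)
        out = inject_missingness(table, spec, 2)
        pd.testing.assert_frame_equal(table, out)

    def test_marginal_rate_within_binomial_bound(self, default_spec):
        n = 10000
        spec = dataclasses.replace(
            default_spec,
            n_participants=n,
            missingness_rates={"birthweight": 0.1},
        )
        table = generate_cohort(spec, 4)
        out = inject_missingness(table, spec, 5)
        missing = out["birthweight"].isna().sum()
        assert abs(missing - 0.1 * n) < 3 * np.sqrt(0.1 * 0.9 * n)

    def test_mar_mechanism_recovers_sex_shift(self, default_spec):
        # the missingness indicator regressed on the always-observed drivers
        # recovers the configured log-odds shifts (MAR by construction)
        n = 40000
        spec = dataclasses.replace(
            default_spec,
            n_participants=n,
            missingness_rates={"birthweight": 0.2},
        )
        table = generate_cohort(spec, 6)
        out = inject_missingness(table, spec, 7)
        y = out["birthweight"].isna().to_numpy(float)
        X = np.column_stack(
            [np.ones(n), out["sex"], out[spec.mar_anchor]]
        )
        fit = fit_logistic_mle(X, y, names=["intercept", "sex", "anchor"])
        for name, truth in (("sex", spec.mar_sex_shift), ("anchor", spec.mar_domain_shift)):
            i = fit.names.index(name)
            se = np.sqrt(fit.cov[i, i])
            assert abs(fit.params[i] - truth) < 3 * se

    def test_outcome_items_blanked_never_derived_labels(self, default_spec):
        spec = dataclasses.replace(default_spec, n_participants=2000)
        table = generate_cohort(spec, 8)
        out = inject_missingness(table, spec, 9)
        blanked = {c for c in out.columns if out[c].isna().any()}
        assert blanked <= set(spec.missingness_rates)


class TestGroundTruthRecovery:
    def test_outcome_coefficients_recovered_on_complete_data(self, default_spec):
        """Fitting the generating model on complete cohorts covers each
        nonzero coefficient with its 95% Wald interval at ~nominal rate."""
        n_rep = 50
        hits = 0
        total = 0
        coefs = default_spec.outcome_coefficients
        spec = dataclasses.replace(default_spec, n_participants=20000)
        for seed in range(n_rep):
            kept = complete_analysis_table(spec, seed=100 + seed)
            X, names = generating_model_design(kept, spec)
            fit = fit_logistic_mle(X, kept["derived_case"].to_numpy(float), names=names)
            for name, truth in coefs.items():
                i = fit.names.index(name)
                se = np.sqrt(fit.cov[i, i])
                hits += abs(fit.params[i] - truth) < 1.96 * se
                total += 1
        assert hits / total >= 0.90
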