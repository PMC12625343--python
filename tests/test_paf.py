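"""Model-based standardisation: scenario PAF point estimates and CIs."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from conftest import complete_analysis_table
from preventsim.derivation import cat_column
from preventsim.models import ModelDesign, ModelFit
from preventsim.paf import (
    PafError,
    PafScenario,
    paf_scenario,
    paf_table,
)
from preventsim.synthetic import default_bcs70_spec


def _single_exposure_table():
    # saturated single-binary-exposure design: exposed (cat "1") risk 0.2,
    # unexposed (cat "0") risk 0.1
    n_exp, n_unexp = 50, 50
    cats = ["1"] * n_exp + ["0"] * n_unexp
    y = [1.0] * 10 + [0.0] * 40 + [1.0] * 5 + [0.0] * 45
    return pd.DataFrame({cat_column("dom"): cats, "derived_case": y})


class TestScenarioValidation:
    def test_increasing_scenario_rejected(self):
        with pytest.raises(PafError):
            PafScenario("dom", "1", "2")

    def test_degenerate_scenario_allowed(self):
        PafScenario("dom", "2", "2")


class TestPafPoint:
    def test_degenerate_scenario_gives_exact_zero(self):
        df = _single_exposure_table()
        design = ModelDesign(
            domains=("dom",),
            level=1,
            include_demographics=False,
            domain_categories=(("dom", ("1",)),),
        )
        fit = design.fit(df)
        est = paf_scenario(fit, df, PafScenario("dom", "1", "1"), design)
        assert est.paf == 0.0

    def test_saturated_model_closed_form(self):
        # predicted means equal group outcome means, so PAF = 1 - 0.1/0.2
        df = _single_exposure_table()
        design = ModelDesign(
            domains=("dom",),
            level=1,
            include_demographics=False,
            domain_categories=(("dom", ("1",)),),
        )
        fit = design.fit(df)
        est = paf_scenario(fit, df, PafScenario("dom", "1", "0"), design)
        assert est.paf == pytest.approx(0.5, abs=1e-9)
        assert est.n_exposed == 50

    def test_matches_direct_standardisation_oracle(self):
        # a known-coefficient model on a fixed 50-row table: the package's PAF
        # equals brute-force averaging of the two predicted-probability vectors
        rng = np.random.default_rng(5)
        n = 50
        df = pd.DataFrame(
            {
                cat_column("dom"): rng.choice(["0", "1", "2", "3+"], n),
                "sex": rng.binomial(1, 0.5, n).astype(float),
                "ethnicity": rng.binomial(1, 0.2, n).astype(float),
                "derived_case": rng.binomial(1, 0.3, n).astype(float),
            }
        )
        design = ModelDesign(domains=("dom",), level=1)
        beta = np.array([-1.2, 0.3, 0.6, 1.1, 0.25, 0.1])
        fit = ModelFit(
            names=design.column_names(),
            params=beta,
            cov=np.eye(6) * 0.01,
            converged=True,
            n_obs=n,
            loglik=0.0,
            n_iter=1,
        )
        scenario = PafScenario("dom", "3+", "1")
        est = paf_scenario(fit, df, scenario, design)

        mask = df[cat_column("dom")] == "3+"
        x_f = design.build(df[mask])
        x_cf = x_f.copy()
        # switch the dummies by hand: zero the 3+ column, set the 1 column
        names = design.column_names()
        x_cf[:, names.index("dom[3+]")] = 0.0
        x_cf[:, names.index("dom[1]")] = 1.0
        p_f = expit(x_f @ beta).mean()
        p_cf = expit(x_cf @ beta).mean()
        assert abs(est.paf - (1 - p_cf / p_f)) < 1e-12

    def test_sign_contract_under_positive_coefficients(self):
        # all score coefficients >= 0 and to < from implies PAF >= 0
        rng = np.random.default_rng(6)
        n = 80
        df = pd.DataFrame(
            {
                cat_column("dom"): rng.choice(["0", "1", "2", "3+"], n),
                "sex": rng.binomial(1, 0.5, n).astype(float),
                "ethnicity": rng.binomial(1, 0.2, n).astype(float),
            }
        )
        design = ModelDesign(domains=("dom",), level=1)
        fit = ModelFit(
            names=design.column_names(),
            params=np.array([-1.0, 0.2, 0.5, 0.9, 0.1, 0.0]),
            cov=np.eye(6) * 0.01,
            converged=True,
            n_obs=n,
            loglik=0.0,
            n_iter=1,
        )
        for frm, to in (("3+", "2"), ("3+", "0"), ("2", "1"), ("1", "0")):
            est = paf_scenario(fit, df, PafScenario("dom", frm, to), design)
            assert est.paf >= 0.0

    def test_row_order_invariance(self):
        df = _single_exposure_table()
        design = ModelDesign(
            domains=("dom",),
            level=1,
            include_demographics=False,
            domain_categories=(("dom", ("1",)),),
        )
        fit = design.fit(df)
        scenario = PafScenario("dom", "1", "0")
        a = paf_scenario(fit, df, scenario, design)
        shuffled = df.sample(frac=1.0, random_state=1)
        b = paf_scenario(fit, shuffled, scenario, design)
        assert a.paf == pytest.approx(b.paf, abs=1e-12)

    def test_empty_exposed_group_names_scenario(self):
        df = _single_exposure_table()
        design = ModelDesign(
            domains=("dom",),
            level=1,
            include_demographics=False,
            domain_categories=(("dom", ("1",)),),
        )
        fit = design.fit(df)
        with pytest.raises(PafError, match="3\\+ to 0"):
            paf_scenario(fit, df, PafScenario("dom", "3+", "0"), design)


class TestPafGrid:
    def test_monotone_generator_orders_top_category_scenarios(self):
        # a monotone dose-response generator makes deeper reductions remove a
        # larger share of the exposed group's risk in nearly every replicate
        spec = default_bcs70_spec()  # cohort-scale so per-category ORs are stable
        wins = 0
        n_rep = 25
        for seed in range(n_rep):
            table = complete_analysis_table(spec, seed=500 + seed)
            ests = paf_table(
                [table],
                domains=["development_behaviour"],
                scenarios=(("3+", "2"), ("3+", "1"), ("3+", "0")),
                ci_method="delta",
                seed=seed,
            )
            pafs = {e.scenario.label: e.paf for e in ests}
            wins += (
                pafs["3+ to 0"] >= pafs["3+ to 1"] >= pafs["3+ to 2"]
            )
        assert wins >= 0.9 * n_rep

    def test_single_table_grid_matches_paf_scenario(self, small_analysis_table):
        from preventsim.models import DEFAULT_DOMAINS, present_categories

        ests = paf_table(
            [small_analysis_table],
            domains=["prenatal_birth"],
            scenarios=(("3+", "0"),),
            ci_method="delta",
        )
        cats = present_categories([small_analysis_table], DEFAULT_DOMAINS)
        design = ModelDesign(level=3, domain_categories=cats)
        fit = design.fit(small_analysis_table)
        direct = paf_scenario(
            fit, small_analysis_table, PafScenario("prenatal_birth", "3+", "0"), design
        )
        assert ests[0].paf == pytest.approx(direct.paf, abs=1e-12)

    def test_bootstrap_ci_brackets_point_estimate(self, small_analysis_table):
        ests = paf_table(
            [small_analysis_table],
            domains=["development_behaviour"],
            scenarios=(("3+", "0"),),
            ci_method="bootstrap",
            n_boot=60,
            seed=3,
        )
        e = ests[0]
        assert e.ci_low < e.paf < e.ci_high
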