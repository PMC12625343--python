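import dataclasses

import numpy as np
import pytest
from hypothesis import settings
from scipy.special import logit

from preventsim.derivation import (
    add_domain_scores,
    derive_domain_indicators,
    derive_outcome_columns,
    select_analytical_sample,
)
from preventsim.synthetic import (
    LTC_COLUMNS,
    SF36_EMOTIONAL,
    SF36_PHYSICAL,
    default_bcs70_spec,
    generate_cohort,
)

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_spec():
    return default_bcs70_spec()


def null_spec(n: int, target: float = 0.119):
    """Spec whose outcome is pure noise at a fixed prevalence."""
    spec = default_bcs70_spec(n)
    return dataclasses.replace(
        spec,
        outcome_coefficients={},
        outcome_intercept=float(logit(target)),
    )


def complete_analysis_table(spec, seed):
    """Complete-data analytical sample with all derived columns attached."""
    df = generate_cohort(spec, seed)
    df = derive_outcome_columns(df, LTC_COLUMNS, SF36_PHYSICAL, SF36_EMOTIONAL)
    df = add_domain_scores(derive_domain_indicators(df, spec.domain_specs), spec.domain_specs)
    kept, _ = select_analytical_sample(df)
    return kept


def generating_model_design(table, spec):
    """Design matrix and names for the generator's own outcome model."""
    coefs = spec.outcome_coefficients
    predictors = {}
    for dom in spec.domain_specs:
        predictors[f"score_{dom.name}"] = np.minimum(
            table[f"derived_score_{dom.name}"].to_numpy(float), 3
        )
    predictors["sex"] = table["sex"].to_numpy(float)
    predictors["ethnicity"] = table["ethnicity"].to_numpy(float)
    for name in spec.adult_covariate_specs:
        predictors[name] = table[name].to_numpy(float)
    log_inc = np.log(table["weekly_income"].to_numpy(float))
    predictors["log_income_z"] = (log_inc - log_inc.mean()) / log_inc.std()
    X = np.column_stack([np.ones(len(table))] + [predictors[c] for c in coefs])
    return X, ["intercept"] + list(coefs)


@pytest.fixture(scope="session")
def small_analysis_table(default_spec):
    spec = dataclasses.replace(default_spec, n_participants=3000)
    return complete_analysis_table(spec, seed=11)
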