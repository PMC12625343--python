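"""Synthetic birth-cohort generator.

Emulates the structure of a 1970s British birth cohort followed to midlife:
five correlated early-life adversity domains (prenatal/birth, development and
behaviour, education, socioeconomic circumstances, parental and family
environment), adult covariates at age 46 that mediate the early-life effects,
22 long-term-condition flags, SF-36 role-limitation items, and
missing-at-random missingness.  The binary outcome "MLTCs with role
limitation" follows a declared logistic model on the true domain adversity
scores, so every downstream stage of the pipeline is testable against known
ground truth without access to the licensed source data.

Adult covariate distributions and indicator prevalences are plausible
placeholders for a 1970 British birth cohort, not estimates of it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import norm

from .derivation import (
    BinaryAsIs,
    BottomDecile,
    DomainSpec,
    ThresholdBelow,
    binarize_adversity,
    cap_category,
    rule_from_dict,
    rule_to_dict,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SpecValidationError",
    "VariableDef",
    "AdultCovariateSpec",
    "CohortSpec",
    "default_bcs70_spec",
    "generate_cohort",
    "inject_missingness",
    "export_cohort",
    "load_cohort",
    "LTC_COLUMNS",
    "SF36_PHYSICAL",
    "SF36_EMOTIONAL",
]


class SpecValidationError(ValueError):
    """Raised when a cohort specification is internally inconsistent."""

    def __init__(self, field_name: str, message: str):
        self.field_name = field_name
        super().__init__(f"{field_name}: {message}")


# ---------------------------------------------------------------------------
# Fixed schema pieces
# ---------------------------------------------------------------------------

# 22 self-reported long-term conditions; weights are the approximate marginal
# prevalences used when allocating which conditions a participant reports.
LTC_PREVALENCE = {
    "ltc_asthma": 0.117,
    "ltc_diabetes": 0.038,
    "ltc_cancer": 0.015,
    "ltc_high_blood_pressure": 0.103,
    "ltc_heart_problems": 0.029,
    "ltc_eczema": 0.088,
    "ltc_chronic_fatigue": 0.015,
    "ltc_stomach_bowel_gallbladder": 0.112,
    "ltc_bladder_kidney": 0.034,
    "ltc_liver_disease": 0.006,
    "ltc_arthritis": 0.076,
    "ltc_stroke": 0.006,
    "ltc_depression": 0.239,
    "ltc_anxiety": 0.186,
    "ltc_hearing_loss": 0.041,
    "ltc_epilepsy": 0.010,
    "ltc_eye_blindness_low_vision": 0.004,
    "ltc_eye_diabetes_associated": 0.003,
    "ltc_eye_glaucoma": 0.005,
    "ltc_endometriosis": 0.023,
    "ltc_menieres": 0.001,
    "ltc_psoriasis": 0.024,
}
LTC_COLUMNS = list(LTC_PREVALENCE)

SF36_PHYSICAL = [f"sf36_phys_{i}" for i in range(1, 5)]
SF36_EMOTIONAL = [f"sf36_emot_{i}" for i in range(1, 4)]


@dataclass(frozen=True)
class VariableDef:
    """How one raw early-life variable is generated."""

    name: str
    kind: str  # "binary" | "continuous"
    prevalence: float = 0.0  # binary only
    mean: float = 0.0  # continuous only
    sd: float = 1.0
    lower: Optional[float] = None  # truncation bound for continuous values

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "kind": self.kind,
            "prevalence": float(self.prevalence),
            "mean": float(self.mean),
            "sd": float(self.sd),
            "lower": None if self.lower is None else float(self.lower),
        }


@dataclass(frozen=True)
class AdultCovariateSpec:
    """Marginal distribution of an age-46 covariate and its dependence on
    early-life adversity (cumulative log-odds shift per total score point)."""

    name: str
    kind: str  # "ordinal" | "binary" | "continuous_log"
    levels: tuple = ()  # ordinal level codes
    base_probs: tuple = ()  # ordinal marginal probabilities
    p: float = 0.5  # binary prevalence
    log_mean: float = 0.0  # continuous_log
    log_sd: float = 1.0
    score_shift: float = 0.3

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "kind": self.kind,
            "levels": [float(v) for v in self.levels],
            "base_probs": [float(v) for v in self.base_probs],
            "p": float(self.p),
            "log_mean": float(self.log_mean),
            "log_sd": float(self.log_sd),
            "score_shift": float(self.score_shift),
        }


@dataclass(frozen=True)
class CohortSpec:
    """Full declaration of a synthetic cohort's generating process."""

    n_participants: int
    domain_specs: tuple  # of DomainSpec
    variable_defs: Mapping[str, VariableDef]
    adult_covariate_specs: Mapping[str, AdultCovariateSpec]
    outcome_coefficients: Mapping[str, float]
    outcome_intercept: Optional[float] = None  # None -> calibrated at generation
    target_case_prevalence: float = 0.119
    excluded_mltc_rate: float = 0.24
    excluded_role_rate: float = 0.038
    latent_domain_loading: float = 0.5
    latent_global_loading: float = 0.3
    ethnicity_minority_rate: float = 0.04
    missingness_rates: Mapping[str, float] = field(default_factory=dict)
    mar_sex_shift: float = 0.4
    mar_domain_shift: float = 0.3
    mar_anchor: str = "maternal_smoking"
    seed: int = 0

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        if self.n_participants < 0:
            raise SpecValidationError("n_participants", "must be non-negative")
        var_names = []
        for dom in self.domain_specs:
            var_names.extend(dom.variable_names)
        if len(set(var_names)) != len(var_names):
            raise SpecValidationError("domain_specs", "variable names collide across domains")
        for v in var_names:
            if v not in self.variable_defs:
                raise SpecValidationError("variable_defs", f"no generation rule for {v!r}")
        for name, vdef in self.variable_defs.items():
            if vdef.kind not in ("binary", "continuous"):
                raise SpecValidationError("variable_defs", f"{name}: unknown kind {vdef.kind!r}")
            if vdef.kind == "binary" and not 0.0 < vdef.prevalence < 1.0:
                raise SpecValidationError("variable_defs", f"{name}: prevalence must be in (0,1)")
        lg, ld = self.latent_global_loading, self.latent_domain_loading
        if lg ** 2 + ld ** 2 >= 1.0:
            raise SpecValidationError("latent_domain_loading", "loadings imply variance > 1")
        predictors = set(self.predictor_names())
        for name in self.outcome_coefficients:
            if name not in predictors:
                raise SpecValidationError(
                    "outcome_coefficients", f"{name!r} does not resolve to a generated column"
                )
        for col, rate in self.missingness_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise SpecValidationError("missingness_rates", f"{col}: rate {rate} outside [0,1]")
            if col in ("sex", "participant_id", self.mar_anchor):
                raise SpecValidationError(
                    "missingness_rates",
                    f"{col} must stay fully observed (it drives the MAR mechanism)",
                )
        if not 0.0 < self.target_case_prevalence < 1.0:
            raise SpecValidationError("target_case_prevalence", "must be in (0,1)")
        if self.excluded_mltc_rate + self.excluded_role_rate >= 1.0:
            raise SpecValidationError("excluded_mltc_rate", "exclusion rates sum to >= 1")

    def predictor_names(self) -> list:
        names = [f"score_{d.name}" for d in self.domain_specs]
        names += ["sex", "ethnicity"]
        names += list(self.adult_covariate_specs)
        names += ["log_income_z"]
        return names

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "n_participants": self.n_participants,
            "domain_specs": [d.to_dict() for d in self.domain_specs],
            "variable_defs": {k: v.to_dict() for k, v in self.variable_defs.items()},
            "adult_covariate_specs": {
                k: v.to_dict() for k, v in self.adult_covariate_specs.items()
            },
            "outcome_coefficients": {
                k: float(v) for k, v in self.outcome_coefficients.items()
            },
            "outcome_intercept": (
                None if self.outcome_intercept is None else float(self.outcome_intercept)
            ),
            "target_case_prevalence": self.target_case_prevalence,
            "excluded_mltc_rate": self.excluded_mltc_rate,
            "excluded_role_rate": self.excluded_role_rate,
            "latent_domain_loading": self.latent_domain_loading,
            "latent_global_loading": self.latent_global_loading,
            "ethnicity_minority_rate": self.ethnicity_minority_rate,
            "missingness_rates": {
                k: float(v) for k, v in self.missingness_rates.items()
            },
            "mar_sex_shift": self.mar_sex_shift,
            "mar_domain_shift": self.mar_domain_shift,
            "mar_anchor": self.mar_anchor,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        return cls(
            n_participants=d["n_participants"],
            domain_specs=tuple(DomainSpec.from_dict(x) for x in d["domain_specs"]),
            variable_defs={
                k: VariableDef(**v) for k, v in d["variable_defs"].items()
            },
            adult_covariate_specs={
                k: AdultCovariateSpec(
                    name=v["name"],
                    kind=v["kind"],
                    levels=tuple(v["levels"]),
                    base_probs=tuple(v["base_probs"]),
                    p=v["p"],
                    log_mean=v["log_mean"],
                    log_sd=v["log_sd"],
                    score_shift=v["score_shift"],
                )
                for k, v in d["adult_covariate_specs"].items()
            },
            outcome_coefficients=dict(d["outcome_coefficients"]),
            outcome_intercept=d.get("outcome_intercept"),
            target_case_prevalence=d.get("target_case_prevalence", 0.119),
            excluded_mltc_rate=d.get("excluded_mltc_rate", 0.24),
            excluded_role_rate=d.get("excluded_role_rate", 0.038),
            latent_domain_loading=d.get("latent_domain_loading", 0.5),
            latent_global_loading=d.get("latent_global_loading", 0.3),
            ethnicity_minority_rate=d.get("ethnicity_minority_rate", 0.04),
            missingness_rates=dict(d.get("missingness_rates", {})),
            mar_sex_shift=d.get("mar_sex_shift", 0.4),
            mar_domain_shift=d.get("mar_domain_shift", 0.3),
            mar_anchor=d.get("mar_anchor", "maternal_smoking"),
            seed=d.get("seed", 0),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CohortSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Default specification
# ---------------------------------------------------------------------------

def default_bcs70_spec(n_participants: int = 8580) -> CohortSpec:
    """Default cohort specification.

    Five domains: prenatal/birth (5 variables, including birthweight with the
    WHO 2500 g low-birthweight cut-off), development and behaviour
    (8 variables, motor scores dichotomised at the bottom decile), education,
    socioeconomic and parental-family (4 variables each).  The default sample
    size of 8580 mirrors the pre-exclusion denominator of the cohort the
    generator emulates; the outcome intercept is calibrated at generation time
    so that case prevalence in the analytical sample is close to 11.9%.
    """
    domains = (
        DomainSpec(
            "prenatal_birth",
            (
                ("birthweight", ThresholdBelow(2500.0, "g")),
                ("maternal_smoking", BinaryAsIs()),
                ("teenage_pregnancy", BinaryAsIs()),
                ("young_maternal_age", BinaryAsIs()),
                ("high_parity", BinaryAsIs()),
            ),
        ),
        DomainSpec(
            "development_behaviour",
            (
                ("rutter_high_risk", BinaryAsIs()),
                ("walking_backwards", BottomDecile()),
                ("behavioural_problems", BinaryAsIs()),
                ("hand_control", BottomDecile()),
                ("temper", BinaryAsIs()),
                ("clumsy", BinaryAsIs()),
                ("balance_right", BottomDecile()),
                ("balance_left", BottomDecile()),
            ),
        ),
        DomainSpec(
            "education_ability",
            (
                ("reading_score", BottomDecile()),
                ("maths_score", BottomDecile()),
                ("vocabulary_score", BottomDecile()),
                ("special_education", BinaryAsIs()),
            ),
        ),
        DomainSpec(
            "socioeconomic",
            (
                ("low_social_class", BinaryAsIs()),
                ("free_school_meals", BinaryAsIs()),
                ("overcrowded_housing", BinaryAsIs()),
                ("no_home_ownership", BinaryAsIs()),
            ),
        ),
        DomainSpec(
            "parental_family",
            (
                ("single_parent", BinaryAsIs()),
                ("parental_divorce", BinaryAsIs()),
                ("low_parental_interest", BinaryAsIs()),
                ("domestic_tension", BinaryAsIs()),
            ),
        ),
    )

    vdefs = {
        "birthweight": VariableDef("birthweight", "continuous", mean=3350.0, sd=500.0, lower=500.0),
        "maternal_smoking": VariableDef("maternal_smoking", "binary", prevalence=0.28),
        "teenage_pregnancy": VariableDef("teenage_pregnancy", "binary", prevalence=0.08),
        "young_maternal_age": VariableDef("young_maternal_age", "binary", prevalence=0.10),
        "high_parity": VariableDef("high_parity", "binary", prevalence=0.15),
        "rutter_high_risk": VariableDef("rutter_high_risk", "binary", prevalence=0.13),
        "walking_backwards": VariableDef("walking_backwards", "continuous"),
        "behavioural_problems": VariableDef("behavioural_problems", "binary", prevalence=0.15),
        "hand_control": VariableDef("hand_control", "continuous"),
        "temper": VariableDef("temper", "binary", prevalence=0.12),
        "clumsy": VariableDef("clumsy", "binary", prevalence=0.10),
        "balance_right": VariableDef("balance_right", "continuous"),
        "balance_left": VariableDef("balance_left", "continuous"),
        "reading_score": VariableDef("reading_score", "continuous"),
        "maths_score": VariableDef("maths_score", "continuous"),
        "vocabulary_score": VariableDef("vocabulary_score", "continuous"),
        "special_education": VariableDef("special_education", "binary", prevalence=0.06),
        "low_social_class": VariableDef("low_social_class", "binary", prevalence=0.22),
        "free_school_meals": VariableDef("free_school_meals", "binary", prevalence=0.12),
        "overcrowded_housing": VariableDef("overcrowded_housing", "binary", prevalence=0.10),
        "no_home_ownership": VariableDef("no_home_ownership", "binary", prevalence=0.30),
        "single_parent": VariableDef("single_parent", "binary", prevalence=0.09),
        "parental_divorce": VariableDef("parental_divorce", "binary", prevalence=0.12),
        "low_parental_interest": VariableDef("low_parental_interest", "binary", prevalence=0.10),
        "domestic_tension": VariableDef("domestic_tension", "binary", prevalence=0.08),
    }

    adult = {
        "exercise_days": AdultCovariateSpec(
            "exercise_days", "ordinal", levels=tuple(range(8)),
            base_probs=(0.15, 0.15, 0.15, 0.13, 0.12, 0.10, 0.10, 0.10),
            score_shift=-0.3,
        ),
        "education_level": AdultCovariateSpec(
            "education_level", "ordinal", levels=tuple(range(6)),
            base_probs=(0.12, 0.30, 0.15, 0.13, 0.20, 0.10), score_shift=-0.3,
        ),
        "nssec": AdultCovariateSpec(
            "nssec", "ordinal", levels=tuple(range(1, 9)),
            base_probs=(0.12, 0.20, 0.13, 0.10, 0.12, 0.13, 0.12, 0.08),
            score_shift=0.3,
        ),
        "smoker": AdultCovariateSpec("smoker", "binary", p=0.25, score_shift=0.3),
        "tv_hours": AdultCovariateSpec(
            "tv_hours", "ordinal", levels=tuple(range(5)),
            base_probs=(0.10, 0.30, 0.30, 0.18, 0.12), score_shift=0.3,
        ),
        "internet_hours": AdultCovariateSpec(
            "internet_hours", "ordinal", levels=tuple(range(5)),
            base_probs=(0.25, 0.35, 0.20, 0.12, 0.08), score_shift=0.15,
        ),
        "partner": AdultCovariateSpec("partner", "binary", p=0.80, score_shift=-0.2),
        "imd": AdultCovariateSpec(
            "imd", "ordinal", levels=tuple(range(1, 11)),
            base_probs=(0.10,) * 10, score_shift=0.3,
        ),
        "financial_difficulty": AdultCovariateSpec(
            "financial_difficulty", "ordinal", levels=tuple(range(5)),
            base_probs=(0.30, 0.30, 0.25, 0.10, 0.05), score_shift=0.3,
        ),
        "audit_pc": AdultCovariateSpec(
            "audit_pc", "ordinal", levels=tuple(range(3)),
            base_probs=(0.15, 0.65, 0.20), score_shift=0.1,
        ),
        "weekly_income": AdultCovariateSpec(
            "weekly_income", "continuous_log", log_mean=np.log(520.0), log_sd=0.5,
            score_shift=-0.08,
        ),
    }

    coefficients = {
        "score_prenatal_birth": 0.35,
        "score_development_behaviour": 0.30,
        "score_education_ability": 0.18,
        "score_socioeconomic": 0.22,
        "score_parental_family": 0.20,
        "sex": 0.25,
        "smoker": 0.30,
        "exercise_days": -0.05,
        "financial_difficulty": 0.12,
        "education_level": -0.08,
        "log_income_z": -0.10,
    }

    missing = {
        "birthweight": 0.10,
        "teenage_pregnancy": 0.05,
        "young_maternal_age": 0.05,
        "high_parity": 0.05,
        "rutter_high_risk": 0.12,
        "walking_backwards": 0.12,
        "behavioural_problems": 0.10,
        "hand_control": 0.12,
        "temper": 0.10,
        "clumsy": 0.10,
        "balance_right": 0.12,
        "balance_left": 0.12,
        "reading_score": 0.12,
        "maths_score": 0.12,
        "vocabulary_score": 0.12,
        "special_education": 0.08,
        "low_social_class": 0.08,
        "free_school_meals": 0.08,
        "overcrowded_housing": 0.08,
        "no_home_ownership": 0.08,
        "single_parent": 0.10,
        "parental_divorce": 0.10,
        "low_parental_interest": 0.10,
        "domestic_tension": 0.10,
        **{name: 0.08 for name in adult},
        **{c: 0.03 for c in SF36_PHYSICAL + SF36_EMOTIONAL},
        "ltc_depression": 0.01,
        "ltc_anxiety": 0.01,
    }

    spec = CohortSpec(
        n_participants=n_participants,
        domain_specs=domains,
        variable_defs=vdefs,
        adult_covariate_specs=adult,
        outcome_coefficients=coefficients,
        missingness_rates=missing,
    )
    spec.validate()
    return spec


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _column_order(spec: CohortSpec) -> list:
    cols = ["participant_id", "sex", "ethnicity"]
    for dom in spec.domain_specs:
        cols.extend(dom.variable_names)
    cols.extend(spec.adult_covariate_specs)
    cols.extend(LTC_COLUMNS)
    cols.extend(SF36_PHYSICAL)
    cols.extend(SF36_EMOTIONAL)
    return cols


def _ordinal_draw(rng, spec: AdultCovariateSpec, centred_score: np.ndarray) -> np.ndarray:
    # cumulative-logit latent: thresholds from the base marginal probabilities,
    # shifted by score_shift log-odds per adversity point
    cum = np.cumsum(spec.base_probs)[:-1]
    thresholds = np.log(cum / (1 - cum))
    latent = spec.score_shift * centred_score + rng.logistic(size=centred_score.size)
    idx = np.searchsorted(thresholds, latent)
    return np.asarray(spec.levels, dtype=float)[idx]


def generate_cohort(spec: CohortSpec, seed: int) -> pd.DataFrame:
    """Generate a complete (no missing cells) cohort table.

    The same ``(spec, seed)`` pair always yields a bit-identical table.
    """
    spec.validate()
    n = spec.n_participants
    cols = _column_order(spec)
    if n == 0:
        return pd.DataFrame({c: pd.Series(dtype=float) for c in cols})

    rng = np.random.default_rng(seed)
    df = pd.DataFrame({"participant_id": np.arange(1, n + 1)})
    df["sex"] = rng.binomial(1, 0.5, n).astype(float)
    df["ethnicity"] = rng.binomial(1, spec.ethnicity_minority_rate, n).astype(float)

    lg, ld = spec.latent_global_loading, spec.latent_domain_loading
    resid_sd = np.sqrt(max(1.0 - lg ** 2 - ld ** 2, 0.0))
    g = rng.standard_normal(n)  # shared adversity factor across domains

    for dom in spec.domain_specs:
        f = rng.standard_normal(n)
        for var in dom.variable_names:
            vdef = spec.variable_defs[var]
            u = lg * g + ld * f + resid_sd * rng.standard_normal(n)
            if vdef.kind == "binary":
                cut = norm.ppf(1.0 - vdef.prevalence)
                df[var] = (u > cut).astype(float)
            else:
                # adversity is the low tail, so the latent factors load negatively
                value = vdef.mean + vdef.sd * (-u)
                if vdef.lower is not None:
                    value = np.maximum(value, vdef.lower)
                df[var] = value

    # true adversity indicators and capped domain scores, derived with the
    # same rules the analysis applies, so ground truth is exactly recoverable
    score_cols = {}
    for dom in spec.domain_specs:
        indicators = np.column_stack(
            [
                binarize_adversity(df[v].to_numpy(float), dom.rule_for(v))
                for v in dom.variable_names
            ]
        )
        raw = indicators.sum(axis=1)
        score_cols[f"score_{dom.name}"] = np.minimum(raw, 3).astype(float)
    total_score = np.sum(list(score_cols.values()), axis=0)
    centred = total_score - total_score.mean()

    for name, aspec in spec.adult_covariate_specs.items():
        if aspec.kind == "ordinal":
            df[name] = _ordinal_draw(rng, aspec, centred)
        elif aspec.kind == "binary":
            p = expit(logit(aspec.p) + aspec.score_shift * centred)
            df[name] = rng.binomial(1, p).astype(float)
        elif aspec.kind == "continuous_log":
            log_val = (
                aspec.log_mean
                + aspec.score_shift * centred
                + aspec.log_sd * rng.standard_normal(n)
            )
            df[name] = np.exp(log_val)
        else:
            raise SpecValidationError("adult_covariate_specs", f"{name}: kind {aspec.kind!r}")

    # predictor frame for the outcome model
    predictors = pd.DataFrame(score_cols)
    predictors["sex"] = df["sex"].to_numpy()
    predictors["ethnicity"] = df["ethnicity"].to_numpy()
    for name in spec.adult_covariate_specs:
        predictors[name] = df[name].to_numpy()
    log_inc = np.log(df["weekly_income"].to_numpy(float))
    sd = log_inc.std()
    predictors["log_income_z"] = (log_inc - log_inc.mean()) / sd if sd > 0 else 0.0

    eta = np.zeros(n)
    for name, beta in spec.outcome_coefficients.items():
        eta += beta * predictors[name].to_numpy(float)

    if spec.outcome_intercept is None:
        target = spec.target_case_prevalence

        def gap(c):
            return expit(c + eta).mean() - target

        intercept = brentq(gap, -30.0, 30.0)
    else:
        intercept = spec.outcome_intercept
    p_case = expit(intercept + eta)

    # outcome-group allocation: exclusion statuses are drawn independently of
    # covariates; within the analytical sample the case indicator follows the
    # declared logistic model
    u = rng.uniform(size=n)
    excl_mltc = u < spec.excluded_mltc_rate
    excl_role = (u >= spec.excluded_mltc_rate) & (
        u < spec.excluded_mltc_rate + spec.excluded_role_rate
    )
    analytical = ~(excl_mltc | excl_role)
    case = analytical & (rng.uniform(size=n) < p_case)
    control = analytical & ~case

    has_mltc = case | excl_mltc
    limited = case | excl_role

    # long-term-condition flags consistent with MLTC status
    count = np.where(
        has_mltc,
        2 + rng.poisson(1.2, n),
        rng.binomial(1, 0.37, n),
    ).astype(int)
    count = np.minimum(count, len(LTC_COLUMNS))
    weights = np.array([LTC_PREVALENCE[c] for c in LTC_COLUMNS])
    gumbel = np.log(weights)[None, :] + rng.gumbel(size=(n, len(LTC_COLUMNS)))
    ranks = np.argsort(np.argsort(-gumbel, axis=1), axis=1)
    flags = (ranks < count[:, None]).astype(float)
    for j, c in enumerate(LTC_COLUMNS):
        df[c] = flags[:, j]

    # SF-36 role-limitation items consistent with limitation status
    both = limited & (rng.uniform(size=n) < 0.315)
    phys_only = limited & ~both & (rng.uniform(size=n) < 0.47)
    emot_only = limited & ~both & ~phys_only
    phys_limited = both | phys_only
    emot_limited = both | emot_only

    def _items(item_cols, limited_mask):
        items = rng.binomial(1, 0.85, size=(n, len(item_cols))).astype(float)
        all_zero = items.sum(axis=1) == 0
        fix = np.flatnonzero(all_zero & ~limited_mask)
        if fix.size:
            items[fix, rng.integers(0, len(item_cols), fix.size)] = 1.0
        items[limited_mask] = 0.0
        return items

    phys_items = _items(SF36_PHYSICAL, phys_limited)
    emot_items = _items(SF36_EMOTIONAL, emot_limited)
    for j, c in enumerate(SF36_PHYSICAL):
        df[c] = phys_items[:, j]
    for j, c in enumerate(SF36_EMOTIONAL):
        df[c] = emot_items[:, j]

    return df[cols]


def inject_missingness(table: pd.DataFrame, spec: CohortSpec, seed: int) -> pd.DataFrame:
    """Blank cells under a missing-at-random mechanism.

    Each variable's missingness probability depends only on the always-observed
    columns sex and one adversity-domain indicator (the anchor variable), via
    configured log-odds shifts; the intercept is solved so the realised
    marginal rate matches the target.
    """
    spec.validate()
    out = table.copy()
    if len(out) == 0 or not spec.missingness_rates:
        return out
    if out[["sex", spec.mar_anchor]].isna().any().any():
        raise SpecValidationError("mar_anchor", "MAR driver columns must be fully observed")
    rng = np.random.default_rng(seed)
    sex = out["sex"].to_numpy(float)
    anchor = out[spec.mar_anchor].to_numpy(float)
    shift = spec.mar_sex_shift * sex + spec.mar_domain_shift * anchor
    for col, rate in spec.missingness_rates.items():
        if rate <= 0.0:
            continue
        if col not in out.columns:
            raise SpecValidationError("missingness_rates", f"unknown column {col!r}")
        if rate >= 1.0:
            out[col] = np.nan
            continue

        def gap(a):
            return expit(a + shift).mean() - rate

        alpha = brentq(gap, -40.0, 40.0)
        p = expit(alpha + shift)
        mask = rng.uniform(size=len(out)) < p
        vals = out[col].to_numpy(float)
        vals[mask] = np.nan
        out[col] = vals
    return out


# ---------------------------------------------------------------------------
# CSV export / import with a data dictionary
# ---------------------------------------------------------------------------

def _data_dictionary(spec: CohortSpec) -> dict:
    dd = {
        "participant_id": {"type": "id", "units": "", "domain": ""},
        "sex": {"type": "binary", "units": "", "domain": "covariate"},
        "ethnicity": {"type": "binary", "units": "", "domain": "covariate"},
    }
    for dom in spec.domain_specs:
        for var in dom.variable_names:
            vdef = spec.variable_defs[var]
            units = "g" if var == "birthweight" else ""
            dd[var] = {
                "type": vdef.kind,
                "units": units,
                "domain": dom.name,
            }
    for name, aspec in spec.adult_covariate_specs.items():
        if aspec.kind == "ordinal":
            dd[name] = {
                "type": "ordinal",
                "units": "",
                "domain": "adult_covariate",
                "levels": [float(v) for v in aspec.levels],
            }
        elif aspec.kind == "binary":
            dd[name] = {"type": "binary", "units": "", "domain": "adult_covariate"}
        else:
            dd[name] = {"type": "continuous", "units": "", "domain": "adult_covariate"}
    for c in LTC_COLUMNS:
        dd[c] = {"type": "binary", "units": "", "domain": "ltc"}
    for c in SF36_PHYSICAL + SF36_EMOTIONAL:
        dd[c] = {"type": "binary", "units": "", "domain": "sf36"}
    return dd


def export_cohort(table: pd.DataFrame, csv_path, dict_path=None, spec: CohortSpec = None) -> None:
    """Write the cohort CSV and, optionally, a companion JSON data dictionary."""
    table.to_csv(csv_path, index=False)
    if dict_path is not None:
        if spec is None:
            raise ValueError("a CohortSpec is required to write the data dictionary")
        with open(dict_path, "w") as fh:
            json.dump(_data_dictionary(spec), fh, indent=1)


def load_cohort(csv_path) -> pd.DataFrame:
    return pd.read_csv(csv_path)
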