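"""Maximum-likelihood logistic regression and the three nested model levels.

The estimator is iteratively reweighted least squares (IRLS, i.e. Fisher
scoring) with step-halving, run to a relative log-likelihood tolerance of
1e-10, with Wald covariance from the inverse observed information.  Model
level 1 relates one domain's score categories to the outcome adjusting for
sex and ethnicity; level 2 enters all five domains jointly; level 3 adds the
age-46 adult factors that may mediate the early-life effects.  Domain scores
enter as indicator dummies against the reference category 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .derivation import CAP_LABELS, cat_column

logger = logging.getLogger(__name__)

__all__ = [
    "ModelError",
    "PerfectSeparationError",
    "ModelFit",
    "ModelDesign",
    "fit_logistic_mle",
    "nested_domain_models",
    "DEFAULT_DOMAINS",
    "ADULT_LINEAR",
    "ADULT_BINARY",
]

DEFAULT_DOMAINS = (
    "prenatal_birth",
    "development_behaviour",
    "education_ability",
    "socioeconomic",
    "parental_family",
)

# ordered adult covariates entered linearly in their level codes by default;
# a config switch expands them to full dummies
ADULT_LINEAR = (
    "exercise_days",
    "education_level",
    "nssec",
    "tv_hours",
    "internet_hours",
    "imd",
    "financial_difficulty",
    "audit_pc",
)
ADULT_BINARY = ("smoker", "partner")
INCOME_COLUMN = "weekly_income"


class ModelError(ValueError):
    pass


class PerfectSeparationError(ModelError):
    """A coefficient diverged during IRLS, indicating (quasi-)separation."""


@dataclass
class ModelFit:
    names: list
    params: np.ndarray
    cov: np.ndarray
    converged: bool
    n_obs: int
    loglik: float
    n_iter: int

    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov))

    def predict(self, X: np.ndarray) -> np.ndarray:
        return expit(np.asarray(X, float) @ self.params)

    def coef(self, name: str) -> float:
        return float(self.params[self.names.index(name)])

    def var(self, name: str) -> float:
        i = self.names.index(name)
        return float(self.cov[i, i])


def _loglik(eta: np.ndarray, y: np.ndarray) -> float:
    # y*eta - log(1 + exp(eta)), numerically stable
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def fit_logistic_mle(
    X,
    y,
    names: Optional[Sequence[str]] = None,
    tol: float = 1e-10,
    max_iter: int = 100,
    ridge: float = 0.0,
    separation_bound: float = 15.0,
) -> ModelFit:
    """Fit a binary logistic model by IRLS with step-halving.

    The log-likelihood is non-decreasing across iterations; convergence is a
    relative change below ``tol``.  A coefficient wandering past
    ``separation_bound`` in absolute value with no penalty is reported as
    perfect separation rather than returned silently.  ``ridge`` adds an L2
    penalty to the information matrix (used as a stabilised fallback inside
    the imputation engine).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ModelError("design matrix and outcome length mismatch")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ModelError("missing cells in the design or outcome; impute first")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ModelError("outcome must be binary 0/1")
    n, p = X.shape
    if names is None:
        names = [f"x{j}" for j in range(p)]
    names = list(names)
    if len(names) != p:
        raise ModelError("coefficient names do not match design columns")

    beta = np.zeros(p)
    eta = X @ beta
    ll = _loglik(eta, y) - 0.5 * ridge * float(beta @ beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mu = expit(eta)
        w = np.maximum(mu * (1.0 - mu), 1e-10)
        z = eta + (y - mu) / w
        Xw = X * w[:, None]
        H = X.T @ Xw + ridge * np.eye(p)
        try:
            beta_new = np.linalg.solve(H, Xw.T @ z)
        except np.linalg.LinAlgError as exc:
            raise ModelError(f"singular information matrix: {exc}") from exc

        # step-halving keeps the (penalised) log-likelihood non-decreasing
        step = beta_new - beta
        ll_new = -np.inf
        for _ in range(40):
            cand = beta + step
            eta_c = X @ cand
            ll_new = _loglik(eta_c, y) - 0.5 * ridge * float(cand @ cand)
            if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                beta_new = cand
                break
            step *= 0.5
        else:
            break

        if ridge == 0.0 and np.max(np.abs(beta_new)) > separation_bound:
            raise PerfectSeparationError(
                "a coefficient diverged past "
                f"|beta| > {separation_bound}; the data are separated"
            )

        delta = ll_new - ll
        beta, eta, ll = beta_new, X @ beta_new, ll_new
        if abs(delta) < tol * (abs(ll) + 1.0):
            converged = True
            break

    mu = expit(eta)
    w = np.maximum(mu * (1.0 - mu), 1e-10)
    H = X.T @ (X * w[:, None]) + ridge * np.eye(p)
    cov = np.linalg.inv(H)
    return ModelFit(
        names=names,
        params=beta,
        cov=cov,
        converged=converged,
        n_obs=n,
        loglik=_loglik(eta, y),
        n_iter=it,
    )


# ---------------------------------------------------------------------------
# Design construction
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelDesign:
    """Declarative design-matrix builder shared by the model, PAF and
    counterfactual stages, so factual and counterfactual designs are built by
    the same code path."""

    domains: tuple = DEFAULT_DOMAINS
    level: int = 3
    adult_linear: tuple = ADULT_LINEAR
    adult_binary: tuple = ADULT_BINARY
    income_column: str = INCOME_COLUMN
    dummy_adult: bool = False
    sex_column: str = "sex"
    ethnicity_column: str = "ethnicity"
    include_demographics: bool = True  # False: score dummies only (saturated fits)
    # optional per-domain category lists (tuple of (domain, categories) pairs);
    # lets sparse categories be dropped without a degenerate all-zero dummy
    domain_categories: Optional[tuple] = None

    def __post_init__(self):
        if self.level not in (1, 2, 3):
            raise ModelError(f"model level must be 1, 2 or 3, got {self.level}")

    def cats_for(self, domain: str) -> tuple:
        if self.domain_categories is not None:
            for dom, cats in self.domain_categories:
                if dom == domain:
                    return tuple(cats)
        return tuple(CAP_LABELS[1:])

    def column_names(self) -> list:
        names = ["intercept"]
        for dom in self.domains:
            names += [f"{dom}[{c}]" for c in self.cats_for(dom)]
        if self.include_demographics:
            names += [self.sex_column, self.ethnicity_column]
        if self.level == 3:
            for colname in self.adult_linear:
                names.append(colname)
            for colname in self.adult_binary:
                names.append(colname)
            names.append("log_income_z")
        return names

    def build(
        self,
        df: pd.DataFrame,
        override: Optional[Mapping[str, str]] = None,
        income_stats: Optional[tuple] = None,
    ) -> np.ndarray:
        """Build the design matrix.

        ``override`` maps a domain name to a score category imposed on every
        row (the counterfactual switch used for standardisation).
        ``income_stats`` freezes the (mean, sd) used to standardise log
        income; by default they are computed from ``df``.
        """
        n = len(df)
        blocks = [np.ones((n, 1))]
        override = override or {}
        for dom in self.domains:
            if dom in override:
                cat = np.full(n, override[dom], dtype=object)
            else:
                cat = df[cat_column(dom)].to_numpy(dtype=object)
            dummies = np.column_stack(
                [(cat == c).astype(float) for c in self.cats_for(dom)]
            )
            blocks.append(dummies)
        if self.include_demographics:
            blocks.append(df[[self.sex_column, self.ethnicity_column]].to_numpy(float))
        if self.level == 3:
            if self.dummy_adult:
                raise NotImplementedError(
                    "full dummy coding of adult covariates is not implemented; "
                    "ordered covariates enter linearly in their level codes"
                )
            blocks.append(df[list(self.adult_linear)].to_numpy(float))
            blocks.append(df[list(self.adult_binary)].to_numpy(float))
            income = df[self.income_column].to_numpy(float)
            if (income <= 0).any():
                raise ModelError("weekly income must be positive for the log transform")
            log_inc = np.log(income)
            if income_stats is None:
                mean, sd = log_inc.mean(), log_inc.std()
            else:
                mean, sd = income_stats
            z = (log_inc - mean) / sd if sd > 0 else np.zeros(n)
            blocks.append(z[:, None])
        X = np.hstack(blocks)
        if np.isnan(X).any():
            raise ModelError("missing cells in the design; impute first")
        return X

    def fit(self, df: pd.DataFrame, outcome: str = "derived_case", **kwargs) -> ModelFit:
        X = self.build(df)
        y = df[outcome].to_numpy(float)
        return fit_logistic_mle(X, y, names=self.column_names(), **kwargs)


# ---------------------------------------------------------------------------
# Nested model levels with pooling across imputed datasets
# ---------------------------------------------------------------------------

def _collapse_sparse_categories(tables: Sequence[pd.DataFrame], domains: Sequence[str]):
    """If a score category is empty in any completed table, merge it upward
    (1 -> 2 -> 3+) in every table so the dummy design stays full rank."""
    tables = [t.copy() for t in tables]
    for dom in domains:
        col = cat_column(dom)
        for c in ("1", "2"):
            if any((t[col] == c).sum() == 0 for t in tables):
                upper = CAP_LABELS[CAP_LABELS.index(c) + 1]
                logger.warning(
                    "domain %s: empty score category %s collapsed into %s", dom, c, upper
                )
                for t in tables:
                    t.loc[t[col] == c, col] = upper
        if any((t[col] == "3+").sum() == 0 for t in tables):
            logger.warning("domain %s: empty top category 3+ collapsed into 2", dom)
            for t in tables:
                t.loc[t[col] == "3+", col] = "2"
    return tables


def _pool_coefficient(fits: Sequence[ModelFit], name: str, alpha: float = 0.05):
    from .imputation import pool_rubin

    if len(fits) == 1:
        f = fits[0]
        est, var = f.coef(name), f.var(name)
        z = norm.ppf(1 - alpha / 2)
        half = z * np.sqrt(var)
        return est, var, est - half, est + half
    est = [f.coef(name) for f in fits]
    var = [f.var(name) for f in fits]
    pooled = pool_rubin(est, var, alpha=alpha)
    return pooled.estimate, pooled.total_variance, pooled.ci_low, pooled.ci_high


def nested_domain_models(
    tables,
    model_level: int,
    domains: Sequence[str] = DEFAULT_DOMAINS,
    outcome: str = "derived_case",
    design_kwargs: Optional[dict] = None,
) -> pd.DataFrame:
    """Fit one of the three nested model levels on M completed tables.

    Returns an odds-ratio table with one row per (domain, score category),
    pooled across the completed tables on the log-odds scale; the reference
    category 0 is implicit (OR 1).  Level 1 fits each domain separately with
    sex and ethnicity; levels 2 and 3 fit all domains jointly.
    """
    if isinstance(tables, pd.DataFrame):
        tables = [tables]
    tables = list(tables)
    if not tables:
        raise ModelError("no completed tables supplied")
    design_kwargs = design_kwargs or {}
    tables = _collapse_sparse_categories(tables, domains)
    cats = present_categories(tables, domains)

    rows = []
    if model_level == 1:
        for dom in domains:
            design = ModelDesign(
                domains=(dom,),
                level=1,
                domain_categories=((dom, dict(cats)[dom]),),
                **design_kwargs,
            )
            fits = [design.fit(t, outcome=outcome) for t in tables]
            rows.extend(_or_rows(fits, dom, model_level))
    else:
        design = ModelDesign(
            domains=tuple(domains),
            level=model_level,
            domain_categories=cats,
            **design_kwargs,
        )
        fits = [design.fit(t, outcome=outcome) for t in tables]
        for dom in domains:
            rows.extend(_or_rows(fits, dom, model_level))
    return pd.DataFrame(rows)


def present_categories(tables: Sequence[pd.DataFrame], domains: Sequence[str]) -> tuple:
    """Per-domain non-reference categories observed in every completed table."""
    out = []
    for dom in domains:
        col = cat_column(dom)
        cats = tuple(
            c
            for c in CAP_LABELS[1:]
            if all((t[col] == c).any() for t in tables)
        )
        out.append((dom, cats))
    return tuple(out)


def _or_rows(fits, domain: str, model_level: int) -> list:
    rows = []
    for c in CAP_LABELS[1:]:
        name = f"{domain}[{c}]"
        if name not in fits[0].names:
            continue
        est, var, lo, hi = _pool_coefficient(fits, name)
        rows.append(
            {
                "domain": domain,
                "category": c,
                "model": model_level,
                "log_odds": est,
                "log_odds_variance": var,
                "or": float(np.exp(est)),
                "ci_low": float(np.exp(lo)),
                "ci_high": float(np.exp(hi)),
                "significant": bool(lo > 0 or hi < 0),
            }
        )
    return rows
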