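"""Multiple imputation by chained equations and Rubin's-rules pooling.

Each incomplete variable is imputed by iterated draws from a conditional
model given all other variables: Bayesian-draw linear regression for
continuous variables, Bayesian-draw logistic regression for binary ones, and
a linear model snapped to the nearest valid level for ordered categorical
codes.  Parameter perturbation (a posterior draw per imputation) makes the M
completed datasets differ, which is what gives Rubin's between-imputation
variance its meaning.  The outcome takes part in the conditional models, but
rows whose outcome was originally missing are deleted from the analysis
tables afterwards (multiple imputation then deletion), so imputed outcome
values are never analysed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ImputationError",
    "ImputationSet",
    "impute_chained",
    "drop_imputed_outcomes",
    "pool_rubin",
    "PooledResult",
    "save_imputation_set",
    "load_imputation_set",
]

RIDGE_FALLBACK = 0.5  # L2 penalty used when an unpenalised conditional fit fails


class ImputationError(ValueError):
    pass


@dataclass
class ImputationSet:
    """M completed copies of a table plus provenance."""

    tables: list
    m: int
    cycles: int
    seed: int
    missing_mask: pd.DataFrame
    variable_models: dict
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.m != len(self.tables):
            raise ImputationError("m does not match the number of tables")


class PooledResult(NamedTuple):
    estimate: float
    within_variance: float
    between_variance: float
    total_variance: float
    df: float
    ci_low: float
    ci_high: float


def pool_rubin(estimates: Sequence[float], variances: Sequence[float], alpha: float = 0.05) -> PooledResult:
    """Pool M estimates and their variances with Rubin's rules.

    total variance T = W + (1 + 1/M) B, with the t reference on
    nu = (M-1) (1 + W / ((1 + 1/M) B))^2 degrees of freedom; when the
    between-imputation variance is zero the reference is normal.
    """
    est = np.asarray(estimates, dtype=float)
    var = np.asarray(variances, dtype=float)
    if est.size != var.size:
        raise ImputationError("estimates and variances differ in length")
    m = est.size
    if m < 2:
        raise ImputationError("Rubin's rules require M >= 2 imputations")
    q = float(est.mean())
    w = float(var.mean())
    # identical estimates carry no between-imputation variance (guard against
    # rounding noise in the sample variance of constant inputs)
    b = 0.0 if np.ptp(est) == 0.0 else float(est.var(ddof=1))
    t = w + (1.0 + 1.0 / m) * b
    if b <= 0.0:
        df = np.inf
        crit = stats.norm.ppf(1 - alpha / 2)
    else:
        df = (m - 1) * (1.0 + w / ((1.0 + 1.0 / m) * b)) ** 2
        crit = stats.t.ppf(1 - alpha / 2, df)
    half = crit * np.sqrt(t)
    return PooledResult(q, w, b, t, float(df), q - half, q + half)


# ---------------------------------------------------------------------------
# Conditional models
# ---------------------------------------------------------------------------

def _linear_draw(X: np.ndarray, y: np.ndarray, rng: np.random.Generator):
    """Posterior draw of (beta, sigma) for a Gaussian linear model."""
    n, p = X.shape
    xtx = X.T @ X + 1e-8 * np.eye(p)
    beta_hat = np.linalg.solve(xtx, X.T @ y)
    resid = y - X @ beta_hat
    dof = max(n - p, 1)
    sigma2 = float(resid @ resid) / dof
    sigma2_star = sigma2 * dof / rng.chisquare(dof)
    cov = sigma2_star * np.linalg.inv(xtx)
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(p))
    beta_star = beta_hat + chol @ rng.standard_normal(p)
    return beta_star, float(np.sqrt(sigma2_star))


def _logistic_draw(X: np.ndarray, y: np.ndarray, rng: np.random.Generator, diagnostics: dict, col: str):
    """Posterior draw of beta for a logistic conditional model, with a
    ridge-stabilised fallback when the unpenalised IRLS fails."""
    from .models import ModelError, PerfectSeparationError, fit_logistic_mle

    try:
        fit = fit_logistic_mle(X, y, max_iter=50, tol=1e-8)
        if not fit.converged:
            raise ModelError("IRLS did not converge")
    except (PerfectSeparationError, ModelError) as exc:
        logger.warning("conditional model for %s: %s; refitting with ridge", col, exc)
        diagnostics.setdefault("ridge_fallbacks", []).append(col)
        fit = fit_logistic_mle(X, y, max_iter=50, tol=1e-8, ridge=RIDGE_FALLBACK)
    chol = np.linalg.cholesky(fit.cov + 1e-12 * np.eye(len(fit.params)))
    return fit.params + chol @ rng.standard_normal(len(fit.params))


def impute_chained(
    table: pd.DataFrame,
    variable_models: Mapping[str, str],
    m: int = 50,
    cycles: int = 10,
    seed: int = 0,
) -> ImputationSet:
    """Impute a numeric table by chained equations.

    ``variable_models`` maps each column that may contain missing cells to one
    of ``linear``, ``logistic`` or ``ordinal``.  Every column of ``table`` is
    used as a predictor in every conditional model.  Observed cells are
    preserved bit-exactly in all M completed tables; the run is fully
    determined by ``seed``.
    """
    if m < 1:
        raise ImputationError("m must be >= 1")
    if cycles < 1:
        raise ImputationError("cycles must be >= 1")
    data = table.astype(float)
    mask = data.isna()
    missing_cols = [c for c in data.columns if mask[c].any()]
    for c in missing_cols:
        if c not in variable_models:
            raise ImputationError(f"no conditional model declared for incomplete column {c!r}")
        if mask[c].all():
            raise ImputationError(f"column {c!r} is 100% missing and cannot be imputed")
    if missing_cols and not any(~mask[c].any() for c in data.columns):
        raise ImputationError("at least one fully observed column is required")
    for c, kind in variable_models.items():
        if kind not in ("linear", "logistic", "ordinal", "lognormal"):
            raise ImputationError(f"{c}: unknown conditional model {kind!r}")

    diagnostics: dict = {"missing_counts": {c: int(mask[c].sum()) for c in missing_cols}}
    ordered = sorted(missing_cols, key=lambda c: mask[c].sum())
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(m)

    completed = []
    for i in range(m):
        rng = np.random.default_rng(child_seeds[i])
        cur = data.copy()
        # initial fill: random draws from the observed margin
        for c in ordered:
            obs_vals = data.loc[~mask[c], c].to_numpy()
            cur.loc[mask[c], c] = rng.choice(obs_vals, size=int(mask[c].sum()))
        if missing_cols:
            for _ in range(cycles):
                for c in ordered:
                    _impute_one(cur, data, mask, c, variable_models[c], rng, diagnostics)
        completed.append(cur)

    return ImputationSet(
        tables=completed,
        m=m,
        cycles=cycles,
        seed=seed,
        missing_mask=mask,
        variable_models=dict(variable_models),
        diagnostics=diagnostics,
    )


def _impute_one(cur, data, mask, col, kind, rng, diagnostics):
    predictors = [c for c in cur.columns if c != col]
    X = np.column_stack([np.ones(len(cur)), cur[predictors].to_numpy(float)])
    obs = (~mask[col]).to_numpy()
    mis = mask[col].to_numpy()
    y_obs = data.loc[obs, col].to_numpy(float)
    if kind == "logistic":
        uniq = np.unique(y_obs)
        if not np.isin(uniq, (0.0, 1.0)).all():
            raise ImputationError(f"{col}: logistic model needs a 0/1 variable")
        if uniq.size < 2:
            # degenerate margin: impute the constant observed value
            cur.loc[mis, col] = uniq[0]
            return
        beta = _logistic_draw(X[obs], y_obs, rng, diagnostics, col)
        from scipy.special import expit

        p = expit(X[mis] @ beta)
        cur.loc[mis, col] = rng.binomial(1, p).astype(float)
    elif kind == "lognormal":
        # strictly positive skewed variables are modelled on the log scale
        if (y_obs <= 0).any():
            raise ImputationError(f"{col}: lognormal model needs positive values")
        beta, sigma = _linear_draw(X[obs], np.log(y_obs), rng)
        draws = X[mis] @ beta + sigma * rng.standard_normal(int(mis.sum()))
        cur.loc[mis, col] = np.exp(draws)
    else:
        beta, sigma = _linear_draw(X[obs], y_obs, rng)
        draws = X[mis] @ beta + sigma * rng.standard_normal(int(mis.sum()))
        if kind == "ordinal":
            levels = np.unique(y_obs)
            idx = np.abs(draws[:, None] - levels[None, :]).argmin(axis=1)
            draws = levels[idx]
        cur.loc[mis, col] = draws


def drop_imputed_outcomes(imp: ImputationSet, outcome_columns: Sequence[str]) -> ImputationSet:
    """Remove rows whose outcome was originally missing from every copy.

    The outcome contributed information to the chained equations, but imputed
    outcome values are not analysed; deletion depends only on the original
    missingness pattern, so the same rows go in every copy.
    """
    outcome_columns = list(outcome_columns)
    for c in outcome_columns:
        if c not in imp.missing_mask.columns:
            raise ImputationError(f"outcome column {c!r} not in the imputed table")
    drop = imp.missing_mask[outcome_columns].any(axis=1)
    n_drop = int(drop.sum())
    if n_drop:
        logger.info("dropping %d rows with originally missing outcome", n_drop)
    keep = ~drop
    tables = [t.loc[keep].copy() for t in imp.tables]
    diagnostics = dict(imp.diagnostics)
    diagnostics["rows_dropped_missing_outcome"] = n_drop
    return ImputationSet(
        tables=tables,
        m=imp.m,
        cycles=imp.cycles,
        seed=imp.seed,
        missing_mask=imp.missing_mask.loc[keep],
        variable_models=imp.variable_models,
        diagnostics=diagnostics,
    )


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_imputation_set(imp: ImputationSet, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, t in enumerate(imp.tables, start=1):
        t.to_csv(directory / f"imputed_{i:02d}.csv", index=False)
    manifest = {
        "m": imp.m,
        "cycles": imp.cycles,
        "seed": imp.seed,
        "variable_models": imp.variable_models,
        "missing_counts": imp.diagnostics.get("missing_counts", {}),
        "diagnostics": {
            k: v for k, v in imp.diagnostics.items() if k != "missing_counts"
        },
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)


def load_imputation_set(directory) -> ImputationSet:
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    tables = []
    for p in sorted(directory.glob("imputed_*.csv")):
        t = pd.read_csv(p)
        # capped score categories are labels ("0".."3+"), not integers
        for c in t.columns:
            if c.startswith("derived_cat_"):
                t[c] = t[c].astype(str)
        tables.append(t)
    mask = tables[0].isna()  # completed tables have no missing cells
    return ImputationSet(
        tables=tables,
        m=manifest["m"],
        cycles=manifest["cycles"],
        seed=manifest["seed"],
        missing_mask=mask,
        variable_models=manifest["variable_models"],
        diagnostics=manifest.get("diagnostics", {}),
    )
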