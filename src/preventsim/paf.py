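"""Scenario population attributable fractions by model-based standardisation.

For a scenario "category a -> category b" within one domain, the exposed group
is every analysed participant whose domain score is in the *from* category.
The factual risk is the mean model-predicted case probability of that group at
its observed covariates; the counterfactual risk is the mean prediction for
the same individuals with the domain's score dummies switched to the *to*
category, everything else held fixed (G-computation).  The population
unattributable fraction PUF is the ratio counterfactual/factual, and
PAF = 1 - PUF: the proportion of the group's outcome prevalence that would not
have occurred had its exposure matched the reference scenario.

Uncertainty comes either from a nonparametric bootstrap (resample the analysis
table, refit, recompute log PUF) or from the delta method on log PUF using the
model's Wald covariance.  Pooling across imputed datasets is always on the
log-PUF scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .derivation import CAP_LABELS, cat_column
from .imputation import pool_rubin
from .models import DEFAULT_DOMAINS, ModelDesign, ModelFit, present_categories

logger = logging.getLogger(__name__)

__all__ = [
    "PafError",
    "PafScenario",
    "PafEstimate",
    "SCENARIOS",
    "paf_scenario",
    "paf_table",
]

_ORDER = {c: i for i, c in enumerate(CAP_LABELS)}

# the six reduction scenarios within a domain
SCENARIOS = (
    ("3+", "2"),
    ("3+", "1"),
    ("3+", "0"),
    ("2", "1"),
    ("2", "0"),
    ("1", "0"),
)


class PafError(ValueError):
    pass


@dataclass(frozen=True)
class PafScenario:
    domain: str
    from_category: str
    to_category: str

    def __post_init__(self):
        for c in (self.from_category, self.to_category):
            if c not in _ORDER:
                raise PafError(f"unknown score category {c!r}")
        if _ORDER[self.to_category] > _ORDER[self.from_category]:
            raise PafError(
                f"scenario must reduce adversity: {self.from_category} -> {self.to_category}"
            )

    @property
    def label(self) -> str:
        return f"{self.from_category} to {self.to_category}"


@dataclass
class PafEstimate:
    scenario: PafScenario
    paf: float
    ci_low: float
    ci_high: float
    log_puf: float
    log_puf_variance: float
    n_exposed: int
    significant: Optional[bool] = None


def _income_stats(df: pd.DataFrame, design: ModelDesign):
    if design.level != 3:
        return None
    log_inc = np.log(df[design.income_column].to_numpy(float))
    return log_inc.mean(), log_inc.std()


def _log_puf_point(fit: ModelFit, df: pd.DataFrame, scenario: PafScenario, design: ModelDesign, stats):
    mask = (df[cat_column(scenario.domain)] == scenario.from_category).to_numpy()
    if not mask.any():
        raise PafError(
            f"no participants in the exposed group for scenario "
            f"{scenario.domain} {scenario.label}"
        )
    sub = df.loc[mask]
    x_f = design.build(sub, income_stats=stats)
    x_cf = design.build(
        sub, override={scenario.domain: scenario.to_category}, income_stats=stats
    )
    p_f = float(fit.predict(x_f).mean())
    p_cf = float(fit.predict(x_cf).mean())
    return np.log(p_cf) - np.log(p_f), p_f, p_cf, int(mask.sum()), sub, x_f, x_cf


def _delta_variance(fit: ModelFit, x_f, x_cf):
    mu_f = fit.predict(x_f)
    mu_cf = fit.predict(x_cf)
    p_f, p_cf = mu_f.mean(), mu_cf.mean()
    grad_f = (mu_f * (1 - mu_f)) @ x_f / len(mu_f)
    grad_cf = (mu_cf * (1 - mu_cf)) @ x_cf / len(mu_cf)
    g = grad_cf / p_cf - grad_f / p_f
    return float(g @ fit.cov @ g)


def paf_scenario(
    fit: ModelFit,
    table: pd.DataFrame,
    scenario: PafScenario,
    design: ModelDesign,
    alpha: float = 0.05,
) -> PafEstimate:
    """Single-dataset scenario PAF with a delta-method CI on log PUF.

    ``fit`` must be a logistic model fitted with ``design`` on ``table`` (or a
    table exchangeable with it); income standardisation is frozen to the full
    table so subgroup predictions line up with the fitted model.
    """
    stats = _income_stats(table, design)
    log_puf, _, _, n_exposed, _, x_f, x_cf = _log_puf_point(
        fit, table, scenario, design, stats
    )
    var = _delta_variance(fit, x_f, x_cf)
    z = norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(var)
    return PafEstimate(
        scenario=scenario,
        paf=1.0 - np.exp(log_puf),
        ci_low=1.0 - np.exp(log_puf + half),
        ci_high=1.0 - np.exp(log_puf - half),
        log_puf=log_puf,
        log_puf_variance=var,
        n_exposed=n_exposed,
        significant=bool(log_puf + half < 0 or log_puf - half > 0),
    )


def significant_domains(or_table: pd.DataFrame) -> list:
    """Domains with any significant score-category OR (used at model level 3)."""
    sig = or_table[or_table["significant"]]
    return sorted(sig["domain"].unique(), key=list(or_table["domain"]).index)


def paf_table(
    tables,
    domains: Optional[Sequence[str]] = None,
    scenarios: Sequence = SCENARIOS,
    model_domains: Sequence[str] = DEFAULT_DOMAINS,
    ci_method: str = "bootstrap",
    n_boot: int = 200,
    seed: int = 0,
    alpha: float = 0.05,
    design_kwargs: Optional[dict] = None,
    or_table: Optional[pd.DataFrame] = None,
) -> list:
    """Pooled scenario PAFs across M completed tables.

    ``domains=None`` restricts the grid to the domains significantly
    associated with the outcome in the fully adjusted model (level 3); pass an
    explicit list to override.  Returns a list of pooled :class:`PafEstimate`
    (empty, with a logged notice, when no domain is significant).
    """
    from .models import nested_domain_models

    if isinstance(tables, pd.DataFrame):
        tables = [tables]
    tables = list(tables)
    if ci_method not in ("bootstrap", "delta"):
        raise PafError(f"unknown ci_method {ci_method!r}")
    design_kwargs = design_kwargs or {}

    if domains is None:
        if or_table is None:
            or_table = nested_domain_models(tables, 3, domains=model_domains)
        domains = significant_domains(or_table)
        if not domains:
            logger.info("no domain significant in the fully adjusted model; empty PAF grid")
            return []

    cats = present_categories(tables, model_domains)
    design = ModelDesign(
        domains=tuple(model_domains), level=3, domain_categories=cats, **design_kwargs
    )
    rng = np.random.default_rng(seed)

    results = []
    per_table = []  # (fit, stats) per completed table
    for t in tables:
        fit = design.fit(t)
        per_table.append((fit, _income_stats(t, design)))

    scen_objs = [
        PafScenario(dom, frm, to) for dom in domains for frm, to in scenarios
    ]

    # per-dataset log PUF and its variance
    points = {s: [] for s in scen_objs}
    variances = {s: [] for s in scen_objs}
    n_exposed = {s: 0 for s in scen_objs}
    for t, (fit, stats) in zip(tables, per_table):
        boot_logs = {s: [] for s in scen_objs} if ci_method == "bootstrap" else None
        if ci_method == "bootstrap":
            n = len(t)
            for _ in range(n_boot):
                idx = rng.integers(0, n, n)
                bt = t.iloc[idx]
                try:
                    bfit = design.fit(bt)
                except Exception:  # unstable resample: skip the draw
                    continue
                bstats = _income_stats(bt, design)
                for s in scen_objs:
                    try:
                        lp = _log_puf_point(bfit, bt, s, design, bstats)[0]
                    except PafError:
                        continue
                    boot_logs[s].append(lp)
        for s in scen_objs:
            lp, _, _, n_exp, _, x_f, x_cf = _log_puf_point(fit, t, s, design, stats)
            points[s].append(lp)
            n_exposed[s] = n_exp
            if ci_method == "delta":
                variances[s].append(_delta_variance(fit, x_f, x_cf))
            else:
                draws = np.asarray(boot_logs[s])
                if draws.size < 10:
                    raise PafError(
                        f"too few usable bootstrap draws for scenario {s.domain} {s.label}"
                    )
                variances[s].append(float(draws.var(ddof=1)))

    for s in scen_objs:
        est = points[s]
        var = variances[s]
        if len(est) == 1:
            lp, v = est[0], var[0]
            z = norm.ppf(1 - alpha / 2)
            lo, hi = lp - z * np.sqrt(v), lp + z * np.sqrt(v)
            t_var = v
        else:
            pooled = pool_rubin(est, var, alpha=alpha)
            lp, t_var, lo, hi = (
                pooled.estimate,
                pooled.total_variance,
                pooled.ci_low,
                pooled.ci_high,
            )
        results.append(
            PafEstimate(
                scenario=s,
                paf=1.0 - np.exp(lp),
                ci_low=1.0 - np.exp(hi),
                ci_high=1.0 - np.exp(lo),
                log_puf=lp,
                log_puf_variance=t_var,
                n_exposed=n_exposed[s],
                significant=bool(hi < 0 or lo > 0),
            )
        )
    return results


def paf_table_frame(estimates: Sequence[PafEstimate]) -> pd.DataFrame:
    """Flatten pooled PAF estimates into a scenario x domain table."""
    rows = []
    for e in estimates:
        rows.append(
            {
                "domain": e.scenario.domain,
                "scenario": e.scenario.label,
                "paf_pct": 100.0 * e.paf,
                "ci_low_pct": 100.0 * e.ci_low,
                "ci_high_pct": 100.0 * e.ci_high,
                "n_exposed": e.n_exposed,
                "significant": e.significant,
            }
        )
    return pd.DataFrame(rows)
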