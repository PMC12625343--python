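"""Counterfactual intervention simulation and projected risk reductions.

A library of published intervention effects (Family Nurse Partnership, Family
Hubs, the UK teenage pregnancy prevention framework) is applied universally
to the cohort: an additive shift moves a raw variable for every eligible
participant (e.g. birthweight +324 g), while a reclassification effect moves a
random fraction of the at-risk group from adverse to non-adverse.  Domain
adversity scores are then recomputed, the category transitions of cases
(participants with MLTCs and role limitation) are tabulated, and the
significant scenario PAFs are applied to the movers to project how many cases
would no longer report the outcome, expressed as an absolute risk reduction
within the adversity group.

Because published reports round these projections inconsistently, both a
fractional convention (PAF x movers, left as a real number) and an integer
convention (nearest-integer removals) are first-class outputs; neither is
silently preferred.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .derivation import (
    CAP_LABELS,
    DomainSpec,
    binarize_adversity,
    cat_column,
    indicator_column,
    score_column,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CounterfactualError",
    "InterventionEffect",
    "TransitionTable",
    "ScenarioResult",
    "table4_intervention_library",
    "apply_effect",
    "apply_all",
    "recompute_scores",
    "transition_table",
    "project_reduction",
    "absolute_risk_reduction_pct",
    "round_half_away",
    "render_case_study",
]

_ORDER = {c: i for i, c in enumerate(CAP_LABELS)}


class CounterfactualError(ValueError):
    pass


@dataclass(frozen=True)
class InterventionEffect:
    """One published intervention effect mapped onto a cohort variable."""

    target_variable: str
    effect_kind: str  # "additive_shift" | "fraction_reclassified"
    magnitude: float  # shift in natural units, or fraction in [0, 1]
    eligibility: str  # "all" | "adverse" (the at-risk group)
    source: str

    def __post_init__(self):
        if self.effect_kind not in ("additive_shift", "fraction_reclassified"):
            raise CounterfactualError(f"unknown effect kind {self.effect_kind!r}")
        if self.effect_kind == "fraction_reclassified" and not 0.0 <= self.magnitude <= 1.0:
            raise CounterfactualError("reclassified fraction must be in [0, 1]")
        if self.eligibility not in ("all", "adverse"):
            raise CounterfactualError(f"unknown eligibility {self.eligibility!r}")


FNP = "Family Nurse Partnership"
FAMILY_HUBS = "Family Hubs"
TEEN_PREG = "Teenage Pregnancy Prevention Framework"


def table4_intervention_library() -> list:
    """The eleven intervention effects mapped onto cohort variables.

    Maternal age at delivery and parity carry no effect: no interventions
    targeting them were identified.
    """
    return [
        InterventionEffect("birthweight", "additive_shift", 324.0, "all", FNP),
        InterventionEffect("maternal_smoking", "fraction_reclassified", 0.08, "adverse", FNP),
        InterventionEffect("teenage_pregnancy", "fraction_reclassified", 0.62, "adverse", TEEN_PREG),
        InterventionEffect("rutter_high_risk", "fraction_reclassified", 0.39, "adverse", FNP),
        InterventionEffect("walking_backwards", "fraction_reclassified", 0.06, "adverse", FAMILY_HUBS),
        InterventionEffect("behavioural_problems", "fraction_reclassified", 0.55, "adverse", FNP),
        InterventionEffect("hand_control", "fraction_reclassified", 0.06, "adverse", FAMILY_HUBS),
        InterventionEffect("temper", "fraction_reclassified", 0.026, "adverse", FNP),
        InterventionEffect("clumsy", "fraction_reclassified", 0.06, "adverse", FAMILY_HUBS),
        InterventionEffect("balance_right", "fraction_reclassified", 0.06, "adverse", FAMILY_HUBS),
        InterventionEffect("balance_left", "fraction_reclassified", 0.06, "adverse", FAMILY_HUBS),
    ]


def round_half_away(x: float) -> int:
    """Round halves away from zero (so 8.5 -> 9), unlike banker's rounding."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _find_rule(domain_specs: Sequence[DomainSpec], variable: str):
    for dom in domain_specs:
        if variable in dom.variable_names:
            return dom, dom.rule_for(variable)
    raise CounterfactualError(f"unknown target variable {variable!r}")


def apply_effect(
    cohort: pd.DataFrame,
    effect: InterventionEffect,
    seed: int,
    domain_specs: Sequence[DomainSpec],
) -> pd.DataFrame:
    """Apply one intervention effect; returns a modified copy.

    Additive shifts update the raw variable and re-derive its adversity
    indicator with the variable's rule.  Reclassification samples
    round(f x n_eligible) of the at-risk participants without replacement and
    sets their adversity indicator to 0; indicators are only ever reduced.
    """
    _, rule = _find_rule(domain_specs, effect.target_variable)
    out = cohort.copy()
    ind_col = indicator_column(effect.target_variable)
    if ind_col not in out.columns:
        raise CounterfactualError(
            f"indicator {ind_col!r} not derived; run the derivation stage first"
        )
    rng = np.random.default_rng(seed)
    if effect.effect_kind == "additive_shift":
        if effect.target_variable not in out.columns:
            raise CounterfactualError(f"unknown target variable {effect.target_variable!r}")
        if effect.eligibility == "all":
            eligible = np.ones(len(out), dtype=bool)
        else:
            eligible = out[ind_col].to_numpy(float) == 1.0
        vals = out[effect.target_variable].to_numpy(float)
        vals[eligible] = vals[eligible] + effect.magnitude
        out[effect.target_variable] = vals
        out[ind_col] = binarize_adversity(vals, rule)
    else:
        eligible = np.flatnonzero(out[ind_col].to_numpy(float) == 1.0)
        k = round_half_away(effect.magnitude * eligible.size)
        if k == 0:
            logger.info(
                "effect on %s: %d eligible x %.3f rounds to zero participants",
                effect.target_variable,
                eligible.size,
                effect.magnitude,
            )
            return out
        chosen = rng.choice(eligible, size=k, replace=False)
        col = out[ind_col].to_numpy(float)
        col[chosen] = 0.0
        out[ind_col] = col
    return out


def _effect_subseed(seed: int, variable: str) -> np.random.SeedSequence:
    # sub-seed tied to the target variable, not to library order, so permuting
    # the (variable-disjoint) library cannot change the result
    return np.random.SeedSequence([int(seed), zlib.crc32(variable.encode())])


def apply_all(
    cohort: pd.DataFrame,
    effects: Sequence[InterventionEffect],
    seed: int,
    domain_specs: Sequence[DomainSpec],
) -> pd.DataFrame:
    """Apply the combined effect of all interventions (universal rollout).

    Effects must target distinct variables; additivity of two effects on one
    variable is undefined.  Each effect draws from an independent sub-seed
    derived from its target variable, so library order is immaterial.
    """
    targets = [e.target_variable for e in effects]
    dupes = {t for t in targets if targets.count(t) > 1}
    if dupes:
        raise CounterfactualError(
            f"multiple effects target the same variable(s): {sorted(dupes)}"
        )
    out = cohort
    for e in effects:
        sub = int(_effect_subseed(seed, e.target_variable).generate_state(1)[0] % (2 ** 31))
        out = apply_effect(out, e, sub, domain_specs)
    return out


def recompute_scores(cohort: pd.DataFrame, domain_specs: Sequence[DomainSpec]) -> pd.DataFrame:
    """Recompute domain raw sums and capped categories from the (possibly
    intervened-on) indicator columns."""
    from .derivation import add_domain_scores

    return add_domain_scores(cohort, domain_specs)


# ---------------------------------------------------------------------------
# Transitions and projections
# ---------------------------------------------------------------------------

@dataclass
class TransitionTable:
    """Category-to-category transition counts among cases for one domain."""

    domain: str
    counts: pd.DataFrame  # index: from-category, columns: to-category
    group_sizes: pd.Series  # baseline cases per from-category

    def movers(self, from_category: str, to_category: str) -> float:
        return float(self.counts.loc[from_category, to_category])

    def percent(self, from_category: str, to_category: str) -> float:
        """Share of the from-category's cases that moved, to one decimal."""
        denom = float(self.group_sizes[from_category])
        if denom == 0:
            raise CounterfactualError(f"no cases with score {from_category}")
        return round(100.0 * self.movers(from_category, to_category) / denom, 1)


def transition_table(
    scores_before,
    scores_after,
    case_mask,
    domain: str,
) -> TransitionTable:
    """Tabulate capped-category transitions among cases.

    ``scores_before``/``scores_after`` are capped category labels on the same
    participants; interventions only remove adversity, so any participant
    whose category increased is an error.
    """
    before = np.asarray(scores_before, dtype=object)
    after = np.asarray(scores_after, dtype=object)
    cases = np.asarray(case_mask, dtype=bool)
    if before.shape != after.shape or before.shape != cases.shape:
        raise CounterfactualError("score vectors and case mask must align")
    for arr in (before, after):
        bad = set(arr) - set(CAP_LABELS)
        if bad:
            raise CounterfactualError(f"unknown score categories {sorted(bad)}")
    b_idx = np.array([_ORDER[c] for c in before])
    a_idx = np.array([_ORDER[c] for c in after])
    if (a_idx > b_idx).any():
        raise CounterfactualError(
            "a participant's adversity score increased; interventions must only reduce adversity"
        )
    counts = pd.DataFrame(0, index=list(CAP_LABELS), columns=list(CAP_LABELS), dtype=float)
    for b, a in zip(before[cases], after[cases]):
        counts.loc[b, a] += 1
    group_sizes = counts.sum(axis=1)
    return TransitionTable(domain=domain, counts=counts, group_sizes=group_sizes)


@dataclass
class ScenarioResult:
    """Projected removals and absolute risk reduction for one scenario.

    ``arr_fractional_pct`` applies the PAF to the movers and leaves the result
    fractional; ``arr_integer_pct`` first rounds the projected removals to the
    nearest whole person.  The two conventions bracket each other within
    100/group_cases percentage points.
    """

    domain: str
    from_category: str
    to_category: str
    movers: float
    paf: float
    group_cases: float
    removals_fractional: float
    removals_integer: int
    arr_fractional_pct: float
    arr_integer_pct: float


def absolute_risk_reduction_pct(removals: float, group_cases: float) -> float:
    """Removals as a percentage of the adversity group's cases (1 decimal)."""
    if group_cases <= 0:
        raise CounterfactualError("group_cases must be positive")
    return round(100.0 * removals / group_cases, 1)


def project_reduction(
    movers: float,
    paf: float,
    group_cases: float,
    domain: str = "",
    from_category: str = "",
    to_category: str = "",
) -> ScenarioResult:
    """Project outcome removals from a transition count and a scenario PAF."""
    if group_cases <= 0:
        raise CounterfactualError("group_cases must be positive")
    if movers < 0 or movers > group_cases:
        raise CounterfactualError("movers must lie in [0, group_cases]")
    frac = paf * movers
    integer = round_half_away(frac)
    return ScenarioResult(
        domain=domain,
        from_category=from_category,
        to_category=to_category,
        movers=movers,
        paf=paf,
        group_cases=group_cases,
        removals_fractional=frac,
        removals_integer=integer,
        arr_fractional_pct=100.0 * frac / group_cases,
        arr_integer_pct=100.0 * integer / group_cases,
    )


def scenario_results_frame(results: Sequence[ScenarioResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "domain": r.domain,
                "scenario": f"{r.from_category} to {r.to_category}",
                "movers": r.movers,
                "paf_pct": round(100.0 * r.paf, 1),
                "group_cases": r.group_cases,
                "removals_fractional": round(r.removals_fractional, 2),
                "removals_integer": r.removals_integer,
                "arr_fractional_pct": round(r.arr_fractional_pct, 1),
                "arr_integer_pct": round(r.arr_integer_pct, 1),
            }
        )
    return pd.DataFrame(rows)


_CASE_STUDY_TEMPLATE = """CASE STUDY - {domain}

Background: a cohort member carried {from_category} adversities in the
{domain} domain in early life and reports multiple long-term conditions with
role limitation in midlife. They are one of {group_cases:.0f} such cases with a
domain adversity score of {from_category}.

Modelled interventions: under the combined, universally applied intervention
package, {movers:.0f} of those {group_cases:.0f} cases ({moved_pct:.1f}%) would have
reduced their adversity score from {from_category} to {to_category}.

Estimated outcome: the scenario's population attributable fraction of
{paf_pct:.1f}% applied to those movers projects {removals_integer:d} cases
(fractional convention {removals_fractional:.2f}) who would no longer report
multiple long-term conditions with role limitation - an absolute risk
reduction of {arr_integer_pct:.1f}% (integer convention) or
{arr_fractional_pct:.1f}% (fractional convention) within the score-{from_category}
group.
"""


def render_case_study(result: ScenarioResult) -> str:
    """Render a narrative case-study summary of one scenario projection."""
    moved_pct = 100.0 * result.movers / result.group_cases
    return _CASE_STUDY_TEMPLATE.format(
        domain=result.domain,
        from_category=result.from_category,
        to_category=result.to_category,
        group_cases=result.group_cases,
        movers=result.movers,
        moved_pct=moved_pct,
        paf_pct=100.0 * result.paf,
        removals_integer=result.removals_integer,
        removals_fractional=result.removals_fractional,
        arr_integer_pct=result.arr_integer_pct,
        arr_fractional_pct=result.arr_fractional_pct,
    )
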