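"""Derivation of adversity indicators, domain scores and the combined outcome.

Early-life variables are dichotomised into adversity indicators (1 = adversity),
summed within each of five conceptual domains, and capped at a top category of
"3+". The outcome combines a count of long-term conditions (two or more =
multimorbidity, MLTC) with SF-36 role-limitation scales: a *case* reports MLTCs
together with role limitation for a physical or emotional problem, a *control*
reports neither. Participants with only one component of the outcome are
excluded from the analytical sample so that the comparison group is clean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence, Union

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DerivationError",
    "BinaryAsIs",
    "ThresholdBelow",
    "ThresholdAbove",
    "BottomDecile",
    "AdversityRule",
    "DomainSpec",
    "CAP_LABELS",
    "GROUP_LABELS",
    "binarize_adversity",
    "cap_category",
    "domain_adversity_score",
    "derive_role_limitation",
    "derive_outcome_group",
    "derive_outcome_columns",
    "derive_domain_indicators",
    "add_domain_scores",
    "select_analytical_sample",
    "indicator_column",
    "score_column",
    "cat_column",
]


class DerivationError(ValueError):
    """Raised when a derivation rule is mis-specified or its input is invalid."""


# ---------------------------------------------------------------------------
# Adversity rules
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BinaryAsIs:
    """The variable is already a 0/1 adversity indicator."""

    kind: str = "binary_as_is"


@dataclass(frozen=True)
class ThresholdBelow:
    """Adversity when the value is strictly below an accepted cut-off."""

    cutoff: float
    units: str = ""
    kind: str = "threshold_below"


@dataclass(frozen=True)
class ThresholdAbove:
    """Adversity when the value is strictly above an accepted cut-off."""

    cutoff: float
    units: str = ""
    kind: str = "threshold_above"


@dataclass(frozen=True)
class BottomDecile:
    """Adversity for values strictly below the empirical 10th percentile.

    Used for variables with no accepted cut-off in the literature: the most
    disadvantaged tenth of the cohort is flagged.  The percentile is the
    linear-interpolation (type-7) sample percentile, and the comparison is
    strict, so ties at the cut-off are never adverse.  Different percentile
    dialects change flag counts, hence the convention is fixed here.
    """

    percentile: float = 10.0
    kind: str = "bottom_decile"


AdversityRule = Union[BinaryAsIs, ThresholdBelow, ThresholdAbove, BottomDecile]

_RULE_CLASSES = {
    "binary_as_is": BinaryAsIs,
    "threshold_below": ThresholdBelow,
    "threshold_above": ThresholdAbove,
    "bottom_decile": BottomDecile,
}


def rule_to_dict(rule: AdversityRule) -> dict:
    d = {"kind": rule.kind}
    if isinstance(rule, (ThresholdBelow, ThresholdAbove)):
        d["cutoff"] = rule.cutoff
        d["units"] = rule.units
    elif isinstance(rule, BottomDecile):
        d["percentile"] = rule.percentile
    return d


def rule_from_dict(d: dict) -> AdversityRule:
    kind = d.get("kind")
    if kind not in _RULE_CLASSES:
        raise DerivationError(f"unknown adversity rule kind: {kind!r}")
    kwargs = {k: v for k, v in d.items() if k != "kind"}
    return _RULE_CLASSES[kind](**kwargs)


@dataclass(frozen=True)
class DomainSpec:
    """One of the five early-life domains: its variables and their rules."""

    name: str
    variables: tuple  # of (variable_name, AdversityRule)

    def __post_init__(self):
        names = [v for v, _ in self.variables]
        if len(set(names)) != len(names):
            raise DerivationError(
                f"domain {self.name!r}: duplicate variable names {names}"
            )

    @property
    def variable_names(self) -> list:
        return [v for v, _ in self.variables]

    def rule_for(self, variable: str) -> AdversityRule:
        for v, rule in self.variables:
            if v == variable:
                return rule
        raise KeyError(variable)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "variables": [
                {"name": v, "rule": rule_to_dict(r)} for v, r in self.variables
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DomainSpec":
        return cls(
            name=d["name"],
            variables=tuple(
                (v["name"], rule_from_dict(v["rule"])) for v in d["variables"]
            ),
        )


# derived-column naming helpers -------------------------------------------------

def indicator_column(variable: str) -> str:
    return f"derived_adv_{variable}"


def score_column(domain: str) -> str:
    return f"derived_score_{domain}"


def cat_column(domain: str) -> str:
    return f"derived_cat_{domain}"


# ---------------------------------------------------------------------------
# Binarisation and scoring
# ---------------------------------------------------------------------------

CAP_LABELS = ("0", "1", "2", "3+")


def binarize_adversity(values, rule: AdversityRule) -> np.ndarray:
    """Dichotomise a vector into adversity indicators (1 = adversity).

    Missing values propagate to missing.  ``BottomDecile`` flags values
    strictly below the type-7 empirical percentile of the non-missing values.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        raise DerivationError("binarize_adversity expects a 1-d vector")
    if v.size == 0:
        raise DerivationError("binarize_adversity: empty vector")
    missing = np.isnan(v)
    if isinstance(rule, BinaryAsIs):
        obs = v[~missing]
        if obs.size and not np.isin(obs, (0.0, 1.0)).all():
            bad = obs[~np.isin(obs, (0.0, 1.0))][0]
            raise DerivationError(
                f"binary_as_is rule applied to non-binary value {bad!r}"
            )
        out = v.copy()
    elif isinstance(rule, ThresholdBelow):
        out = (v < rule.cutoff).astype(float)
    elif isinstance(rule, ThresholdAbove):
        out = (v > rule.cutoff).astype(float)
    elif isinstance(rule, BottomDecile):
        obs = v[~missing]
        if obs.size == 0:
            raise DerivationError("bottom_decile rule: all values missing")
        cut = np.percentile(obs, rule.percentile)  # type-7 linear interpolation
        out = (v < cut).astype(float)
    else:  # pragma: no cover - defensive
        raise DerivationError(f"unknown rule {rule!r}")
    out[missing] = np.nan
    return out


def cap_category(raw_sum) -> np.ndarray:
    """Cap a raw domain sum into the categories 0, 1, 2, 3+.

    Very high scores (4+) are sparse, so three-or-more adversities collapse
    into a single top category.  Capping an already-capped value is a no-op.
    """
    raw = np.asarray(raw_sum)
    if (raw < 0).any():
        raise DerivationError("adversity sums must be non-negative")
    capped = np.minimum(raw, 3)
    return np.array([CAP_LABELS[int(c)] for c in capped], dtype=object)


def domain_adversity_score(indicators) -> pd.DataFrame:
    """Sum a participants x indicators binary matrix into domain scores.

    Scores are only defined on complete (observed or imputed) indicators; a
    missing cell is an error directing the caller to impute first.
    """
    mat = np.asarray(indicators, dtype=float)
    if mat.ndim == 1:
        mat = mat[:, None]
    if np.isnan(mat).any():
        raise DerivationError(
            "missing adversity indicators: impute before scoring"
        )
    if not np.isin(mat, (0.0, 1.0)).all():
        raise DerivationError("adversity indicators must be 0/1")
    raw = mat.sum(axis=1).astype(int)
    return pd.DataFrame({"raw_sum": raw, "capped_category": cap_category(raw)})


def derive_domain_indicators(df: pd.DataFrame, domain_specs: Sequence[DomainSpec]) -> pd.DataFrame:
    """Append ``derived_adv_*`` indicator columns for every domain variable."""
    out = df.copy()
    for dom in domain_specs:
        for var, rule in dom.variables:
            if var not in out.columns:
                raise DerivationError(f"variable {var!r} not in table")
            out[indicator_column(var)] = binarize_adversity(out[var].to_numpy(float), rule)
    return out


def add_domain_scores(df: pd.DataFrame, domain_specs: Sequence[DomainSpec]) -> pd.DataFrame:
    """Append per-domain raw sums and capped categories from indicator columns."""
    out = df.copy()
    for dom in domain_specs:
        cols = [indicator_column(v) for v in dom.variable_names]
        missing_cols = [c for c in cols if c not in out.columns]
        if missing_cols:
            raise DerivationError(
                f"indicators not derived for domain {dom.name!r}: {missing_cols}"
            )
        scores = domain_adversity_score(out[cols].to_numpy(float))
        out[score_column(dom.name)] = scores["raw_sum"].to_numpy()
        out[cat_column(dom.name)] = scores["capped_category"].to_numpy()
    return out


# ---------------------------------------------------------------------------
# Outcome
# ---------------------------------------------------------------------------

GROUP_LABELS = ("case", "control", "excluded_role_only", "excluded_mltc_only")


def derive_role_limitation(items, expected_count: int):
    """Score one SF-36 role-limitation scale for one participant.

    The scale score is the mean of the answered binary items (1 = no
    limitation); a score of exactly 0 indicates that problems limited the
    participant.  If every item is missing the flag is missing.
    """
    arr = np.asarray(items, dtype=float)
    if arr.shape != (expected_count,):
        raise DerivationError(
            f"expected {expected_count} items, got shape {arr.shape}"
        )
    obs = arr[~np.isnan(arr)]
    if obs.size and not np.isin(obs, (0.0, 1.0)).all():
        raise DerivationError("role-limitation items must be 0/1 or missing")
    if obs.size == 0:
        return np.nan
    return bool(obs.mean() == 0.0)


def _role_limitation_vector(items: np.ndarray) -> np.ndarray:
    """Vectorised mean-of-answered scoring; returns 1/0/nan per row."""
    obs = ~np.isnan(items)
    if not np.isin(items[obs], (0.0, 1.0)).all():
        raise DerivationError("role-limitation items must be 0/1 or missing")
    n_obs = obs.sum(axis=1)
    total = np.nansum(items, axis=1)
    out = np.where(n_obs > 0, (total == 0).astype(float), np.nan)
    return out


def derive_outcome_group(ltc_flags, physical_limited, emotional_limited) -> dict:
    """Classify a single participant into one of the four outcome groups.

    Returns a dict with ``ltc_count``, the two limitation flags and ``group``
    (missing/None when the inputs do not determine it).
    """
    flags = np.asarray(ltc_flags, dtype=float)
    obs = flags[~np.isnan(flags)]
    if obs.size and not np.isin(obs, (0.0, 1.0)).all():
        raise DerivationError("long-term condition flags must be 0/1 or missing")
    n_yes = int(np.nansum(flags))
    n_miss = int(np.isnan(flags).sum())
    if n_yes >= 2:
        mltc = True
    elif n_yes + n_miss < 2:
        mltc = False
    else:
        mltc = None

    def _tri(x):
        if x is None or (isinstance(x, float) and np.isnan(x)):
            return None
        return bool(x)

    phys, emot = _tri(physical_limited), _tri(emotional_limited)
    if phys or emot:
        limited = True
    elif phys is False and emot is False:
        limited = False
    else:
        limited = None

    if mltc is None or limited is None:
        group = None
    elif mltc and limited:
        group = "case"
    elif not mltc and not limited:
        group = "control"
    elif limited:
        group = "excluded_role_only"
    else:
        group = "excluded_mltc_only"
    return {
        "ltc_count": n_yes,
        "physical_limited": phys,
        "emotional_limited": emot,
        "group": group,
    }


def derive_outcome_columns(
    df: pd.DataFrame,
    ltc_cols: Sequence[str],
    phys_cols: Sequence[str],
    emot_cols: Sequence[str],
) -> pd.DataFrame:
    """Append derived outcome columns to a cohort table.

    Adds ``derived_ltc_count``, the two limitation flags, ``derived_group``
    and ``derived_case`` (1 case, 0 control, missing for excluded groups or
    undetermined outcomes).
    """
    out = df.copy()
    ltc = out[list(ltc_cols)].to_numpy(dtype=float)
    obs = ~np.isnan(ltc)
    if not np.isin(ltc[obs], (0.0, 1.0)).all():
        raise DerivationError("long-term condition flags must be 0/1 or missing")
    n_yes = np.nansum(ltc, axis=1)
    n_miss = np.isnan(ltc).sum(axis=1)
    mltc = np.where(n_yes >= 2, 1.0, np.where(n_yes + n_miss < 2, 0.0, np.nan))

    phys = _role_limitation_vector(out[list(phys_cols)].to_numpy(dtype=float))
    emot = _role_limitation_vector(out[list(emot_cols)].to_numpy(dtype=float))
    limited = np.where(
        (phys == 1) | (emot == 1),
        1.0,
        np.where((phys == 0) & (emot == 0), 0.0, np.nan),
    )

    group = np.full(len(out), None, dtype=object)
    known = ~np.isnan(mltc) & ~np.isnan(limited)
    group[known & (mltc == 1) & (limited == 1)] = "case"
    group[known & (mltc == 0) & (limited == 0)] = "control"
    group[known & (mltc == 0) & (limited == 1)] = "excluded_role_only"
    group[known & (mltc == 1) & (limited == 0)] = "excluded_mltc_only"

    case = np.where(
        group == "case", 1.0, np.where(group == "control", 0.0, np.nan)
    )

    out["derived_ltc_count"] = n_yes.astype(int)
    out["derived_phys_limited"] = phys
    out["derived_emot_limited"] = emot
    out["derived_group"] = group
    out["derived_case"] = case
    return out


def select_analytical_sample(df: pd.DataFrame):
    """Retain cases and controls; log counts of every excluded group.

    Returns ``(kept, counts)`` where counts tallies each group plus rows whose
    outcome could not be determined.
    """
    if "derived_group" not in df.columns:
        raise DerivationError("derive the outcome before sample selection")
    group = df["derived_group"]
    counts = {label: int((group == label).sum()) for label in GROUP_LABELS}
    counts["missing"] = int(group.isna().sum())
    kept = df[group.isin(["case", "control"])].copy()
    logger.info(
        "analytical sample: %d retained (%s)",
        len(kept),
        ", ".join(f"{k}={v}" for k, v in counts.items()),
    )
    return kept, counts
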