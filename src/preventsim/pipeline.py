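"""End-to-end study orchestration: derive, impute, model, PAF, simulate.

Each stage reads the previous stage's persisted artefacts from the run
directory, so stages can be run in isolation or as one `run`.  All randomness
flows from four named seeds (cohort, imputation, intervention, bootstrap);
re-running a config byte-identically reproduces every CSV artefact.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .counterfactual import (
    TransitionTable,
    project_reduction,
    render_case_study,
    scenario_results_frame,
    table4_intervention_library,
    apply_all,
    recompute_scores,
    transition_table,
)
from .derivation import (
    cat_column,
    derive_outcome_columns,
    derive_domain_indicators,
    add_domain_scores,
    select_analytical_sample,
)
from .imputation import (
    drop_imputed_outcomes,
    impute_chained,
    load_imputation_set,
    save_imputation_set,
)
from .models import nested_domain_models
from .paf import paf_table, paf_table_frame
from .synthetic import (
    CohortSpec,
    LTC_COLUMNS,
    SF36_EMOTIONAL,
    SF36_PHYSICAL,
    default_bcs70_spec,
    export_cohort,
    generate_cohort,
    inject_missingness,
    load_cohort,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "StageError",
    "run_study",
    "validate_input_csv",
    "ValidationReport",
]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")


@dataclass
class RunConfig:
    """Configuration of a full study run."""

    output_dir: str
    input_csv: Optional[str] = None  # None -> synthetic cohort
    input_dictionary: Optional[str] = None
    cohort_spec_yaml: Optional[str] = None
    n_participants: Optional[int] = None
    m_imputations: int = 50
    cycles: int = 10
    paf_ci_method: str = "bootstrap"
    paf_bootstrap_reps: int = 200
    seed_cohort: int = 2024
    seed_imputation: int = 2025
    seed_intervention: int = 2026
    seed_bootstrap: int = 2027
    intervention_overrides: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def cohort_spec(self) -> CohortSpec:
        if self.cohort_spec_yaml is not None:
            spec = CohortSpec.from_yaml(self.cohort_spec_yaml)
        else:
            spec = default_bcs70_spec()
        if self.n_participants is not None:
            spec = dataclasses.replace(spec, n_participants=self.n_participants)
        return spec


def _analysis_columns(spec: CohortSpec) -> list:
    cols = []
    for dom in spec.domain_specs:
        cols.extend(dom.variable_names)
    cols += ["sex", "ethnicity"]
    cols += list(spec.adult_covariate_specs)
    cols += ["derived_case"]
    return cols


def _variable_models(spec: CohortSpec) -> dict:
    models = {}
    for name, vdef in spec.variable_defs.items():
        models[name] = "linear" if vdef.kind == "continuous" else "logistic"
    for name, aspec in spec.adult_covariate_specs.items():
        if aspec.kind == "ordinal":
            models[name] = "ordinal"
        elif aspec.kind == "binary":
            models[name] = "logistic"
        else:
            models[name] = "lognormal"
    models["derived_case"] = "logistic"
    return models


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_cohort(cfg: RunConfig, outdir: Path) -> None:
    """Generate or load the cohort and derive the combined outcome."""
    spec = cfg.cohort_spec()
    if cfg.input_csv is None:
        table = generate_cohort(spec, cfg.seed_cohort)
        table = inject_missingness(table, spec, cfg.seed_cohort + 1)
    else:
        report = validate_input_csv(cfg.input_csv, cfg.input_dictionary)
        if report.violations:
            raise ValueError(
                f"input CSV failed validation with {len(report.violations)} violation(s); "
                "first: " + report.violations[0]["message"]
            )
        table = load_cohort(cfg.input_csv)
    derived = derive_outcome_columns(table, LTC_COLUMNS, SF36_PHYSICAL, SF36_EMOTIONAL)
    _, counts = select_analytical_sample(derived)
    export_cohort(derived, outdir / "cohort_derived.csv", outdir / "data_dictionary.json", spec)
    spec.to_yaml(outdir / "cohort_spec.yaml")
    with open(outdir / "exclusion_counts.json", "w") as fh:
        json.dump(counts, fh, indent=1)


def imputed_analysis_tables(derived: pd.DataFrame, spec: CohortSpec, m: int, cycles: int, seed: int):
    """Impute the analysis view, delete originally-missing outcomes, and
    derive adversity scores in each completed dataset.

    Returns the :class:`ImputationSet` whose tables are the M analysis-ready
    completed datasets (cases and controls with observed outcomes only).
    """
    view = derived[_analysis_columns(spec)]
    imp = impute_chained(view, _variable_models(spec), m=m, cycles=cycles, seed=seed)
    imp = drop_imputed_outcomes(imp, ["derived_case"])
    imp.tables = [
        add_domain_scores(
            derive_domain_indicators(t, spec.domain_specs), spec.domain_specs
        )
        for t in imp.tables
    ]
    return imp


def stage_impute(cfg: RunConfig, outdir: Path) -> None:
    """Chained-equations imputation, outcome deletion, score derivation."""
    spec = CohortSpec.from_yaml(outdir / "cohort_spec.yaml")
    derived = pd.read_csv(outdir / "cohort_derived.csv")
    imp = imputed_analysis_tables(
        derived, spec, cfg.m_imputations, cfg.cycles, cfg.seed_imputation
    )
    save_imputation_set(imp, outdir / "imputation")


def stage_model(cfg: RunConfig, outdir: Path) -> None:
    """The three nested model levels, pooled across imputations."""
    imp = load_imputation_set(outdir / "imputation")
    frames = [nested_domain_models(imp.tables, level) for level in (1, 2, 3)]
    or_table = pd.concat(frames, ignore_index=True)
    or_table.to_csv(outdir / "or_table.csv", index=False)
    or_table.to_json(outdir / "or_table.json", orient="records", indent=1)


def stage_paf(cfg: RunConfig, outdir: Path) -> None:
    """Scenario PAFs for the domains significant in the fully adjusted model."""
    imp = load_imputation_set(outdir / "imputation")
    or_table = pd.read_csv(outdir / "or_table.csv")
    estimates = paf_table(
        imp.tables,
        or_table=or_table[or_table["model"] == 3],
        ci_method=cfg.paf_ci_method,
        n_boot=cfg.paf_bootstrap_reps,
        seed=cfg.seed_bootstrap,
    )
    paf_table_frame(estimates).to_csv(outdir / "paf_table.csv", index=False)
    with open(outdir / "paf_estimates.json", "w") as fh:
        json.dump(
            [
                {
                    "domain": e.scenario.domain,
                    "from": e.scenario.from_category,
                    "to": e.scenario.to_category,
                    "paf": e.paf,
                    "ci_low": e.ci_low,
                    "ci_high": e.ci_high,
                    "log_puf": e.log_puf,
                    "log_puf_variance": e.log_puf_variance,
                    "n_exposed": e.n_exposed,
                    "significant": e.significant,
                }
                for e in estimates
            ],
            fh,
            indent=1,
        )


def stage_simulate(cfg: RunConfig, outdir: Path) -> None:
    """Apply the intervention library, tabulate transitions, project ARRs."""
    spec = CohortSpec.from_yaml(outdir / "cohort_spec.yaml")
    imp = load_imputation_set(outdir / "imputation")
    with open(outdir / "paf_estimates.json") as fh:
        paf_estimates = json.load(fh)
    effects = table4_intervention_library()
    for e in effects:
        if e.target_variable in cfg.intervention_overrides:
            raise NotImplementedError("intervention overrides are not supported yet")
    pd.DataFrame([dataclasses.asdict(e) for e in effects]).to_csv(
        outdir / "intervention_library.csv", index=False
    )

    sig = [p for p in paf_estimates if p["significant"]]
    domains = sorted({p["domain"] for p in sig})
    if not domains:
        logger.info("no significant PAF scenario; nothing to simulate")
        scenario_results_frame([]).to_csv(outdir / "scenario_results.csv", index=False)
        return

    # transitions averaged over the M completed datasets; interventions are
    # re-drawn per dataset from per-dataset sub-seeds
    ss = np.random.SeedSequence(cfg.seed_intervention)
    sub_seeds = [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(imp.m)]
    sum_counts = {d: None for d in domains}
    for t, sub in zip(imp.tables, sub_seeds):
        after = recompute_scores(
            apply_all(t, effects, sub, spec.domain_specs), spec.domain_specs
        )
        cases = t["derived_case"].to_numpy(float) == 1.0
        for d in domains:
            tr = transition_table(
                t[cat_column(d)].to_numpy(object),
                after[cat_column(d)].to_numpy(object),
                cases,
                d,
            )
            sum_counts[d] = tr.counts if sum_counts[d] is None else sum_counts[d] + tr.counts
    results = []
    for d in domains:
        counts = sum_counts[d] / imp.m
        tr = TransitionTable(domain=d, counts=counts, group_sizes=counts.sum(axis=1))
        counts.to_csv(outdir / f"transitions_{d}.csv")
        for p in sig:
            if p["domain"] != d:
                continue
            movers = tr.movers(p["from"], p["to"])
            group_cases = float(tr.group_sizes[p["from"]])
            if group_cases == 0:
                continue
            results.append(
                project_reduction(
                    movers,
                    p["paf"],
                    group_cases,
                    domain=d,
                    from_category=p["from"],
                    to_category=p["to"],
                )
            )
    scenario_results_frame(results).to_csv(outdir / "scenario_results.csv", index=False)
    if results:
        best = max(results, key=lambda r: r.movers)
        (outdir / "case_study.txt").write_text(render_case_study(best))


_STAGES = (
    ("cohort", stage_cohort),
    ("impute", stage_impute),
    ("model", stage_model),
    ("paf", stage_paf),
    ("simulate", stage_simulate),
)


def run_study(cfg: RunConfig) -> Path:
    """Run every stage in order; returns the run directory.

    Stage failures propagate with the stage name; partial outputs are kept
    for debugging.
    """
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, fn in _STAGES:
        logger.info("[%s] starting", name)
        try:
            fn(cfg, outdir)
        except Exception as exc:
            raise StageError(name, exc) from exc
        logger.info("[%s] done", name)
    manifest = {
        "package_version": __version__,
        "config": cfg.to_dict(),
        "seeds": {
            "cohort": cfg.seed_cohort,
            "imputation": cfg.seed_imputation,
            "intervention": cfg.seed_intervention,
            "bootstrap": cfg.seed_bootstrap,
        },
        "artefacts": sorted(p.name for p in outdir.iterdir() if p.is_file()),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return outdir


# ---------------------------------------------------------------------------
# Input validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    violations: list

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_input_csv(path, dict_path) -> ValidationReport:
    """Check a cohort CSV against its JSON data dictionary; no mutation."""
    if dict_path is None:
        raise ValueError("a data dictionary is required to validate an input CSV")
    df = pd.read_csv(path)
    with open(dict_path) as fh:
        dictionary = json.load(fh)
    violations = []
    for col in df.columns:
        if col not in dictionary:
            violations.append(
                {"row": None, "column": col, "kind": "undeclared column",
                 "message": f"column {col!r} missing from the data dictionary"}
            )
    for col, meta in dictionary.items():
        if col not in df.columns:
            violations.append(
                {"row": None, "column": col, "kind": "missing column",
                 "message": f"declared column {col!r} absent from the CSV"}
            )
            continue
        series = df[col]
        ctype = meta.get("type")
        if ctype == "id":
            if series.duplicated().any():
                row = int(series.index[series.duplicated()][0])
                violations.append(
                    {"row": row, "column": col, "kind": "duplicate id",
                     "message": f"duplicate participant id at row {row}"}
                )
            continue
        numeric = pd.to_numeric(series, errors="coerce")
        bad_type = series.notna() & numeric.isna()
        if bad_type.any():
            row = int(series.index[bad_type][0])
            violations.append(
                {"row": row, "column": col, "kind": "non-numeric",
                 "message": f"non-numeric value in {col!r} at row {row}"}
            )
            continue
        if ctype == "binary":
            bad = series.notna() & ~numeric.isin([0, 1])
            if bad.any():
                row = int(series.index[bad][0])
                violations.append(
                    {"row": row, "column": col, "kind": "out of range",
                     "message": f"non-binary value {numeric[bad].iloc[0]!r} in {col!r} at row {row}"}
                )
        elif ctype == "ordinal" and "levels" in meta:
            bad = series.notna() & ~numeric.isin(meta["levels"])
            if bad.any():
                row = int(series.index[bad][0])
                violations.append(
                    {"row": row, "column": col, "kind": "out of range",
                     "message": f"value outside declared levels in {col!r} at row {row}"}
                )
        elif ctype == "continuous" and meta.get("units") == "g":
            bad = series.notna() & (numeric <= 0)
            if bad.any():
                row = int(series.index[bad][0])
                violations.append(
                    {"row": row, "column": col, "kind": "out of range",
                     "message": f"non-positive weight in {col!r} at row {row}"}
                )
    return ValidationReport(violations=violations)
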