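"""Run configuration, schema validation, pipeline orchestration and reports.

The pipeline runs score -> inclusion filter -> tertile/linear associations ->
mediation, reading delimited-text tables and writing tidy CSV/JSON outputs
plus a provenance manifest (config hash, pattern hash, cutpoints, seed,
package version) so a rerun with the same inputs is reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import (
    SERUM_AAS,
    ModelLadder,
    ascertain_t2dm,
    fit_linear_std,
    fit_tertile_logistic,
    food_group_trend,
    score_and_cut,
    serum_quartile_logistic,
)
from .dietary import InclusionCriteria, apply_inclusion, ffq_to_intake, load_composition
from .mediation import MediationSpec, bootstrap_mediation
from .pattern import SCORED_AAS, compute_aaci, compute_beta_ratios, load_pattern
from .simulate import SimulationConfig, simulate_cohort, simulate_ffq

# ------------------------------------------------------------- validation --

#: Column -> (required, must_be_non_negative) for the wide cohort table.
COHORT_SCHEMA: dict[str, tuple[bool, bool]] = {
    "aaci": (False, True),
    "age": (True, True),
    "sex": (True, False),
    "bmi": (True, True),
    "energy_kcal": (True, True),
    "protein_g": (True, True),
    "fiber_g": (True, True),
    "sfa_g": (True, True),
    "fasting_glucose": (False, True),
    "two_hour_glucose": (False, True),
    "hba1c": (False, True),
    **{f"serum_{aa}": (True, True) for aa in SERUM_AAS},
}


def validate_schema(table: pd.DataFrame, schema: dict[str, tuple[bool, bool]] = None) -> list[str]:
    """Return every violation (missing column, negative value) in one pass."""
    schema = schema if schema is not None else COHORT_SCHEMA
    violations: list[str] = []
    for col, (required, non_negative) in schema.items():
        if col not in table.columns:
            if required:
                violations.append(f"missing required column: {col}")
            continue
        if non_negative:
            vals = pd.to_numeric(table[col], errors="coerce")
            bad = table.index[vals < 0].tolist()
            if bad:
                violations.append(f"negative values in {col} at rows {bad[:10]}")
    return violations


# ------------------------------------------------------------ run config --


@dataclass
class RunConfig:
    """Everything one pipeline run needs, loadable from YAML."""

    out_dir: str = "aaci_run"
    pattern_path: str | None = None
    cohort_path: str | None = None  # wide cohort CSV; simulated when absent
    intake_path: str | None = None  # per-subject amino-acid intake CSV
    ffq_path: str | None = None
    composition_path: str | None = None
    seed: int = 0
    n_subjects: int = 2000
    tertile_cutpoints: tuple[float, float] | None = None
    run_mediation: bool = True
    run_associations: bool = True
    n_bootstrap: int = 200
    outcome_link: str = "probit"
    mediators: tuple[str, ...] = ("serum_valine", "serum_glutamic_acid", "serum_histidine")
    mediation_covariates: tuple[str, ...] = ("age", "sex", "bmi")
    ladder: ModelLadder = field(default_factory=ModelLadder)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        ladder = raw.pop("ladder", None)
        cfg = cls(**raw)
        if ladder is not None:
            cfg.ladder = ModelLadder(models=ladder)
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


# -------------------------------------------------------------- pipeline --


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write all stage outputs under out_dir.

    Returns the provenance manifest (also written to ``provenance.json``),
    which lists every output file produced.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}
    pattern = load_pattern(config.pattern_path)
    ratios = compute_beta_ratios(pattern)

    # --- inputs: load or simulate
    ground_truth = None
    if config.cohort_path:
        cohort = pd.read_csv(config.cohort_path)
        if config.intake_path:
            intakes = pd.read_csv(config.intake_path, index_col=0)
        elif config.ffq_path and config.composition_path:
            records = pd.read_csv(config.ffq_path)
            table = load_composition(config.composition_path)
            intakes = ffq_to_intake(records, table)
        else:
            intakes = None
    else:
        sim = SimulationConfig(n_subjects=config.n_subjects, seed=config.seed)
        cohort, truth = simulate_cohort(sim)
        ground_truth = asdict(truth)
        intakes = None

    violations = validate_schema(cohort)
    if violations:
        raise ValueError("cohort table failed validation:\n  " + "\n  ".join(violations))

    # --- score
    if intakes is not None:
        scored = compute_aaci(intakes, ratios)
        cohort = cohort.merge(
            scored[["aaci"]], left_on="subject_id", right_index=True, how="left"
        ) if "subject_id" in cohort.columns else cohort.assign(aaci=scored["aaci"].to_numpy())
    if "aaci" not in cohort.columns:
        raise ValueError("no AACI available: supply intakes/FFQ or a pre-scored cohort")

    # --- inclusion
    if "t2dm_incident" not in cohort.columns:
        cohort["t2dm_incident"] = ascertain_t2dm(cohort).astype(float)
    cohort, ledger = apply_inclusion(cohort, InclusionCriteria())
    (out / "exclusion_ledger.json").write_text(json.dumps(ledger, indent=2))
    outputs["exclusion_ledger"] = "exclusion_ledger.json"

    cohort, cuts = score_and_cut(cohort.drop(columns=["tertile"], errors="ignore"),
                                 cohort["aaci"], config.tertile_cutpoints)
    cohort.to_csv(out / "scored_cohort.csv", index=False)
    outputs["scored_cohort"] = "scored_cohort.csv"

    report_sections = [f"# AACI analysis report\n\nTertile cutpoints: {cuts[0]:.3f}, {cuts[1]:.3f}\n"]
    results: dict = {"cutpoints": cuts, "exclusions": ledger}

    # --- associations
    if config.run_associations:
        assoc = fit_tertile_logistic(cohort, config.ladder)
        rows = []
        for name, res in assoc.items():
            for _, r in res.table.iterrows():
                rows.append({"model": name, "p_trend": res.p_trend, **r})
        assoc_df = pd.DataFrame(rows)
        assoc_df.to_csv(out / "tertile_associations.csv", index=False)
        outputs["tertile_associations"] = "tertile_associations.csv"
        results["tertile"] = {
            name: {"p_trend": res.p_trend, "rr": res.table["rr"].tolist()}
            for name, res in assoc.items()
        }
        report_sections.append("## Incident T2DM by AACI tertile (odds ratios)\n\n"
                               + assoc_df.to_string(index=False) + "\n")

        serum_rows = []
        for aa in SERUM_AAS:
            col = f"serum_{aa}"
            if col not in cohort.columns:
                continue
            for model, (beta, p) in fit_linear_std(cohort, col, config.ladder).items():
                serum_rows.append({"serum_aa": aa, "model": model, "beta": beta, "p": p})
        serum_df = pd.DataFrame(serum_rows)
        serum_df.to_csv(out / "serum_associations.csv", index=False)
        outputs["serum_associations"] = "serum_associations.csv"
        report_sections.append("## Standardized AACI -> serum amino-acid betas\n\n"
                               + serum_df.pivot(index="serum_aa", columns="model", values="beta")
                               .round(4).to_string() + "\n")
        if "hba1c" in cohort.columns:
            results["hba1c"] = fit_linear_std(cohort, "hba1c", config.ladder)

    # --- mediation
    if config.run_mediation:
        spec = MediationSpec(
            exposure="aaci",
            mediators=config.mediators,
            outcome="t2dm_incident",
            covariates=config.mediation_covariates,
            n_bootstrap=config.n_bootstrap,
            seed=config.seed,
            outcome_link=config.outcome_link,
        )
        med = bootstrap_mediation(cohort, spec)
        med_payload = {
            "beta_tot": med.beta_tot,
            "direct": med.direct,
            "a_path": med.a_path,
            "b_path": med.b_path,
            "indirect": med.indirect,
            "percent_mediated": med.percent_mediated,
            "total_percent_mediated": med.total_percent_mediated,
            "p_values": med.p_values,
            "ci": med.ci,
            "n": med.n,
            "n_boot_dropped": med.n_boot_dropped,
        }
        (out / "mediation.json").write_text(json.dumps(_jsonable(med_payload), indent=2))
        outputs["mediation"] = "mediation.json"
        results["mediation"] = med_payload
        report_sections.append("## Mediation decomposition\n\n```\n" + med.summary() + "\n```\n")

    (out / "report.md").write_text("\n".join(report_sections))
    outputs["report"] = "report.md"

    provenance = {
        "package_version": __version__,
        "seed": config.seed,
        "tertile_cutpoints": list(cuts),
        "pattern": {aa: pattern.levels[aa] for aa in SCORED_AAS},
        "pattern_sha256": _sha256(Path(config.pattern_path)) if config.pattern_path else "builtin:who2007",
        "outputs": outputs,
        "ground_truth": ground_truth,
    }
    (out / "provenance.json").write_text(json.dumps(_jsonable(provenance), indent=2))
    results["provenance"] = provenance
    return results


def write_simulation(config: SimulationConfig, out_dir) -> dict[str, str]:
    """Write a simulated dataset bundle (cohort, FFQ, composition, truth)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort, truth = simulate_cohort(config)
    records, composition = simulate_ffq(config)
    cohort.to_csv(out / "cohort.csv")
    records.to_csv(out / "ffq.csv", index=False)
    composition.to_csv(out / "composition.csv", index=False)
    (out / "ground_truth.json").write_text(json.dumps(_jsonable(asdict(truth)), indent=2))
    return {
        "cohort": "cohort.csv",
        "ffq": "ffq.csv",
        "composition": "composition.csv",
        "ground_truth": "ground_truth.json",
    }
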