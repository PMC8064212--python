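"""FFQ processing: food-composition lookup, intake derivation, inclusion filters.

A food-frequency questionnaire records, per subject and food item, how often
the item is eaten (events/day) and the portion per event (g).  Daily nutrient
intakes follow by multiplying through a per-100 g food-composition table and
summing over items.  Cohort inclusion (age, energy range, diabetes-free
baseline, serum amino acids measured) is applied afterwards with a
deterministic exclusion ledger.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pattern import SCORED_AAS

#: Nutrient columns a composition table must provide per 100 g of food.
MACRO_NUTRIENTS = ("energy_kcal", "protein_g", "fiber_g", "sfa_g")
AA_MG_COLUMNS = tuple(f"{aa}_mg" for aa in SCORED_AAS)

# conversion factors for common FFQ frequency encodings -> events/day
FREQUENCY_FACTORS = {"day": 1.0, "week": 1 / 7.0, "month": 1 / 30.44}

#: Reasons, in the fixed precedence order used by :func:`apply_inclusion`.
EXCLUSION_ORDER = ("age", "energy_low", "energy_high", "baseline_diabetes", "missing_serum")


class FFQError(ValueError):
    """Invalid FFQ records or composition table."""


def frequency_per_day(value: float, unit: str = "day") -> float:
    """Normalise a frequency to events/day (units: day, week, month)."""
    try:
        return float(value) * FREQUENCY_FACTORS[unit]
    except KeyError:
        raise FFQError(f"unknown frequency unit {unit!r}; use one of {sorted(FREQUENCY_FACTORS)}")


def load_composition(path) -> pd.DataFrame:
    """Read a composition CSV (one row per food, amounts per 100 g)."""
    table = pd.read_csv(path)
    return validate_composition(table)


def validate_composition(table: pd.DataFrame) -> pd.DataFrame:
    need = ["food_id", "food_group", *MACRO_NUTRIENTS, *AA_MG_COLUMNS]
    missing = [c for c in need if c not in table.columns]
    if missing:
        raise FFQError(f"composition table missing columns: {missing}")
    numeric = table[[*MACRO_NUTRIENTS, *AA_MG_COLUMNS]].astype(float)
    if (numeric.to_numpy() < 0).any():
        bad = table.loc[(numeric < 0).any(axis=1), "food_id"].tolist()
        raise FFQError(f"negative amounts in composition table for foods: {bad}")
    if table["food_id"].duplicated().any():
        dup = table.loc[table["food_id"].duplicated(), "food_id"].tolist()
        raise FFQError(f"duplicate food_id in composition table: {dup}")
    return table


def _check_records(records: pd.DataFrame, table: pd.DataFrame) -> None:
    need = ["subject_id", "food_id", "frequency_per_day", "portion_g"]
    missing = [c for c in need if c not in records.columns]
    if missing:
        raise FFQError(f"FFQ records missing columns: {missing}")
    unknown = sorted(set(records["food_id"]) - set(table["food_id"]))
    if unknown:
        raise FFQError(f"FFQ references food ids absent from the composition table: {unknown}")
    amounts = records[["frequency_per_day", "portion_g"]].astype(float)
    if (amounts.to_numpy() < 0).any():
        raise FFQError("negative frequency or portion in FFQ records")


def ffq_to_intake(
    records: pd.DataFrame, table: pd.DataFrame, subjects=None
) -> pd.DataFrame:
    """Daily nutrient and amino-acid intakes per subject.

    intake[x] = sum over items of frequency_per_day * portion_g * per100g[x] / 100.
    Amino acids come out in mg/day, macronutrients in their per-100 g units
    (kcal/day, g/day).  Subjects listed in ``subjects`` but absent from
    ``records`` get all-zero rows.
    """
    _check_records(records, table)
    nutrient_cols = [*MACRO_NUTRIENTS, *AA_MG_COLUMNS]
    comp = table.set_index("food_id")[nutrient_cols].astype(float)
    grams = (
        records["frequency_per_day"].astype(float) * records["portion_g"].astype(float)
    ).to_numpy()
    contrib = comp.loc[records["food_id"]].to_numpy() * grams[:, None] / 100.0
    out = (
        pd.DataFrame(contrib, columns=nutrient_cols)
        .assign(subject_id=records["subject_id"].to_numpy())
        .groupby("subject_id")
        .sum()
    )
    if subjects is not None:
        out = out.reindex(pd.Index(subjects, name="subject_id"), fill_value=0.0)
    # expose plain amino-acid names for the scorer alongside the _mg columns
    out = out.rename(columns=dict(zip(AA_MG_COLUMNS, SCORED_AAS)))
    return out


def food_group_profile(
    records: pd.DataFrame, table: pd.DataFrame, subjects=None
) -> pd.DataFrame:
    """Daily g/day per food group per subject (0 for groups never eaten)."""
    _check_records(records, table)
    groups = table.set_index("food_id")["food_group"]
    df = pd.DataFrame(
        {
            "subject_id": records["subject_id"].to_numpy(),
            "food_group": groups.loc[records["food_id"]].to_numpy(),
            "g_day": (
                records["frequency_per_day"].astype(float) * records["portion_g"].astype(float)
            ).to_numpy(),
        }
    )
    wide = df.pivot_table(
        index="subject_id", columns="food_group", values="g_day", aggfunc="sum", fill_value=0.0
    )
    wide = wide.reindex(columns=sorted(groups.unique()), fill_value=0.0)
    if subjects is not None:
        wide = wide.reindex(pd.Index(subjects, name="subject_id"), fill_value=0.0)
    wide.columns.name = None
    return wide


@dataclass(frozen=True)
class InclusionCriteria:
    """Cohort inclusion rules applied at baseline."""

    age_range: tuple[float, float] = (20.0, 74.0)
    energy_range: tuple[float, float] = (500.0, 4500.0)
    require_diabetes_free_baseline: bool = True
    require_serum_aas: bool = False
    serum_columns: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        for name in ("age_range", "energy_range"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must be increasing, got {(lo, hi)}")


def apply_inclusion(
    cohort: pd.DataFrame, criteria: InclusionCriteria = InclusionCriteria()
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Filter a cohort and return it with a per-reason exclusion ledger.

    Criteria are checked in the fixed order age -> energy-low -> energy-high ->
    baseline diabetes -> missing serum amino acids, and each excluded subject
    is counted once, under the first criterion it fails, so ledgers are
    deterministic.  ``retained + sum(exclusions) == len(cohort)`` always.
    """
    for col in ("age", "energy_kcal"):
        if col not in cohort.columns:
            raise FFQError(f"inclusion filtering requires column {col!r}")
    age = cohort["age"].astype(float)
    energy = cohort["energy_kcal"].astype(float)
    lo_a, hi_a = criteria.age_range
    lo_e, hi_e = criteria.energy_range

    reasons = {
        "age": (age < lo_a) | (age > hi_a),
        "energy_low": energy < lo_e,
        "energy_high": energy > hi_e,
        "baseline_diabetes": (
            cohort.get("t2dm_baseline", pd.Series(False, index=cohort.index))
            .fillna(False)
            .astype(bool)
            if criteria.require_diabetes_free_baseline
            else pd.Series(False, index=cohort.index)
        ),
        "missing_serum": (
            cohort[list(criteria.serum_columns)].isna().any(axis=1)
            if criteria.require_serum_aas and criteria.serum_columns
            else pd.Series(False, index=cohort.index)
        ),
    }

    ledger: dict[str, int] = {}
    excluded = pd.Series(False, index=cohort.index)
    for reason in EXCLUSION_ORDER:
        hit = reasons[reason] & ~excluded
        ledger[reason] = int(hit.sum())
        excluded |= reasons[reason]
    retained = cohort.loc[~excluded].copy()
    ledger["retained"] = int(len(retained))
    return retained, ledger
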