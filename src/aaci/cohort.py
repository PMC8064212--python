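"""Cohort statistics: case ascertainment, baseline tables, association models.

The analysis ladder mirrors a standard nutritional-epidemiology workflow:

* incident type-2-diabetes ascertainment from self-report, treatment and
  OGTT glucose thresholds;
* a descriptive baseline table by exposure tertile (ANOVA / chi-square);
* logistic models of incident T2DM on exposure tertiles under nested
  covariate sets (Model 1..4), with a p-for-trend from an ordinal score;
* standardized linear models of continuous outcomes (serum amino acids,
  HbA1c) on the continuous exposure;
* quartile logistic models for single serum amino acids;
* Spearman correlation of food-group intake with the exposure.

Logistic models return exponentiated coefficients.  These are odds ratios;
the output labels them "rr" following the convention of cohort reports that
read cumulative-incidence odds ratios as relative risks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .pattern import assign_tertiles

#: The 18 serum amino acids quantified in the cohort panel (column prefix
#: ``serum_`` in cohort tables; concentrations in umol/L).
SERUM_AAS: tuple[str, ...] = (
    "threonine",
    "glutamine",
    "leucine",
    "arginine",
    "valine",
    "isoleucine",
    "serine",
    "methionine",
    "glycine",
    "alanine",
    "lysine",
    "glutamic_acid",
    "aspartic_acid",
    "tyrosine",
    "phenylalanine",
    "tryptophan",
    "proline",
    "histidine",
)

FASTING_THRESHOLD = 7.0  # mmol/L
TWO_HOUR_THRESHOLD = 11.1  # mmol/L


@dataclass(frozen=True)
class ModelLadder:
    """Nested covariate sets for the adjustment ladder (model1 c model2 c ...)."""

    models: dict[str, list[str]] = field(
        default_factory=lambda: {
            "model1": ["age", "sex"],
            "model2": ["age", "sex", "bmi", "education", "smoking", "drinking", "exercise"],
            "model3": [
                "age", "sex", "bmi", "education", "smoking", "drinking", "exercise",
                "energy_kcal", "protein_g", "fiber_g", "sfa_g", "diet_quality",
            ],
            "model4": [
                "age", "sex", "bmi", "education", "smoking", "drinking", "exercise",
                "energy_kcal", "protein_g", "fiber_g", "sfa_g", "diet_quality",
                "homa_ir", "tc", "tg", "hdl", "ldl",
            ],
        }
    )

    def __post_init__(self) -> None:
        names = list(self.models)
        for a, b in zip(names, names[1:]):
            if not set(self.models[a]) <= set(self.models[b]):
                raise ValueError(f"covariate sets must be nested: {a} not within {b}")

    def items(self):
        return self.models.items()


@dataclass
class AssociationResult:
    """Per-category ratio estimates from one categorical logistic model."""

    exposure: str
    model: str
    covariates: list[str]
    table: pd.DataFrame  # category, n, cases, rr, ci_low, ci_high, p
    p_trend: float
    n_dropped: int = 0


def ascertain_t2dm(cohort: pd.DataFrame) -> pd.Series:
    """Incident T2DM flag per subject.

    A subject is a case if any of: self-reported diagnosis, diabetes
    treatment, fasting glucose >= 7.0 mmol/L, 2-h OGTT glucose >= 11.1 mmol/L
    (both thresholds inclusive).  Missing components never qualify; a subject
    with all four components missing is indeterminate (NA, for exclusion).
    """
    n = len(cohort)

    def col(name):
        return cohort[name] if name in cohort.columns else pd.Series(np.nan, index=cohort.index)

    self_report = col("self_report_t2dm")
    treatment = col("t2dm_treatment")
    fasting = pd.to_numeric(col("fasting_glucose"), errors="coerce")
    two_hour = pd.to_numeric(col("two_hour_glucose"), errors="coerce")

    all_missing = (
        self_report.isna() & treatment.isna() & fasting.isna() & two_hour.isna()
    )
    def truthy(s: pd.Series) -> np.ndarray:
        return s.astype("boolean").fillna(False).to_numpy(dtype=bool)

    case = pd.Series(
        truthy(self_report)
        | truthy(treatment)
        | (fasting >= FASTING_THRESHOLD).to_numpy(dtype=bool)
        | (two_hour >= TWO_HOUR_THRESHOLD).to_numpy(dtype=bool),
        index=cohort.index,
    )
    flag = case.astype("boolean")
    flag[all_missing] = pd.NA
    flag.name = "t2dm_incident"
    assert len(flag) == n
    return flag


def baseline_table(
    cohort: pd.DataFrame,
    continuous: list[str],
    categorical: list[str],
    by: str = "tertile",
) -> pd.DataFrame:
    """Descriptive baseline table by exposure category.

    Continuous variables: mean (SD) per category and a one-way ANOVA p-value.
    Categorical variables: n (%) per category and a chi-square p-value.
    """
    if isinstance(cohort[by].dtype, pd.CategoricalDtype):
        labels = list(cohort[by].cat.categories)
    else:
        labels = sorted(cohort[by].dropna().unique())
    counts = cohort[by].value_counts()
    empty = [lab for lab in labels if counts.get(lab, 0) == 0]
    if empty:
        raise ValueError(f"empty exposure categories in baseline table: {empty}")
    rows = []
    for var in continuous:
        cells = {}
        samples = []
        for lab in labels:
            x = cohort.loc[cohort[by] == lab, var].dropna().astype(float)
            samples.append(x)
            cells[lab] = f"{x.mean():.2f} ({x.std(ddof=1):.2f})"
        p = stats.f_oneway(*samples).pvalue if all(len(s) > 1 for s in samples) else np.nan
        rows.append({"variable": var, "kind": "continuous", **cells, "p_value": p})
    for var in categorical:
        cells = {}
        counts = []
        for lab in labels:
            x = cohort.loc[cohort[by] == lab, var].dropna().astype(int)
            k, n = int(x.sum()), len(x)
            counts.append([k, n - k])
            cells[lab] = f"{k} ({100 * k / n:.1f}%)" if n else "0 (—)"
        tab = np.asarray(counts).T
        p = stats.chi2_contingency(tab).pvalue if (tab.sum(axis=0) > 0).all() else np.nan
        rows.append({"variable": var, "kind": "categorical", **cells, "p_value": p})
    return pd.DataFrame(rows)


def _listwise(cohort: pd.DataFrame, cols: list[str]) -> tuple[pd.DataFrame, int]:
    sub = cohort[cols].dropna()
    return cohort.loc[sub.index], len(cohort) - len(sub)


def _fit_logit(y: np.ndarray, X: pd.DataFrame):
    model = sm.Logit(y, sm.add_constant(X, has_constant="add"))
    try:
        return model.fit(disp=0, maxiter=200)
    except Exception as exc:  # pragma: no cover - statsmodels raises various types
        raise RuntimeError(f"logistic fit failed ({exc}); check for separation") from exc


def _categorical_logistic(
    cohort: pd.DataFrame,
    category_col: str,
    outcome: str,
    covariates: list[str],
    model_name: str,
    exposure_name: str,
) -> AssociationResult:
    """Shared machinery for tertile/quartile logistic association models."""
    cols = [category_col, outcome, *covariates]
    data, n_dropped = _listwise(cohort, cols)
    y = data[outcome].astype(float).to_numpy()
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError(f"outcome {outcome!r} must be binary 0/1")
    cats = sorted(data[category_col].unique())
    dummies = pd.get_dummies(data[category_col], prefix=category_col, drop_first=True).astype(float)
    X = pd.concat([dummies, data[covariates].astype(float)], axis=1)
    fit = _fit_logit(y, X)
    ci = fit.conf_int()
    rows = [
        {
            "category": cats[0],
            "n": int((data[category_col] == cats[0]).sum()),
            "cases": int(y[(data[category_col] == cats[0]).to_numpy()].sum()),
            "rr": 1.0,
            "ci_low": np.nan,
            "ci_high": np.nan,
            "p": np.nan,
        }
    ]
    for cat in cats[1:]:
        name = f"{category_col}_{cat}"
        mask = (data[category_col] == cat).to_numpy()
        k = int(y[mask].sum())
        if k == 0 or k == mask.sum():
            rows.append(
                {"category": cat, "n": int(mask.sum()), "cases": k,
                 "rr": np.nan, "ci_low": np.nan, "ci_high": np.nan, "p": np.nan}
            )
            continue
        rows.append(
            {
                "category": cat,
                "n": int(mask.sum()),
                "cases": k,
                "rr": float(np.exp(fit.params[name])),
                "ci_low": float(np.exp(ci.loc[name, 0])),
                "ci_high": float(np.exp(ci.loc[name, 1])),
                "p": float(fit.pvalues[name]),
            }
        )
    # p for trend: ordinal category score (1..k) entered as a single linear term
    score = data[category_col].map({c: i + 1 for i, c in enumerate(cats)}).astype(float)
    X_trend = pd.concat([score.rename("trend"), data[covariates].astype(float)], axis=1)
    fit_trend = _fit_logit(y, X_trend)
    return AssociationResult(
        exposure=exposure_name,
        model=model_name,
        covariates=list(covariates),
        table=pd.DataFrame(rows),
        p_trend=float(fit_trend.pvalues["trend"]),
        n_dropped=n_dropped,
    )


def fit_tertile_logistic(
    cohort: pd.DataFrame,
    ladder: ModelLadder = None,
    exposure: str = "tertile",
    outcome: str = "t2dm_incident",
) -> dict[str, AssociationResult]:
    """Tertile logistic models of incident T2DM under each ladder model.

    The lowest tertile is the reference (ratio fixed at 1); other categories
    get exponentiated coefficients with Wald 95% CIs; missing covariates are
    handled by listwise deletion with the dropped count recorded.
    """
    ladder = ladder or ModelLadder()
    return {
        name: _categorical_logistic(cohort, exposure, outcome, covs, name, exposure)
        for name, covs in ladder.items()
    }


def fit_linear_std(
    cohort: pd.DataFrame,
    outcome: str,
    ladder: ModelLadder = None,
    exposure: str = "aaci",
) -> dict[str, tuple[float, float]]:
    """Standardized beta (and two-sided p) of the exposure on a continuous outcome.

    Exposure and outcome are z-scored within the analysis sample before the
    OLS fit, so the coefficient is a fully standardized beta; covariates enter
    unstandardized (their scaling does not affect the exposure beta).
    """
    ladder = ladder or ModelLadder()
    out: dict[str, tuple[float, float]] = {}
    for name, covs in ladder.items():
        data, _ = _listwise(cohort, [exposure, outcome, *covs])
        x = data[exposure].astype(float)
        y = data[outcome].astype(float)
        if x.std(ddof=0) == 0 or y.std(ddof=0) == 0:
            raise ValueError(f"zero variance in {exposure!r} or {outcome!r}")
        z = lambda s: (s - s.mean()) / s.std(ddof=0)
        X = pd.concat([z(x).rename("exposure"), data[covs].astype(float)], axis=1)
        fit = sm.OLS(z(y).to_numpy(), sm.add_constant(X, has_constant="add")).fit()
        out[name] = (float(fit.params["exposure"]), float(fit.pvalues["exposure"]))
    return out


def serum_quartile_logistic(
    cohort: pd.DataFrame,
    aa: str,
    covariates: list[str],
    outcome: str = "t2dm_incident",
) -> AssociationResult:
    """Quartile logistic model for one serum amino acid (reference = Q1).

    Quartile cutpoints are cohort-specific sample quantiles.  The covariate
    list is the caller's; for the headline analysis it includes the dietary
    exposure (AACI) itself along with demographic, dietary and biochemical
    covariates.
    """
    col = aa if aa in cohort.columns else f"serum_{aa}"
    data = cohort.dropna(subset=[col]).copy()
    q = data[col].rank(method="average", pct=True)
    data["_quartile"] = np.select(
        [q <= 0.25, q <= 0.5, q <= 0.75], ["Q1", "Q2", "Q3"], "Q4"
    )
    return _categorical_logistic(data, "_quartile", outcome, covariates, "fig1", col)


def food_group_trend(
    cohort: pd.DataFrame, group_profile: pd.DataFrame, exposure: str = "aaci"
) -> pd.DataFrame:
    """Spearman correlation of each food group's intake with the exposure.

    Also reports mean g/day per exposure tertile so the direction of the
    trend can be read off.  Constant group intakes give NA correlations.
    """
    merged = group_profile.join(cohort.set_index(cohort.index)[[exposure]], how="inner")
    if "tertile" in cohort.columns:
        merged = merged.join(cohort["tertile"])
        tertiles = sorted(merged["tertile"].dropna().unique())
    else:
        tertiles = []
    rows = []
    for group in group_profile.columns:
        x = merged[group].astype(float)
        if x.nunique() <= 1:
            rho, p = np.nan, np.nan
        else:
            rho, p = stats.spearmanr(x, merged[exposure])
        row = {"food_group": group, "spearman_rho": rho, "p_value": p}
        for t in tertiles:
            row[f"mean_{t}"] = float(x[merged["tertile"] == t].mean())
        rows.append(row)
    return pd.DataFrame(rows)


def score_and_cut(
    cohort: pd.DataFrame, aaci: pd.Series, cutpoints=None
) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Attach an AACI column and its tertile labels to a cohort table."""
    out = cohort.copy()
    out["aaci"] = aaci
    labels, cuts = assign_tertiles(out["aaci"], cutpoints)
    out["tertile"] = labels
    return out, cuts
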