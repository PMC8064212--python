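"""Amino-acid composition index (AACI) against a human-requirement pattern.

The AACI measures how far a diet's essential-amino-acid composition departs
from a reference requirement pattern (HRAAP, the WHO 2007 adult pattern by
default).  Composition is expressed as the ratio of each amino acid to
tryptophan, so the index is invariant to the overall amount eaten and to the
intake unit, and depends only on the *mix* of amino acids:

    beta_i = pattern_i / pattern_trp                       (reference ratios)
    q_i    = | (intake_i / intake_trp) / beta_i  -  1 |    (satisfaction score)
    AACI   = sum over the 11 scored amino acids of q_i

A perfectly HRAAP-proportional diet scores 0; larger values mean worse
adherence.  Tryptophan is one of the 11 scored amino acids but its own term
is identically 0 (its ratio to itself is 1 and its beta is 1), so it
contributes nothing to the sum.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The 11 scored amino acids: nine essential plus the two conditionally
#: essential (cysteine, tyrosine).  Tryptophan is the ratio denominator and
#: is listed among them; its satisfaction term is identically zero.
SCORED_AAS: tuple[str, ...] = (
    "isoleucine",
    "leucine",
    "lysine",
    "methionine",
    "phenylalanine",
    "threonine",
    "valine",
    "histidine",
    "tryptophan",
    "cysteine",
    "tyrosine",
)

TRYPTOPHAN = "tryptophan"

TERTILE_LABELS = ("T1", "T2", "T3")


class PatternError(ValueError):
    """Invalid reference pattern (missing amino acid or non-positive level)."""


class IntakeError(ValueError):
    """Invalid intake profile (non-positive tryptophan, negative intake)."""


@dataclass(frozen=True)
class HRAAPPattern:
    """Reference requirement level per amino acid, in any consistent unit.

    Only ratios between levels enter the index, so mg/g protein, mg/kg body
    weight per day, or any other consistent unit all give the same AACI.
    """

    levels: dict[str, float]
    scored_aas: tuple[str, ...] = field(default=SCORED_AAS)

    def __post_init__(self) -> None:
        if TRYPTOPHAN not in self.levels:
            raise PatternError("reference pattern must include tryptophan")
        for aa in self.scored_aas:
            level = self.levels.get(aa)
            if level is None:
                raise PatternError(f"reference pattern missing amino acid: {aa}")
            if not np.isfinite(level) or level <= 0:
                raise PatternError(f"non-positive reference level for {aa}: {level}")


@dataclass(frozen=True)
class BetaRatios:
    """Reference-pattern amino-acid levels expressed as ratios to tryptophan."""

    ratios: dict[str, float]

    def __post_init__(self) -> None:
        if abs(self.ratios.get(TRYPTOPHAN, np.nan) - 1.0) > 1e-12:
            raise PatternError("tryptophan beta-ratio must equal 1")
        for aa, r in self.ratios.items():
            if not np.isfinite(r) or r <= 0:
                raise PatternError(f"non-positive beta-ratio for {aa}: {r}")


def load_pattern(path=None) -> HRAAPPattern:
    """Load a reference pattern from a 2-column ``amino_acid,level`` CSV.

    With no ``path`` the packaged WHO 2007 adult pattern is returned.
    Amino-acid names are matched case-insensitively.
    """
    if path is None:
        ref = importlib.resources.files("aaci").joinpath("data/hraap_who2007.csv")
        with importlib.resources.as_file(ref) as p:
            table = pd.read_csv(p)
    else:
        table = pd.read_csv(path)
    expected = {"amino_acid", "level"}
    if not expected.issubset(table.columns):
        raise PatternError(f"pattern file needs columns {sorted(expected)}, got {list(table.columns)}")
    names = table["amino_acid"].astype(str).str.strip().str.lower()
    unknown = sorted(set(names) - set(SCORED_AAS))
    if unknown:
        raise PatternError(f"unrecognised amino acids in pattern file: {unknown}")
    levels = dict(zip(names, table["level"].astype(float)))
    return HRAAPPattern(levels=levels)


def compute_beta_ratios(pattern: HRAAPPattern) -> BetaRatios:
    """Ratio of each scored amino acid's requirement level to tryptophan's."""
    trp = pattern.levels[TRYPTOPHAN]
    return BetaRatios({aa: pattern.levels[aa] / trp for aa in pattern.scored_aas})


def _intake_matrix(intakes: pd.DataFrame) -> pd.DataFrame:
    missing = [aa for aa in SCORED_AAS if aa not in intakes.columns]
    if missing:
        raise IntakeError(f"intake table missing amino-acid columns: {missing}")
    aa = intakes[list(SCORED_AAS)].astype(float)
    if (aa.to_numpy() < 0).any():
        bad = intakes.index[(aa < 0).any(axis=1)].tolist()
        raise IntakeError(f"negative amino-acid intakes for subjects: {bad[:10]}")
    trp = aa[TRYPTOPHAN].to_numpy()
    if (trp <= 0).any() or not np.isfinite(trp).all():
        bad = intakes.index[(aa[TRYPTOPHAN] <= 0) | ~np.isfinite(aa[TRYPTOPHAN])].tolist()
        raise IntakeError(
            f"tryptophan intake must be strictly positive; offending subjects: {bad[:10]}"
        )
    return aa


def compute_satisfaction(intakes: pd.DataFrame, ratios: BetaRatios) -> pd.DataFrame:
    """Per-amino-acid satisfaction scores q_i for each subject.

    Parameters
    ----------
    intakes
        One row per subject (index = subject id), one column per scored amino
        acid, all in the same intake unit.  Extra columns are ignored.
    ratios
        Reference ratios from :func:`compute_beta_ratios`.

    Returns
    -------
    DataFrame of q_i scores, columns in :data:`SCORED_AAS` order.  Both
    deficiency and excess relative to the pattern score positive; the
    tryptophan column is exactly 0.
    """
    aa = _intake_matrix(intakes)
    trp = aa[TRYPTOPHAN].to_numpy()[:, None]
    beta = np.array([ratios.ratios[a] for a in SCORED_AAS])
    q = np.abs((aa.to_numpy() / trp) / beta - 1.0)
    q[:, list(SCORED_AAS).index(TRYPTOPHAN)] = 0.0  # identically zero by construction
    return pd.DataFrame(q, index=intakes.index, columns=list(SCORED_AAS))


def compute_aaci(intakes: pd.DataFrame, ratios: BetaRatios) -> pd.DataFrame:
    """Score subjects: satisfaction terms plus their sum, the AACI.

    Returns a DataFrame with one ``q_<aa>`` column per scored amino acid and
    an ``aaci`` column (the sum over all 11 terms, tryptophan's zero term
    included).  Lower AACI means closer adherence to the reference pattern.
    """
    q = compute_satisfaction(intakes, ratios)
    out = q.add_prefix("q_")
    out["aaci"] = q.to_numpy().sum(axis=1)
    return out


def assign_tertiles(
    values, cutpoints: tuple[float, float] | None = None
) -> tuple[pd.Series, tuple[float, float]]:
    """Split a continuous exposure into tertiles T1/T2/T3.

    Without explicit ``cutpoints`` the empirical 33.3%/66.7% quantiles
    (linear interpolation) are used.  Intervals are half-open with closed
    upper bounds — (-inf, c1], (c1, c2], (c2, inf) — so a value tied with a
    cutpoint falls in the lower category, matching the conventional
    "<c1 / c1–c2 / >c2" labelling.  Returns the labels and the cutpoints
    actually used, for run metadata.
    """
    v = pd.Series(values).astype(float)
    if cutpoints is None:
        if v.nunique() < 3:
            raise ValueError("need at least 3 distinct values to form tertiles")
        c1, c2 = np.quantile(v.to_numpy(), [1 / 3, 2 / 3])
        # values identical up to floating jitter are degenerate too
        if np.isclose(c1, c2, rtol=1e-9, atol=1e-12):
            raise ValueError("degenerate tertiles: 33.3% and 66.7% quantiles coincide")
    else:
        c1, c2 = map(float, cutpoints)
        if not c1 < c2:
            raise ValueError(f"cutpoints must be increasing, got {cutpoints}")
    labels = pd.Series(
        np.select([v <= c1, v <= c2], [TERTILE_LABELS[0], TERTILE_LABELS[1]], TERTILE_LABELS[2]),
        index=v.index,
        name="tertile",
    )
    return labels, (float(c1), float(c2))
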