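"""GOLD grading/grouping and rule-based treatable-trait annotation.

Cut-offs follow the instrument conventions in the source rule set: inclusive
``>=`` at lower bounds and strict ``<`` at upper bounds. Two traits carry dual
cut-offs (disease impact: CAT >= 10 and >= 18; health-related quality of life:
SGRQ >= 25 and >= 46). A trait evaluated on a missing input is reported as
not-evaluable (None) rather than absent: absence is a clinical claim.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping
import math
import warnings

import pandas as pd


class InstrumentRangeError(ValueError):
    """An instrument score outside its valid range."""


def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value))


def _check_range(name: str, value: float, lower: float, upper: float) -> None:
    if not (lower <= value <= upper):
        raise InstrumentRangeError(
            f"{name} score {value} outside valid range [{lower}, {upper}]"
        )


def gold_grade(fev1_pct: float) -> int:
    """Spirometric airflow-limitation grade from FEV1 % predicted:
    1 if >= 80; 2 if [50, 80); 3 if [30, 50); 4 if < 30."""
    if fev1_pct <= 0:
        raise InstrumentRangeError(f"FEV1 %predicted must be positive, got {fev1_pct}")
    if fev1_pct >= 80:
        return 1
    if fev1_pct >= 50:
        return 2
    if fev1_pct >= 30:
        return 3
    return 4


def obstruction_category(fev1_pct: float) -> str:
    """Airflow-obstruction trait label; the four categories partition (0, inf)."""
    return {1: "mild", 2: "moderate", 3: "severe", 4: "very severe"}[gold_grade(fev1_pct)]


def high_exacerbation_risk(exacerbations: float, hospitalisations: float) -> bool:
    """Frequent-exacerbation predicate, shared by the trait and the GOLD
    group split: >= 2 exacerbations or >= 1 hospitalisation in the past year."""
    if exacerbations < 0 or hospitalisations < 0:
        raise InstrumentRangeError("event counts must be >= 0")
    return exacerbations >= 2 or hospitalisations >= 1


def gold_group(exacerbations: float, hospitalisations: float, cat: float) -> str:
    """ABCD group: risk from exacerbation history, symptoms from CAT >= 10.

    A = low risk / low symptoms, B = low/high, C = high/low, D = high/high.
    """
    _check_range("CAT", cat, 0, 40)
    risk = high_exacerbation_risk(exacerbations, hospitalisations)
    symptomatic = cat >= 10
    if risk:
        return "D" if symptomatic else "C"
    return "B" if symptomatic else "A"


def cci_band(score: float) -> str:
    """Charlson Comorbidity Index band: mild 1-2, moderate 3-4, severe >= 5.

    A score of 0 sits below the published bands and is reported as mild with a
    warning.
    """
    if score < 0:
        raise InstrumentRangeError(f"CCI must be >= 0, got {score}")
    if score < 1:
        warnings.warn("CCI 0 is below the banded range; reported as mild", stacklevel=2)
        return "mild"
    if score <= 2:
        return "mild"
    if score <= 4:
        return "moderate"
    return "severe"


def cat_impact_band(score: float) -> str:
    """CAT impact band: <= 10 low, 11-20 medium, 21-30 high, 31-40 very high."""
    _check_range("CAT", score, 0, 40)
    if score <= 10:
        return "low"
    if score <= 20:
        return "medium"
    if score <= 30:
        return "high"
    return "very high"


@dataclass(frozen=True)
class TraitRule:
    """One treatable-trait predicate over a participant record."""

    name: str
    domain: str  # pulmonary | physical | symptoms-health-status | behavioural
    variables: tuple[str, ...]
    description: str

    def evaluate(self, record: Mapping):
        raise NotImplementedError


#: trait name -> (domain, required variables, predicate, range checks)
_RANGES = {
    "cat": (0, 40),
    "mmrc": (0, 4),
    "hads_a": (0, 21),
    "hads_d": (0, 21),
    "sgrq_total": (0, 100),
    "bpaat": (0, 8),
}

TRAIT_DEFINITIONS: dict[str, tuple[str, tuple[str, ...]]] = {
    "frequent_exacerbations": ("pulmonary", ("exacerbations", "hospitalisations")),
    "poor_nutritional_status": ("physical", ("bmi",)),
    "lower_limb_muscle_dysfunction": ("physical", ("qms_pct",)),
    "low_functional_status": ("physical", ("sts_pct",)),
    "activity_related_dyspnoea": ("symptoms-health-status", ("mmrc",)),
    "disease_impact_cat10": ("symptoms-health-status", ("cat",)),
    "disease_impact_cat18": ("symptoms-health-status", ("cat",)),
    "anxiety": ("symptoms-health-status", ("hads_a",)),
    "depression": ("symptoms-health-status", ("hads_d",)),
    "hrqol_impairment_sgrq25": ("symptoms-health-status", ("sgrq_total",)),
    "hrqol_impairment_sgrq46": ("symptoms-health-status", ("sgrq_total",)),
    "current_smoking": ("behavioural", ("smoking_status",)),
    "physical_inactivity": ("behavioural", ("bpaat",)),
}

#: Binary trait columns emitted by :func:`annotate_traits` (the airflow
#: obstruction category is categorical and handled separately).
TRAIT_NAMES: list[str] = list(TRAIT_DEFINITIONS)


_TRAIT_PREDICATES = {
    "frequent_exacerbations": lambda r: high_exacerbation_risk(
        r["exacerbations"], r["hospitalisations"]
    ),
    "poor_nutritional_status": lambda r: r["bmi"] < 21 or r["bmi"] > 30,
    "lower_limb_muscle_dysfunction": lambda r: r["qms_pct"] < 70,
    "low_functional_status": lambda r: r["sts_pct"] < 70,
    "activity_related_dyspnoea": lambda r: r["mmrc"] >= 2,
    "disease_impact_cat10": lambda r: r["cat"] >= 10,
    "disease_impact_cat18": lambda r: r["cat"] >= 18,
    "anxiety": lambda r: r["hads_a"] >= 8,
    "depression": lambda r: r["hads_d"] >= 8,
    "hrqol_impairment_sgrq25": lambda r: r["sgrq_total"] >= 25,
    "hrqol_impairment_sgrq46": lambda r: r["sgrq_total"] >= 46,
    "current_smoking": lambda r: r["smoking_status"] == "current",
    "physical_inactivity": lambda r: r["bpaat"] <= 3,
}


def annotate_traits(record: Mapping) -> dict:
    """Annotate one participant record with all treatable traits and bands.

    Returns a mapping with one boolean (or None = not-evaluable) entry per
    trait plus the airflow-obstruction category, GOLD grade/group, CCI band
    and CAT impact band. Out-of-range scores raise an error naming the
    instrument; missing inputs make the dependent traits not-evaluable.
    """
    for name, (lower, upper) in _RANGES.items():
        value = record.get(name)
        if not _is_missing(value):
            _check_range(name.upper(), value, lower, upper)

    out: dict = {}
    fev1 = record.get("fev1_pct")
    out["airflow_obstruction"] = None if _is_missing(fev1) else obstruction_category(fev1)
    out["gold_grade"] = None if _is_missing(fev1) else gold_grade(fev1)

    group_inputs = [record.get(v) for v in ("exacerbations", "hospitalisations", "cat")]
    out["gold_group"] = (
        None if any(_is_missing(v) for v in group_inputs) else gold_group(*group_inputs)
    )
    cci = record.get("cci")
    out["cci_band"] = None if _is_missing(cci) else cci_band(cci)
    cat = record.get("cat")
    out["cat_impact_band"] = None if _is_missing(cat) else cat_impact_band(cat)

    for trait, (_, variables) in TRAIT_DEFINITIONS.items():
        if any(_is_missing(record.get(v)) for v in variables):
            out[trait] = None
        else:
            out[trait] = bool(_TRAIT_PREDICATES[trait](record))
    return out


def annotate_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Trait table for a cohort: one row per participant-timepoint."""
    rows = [annotate_traits(rec) for rec in cohort.to_dict("records")]
    traits = pd.DataFrame(rows)
    keys = [c for c in ("participant_id", "timepoint") if c in cohort.columns]
    return pd.concat([cohort[keys].reset_index(drop=True), traits], axis=1)


def trait_prevalence(cohort: pd.DataFrame, assignments: pd.DataFrame) -> pd.DataFrame:
    """Per-profile trait prevalence among evaluable participants.

    Returns a long table (trait x profile) with the evaluable denominator,
    the count with the trait present and the percentage. Empty profiles are
    reported with n = 0 and an undefined (NaN) percentage.
    """
    traits = annotate_cohort(cohort)
    merged = traits.merge(
        assignments[["participant_id", "profile"]], on="participant_id", how="left"
    )
    profiles = sorted(assignments["profile"].unique())
    records = []
    for trait in TRAIT_NAMES:
        for profile in profiles:
            cell = merged.loc[merged["profile"] == profile, trait]
            evaluable = cell.notna().sum()
            present = int(cell.fillna(False).astype(bool).sum())
            records.append(
                {
                    "trait": trait,
                    "profile": profile,
                    "n_evaluable": int(evaluable),
                    "n_present": present,
                    "percentage": (100.0 * present / evaluable) if evaluable else float("nan"),
                }
            )
    return pd.DataFrame(records)
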