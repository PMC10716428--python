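"""Clinical variable catalog for the CKD progression pipeline.

Four categories of EHR variables are modeled: demographics, vital
information, lab tests, and health behaviors.  A subset of them (the
*essential* set) covers all demographics and vitals, the eight most
frequently measured labs, and the three primary behavior indicators.
"""

from __future__ import annotations

from dataclasses import dataclass

DEMOGRAPHICS = "demographics"
VITAL = "vital"
LAB = "lab"
BEHAVIOR = "behavior"

CATEGORIES = (DEMOGRAPHICS, VITAL, LAB, BEHAVIOR)

#: Time feature appended to every assembled feature vector.
TIME_FEATURE = "time"


@dataclass(frozen=True)
class Variable:
    """One catalog entry.

    Parameters
    ----------
    name : str
        Snake-case variable name used in observation tables and feature
        matrices.
    category : str
        One of :data:`CATEGORIES`.
    essential : bool
        Whether the variable belongs to the essential set.
    """

    name: str
    category: str
    essential: bool = False

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")


DEFAULT_CATALOG: tuple[Variable, ...] = (
    # demographics (static; all essential)
    Variable("sex", DEMOGRAPHICS, True),
    Variable("race", DEMOGRAPHICS, True),
    # vital information (all essential)
    Variable("systolic_bp", VITAL, True),
    Variable("diastolic_bp", VITAL, True),
    Variable("bmi", VITAL, True),
    Variable("oxygen_saturation", VITAL, True),
    Variable("height", VITAL, True),
    Variable("weight", VITAL, True),
    # lab tests (the eight most frequent are essential)
    Variable("albumin", LAB, True),
    Variable("blood_urea_nitrogen", LAB, True),
    Variable("calcium", LAB, True),
    Variable("creatinine", LAB, True),
    Variable("ferritin", LAB),
    Variable("hba1c", LAB),
    Variable("hgb", LAB, True),
    Variable("cholesterol", LAB),
    Variable("ldl", LAB),
    Variable("hdl", LAB),
    Variable("parathyroid_hormone", LAB),
    Variable("phosphorous", LAB, True),
    Variable("saturation", LAB),
    Variable("triglycerides", LAB),
    Variable("uric_acid", LAB),
    Variable("urine_creatinine", LAB),
    Variable("urine_micro_albumin", LAB),
    Variable("urine_protein", LAB),
    Variable("urine_rbc_count", LAB),
    Variable("vitamin_d25", LAB),
    Variable("bicarbs_co2", LAB, True),
    Variable("egfr", LAB, True),
    # health behaviors (primary usage indicators are essential)
    Variable("illegal_drug_use", BEHAVIOR, True),
    Variable("injection_use", BEHAVIOR),
    Variable("iv_use", BEHAVIOR),
    Variable("pill_use", BEHAVIOR),
    Variable("marijuana_use", BEHAVIOR),
    Variable("alcohol_use", BEHAVIOR, True),
    Variable("smoking_status", BEHAVIOR, True),
    Variable("cigarette_use", BEHAVIOR),
    Variable("cigar_use", BEHAVIOR),
    Variable("tobacco_use", BEHAVIOR),
)

#: Integer codes used for behavior variables in observation tables.
BEHAVIOR_CODES = {0: "no", 1: "yes"}

#: Integer codes for static demographic fields.
SEX_CODES = {0: "female", 1: "male"}
RACE_CODES = {0: "african_american", 1: "white", 2: "others"}


def catalog_names(
    catalog: tuple[Variable, ...] = DEFAULT_CATALOG,
    *,
    categories: tuple[str, ...] | None = None,
    essential_only: bool = False,
) -> list[str]:
    """Return variable names filtered by category and essential flag."""
    out = []
    for v in catalog:
        if categories is not None and v.category not in categories:
            continue
        if essential_only and not v.essential:
            continue
        out.append(v.name)
    return out


def by_name(catalog: tuple[Variable, ...] = DEFAULT_CATALOG) -> dict[str, Variable]:
    return {v.name: v for v in catalog}
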