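"""Cohort construction: inclusion criteria, stratification, transactions.

A patient enters the analysis cohort iff, over the study window, they are
45 or older, have at least one valid BMI measurement (18.5-206 inclusive),
carry an assigned race/ethnicity from the final category list, have at
least one ICD-10-CM diagnosis record, and have *no* ICD-9-CM record (a
mixed-vintage chart cannot be aggregated reliably).  Included patients are
assigned to a (race, age-band, obesity-class) stratum and their in-window
diagnoses are collapsed to a set of eligible parental categories — one
"transaction" per patient for the frequent-itemset miner.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from datetime import date
from typing import Iterable, Mapping, NamedTuple

import numpy as np
import pandas as pd

from .icd import ChapterFilter, default_filter, try_normalize

logger = logging.getLogger(__name__)

__all__ = [
    "DiagnosisRecord",
    "PatientProfile",
    "StratumKey",
    "TransactionSet",
    "FINAL_RACES",
    "EXCLUDED",
    "DEFAULT_WINDOW",
    "map_race",
    "apply_inclusion",
    "assign_stratum",
    "build_cohort",
    "build_transactions",
    "cohort_summary",
    "exclusion_counts",
]

# Age / BMI thresholds (inclusive boundaries throughout).
MIN_AGE = 45
ELDERLY_AGE = 65
BMI_MIN = 18.5
BMI_MAX = 206.0
OBESITY_CUTOFF = 30.0

MIDDLE_AGED = "middle_aged"
ELDERLY = "elderly"
WITH_OBESITY = "with_obesity"
WITHOUT_OBESITY = "without_obesity"
AGE_BANDS = (MIDDLE_AGED, ELDERLY)
OBESITY_CLASSES = (WITHOUT_OBESITY, WITH_OBESITY)

#: Final race/ethnicity analysis categories.
FINAL_RACES: tuple[str, ...] = (
    "African American",
    "Asian/Pacific Islander",
    "Biracial",
    "Caucasian",
    "Hispanic",
    "Native American",
)

#: Sentinel for source labels that are deliberately dropped from analysis.
EXCLUDED = "excluded"

#: Two-year aggregation window.
DEFAULT_WINDOW: tuple[date, date] = (date(2016, 1, 1), date(2017, 12, 31))

# Source label -> final category.  Asian, Pacific Islander and the combined
# label merge into one category (the source system cannot separate them);
# missing/other/uninterpretable labels are excluded outright.
DEFAULT_RACE_MAP: dict[str, str] = {
    "African American": "African American",
    "Asian": "Asian/Pacific Islander",
    "Pacific Islander": "Asian/Pacific Islander",
    "Asian/Pacific Islander": "Asian/Pacific Islander",
    "Biracial": "Biracial",
    "Caucasian": "Caucasian",
    "Hispanic": "Hispanic",
    "Native American": "Native American",
    "": EXCLUDED,
    "Other": EXCLUDED,
    "Mid-Eastern Indian": EXCLUDED,
}

# Canonical exclusion-reason codes.
REASON_AGE = "age"
REASON_BMI = "bmi"
REASON_RACE = "race"
REASON_NO_ICD10 = "no_icd10"
REASON_ICD9 = "icd9"
ALL_REASONS = (REASON_AGE, REASON_BMI, REASON_RACE, REASON_NO_ICD10, REASON_ICD9)


class UnknownRaceLabelError(KeyError):
    """Raised in strict mode for a source race label absent from the mapping."""


def map_race(
    label: object,
    table: Mapping[str, str] | None = None,
    *,
    strict: bool = True,
) -> str:
    """Map a source race/ethnicity label to a final analysis category.

    Returns a final category or :data:`EXCLUDED`.  Unrecognized labels
    raise :class:`UnknownRaceLabelError` when ``strict`` (the default);
    otherwise they are logged and excluded.
    """
    table = DEFAULT_RACE_MAP if table is None else table
    if label is None or (isinstance(label, float) and np.isnan(label)):
        label = ""
    key = str(label).strip()
    if key in table:
        return table[key]
    if strict:
        raise UnknownRaceLabelError(key)
    logger.warning("unrecognized race/ethnicity label %r -> excluded", key)
    return EXCLUDED


class StratumKey(NamedTuple):
    race: str
    age_band: str
    obesity_class: str


@dataclass(frozen=True)
class DiagnosisRecord:
    """One patient-encounter-code row from the raw diagnosis table."""

    patient_id: str
    encounter_id: str
    date: date
    code: str
    code_system: str = "ICD10"

    @property
    def is_icd9(self) -> bool:
        return "9" in _norm_system(self.code_system)

    @property
    def is_icd10(self) -> bool:
        return "10" in _norm_system(self.code_system)


def _norm_system(label: object) -> str:
    return str(label).upper().replace("-", "").replace(" ", "")


@dataclass(frozen=True)
class PatientProfile:
    """Demographics plus derived inclusion flags and stratum assignment."""

    patient_id: str
    race_raw: str
    race: str
    age_years: int
    bmi_values: tuple[float, ...] = ()
    mean_bmi: float | None = None
    included: bool = False
    exclusion_reasons: tuple[str, ...] = ()
    age_band: str | None = None
    obesity_class: str | None = None


def valid_bmi_mean(values: Iterable[float]) -> float | None:
    """Unweighted mean of BMI values inside [18.5, 206]; None when none valid."""
    valid = [v for v in values if BMI_MIN <= v <= BMI_MAX]
    return float(np.mean(valid)) if valid else None


def _inclusion_reasons(
    age_years: int,
    bmi_values: Iterable[float],
    race: str,
    has_icd10: bool,
    has_icd9: bool,
) -> tuple[str, ...]:
    """All failed criteria (never short-circuited)."""
    reasons = []
    if age_years < MIN_AGE:
        reasons.append(REASON_AGE)
    if valid_bmi_mean(bmi_values) is None:
        reasons.append(REASON_BMI)
    if race not in FINAL_RACES:
        reasons.append(REASON_RACE)
    if not has_icd10:
        reasons.append(REASON_NO_ICD10)
    if has_icd9:
        reasons.append(REASON_ICD9)
    return tuple(reasons)


def apply_inclusion(
    profile: PatientProfile,
    records: Iterable[DiagnosisRecord],
    window: tuple[date, date] = DEFAULT_WINDOW,
) -> PatientProfile:
    """Evaluate every inclusion criterion for one patient.

    Exclusion is a result, not an error: the returned profile carries the
    full set of failed criteria, and the derived fields (mean BMI, age
    band, obesity class) are populated for included patients.
    """
    lo, hi = window
    in_window = [r for r in records if lo <= r.date <= hi]
    has_icd10 = any(r.is_icd10 for r in in_window)
    has_icd9 = any(r.is_icd9 for r in in_window)
    reasons = _inclusion_reasons(
        profile.age_years, profile.bmi_values, profile.race, has_icd10, has_icd9
    )
    mean_bmi = valid_bmi_mean(profile.bmi_values)
    included = not reasons
    prof = replace(
        profile,
        mean_bmi=mean_bmi,
        included=included,
        exclusion_reasons=reasons,
    )
    if included:
        key = assign_stratum(prof)
        prof = replace(prof, age_band=key.age_band, obesity_class=key.obesity_class)
    return prof


def assign_stratum(profile: PatientProfile) -> StratumKey:
    """Stratum of an included patient: 45-64 vs 65+, mean BMI >= 30 vs < 30."""
    if not profile.included:
        raise ValueError("assign_stratum requires an included profile")
    if profile.mean_bmi is None:
        raise ValueError("profile has no valid BMI")
    age_band = ELDERLY if profile.age_years >= ELDERLY_AGE else MIDDLE_AGED
    obesity = WITH_OBESITY if profile.mean_bmi >= OBESITY_CUTOFF else WITHOUT_OBESITY
    return StratumKey(profile.race, age_band, obesity)


@dataclass(frozen=True)
class TransactionSet:
    """Per-stratum patient -> set-of-categories mapping with denominator."""

    stratum: StratumKey
    transactions: Mapping[str, frozenset[str]]
    n_patients: int

    def __post_init__(self) -> None:
        non_empty = sum(1 for t in self.transactions.values() if t)
        if self.n_patients < non_empty:
            raise ValueError("n_patients smaller than non-empty transaction count")


# ---------------------------------------------------------------------------
# Bulk (DataFrame) path
# ---------------------------------------------------------------------------

def _window_mask(dates: pd.Series, window: tuple[date, date]) -> pd.Series:
    d = pd.to_datetime(dates).dt.date
    return (d >= window[0]) & (d <= window[1])


def build_cohort(
    demographics: pd.DataFrame,
    diagnoses: pd.DataFrame,
    *,
    window: tuple[date, date] = DEFAULT_WINDOW,
    race_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Apply the inclusion criteria to whole tables at once.

    Parameters
    ----------
    demographics
        Columns ``patient_id``, ``race``, ``age``, ``bmi``; multiple rows
        per patient are allowed (one per BMI measurement).
    diagnoses
        Columns ``patient_id``, ``encounter_id``, ``date`` (ISO-8601),
        ``code``, ``code_system``.

    Returns
    -------
    DataFrame indexed by ``patient_id`` with race, age, BMI summary,
    ``included`` flag, the tuple of exclusion reasons, and for included
    patients the age band and obesity class.
    """
    demo = demographics.copy()
    demo["race"] = demo["race"].fillna("")
    grouped = demo.groupby("patient_id", sort=True)
    race_raw = grouped["race"].first()
    age = grouped["age"].first().astype(int)

    bmi = demo[["patient_id", "bmi"]].dropna(subset=["bmi"])
    valid = bmi[(bmi["bmi"] >= BMI_MIN) & (bmi["bmi"] <= BMI_MAX)]
    mean_bmi = valid.groupby("patient_id")["bmi"].mean()
    n_bmi = bmi.groupby("patient_id")["bmi"].size()

    mapped = race_raw.map(lambda v: map_race(v, race_map, strict=False))

    in_win = _window_mask(diagnoses["date"], window)
    systems = diagnoses["code_system"].map(_norm_system)
    icd10_pids = set(diagnoses.loc[in_win & systems.str.contains("10"), "patient_id"])
    icd9_pids = set(diagnoses.loc[in_win & systems.str.contains("9") & ~systems.str.contains("10"), "patient_id"])

    out = pd.DataFrame(
        {
            "race_raw": race_raw,
            "race": mapped,
            "age_years": age,
            "n_bmi": n_bmi.reindex(race_raw.index, fill_value=0).astype(int),
            "mean_bmi": mean_bmi.reindex(race_raw.index),
        }
    )
    out["has_icd10"] = out.index.isin(icd10_pids)
    out["has_icd9"] = out.index.isin(icd9_pids)

    fail_age = out["age_years"] < MIN_AGE
    fail_bmi = out["mean_bmi"].isna()
    fail_race = ~out["race"].isin(FINAL_RACES)
    fail_dx = ~out["has_icd10"]
    fail_icd9 = out["has_icd9"]

    def _reasons(i: int) -> tuple[str, ...]:
        r = []
        if fail_age.iat[i]:
            r.append(REASON_AGE)
        if fail_bmi.iat[i]:
            r.append(REASON_BMI)
        if fail_race.iat[i]:
            r.append(REASON_RACE)
        if fail_dx.iat[i]:
            r.append(REASON_NO_ICD10)
        if fail_icd9.iat[i]:
            r.append(REASON_ICD9)
        return tuple(r)

    any_fail = (fail_age | fail_bmi | fail_race | fail_dx | fail_icd9).to_numpy()
    out["exclusion_reasons"] = [
        _reasons(i) if any_fail[i] else () for i in range(len(out))
    ]
    out["included"] = ~any_fail
    out["age_band"] = np.where(
        out["included"],
        np.where(out["age_years"] >= ELDERLY_AGE, ELDERLY, MIDDLE_AGED),
        None,
    )
    out["obesity_class"] = np.where(
        out["included"],
        np.where(out["mean_bmi"] >= OBESITY_CUTOFF, WITH_OBESITY, WITHOUT_OBESITY),
        None,
    )
    n_inc = int(out["included"].sum())
    logger.info("cohort: %d/%d patients included", n_inc, len(out))
    return out


def exclusion_counts(cohort: pd.DataFrame) -> dict[str, int]:
    """Patients failing each criterion (a patient may count under several)."""
    counts = {r: 0 for r in ALL_REASONS}
    for reasons in cohort.loc[~cohort["included"], "exclusion_reasons"]:
        for r in reasons:
            counts[r] += 1
    return counts


def build_transactions(
    cohort: pd.DataFrame,
    diagnoses: pd.DataFrame,
    chapter_filter: ChapterFilter | None = None,
    *,
    window: tuple[date, date] = DEFAULT_WINDOW,
    drop_empty: bool = False,
) -> dict[StratumKey, TransactionSet]:
    """Collapse in-window ICD-10 diagnoses to per-patient category sets.

    Every included patient appears in exactly one stratum.  Patients whose
    codes all fall outside the chapter filter keep an empty transaction and
    still count in the denominator unless ``drop_empty`` is set.
    Malformed codes are logged, never silently discarded.
    """
    chapter_filter = chapter_filter or default_filter()
    included = cohort[cohort["included"]]
    if included.empty:
        logger.warning("empty cohort: no included patients")
        return {}

    in_win = _window_mask(diagnoses["date"], window)
    systems = diagnoses["code_system"].map(_norm_system)
    dx = diagnoses.loc[in_win & systems.str.contains("10"), ["patient_id", "code"]]
    dx = dx[dx["patient_id"].isin(set(included.index))]

    # Normalize per unique raw string (the raw vocabulary is small).
    uniq = dx["code"].unique()
    cat_map: dict[str, str | None] = {}
    malformed: list[str] = []
    for raw in uniq:
        code = try_normalize(raw)
        if code is None:
            malformed.append(str(raw))
            cat_map[raw] = None
        else:
            cat_map[raw] = code.category if code.category in chapter_filter else None
    if malformed:
        logger.warning(
            "%d malformed diagnosis codes dropped from transactions: %s%s",
            len(malformed),
            malformed[:5],
            "..." if len(malformed) > 5 else "",
        )

    dx = dx.assign(category=dx["code"].map(cat_map)).dropna(subset=["category"])
    per_patient = dx.groupby("patient_id")["category"].agg(frozenset)

    out: dict[StratumKey, TransactionSet] = {}
    keys = included.groupby(["race", "age_band", "obesity_class"], sort=True)
    for (race, band, obesity), group in keys:
        txns = {
            pid: per_patient.get(pid, frozenset()) for pid in sorted(group.index)
        }
        if drop_empty:
            txns = {pid: items for pid, items in txns.items() if items}
        key = StratumKey(race, band, obesity)
        out[key] = TransactionSet(stratum=key, transactions=txns, n_patients=len(txns))
    return out


def cohort_summary(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-stratum patient counts with share of the age-band cohort."""
    inc = cohort[cohort["included"]]
    rows = []
    for (band, race, obesity), grp in inc.groupby(
        ["age_band", "race", "obesity_class"], sort=True
    ):
        n_band = int((inc["age_band"] == band).sum())
        rows.append(
            {
                "age_band": band,
                "race": race,
                "obesity_class": obesity,
                "n_patients": len(grp),
                "pct_of_age_cohort": round(100.0 * len(grp) / n_band, 2),
            }
        )
    return pd.DataFrame(rows)
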