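"""Baseline covariates over the 12 months before index.

Charlson Comorbidity Index (CCI) from ICD-10 diagnoses (Quan mapping, original
Charlson weights, age points: one per decade of age from 50, capped at 4), plus
hospitalization count, distinct GP contacts and sick-leave days.  The condition
mapping is an editable table ``(condition, icd10_prefixes, weight)``; pass a
custom table to :func:`compute_cci` to switch variants.

All covariates use the strict half-open baseline window ``[index - 365 d, index)``:
nothing dated on or after the index date may leak in.  Inpatient diagnoses count
regardless of qualifier; outpatient diagnoses only when confirmed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .claims import ClaimsDataset, quarter_key

__all__ = [
    "CHARLSON_TABLE",
    "CHARLSON_HIERARCHY",
    "compute_cci",
    "age_points",
    "baseline_utilization",
    "compute_baseline_covariates",
    "BASELINE_DAYS",
]

BASELINE_DAYS = 365

# Quan et al. ICD-10 coding algorithm with the original Charlson weights.
# Prefixes are matched dotless: a diagnosis matches a condition if its
# dot-stripped code starts with any listed prefix.
CHARLSON_TABLE: tuple[tuple[str, tuple[str, ...], int], ...] = (
    ("myocardial_infarction", ("I21", "I22", "I252"), 1),
    ("congestive_heart_failure",
     ("I099", "I110", "I130", "I132", "I255", "I420", "I425", "I426", "I427",
      "I428", "I429", "I43", "I50", "P290"), 1),
    ("peripheral_vascular",
     ("I70", "I71", "I731", "I738", "I739", "I771", "I790", "I792", "K551",
      "K558", "K559", "Z958", "Z959"), 1),
    ("cerebrovascular",
     ("G45", "G46", "H340", "I60", "I61", "I62", "I63", "I64", "I65", "I66",
      "I67", "I68", "I69"), 1),
    ("dementia", ("F00", "F01", "F02", "F03", "F051", "G30", "G311"), 1),
    ("chronic_pulmonary",
     ("I278", "I279", "J40", "J41", "J42", "J43", "J44", "J45", "J46", "J47",
      "J60", "J61", "J62", "J63", "J64", "J65", "J66", "J67", "J684", "J701",
      "J703"), 1),
    ("rheumatic",
     ("M05", "M06", "M315", "M32", "M33", "M34", "M351", "M353", "M360"), 1),
    ("peptic_ulcer", ("K25", "K26", "K27", "K28"), 1),
    ("mild_liver",
     ("B18", "K700", "K701", "K702", "K703", "K709", "K713", "K714", "K715",
      "K717", "K73", "K74", "K760", "K762", "K763", "K764", "K768", "K769",
      "Z944"), 1),
    ("diabetes_uncomplicated",
     ("E100", "E101", "E106", "E108", "E109", "E110", "E111", "E116", "E118",
      "E119", "E120", "E121", "E126", "E128", "E129", "E130", "E131", "E136",
      "E138", "E139", "E140", "E141", "E146", "E148", "E149"), 1),
    ("diabetes_complicated",
     ("E102", "E103", "E104", "E105", "E107", "E112", "E113", "E114", "E115",
      "E117", "E122", "E123", "E124", "E125", "E127", "E132", "E133", "E134",
      "E135", "E137", "E142", "E143", "E144", "E145", "E147"), 2),
    ("hemiplegia",
     ("G041", "G114", "G801", "G802", "G81", "G82", "G830", "G831", "G832",
      "G833", "G834", "G839"), 2),
    ("renal",
     ("I120", "I131", "N032", "N033", "N034", "N035", "N036", "N037", "N052",
      "N053", "N054", "N055", "N056", "N057", "N18", "N19", "N250", "Z490",
      "Z491", "Z492", "Z940", "Z992"), 2),
    ("any_malignancy",
     tuple(f"C{i:02d}" for i in list(range(0, 27)) + list(range(30, 35))
           + list(range(37, 42)) + [43] + list(range(45, 59))
           + list(range(60, 77)) + list(range(81, 86)) + [88]
           + list(range(90, 98))), 2),
    ("moderate_severe_liver",
     ("I850", "I859", "I864", "I982", "K704", "K711", "K721", "K729", "K765",
      "K766", "K767"), 3),
    ("metastatic_solid_tumor", ("C77", "C78", "C79", "C80"), 6),
    ("aids", ("B20", "B21", "B22", "B24"), 6),
)

#: higher-weight condition supersedes the milder one when both are present
CHARLSON_HIERARCHY: tuple[tuple[str, str], ...] = (
    ("metastatic_solid_tumor", "any_malignancy"),
    ("moderate_severe_liver", "mild_liver"),
    ("diabetes_complicated", "diabetes_uncomplicated"),
)


def age_points(age: float) -> int:
    """Age adjustment: 1 point per decade from age 50, capped at 4 (age >= 80)."""
    return int(np.clip(int(age) // 10 - 4, 0, 4))


def compute_cci(codes: Iterable[str], age: float,
                table: Sequence[tuple[str, tuple[str, ...], int]] = CHARLSON_TABLE,
                hierarchy: Sequence[tuple[str, str]] = CHARLSON_HIERARCHY) -> int:
    """Age-adjusted Charlson score for one patient's baseline diagnosis codes."""
    flat = {str(c).replace(".", "").upper() for c in codes}
    present = set()
    for condition, prefixes, _w in table:
        if any(code.startswith(prefixes) for code in flat):
            present.add(condition)
    for severe, mild in hierarchy:
        if severe in present:
            present.discard(mild)
    weights = {cond: w for cond, _p, w in table}
    return sum(weights[c] for c in present) + age_points(age)


def _condition_matrix(codes: pd.DataFrame,
                      table: Sequence[tuple[str, tuple[str, ...], int]]) -> pd.DataFrame:
    """Person x condition indicator matrix from a (person_id, code) frame."""
    flat = codes["code"].str.replace(".", "", regex=False).str.upper()
    out = {}
    for condition, prefixes, _w in table:
        hit = flat.str.startswith(prefixes)
        out[condition] = codes.loc[hit, "person_id"].unique()
    persons = codes["person_id"].unique()
    mat = pd.DataFrame(False, index=pd.Index(persons, name="person_id"),
                       columns=[c for c, _p, _w in table])
    for condition, hit_persons in out.items():
        mat.loc[mat.index.isin(hit_persons), condition] = True
    return mat


def cci_scores(diagnoses: pd.DataFrame, ages: pd.Series,
               table: Sequence[tuple[str, tuple[str, ...], int]] = CHARLSON_TABLE,
               hierarchy: Sequence[tuple[str, str]] = CHARLSON_HIERARCHY) -> pd.Series:
    """Vectorized CCI for many persons.

    ``diagnoses``: frame with person_id and code, already restricted to the
    baseline window and qualifying settings.  ``ages``: age at index indexed by
    person_id (defines the output index; persons without codes score age points
    only).
    """
    result = pd.Series(0, index=ages.index, dtype=int)
    if len(diagnoses):
        mat = _condition_matrix(diagnoses[["person_id", "code"]], table)
        for severe, mild in hierarchy:
            mat.loc[mat[severe], mild] = False
        weights = np.array([w for _c, _p, w in table])
        scores = (mat.to_numpy() @ weights).astype(int)
        result = result.add(pd.Series(scores, index=mat.index), fill_value=0)
    age_pts = ages.fillna(0).astype(int).floordiv(10).sub(4).clip(0, 4)
    return (result.reindex(ages.index).fillna(0) + age_pts).astype(int)


@dataclass
class BaselineWindow:
    """Half-open per-person window [index - days, index)."""
    index_dates: pd.Series  # indexed by person_id
    days: int = BASELINE_DAYS

    def mask(self, events: pd.DataFrame, date_col: str = "date") -> pd.Series:
        idx = events["person_id"].map(self.index_dates)
        lo = idx - pd.to_timedelta(self.days, unit="D")
        return (events[date_col] >= lo) & (events[date_col] < idx)


def baseline_utilization(ds: ClaimsDataset, index_dates: pd.Series,
                         days: int = BASELINE_DAYS) -> pd.DataFrame:
    """Counts over the baseline window, indexed by person_id.

    * ``n_hospitalizations`` — admissions with admission date in the window
      (an admission before the window that straddles its start does not count).
    * ``n_gp_visits`` — distinct billed (physician, quarter) GP contacts;
      quarterly billing hides repeat visits to the same physician.
    * ``sick_leave_days`` — summed days from the sick-leave stream.
    """
    win = BaselineWindow(index_dates, days)
    out = pd.DataFrame(index=index_dates.index)

    hosp = ds.costs[ds.costs["category"] == "hospitalization"]
    if len(hosp):
        m = win.mask(hosp, "admission_date")
        out["n_hospitalizations"] = hosp.loc[m].groupby("person_id").size()
    visits = ds.costs[(ds.costs["category"] == "outpatient_visit")
                      & (ds.costs["physician_role"] == "gp")]
    if len(visits):
        v = visits.loc[win.mask(visits)]
        if len(v):
            q = quarter_key(v["date"])
            uniq = v.assign(q=q).drop_duplicates(["person_id", "physician_id", "q"])
            out["n_gp_visits"] = uniq.groupby("person_id").size()
    sl = ds.sick_leave
    if len(sl):
        s = sl.loc[win.mask(sl)]
        out["sick_leave_days"] = s.groupby("person_id")["days"].sum()
    for col in ("n_hospitalizations", "n_gp_visits", "sick_leave_days"):
        if col not in out:
            out[col] = 0
    return out.fillna(0).astype(int)


def compute_baseline_covariates(ds: ClaimsDataset, cohort: pd.DataFrame,
                                days: int = BASELINE_DAYS) -> pd.DataFrame:
    """Forced-covariate table (age, sex, CCI, utilization) for a cohort.

    ``cohort`` needs columns person_id, index_date, age_at_index, sex.
    Returns one row per cohort person.
    """
    index_dates = cohort.set_index("person_id")["index_date"]
    win = BaselineWindow(index_dates, days)
    dx = ds.diagnoses[ds.diagnoses["person_id"].isin(index_dates.index)]
    qualifying = dx[(dx["setting"] == "inpatient") | (dx["qualifier"] == "confirmed")]
    qualifying = qualifying.loc[win.mask(qualifying)]
    ages = cohort.set_index("person_id")["age_at_index"]
    cov = baseline_utilization(ds, index_dates, days)
    cov["cci"] = cci_scores(qualifying, ages)
    cov["age_at_index"] = ages
    cov["female"] = (cohort.set_index("person_id")["sex"] == "female").astype(int)
    return cov.reset_index().rename(columns={"index": "person_id"})
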