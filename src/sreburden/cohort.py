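"""Cohort construction: incident bone-metastasis cases, SRE/non-SRE groups,
index dates and the attrition table.

Eligibility chain (new-user / incident design on claims):

1. Incident bone metastasis (BM, ICD-10 C79.5): at least one inpatient or two
   confirmed outpatient diagnoses in two *different calendar quarters* inside
   the inclusion window, with no BM diagnosis at all before the inclusion
   window (washout year).  The incident date is the inpatient date or the
   first of the two confirming outpatient diagnoses, whichever is earlier.
2. A solid-tumor diagnosis (C00–C76, inpatient or confirmed outpatient) within
   12 months before to 3 months after the incident BM date.
3. Age >= 18 at the BM date.
4. One continuous enrollment interval covering the year before BM through the
   person's data end (death or end of data), abutting intervals merged.
5. Skeletal-related events (SRE) are detected from configured diagnosis and
   procedure codes between the BM date and the inclusion end; the first SRE is
   the index date of the SRE group.  Non-SRE patients receive a random index:
   BM date plus an offset resampled from the SRE group's BM-to-index offsets.
6. Bone-targeting-agent (BTA) naivety: any BTA dispensing before BM, or
   between BM and the index date, excludes the person.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .claims import (ClaimsDataset, CodeListConfig, StudyWindow, quarter_key)

__all__ = [
    "find_incident_bm",
    "confirm_solid_tumor",
    "detect_sres",
    "first_sre_table",
    "assign_random_index",
    "apply_bta_naive_filter",
    "classify_st_type",
    "build_cohorts",
    "ATTRITION_STAGES",
]

ATTRITION_STAGES = (
    "persons_in_dataset",
    "incident_bm_in_inclusion_window",
    "solid_tumor_confirmed",
    "age_18_at_bm",
    "continuous_enrollment_12m_pre_bm",
    "no_bta_before_bm",
    "index_date_assigned",
    "no_bta_between_bm_and_index",
    "final_cohort",
)

DAYS_PER_YEAR = 365.25


def _bm_evidence(ds: ClaimsDataset) -> pd.DataFrame:
    """BM-coded diagnoses that can ever count as evidence."""
    dx = ds.diagnoses
    bm = dx[ds.config.is_bm(dx["code"])]
    ok = (bm["setting"] == "inpatient") | (bm["qualifier"] == "confirmed")
    return bm[ok]


def find_incident_bm(ds: ClaimsDataset, window: StudyWindow | None = None) -> pd.DataFrame:
    """Incident BM date per person, or no row if the person does not qualify.

    Returns a frame (person_id, bm_date).  The outpatient route requires two
    confirmed diagnoses in two different calendar quarters with no constraint
    on their gap; the qualifying date is the first of the pair.  Any BM-coded
    evidence before the inclusion window start disqualifies (prevalent case).
    """
    window = window or StudyWindow()
    bm = _bm_evidence(ds)
    if bm.empty:
        return pd.DataFrame(columns=["person_id", "bm_date"])
    prevalent = set(bm.loc[bm["date"] < window.inclusion_start, "person_id"])

    inp = bm[bm["setting"] == "inpatient"].groupby("person_id")["date"].min()

    out = bm[bm["setting"] == "outpatient"].copy()
    out_route = pd.Series(dtype="datetime64[ns]")
    if len(out):
        out["q"] = quarter_key(out["date"])
        g = out.groupby("person_id")
        nq = g["q"].nunique()
        multi = nq[nq >= 2].index
        out_route = out[out["person_id"].isin(multi)].groupby("person_id")["date"].min()

    cand = pd.concat([inp, out_route], axis=1, keys=["inp", "out"]).min(axis=1)
    cand = cand[(cand >= window.inclusion_start) & (cand <= window.inclusion_end)]
    cand = cand[~cand.index.isin(prevalent)]
    return cand.rename("bm_date").rename_axis("person_id").reset_index()


def confirm_solid_tumor(ds: ClaimsDataset, bm_dates: pd.Series,
                        window_before_months: int = 12,
                        window_after_months: int = 3) -> tuple[pd.Index, pd.DataFrame]:
    """Solid-tumor confirmation around the BM date.

    ``bm_dates``: Series of BM dates indexed by person_id.  Returns the index
    of persons with at least one qualifying C00–C76 diagnosis in
    ``[bm - 12 months, bm + 3 months]`` together with the full qualifying ST
    diagnosis history (person_id, date, code) for later subtype classification.
    """
    dx = ds.diagnoses[ds.diagnoses["person_id"].isin(bm_dates.index)]
    st = dx[ds.config.is_st(dx["code"])]
    st = st[(st["setting"] == "inpatient") | (st["qualifier"] == "confirmed")]
    if st.empty:
        return pd.Index([]), pd.DataFrame(columns=["person_id", "date", "code"])
    bm = st["person_id"].map(bm_dates)
    lo = bm - pd.DateOffset(months=window_before_months)
    hi = bm + pd.DateOffset(months=window_after_months)
    hist = st.loc[(st["date"] >= lo) & (st["date"] <= hi),
                  ["person_id", "date", "code"]].reset_index(drop=True)
    return pd.Index(hist["person_id"].unique()), hist


def detect_sres(ds: ClaimsDataset, bm_dates: pd.Series,
                window: StudyWindow | None = None,
                end: pd.Timestamp | None = None) -> pd.DataFrame:
    """SRE events per person between the BM date and ``end``.

    SREs are recognised from configured diagnosis codes (inpatient any,
    outpatient confirmed) and procedure codes, matched by prefix.  ``end``
    defaults to the inclusion end, which is the group-assignment horizon; pass
    the data end to enumerate later SREs for censoring.  Returns
    (person_id, date, sre_type) with one row per event/type.
    """
    window = window or StudyWindow()
    end = end if end is not None else window.inclusion_end
    frames = []
    dx = ds.diagnoses[ds.diagnoses["person_id"].isin(bm_dates.index)]
    dx = dx[(dx["setting"] == "inpatient") | (dx["qualifier"] == "confirmed")]
    flat = dx["code"].astype(str).str.replace(".", "", regex=False)
    for sre_type, prefixes in ds.config.sre_diagnosis_map().items():
        if not prefixes:
            continue
        pre = tuple(p.replace(".", "") for p in prefixes)
        hit = dx[flat.str.startswith(pre)]
        frames.append(hit[["person_id", "date"]].assign(sre_type=sre_type))
    pr = ds.procedures[ds.procedures["person_id"].isin(bm_dates.index)]
    for sre_type, prefixes in ds.config.sre_procedure_map().items():
        if not prefixes:
            continue
        hit = pr[pr["code"].astype(str).str.startswith(tuple(prefixes))]
        frames.append(hit[["person_id", "date"]].assign(sre_type=sre_type))
    if not frames:
        return pd.DataFrame(columns=["person_id", "date", "sre_type"])
    ev = pd.concat(frames, ignore_index=True)
    bm = ev["person_id"].map(bm_dates)
    ev = ev[(ev["date"] >= bm) & (ev["date"] <= end)]
    return (ev.drop_duplicates(["person_id", "date", "sre_type"])
              .sort_values(["person_id", "date"]).reset_index(drop=True))


def first_sre_table(sre_events: pd.DataFrame) -> pd.DataFrame:
    """First SRE date and type per person; same-day multiple types -> ``multiple``."""
    if sre_events.empty:
        return pd.DataFrame(columns=["person_id", "index_date", "sre_type"])
    first_date = sre_events.groupby("person_id")["date"].min()
    at_first = sre_events[sre_events["date"] == sre_events["person_id"].map(first_date)]
    types = at_first.groupby("person_id")["sre_type"].agg(
        lambda s: s.iloc[0] if s.nunique() == 1 else "multiple")
    return pd.DataFrame({"index_date": first_date, "sre_type": types}).reset_index()


def assign_random_index(non_sre: pd.DataFrame, offsets_days: np.ndarray,
                        seed: int, max_attempts: int = 100) -> pd.Series:
    """Random index dates for the non-SRE group.

    Each person draws ``bm_date + offset`` with the offset resampled with
    replacement from the SRE group's BM-to-index offsets, redrawing up to
    ``max_attempts`` times until the date falls inside
    ``[bm_date, person data end]``.  Persons with no feasible draw get NaT
    (they are excluded and counted in attrition).

    ``non_sre`` needs columns person_id, bm_date, person_end.
    """
    offsets_days = np.asarray(offsets_days, dtype=np.int64)
    if offsets_days.size == 0:
        raise ValueError("empty SRE offset pool: cannot assign random index dates")
    rng = np.random.default_rng(seed)
    bm = non_sre["bm_date"].to_numpy()
    end = non_sre["person_end"].to_numpy()
    assigned = np.full(len(non_sre), np.datetime64("NaT"), dtype="datetime64[ns]")
    pending = np.arange(len(non_sre))
    for _ in range(max_attempts):
        if pending.size == 0:
            break
        draw = rng.choice(offsets_days, size=pending.size, replace=True)
        cand = bm[pending] + draw.astype("timedelta64[D]")
        ok = cand <= end[pending]
        assigned[pending[ok]] = cand[ok]
        pending = pending[~ok]
    return pd.Series(assigned, index=non_sre["person_id"].to_numpy(), name="index_date")


def apply_bta_naive_filter(ds: ClaimsDataset, frame: pd.DataFrame) -> pd.Series:
    """BTA-naivety decision per person: keep / bta_pre_bm / bta_bm_to_index.

    ``frame`` needs columns person_id, bm_date, index_date.  A dispensing of a
    bone-targeting agent strictly before the BM date triggers ``bta_pre_bm``;
    one on/after BM but strictly before the index date triggers
    ``bta_bm_to_index``.  A BTA on or after the index date is kept — it later
    censors follow-up instead.
    """
    disp = ds.dispensings
    bta = disp[ds.config.is_bta(disp["atc_code"])]
    first_bta = bta.groupby("person_id")["date"].min()
    f = frame.set_index("person_id")
    d = f.index.map(first_bta)
    reason = pd.Series("keep", index=f.index)
    has = pd.notna(d)
    pre = has & (d < f["bm_date"])
    mid = has & ~pre & (d < f["index_date"])
    reason[pre] = "bta_pre_bm"
    reason[mid] = "bta_bm_to_index"
    return reason


def classify_st_type(st_history: pd.DataFrame, index_dates: pd.Series,
                     named_groups: tuple[str, ...]) -> pd.Series:
    """Solid-tumor subtype per person from the latest ST code at/before index.

    The subtype is the named 3-character group (e.g. C34 lung, C61 prostate) of
    the latest dated solid-tumor code on or before the index date.  If the
    latest date carries codes from two or more different named groups, or only
    codes outside the named groups, the person is classified ``other``.
    """
    out = pd.Series("other", index=index_dates.index, dtype=object)
    if st_history.empty:
        return out
    h = st_history.copy()
    h["index_date"] = h["person_id"].map(index_dates)
    h = h[h["date"] <= h["index_date"]]
    if h.empty:
        return out
    latest = h.groupby("person_id")["date"].max()
    at_latest = h[h["date"] == h["person_id"].map(latest)].copy()
    at_latest["grp"] = at_latest["code"].str[:3]
    at_latest = at_latest[at_latest["grp"].isin(named_groups)]
    named = at_latest.groupby("person_id")["grp"].agg(
        lambda s: s.iloc[0] if s.nunique() == 1 else "other")
    out.loc[named.index.intersection(out.index)] = named
    return out


def _age_at(dates: pd.Series, births: pd.Series) -> pd.Series:
    if len(dates) == 0:
        return pd.Series(dtype="Int64", index=dates.index)
    return ((pd.to_datetime(dates) - pd.to_datetime(births)).dt.days
            / DAYS_PER_YEAR).pipe(np.floor).astype("Int64")


@dataclass
class CohortResult:
    cohort: pd.DataFrame
    attrition: pd.DataFrame
    sre_events: pd.DataFrame  # all detected SREs up to inclusion end


def build_cohorts(ds: ClaimsDataset, window: StudyWindow | None = None,
                  seed: int = 0) -> CohortResult:
    """Run the full eligibility chain and return cohorts plus attrition.

    The cohort frame has one row per eligible person: person_id, bm_date,
    group (SRE/non_SRE), index_date, sre_type, st_type, age_at_index, sex.
    The attrition table lists (criterion, n_remaining), non-increasing.
    """
    window = window or StudyWindow()
    attrition: list[tuple[str, int]] = []
    attrition.append(("persons_in_dataset", len(ds.persons)))

    bm = find_incident_bm(ds, window)
    attrition.append(("incident_bm_in_inclusion_window", len(bm)))
    bm_dates = bm.set_index("person_id")["bm_date"]

    st_persons, st_history = confirm_solid_tumor(ds, bm_dates)
    bm = bm[bm["person_id"].isin(st_persons)]
    attrition.append(("solid_tumor_confirmed", len(bm)))

    persons = ds.persons.set_index("person_id")
    bm = bm.merge(persons[["birth_date", "sex", "death_date"]],
                  left_on="person_id", right_index=True).reset_index(drop=True)
    for col in ("bm_date", "birth_date", "death_date"):
        bm[col] = pd.to_datetime(bm[col])
    age_at_bm = _age_at(bm["bm_date"], bm["birth_date"])
    bm = bm[age_at_bm >= 18]
    attrition.append(("age_18_at_bm", len(bm)))

    # one merged interval must cover [bm - 12 months, min(death, data_end)]
    bm["person_end"] = bm["death_date"].fillna(window.data_end).clip(upper=window.data_end)
    need_start = bm["bm_date"] - pd.DateOffset(months=12)
    enr = ds.enrollment.merge(
        bm[["person_id", "person_end"]].assign(need_start=need_start.to_numpy()),
        on="person_id")
    covered = enr[(enr["start_date"] <= enr["need_start"])
                  & (enr["end_date"] >= enr["person_end"])]["person_id"].unique()
    bm = bm[bm["person_id"].isin(covered)]
    attrition.append(("continuous_enrollment_12m_pre_bm", len(bm)))

    # BTA strictly before BM (rule i) — checked before index assignment so the
    # SRE offset pool already reflects the BTA-naive-at-BM population
    disp = ds.dispensings
    bta = disp[ds.config.is_bta(disp["atc_code"])]
    first_bta = bta.groupby("person_id")["date"].min()
    fb = bm["person_id"].map(first_bta)
    bm = bm[~(pd.notna(fb) & (fb.to_numpy() < bm["bm_date"].to_numpy()))]
    attrition.append(("no_bta_before_bm", len(bm)))

    bm_dates = bm.set_index("person_id")["bm_date"]
    sre_events = detect_sres(ds, bm_dates, window)
    first_sre = first_sre_table(sre_events)

    sre_rows = bm.merge(first_sre, on="person_id")
    sre_rows["index_date"] = pd.to_datetime(sre_rows["index_date"])
    sre_rows["group"] = "SRE"
    offsets = (sre_rows["index_date"] - sre_rows["bm_date"]).dt.days.to_numpy()

    non = bm[~bm["person_id"].isin(first_sre["person_id"])].copy()
    if len(non):
        if offsets.size == 0:
            raise ValueError("no SRE patients: cannot build the random-index pool")
        idx = assign_random_index(non, offsets, seed)
        non["index_date"] = non["person_id"].map(idx)
        non = non[non["index_date"].notna()]
    else:
        non["index_date"] = pd.NaT
    non["group"] = "non_SRE"
    non["sre_type"] = pd.NA

    cohort = pd.concat([sre_rows, non], ignore_index=True)
    cohort["index_date"] = pd.to_datetime(cohort["index_date"])
    attrition.append(("index_date_assigned", len(cohort)))

    reason = apply_bta_naive_filter(ds, cohort)
    keep = reason[reason == "keep"].index
    cohort = cohort[cohort["person_id"].isin(keep)]
    attrition.append(("no_bta_between_bm_and_index", len(cohort)))

    index_dates = cohort.set_index("person_id")["index_date"]
    cohort["st_type"] = classify_st_type(
        st_history, index_dates, tuple(ds.config.st_subgroup_codes)).reindex(
        cohort["person_id"]).to_numpy()
    cohort["age_at_index"] = _age_at(cohort["index_date"], cohort["birth_date"])
    attrition.append(("final_cohort", len(cohort)))

    cohort = cohort[["person_id", "bm_date", "group", "index_date", "sre_type",
                     "st_type", "age_at_index", "sex", "death_date",
                     "person_end"]].reset_index(drop=True)
    att = pd.DataFrame(attrition, columns=["criterion", "n_remaining"])
    return CohortResult(cohort=cohort, attrition=att, sre_events=sre_events)
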