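"""Follow-up, per-patient-year (ppy) outcome aggregation and rate ratios.

Follow-up runs from the index date until the first of: death, initiation of a
bone-targeting agent (BTA), a later SRE (non-SRE group only) or the end of
data.  All outcomes are pooled group totals divided by pooled person-years —
never a mean of per-person ratios.  Rate-ratio p-values come from a seeded
patient-level bootstrap (see :mod:`sreburden.stats`).

Conventions: person-years = days / 365.25 with a minimum follow-up of one day;
hospitalization days are discharge - admission (night count) truncated to the
follow-up interval; events dated inside ``[start, end]`` (inclusive) count.
Reported rates and ratios are rounded to two decimals; raw values are kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .claims import ClaimsDataset, StudyWindow, quarter_key
from .cohort import detect_sres
from .stats import bootstrap_rate_ratio_pvalue, test_baseline_difference

__all__ = [
    "FollowUp",
    "RateRatioResult",
    "compute_followups",
    "rate_ppy",
    "rate_ratio",
    "person_level_outcomes",
    "aggregate_hcru",
    "aggregate_costs",
    "outcomes_table",
    "subgroup_analysis",
    "mortality_stratified_costs",
    "cumulative_monthly_costs",
    "test_baseline_difference",
    "HCRU_OUTCOMES",
    "COST_OUTCOMES",
]

DAYS_PER_YEAR = 365.25
MONTH_DAYS = DAYS_PER_YEAR / 12.0

HCRU_OUTCOMES = (
    "n_hospitalizations",
    "n_sre_hospitalizations",
    "hospitalization_days",
    "sre_hospitalization_days",
    "n_gp_visits",
    "n_specialist_visits",
    "n_rehab_stays",
    "n_prescriptions",
)
COST_OUTCOMES = (
    "cost_hospitalization",
    "cost_outpatient_visits",
    "cost_rehabilitation",
    "cost_prescriptions",
    "cost_aids_remedies",
    "cost_total",
)


@dataclass(frozen=True)
class FollowUp:
    person_id: str
    start: pd.Timestamp
    end: pd.Timestamp
    end_reason: str
    person_years: float


@dataclass(frozen=True)
class RateRatioResult:
    outcome: str
    rate_sre: float
    rate_non_sre: float
    ratio: float  # nan when the non-SRE rate is zero (undefined, printed "-")
    p_value: float


def compute_followups(cohort: pd.DataFrame, ds: ClaimsDataset,
                      window: StudyWindow | None = None) -> pd.DataFrame:
    """Censored follow-up per cohort person.

    Returns (person_id, group, start, end, end_reason, person_years).  The end
    is the earliest of death, first BTA dispensing at/after index, first SRE
    strictly after index (non-SRE group only) and the data end; ties resolve
    death > bta_initiation > later_sre > data_end.  Follow-up is clamped to a
    minimum of one day.
    """
    window = window or StudyWindow()
    f = cohort.set_index("person_id")
    start = f["index_date"]

    disp = ds.dispensings
    bta = disp[ds.config.is_bta(disp["atc_code"])]
    bta = bta[bta["person_id"].isin(f.index)]
    bta = bta[bta["date"] >= bta["person_id"].map(start)]
    first_bta = bta.groupby("person_id")["date"].min()

    bm_dates = f["bm_date"]
    all_sres = detect_sres(ds, bm_dates, window, end=window.data_end)
    later = all_sres[all_sres["date"] > all_sres["person_id"].map(start)]
    first_later_sre = later.groupby("person_id")["date"].min()

    ends = pd.DataFrame(index=f.index)
    ends["death"] = f["death_date"]
    ends["bta_initiation"] = f.index.map(first_bta)
    ends["later_sre"] = f.index.map(first_later_sre)
    ends.loc[f["group"] != "non_SRE", "later_sre"] = pd.NaT
    ends["data_end"] = window.data_end
    ends = ends.apply(pd.to_datetime)

    end = ends.min(axis=1)
    # tie-break by column order: death > bta > later_sre > data_end
    reason = ends.eq(end, axis=0).idxmax(axis=1)

    clamped = end <= start
    if clamped.any():
        warnings.warn(f"{int(clamped.sum())} follow-up(s) clamped to 1 day",
                      stacklevel=2)
        end = end.where(~clamped, start + pd.Timedelta(days=1))
    py = (end - start).dt.days / DAYS_PER_YEAR
    out = pd.DataFrame({"group": f["group"], "start": start, "end": end,
                        "end_reason": reason, "person_years": py})
    return out.reset_index().rename(columns={"index": "person_id"})


def rate_ppy(total: float, person_years: float) -> float:
    """Pooled rate per patient-year: group total / group person-years."""
    if person_years <= 0:
        raise ValueError("person-years must be positive")
    return float(total) / float(person_years)


def rate_ratio(outcome: str, events_sre, py_sre, events_non_sre, py_non_sre,
               n_boot: int = 2000, seed: int = 0) -> RateRatioResult:
    """Pooled-rate ratio SRE/non-SRE with a bootstrap p-value.

    Inputs are per-person totals and person-years (patient-level data is what
    the bootstrap resamples).  A zero non-SRE rate leaves the ratio undefined
    (NaN), mirroring "–" table rows.
    """
    r1 = rate_ppy(np.sum(events_sre), np.sum(py_sre))
    r0 = rate_ppy(np.sum(events_non_sre), np.sum(py_non_sre))
    if r0 == 0:
        return RateRatioResult(outcome, r1, r0, float("nan"), float("nan"))
    p = bootstrap_rate_ratio_pvalue(events_sre, py_sre, events_non_sre,
                                    py_non_sre, n_boot=n_boot, seed=seed)
    return RateRatioResult(outcome, r1, r0, r1 / r0, p)


def _interval_overlap_days(a_start, a_end, b_start, b_end) -> np.ndarray:
    lo = np.maximum(a_start, b_start)
    hi = np.minimum(a_end, b_end)
    d = (hi - lo) / np.timedelta64(1, "D")
    return np.clip(d, 0, None)


def person_level_outcomes(ds: ClaimsDataset, followups: pd.DataFrame) -> pd.DataFrame:
    """Per-person outcome totals within follow-up; the basis of every aggregate.

    One row per followed person with the HCRU counts, category costs and
    person-years.  Events dated in [start, end] count; hospitalization days are
    night counts truncated to follow-up; outpatient visits deduplicate to one
    billed contact per (physician, quarter).
    """
    f = followups.set_index("person_id")
    out = pd.DataFrame(index=f.index)
    out["group"] = f["group"]
    out["person_years"] = f["person_years"]
    out["deceased"] = (f["end_reason"] == "death").astype(int)
    for col in HCRU_OUTCOMES + COST_OUTCOMES:
        out[col] = 0.0

    costs = ds.costs[ds.costs["person_id"].isin(f.index)].copy()
    start = costs["person_id"].map(f["start"])
    end = costs["person_id"].map(f["end"])

    # hospitalizations: admissions by admission date; days by interval overlap
    hosp = costs[costs["category"] == "hospitalization"]
    hs, he = start[hosp.index], end[hosp.index]
    in_fu = (hosp["admission_date"] >= hs) & (hosp["admission_date"] <= he)
    adm = hosp[in_fu]
    out["n_hospitalizations"] = adm.groupby("person_id").size().reindex(out.index).fillna(0)
    out["cost_hospitalization"] = adm.groupby("person_id")["amount"].sum().reindex(out.index).fillna(0)

    overlap = _interval_overlap_days(hosp["admission_date"].to_numpy(),
                                     hosp["discharge_date"].to_numpy(),
                                     hs.to_numpy(), he.to_numpy())
    days = pd.Series(overlap, index=hosp.index)
    out["hospitalization_days"] = days.groupby(hosp["person_id"]).sum().reindex(out.index).fillna(0)

    # SRE-related: admissions whose stay covers an inpatient SRE-coded diagnosis
    sre_dx_prefixes = tuple(
        p.replace(".", "")
        for pre in ds.config.sre_diagnosis_map().values() for p in pre)
    dx = ds.diagnoses
    sre_dx = dx[(dx["setting"] == "inpatient")
                & dx["code"].str.replace(".", "", regex=False).str.startswith(sre_dx_prefixes)]
    if len(hosp) and len(sre_dx):
        j = hosp.reset_index().merge(
            sre_dx[["person_id", "date"]].rename(columns={"date": "dx_date"}),
            on="person_id")
        j = j[(j["dx_date"] >= j["admission_date"]) & (j["dx_date"] <= j["discharge_date"])]
        sre_adm = hosp.loc[j["index"].unique()]
        in_fu_s = in_fu.loc[sre_adm.index]
        out["n_sre_hospitalizations"] = (sre_adm[in_fu_s].groupby("person_id").size()
                                         .reindex(out.index).fillna(0))
        od = days.loc[sre_adm.index]
        out["sre_hospitalization_days"] = (od.groupby(sre_adm["person_id"]).sum()
                                           .reindex(out.index).fillna(0))

    # outpatient visits, billed once per (physician, quarter)
    visits = costs[costs["category"] == "outpatient_visit"]
    vin = visits[(visits["date"] >= start[visits.index]) & (visits["date"] <= end[visits.index])]
    if len(vin):
        vin = vin.assign(q=quarter_key(vin["date"]))
        uniq = vin.drop_duplicates(["person_id", "physician_id", "q"])
        gp = uniq[uniq["physician_role"] == "gp"]
        sp = uniq[uniq["physician_role"] == "specialist"]
        out["n_gp_visits"] = gp.groupby("person_id").size().reindex(out.index).fillna(0)
        out["n_specialist_visits"] = sp.groupby("person_id").size().reindex(out.index).fillna(0)
        out["cost_outpatient_visits"] = (vin.groupby("person_id")["amount"].sum()
                                         .reindex(out.index).fillna(0))

    def _cat(cat: str, count_col: str | None, cost_col: str):
        c = costs[costs["category"].isin(cat if isinstance(cat, tuple) else (cat,))]
        cin = c[(c["date"] >= start[c.index]) & (c["date"] <= end[c.index])]
        if count_col is not None:
            out[count_col] = cin.groupby("person_id").size().reindex(out.index).fillna(0)
        out[cost_col] = cin.groupby("person_id")["amount"].sum().reindex(out.index).fillna(0)

    _cat("rehabilitation", "n_rehab_stays", "cost_rehabilitation")
    _cat("prescription", "n_prescriptions", "cost_prescriptions")
    _cat(("aid", "remedy"), None, "cost_aids_remedies")

    out["cost_total"] = (out["cost_hospitalization"] + out["cost_outpatient_visits"]
                         + out["cost_rehabilitation"] + out["cost_prescriptions"]
                         + out["cost_aids_remedies"])
    return out.reset_index()


def _group_rates(person_table: pd.DataFrame, outcomes) -> pd.DataFrame:
    rows = []
    for group, g in person_table.groupby("group"):
        py = g["person_years"].sum()
        for oc in outcomes:
            rows.append((group, oc, len(g), rate_ppy(g[oc].sum(), py)))
    return pd.DataFrame(rows, columns=["group", "outcome", "n", "rate_ppy"])


def aggregate_hcru(person_table: pd.DataFrame) -> pd.DataFrame:
    """Per-group pooled HCRU rates per patient-year."""
    return _group_rates(person_table, HCRU_OUTCOMES)


def aggregate_costs(person_table: pd.DataFrame) -> pd.DataFrame:
    """Per-group pooled cost rates (EUR ppy) by category plus their total."""
    return _group_rates(person_table, COST_OUTCOMES)


def outcomes_table(person_table: pd.DataFrame, n_boot: int = 2000,
                   seed: int = 0) -> pd.DataFrame:
    """Comparative outcome table: ppy rates per group, rate ratio, p-value.

    One row per HCRU and cost outcome (14 rows).  Rounded ``rate_*_2dp`` /
    ``ratio_2dp`` columns are the reporting values; raw columns stay unrounded.
    """
    sre = person_table[person_table["group"] == "SRE"]
    non = person_table[person_table["group"] == "non_SRE"]
    rows = []
    for i, oc in enumerate(HCRU_OUTCOMES + COST_OUTCOMES):
        rr = rate_ratio(oc, sre[oc].to_numpy(), sre["person_years"].to_numpy(),
                        non[oc].to_numpy(), non["person_years"].to_numpy(),
                        n_boot=n_boot, seed=seed + i)
        rows.append((oc, rr.rate_sre, rr.rate_non_sre, rr.ratio, rr.p_value))
    t = pd.DataFrame(rows, columns=["outcome", "rate_sre", "rate_non_sre",
                                    "ratio", "p_value"])
    for col in ("rate_sre", "rate_non_sre", "ratio"):
        t[col + "_2dp"] = t[col].round(2)
    return t


def subgroup_analysis(person_table: pd.DataFrame, cohort: pd.DataFrame,
                      by: str) -> pd.DataFrame:
    """Pooled ppy outcome rates within SRE-cohort subgroups.

    ``by`` is ``sre_type`` or ``st_type``.  Empty subgroups yield a size-0 row
    with absent rates.
    """
    if by not in ("sre_type", "st_type"):
        raise ValueError("subgroups are defined by sre_type or st_type")
    labels = cohort.set_index("person_id")[by]
    t = person_table[person_table["group"] == "SRE"].copy()
    t["subgroup"] = t["person_id"].map(labels)
    rows = []
    outcomes = HCRU_OUTCOMES + COST_OUTCOMES
    for sub, g in t.groupby("subgroup", dropna=False):
        py = g["person_years"].sum()
        for oc in outcomes:
            r = rate_ppy(g[oc].sum(), py) if len(g) and py > 0 else float("nan")
            rows.append((sub, oc, len(g), r))
    return pd.DataFrame(rows, columns=["subgroup", "outcome", "n", "rate_ppy"])


def mortality_stratified_costs(person_table: pd.DataFrame) -> pd.DataFrame:
    """Group x vital-status pooled total cost ppy (deceased = censored by death)."""
    rows = []
    for (group, dead), g in person_table.groupby(["group", "deceased"]):
        py = g["person_years"].sum()
        rows.append((group, "deceased" if dead else "survived", len(g),
                     rate_ppy(g["cost_total"].sum(), py) if py > 0 else float("nan")))
    cells = pd.DataFrame(rows, columns=["group", "vital_status", "n",
                                        "cost_total_ppy"])
    # flag empty cells explicitly
    for group in person_table["group"].unique():
        for status in ("deceased", "survived"):
            if not ((cells["group"] == group) & (cells["vital_status"] == status)).any():
                cells.loc[len(cells)] = (group, status, 0, float("nan"))
    return cells.sort_values(["group", "vital_status"]).reset_index(drop=True)


def cumulative_monthly_costs(ds: ClaimsDataset, followups: pd.DataFrame,
                             horizon: int = 24,
                             cumulative: bool = True) -> pd.DataFrame:
    """Cost per patient-month over the first ``horizon`` months after index.

    Months are 365.25/12 days long.  For month m the cumulative variant reports
    (total cost within the first m months of follow-up) / (person-months at
    risk over the first m months), per group, plus the between-group difference
    and ratio.  ``cumulative=False`` reports each month on its own.  Months
    with zero persons at risk are flagged with NaN, never imputed.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    f = followups.set_index("person_id")
    month = pd.to_timedelta(MONTH_DAYS, unit="D")

    costs = ds.costs[ds.costs["person_id"].isin(f.index)]
    start = costs["person_id"].map(f["start"])
    end = costs["person_id"].map(f["end"])
    in_fu = (costs["date"] >= start) & (costs["date"] <= end)
    c = costs[in_fu]
    mi = ((c["date"] - start[c.index]).dt.days / MONTH_DAYS).astype(int)
    c = c.assign(month=mi + 1, group=c["person_id"].map(f["group"]))
    c = c[c["month"] <= horizon]
    cost_by = c.groupby(["group", "month"])["amount"].sum()

    months = np.arange(1, horizon + 1)
    rows = {}
    for group, g in f.groupby("group"):
        fu_days = (g["end"] - g["start"]).dt.days.to_numpy()
        # person-months at risk inside month m: overlap of follow-up with
        # [(m-1)*L, m*L), in units of months
        at_risk = np.clip(
            (np.minimum(fu_days[None, :], months[:, None] * MONTH_DAYS)
             - (months[:, None] - 1) * MONTH_DAYS) / MONTH_DAYS, 0, None)
        pm = at_risk.sum(axis=1)
        cost = np.array([cost_by.get((group, m), 0.0) for m in months])
        if cumulative:
            pm_c, cost_c = np.cumsum(pm), np.cumsum(cost)
        else:
            pm_c, cost_c = pm, cost
        with np.errstate(divide="ignore", invalid="ignore"):
            rows[group] = np.where(pm_c > 0, cost_c / pm_c, np.nan)
    out = pd.DataFrame({"month": months})
    for group, series in rows.items():
        out[f"cost_pm_{group}"] = series
    if {"cost_pm_SRE", "cost_pm_non_SRE"} <= set(out.columns):
        out["difference"] = out["cost_pm_SRE"] - out["cost_pm_non_SRE"]
        out["ratio"] = out["cost_pm_SRE"] / out["cost_pm_non_SRE"]
    return out
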