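"""Seeded synthetic claims generator with known ground truth.

Emulates the structure of a German statutory-insurance extract for patients
with bone metastases (BM) from solid tumors: quarterly-billed outpatient
contacts, inpatient vs outpatient diagnoses with confirmation qualifiers,
itemized category costs, BM/solid-tumor/SRE coding, bone-targeting-agent (BTA)
dispensings, and death.

The causal structure is deliberately simple and fully known:

* a latent log-normal *frailty* ``exp(z)``, ``z ~ N(0, frailty_sd^2)``, raises
  the SRE hazard, the death hazard, baseline cost intensity and the rate of
  background codes in all seven hdPS dimensions — so SRE status is confounded
  with baseline costs, and the claims codes carry real proxy information about
  the confounder for the hdPS to find;
* competing post-BM events (first SRE, death, BTA initiation) have exponential
  waiting times with log-rates linear in ``z``;
* per-category cost events are Poisson with log-normal amounts; entering the
  SRE state multiplies a category's event rate and/or amounts by its configured
  effect; the last weeks of life carry an end-of-life intensity boost;
* outpatient contacts are billed at most once per (person, physician, quarter).

Everything is driven by one ``numpy`` Generator: identical config + seed gives
identical output.  Claims are emitted only where downstream windows can read
them (from one washout year before the BM diagnosis to the person's data end);
persons without a BM diagnosis contribute person/enrollment rows only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .claims import ClaimsDataset, CodeListConfig, StudyWindow, validate_dataset

__all__ = [
    "CostModel",
    "SimulationConfig",
    "GroundTruth",
    "generate_population",
    "generate_event_histories",
    "generate_claims",
    "true_effect_summary",
]

DAYS_PER_YEAR = 365.25
_EPOCH = np.datetime64("1970-01-01")


def _days(ts) -> int:
    return int((np.datetime64(ts, "D") - _EPOCH).astype(int))


@dataclass(frozen=True)
class CostModel:
    """One cost category: Poisson event rate with log-normal amounts.

    ``rate_multiplier``/``amount_multiplier`` are the multiplicative effect of
    being in the SRE state (post first SRE) on event intensity and amounts.
    """

    rate_per_year: float
    amount_mu: float
    amount_sigma: float
    rate_multiplier: float = 1.0
    amount_multiplier: float = 1.0

    @property
    def mean_amount(self) -> float:
        return float(np.exp(self.amount_mu + self.amount_sigma ** 2 / 2))

    @property
    def cost_multiplier(self) -> float:
        return self.rate_multiplier * self.amount_multiplier


def _default_cost_models() -> dict[str, CostModel]:
    # baseline (non-SRE) intensities sized so pooled EUR-per-patient-year
    # magnitudes echo published German claims figures for this population;
    # multipliers echo the corresponding category rate ratios
    return {
        "hospitalization": CostModel(3.3, np.log(355) - 0.125, 0.5, 1.09, 1.13),
        "visit_gp": CostModel(5.6, np.log(88) - 0.18, 0.6, 1.00, 1.04),
        "visit_specialist": CostModel(13.5, np.log(88) - 0.18, 0.6, 1.05, 1.04),
        "rehabilitation": CostModel(0.25, np.log(152) - 0.125, 0.5, 5.5, 1.0),
        "prescription": CostModel(42.9, np.log(158) - 0.72, 1.2, 1.01, 0.89),
        "aid": CostModel(4.0, np.log(200) - 0.405, 0.9, 1.10, 1.11),
        "remedy": CostModel(3.0, np.log(169) - 0.245, 0.7, 1.10, 1.11),
    }


def _default_st_probs() -> dict[str, float]:
    return {"C34": 0.23, "C61": 0.18, "C50": 0.15, "C64": 0.065, "C67": 0.04,
            "other": 0.335}


def _default_sre_type_probs() -> dict[str, float]:
    return {"pathological_fracture": 0.33, "spinal_cord_compression": 0.30,
            "radiation_to_bone": 0.21, "surgery_to_bone": 0.05, "multiple": 0.11}


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterization of the synthetic claims world (seed-deterministic)."""

    n_persons: int = 20_000
    seed: int = 0

    # demographics
    age_mean: float = 69.5
    age_sd: float = 11.6
    age_min: float = 18.0
    age_max: float = 100.0
    sex_ratio_female: float = 0.39

    # latent confounder
    frailty_sd: float = 0.4

    # BM diagnosis placement
    bm_probability: float = 0.85
    prevalent_bm_probability: float = 0.04
    outpatient_route_probability: float = 0.40
    missing_confirmation_probability: float = 0.08
    same_quarter_probability: float = 0.08
    st_missing_probability: float = 0.04
    late_enrollment_probability: float = 0.05

    # post-BM event hazards (per year)
    sre_hazard_base: float = 0.75
    sre_log_hazard_on_frailty: float = 1.2
    sre_recurrence_rate: float = 0.4
    mortality_hazard_base: float = 0.70
    mortality_log_hazard_on_frailty: float = 0.3
    bta_pre_bm_probability: float = 0.10
    bta_post_bm_rate: float = 0.75

    st_type_probabilities: dict[str, float] = field(default_factory=_default_st_probs)
    sre_type_probabilities: dict[str, float] = field(default_factory=_default_sre_type_probs)
    #: per-subtype cost-intensity factor (lung cancer is the costliest subtype)
    st_type_cost_multipliers: dict[str, float] = field(
        default_factory=lambda: {"C34": 1.5})

    # cost process
    cost_models: dict[str, CostModel] = field(default_factory=_default_cost_models)
    cost_log_on_frailty: float = 0.6
    hosp_mean_los: float = 9.3
    hosp_los_multiplier: float = 1.065
    eol_rate_multiplier: float = 1.5
    eol_days: int = 30
    #: fraction of SRE-state admissions documented with an SRE diagnosis code
    sre_hosp_tag_probability: float = 0.12

    # background code dimensions (rx/aids/remedies ride on the cost streams)
    dim_rates: dict[str, float] = field(default_factory=lambda: {
        "inpatient_dx": 1.5, "outpatient_dx": 6.0,
        "outpatient_treatment": 5.0, "inpatient_treatment": 0.8})
    dimension_vocab_sizes: dict[str, int] = field(default_factory=lambda: {
        "inpatient_dx": 20, "outpatient_dx": 20, "rx": 20,
        "outpatient_treatment": 20, "inpatient_treatment": 20,
        "aids": 20, "remedies": 20})
    code_prevalence_decay: float = 0.95
    code_log_on_frailty: float = 1.0

    def __post_init__(self):
        if self.n_persons < 0:
            raise ValueError("n_persons must be >= 0")
        for name in ("bm_probability", "sex_ratio_female", "prevalent_bm_probability",
                     "outpatient_route_probability", "bta_pre_bm_probability"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for probs in (self.st_type_probabilities, self.sre_type_probabilities):
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError("probabilities must sum to 1")
        for name in ("sre_hazard_base", "mortality_hazard_base", "bta_post_bm_rate",
                     "frailty_sd", "sre_recurrence_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    # -- derived truths ----------------------------------------------------
    def category_cost_multipliers(self) -> dict[str, float]:
        out = dict()
        for name, m in self.cost_models.items():
            mult = m.cost_multiplier
            if name == "hospitalization":
                mult *= self.hosp_los_multiplier
            out[name] = mult
        return out

    def implied_total_cost_multiplier(self) -> float:
        """Expected total-cost ratio (SRE state vs baseline) implied by config."""
        base = sre = 0.0
        for name, m in self.cost_models.items():
            w = m.rate_per_year * m.mean_amount
            if name == "hospitalization":
                w *= self.hosp_mean_los
            base += w
            mult = m.cost_multiplier
            if name == "hospitalization":
                mult *= self.hosp_los_multiplier
            sre += w * mult
        return sre / base

    def with_uniform_cost_multiplier(self, multiplier: float) -> "SimulationConfig":
        """Variant where every category's cost effect is exactly ``multiplier``
        (applied to amounts; event rates and length of stay unchanged)."""
        models = {name: replace(m, rate_multiplier=1.0, amount_multiplier=multiplier)
                  for name, m in self.cost_models.items()}
        return replace(self, cost_models=models, hosp_los_multiplier=1.0)


@dataclass
class GroundTruth:
    """Per-person latent state persisted alongside the dataset for recovery tests."""

    table: pd.DataFrame  # person-level latent variables and true event dates
    config: SimulationConfig


# ---------------------------------------------------------------------------
# vocabularies (fixed, deterministic, disjoint from eligibility/SRE code lists)
# ---------------------------------------------------------------------------

_CHRONIC_ICD = [
    # Charlson-relevant chronic codes so the comorbidity index has real signal
    "I21.9", "I50.1", "I70.2", "I63.9", "F03", "J44.9", "M05.9", "K25.9",
    "K70.3", "E11.9", "E11.2", "G81.9", "N18.9", "K72.9", "I25.2",
]
_FILLER_LETTERS = "EFGHIJKMNR"


def _icd_vocab(size: int) -> list[str]:
    fillers = []
    i = 0
    while len(fillers) < size:
        letter = _FILLER_LETTERS[i % len(_FILLER_LETTERS)]
        num = 10 + (i * 7) % 80
        code = f"{letter}{num:02d}.{i % 10}"
        if code not in fillers and code not in _CHRONIC_ICD \
                and not code.startswith(("G95", "M49", "M84", "C79")):
            fillers.append(code)
        i += 1
    # chronic (Charlson-relevant) codes interleaved mid-ranking so comorbidity
    # prevalence is realistic rather than dominating the frequency spectrum
    vocab = list(fillers)
    for j, code in enumerate(_CHRONIC_ICD):
        vocab.insert(min(3 + 3 * j, len(vocab)), code)
    return vocab[:size]


def _atc_vocab(size: int) -> list[str]:
    level1 = "ABCDGHJLNRSV"  # excludes M to stay clear of BTA codes M05BA*
    return [f"{level1[i % len(level1)]}{(i * 3) % 16 + 1:02d}A{chr(65 + i % 6)}"
            f"{(i * 5) % 90 + 1:02d}" for i in range(size)]


def _ops_vocab(size: int, setting: str) -> list[str]:
    # OPS-like "x-xxx" codes, avoiding the SRE procedure prefixes 5-78/5-79/8-52
    out = []
    i = 0
    while len(out) < size:
        a = (1, 3, 5, 8, 9)[i % 5]
        b = 100 + (i * 13) % 600
        code = f"{a}-{b}{'a' if setting == 'outpatient' else ''}"
        if not code.startswith(("5-78", "5-79", "8-52")):
            out.append(code)
        i += 1
    return out[:size]


def _aid_vocab(size: int, prefix: str) -> list[str]:
    return [f"{prefix}{i + 1:03d}" for i in range(size)]


def _decay_probs(size: int, decay: float) -> np.ndarray:
    p = decay ** np.arange(size)
    return p / p.sum()


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate_population(config: SimulationConfig,
                        rng: np.random.Generator | None = None,
                        window: StudyWindow | None = None
                        ) -> tuple[pd.DataFrame, pd.Series]:
    """Persons (id, birth date, sex) plus the latent frailty ``z`` per person.

    Ages are truncated-normal; birth dates anchor age to the middle of the
    inclusion window so that age at the BM diagnosis is near the configured
    distribution.  Death dates are filled in by the event-history stage.
    """
    if config.n_persons < 0:
        raise ValueError("n_persons must be >= 0")
    rng = rng or np.random.default_rng(config.seed)
    window = window or StudyWindow()
    n = config.n_persons
    ids = np.array([f"P{i:07d}" for i in range(n)])
    sex = np.where(rng.random(n) < config.sex_ratio_female, "female", "male")
    age = rng.normal(config.age_mean, config.age_sd, n)
    while True:  # redraw outside the truncation bounds
        bad = (age < config.age_min) | (age > config.age_max)
        if not bad.any():
            break
        age[bad] = rng.normal(config.age_mean, config.age_sd, int(bad.sum()))
    mid = window.inclusion_start + (window.inclusion_end - window.inclusion_start) / 2
    birth = mid - pd.to_timedelta((age * DAYS_PER_YEAR).round(), unit="D")
    persons = pd.DataFrame({"person_id": ids, "birth_date": birth,
                            "sex": sex, "death_date": pd.NaT})
    z = pd.Series(rng.normal(0.0, config.frailty_sd, n), index=ids, name="frailty")
    return persons, z


def _draw_st_codes(rng, sex: np.ndarray, probs: dict[str, float]) -> np.ndarray:
    """Primary solid-tumor subtype per person, consistent with sex."""
    names = list(probs)
    base = np.array([probs[k] for k in names])
    codes = np.empty(len(sex), dtype=object)
    for s in ("female", "male"):
        m = sex == s
        p = base.copy()
        if s == "female" and "C61" in names:
            p[names.index("C61")] = 0.0  # no female prostate cancer
        if s == "male" and "C50" in names:
            p[names.index("C50")] *= 0.02  # male breast cancer is rare
        p = p / p.sum()
        codes[m] = rng.choice(names, size=int(m.sum()), p=p)
    return codes


_ST_FULL_CODE = {"C34": "C34.9", "C61": "C61", "C50": "C50.9", "C64": "C64",
                 "C67": "C67.9"}
_OTHER_ST = ("C15.9", "C16.9", "C18.9", "C25.9")

_SRE_DX_CODE = {"pathological_fracture": "M84.46", "spinal_cord_compression": "G95.2"}
_SRE_PROC_CODE = {"surgery_to_bone": "5-785", "radiation_to_bone": "8-522"}


def generate_event_histories(persons: pd.DataFrame, frailty: pd.Series,
                             config: SimulationConfig,
                             rng: np.random.Generator,
                             window: StudyWindow | None = None
                             ) -> tuple[ClaimsDataset, pd.DataFrame]:
    """All claims streams plus the ground-truth table for a generated population.

    See the module docstring for the causal structure.  Returns the (validated)
    dataset and a per-person ground-truth frame.
    """
    window = window or StudyWindow()
    n = len(persons)
    ids = persons["person_id"].to_numpy()
    z = frailty.reindex(ids).to_numpy()
    sex = persons["sex"].to_numpy()

    d_start, d_end = _days(window.data_start), _days(window.data_end)
    i_start, i_end = _days(window.inclusion_start), _days(window.inclusion_end)

    # --- enrollment -------------------------------------------------------
    enroll_start = np.full(n, d_start, dtype=np.int64)
    late = rng.random(n) < config.late_enrollment_probability
    enroll_start[late] = d_start + rng.integers(365, 4 * 365, int(late.sum()))

    # --- BM placement -----------------------------------------------------
    has_bm = rng.random(n) < config.bm_probability
    bm_day = np.full(n, -1, dtype=np.int64)
    nbm = int(has_bm.sum())
    bm_day[has_bm] = rng.integers(i_start, i_end + 1, nbm)
    prevalent = has_bm & (rng.random(n) < config.prevalent_bm_probability)

    # --- post-BM latent event times (years from BM) -----------------------
    with np.errstate(over="ignore"):
        sre_rate = config.sre_hazard_base * np.exp(config.sre_log_hazard_on_frailty * z)
        death_rate = config.mortality_hazard_base * np.exp(
            config.mortality_log_hazard_on_frailty * z)
    t_sre = (rng.exponential(1.0, n) / np.maximum(sre_rate, 1e-12)
             if config.sre_hazard_base > 0 else np.full(n, np.inf))
    t_death = rng.exponential(1.0, n) / np.maximum(death_rate, 1e-12)
    t_bta = (rng.exponential(1.0, n) / config.bta_post_bm_rate
             if config.bta_post_bm_rate > 0 else np.full(n, np.inf))

    death_day = np.where(has_bm, bm_day + (t_death * DAYS_PER_YEAR).astype(np.int64),
                         np.iinfo(np.int64).max)
    died = has_bm & (death_day <= d_end)
    person_end = np.where(died, death_day, d_end)

    sre_day = bm_day + (np.minimum(t_sre, 1e6) * DAYS_PER_YEAR).astype(np.int64)
    sre_observed = has_bm & np.isfinite(t_sre) & (sre_day <= person_end) \
        & (sre_day <= d_end)
    sre_day = np.where(sre_observed, sre_day, np.iinfo(np.int64).max)

    bta_pre = has_bm & (rng.random(n) < config.bta_pre_bm_probability)
    bta_day = bm_day + (np.minimum(t_bta, 1e6) * DAYS_PER_YEAR).astype(np.int64)
    bta_post = has_bm & np.isfinite(t_bta) & (bta_day <= person_end)
    bta_day = np.where(bta_post, bta_day, np.iinfo(np.int64).max)

    st_sub = _draw_st_codes(rng, sex, config.st_type_probabilities)
    st_missing = has_bm & (rng.random(n) < config.st_missing_probability)

    sre_types = np.array(list(config.sre_type_probabilities))
    sre_type = rng.choice(sre_types, size=n,
                          p=list(config.sre_type_probabilities.values()))

    # --- record buffers ---------------------------------------------------
    dx_rows: list[pd.DataFrame] = []
    proc_rows: list[pd.DataFrame] = []
    disp_rows: list[pd.DataFrame] = []
    cost_rows: list[pd.DataFrame] = []
    sick_rows: list[pd.DataFrame] = []

    def _dates(day_ints: np.ndarray) -> pd.Series:
        return pd.to_datetime(day_ints, unit="D")

    bm_idx = np.flatnonzero(has_bm)
    pid_bm = ids[bm_idx]

    # BM evidence --------------------------------------------------------
    outp_route = rng.random(n) < config.outpatient_route_probability
    route_out = bm_idx[outp_route[bm_idx]]
    route_inp = bm_idx[~outp_route[bm_idx]]
    dx_rows.append(pd.DataFrame({
        "person_id": ids[route_inp], "date": _dates(bm_day[route_inp]),
        "code": "C79.5", "setting": "inpatient", "qualifier": None}))
    # outpatient route: first confirmed code at BM, second later
    first = pd.DataFrame({"person_id": ids[route_out],
                          "date": _dates(bm_day[route_out]), "code": "C79.5",
                          "setting": "outpatient", "qualifier": "confirmed"})
    dx_rows.append(first)
    miss = rng.random(len(route_out)) < config.missing_confirmation_probability
    same_q = (~miss) & (rng.random(len(route_out)) < config.same_quarter_probability)
    second_day = bm_day[route_out] + rng.integers(20, 130, len(route_out))
    d2 = pd.to_datetime(second_day, unit="D")
    d1 = pd.to_datetime(bm_day[route_out], unit="D")
    need_diff = ~miss & ~same_q
    same = need_diff & (d1.to_period("Q") == d2.to_period("Q"))
    # push the confirming code into the next quarter where needed
    pushed = (d1[same].to_period("Q") + 1).to_timestamp() + pd.to_timedelta(
        rng.integers(3, 40, int(same.sum())), unit="D")
    d2 = d2.to_series().reset_index(drop=True)
    d2[np.flatnonzero(same)] = pushed
    force_same = same_q & (d1.to_period("Q") != pd.DatetimeIndex(d2).to_period("Q"))
    d2[np.flatnonzero(force_same)] = d1[force_same] + pd.to_timedelta(5, unit="D")
    keep2 = ~miss
    dx_rows.append(pd.DataFrame({
        "person_id": ids[route_out[keep2]],
        "date": pd.DatetimeIndex(d2)[keep2], "code": "C79.5",
        "setting": "outpatient", "qualifier": "confirmed"}))
    # prevalent cases: an extra inpatient BM code during the washout year
    prev_idx = np.flatnonzero(prevalent)
    dx_rows.append(pd.DataFrame({
        "person_id": ids[prev_idx],
        "date": _dates(rng.integers(d_start, i_start, len(prev_idx))),
        "code": "C79.5", "setting": "inpatient", "qualifier": None}))

    # solid-tumor diagnoses ----------------------------------------------
    st_code = np.array([_ST_FULL_CODE.get(s, "") for s in st_sub], dtype=object)
    other_mask = st_sub == "other"
    st_code[other_mask] = rng.choice(_OTHER_ST, int(other_mask.sum()))
    st_day = bm_day - rng.integers(30, 300, n)
    st_day[st_missing] = bm_day[st_missing] - rng.integers(400, 600, int(st_missing.sum()))
    sub = bm_idx
    dx_rows.append(pd.DataFrame({
        "person_id": ids[sub], "date": _dates(st_day[sub]),
        "code": st_code[sub], "setting": "inpatient", "qualifier": None}))
    # a confirming outpatient repeat shortly before BM
    rep = sub[rng.random(len(sub)) < 0.7]
    dx_rows.append(pd.DataFrame({
        "person_id": ids[rep], "date": _dates(np.maximum(st_day[rep] + 25, bm_day[rep]
                                                         - rng.integers(0, 25, len(rep)))),
        "code": st_code[rep], "setting": "outpatient", "qualifier": "confirmed"}))

    # SRE events ----------------------------------------------------------
    sre_idx = np.flatnonzero(sre_observed)

    def _emit_sre_event(idx: np.ndarray, day: np.ndarray, types: np.ndarray):
        for t in ("pathological_fracture", "spinal_cord_compression"):
            m = types == t
            if m.any():
                dx_rows.append(pd.DataFrame({
                    "person_id": ids[idx[m]], "date": _dates(day[m]),
                    "code": _SRE_DX_CODE[t], "setting": "inpatient",
                    "qualifier": None}))
        for t in ("surgery_to_bone", "radiation_to_bone"):
            m = types == t
            if m.any():
                proc_rows.append(pd.DataFrame({
                    "person_id": ids[idx[m]], "date": _dates(day[m]),
                    "code": _SRE_PROC_CODE[t],
                    "setting": "inpatient" if t == "surgery_to_bone" else "outpatient"}))
        m = types == "multiple"
        if m.any():
            dx_rows.append(pd.DataFrame({
                "person_id": ids[idx[m]], "date": _dates(day[m]),
                "code": _SRE_DX_CODE["pathological_fracture"],
                "setting": "inpatient", "qualifier": None}))
            proc_rows.append(pd.DataFrame({
                "person_id": ids[idx[m]], "date": _dates(day[m]),
                "code": _SRE_PROC_CODE["radiation_to_bone"], "setting": "outpatient"}))

    _emit_sre_event(sre_idx, sre_day[sre_idx], sre_type[sre_idx])
    # one possible recurrent SRE after the first
    if config.sre_recurrence_rate > 0 and len(sre_idx):
        gap = (rng.exponential(1.0 / config.sre_recurrence_rate, len(sre_idx))
               * DAYS_PER_YEAR).astype(np.int64)
        day2 = sre_day[sre_idx] + np.maximum(gap, 1)
        ok = day2 <= np.minimum(person_end[sre_idx], d_end)
        types2 = rng.choice(sre_types, size=int(ok.sum()),
                            p=list(config.sre_type_probabilities.values()))
        _emit_sre_event(sre_idx[ok], day2[ok], types2)

    # BTA dispensings ------------------------------------------------------
    pre_idx = np.flatnonzero(bta_pre)
    pre_day = bm_day[pre_idx] - rng.integers(30, 400, len(pre_idx))
    post_idx = np.flatnonzero(bta_post)
    bta_people = np.concatenate([pre_idx, post_idx])
    bta_days = np.concatenate([pre_day, bta_day[post_idx]])
    if len(bta_people):
        atc = rng.choice(["M05BA08", "M05BA03"], len(bta_people))
        amt = rng.lognormal(np.log(320), 0.3, len(bta_people))
        disp_rows.append(pd.DataFrame({
            "person_id": ids[bta_people], "date": _dates(bta_days),
            "atc_code": atc, "cost": amt}))
        cost_rows.append(pd.DataFrame({
            "person_id": ids[bta_people], "date": _dates(bta_days),
            "category": "prescription", "amount": amt, "code": None,
            "admission_date": pd.NaT, "discharge_date": pd.NaT,
            "physician_role": None, "physician_id": None}))

    # --- cost / code segments --------------------------------------------
    # claims emitted in [max(enroll_start, bm - 370 d), person_end]
    gen_start = np.maximum(enroll_start[bm_idx], bm_day[bm_idx] - 370)
    gen_end = np.minimum(person_end[bm_idx], d_end)
    sre_start_bm = sre_day[bm_idx].astype(float)
    eol_start = np.where(died[bm_idx], person_end[bm_idx] - config.eol_days,
                         np.inf).astype(float)

    t1 = np.minimum(sre_start_bm, eol_start)
    t2 = np.maximum(sre_start_bm, eol_start)
    # the flags: first segment neither state; middle segment = whichever of
    # SRE-state / end-of-life started first; last segment both
    segs = []
    for lo, hi, after1, after2 in (
            (gen_start.astype(float), np.minimum(t1, gen_end.astype(float)), False, False),
            (np.maximum(gen_start, t1), np.minimum(t2, gen_end.astype(float)), True, False),
            (np.maximum(gen_start, t2), gen_end.astype(float), True, True)):
        ok = hi > lo
        loc = np.flatnonzero(ok)
        if not after1:
            f_sre = np.zeros(len(loc), bool); f_eol = np.zeros(len(loc), bool)
        elif not after2:
            first_is_sre = sre_start_bm[loc] <= eol_start[loc]
            f_sre = first_is_sre; f_eol = ~first_is_sre
        else:
            f_sre = np.ones(len(loc), bool); f_eol = np.ones(len(loc), bool)
        segs.append(pd.DataFrame({"loc": loc, "start": lo[loc], "end": hi[loc],
                                  "sre": f_sre, "eol": f_eol}))
    seg = pd.concat(segs, ignore_index=True)
    seg_loc = seg["loc"].to_numpy()
    seg_years = (seg["end"].to_numpy() - seg["start"].to_numpy()) / DAYS_PER_YEAR
    seg_sre = seg["sre"].to_numpy()
    seg_eol = seg["eol"].to_numpy()
    z_bm = z[bm_idx]
    st_factor = np.array([config.st_type_cost_multipliers.get(s, 1.0)
                          for s in st_sub])[bm_idx]
    cost_frail = np.exp(config.cost_log_on_frailty * z_bm[seg_loc]) \
        * st_factor[seg_loc]

    def _poisson_events(rate: float, rate_mult_sre: float):
        lam = rate * cost_frail * seg_years \
            * np.where(seg_sre, rate_mult_sre, 1.0) \
            * np.where(seg_eol, config.eol_rate_multiplier, 1.0)
        nev = rng.poisson(lam)
        rep = np.repeat(np.arange(len(seg)), nev)
        u = rng.random(len(rep))
        day = (seg["start"].to_numpy()[rep]
               + u * (seg["end"].to_numpy()[rep] - seg["start"].to_numpy()[rep])
               ).astype(np.int64)
        return rep, day

    def _amounts(model: CostModel, rep: np.ndarray) -> np.ndarray:
        a = rng.lognormal(model.amount_mu, model.amount_sigma, len(rep))
        return a * np.where(seg_sre[rep], model.amount_multiplier, 1.0)

    def _cost_frame(rep, day, category, amount, **extra):
        base = {"person_id": pid_bm[seg_loc[rep]], "date": _dates(day),
                "category": category, "amount": amount, "code": None,
                "admission_date": pd.NaT, "discharge_date": pd.NaT,
                "physician_role": None, "physician_id": None}
        base.update(extra)
        return pd.DataFrame(base)

    # hospitalizations: amount = per-diem x nights; LOS geometric
    hm = config.cost_models["hospitalization"]
    rep, day = _poisson_events(hm.rate_per_year, hm.rate_multiplier)
    mean_los = config.hosp_mean_los * np.where(seg_sre[rep],
                                               config.hosp_los_multiplier, 1.0)
    los = rng.geometric(1.0 / mean_los) if len(rep) else np.array([], dtype=int)
    perdiem = _amounts(hm, rep)
    cost_rows.append(_cost_frame(rep, day, "hospitalization", perdiem * los,
                                 admission_date=_dates(day),
                                 discharge_date=_dates(day + los)))
    # a fraction of SRE-state admissions carries an SRE diagnosis, so the
    # SRE-related hospitalization outcomes are a genuine subset of all-cause
    # without changing the configured total hospitalization intensity
    tag = seg_sre[rep] & (rng.random(len(rep)) < config.sre_hosp_tag_probability)
    if tag.any():
        dx_rows.append(pd.DataFrame({
            "person_id": pid_bm[seg_loc[rep[tag]]], "date": _dates(day[tag]),
            "code": _SRE_DX_CODE["pathological_fracture"],
            "setting": "inpatient", "qualifier": None}))

    # outpatient visits (billed once per physician and quarter)
    for role, model_name, pool in (("gp", "visit_gp", 2),
                                   ("specialist", "visit_specialist", 8)):
        vm = config.cost_models[model_name]
        rep, day = _poisson_events(vm.rate_per_year, vm.rate_multiplier)
        amt = _amounts(vm, rep)
        phys = rng.integers(0, pool, len(rep))
        frame = _cost_frame(rep, day, "outpatient_visit", amt,
                            physician_role=role)
        frame["physician_id"] = [f"{p}:{role}{k}" for p, k in
                                 zip(frame["person_id"], phys)]
        q = frame["date"].dt.year * 4 + frame["date"].dt.quarter
        frame = frame.loc[~frame.assign(q=q).duplicated(
            ["person_id", "physician_id", "q"]).to_numpy()]
        cost_rows.append(frame)

    # rehabilitation, prescriptions, aids, remedies
    rm = config.cost_models["rehabilitation"]
    rep, day = _poisson_events(rm.rate_per_year, rm.rate_multiplier)
    cost_rows.append(_cost_frame(rep, day, "rehabilitation", _amounts(rm, rep)))

    pm = config.cost_models["prescription"]
    rep, day = _poisson_events(pm.rate_per_year, pm.rate_multiplier)
    amt = _amounts(pm, rep)
    atc_vocab = np.array(_atc_vocab(config.dimension_vocab_sizes["rx"]))
    atc = atc_vocab[rng.choice(len(atc_vocab), len(rep),
                               p=_decay_probs(len(atc_vocab),
                                              config.code_prevalence_decay))]
    cost_rows.append(_cost_frame(rep, day, "prescription", amt))
    disp_rows.append(pd.DataFrame({"person_id": pid_bm[seg_loc[rep]],
                                   "date": _dates(day), "atc_code": atc,
                                   "cost": amt}))

    for cat, vocab_name, prefix in (("aid", "aids", "AID"), ("remedy", "remedies", "REM")):
        am = config.cost_models[cat]
        rep, day = _poisson_events(am.rate_per_year, am.rate_multiplier)
        vocab = np.array(_aid_vocab(config.dimension_vocab_sizes[vocab_name], prefix))
        codes = vocab[rng.choice(len(vocab), len(rep),
                                 p=_decay_probs(len(vocab),
                                                config.code_prevalence_decay))]
        cost_rows.append(_cost_frame(rep, day, cat, _amounts(am, rep), code=codes))

    # background diagnosis / procedure dimensions -------------------------
    code_frail = np.exp(config.code_log_on_frailty * z_bm)
    span_years = np.maximum(gen_end - gen_start, 0) / DAYS_PER_YEAR

    def _background(rate: float, vocab: np.ndarray):
        lam = rate * code_frail * span_years
        nev = rng.poisson(lam)
        rep = np.repeat(np.arange(len(bm_idx)), nev)
        u = rng.random(len(rep))
        day = (gen_start[rep] + u * (gen_end[rep] - gen_start[rep])).astype(np.int64)
        codes = vocab[rng.choice(len(vocab), len(rep),
                                 p=_decay_probs(len(vocab),
                                                config.code_prevalence_decay))]
        return rep, day, codes

    icd_vocab = np.array(_icd_vocab(config.dimension_vocab_sizes["outpatient_dx"]))
    rep, day, codes = _background(config.dim_rates["outpatient_dx"], icd_vocab)
    qual = np.where(rng.random(len(rep)) < 0.9, "confirmed", "suspected")
    dx_rows.append(pd.DataFrame({"person_id": pid_bm[rep], "date": _dates(day),
                                 "code": codes, "setting": "outpatient",
                                 "qualifier": qual}))
    icd_vocab_in = np.array(_icd_vocab(config.dimension_vocab_sizes["inpatient_dx"]))
    rep, day, codes = _background(config.dim_rates["inpatient_dx"], icd_vocab_in)
    dx_rows.append(pd.DataFrame({"person_id": pid_bm[rep], "date": _dates(day),
                                 "code": codes, "setting": "inpatient",
                                 "qualifier": None}))
    for dim, setting in (("outpatient_treatment", "outpatient"),
                         ("inpatient_treatment", "inpatient")):
        vocab = np.array(_ops_vocab(config.dimension_vocab_sizes[dim], setting))
        rep, day, codes = _background(config.dim_rates[dim], vocab)
        proc_rows.append(pd.DataFrame({"person_id": pid_bm[rep], "date": _dates(day),
                                       "code": codes, "setting": setting}))

    # sick leave (working-age persons only) -------------------------------
    age_at_bm = (bm_day[bm_idx] - persons["birth_date"].to_numpy()[bm_idx]
                 .astype("datetime64[D]").astype(np.int64)) / DAYS_PER_YEAR
    working = age_at_bm < 60
    lam = 1.5 * span_years * np.exp(0.3 * z_bm) * working
    nev = rng.poisson(lam)
    rep = np.repeat(np.arange(len(bm_idx)), nev)
    u = rng.random(len(rep))
    day = (gen_start[rep] + u * (gen_end[rep] - gen_start[rep])).astype(np.int64)
    sick_rows.append(pd.DataFrame({"person_id": pid_bm[rep], "date": _dates(day),
                                   "days": rng.poisson(7, len(rep)) + 1}))

    # --- assemble ---------------------------------------------------------
    persons_out = persons.copy()
    persons_out["death_date"] = pd.NaT
    persons_out.loc[died, "death_date"] = pd.to_datetime(death_day[died], unit="D")
    enrollment = pd.DataFrame({
        "person_id": ids,
        "start_date": pd.to_datetime(enroll_start, unit="D"),
        "end_date": pd.to_datetime(
            np.maximum(np.minimum(person_end, d_end), enroll_start), unit="D")})

    def _cat_frames(frames: list[pd.DataFrame], cols: list[str]) -> pd.DataFrame:
        frames = [f for f in frames if len(f)]
        if not frames:
            return pd.DataFrame(columns=cols)
        out = pd.concat(frames, ignore_index=True)[cols]
        return out.sort_values(["person_id", "date"], kind="stable").reset_index(drop=True)

    ds = ClaimsDataset(
        persons=persons_out,
        enrollment=enrollment,
        diagnoses=_cat_frames(dx_rows, ["person_id", "date", "code", "setting",
                                        "qualifier"]),
        procedures=_cat_frames(proc_rows, ["person_id", "date", "code", "setting"]),
        dispensings=_cat_frames(disp_rows, ["person_id", "date", "atc_code", "cost"]),
        costs=_cat_frames(cost_rows, ["person_id", "date", "category", "amount",
                                      "code", "admission_date", "discharge_date",
                                      "physician_role", "physician_id"]),
        sick_leave=_cat_frames(sick_rows, ["person_id", "date", "days"]),
        config=CodeListConfig(),
    )

    truth = pd.DataFrame({
        "person_id": ids,
        "frailty": z,
        "has_bm": has_bm,
        "prevalent_bm": prevalent,
        "bm_date": pd.to_datetime(np.where(has_bm, bm_day, 0),
                                  unit="D").where(pd.Series(has_bm), pd.NaT),
        "true_sre_date": pd.to_datetime(
            np.where(sre_observed, sre_day, 0), unit="D").where(
            pd.Series(sre_observed), pd.NaT),
        "sre_type": np.where(sre_observed, sre_type, None),
        "death_date": pd.to_datetime(np.where(died, death_day, 0),
                                     unit="D").where(pd.Series(died), pd.NaT),
        "bta_pre_bm": bta_pre,
        "bta_post_date": pd.to_datetime(np.where(bta_post, bta_day, 0),
                                        unit="D").where(pd.Series(bta_post), pd.NaT),
        "st_type": st_sub,
        "st_missing": st_missing,
        "late_enrollment": late,
    })
    return ds, truth


def generate_claims(config: SimulationConfig,
                    window: StudyWindow | None = None
                    ) -> tuple[ClaimsDataset, GroundTruth]:
    """End-to-end generation: population + event histories, validated."""
    rng = np.random.default_rng(config.seed)
    persons, z = generate_population(config, rng, window)
    ds, truth = generate_event_histories(persons, z, config, rng, window)
    ds = validate_dataset(ds)
    return ds, GroundTruth(table=truth, config=config)


def true_effect_summary(ground_truth: GroundTruth,
                        person_table: pd.DataFrame | None = None) -> pd.DataFrame:
    """Configured-vs-realized effect table.

    Always reports the configured per-category cost multipliers and the implied
    total-cost multiplier.  Given a person-level outcome table (from
    :func:`sreburden.outcomes.person_level_outcomes`) it adds the realized
    crude SRE/non-SRE total-cost ratio, whose deviation from the configured
    truth is the confounding bias the matching is expected to remove.
    """
    cfg = ground_truth.config
    rows = [("cost_multiplier:" + k, v)
            for k, v in cfg.category_cost_multipliers().items()]
    rows.append(("implied_total_cost_multiplier", cfg.implied_total_cost_multiplier()))
    if person_table is not None:
        g = person_table.groupby("group")
        rate = g["cost_total"].sum() / g["person_years"].sum()
        if {"SRE", "non_SRE"} <= set(rate.index):
            rows.append(("realized_crude_total_cost_ratio",
                         float(rate["SRE"] / rate["non_SRE"])))
    return pd.DataFrame(rows, columns=["quantity", "value"])
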