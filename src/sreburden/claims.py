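"""Claims data model: record schemas, validation, readers/writers, calendar helpers.

The pipeline's sole input is a :class:`ClaimsDataset` — seven delimited tables
emulating a German statutory-insurance ("sickness fund") extract:

========================  =====================================================================
table                     columns
========================  =====================================================================
``persons.csv``           person_id, birth_date, sex, death_date
``enrollment.csv``        person_id, start_date, end_date
``diagnoses.csv``         person_id, date, code, setting, qualifier
``procedures.csv``        person_id, date, code, setting
``dispensings.csv``       person_id, date, atc_code, cost
``costs.csv``             person_id, date, category, amount, code,
                          admission_date, discharge_date, physician_role, physician_id
``sick_leave.csv``        person_id, date, days
========================  =====================================================================

Dates are ISO-8601, files UTF-8 and comma-delimited.  Outpatient diagnoses carry a
qualifier with the German G/V/A/Z semantics, named abstractly: only ``confirmed``
(G) counts toward any confirmation rule.  Outpatient claims are accounted
quarterly in Germany; dates are kept at day resolution throughout and quarter
identity is derived where a rule needs it.
"""

from __future__ import annotations

import hashlib
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SETTINGS",
    "QUALIFIERS",
    "COST_CATEGORIES",
    "SRE_TYPES",
    "ClaimsError",
    "ClaimsValidationError",
    "StudyWindow",
    "CodeListConfig",
    "ClaimsDataset",
    "normalize_icd10",
    "quarter_of",
    "quarter_key",
    "load_claims",
    "write_claims",
    "write_outputs",
]

SETTINGS = ("inpatient", "outpatient")
QUALIFIERS = ("confirmed", "suspected", "excluded", "status_post")
COST_CATEGORIES = (
    "hospitalization",
    "outpatient_visit",
    "rehabilitation",
    "prescription",
    "aid",
    "remedy",
)
SRE_TYPES = (
    "pathological_fracture",
    "spinal_cord_compression",
    "surgery_to_bone",
    "radiation_to_bone",
)

_ICD10_RE = re.compile(r"^[A-Z][0-9]{2}(\.[0-9A-Z]{0,2})?$")

TABLE_COLUMNS: dict[str, list[str]] = {
    "persons": ["person_id", "birth_date", "sex", "death_date"],
    "enrollment": ["person_id", "start_date", "end_date"],
    "diagnoses": ["person_id", "date", "code", "setting", "qualifier"],
    "procedures": ["person_id", "date", "code", "setting"],
    "dispensings": ["person_id", "date", "atc_code", "cost"],
    "costs": [
        "person_id",
        "date",
        "category",
        "amount",
        "code",
        "admission_date",
        "discharge_date",
        "physician_role",
        "physician_id",
    ],
    "sick_leave": ["person_id", "date", "days"],
}

_DATE_COLUMNS = ("birth_date", "death_date", "start_date", "end_date", "date",
                 "admission_date", "discharge_date")


class ClaimsError(Exception):
    """Base error for claims input problems."""


class ClaimsValidationError(ClaimsError):
    """Raised when records violate an invariant; carries a row-level report."""

    def __init__(self, message: str, report: pd.DataFrame | None = None):
        super().__init__(message)
        #: DataFrame with columns (table, row, problem) for each rejected record
        self.report = report if report is not None else pd.DataFrame(
            columns=["table", "row", "problem"])


def normalize_icd10(code: str) -> str:
    """Normalize an ICD-10-GM code to canonical ``A00.XX`` form.

    Uppercases, strips whitespace and trailing markers, and inserts the dot
    after the third character when missing (``c795`` -> ``C79.5``).  Raises
    :class:`ClaimsValidationError` if the result is not a valid code shape.
    """
    c = str(code).strip().upper().replace(" ", "")
    # strip German 'Ausrufezeichen'/star markers occasionally appended
    c = c.rstrip("!*+")
    if len(c) > 3 and c[3] != ".":
        c = c[:3] + "." + c[3:]
    if c.endswith("."):
        c = c[:-1]
    if not _ICD10_RE.match(c):
        raise ClaimsValidationError(f"not a valid ICD-10 code: {code!r}")
    return c


def quarter_of(date) -> tuple[int, int]:
    """Return ``(year, quarter)`` for a date; Jan–Mar -> 1 … Oct–Dec -> 4."""
    ts = pd.Timestamp(date)
    return int(ts.year), int((ts.month - 1) // 3) + 1


def quarter_key(dates) -> np.ndarray:
    """Vectorized integer quarter key ``year*4 + (quarter-1)`` for a date series."""
    d = pd.DatetimeIndex(pd.Series(dates).values)
    return (d.year * 4 + (d.month - 1) // 3).to_numpy()


@dataclass(frozen=True)
class StudyWindow:
    """Observation and inclusion windows of the study period.

    Data run 2010-01-01..2018-06-30; incident diagnoses are accepted in
    2011-01-01..2017-06-30 so that a full washout year precedes every incident
    case and at least 12 months of potential follow-up succeed every index.
    """

    data_start: pd.Timestamp = pd.Timestamp("2010-01-01")
    data_end: pd.Timestamp = pd.Timestamp("2018-06-30")
    inclusion_start: pd.Timestamp = pd.Timestamp("2011-01-01")
    inclusion_end: pd.Timestamp = pd.Timestamp("2017-06-30")

    def __post_init__(self):
        if not (self.data_start < self.inclusion_start
                < self.inclusion_end < self.data_end):
            raise ValueError("window ordering violated: need "
                             "data_start < inclusion_start < inclusion_end < data_end")


def _expand_range(lo: str, hi: str) -> tuple[str, ...]:
    """Expand an ICD chapter range like C00..C76 to 3-character prefixes."""
    letter = lo[0]
    if hi[0] != letter:
        raise ValueError(f"range must stay within one letter: {lo}-{hi}")
    return tuple(f"{letter}{i:02d}" for i in range(int(lo[1:3]), int(hi[1:3]) + 1))


@dataclass
class CodeListConfig:
    """Editable code lists driving eligibility, SRE detection and censoring.

    Defaults are documented placeholders in the shape of German coding practice
    (ICD-10-GM, OPS-like procedure codes, ATC) and must be reviewed against the
    local coding catalogue before any real-data use.
    """

    bm_codes: tuple[str, ...] = ("C79.5",)
    st_code_ranges: tuple[tuple[str, str], ...] = (("C00", "C76"),)
    #: per SRE type: ICD-10 diagnosis prefixes and/or procedure-code prefixes
    sre_definitions: dict[str, dict[str, tuple[str, ...]]] = field(default_factory=lambda: {
        "pathological_fracture": {"diagnosis_codes": ("M49.5", "M84.4"),
                                  "procedure_codes": ()},
        "spinal_cord_compression": {"diagnosis_codes": ("G95.2",),
                                    "procedure_codes": ()},
        "surgery_to_bone": {"diagnosis_codes": (),
                            "procedure_codes": ("5-78", "5-79")},
        "radiation_to_bone": {"diagnosis_codes": (),
                              "procedure_codes": ("8-52",)},
    })
    bta_atc_codes: tuple[str, ...] = ("M05BA08", "M05BA03", "M05BX04", "L01XX")
    st_subgroup_codes: tuple[str, ...] = ("C34", "C61", "C50", "C64", "C67")

    def __post_init__(self):
        if set(self.sre_definitions) != set(SRE_TYPES):
            raise ValueError(f"sre_definitions must define exactly {set(SRE_TYPES)}")

    # -- matchers ----------------------------------------------------------
    def is_bm(self, codes: pd.Series) -> pd.Series:
        return codes.isin(self.bm_codes)

    def st_prefixes(self) -> tuple[str, ...]:
        out: list[str] = []
        for lo, hi in self.st_code_ranges:
            out.extend(_expand_range(lo, hi))
        return tuple(out)

    def is_st(self, codes: pd.Series) -> pd.Series:
        return codes.astype(str).str[:3].isin(self.st_prefixes())

    def is_bta(self, atc_codes: pd.Series) -> pd.Series:
        pat = tuple(self.bta_atc_codes)
        return atc_codes.astype(str).str.startswith(pat)

    def sre_diagnosis_map(self) -> dict[str, tuple[str, ...]]:
        return {t: tuple(d.get("diagnosis_codes", ())) for t, d in self.sre_definitions.items()}

    def sre_procedure_map(self) -> dict[str, tuple[str, ...]]:
        return {t: tuple(d.get("procedure_codes", ())) for t, d in self.sre_definitions.items()}

    # -- serialization -----------------------------------------------------
    def to_yaml(self, path) -> None:
        payload = {
            "bm_codes": list(self.bm_codes),
            "st_code_ranges": [list(r) for r in self.st_code_ranges],
            "sre_definitions": {
                t: {k: list(v) for k, v in d.items()}
                for t, d in self.sre_definitions.items()
            },
            "bta_atc_codes": list(self.bta_atc_codes),
            "st_subgroup_codes": list(self.st_subgroup_codes),
        }
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "CodeListConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(
            bm_codes=tuple(raw["bm_codes"]),
            st_code_ranges=tuple(tuple(r) for r in raw["st_code_ranges"]),
            sre_definitions={t: {k: tuple(v) for k, v in d.items()}
                             for t, d in raw["sre_definitions"].items()},
            bta_atc_codes=tuple(raw["bta_atc_codes"]),
            st_subgroup_codes=tuple(raw["st_subgroup_codes"]),
        )


@dataclass
class ClaimsDataset:
    """In-memory claims extract: one DataFrame per table, schema as documented."""

    persons: pd.DataFrame
    enrollment: pd.DataFrame
    diagnoses: pd.DataFrame
    procedures: pd.DataFrame
    dispensings: pd.DataFrame
    costs: pd.DataFrame
    sick_leave: pd.DataFrame
    config: CodeListConfig = field(default_factory=CodeListConfig)

    def counts(self) -> dict[str, int]:
        return {name: len(getattr(self, name)) for name in TABLE_COLUMNS}

    def tables(self) -> dict[str, pd.DataFrame]:
        return {name: getattr(self, name) for name in TABLE_COLUMNS}

    @classmethod
    def empty(cls, config: CodeListConfig | None = None) -> "ClaimsDataset":
        frames = {name: pd.DataFrame(columns=cols) for name, cols in TABLE_COLUMNS.items()}
        for name, df in frames.items():
            frames[name] = _coerce_types(name, df)
        return cls(config=config or CodeListConfig(), **frames)


def _coerce_types(name: str, df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    for col in df.columns:
        if col in _DATE_COLUMNS:
            df[col] = pd.to_datetime(df[col], format="ISO8601", errors="coerce")
        elif col in ("amount", "cost"):
            df[col] = pd.to_numeric(df[col], errors="coerce")
        elif col == "days":
            df[col] = pd.to_numeric(df[col], errors="coerce").fillna(0).astype(int)
        elif col == "person_id":
            df[col] = df[col].astype(str)
    return df


def _validate_table(name: str, df: pd.DataFrame,
                    problems: list[tuple[str, int, str]]) -> pd.DataFrame:
    """Type-coerce one table and record row-level invariant violations."""
    missing = [c for c in TABLE_COLUMNS[name] if c not in df.columns]
    if missing:
        raise ClaimsValidationError(f"table {name!r} missing columns {missing}")
    df = _coerce_types(name, df[TABLE_COLUMNS[name]])

    def flag(mask: pd.Series, problem: str):
        for row in df.index[mask.fillna(False)]:
            problems.append((name, int(row), problem))

    if name == "persons":
        flag(df["person_id"].duplicated(), "duplicate person_id")
        flag(df["birth_date"].isna(), "malformed birth_date")
        flag(~df["sex"].isin(["female", "male"]), "sex must be female|male")
        has_death = df["death_date"].notna()
        flag(has_death & (df["death_date"] < df["birth_date"]),
             "death_date before birth_date")
    elif name == "enrollment":
        flag(df["start_date"].isna() | df["end_date"].isna(), "malformed date")
        flag(df["end_date"] < df["start_date"], "enrollment end before start")
    elif name == "diagnoses":
        flag(df["date"].isna(), "malformed date")
        flag(~df["setting"].isin(SETTINGS), "setting must be inpatient|outpatient")
        norm = []
        bad = np.zeros(len(df), dtype=bool)
        for i, c in enumerate(df["code"]):
            try:
                norm.append(normalize_icd10(c))
            except ClaimsError:
                norm.append(str(c))
                bad[i] = True
        df["code"] = norm
        flag(pd.Series(bad, index=df.index), "malformed ICD-10 code")
        inpatient = df["setting"] == "inpatient"
        flag(inpatient & df["qualifier"].notna(), "inpatient diagnosis with qualifier")
        flag(~inpatient & ~df["qualifier"].isin(QUALIFIERS), "unknown qualifier")
    elif name == "procedures":
        flag(df["date"].isna(), "malformed date")
        flag(~df["setting"].isin(SETTINGS), "setting must be inpatient|outpatient")
    elif name == "dispensings":
        flag(df["date"].isna(), "malformed date")
        flag(df["cost"].isna() | (df["cost"] < 0), "cost must be >= 0")
    elif name == "costs":
        flag(df["date"].isna(), "malformed date")
        flag(~df["category"].isin(COST_CATEGORIES),
             f"category must be one of {COST_CATEGORIES}")
        flag(df["amount"].isna() | (df["amount"] < 0), "amount must be >= 0")
        hosp = df["category"] == "hospitalization"
        flag(hosp & (df["admission_date"].isna() | df["discharge_date"].isna()),
             "hospitalization item without admission/discharge dates")
        flag(hosp & (df["discharge_date"] < df["admission_date"]),
             "discharge before admission")
    elif name == "sick_leave":
        flag(df["date"].isna(), "malformed date")
        flag(pd.Series(df["days"].to_numpy() < 0, index=df.index), "days must be >= 0")
    return df


def _normalize_enrollment(df: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping or abutting (gap 0 day) intervals per person."""
    if df.empty:
        return df
    df = df.sort_values(["person_id", "start_date"]).reset_index(drop=True)
    merged = []
    n_merged = 0
    for pid, g in df.groupby("person_id", sort=False):
        cur_s, cur_e = None, None
        for s, e in zip(g["start_date"], g["end_date"]):
            if cur_s is None:
                cur_s, cur_e = s, e
            elif s <= cur_e + pd.Timedelta(days=1):
                cur_e = max(cur_e, e)
                n_merged += 1
            else:
                merged.append((pid, cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append((pid, cur_s, cur_e))
    if n_merged:
        warnings.warn(f"normalized {n_merged} overlapping/abutting enrollment intervals",
                      stacklevel=3)
    return pd.DataFrame(merged, columns=["person_id", "start_date", "end_date"])


def validate_dataset(ds: ClaimsDataset) -> ClaimsDataset:
    """Validate all tables against the type invariants; raise on any violation."""
    problems: list[tuple[str, int, str]] = []
    frames = {}
    for name in TABLE_COLUMNS:
        frames[name] = _validate_table(name, getattr(ds, name), problems)
    if problems:
        report = pd.DataFrame(problems, columns=["table", "row", "problem"])
        head = report.head(10).to_string(index=False)
        raise ClaimsValidationError(
            f"{len(problems)} invalid record(s); first rows:\n{head}", report)
    frames["enrollment"] = _normalize_enrollment(frames["enrollment"])
    return ClaimsDataset(config=ds.config, **frames)


def load_claims(path: str | Path | Mapping[str, str | Path],
                config: CodeListConfig | None = None) -> ClaimsDataset:
    """Read the claims tables from a directory (or per-table path mapping).

    All records are validated against the type invariants; malformed dates or
    codes raise :class:`ClaimsValidationError` whose ``report`` attribute lists
    the offending table and row numbers.  Overlapping enrollment intervals are
    normalized with a warning.  A missing ``sick_leave.csv`` is treated as an
    empty stream.
    """
    if isinstance(path, (str, Path)):
        base = Path(path)
        paths = {name: base / f"{name}.csv" for name in TABLE_COLUMNS}
    else:
        paths = {name: Path(p) for name, p in path.items()}
    frames = {}
    for name in TABLE_COLUMNS:
        p = paths.get(name)
        if p is None or not Path(p).exists():
            if name == "sick_leave":
                frames[name] = pd.DataFrame(columns=TABLE_COLUMNS[name])
                continue
            raise ClaimsError(f"missing input table: {name} ({p})")
        frames[name] = pd.read_csv(p, dtype={"person_id": str})
    ds = ClaimsDataset(config=config or CodeListConfig(), **frames)
    return validate_dataset(ds)


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    out = df.copy()
    for col in out.columns:
        if col in _DATE_COLUMNS and len(out):
            out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def write_claims(ds: ClaimsDataset, out_dir: str | Path) -> pd.DataFrame:
    """Write the seven claims tables to ``out_dir``; returns the file manifest."""
    return write_outputs(ds.tables(), out_dir)


def write_outputs(tables: Mapping[str, pd.DataFrame], out_dir: str | Path) -> pd.DataFrame:
    """Write tables as CSV with deterministic column order; return a manifest.

    The manifest lists (file, rows, sha256) per table and is itself written to
    ``manifest.csv``.  Writing the same tables twice yields identical checksums.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for name in sorted(tables):
        df = tables[name]
        path = out / f"{name}.csv"
        _write_csv(df.reset_index(drop=True), path)
        digest = hashlib.sha256(path.read_bytes()).hexdigest()
        rows.append((path.name, len(df), digest))
    manifest = pd.DataFrame(rows, columns=["file", "rows", "sha256"])
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
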