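"""Shared fixtures: a hand-rolled tiny-claims builder and session-scoped
synthetic pipeline runs used across test modules."""

from __future__ import annotations

import warnings
from dataclasses import replace

import pandas as pd
import pytest

from sreburden.claims import ClaimsDataset, CodeListConfig, TABLE_COLUMNS, validate_dataset
from sreburden.pipeline import PipelineConfig, run_pipeline
from sreburden.simulate import SimulationConfig

warnings.filterwarnings("ignore", message=".*clamped.*")


def make_dataset(persons=None, enrollment=None, diagnoses=None, procedures=None,
                 dispensings=None, costs=None, sick_leave=None,
                 config: CodeListConfig | None = None,
                 validate: bool = True) -> ClaimsDataset:
    """Build a small claims dataset from lists of dicts, with full defaults.

    Persons default to one enrollment interval covering the whole data window.
    """
    persons = persons or []
    frames = {}

    def frame(rows, table):
        df = pd.DataFrame(rows or [], columns=TABLE_COLUMNS[table])
        return df

    frames["persons"] = frame(persons, "persons")
    if enrollment is None and persons:
        enrollment = [{"person_id": p["person_id"], "start_date": "2010-01-01",
                       "end_date": "2018-06-30"} for p in persons]
    frames["enrollment"] = frame(enrollment, "enrollment")
    frames["diagnoses"] = frame(diagnoses, "diagnoses")
    frames["procedures"] = frame(procedures, "procedures")
    frames["dispensings"] = frame(dispensings, "dispensings")
    frames["costs"] = frame(costs, "costs")
    frames["sick_leave"] = frame(sick_leave, "sick_leave")
    ds = ClaimsDataset(config=config or CodeListConfig(), **frames)
    return validate_dataset(ds) if validate else ds


def person(pid, birth="1950-06-15", sex="male", death=None):
    return {"person_id": pid, "birth_date": birth, "sex": sex, "death_date": death}


def dx(pid, date, code, setting="inpatient", qualifier=None):
    if setting == "outpatient" and qualifier is None:
        qualifier = "confirmed"
    return {"person_id": pid, "date": date, "code": code, "setting": setting,
            "qualifier": qualifier}


def cost(pid, date, category, amount, **meta):
    row = {"person_id": pid, "date": date, "category": category,
           "amount": amount, "code": None, "admission_date": None,
           "discharge_date": None, "physician_role": None, "physician_id": None}
    if category == "hospitalization":
        row["admission_date"] = meta.pop("admission", date)
        row["discharge_date"] = meta.pop("discharge", date)
    row.update(meta)
    return row


@pytest.fixture(scope="session")
def small_sim():
    """Moderate synthetic world (n=2000) shared by structural tests."""
    from sreburden.simulate import generate_claims
    cfg = replace(SimulationConfig(), n_persons=2000, seed=11)
    ds, truth = generate_claims(cfg)
    return cfg, ds, truth


@pytest.fixture(scope="session")
def small_pipeline():
    """Full pipeline run (n=4000) shared by matching/outcome property tests."""
    cfg = PipelineConfig(sim=replace(SimulationConfig(), n_persons=4000, seed=5),
                         n_boot=100)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_pipeline(cfg)
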