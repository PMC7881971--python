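"""One-call orchestration: simulate -> cohorts -> hdPS match -> outcomes.

Every stochastic stage takes an explicit seed; a run writes its configuration
and a manifest (versions, seeds, row counts, wall time per stage) next to its
outputs, so any result directory is self-describing and reproducible.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .claims import ClaimsDataset, StudyWindow, load_claims, write_outputs
from .cohort import CohortResult, build_cohorts
from .comorbidity import compute_baseline_covariates
from .hdps import (MatchedPairs, balance_table, baseline_code_counts,
                   build_recurrence_covariates, enumerate_candidate_codes,
                   fit_propensity_model, match_nearest_neighbor,
                   prioritize_covariates)
from .outcomes import (compute_followups, cumulative_monthly_costs,
                       mortality_stratified_costs, outcomes_table,
                       person_level_outcomes, subgroup_analysis)
from .simulate import GroundTruth, SimulationConfig, generate_claims

log = logging.getLogger("sreburden")

# the four covariates the propensity model always receives, plus the two raw
# baseline-utilization counts that the matched baseline table also balances
FORCED_COVARIATES = ["age_at_index", "female", "sick_leave_days", "cci",
                     "n_hospitalizations", "n_gp_visits"]


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run (seeds are per stage)."""

    sim: SimulationConfig = field(default_factory=SimulationConfig)
    window: StudyWindow = field(default_factory=StudyWindow)
    seed_cohort: int = 1
    seed_match: int = 2
    seed_outcomes: int = 3
    k_per_dimension: int = 100
    caliper: float = 0.01
    ridge: float = 1e-4
    min_prevalence: float = 0.01
    ranking_method: str = "exposure_assoc"
    pooled_top_k: bool = False
    n_boot: int = 500
    monthly_horizon: int = 24
    write_claims_tables: bool = False

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, pd.Timestamp):
                return o.strftime("%Y-%m-%d")
            raise TypeError(o)
        return json.dumps(asdict(self), indent=2, default=default)


@dataclass
class MatchingResult:
    covariates: pd.DataFrame      # forced covariates, indexed by person_id
    selected: pd.DataFrame        # selected empirical covariates with priority
    scores: pd.Series             # propensity score per person
    matched: MatchedPairs
    balance: pd.DataFrame


def run_matching(ds: ClaimsDataset, cohort: pd.DataFrame,
                 k_per_dimension: int = 100, caliper: float = 0.01,
                 ridge: float = 1e-4, min_prevalence: float = 0.01,
                 ranking_method: str = "exposure_assoc",
                 pooled_top_k: bool = False, seed: int = 0,
                 proxy_outcome: pd.Series | None = None) -> MatchingResult:
    """hdPS covariate selection, propensity model and 1:1 caliper matching."""
    forced = compute_baseline_covariates(ds, cohort).set_index("person_id")
    index_dates = cohort.set_index("person_id")["index_date"]
    exposure = (cohort.set_index("person_id")["group"] == "SRE").astype(int)

    counts = baseline_code_counts(ds, index_dates)
    candidates = enumerate_candidate_codes(counts, len(cohort), min_prevalence)
    cov_matrix, meta = build_recurrence_covariates(counts, candidates,
                                                  forced.index)
    selected = prioritize_covariates(cov_matrix, meta, exposure,
                                     k_per_dimension, method=ranking_method,
                                     proxy_outcome=proxy_outcome,
                                     pooled=pooled_top_k)
    model = fit_propensity_model(cov_matrix[selected["name"].tolist()],
                                 forced[FORCED_COVARIATES], exposure,
                                 ridge=ridge)
    scores = model.scores
    matched = match_nearest_neighbor(scores[exposure == 1], scores[exposure == 0],
                                     caliper=caliper, seed=seed)
    balance = balance_table(forced[FORCED_COVARIATES], exposure, matched)
    return MatchingResult(covariates=forced, selected=selected, scores=scores,
                          matched=matched, balance=balance)


@dataclass
class PipelineResult:
    config: PipelineConfig
    dataset: ClaimsDataset
    ground_truth: GroundTruth
    cohorts: CohortResult
    matching: MatchingResult
    person_table_crude: pd.DataFrame
    person_table_matched: pd.DataFrame
    followups_matched: pd.DataFrame
    table3: pd.DataFrame
    table4_sre: pd.DataFrame
    table4_st: pd.DataFrame
    fig5: pd.DataFrame
    fig6: pd.DataFrame
    manifest: dict

    def crude_total_cost_ratio(self) -> float:
        g = self.person_table_crude.groupby("group")
        r = g["cost_total"].sum() / g["person_years"].sum()
        return float(r["SRE"] / r["non_SRE"])

    def matched_total_cost_ratio(self) -> float:
        row = self.table3.set_index("outcome").loc["cost_total"]
        return float(row["ratio"])


def run_pipeline(config: PipelineConfig,
                 dataset: ClaimsDataset | None = None,
                 out_dir: str | Path | None = None) -> PipelineResult:
    """Execute the full analysis; optionally persist all stage outputs.

    ``dataset`` may be a pre-loaded claims extract; otherwise the synthetic
    generator runs with ``config.sim``.  Any stage failure raises with the
    stage name in the message.
    """
    manifest: dict = {"version": __version__, "stages": {}, "seeds": {
        "sim": config.sim.seed, "cohort": config.seed_cohort,
        "match": config.seed_match, "outcomes": config.seed_outcomes}}

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:  # annotate with stage context
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        manifest["stages"][name] = {"seconds": round(time.perf_counter() - t0, 2)}
        log.info("stage %s done in %.1fs", name, manifest["stages"][name]["seconds"])
        return result

    if dataset is None:
        ds, truth = stage("simulate", lambda: generate_claims(config.sim, config.window))
    else:
        ds, truth = dataset, GroundTruth(table=pd.DataFrame(), config=config.sim)
    manifest["stages"].setdefault("simulate", {})["rows"] = ds.counts()

    cohorts = stage("cohorts", lambda: build_cohorts(ds, config.window,
                                                     seed=config.seed_cohort))
    manifest["stages"]["cohorts"]["rows"] = {
        "cohort": len(cohorts.cohort),
        "sre": int((cohorts.cohort["group"] == "SRE").sum()),
        "non_sre": int((cohorts.cohort["group"] == "non_SRE").sum())}

    matching = stage("match", lambda: run_matching(
        ds, cohorts.cohort, config.k_per_dimension, config.caliper,
        config.ridge, config.min_prevalence, config.ranking_method,
        config.pooled_top_k, seed=config.seed_match))
    manifest["stages"]["match"]["rows"] = {"pairs": len(matching.matched.pairs),
                                           "covariates": len(matching.selected)}

    def _outcomes():
        fu_all = compute_followups(cohorts.cohort, ds, config.window)
        pt_all = person_level_outcomes(ds, fu_all)
        ids = matching.matched.matched_ids()
        cohort_m = cohorts.cohort[cohorts.cohort["person_id"].isin(ids)]
        fu_m = fu_all[fu_all["person_id"].isin(ids)]
        pt_m = pt_all[pt_all["person_id"].isin(ids)]
        t3 = outcomes_table(pt_m, n_boot=config.n_boot, seed=config.seed_outcomes)
        t4a = subgroup_analysis(pt_m, cohort_m, "sre_type")
        t4b = subgroup_analysis(pt_m, cohort_m, "st_type")
        fig5 = mortality_stratified_costs(pt_m)
        fig6 = cumulative_monthly_costs(ds, fu_m, horizon=config.monthly_horizon)
        return fu_all, pt_all, fu_m, pt_m, t3, t4a, t4b, fig5, fig6

    fu_all, pt_all, fu_m, pt_m, t3, t4a, t4b, fig5, fig6 = stage("outcomes", _outcomes)
    manifest["stages"]["outcomes"]["rows"] = {"followed": len(fu_all),
                                              "matched_followed": len(fu_m)}

    result = PipelineResult(config=config, dataset=ds, ground_truth=truth,
                            cohorts=cohorts, matching=matching,
                            person_table_crude=pt_all, person_table_matched=pt_m,
                            followups_matched=fu_m, table3=t3, table4_sre=t4a,
                            table4_st=t4b, fig5=fig5, fig6=fig6,
                            manifest=manifest)
    if out_dir is not None:
        write_results(result, out_dir)
    return result


def write_results(result: PipelineResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "pipeline_config.json").write_text(result.config.to_json())
    tables = {
        "cohort": result.cohorts.cohort,
        "attrition": result.cohorts.attrition,
        "pairs": result.matching.matched.pairs,
        "scores": result.matching.scores.rename("score").rename_axis("person_id")
                       .reset_index(),
        "balance": result.matching.balance,
        "selected_covariates": result.matching.selected,
        "table3": result.table3,
        "table4_sre": result.table4_sre,
        "table4_st": result.table4_st,
        "fig5_data": result.fig5,
        "fig6_data": result.fig6,
    }
    if result.config.write_claims_tables:
        tables.update(result.dataset.tables())
        if len(result.ground_truth.table):
            tables["ground_truth"] = result.ground_truth.table
    manifest = write_outputs(tables, out)
    result.manifest["files"] = manifest.to_dict("records")
    (out / "run_manifest.json").write_text(json.dumps(result.manifest, indent=2))


_REPORT_SECTIONS = (
    ("Attrition", "attrition.csv"),
    ("Baseline balance", "balance.csv"),
    ("Outcomes (per patient-year)", "table3.csv"),
    ("SRE-type subgroups", "table4_sre.csv"),
    ("Solid-tumor-type subgroups", "table4_st.csv"),
    ("Costs by vital status", "fig5_data.csv"),
    ("Cumulative monthly costs", "fig6_data.csv"),
)


def render_report(results_dir: str | Path) -> str:
    """Markdown report with the attrition, balance, outcome and subgroup tables.

    Missing inputs produce a flagged gap instead of failing, so a partial run
    still renders a partial report.  Rendering is deterministic.
    """
    base = Path(results_dir)
    parts = ["# SRE burden analysis report", ""]
    for title, fname in _REPORT_SECTIONS:
        parts.append(f"## {title}")
        path = base / fname
        if not path.exists():
            parts.append(f"_missing: {fname}_")
        else:
            df = pd.read_csv(path)
            parts.append("```")
            parts.append(df.round(4).to_string(index=False))
            parts.append("```")
        parts.append("")
    return "\n".join(parts)
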