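"""Follow-up censoring, pooled per-patient-year rates, rate ratios, subgroup
and time-series outputs."""

import warnings
from dataclasses import replace
from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from sreburden.claims import StudyWindow
from sreburden.outcomes import (HCRU_OUTCOMES, COST_OUTCOMES,
                                compute_followups, cumulative_monthly_costs,
                                mortality_stratified_costs, person_level_outcomes,
                                rate_ppy, rate_ratio, subgroup_analysis)
from sreburden.outcomes import test_baseline_difference as baseline_difference_test
from .conftest import make_dataset, person, dx, cost


def _cohort_row(pid="p1", group="SRE", bm="2013-06-01", index="2013-09-01",
                death=None):
    return {"person_id": pid, "bm_date": pd.Timestamp(bm), "group": group,
            "index_date": pd.Timestamp(index),
            "death_date": pd.Timestamp(death) if death else pd.NaT}


class TestFollowUp:
    def _fu(self, ds, rows):
        cohort = pd.DataFrame(rows)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return compute_followups(cohort, ds).set_index("person_id")

    def test_no_events_runs_to_data_end(self):
        ds = make_dataset(persons=[person("p1")])
        fu = self._fu(ds, [_cohort_row()])
        assert fu.loc["p1", "end"] == pd.Timestamp("2018-06-30")
        assert fu.loc["p1", "end_reason"] == "data_end"

    def test_death_before_bta_wins(self):
        ds = make_dataset(
            persons=[person("p1", death="2014-01-01")],
            dispensings=[{"person_id": "p1", "date": "2014-03-01",
                          "atc_code": "M05BA08", "cost": 300.0}])
        fu = self._fu(ds, [_cohort_row(death="2014-01-01")])
        assert fu.loc["p1", "end_reason"] == "death"
        assert fu.loc["p1", "end"] == pd.Timestamp("2014-01-01")

    def test_non_sre_censored_at_later_sre(self):
        ds = make_dataset(
            persons=[person("p1")],
            diagnoses=[dx("p1", "2013-06-01", "C79.5"),
                       dx("p1", "2013-10-11", "M84.46")],  # 40 d post-index
            dispensings=[{"person_id": "p1", "date": "2013-10-31",
                          "atc_code": "M05BA08", "cost": 300.0}])
        fu = self._fu(ds, [_cohort_row(group="non_SRE")])
        assert fu.loc["p1", "end_reason"] == "later_sre"
        assert fu.loc["p1", "end"] == pd.Timestamp("2013-10-11")

    def test_sre_group_not_censored_by_later_sre(self):
        ds = make_dataset(
            persons=[person("p1")],
            diagnoses=[dx("p1", "2013-06-01", "C79.5"),
                       dx("p1", "2013-10-11", "M84.46")])
        fu = self._fu(ds, [_cohort_row(group="SRE")])
        assert fu.loc["p1", "end_reason"] == "data_end"

    def test_minimum_follow_up_one_day(self):
        ds = make_dataset(persons=[person("p1", death="2013-09-01")])
        fu = self._fu(ds, [_cohort_row(death="2013-09-01")])
        assert fu.loc["p1", "person_years"] == pytest.approx(1 / 365.25)


class TestRates:
    def test_zero_events(self):
        assert rate_ppy(0, 10.0) == 0.0

    def test_pooled_rate_is_not_mean_of_ratios(self):
        """10 events over 0.5 + 1.5 py pool to 5.0 ppy (mean of per-person
        ratios would give 12.5)."""
        assert rate_ppy(10, 0.5 + 1.5) == pytest.approx(5.0)

    def test_cost_rate(self):
        assert rate_ppy(46_000, 2.0) == pytest.approx(23_000)

    def test_zero_person_time_rejected(self):
        with pytest.raises(ValueError):
            rate_ppy(1, 0.0)

    def test_printed_total_cost_ratio(self):
        rr = rate_ratio("cost_total", [23689.54], [1.0], [20403.27], [1.0],
                        n_boot=10, seed=0)
        assert round(rr.ratio, 2) == 1.16

    def test_equal_rates_ratio_one(self):
        rr = rate_ratio("x", [5.0, 5.0], [1.0, 1.0], [10.0], [2.0],
                        n_boot=10, seed=0)
        assert rr.ratio == pytest.approx(1.0)

    def test_specialist_visit_ratio(self):
        rr = rate_ratio("visits", [12.70], [1.0], [12.07], [1.0],
                        n_boot=10, seed=0)
        assert round(rr.ratio, 2) == 1.05

    def test_zero_denominator_flagged(self):
        rr = rate_ratio("x", [1.0], [1.0], [0.0], [1.0], n_boot=10, seed=0)
        assert np.isnan(rr.ratio) and np.isnan(rr.p_value)


class TestAggregation:
    def _ds(self):
        return make_dataset(
            persons=[person("p1")],
            diagnoses=[dx("p1", "2014-02-02", "M84.46")],  # during the stay
            costs=[
                # admission 5 days before censoring, discharge 5 days after
                cost("p1", "2014-02-24", "hospitalization", 5000.0,
                     admission="2014-02-24", discharge="2014-03-06"),
                # admission fully outside follow-up
                cost("p1", "2015-01-01", "hospitalization", 4000.0,
                     admission="2015-01-01", discharge="2015-01-10"),
                # SRE-coded admission during follow-up
                cost("p1", "2014-02-01", "hospitalization", 3000.0,
                     admission="2014-02-01", discharge="2014-02-06"),
                cost("p1", "2014-02-10", "prescription", 50.0),
                cost("p1", "2014-05-10", "prescription", 70.0),  # after end
            ])

    def _followups(self):
        return pd.DataFrame({
            "person_id": ["p1"], "group": ["SRE"],
            "start": [pd.Timestamp("2014-01-01")],
            "end": [pd.Timestamp("2014-03-01")],
            "end_reason": ["bta_initiation"], "person_years": [59 / 365.25]})

    def test_interval_truncation_and_censoring(self):
        pt = person_level_outcomes(self._ds(), self._followups()).set_index("person_id")
        # straddling admission contributes exactly 5 in-window nights
        assert pt.loc["p1", "hospitalization_days"] == 5 + 5
        assert pt.loc["p1", "n_hospitalizations"] == 2  # outside-FU one excluded
        assert pt.loc["p1", "n_prescriptions"] == 1     # post-censoring excluded
        assert pt.loc["p1", "cost_prescriptions"] == 50.0

    def test_sre_related_subset_of_all_cause(self):
        pt = person_level_outcomes(self._ds(), self._followups()).set_index("person_id")
        assert pt.loc["p1", "n_sre_hospitalizations"] == 1
        assert pt.loc["p1", "n_hospitalizations"] >= pt.loc["p1", "n_sre_hospitalizations"]
        assert pt.loc["p1", "sre_hospitalization_days"] == 5

    def test_additivity_total_equals_category_sum(self, small_pipeline):
        pt = small_pipeline.person_table_matched
        parts = pt[list(COST_OUTCOMES[:-1])].sum(axis=1)
        assert np.allclose(parts, pt["cost_total"])

    def test_pooling_identity_against_enumeration_oracle(self, small_pipeline):
        """Group ppy rate equals sum(events)/sum(years) enumerated per person."""
        pt = small_pipeline.person_table_matched
        t3 = small_pipeline.table3.set_index("outcome")
        for outcome in ("n_hospitalizations", "cost_total", "n_gp_visits"):
            for group, col in (("SRE", "rate_sre"), ("non_SRE", "rate_non_sre")):
                g = pt[pt["group"] == group]
                num = sum(g[outcome].to_numpy())   # explicit per-person scan
                den = sum(g["person_years"].to_numpy())
                assert t3.loc[outcome, col] == pytest.approx(num / den)

    def test_no_event_after_followup_end_contributes(self, small_pipeline):
        """Adversarial: shifting every cost record past the data end zeroes
        every cost aggregate."""
        ds = small_pipeline.dataset
        import dataclasses
        shifted = dataclasses.replace(
            ds, costs=ds.costs.assign(
                date=ds.costs["date"] + pd.Timedelta(days=4000),
                admission_date=ds.costs["admission_date"] + pd.Timedelta(days=4000),
                discharge_date=ds.costs["discharge_date"] + pd.Timedelta(days=4000)))
        fu = small_pipeline.followups_matched
        pt = person_level_outcomes(shifted, fu)
        assert pt["cost_total"].sum() == 0
        assert pt["hospitalization_days"].sum() == 0


class TestSubgroups:
    def test_partition_sizes_sum_to_sre_cohort(self, small_pipeline):
        pt = small_pipeline.person_table_matched
        coh = small_pipeline.cohorts.cohort
        t4 = subgroup_analysis(pt, coh, "sre_type")
        sizes = t4[t4["outcome"] == "cost_total"]["n"].sum()
        assert sizes == (pt["group"] == "SRE").sum()

    def test_invalid_subgroup_key_rejected(self, small_pipeline):
        with pytest.raises(ValueError):
            subgroup_analysis(small_pipeline.person_table_matched,
                              small_pipeline.cohorts.cohort, "sex")

    def test_lung_cancer_has_highest_total_cost(self, small_pipeline):
        """The configured lung-cancer cost factor is the largest, so the lung
        subgroup must carry the highest total cost ppy."""
        t4 = subgroup_analysis(small_pipeline.person_table_matched,
                               small_pipeline.cohorts.cohort, "st_type")
        tot = t4[t4["outcome"] == "cost_total"].set_index("subgroup")["rate_ppy"]
        assert tot.idxmax() == "C34"


class TestMortalityStratified:
    def test_cells_partition_cohort(self, small_pipeline):
        cells = mortality_stratified_costs(small_pipeline.person_table_matched)
        assert cells["n"].sum() == len(small_pipeline.person_table_matched)

    def test_all_survivors_flags_empty_deceased_cells(self):
        pt = pd.DataFrame({"person_id": ["a", "b"], "group": ["SRE", "non_SRE"],
                           "person_years": [1.0, 1.0], "deceased": [0, 0],
                           "cost_total": [100.0, 90.0]})
        cells = mortality_stratified_costs(pt).set_index(["group", "vital_status"])
        assert cells.loc[("SRE", "deceased"), "n"] == 0
        assert np.isnan(cells.loc[("SRE", "deceased"), "cost_total_ppy"])

    def test_end_of_life_spike_raises_deceased_costs(self):
        """With a strong terminal-phase boost, deceased patients cost more ppy
        than survivors in both groups."""
        from sreburden.simulate import SimulationConfig, generate_claims
        from sreburden.cohort import build_cohorts
        cfg = replace(SimulationConfig(), n_persons=4000, seed=55,
                      eol_rate_multiplier=3.0, eol_days=60)
        ds, _ = generate_claims(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            coh = build_cohorts(ds, seed=1)
            fu = compute_followups(coh.cohort, ds)
            pt = person_level_outcomes(ds, fu)
        cells = mortality_stratified_costs(pt).set_index(["group", "vital_status"])
        for grp in ("SRE", "non_SRE"):
            assert cells.loc[(grp, "deceased"), "cost_total_ppy"] > \
                cells.loc[(grp, "survived"), "cost_total_ppy"]


class TestMonthlySeries:
    def _ds_constant(self, amounts={"SRE": 100.0, "non_SRE": 100.0}):
        costs = []
        persons = []
        rows = []
        for grp, amt in amounts.items():
            pid = f"p_{grp}"
            persons.append(person(pid))
            rows.append({"person_id": pid, "group": grp,
                         "start": pd.Timestamp("2013-01-01"),
                         "end": pd.Timestamp("2015-01-01"),
                         "end_reason": "data_end", "person_years": 2.0})
            # one cost event at each month midpoint
            for m in range(24):
                day = pd.Timestamp("2013-01-01") + pd.Timedelta(
                    days=int(365.25 / 12 * m + 10))
                costs.append(cost(pid, day.strftime("%Y-%m-%d"),
                                  "prescription", amt))
        ds = make_dataset(persons=persons, costs=costs)
        return ds, pd.DataFrame(rows)

    def test_constant_equal_costs_give_unit_ratio(self):
        ds, fu = self._ds_constant()
        out = cumulative_monthly_costs(ds, fu, horizon=24)
        assert np.allclose(out["difference"], 0.0)
        assert np.allclose(out["ratio"], 1.0)

    def test_constant_ratio_is_closed_form(self):
        ds, fu = self._ds_constant({"SRE": 125.0, "non_SRE": 100.0})
        out = cumulative_monthly_costs(ds, fu, horizon=24)
        assert np.allclose(out["ratio"], 1.25)
        assert np.allclose(out["difference"], 25.0, atol=0.05)

    def test_censored_person_contributes_fractional_month(self):
        rows = [{"person_id": "p1", "group": "SRE",
                 "start": pd.Timestamp("2013-01-01"),
                 "end": pd.Timestamp("2013-01-16"),  # half a month
                 "end_reason": "death", "person_years": 15 / 365.25}]
        ds = make_dataset(persons=[person("p1")],
                          costs=[cost("p1", "2013-01-10", "prescription", 60.0)])
        out = cumulative_monthly_costs(ds, pd.DataFrame(rows), horizon=2)
        frac = 15 / (365.25 / 12)
        assert out["cost_pm_SRE"].iloc[0] == pytest.approx(60.0 / frac)
        # no one at risk in month 2 -> flagged, not imputed
        assert out["cost_pm_SRE"].iloc[1] == pytest.approx(60.0 / frac)

    def test_invalid_horizon(self):
        ds, fu = self._ds_constant()
        with pytest.raises(ValueError):
            cumulative_monthly_costs(ds, fu, horizon=0)


class TestBaselineTests:
    def test_identical_groups_p_near_one(self):
        x = np.arange(20, dtype=float)
        assert baseline_difference_test(x, x, "continuous_skewed") > 0.9
        b = np.array([0, 1] * 10, dtype=float)
        assert baseline_difference_test(b, b, "binary") > 0.9

    def test_mwu_matches_exhaustive_permutation(self):
        """3-vs-3 Mann-Whitney p equals brute force over all 20 splits."""
        x1 = np.array([1.0, 4.0, 6.0])
        x0 = np.array([2.0, 3.0, 5.0])
        pooled = np.concatenate([x1, x0])

        def u_stat(a, b):
            return sum((ai > bj) + 0.5 * (ai == bj) for ai in a for bj in b)

        observed = u_stat(x1, x0)
        n = len(pooled)
        count = 0
        total = 0
        for idx in combinations(range(n), 3):
            a = pooled[list(idx)]
            b = pooled[[i for i in range(n) if i not in idx]]
            u = u_stat(a, b)
            # two-sided: as or more extreme in either direction
            if abs(u - 4.5) >= abs(observed - 4.5) - 1e-12:
                count += 1
            total += 1
        exact_p = count / total
        got = baseline_difference_test(x1, x0, "continuous_skewed")
        assert got == pytest.approx(exact_p)

    def test_chi_squared_matches_hand_formula(self):
        """2x2 table built from printed-style proportions reproduces the
        closed-form Pearson statistic."""
        x1 = np.repeat([1.0, 0.0], [42, 58])
        x0 = np.repeat([1.0, 0.0], [35, 65])
        table = np.array([[42, 58], [35, 65]], dtype=float)
        n = table.sum()
        exp = np.outer(table.sum(1), table.sum(0)) / n
        stat = ((table - exp) ** 2 / exp).sum()
        from scipy.stats import chi2
        expected_p = float(chi2.sf(stat, 1))
        got = baseline_difference_test(x1, x0, "binary")
        assert got == pytest.approx(expected_p)

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError):
            baseline_difference_test([1.0], [2.0, 3.0], "binary")
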