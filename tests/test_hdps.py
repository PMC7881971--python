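"""High-dimensional propensity score: covariate construction, prioritization,
model fitting, caliper matching (with an exhaustive oracle) and balance."""

import itertools
import warnings
from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from sreburden.hdps import (build_recurrence_covariates, dimension_events,
                            enumerate_candidate_codes, fit_propensity_model,
                            match_nearest_neighbor, prioritize_covariates,
                            standardized_difference)


def _counts(rows):
    return pd.DataFrame(rows, columns=["person_id", "dimension", "code", "count"])


class TestCandidateCodes:
    def test_direct_prevalence_count(self):
        rows = [(f"p{i}", "rx", "A01AA01", 1) for i in range(40)]
        prev = enumerate_candidate_codes(_counts(rows), n_persons=100)
        assert prev["prevalence"].iloc[0] == pytest.approx(0.40)

    def test_universal_code_excluded_as_zero_variance(self):
        rows = [(f"p{i}", "rx", "A01AA01", 2) for i in range(100)]
        prev = enumerate_candidate_codes(_counts(rows), n_persons=100)
        assert len(prev) == 0

    def test_rare_code_discarded(self):
        rows = [("p0", "rx", "A01AA01", 1)]
        prev = enumerate_candidate_codes(_counts(rows), n_persons=1000)
        assert len(prev) == 0

    def test_empty_dimension_empty_table(self):
        prev = enumerate_candidate_codes(_counts([]), n_persons=10)
        assert len(prev) == 0


class TestRecurrence:
    def _build(self, counts_per_person):
        rows = [(f"p{i}", "rx", "X", c) for i, c in enumerate(counts_per_person)]
        counts = _counts(rows)
        cand = pd.DataFrame({"dimension": ["rx"], "code": ["X"],
                             "prevalence": [0.5]})
        persons = pd.Index([f"p{i}" for i in range(len(counts_per_person) + 2)])
        return build_recurrence_covariates(counts, cand, persons)

    def test_degenerate_thresholds_collapse_to_once(self):
        mat, meta = self._build([1, 1, 1])
        assert list(meta["recurrence_level"]) == ["once"]

    def test_quartile_thresholds_from_counts(self):
        """counts {1,2,4,8}: median 3, p75 5 -> three distinct covariates."""
        mat, meta = self._build([1, 2, 4, 8])
        got = meta.set_index("recurrence_level")["threshold"]
        assert got["once"] == 1 and got["sporadic"] == 3 and got["frequent"] == 5
        assert mat["rx::X::sporadic"].sum() == 2  # counts 4 and 8
        assert mat["rx::X::frequent"].sum() == 1  # only the count of 8
        assert mat.loc["p3", "rx::X::frequent"] == 1

    def test_person_without_counts_gets_zeros(self):
        mat, _ = self._build([1, 2, 4, 8])
        assert mat.loc["p5"].sum() == 0


class TestPrioritization:
    def _fixture(self, n=200, seed=0):
        rng = np.random.default_rng(seed)
        persons = pd.Index([f"p{i}" for i in range(n)])
        exposure = pd.Series(rng.integers(0, 2, n), index=persons)
        cols, meta = {}, []
        for d in ("inpatient_dx", "rx"):
            for j in range(6):
                name = f"{d}::C{j}::once"
                p = 0.2 + 0.05 * j
                x = rng.random(n) < p + (0.2 * exposure if j == 0 else 0)
                cols[name] = x.astype(int)
                meta.append((name, d, f"C{j}", "once", 1.0, float(x.mean())))
        mat = pd.DataFrame(cols, index=persons)
        meta = pd.DataFrame(meta, columns=["name", "dimension", "code",
                                           "recurrence_level", "threshold",
                                           "prevalence"])
        return mat, meta, exposure

    def test_top_k_per_dimension(self):
        mat, meta, exposure = self._fixture()
        sel = prioritize_covariates(mat, meta, exposure, k_per_dimension=3)
        assert (sel.groupby("dimension").size() <= 3).all()
        assert len(sel) <= 6

    def test_fewer_than_k_keeps_all(self):
        mat, meta, exposure = self._fixture()
        sel = prioritize_covariates(mat, meta, exposure, k_per_dimension=100)
        assert len(sel) == len(meta)

    def test_balanced_covariate_ranked_last(self):
        persons = pd.Index([f"p{i}" for i in range(100)])
        exposure = pd.Series([0, 1] * 50, index=persons)
        mat = pd.DataFrame({"rx::A::once": [1, 1, 0, 0] * 25,
                            "rx::B::once": exposure.to_numpy()}, index=persons)
        meta = pd.DataFrame({
            "name": ["rx::A::once", "rx::B::once"], "dimension": ["rx", "rx"],
            "code": ["A", "B"], "recurrence_level": ["once", "once"],
            "threshold": [1.0, 1.0], "prevalence": [0.5, 0.5]})
        sel = prioritize_covariates(mat, meta, exposure, k_per_dimension=2)
        assert sel["name"].iloc[0] == "rx::B::once"
        assert sel["priority"].iloc[-1] == pytest.approx(0.0, abs=1e-9)

    def test_bross_ranking_needs_outcome(self):
        mat, meta, exposure = self._fixture()
        with pytest.raises(ValueError):
            prioritize_covariates(mat, meta, exposure, method="bross")
        proxy = pd.Series(np.random.default_rng(1).integers(0, 2, len(mat)),
                          index=mat.index)
        sel = prioritize_covariates(mat, meta, exposure, method="bross",
                                    proxy_outcome=proxy)
        assert "priority" in sel


class TestPropensityModel:
    def _data(self, n=400, seed=0):
        rng = np.random.default_rng(seed)
        persons = pd.Index([f"p{i}" for i in range(n)])
        forced = pd.DataFrame({
            "age_at_index": rng.normal(70, 10, n),
            "female": rng.integers(0, 2, n),
            "sick_leave_days": rng.poisson(2, n),
            "cci": rng.poisson(10, n)}, index=persons)
        return persons, forced, rng

    def test_independent_exposure_scores_near_prevalence(self):
        persons, forced, rng = self._data()
        exposure = pd.Series(rng.random(len(persons)) < 0.3,
                             index=persons).astype(int)
        cov = pd.DataFrame(index=persons)
        model = fit_propensity_model(cov, forced, exposure)
        assert model.scores.between(0.1, 0.6).all()
        assert abs(model.scores.mean() - exposure.mean()) < 0.05

    def test_perfect_separation_stays_finite(self):
        persons, forced, rng = self._data(n=100)
        exposure = pd.Series([1] * 50 + [0] * 50, index=persons)
        cov = pd.DataFrame({"rx::X::once": exposure.to_numpy()}, index=persons)
        model = fit_propensity_model(cov, forced, exposure, ridge=1e-4)
        assert np.all(np.isfinite(model.coef))
        assert model.scores.between(1e-12, 1 - 1e-12).all()

    def test_scores_strictly_inside_unit_interval(self, small_pipeline):
        s = small_pipeline.matching.scores
        assert (s > 0).all() and (s < 1).all()

    def test_adding_forced_covariates_never_increases_deviance(self):
        """Nested-model property on fixed data (near-unpenalized fit)."""
        persons, forced, rng = self._data(n=500, seed=3)
        eta = 0.05 * (forced["age_at_index"] - 70) + 0.3 * forced["female"]
        exposure = pd.Series(
            rng.random(len(persons)) < 1 / (1 + np.exp(-eta)),
            index=persons).astype(int)
        cov = pd.DataFrame({"rx::X::once": rng.integers(0, 2, len(persons))},
                           index=persons)
        small = fit_propensity_model(cov, forced[["cci"]], exposure, ridge=1e-8)
        big = fit_propensity_model(cov, forced, exposure, ridge=1e-8)
        assert big.deviance <= small.deviance + 1e-6


def oracle_greedy_match(treated, controls, caliper):
    """Exhaustive oracle: lexicographically minimal distance sequence over all
    feasible 1:1 assignments, processed in the given treated order."""
    best = None
    control_items = list(controls.items())
    for perm in itertools.product(range(len(control_items) + 1),
                                  repeat=len(treated)):
        used = set()
        dists, pairs, ok = [], [], True
        for (tid, ts), choice in zip(treated.items(), perm):
            if choice == len(control_items):
                dists.append(np.inf)
                continue
            cid, cs = control_items[choice]
            d = abs(ts - cs)
            if cid in used or d > caliper:
                ok = False
                break
            used.add(cid)
            dists.append(d)
            pairs.append((tid, cid))
        if not ok:
            continue
        key = tuple(dists)
        if best is None or key < best[0]:
            best = (key, pairs)
    return sorted(best[1])


class TestMatching:
    def test_nearest_within_caliper(self):
        t = pd.Series({"t1": 0.50})
        c = pd.Series({"c1": 0.505, "c2": 0.80})
        m = match_nearest_neighbor(t, c, caliper=0.01, seed=0)
        assert list(m.pairs["control_id"]) == ["c1"]
        assert m.pairs["distance"].iloc[0] == pytest.approx(0.005)

    def test_outside_caliper_unmatched(self):
        m = match_nearest_neighbor(pd.Series({"t1": 0.50}),
                                   pd.Series({"c1": 0.52}), caliper=0.01, seed=0)
        assert len(m.pairs) == 0
        assert m.n_unmatched_treated == 1

    def test_identical_scores_all_pair_at_distance_zero(self):
        t = pd.Series({f"t{i}": 0.4 for i in range(5)})
        c = pd.Series({f"c{i}": 0.4 for i in range(5)})
        m = match_nearest_neighbor(t, c, caliper=0.01, seed=0)
        assert len(m.pairs) == 5
        assert (m.pairs["distance"] == 0).all()

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            match_nearest_neighbor(pd.Series(dtype=float),
                                   pd.Series({"c": 0.5}))

    @pytest.mark.parametrize("seed", range(12))
    def test_oracle_equivalence_on_tiny_instances(self, seed):
        """Greedy-within-caliper equals the exhaustive lexicographic-minimum
        assignment on instances of up to 12 persons."""
        rng = np.random.default_rng(seed)
        nt, nc = rng.integers(1, 6, 2)
        treated = pd.Series(np.round(rng.random(nt), 3),
                            index=[f"t{i}" for i in range(nt)])
        controls = pd.Series(np.round(rng.random(nc), 3) + 1e-4,
                             index=[f"c{i}" for i in range(nc)])
        caliper = 0.2
        m = match_nearest_neighbor(treated, controls, caliper=caliper, seed=seed)
        order = np.random.default_rng(seed).permutation(len(treated))
        ordered = treated.iloc[order]
        expected = oracle_greedy_match(ordered, controls, caliper + 1e-12)
        got = sorted(zip(m.pairs["treated_id"], m.pairs["control_id"]))
        assert got == expected

    def test_caliper_never_violated(self, small_pipeline):
        pairs = small_pipeline.matching.matched.pairs
        assert (pairs["distance"] <= 0.01 + 1e-12).all()
        ids = np.concatenate([pairs["treated_id"], pairs["control_id"]])
        assert len(ids) == len(set(ids))  # each person in at most one pair


class TestStandardizedDifference:
    def test_identical_samples_zero(self):
        x = [1.0, 2.0, 3.0]
        assert standardized_difference(x, x) == 0.0

    def test_unit_difference_is_100_percent(self):
        rng = np.random.default_rng(0)
        x1 = rng.normal(1.0, 1.0, 200_000)
        x0 = rng.normal(0.0, 1.0, 200_000)
        assert standardized_difference(x1, x0) == pytest.approx(100.0, abs=1.5)

    def test_binary_closed_form(self):
        x1 = np.repeat([1, 0], [42, 58])
        x0 = np.repeat([1, 0], [35, 65])
        expected = 100 * (0.42 - 0.35) / np.sqrt(
            (0.42 * 0.58 + 0.35 * 0.65) / 2)
        got = standardized_difference(x1, x0, binary=True)
        assert got == pytest.approx(expected)

    def test_degenerate_variances(self):
        assert standardized_difference([1, 1], [1, 1], binary=True) == 0.0
        assert standardized_difference([1, 1], [0, 0], binary=True) == np.inf


class TestBalance:
    def test_postmatch_forced_covariates_balanced(self, small_pipeline):
        bal = small_pipeline.matching.balance
        after = bal[bal["phase"] == "after"]
        assert (after["smd_pct"].abs() < 10).all()

    def test_strongly_confounded_data_imbalanced_before_matching(self):
        """By construction of the simulation, a strong frailty confounder
        shows up as |SMD| > 10 on at least one baseline covariate."""
        from sreburden.simulate import SimulationConfig, generate_claims
        from sreburden.cohort import build_cohorts
        from sreburden.pipeline import run_matching
        cfg = replace(SimulationConfig(), n_persons=4000, seed=77,
                      frailty_sd=1.0, mortality_log_hazard_on_frailty=0.0,
                      sre_log_hazard_on_frailty=1.5)
        ds, _ = generate_claims(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            coh = build_cohorts(ds, seed=1)
            m = run_matching(ds, coh.cohort, seed=2)
        before = m.balance[m.balance["phase"] == "before"]
        assert before["smd_pct"].abs().max() > 10

    def test_zero_variance_covariate_reported_not_nan(self):
        from sreburden.hdps import balance_table, MatchedPairs
        persons = pd.Index(["a", "b", "c", "d"])
        cov = pd.DataFrame({"flat": [1.0, 1.0, 1.0, 1.0]}, index=persons)
        exposure = pd.Series([1, 1, 0, 0], index=persons)
        matched = MatchedPairs(pairs=pd.DataFrame(
            {"treated_id": ["a"], "control_id": ["c"], "distance": [0.0]}),
            caliper=0.01)
        bal = balance_table(cov, exposure, matched)
        assert (bal["smd_pct"] == 0).all()
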