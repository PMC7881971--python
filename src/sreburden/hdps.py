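"""High-dimensional propensity score (hdPS) over seven claims dimensions.

The hdPS automates confounder selection: within each claims "dimension"
(inpatient diagnoses, outpatient diagnoses, drug dispensings, outpatient
treatments, inpatient treatments, aids, remedies) candidate codes are screened
by prevalence in the 12-month baseline window, expanded into recurrence-level
indicator covariates (once / sporadic / frequent), ranked by their potential
for confounding, and the top ``k`` per dimension enter a logistic propensity
model together with forced covariates (age, sex, sick-leave days, Charlson
index).  Matching is 1:1 greedy nearest neighbor on the probability scale with
a hard caliper.
"""

from __future__ import annotations

from bisect import bisect_left, insort
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .claims import ClaimsDataset
from .stats import test_baseline_difference

__all__ = [
    "DIMENSIONS",
    "baseline_code_counts",
    "enumerate_candidate_codes",
    "build_recurrence_covariates",
    "prioritize_covariates",
    "fit_propensity_model",
    "match_nearest_neighbor",
    "standardized_difference",
    "balance_table",
    "PropensityModel",
    "MatchedPairs",
]

DIMENSIONS = (
    "inpatient_dx",
    "outpatient_dx",
    "rx",
    "outpatient_treatment",
    "inpatient_treatment",
    "aids",
    "remedies",
)


def dimension_events(ds: ClaimsDataset, dimension: str) -> pd.DataFrame:
    """(person_id, date, code) stream for one hdPS dimension."""
    if dimension == "inpatient_dx":
        d = ds.diagnoses[ds.diagnoses["setting"] == "inpatient"]
        return d[["person_id", "date", "code"]]
    if dimension == "outpatient_dx":
        d = ds.diagnoses[(ds.diagnoses["setting"] == "outpatient")
                         & (ds.diagnoses["qualifier"] == "confirmed")]
        return d[["person_id", "date", "code"]]
    if dimension == "rx":
        return ds.dispensings.rename(columns={"atc_code": "code"})[
            ["person_id", "date", "code"]]
    if dimension == "outpatient_treatment":
        d = ds.procedures[ds.procedures["setting"] == "outpatient"]
        return d[["person_id", "date", "code"]]
    if dimension == "inpatient_treatment":
        d = ds.procedures[ds.procedures["setting"] == "inpatient"]
        return d[["person_id", "date", "code"]]
    if dimension == "aids":
        d = ds.costs[(ds.costs["category"] == "aid") & ds.costs["code"].notna()]
        return d[["person_id", "date", "code"]]
    if dimension == "remedies":
        d = ds.costs[(ds.costs["category"] == "remedy") & ds.costs["code"].notna()]
        return d[["person_id", "date", "code"]]
    raise ValueError(f"unknown dimension: {dimension!r}")


def baseline_code_counts(ds: ClaimsDataset, index_dates: pd.Series,
                         days: int = 365) -> pd.DataFrame:
    """Per (person, dimension, code) occurrence counts in [index - days, index)."""
    frames = []
    for dim in DIMENSIONS:
        ev = dimension_events(ds, dim)
        ev = ev[ev["person_id"].isin(index_dates.index)]
        if ev.empty:
            continue
        idx = ev["person_id"].map(index_dates)
        lo = idx - pd.to_timedelta(days, unit="D")
        ev = ev[(ev["date"] >= lo) & (ev["date"] < idx)]
        if ev.empty:
            continue
        g = (ev.groupby(["person_id", "code"]).size()
               .rename("count").reset_index().assign(dimension=dim))
        frames.append(g)
    if not frames:
        return pd.DataFrame(columns=["person_id", "dimension", "code", "count"])
    return pd.concat(frames, ignore_index=True)[
        ["person_id", "dimension", "code", "count"]]


def enumerate_candidate_codes(counts: pd.DataFrame, n_persons: int,
                              min_prevalence: float = 0.01) -> pd.DataFrame:
    """Per-dimension code prevalence table; rare and universal codes dropped.

    Prevalence is the fraction of cohort persons with >= 1 baseline occurrence.
    Codes present in fewer than ``min_prevalence`` of persons carry too little
    information; codes present in everyone have zero variance.  Both are
    discarded.
    """
    if counts.empty:
        return pd.DataFrame(columns=["dimension", "code", "prevalence"])
    prev = (counts.groupby(["dimension", "code"])["person_id"].nunique()
            / float(n_persons)).rename("prevalence").reset_index()
    keep = (prev["prevalence"] >= min_prevalence) & (prev["prevalence"] < 1.0)
    return prev[keep].reset_index(drop=True)


def build_recurrence_covariates(counts: pd.DataFrame, candidates: pd.DataFrame,
                                persons: pd.Index) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expand candidate codes into once/sporadic/frequent indicator covariates.

    Thresholds per code, from the nonzero per-person counts: ``once`` = count
    >= 1, ``sporadic`` = count >= median, ``frequent`` = count >= 75th
    percentile.  Degenerate duplicates (equal thresholds) are collapsed onto
    the lowest recurrence level.  Returns the person x covariate 0/1 matrix and
    a covariate metadata frame (name, dimension, code, recurrence_level,
    threshold, prevalence).
    """
    cols: dict[str, np.ndarray] = {}
    meta = []
    if len(candidates):
        sub = counts.merge(candidates[["dimension", "code"]], on=["dimension", "code"])
        for (dim, code), g in sub.groupby(["dimension", "code"], sort=True):
            c = g["count"].to_numpy()
            med, p75 = np.percentile(c, [50, 75])
            thresholds = {"once": 1.0, "sporadic": float(med), "frequent": float(p75)}
            seen: set[float] = set()
            for level in ("once", "sporadic", "frequent"):
                t = thresholds[level]
                if t in seen:
                    continue  # collapse degenerate duplicate
                seen.add(t)
                ind = pd.Series(0, index=persons, dtype=np.int8)
                hit = g.loc[g["count"] >= t, "person_id"]
                ind.loc[ind.index.isin(hit)] = 1
                name = f"{dim}::{code}::{level}"
                cols[name] = ind.to_numpy()
                meta.append((name, dim, code, level, t, float(ind.mean())))
    mat = pd.DataFrame(cols, index=persons)
    meta_df = pd.DataFrame(meta, columns=["name", "dimension", "code",
                                          "recurrence_level", "threshold",
                                          "prevalence"])
    return mat, meta_df


def prioritize_covariates(cov_matrix: pd.DataFrame, meta: pd.DataFrame,
                          exposure: pd.Series, k_per_dimension: int = 100,
                          method: str = "exposure_assoc",
                          proxy_outcome: pd.Series | None = None,
                          pooled: bool = False) -> pd.DataFrame:
    """Rank covariates by confounding potential; keep the top k per dimension.

    ``exposure`` is the 0/1 SRE label aligned to ``cov_matrix`` rows.  The
    default priority is the absolute log prevalence ratio between exposed and
    unexposed (with a continuity correction).  ``method='bross'`` uses the
    Bross bias multiplier and needs a binary ``proxy_outcome`` (e.g. death
    within follow-up).  With ``pooled=True`` a single top ``7*k`` across all
    dimensions is kept instead of k per dimension.
    """
    if meta.empty:
        return meta.assign(priority=pd.Series(dtype=float))
    z = exposure.reindex(cov_matrix.index).to_numpy().astype(bool)
    X = cov_matrix.to_numpy()
    n1, n0 = z.sum(), (~z).sum()
    p1 = (X[z].sum(axis=0) + 0.5) / (n1 + 1.0)
    p0 = (X[~z].sum(axis=0) + 0.5) / (n0 + 1.0)
    if method == "exposure_assoc":
        priority = np.abs(np.log(p1 / p0))
    elif method == "bross":
        if proxy_outcome is None:
            raise ValueError("bross ranking needs a binary proxy_outcome")
        y = proxy_outcome.reindex(cov_matrix.index).to_numpy().astype(bool)
        c = X.astype(bool)
        py1 = (np.array([y[c[:, j]].sum() for j in range(X.shape[1])]) + 0.5) \
            / (c.sum(axis=0) + 1.0)
        py0 = (np.array([y[~c[:, j]].sum() for j in range(X.shape[1])]) + 0.5) \
            / ((~c).sum(axis=0) + 1.0)
        rr_cd = py1 / py0
        bias = (p1 * (rr_cd - 1) + 1) / (p0 * (rr_cd - 1) + 1)
        priority = np.abs(np.log(bias))
    else:
        raise ValueError(f"unknown ranking method: {method!r}")
    ranked = meta.assign(priority=pd.Series(priority, index=meta.index))
    ranked = ranked.sort_values(["priority", "name"], ascending=[False, True])
    if pooled:
        return ranked.head(k_per_dimension * len(DIMENSIONS)).reset_index(drop=True)
    return (ranked.groupby("dimension", group_keys=False)
                  .head(k_per_dimension).reset_index(drop=True))


@dataclass
class PropensityModel:
    """Fitted logistic propensity model with standardized design."""

    feature_names: list[str]
    coef: np.ndarray
    intercept: float
    means: np.ndarray
    stds: np.ndarray
    scores: pd.Series  # per-person probability of exposure, in (0, 1)
    deviance: float
    ridge: float

    def predict(self, X: pd.DataFrame) -> pd.Series:
        Z = (X[self.feature_names].to_numpy(float) - self.means) / self.stds
        eta = Z @ self.coef + self.intercept
        return pd.Series(1.0 / (1.0 + np.exp(-eta)), index=X.index)


def fit_propensity_model(covariates: pd.DataFrame, forced: pd.DataFrame,
                         exposure: pd.Series, ridge: float = 1e-4) -> PropensityModel:
    """Penalized-ML logistic regression of exposure on forced + selected covariates.

    Covariates are standardized and a small ridge penalty keeps coefficients
    finite under separation (hundreds of sparse binary predictors).  Scores are
    strictly inside (0, 1).
    """
    X = pd.concat([forced, covariates], axis=1)
    X = X.loc[:, ~X.columns.duplicated()]
    y = exposure.reindex(X.index).to_numpy().astype(int)
    M = X.to_numpy(float)
    means = M.mean(axis=0)
    stds = M.std(axis=0)
    keep = stds > 0
    if not keep.any():
        # null model: intercept only
        p = max(min(y.mean(), 1 - 1e-12), 1e-12)
        scores = pd.Series(np.full(len(y), p), index=X.index)
        dev = -2 * np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))
        return PropensityModel([], np.array([]), float(np.log(p / (1 - p))),
                               np.array([]), np.array([]), scores, float(dev), ridge)
    names = [c for c, k in zip(X.columns, keep) if k]
    Z = (M[:, keep] - means[keep]) / stds[keep]
    clf = LogisticRegression(C=1.0 / ridge, solver="lbfgs",
                             max_iter=5000, tol=1e-8)
    clf.fit(Z, y)
    if not np.all(np.isfinite(clf.coef_)):
        raise RuntimeError("propensity model failed to converge to finite coefficients")
    eta = Z @ clf.coef_.ravel() + clf.intercept_[0]
    p = 1.0 / (1.0 + np.exp(-eta))
    p = np.clip(p, 1e-12, 1 - 1e-12)
    dev = -2 * np.sum(y * np.log(p) + (1 - y) * np.log(1 - p))
    return PropensityModel(names, clf.coef_.ravel().copy(), float(clf.intercept_[0]),
                           means[keep], stds[keep],
                           pd.Series(p, index=X.index), float(dev), ridge)


@dataclass
class MatchedPairs:
    """1:1 matched cohort: (treated, control, |score distance|) per pair."""

    pairs: pd.DataFrame  # columns treated_id, control_id, distance
    caliper: float
    n_unmatched_treated: int = 0

    def matched_ids(self) -> pd.Index:
        return pd.Index(np.concatenate([self.pairs["treated_id"].to_numpy(),
                                        self.pairs["control_id"].to_numpy()]))


def match_nearest_neighbor(scores_treated: pd.Series, scores_control: pd.Series,
                           caliper: float = 0.01, seed: int = 0) -> MatchedPairs:
    """Greedy 1:1 nearest-neighbor matching without replacement.

    Treated persons are processed in a seeded random order; each takes the
    nearest still-available control on the probability scale, provided the
    distance is within the caliper.  Treated with no admissible control are
    dropped.
    """
    if len(scores_treated) == 0 or len(scores_control) == 0:
        raise ValueError("both groups must be non-empty for matching")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(scores_treated))
    t_ids = scores_treated.index.to_numpy()
    t_scores = scores_treated.to_numpy(float)
    # available controls kept sorted by (score, id) for nearest lookup
    ctrl = sorted(zip(scores_control.to_numpy(float), scores_control.index.to_numpy()))
    pairs = []
    unmatched = 0
    for i in order:
        if not ctrl:
            unmatched += 1
            continue
        s = t_scores[i]
        j = bisect_left(ctrl, (s,))
        best = None
        for cand in (j - 1, j):
            if 0 <= cand < len(ctrl):
                d = abs(ctrl[cand][0] - s)
                if best is None or d < best[0]:
                    best = (d, cand)
        if best is not None and best[0] <= caliper + 1e-12:
            d, cand = best
            score_c, cid = ctrl.pop(cand)
            pairs.append((t_ids[i], cid, d))
        else:
            unmatched += 1
    df = pd.DataFrame(pairs, columns=["treated_id", "control_id", "distance"])
    return MatchedPairs(pairs=df, caliper=caliper, n_unmatched_treated=unmatched)


def standardized_difference(values_treated, values_control,
                            binary: bool = False) -> float:
    """Standardized mean difference in percent.

    ``100 * (m1 - m0) / sqrt((s1^2 + s0^2) / 2)``; for a binary covariate the
    variance is ``p (1 - p)``.  Degenerate case: both variances zero returns 0
    when the means agree and signed infinity otherwise.
    """
    x1 = np.asarray(values_treated, float)
    x0 = np.asarray(values_control, float)
    m1, m0 = x1.mean(), x0.mean()
    if binary:
        v1, v0 = m1 * (1 - m1), m0 * (1 - m0)
    else:
        v1 = x1.var(ddof=1) if len(x1) > 1 else 0.0
        v0 = x0.var(ddof=1) if len(x0) > 1 else 0.0
    denom = np.sqrt((v1 + v0) / 2.0)
    if denom == 0:
        if m1 == m0:
            return 0.0
        return float(np.sign(m1 - m0) * np.inf)
    return float(100.0 * (m1 - m0) / denom)


_BALANCE_KINDS = {"age_at_index": "continuous_normal", "female": "binary",
                  "cci": "continuous_skewed", "n_hospitalizations": "continuous_skewed",
                  "n_gp_visits": "continuous_skewed",
                  "sick_leave_days": "continuous_skewed"}


def balance_table(covariates: pd.DataFrame, exposure: pd.Series,
                  matched: MatchedPairs) -> pd.DataFrame:
    """Before/after balance report for a covariate table.

    ``covariates`` is indexed by person_id; ``exposure`` is the 0/1 SRE label.
    Per covariate and phase: group means, standardized difference (percent) and
    a two-group test p-value.  Zero-variance covariates are reported with the
    degenerate SMD convention rather than NaN.
    """
    rows = []
    matched_t = matched.pairs["treated_id"].to_numpy()
    matched_c = matched.pairs["control_id"].to_numpy()
    e = exposure.reindex(covariates.index).astype(bool)
    for col in covariates.columns:
        binary = set(covariates[col].dropna().unique()) <= {0, 1}
        kind = _BALANCE_KINDS.get(col, "binary" if binary else "continuous_skewed")
        for phase, (ids1, ids0) in {
            "before": (covariates.index[e], covariates.index[~e]),
            "after": (matched_t, matched_c),
        }.items():
            x1 = covariates.loc[ids1, col].to_numpy(float)
            x0 = covariates.loc[ids0, col].to_numpy(float)
            smd = standardized_difference(x1, x0, binary=binary)
            try:
                p = test_baseline_difference(x1, x0, kind)
            except ValueError:
                p = float("nan")
            rows.append((col, phase, x1.mean(), x0.mean(), smd, p))
    return pd.DataFrame(rows, columns=["covariate", "phase", "mean_treated",
                                       "mean_control", "smd_pct", "p_value"])
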