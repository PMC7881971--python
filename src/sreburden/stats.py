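"""Shared statistical primitives: group-difference tests and the bootstrap
rate-ratio test.

The rate-ratio p-value is a patient-level nonparametric bootstrap: persons are
resampled with replacement within each group, the pooled per-patient-year rate
ratio is recomputed per replicate, and a two-sided p-value is read off the
bootstrap distribution of the log ratio by confidence-interval inversion.  This
avoids any Poisson assumption, which pooled cost totals would violate badly.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

__all__ = ["test_baseline_difference", "bootstrap_rate_ratio_pvalue", "share_pct"]


def share_pct(part: float, whole: float, decimals: int = 2) -> float:
    """Percentage share rounded to the reporting precision (default 2 dp)."""
    if whole == 0:
        raise ValueError("whole must be nonzero")
    return round(100.0 * part / whole, decimals)


def test_baseline_difference(values_treated, values_control, var_kind: str) -> float:
    """p-value for a between-group baseline difference.

    ``var_kind`` selects the test: ``binary`` -> Pearson chi-squared on the
    2x2 table, ``continuous_normal`` -> Welch t test,
    ``continuous_skewed`` -> Mann-Whitney U.
    """
    x1 = np.asarray(values_treated, dtype=float)
    x0 = np.asarray(values_control, dtype=float)
    if len(x1) < 2 or len(x0) < 2:
        raise ValueError("need at least 2 observations per group")
    if var_kind == "binary":
        table = np.array([[np.sum(x1 == 1), np.sum(x1 == 0)],
                          [np.sum(x0 == 1), np.sum(x0 == 0)]], dtype=float)
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            return 1.0
        return float(sps.chi2_contingency(table, correction=False)[1])
    if var_kind == "continuous_normal":
        if np.var(x1) == 0 and np.var(x0) == 0:
            return 1.0 if np.mean(x1) == np.mean(x0) else 0.0
        return float(sps.ttest_ind(x1, x0, equal_var=False).pvalue)
    if var_kind == "continuous_skewed":
        if np.var(np.concatenate([x1, x0])) == 0:
            return 1.0
        return float(sps.mannwhitneyu(x1, x0, alternative="two-sided").pvalue)
    raise ValueError(f"unknown var_kind: {var_kind!r}")


def bootstrap_rate_ratio_pvalue(events1, py1, events0, py0,
                                n_boot: int = 2000, seed: int = 0) -> float:
    """Two-sided bootstrap p-value for the pooled rate ratio.

    ``events*``/``py*``: per-person event (or cost) totals and person-years for
    the two groups.  Returns the CI-inversion p-value
    ``2 * min(P(log RR* <= 0), P(log RR* >= 0))`` with a +1 continuity term.
    """
    e1 = np.asarray(events1, float); t1 = np.asarray(py1, float)
    e0 = np.asarray(events0, float); t0 = np.asarray(py0, float)
    rng = np.random.default_rng(seed)
    n1, n0 = len(e1), len(e0)
    i1 = rng.integers(0, n1, size=(n_boot, n1))
    i0 = rng.integers(0, n0, size=(n_boot, n0))
    r1 = e1[i1].sum(axis=1) / t1[i1].sum(axis=1)
    r0 = e0[i0].sum(axis=1) / t0[i0].sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        log_rr = np.log(r1) - np.log(r0)
    log_rr = log_rr[np.isfinite(log_rr)]
    if log_rr.size == 0:
        return float("nan")
    b = log_rr.size
    p_lo = (np.sum(log_rr <= 0) + 1) / (b + 1)
    p_hi = (np.sum(log_rr >= 0) + 1) / (b + 1)
    return float(min(1.0, 2 * min(p_lo, p_hi)))
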