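"""ROC/AUC, Youden cutoff, survival and contingency analyses.

AUC is the Mann-Whitney concordance probability with ties counted 1/2;
its 95% CI uses the DeLong variance estimator.  The risk cutoff is the
score threshold maximizing the Youden index J = sensitivity +
specificity - 1 on the training cohort, then frozen for all cohorts.

Contingency tests follow the convention of mainstream statistical
software: 2x2 tables with all expected counts >= 5 use the Pearson
chi-square with Yates continuity correction, larger tables with all
expected counts >= 5 use the uncorrected chi-square, and any table with
an expected count < 5 uses the Fisher exact test.  P values are reported
to 3 decimals; values above .999 print as ">.999".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError, ParameterError

__all__ = [
    "roc_auc_ci",
    "youden_cutoff",
    "km_logrank",
    "association_table",
    "ContingencyResult",
    "format_p",
]


# ---------------------------------------------------------------------------
# ROC / AUC


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise InputError("both classes must be present")
    return labels


def auc_mann_whitney(scores, labels) -> float:
    """Concordance-probability AUC with ties counted 1/2."""
    labels = _check_binary(np.asarray(labels))
    scores = np.asarray(scores, dtype=float)
    pos = labels == 1
    n1, n0 = int(pos.sum()), int((~pos).sum())
    r = stats.rankdata(scores)
    return float((r[pos].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def roc_auc_ci(scores, labels, alpha: float = 0.05) -> tuple[float, tuple[float, float]]:
    """AUC and its DeLong 95% CI (clipped to [0, 1])."""
    labels = _check_binary(np.asarray(labels))
    scores = np.asarray(scores, dtype=float)
    x = scores[labels == 1]
    y = scores[labels == 0]
    m, n = len(x), len(y)
    # placement values: V10[i] = P(score_neg < x_i) + .5 P(=), via ranks
    both = np.concatenate([x, y])
    r_all = stats.rankdata(both)
    r_x = stats.rankdata(x)
    r_y = stats.rankdata(y)
    v10 = (r_all[:m] - r_x) / n
    v01 = 1.0 - (r_all[m:] - r_y) / m
    auc = float(v10.mean())
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = float(np.sqrt(s10 / m + s01 / n))
    z = stats.norm.ppf(1 - alpha / 2)
    lo = max(0.0, auc - z * se)
    hi = min(1.0, auc + z * se)
    return auc, (lo, hi)


def youden_cutoff(scores, labels) -> tuple[float, float]:
    """Threshold maximizing J = sensitivity + specificity - 1.

    Every midpoint between adjacent distinct observed scores is
    evaluated with the rule ``score >= cutoff -> positive``.  Ties in J
    resolve to the lower threshold (higher sensitivity).  Identical
    scores give J = 0.
    """
    labels = _check_binary(np.asarray(labels))
    scores = np.asarray(scores, dtype=float)
    distinct = np.unique(scores)
    if len(distinct) == 1:
        return float(distinct[0]), 0.0
    cuts = (distinct[:-1] + distinct[1:]) / 2.0
    n1 = (labels == 1).sum()
    n0 = (labels == 0).sum()
    best_j, best_cut = -np.inf, None
    for c in cuts:
        pred = scores >= c
        sens = (pred & (labels == 1)).sum() / n1
        spec = (~pred & (labels == 0)).sum() / n0
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best_cut = j, c
    return float(best_cut), float(max(best_j, 0.0))


# ---------------------------------------------------------------------------
# survival


def km_logrank(groups, times, events) -> dict:
    """Kaplan-Meier estimates per group and the two-group log-rank test.

    ``groups`` holds "high"/"low" per patient.  Returns per-group median
    survival with quartiles (np.inf when not reached) and the log-rank
    chi-square (df 1) with its p-value.  Curves are returned as plain
    (time, survival) coordinate tables.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test
    from lifelines.utils import qth_survival_times

    groups = np.asarray(groups)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if events.sum() < 1:
        raise InputError("need at least one observed event")
    out: dict = {"groups": {}}
    for g in ("high", "low"):
        sel = groups == g
        if sel.sum() == 0:
            raise InputError(f"group {g!r} has no patients")
        kmf = KaplanMeierFitter().fit(times[sel], events[sel], label=g)
        sf = kmf.survival_function_
        med = float(qth_survival_times(0.5, sf).squeeze())
        q25 = float(qth_survival_times(0.75, sf).squeeze())  # 25th pct of time
        q75 = float(qth_survival_times(0.25, sf).squeeze())
        out["groups"][g] = {
            "n": int(sel.sum()),
            "events": int(events[sel].sum()),
            "median": med,
            "iqr": (q25, q75),
            "curve": list(zip(sf.index.to_list(), sf[g].to_list())),
        }
    hi = groups == "high"
    res = logrank_test(times[hi], times[~hi], events[hi], events[~hi])
    out["logrank_statistic"] = float(res.test_statistic)
    out["logrank_p"] = float(res.p_value)
    return out


def median_followup_reverse_km(times, events) -> float:
    """Median follow-up by the reverse Kaplan-Meier method.

    Censoring is treated as the event of interest (observed deaths are
    censored), the standard way to summarize follow-up duration.
    """
    from lifelines import KaplanMeierFitter

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    kmf = KaplanMeierFitter().fit(times, 1 - events)
    return float(kmf.median_survival_time_)


# ---------------------------------------------------------------------------
# contingency tests


def format_p(p: float) -> str:
    if round(p, 3) > 0.999:
        return ">.999"
    return f"{p:.3f}".lstrip("0") if round(p, 3) >= 0.001 else "<.001"


@dataclass(frozen=True)
class ContingencyResult:
    observed: np.ndarray
    test: str  # chi-square | chi-square-yates | fisher
    statistic: float | None
    p: float

    @property
    def p_formatted(self) -> str:
        return format_p(self.p)


def _fisher_rxc(table: np.ndarray) -> float:
    """Exact conditional test for small r x c tables (fixed margins).

    Sums the probability of every table with the observed margins whose
    hypergeometric probability does not exceed the observed one.
    Feasible for the small count tables where expected frequencies fall
    below 5; guarded by an enumeration cap.
    """
    from math import lgamma

    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n = int(table.sum())
    if n > 500 or table.size > 12:
        raise ParameterError("table too large for exact r x c enumeration")

    def lfact(k):
        return lgamma(k + 1)

    log_const = sum(lfact(r) for r in rows) + sum(lfact(c) for c in cols) - lfact(n)

    def log_prob(t):
        return log_const - sum(lfact(v) for v in t)

    obs_lp = log_prob(table.ravel())
    r, c = table.shape
    total_p = 0.0

    def rec(row_idx, remaining_cols, cells):
        nonlocal total_p
        if row_idx == r - 1:
            last = remaining_cols
            if np.all(last >= 0):
                lp = log_prob(cells + list(last))
                if lp <= obs_lp + 1e-9:
                    total_p += np.exp(lp)
            return
        target = rows[row_idx]

        def fill(col_idx, left, row_cells):
            if col_idx == c - 1:
                v = left
                if 0 <= v <= remaining_cols[col_idx]:
                    rec(row_idx + 1, remaining_cols - np.array(row_cells + [v]),
                        cells + row_cells + [v])
                return
            hi = min(left, remaining_cols[col_idx])
            for v in range(hi + 1):
                fill(col_idx + 1, left - v, row_cells + [v])

        fill(0, int(target), [])

    rec(0, cols.copy(), [])
    return min(total_p, 1.0)


def association_table(group, variable=None) -> ContingencyResult:
    """Cross-tabulate a categorical variable against high/low risk groups.

    Accepts either two per-patient categorical arrays or a precomputed
    count table (2D array, variable levels x groups).
    """
    if variable is None:
        observed = np.asarray(group, dtype=int)
        if observed.ndim != 2:
            raise InputError("count table must be 2D")
    else:
        tab = pd.crosstab(pd.Series(variable, name="var"), pd.Series(group, name="group"))
        observed = tab.to_numpy(dtype=int)
    if observed.min() < 0:
        raise InputError("negative cell counts")
    if (observed.sum(axis=0) == 0).any() or (observed.sum(axis=1) == 0).any():
        raise InputError("empty margin in contingency table")
    if observed.shape[0] < 2 or observed.shape[1] < 2:
        raise InputError("need at least 2 categories on each margin")
    expected = stats.contingency.expected_freq(observed)
    if expected.min() >= 5:
        is2x2 = observed.shape == (2, 2)
        chi2, p, _, _ = stats.chi2_contingency(observed, correction=is2x2)
        return ContingencyResult(
            observed=observed,
            test="chi-square-yates" if is2x2 else "chi-square",
            statistic=float(chi2),
            p=float(p),
        )
    if observed.shape == (2, 2):
        res = stats.fisher_exact(observed)
        return ContingencyResult(observed=observed, test="fisher", statistic=None, p=float(res.pvalue))
    try:
        p = _fisher_rxc(observed)
        return ContingencyResult(observed=observed, test="fisher", statistic=None, p=p)
    except ParameterError:
        chi2, p, _, _ = stats.chi2_contingency(observed, correction=False)
        return ContingencyResult(observed=observed, test="chi-square", statistic=float(chi2), p=float(p))
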