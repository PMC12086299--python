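"""Paired pre/post statistical harness for microstate studies.

The analysis pattern: pre/post comparisons use the exact Wilcoxon
signed-rank test (the Shapiro-Wilk test having indicated non-normality for
such parameters), p-values are Benjamini-Hochberg corrected within each
report table, and change-score associations (e.g. change in a transition
deviation vs change in the STAI-S state-anxiety score) use Pearson's
product-moment correlation with t = r * sqrt((n-2)/(1-r^2)) on n-2 degrees
of freedom.

The exact Wilcoxon test drops zero differences, mid-ranks ties, and
computes the two-sided p by full enumeration of the 2^m sign assignments
(via the standard rank-sum distribution recursion; a brute-force
enumeration oracle lives in the test suite). Above m = 25 nonzero
differences it falls back to the normal approximation and says so in the
result's ``method``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .containers import (
    DegenerateDataError,
    ParameterError,
    StudyDataset,
    TestResult,
)

logger = logging.getLogger("eegmicrostates")

EXACT_WILCOXON_LIMIT = 25


def shapiro_wilk(x) -> TestResult:
    """Shapiro-Wilk normality test (gates Wilcoxon vs parametric choices)."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ParameterError("Shapiro-Wilk needs n >= 3")
    if x.size > 5000:
        raise ParameterError("Shapiro-Wilk supports n <= 5000")
    if np.ptp(x) == 0:
        raise DegenerateDataError("constant sample has no normality test")
    w, p = sp_stats.shapiro(x)
    return TestResult(statistic_name="W", value=float(w), p=float(p),
                      method="shapiro-wilk")


# ---------------------------------------------------------------------------
# exact Wilcoxon signed-rank
# ---------------------------------------------------------------------------


def _signed_rank_distribution(doubled_ranks: np.ndarray) -> np.ndarray:
    """Counts of sign-assignment outcomes for V*2 = sum of chosen doubled ranks.

    Entry j counts the sign patterns whose positive-rank sum equals j/2.
    Equivalent to full enumeration of all 2^m sign assignments.
    """
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for d in doubled_ranks:
        d = int(d)
        new = counts.copy()
        new[d:] += counts[: total + 1 - d]
        counts = new
    return counts


def wilcoxon_signed_rank_exact(pre, post) -> TestResult:
    """Exact two-sided Wilcoxon signed-rank test on paired samples.

    V is the sum of the ranks of positive differences (post - pre). Zero
    differences are dropped, ties receive mid-ranks, and the exact p is the
    two-sided tail of the full sign-assignment distribution (doubling the
    tail of V, capped at 1, the R ``wilcox.test`` convention).
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ParameterError("pre and post must have equal length")
    diffs = post - pre
    diffs = diffs[diffs != 0.0]
    m = diffs.size
    if m == 0:
        raise DegenerateDataError("all paired differences are zero")
    ranks = sp_stats.rankdata(np.abs(diffs))
    v = float(ranks[diffs > 0].sum())
    if m <= EXACT_WILCOXON_LIMIT:
        doubled = np.rint(2.0 * ranks).astype(int)
        dist = _signed_rank_distribution(doubled)
        total = dist.sum()
        v2 = int(round(2.0 * v))
        p_low = dist[: v2 + 1].sum() / total
        p_high = dist[v2:].sum() / total
        p = min(1.0, 2.0 * min(p_low, p_high))
        method = "exact"
    else:
        mu = m * (m + 1) / 4.0
        # tie-corrected variance of V
        sigma2 = (m * (m + 1) * (2 * m + 1) / 24.0
                  - _tie_correction(np.abs(diffs)))
        z = (v - mu) / np.sqrt(sigma2)
        p = float(2.0 * sp_stats.norm.sf(abs(z)))
        method = "normal-approximation"
        logger.info("Wilcoxon: m=%d > %d, using normal approximation",
                    m, EXACT_WILCOXON_LIMIT)
    return TestResult(statistic_name="V", value=v, p=p, method=method)


def _tie_correction(absdiffs: np.ndarray) -> float:
    _, counts = np.unique(absdiffs, return_counts=True)
    return float(np.sum(counts**3 - counts) / 48.0)


# ---------------------------------------------------------------------------
# multiplicity and correlations
# ---------------------------------------------------------------------------


def benjamini_hochberg(pvals) -> np.ndarray:
    """Step-up BH adjusted p-values, returned in the input order."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ParameterError("pvals must be 1-D")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ParameterError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, m * p[i] / rank_from_top)
        adjusted[i] = running_min
    return adjusted


def pearson_change_correlation(delta_x, delta_y) -> TestResult:
    """Pearson r between two change scores, with t, df = n-2, two-sided p."""
    x = np.asarray(delta_x, dtype=float)
    y = np.asarray(delta_y, dtype=float)
    if x.shape != y.shape:
        raise ParameterError("change scores must have equal length")
    n = x.size
    if n < 3:
        raise ParameterError("Pearson correlation needs n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("zero-variance change score")
    r, _ = sp_stats.pearsonr(x, y)
    r = float(np.clip(r, -1.0, 1.0))
    df = n - 2
    if abs(r) >= 1.0:
        t = np.inf if r > 0 else -np.inf
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r**2))
        p = float(2.0 * sp_stats.t.sf(abs(t), df))
    return TestResult(statistic_name="t", value=float(t), p=p, df=df, r=r,
                      method="pearson")


# ---------------------------------------------------------------------------
# study-level report tables
# ---------------------------------------------------------------------------


def _paired_wide(df: pd.DataFrame, value: str) -> pd.DataFrame:
    """subject-indexed pre/post columns for one value column."""
    wide = df.pivot_table(index="subject", columns="timing", values=value)
    return wide.dropna(subset=["pre", "post"])


def _adjust_within_table(out: pd.DataFrame) -> pd.DataFrame:
    """BH over the table's defined p-values; undefined rows stay NaN."""
    p = out["p"].to_numpy(dtype=float)
    adjusted = np.full(p.size, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        adjusted[ok] = benjamini_hochberg(p[ok])
    out["p_adjusted"] = adjusted
    return out


def _wilcoxon_rows(value_specs, sessions) -> pd.DataFrame:
    rows = []
    for label, sub_df, value in value_specs:
        for session in sessions:
            cur = sub_df[sub_df["session"] == session]
            wide = _paired_wide(cur, value)
            row = {"comparison": label, "site": session,
                   "statistic_name": "V", "n": len(wide),
                   "statistic": np.nan, "p": np.nan}
            try:
                res = wilcoxon_signed_rank_exact(wide["pre"], wide["post"])
                row.update(statistic=res.value, p=res.p)
            except (ParameterError, DegenerateDataError) as exc:
                logger.warning("Wilcoxon undefined for %s / %s: %s",
                               label, session, exc)
            rows.append(row)
    return _adjust_within_table(pd.DataFrame(rows))


def _pearson_rows(specs, sessions) -> pd.DataFrame:
    rows = []
    for label, session, dx, dy in specs:
        row = {"comparison": label, "site": session, "statistic_name": "t",
               "statistic": np.nan, "df": len(dx) - 2, "r": np.nan,
               "n": len(dx), "p": np.nan}
        try:
            res = pearson_change_correlation(dx, dy)
            row.update(statistic=res.value, df=res.df, r=res.r, p=res.p)
        except (ParameterError, DegenerateDataError) as exc:
            logger.warning("correlation undefined for %s / %s: %s",
                           label, session, exc)
        rows.append(row)
    return _adjust_within_table(pd.DataFrame(rows))


def _delta(df: pd.DataFrame, session: str, value: str) -> pd.Series:
    wide = _paired_wide(df[df["session"] == session], value)
    return wide["post"] - wide["pre"]


def run_study_analysis(study: StudyDataset, params: pd.DataFrame,
                       transitions: pd.DataFrame,
                       classes: tuple = ("D", "C")) -> dict:
    """Emit the four report tables plus the baseline severity correlations.

    ``params``: tidy rows (subject, session, timing, class, duration_ms,
    occurrence_per_s, contribution). ``transitions``: tidy rows (subject,
    session, timing, dev_CD, dev_DC). Pre/post comparisons are exact
    Wilcoxon tests; change-score associations with the STAI-like score are
    Pearson correlations; p-values are BH-adjusted within each table.
    """
    sessions = list(study.sessions)
    stai = pd.DataFrame([
        {"subject": s.subject_id, "session": sess,
         "delta_stai": s.stai[sess]["post"] - s.stai[sess]["pre"]}
        for s in study.subjects for sess in sessions
    ])

    # pre/post duration and contribution of classes D and C
    prepost_specs = []
    for metric, column in (("Duration", "duration_ms"),
                           ("Contribution", "contribution")):
        for cls in classes:
            sub = params[params["class"] == cls]
            prepost_specs.append((f"{metric} of microstate map {cls}", sub, column))
    prepost_params = _wilcoxon_rows(prepost_specs, sessions)

    # pre/post transition deviations C->D and D->C
    trans_specs = [
        ("From microstate map C to microstate map D", transitions, "dev_CD"),
        ("From microstate map D to microstate map C", transitions, "dev_DC"),
    ]
    prepost_trans = _wilcoxon_rows(trans_specs, sessions)

    # change in parameter vs change in STAI-S
    param_corr_specs = []
    for metric, column in (("Duration", "duration_ms"),
                           ("Contribution", "contribution")):
        for cls in classes:
            sub = params[params["class"] == cls]
            for session in sessions:
                d_param = _delta(sub, session, column)
                merged = pd.concat([d_param.rename("dx"),
                                    stai[stai["session"] == session]
                                    .set_index("subject")["delta_stai"]],
                                   axis=1).dropna()
                param_corr_specs.append((f"{metric} of microstate map {cls}", session,
                               merged["dx"], merged["delta_stai"]))
    param_corr = _pearson_rows(param_corr_specs, sessions)

    # change in transition deviation vs change in STAI-S
    trans_corr_specs = []
    for label, column in (("From microstate map C to microstate map D", "dev_CD"),
                          ("From microstate map D to microstate map C", "dev_DC")):
        for session in sessions:
            d_dev = _delta(transitions, session, column)
            merged = pd.concat([d_dev.rename("dx"),
                                stai[stai["session"] == session]
                                .set_index("subject")["delta_stai"]],
                               axis=1).dropna()
            trans_corr_specs.append((label, session, merged["dx"], merged["delta_stai"]))
    trans_corr = _pearson_rows(trans_corr_specs, sessions)

    # baseline severity correlations: MADRS vs occurrence-A and duration-D
    first = sessions[0]
    madrs = pd.Series({s.subject_id: s.madrs for s in study.subjects},
                      name="madrs")
    base_specs = []
    for label, cls, column in (
        ("Occurrence of microstate map A", "A", "occurrence_per_s"),
        ("Duration of microstate map D", "D", "duration_ms"),
    ):
        sub = params[(params["class"] == cls) & (params["session"] == first)
                     & (params["timing"] == "pre")]
        merged = pd.concat([sub.set_index("subject")[column].rename("x"),
                            madrs], axis=1).dropna()
        base_specs.append((label, first, merged["x"], merged["madrs"]))
    baseline = _pearson_rows(base_specs, [first])

    return {"parameters_prepost": prepost_params, "transitions_prepost": prepost_trans,
            "parameters_vs_stai": param_corr, "transitions_vs_stai": trans_corr,
            "baseline_madrs": baseline}
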