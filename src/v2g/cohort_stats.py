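"""Cohort statistics: correlations, t-tests, random-intercept LME, summaries.

These are the patient- and slice-level comparisons used on the 16-patient
cohort: Pearson correlation between outcome (change in ejection fraction) and
the mechanical/geometric predictors, unpaired Student t-tests between outcome
groups, paired t-tests and a random-intercept linear mixed-effects model for
the paired model comparisons with patient-slice clustering.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import V2GError

log = logging.getLogger(__name__)


def _finite_vec(x, name):
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or not np.all(np.isfinite(x)):
        raise V2GError(f"{name} must be a finite 1-D vector")
    return x


def pearson_corr(x, y) -> tuple[float, float]:
    """Sample Pearson r with two-sided p from the t transform (n-2 df)."""
    x, y = _finite_vec(x, "x"), _finite_vec(y, "y")
    if x.size != y.size or x.size < 3:
        raise V2GError("need equal-length vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise V2GError("correlation undefined for zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def unpaired_ttest(a, b, equal_var: bool = True):
    """Two-sided two-sample t-test (Student by default, Welch optional).

    Returns (t, p, (mean_a, mean_b), (sd_a, sd_b)); sample SDs use ddof=1.
    """
    a, b = _finite_vec(a, "a"), _finite_vec(b, "b")
    if a.size < 2 or b.size < 2:
        raise V2GError("each group needs at least 2 observations")
    means = (float(np.mean(a)), float(np.mean(b)))
    sds = (float(np.std(a, ddof=1)), float(np.std(b, ddof=1)))
    if sds == (0.0, 0.0):
        # degenerate variance: exact-equality shortcut
        p = 1.0 if means[0] == means[1] else 0.0
        return 0.0 if means[0] == means[1] else np.inf, p, means, sds
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p), means, sds


def paired_ttest(a, b):
    """Two-sided paired t-test on the differences a - b.

    Zero-variance differences short-circuit: p = 1 for identical pairs
    (flagged with t = 0), p = 0 for a constant non-zero shift.
    """
    a, b = _finite_vec(a, "a"), _finite_vec(b, "b")
    if a.size != b.size or a.size < 2:
        raise V2GError("need equal-length pairs, n >= 2")
    d = a - b
    if np.std(d, ddof=1) == 0:
        if np.all(d == 0):
            log.warning("paired t-test on identical vectors; p = 1 by convention")
            return 0.0, 1.0
        return np.inf if d[0] > 0 else -np.inf, 0.0
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p)


def lme_random_intercept(values, patients, conditions):
    """Random-intercept-per-patient LME with a fixed condition effect.

    Fit by REML (profiled restricted likelihood over the variance ratio);
    returns (fixed effect estimate, Wald two-sided p).  Singular fits fall
    back to zero between-patient variance with a warning, which reduces the
    Wald test to an ordinary regression test.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame({
        "value": np.asarray(values, dtype=float),
        "patient": np.asarray(patients),
        "condition": np.asarray(conditions),
    })
    if df.patient.nunique() < 2:
        raise V2GError("need at least 2 patients")
    levels = sorted(df.condition.unique())
    if len(levels) != 2:
        raise V2GError("need exactly 2 condition labels")
    df["x"] = (df.condition == levels[1]).astype(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = smf.mixedlm("value ~ x", df, groups=df["patient"]).fit(
                reml=True)
            effect = float(fit.params["x"])
            p = float(fit.pvalues["x"])
        except Exception:
            log.warning("singular LME fit; falling back to zero "
                        "between-patient variance")
            ols = sm.OLS(df.value, sm.add_constant(df.x)).fit()
            effect, p = float(ols.params["x"]), float(ols.pvalues["x"])
    if not np.isfinite(p):
        ols = sm.OLS(df.value, sm.add_constant(df.x)).fit()
        effect, p = float(ols.params["x"]), float(ols.pvalues["x"])
    return effect, p


@dataclass(frozen=True)
class GroupSummary:
    field: str
    mean1: float
    sd1: float
    mean2: float
    sd2: float
    percent_difference: float
    p: float


def group_summary(cohort: pd.DataFrame, field: str,
                  group_col: str = "group") -> GroupSummary:
    """Mean +/- SD per outcome group, percent difference and Student-t p.

    Percent difference is (mean2 - mean1) / mean1 * 100.
    """
    g1 = cohort.loc[cohort[group_col] == 1, field].to_numpy(dtype=float)
    g2 = cohort.loc[cohort[group_col] == 2, field].to_numpy(dtype=float)
    _, p, (m1, m2), (s1, s2) = unpaired_ttest(g1, g2)
    pct = (m2 - m1) / m1 * 100.0 if m1 != 0 else np.nan
    sw1, sw2 = stats.shapiro(g1), stats.shapiro(g2)
    log.info("normality (Shapiro-Wilk) %s: group1 p=%.3f group2 p=%.3f",
             field, sw1.pvalue, sw2.pvalue)
    return GroupSummary(field, m1, s1, m2, s2, pct, p)


def percent_difference(a: float, b: float) -> float:
    """(b - a) / a * 100."""
    return (b - a) / a * 100.0
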