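"""Cohort-level statistics for the 8 functional parameters.

Implements the discrimination pipeline: two-sided pooled-variance Student's
t per parameter (with a Lilliefors/Kolmogorov-Smirnov normality check per
group), per-parameter logistic regression on the z-standardized feature
(odds ratio per 1 SD with Wald 95% CI), and a combined multivariable
logistic model whose C-statistic (ROC AUC) is reported with a DeLong 95%
confidence interval.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .io import FEATURE_NAMES

logger = logging.getLogger(__name__)

GROUP_CONTROL = "normal"
GROUP_CASE = "dm"


@dataclass
class GroupComparison:
    parameter: str
    mean_sd: dict  # group -> (mean, sd)
    n: dict  # group -> count
    t_statistic: float
    p_value: float
    normality_p: dict  # group -> KS normality p
    degenerate: bool = False


@dataclass
class LogisticResult:
    parameter: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    separation: bool = False
    per_sd: bool = True


@dataclass
class DiscriminationResult:
    parameters: list
    per_parameter: list  # list[LogisticResult]
    c_statistic: float
    ci_low: float
    ci_high: float
    roc_points: pd.DataFrame = field(default_factory=pd.DataFrame)
    n_used: int = 0
    n_dropped: int = 0


class DegenerateVarianceError(ValueError):
    """Both groups have zero pooled variance; the t-statistic is undefined."""


class CohortError(ValueError):
    pass


def _split_groups(table: pd.DataFrame, parameter: str
                  ) -> tuple[np.ndarray, np.ndarray]:
    g = table["group"].astype(str).str.lower()
    x0 = table.loc[g == GROUP_CONTROL, parameter].dropna().to_numpy(float)
    x1 = table.loc[g == GROUP_CASE, parameter].dropna().to_numpy(float)
    return x0, x1


def pooled_t(x0: np.ndarray, x1: np.ndarray) -> tuple[float, float]:
    """Two-sided pooled-variance Student's t (df = n0 + n1 - 2).

    Orientation follows the control-minus-case convention, so a higher
    case-group mean yields a negative t.
    """
    n0, n1 = len(x0), len(x1)
    sp2 = (((n0 - 1) * x0.var(ddof=1) + (n1 - 1) * x1.var(ddof=1))
           / (n0 + n1 - 2))
    if sp2 <= 0:
        raise DegenerateVarianceError("zero pooled variance")
    t = (x0.mean() - x1.mean()) / math.sqrt(sp2 * (1 / n0 + 1 / n1))
    p = 2 * sps.t.sf(abs(t), df=n0 + n1 - 2)
    return float(t), float(p)


def compare_groups(table: pd.DataFrame,
                   parameters: list[str] | None = None
                   ) -> list[GroupComparison]:
    """Per-parameter control-vs-case comparison.

    Pooled-variance two-sided Student's t for each parameter, with the
    Lilliefors (Kolmogorov-Smirnov with estimated moments) normality p per
    group reported alongside.  Parameters missing in either group are
    skipped with a warning; zero-variance parameters are reported as
    degenerate rather than as a number.
    """
    parameters = parameters or FEATURE_NAMES
    out = []
    for p in parameters:
        x0, x1 = _split_groups(table, p)
        if len(x0) < 2 or len(x1) < 2:
            logger.warning("parameter %s: fewer than 2 subjects per group; skipped", p)
            continue
        norm_p = {}
        for grp, x in ((GROUP_CONTROL, x0), (GROUP_CASE, x1)):
            if x.std(ddof=1) > 0:
                norm_p[grp] = float(lilliefors(x, dist="norm")[1])
            else:
                norm_p[grp] = math.nan
        comp = GroupComparison(
            parameter=p,
            mean_sd={GROUP_CONTROL: (float(x0.mean()), float(x0.std(ddof=1))),
                     GROUP_CASE: (float(x1.mean()), float(x1.std(ddof=1)))},
            n={GROUP_CONTROL: len(x0), GROUP_CASE: len(x1)},
            t_statistic=math.nan, p_value=math.nan, normality_p=norm_p)
        try:
            comp.t_statistic, comp.p_value = pooled_t(x0, x1)
        except DegenerateVarianceError:
            comp.degenerate = True
            logger.warning("parameter %s: zero pooled variance", p)
        out.append(comp)
    return out


def sex_chi_square(table: pd.DataFrame, column: str = "sex") -> tuple[float, float]:
    """Chi-square test of the sex-by-group contingency (when demographics present)."""
    contingency = pd.crosstab(table["group"], table[column])
    chi2, p, _, _ = sps.chi2_contingency(contingency)
    return float(chi2), float(p)


def _design(table: pd.DataFrame, parameters: list[str]
            ) -> tuple[np.ndarray, np.ndarray, int]:
    cols = ["group"] + parameters
    sub = table[cols].dropna()
    n_dropped = len(table) - len(sub)
    y = (sub["group"].astype(str).str.lower() == GROUP_CASE).to_numpy(int)
    X = sub[parameters].to_numpy(float)
    return X, y, n_dropped


def _zscore(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    return (X - X.mean(axis=0)) / sd


def univariate_logistic(table: pd.DataFrame, parameter: str) -> LogisticResult:
    """Logistic fit of case status on one z-standardized parameter.

    The odds ratio is per 1 SD of the parameter, with a Wald 95% CI.
    Perfect (or quasi-perfect) separation is flagged and the CI reported
    as unbounded.
    """
    X, y, _ = _design(table, [parameter])
    if y.min() == y.max():
        raise CohortError("both groups must be represented")
    Xz = sm.add_constant(_zscore(X))
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, Xz).fit(disp=0, maxiter=200)
        beta = fit.params[1]
        se = fit.bse[1]
        pval = float(fit.pvalues[1])
        separation = bool(not np.isfinite(se) or se > 50 or abs(beta) > 20)
    except (PerfectSeparationError, np.linalg.LinAlgError):
        beta, se, pval, separation = math.inf, math.inf, 0.0, True
    if separation:
        logger.warning("parameter %s: (quasi-)perfect separation", parameter)
        return LogisticResult(parameter, math.exp(min(beta, 700)),
                              0.0, math.inf, pval, separation=True)
    lo, hi = math.exp(beta - 1.959963984540054 * se), math.exp(beta + 1.959963984540054 * se)
    return LogisticResult(parameter, math.exp(beta), lo, hi, pval)


def mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """All-pairs AUC: P(score_case > score_control) + 0.5 P(tie)."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    pos, neg = s[y == 1], s[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        return math.nan
    diff = pos[:, None] - neg[None, :]
    return float(((diff > 0).sum() + 0.5 * (diff == 0).sum())
                 / (len(pos) * len(neg)))


def delong_ci(scores: np.ndarray, labels: np.ndarray, alpha: float = 0.05
              ) -> tuple[float, float, float]:
    """AUC with a DeLong 95% CI (placement-value variance), clipped to [0, 1]."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    pos, neg = s[y == 1], s[y == 0]
    m, n = len(pos), len(neg)
    # placement values: for each positive, fraction of negatives it beats
    cmp_mat = (pos[:, None] > neg[None, :]).astype(float) \
        + 0.5 * (pos[:, None] == neg[None, :])
    v10 = cmp_mat.mean(axis=1)  # per-positive
    v01 = cmp_mat.mean(axis=0)  # per-negative
    auc = float(cmp_mat.mean())
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) \
        + (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    z = sps.norm.ppf(1 - alpha / 2)
    half = z * math.sqrt(max(var, 0.0))
    return auc, max(0.0, auc - half), min(1.0, auc + half)


def combined_roc(table: pd.DataFrame,
                 parameters: list[str] | None = None) -> DiscriminationResult:
    """Multivariable logistic discrimination over the listed parameters.

    Fits case status on all z-standardized parameters jointly, scores each
    subject with the fitted probability, and reports the C-statistic
    (trapezoidal ROC AUC, identical to the Mann-Whitney pair count) with a
    DeLong 95% CI, plus the per-parameter univariate odds ratios.  Rows
    with any missing parameter are dropped listwise.
    """
    parameters = parameters or FEATURE_NAMES
    X, y, n_dropped = _design(table, parameters)
    if n_dropped:
        logger.info("dropped %d rows with missing features", n_dropped)
    if y.min() == y.max():
        raise CohortError("both groups must be represented")
    Xz = sm.add_constant(_zscore(X))
    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, Xz).fit(disp=0, maxiter=200)
    except np.linalg.LinAlgError as e:
        raise CohortError(f"collinear parameters; logistic fit failed: {e}")
    scores = np.asarray(fit.predict(Xz))
    auc, lo, hi = delong_ci(scores, y)
    fpr_tpr = roc_points(scores, y)
    per_param = [univariate_logistic(table, p) for p in parameters]
    return DiscriminationResult(
        parameters=list(parameters), per_parameter=per_param,
        c_statistic=auc, ci_low=lo, ci_high=hi,
        roc_points=fpr_tpr, n_used=len(y), n_dropped=n_dropped)


def roc_points(scores: np.ndarray, labels: np.ndarray) -> pd.DataFrame:
    """Empirical ROC curve points (fpr, tpr, threshold)."""
    from sklearn.metrics import roc_curve
    fpr, tpr, thr = roc_curve(labels, scores)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def comparison_table(comparisons: list[GroupComparison]) -> pd.DataFrame:
    rows = []
    for c in comparisons:
        m0, s0 = c.mean_sd[GROUP_CONTROL]
        m1, s1 = c.mean_sd[GROUP_CASE]
        rows.append({
            "parameter": c.parameter,
            "normal_mean": m0, "normal_sd": s0,
            "dm_mean": m1, "dm_sd": s1,
            "t_statistic": c.t_statistic, "p_value": c.p_value,
            "normality_p_normal": c.normality_p.get(GROUP_CONTROL),
            "normality_p_dm": c.normality_p.get(GROUP_CASE),
            "degenerate": c.degenerate,
        })
    return pd.DataFrame(rows)


def regression_table(results: list[LogisticResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "parameter": r.parameter, "odds_ratio": r.odds_ratio,
        "ci_lower": r.ci_low, "ci_upper": r.ci_high,
        "p_value": r.p_value, "separation": r.separation,
    } for r in results])
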