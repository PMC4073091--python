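"""Group-level inferential statistics for the fitted observer parameters.

Covers the contrasts the analysis pipeline reports: one-sample/paired/
two-sample Student t tests, Pearson and Spearman correlations, partial
correlations by residualisation (ranks first for the Spearman variant),
one-way repeated-measures ANOVA with Greenhouse-Geisser correction, the
prior-accuracy contrast (|prior SD - performance SD| for self vs. agent),
the median-split learning analysis, and Bonferroni adjustment.

Participants with flat agent priors are excluded from parametric SD
contrasts but retained for rank-based correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InputError, StatisticError

__all__ = [
    "TTestResult",
    "CorrelationResult",
    "RmAnovaResult",
    "one_sample_t",
    "paired_t",
    "two_sample_t",
    "correlations",
    "partial_correlation",
    "rm_anova_gg",
    "prior_accuracy_contrast",
    "median_split_learning",
    "bonferroni",
]


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int
    method: str

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class RmAnovaResult:
    F: float
    df1: float
    df2: float
    epsilon: float
    p_gg: float
    p_uncorrected: float

    def to_dict(self) -> dict:
        return asdict(self)


def _check_1d(x, min_n: int, name: str = "values") -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise InputError(f"{name} must be 1-dimensional")
    if len(x) < min_n:
        raise StatisticError(f"{name}: need at least {min_n} observations, got {len(x)}")
    return x


def one_sample_t(values, mu: float = 0.0) -> TTestResult:
    """Two-sided one-sample Student t test with df = n - 1.

    All values exactly equal to ``mu`` give t = 0, p = 1 (no deviation at
    all); zero variance around a different mean is an error.
    """
    x = _check_1d(values, 2)
    if np.std(x, ddof=1) == 0:
        if x[0] == mu:
            return TTestResult(0.0, len(x) - 1, 1.0, len(x))
        raise StatisticError("zero variance: t statistic undefined")
    t, p = sps.ttest_1samp(x, mu)
    return TTestResult(float(t), len(x) - 1, float(p), len(x))


def paired_t(x, y) -> TTestResult:
    """Two-sided paired Student t test (t = 0, p = 1 for identical vectors)."""
    x = _check_1d(x, 2, "x")
    y = _check_1d(y, 2, "y")
    if len(x) != len(y):
        raise InputError("paired vectors must have equal length")
    d = x - y
    if np.std(d, ddof=1) == 0:
        if np.all(d == d[0]) and d[0] == 0:
            return TTestResult(0.0, len(d) - 1, 1.0, len(d))
        raise StatisticError("zero variance of differences: t statistic undefined")
    t, p = sps.ttest_rel(x, y)
    return TTestResult(float(t), len(x) - 1, float(p), len(x))


def two_sample_t(x, y) -> TTestResult:
    """Two-sided independent-samples Student t (pooled variance, df = n1+n2-2)."""
    x = _check_1d(x, 2, "x")
    y = _check_1d(y, 2, "y")
    if np.std(np.concatenate([x - x.mean(), y - y.mean()]), ddof=2) == 0:
        if x.mean() == y.mean():
            return TTestResult(0.0, len(x) + len(y) - 2, 1.0, len(x) + len(y))
        raise StatisticError("zero within-group variance: t statistic undefined")
    t, p = sps.ttest_ind(x, y, equal_var=True)
    return TTestResult(float(t), len(x) + len(y) - 2, float(p), len(x) + len(y))


def correlations(x, y, method: str = "pearson") -> CorrelationResult:
    """Pearson product-moment or Spearman rank correlation with p-value."""
    x = _check_1d(x, 3, "x")
    y = _check_1d(y, 3, "y")
    if len(x) != len(y):
        raise InputError("x and y must have equal length")
    if np.std(x) == 0 or np.std(y) == 0:
        raise StatisticError("zero variance: correlation undefined")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise InputError(f"unknown method {method!r}")
    return CorrelationResult(float(r), float(p), len(x), method)


def partial_correlation(x, y, covar, method: str = "pearson") -> CorrelationResult:
    """Correlation of x and y after removing a single covariate.

    Both variables are residualised on the covariate by OLS and the residuals
    correlated; for the Spearman variant all three vectors are rank-
    transformed first.  The p-value uses the t approximation with df = n - 3.
    """
    x = _check_1d(x, 4, "x")
    y = _check_1d(y, 4, "y")
    c = _check_1d(covar, 4, "covar")
    if not (len(x) == len(y) == len(c)):
        raise InputError("x, y and covar must have equal length")
    if np.std(c) == 0:
        raise StatisticError("covariate has zero variance")
    if method == "spearman":
        x, y, c = sps.rankdata(x), sps.rankdata(y), sps.rankdata(c)
    elif method != "pearson":
        raise InputError(f"unknown method {method!r}")
    n = len(x)
    X = np.column_stack([np.ones(n), c])

    def _resid(v):
        beta, *_ = np.linalg.lstsq(X, v, rcond=None)
        return v - X @ beta

    rx, ry = _resid(x), _resid(y)
    if np.std(rx) < 1e-12 * max(1.0, np.std(x)) or np.std(ry) < 1e-12 * max(1.0, np.std(y)):
        raise StatisticError("variable is collinear with the covariate")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 3
    r_clamped = min(max(r, -1.0 + 1e-15), 1.0 - 1e-15)
    t = r_clamped * np.sqrt(df / (1.0 - r_clamped**2))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return CorrelationResult(r, p, n, f"partial-{method}")


def rm_anova_gg(matrix) -> RmAnovaResult:
    """One-way repeated-measures ANOVA with Greenhouse-Geisser correction.

    ``matrix`` is subjects x levels with complete cases.  Epsilon is computed
    from the double-centred sample covariance of the level scores; corrected
    dfs are eps*(L-1) and eps*(L-1)*(n-1).  With two levels epsilon is
    exactly 1.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2:
        raise InputError("matrix must be subjects x levels")
    n, L = m.shape
    if n < 2 or L < 2:
        raise InputError("need at least 2 subjects and 2 levels")
    if np.any(~np.isfinite(m)):
        raise InputError("missing cells in repeated-measures matrix")

    grand = m.mean()
    subj_means = m.mean(axis=1, keepdims=True)
    level_means = m.mean(axis=0, keepdims=True)
    ss_level = n * float(np.sum((level_means - grand) ** 2))
    resid = m - subj_means - level_means + grand
    ss_error = float(np.sum(resid**2))
    df1, df2 = L - 1, (L - 1) * (n - 1)
    if ss_error == 0:
        F = 0.0 if ss_level == 0 else np.inf
    else:
        F = (ss_level / df1) / (ss_error / df2)

    S = np.cov(m, rowvar=False, ddof=1)
    J = np.eye(L) - np.ones((L, L)) / L
    Sc = J @ S @ J
    denom = (L - 1) * float(np.sum(Sc**2))
    epsilon = 1.0 if denom == 0 else float(np.trace(Sc) ** 2 / denom)
    epsilon = min(max(epsilon, 1.0 / (L - 1)), 1.0)

    p_unc = float(sps.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    p_gg = float(sps.f.sf(F, epsilon * df1, epsilon * df2)) if np.isfinite(F) else 0.0
    return RmAnovaResult(float(F), epsilon * df1, epsilon * df2, epsilon, p_gg, p_unc)


def prior_accuracy_contrast(group_table: pd.DataFrame) -> dict:
    """How well priors track true performance, self vs. agent.

    Per participant the absolute deviation |prior SD - performance SD| is
    computed for both conditions; the paired contrast (agent minus self) runs
    on flat-excluded participants.  Also reports the one-sample contrast of
    (self prior SD - performance SD) against zero over all participants.
    """
    required = {"performance_sd", "self_prior_sd", "agent_prior_sd", "agent_flat"}
    missing = required - set(group_table.columns)
    if missing:
        raise InputError(f"group table is missing columns {sorted(missing)}")
    gt = group_table
    self_diff = (gt["self_prior_sd"] - gt["performance_sd"]).to_numpy(dtype=float)
    report: dict = {
        "self_prior_minus_performance": one_sample_t(self_diff, 0.0).to_dict(),
        "n_total": int(len(gt)),
    }
    nonflat = gt.loc[~gt["agent_flat"].astype(bool)]
    report["n_nonflat"] = int(len(nonflat))
    if len(nonflat) < 2:
        report["deviation_contrast"] = None
        report["notice"] = "agent priors flat for (almost) all participants; paired contrast skipped"
        return report
    self_dev = (nonflat["self_prior_sd"] - nonflat["performance_sd"]).abs().to_numpy(dtype=float)
    agent_dev = (nonflat["agent_prior_sd"] - nonflat["performance_sd"]).abs().to_numpy(dtype=float)
    report["mean_self_deviation"] = float(np.mean(self_dev))
    report["mean_agent_deviation"] = float(np.mean(agent_dev))
    report["median_self_deviation"] = float(np.median(self_dev))
    report["median_agent_deviation"] = float(np.median(agent_dev))
    # fitted prior SDs are heavy-tailed when the weight is near zero, so the
    # per-participant majority is the robust directional summary
    report["fraction_agent_closer"] = float(np.mean(agent_dev < self_dev))
    report["deviation_contrast"] = paired_t(agent_dev, self_dev).to_dict()
    return report


def median_split_learning(group_table: pd.DataFrame) -> dict:
    """Learning (perf SD during - before) in narrow- vs. wide-prior groups.

    Participants are ordered by self prior SD and split at the median into
    two groups; ties at the median, and the median participant when n is odd,
    go to the lower (narrow-prior) group.  Reports the two-sample t on
    learning scores and the continuous correlation version.
    """
    required = {"self_prior_sd", "perf_sd_before", "perf_sd_during"}
    missing = required - set(group_table.columns)
    if missing:
        raise InputError(f"group table is missing columns {sorted(missing)}")
    if len(group_table) < 4:
        raise StatisticError("median split needs at least 4 participants")
    gt = group_table.reset_index(drop=True)
    learning = (gt["perf_sd_during"] - gt["perf_sd_before"]).to_numpy(dtype=float)
    order = np.lexsort((np.arange(len(gt)), gt["self_prior_sd"].to_numpy(dtype=float)))
    n_low = int(np.ceil(len(gt) / 2))
    low, high = order[:n_low], order[n_low:]
    ttest = two_sample_t(learning[high], learning[low])
    try:
        corr = correlations(
            gt["self_prior_sd"].to_numpy(dtype=float), learning, "pearson"
        ).to_dict()
    except StatisticError:
        corr = None  # constant learning scores: no relation to estimate
    return {
        "group_sizes": [int(len(low)), int(len(high))],
        "mean_learning_narrow": float(np.mean(learning[low])),
        "mean_learning_wide": float(np.mean(learning[high])),
        "t_test": ttest.to_dict(),
        "correlation": corr,
    }


def bonferroni(p_values, m: int | None = None):
    """Bonferroni adjustment: min(1, m * p) per value."""
    p = np.atleast_1d(np.asarray(p_values, dtype=float))
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if m is None:
        m = len(p)
    if m < len(p):
        raise ValueError("m must be at least the number of p-values")
    adj = np.minimum(1.0, m * p)
    return float(adj[0]) if np.isscalar(p_values) or np.ndim(p_values) == 0 else adj
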