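"""Trial filtering and the estimation-error regression.

The model predicts, within any one parameter cell,

    estimation error = -w * performance error + noise,

so the negative slope of an ordinary least-squares regression of estimation
error (report minus true stop) on performance error (true stop minus target)
is a direct, model-free readout of the prior weighting w.  Before the
regression, unusually slow trials are flagged: estimation times beyond 2 SD
of their cell mean (all trials), and reaction times beyond 2 SD (agent
trials only, as an attention control).  Rows are only ever flagged, never
dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .errors import EstimationError, InputError

__all__ = ["RegressionResult", "ErrorRegression", "apply_exclusions", "fit_error_regression"]

#: exclusion reason codes
REASON_EST_TIME = "est_time"
REASON_AGENT_RT = "agent_rt"


@dataclass(frozen=True)
class RegressionResult:
    """OLS fit of estimation error on performance error for one cell."""

    slope: float
    intercept: float
    slope_se: float
    residual_sd_px: float
    n_used: int

    @property
    def weighting(self) -> float:
        """Empirical prior weighting, identically -slope."""
        return -self.slope

    def to_dict(self) -> dict:
        d = asdict(self)
        d["weighting"] = self.weighting
        return d


def _cell_columns(trials: pd.DataFrame) -> list[str]:
    cols = ["participant_id", "condition"]
    if "task" in trials.columns:
        cols.append("task")
    return [c for c in cols if c in trials.columns]


def apply_exclusions(trials: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with ``excluded``/``excluded_reason`` set.

    The 2-SD rule is two-sided, |t - mean| > 2 SD, with mean/SD computed over
    all trials of the cell (participant x condition, x task when a ``task``
    column is present) — including already-flagged rows, so re-applying is a
    no-op.  Cells with SD = 0 exclude nothing (strict inequality).
    """
    for col in ("estimation_time_s", "condition"):
        if col not in trials.columns:
            raise InputError(f"missing required column {col!r}")
    out = trials.copy()
    if not out.index.is_unique:
        out = out.reset_index(drop=True)
    n = len(out)
    pos_of = {idx: i for i, idx in enumerate(out.index)}
    reasons = [[] for _ in range(n)]
    cell_cols = _cell_columns(out)
    grouped = out.groupby(cell_cols, sort=False, dropna=False) if cell_cols else [(None, out)]

    for _, cell in grouped:
        est = cell["estimation_time_s"].to_numpy(dtype=float)
        m = np.nanmean(est)
        s = np.nanstd(est, ddof=1) if len(est) > 1 else 0.0
        if s > 0:
            for idx, flag in zip(cell.index, np.abs(est - m) > 2.0 * s):
                if flag:
                    reasons[pos_of[idx]].append(REASON_EST_TIME)
        agent = cell[cell["condition"] == "agent"]
        if len(agent) > 1 and "reaction_time_s" in agent.columns:
            rt = agent["reaction_time_s"].to_numpy(dtype=float)
            m = np.nanmean(rt)
            s = np.nanstd(rt, ddof=1)
            if s > 0:
                for idx, flag in zip(agent.index, np.abs(rt - m) > 2.0 * s):
                    if flag:
                        reasons[pos_of[idx]].append(REASON_AGENT_RT)

    out["excluded"] = [bool(r) for r in reasons]
    out["excluded_reason"] = ["+".join(r) for r in reasons]
    return out


class ErrorRegression(BaseEstimator):
    """OLS of estimation error on performance error (scikit-learn style).

    Parameters
    ----------
    include_excluded : bool, default False
        Fit on all rows instead of only non-excluded ones.

    Attributes (after ``fit``)
    --------------------------
    slope_, intercept_, slope_se_, residual_sd_, n_used_, weighting_
    result_ : :class:`RegressionResult`
    """

    def __init__(self, include_excluded: bool = False):
        self.include_excluded = include_excluded

    def fit(self, trials: pd.DataFrame, y=None):
        df = trials
        if not self.include_excluded and "excluded" in df.columns:
            df = df.loc[~df["excluded"].astype(bool)]
        x = (df["true_stop_x_px"] - df["target_x_px"]).to_numpy(dtype=float)
        yv = (df["estimate_x_px"] - df["true_stop_x_px"]).to_numpy(dtype=float)
        n = len(x)
        if n < 3:
            raise EstimationError(f"need at least 3 usable trials, got {n}")
        sxx = float(np.sum((x - x.mean()) ** 2))
        if sxx == 0.0:
            raise EstimationError("performance errors have zero variance")
        slope = float(np.sum((x - x.mean()) * (yv - yv.mean())) / sxx)
        intercept = float(yv.mean() - slope * x.mean())
        resid = yv - (intercept + slope * x)
        ms_resid = float(np.sum(resid**2) / (n - 2))
        self.slope_ = slope
        self.intercept_ = intercept
        self.slope_se_ = float(np.sqrt(ms_resid / sxx))
        self.residual_sd_ = float(np.sqrt(ms_resid))
        self.n_used_ = n
        self.weighting_ = -slope
        self.result_ = RegressionResult(
            slope=slope,
            intercept=intercept,
            slope_se=self.slope_se_,
            residual_sd_px=self.residual_sd_,
            n_used=n,
        )
        return self

    def predict(self, trials: pd.DataFrame) -> np.ndarray:
        x = (trials["true_stop_x_px"] - trials["target_x_px"]).to_numpy(dtype=float)
        return self.intercept_ + self.slope_ * x


def fit_error_regression(trials: pd.DataFrame, include_excluded: bool = False) -> RegressionResult:
    """Functional wrapper around :class:`ErrorRegression`."""
    return ErrorRegression(include_excluded=include_excluded).fit(trials).result_
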