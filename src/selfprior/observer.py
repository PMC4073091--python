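"""Bayesian observer models of position reports.

The observer combines a Gaussian prior over outcomes (centred on the goal)
with Gaussian sensory evidence about the true outcome.  The reported position
is the posterior mode,

    x_estimate = w * (x_prior + shift_prior) + (1 - w) * (x_evidence + d * shift_evidence),
    w = sigma_evidence^2 / (sigma_prior^2 + sigma_evidence^2),

where ``d`` is the direction of stimulus motion (+1/-1) when the evidence
shift is direction-coupled.  The report distribution given the true outcome is
Gaussian with SD ``(1 - w) * sigma_evidence`` (the evidence noise propagated
through the weighting).  Parameters are tied across experimental factors
according to a :class:`ModelSpec`, fitted by maximum likelihood with
multi-start quasi-Newton optimisation in log-SD coordinates, and compared by
BIC.  Percentile bootstrap supplies confidence intervals.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from sklearn.base import BaseEstimator

from ._rng import derive_rng
from .errors import ConfigError, FitError, InputError, StatisticError

__all__ = [
    "ModelSpec",
    "FitResult",
    "BayesianObserver",
    "MODEL_PRESETS",
    "get_model_spec",
    "posterior_weight",
    "predict_estimate",
    "neg_log_likelihood",
    "count_free_params",
    "fit_model",
    "compute_bic",
    "compare_models",
    "bootstrap_cis",
    "classify_flat",
    "FLAT_PRIOR_THRESHOLD",
]

#: Fitted prior SDs above this value (px) are classified as "flat": the prior
#: is so wide that it contributes no perceptual bias (weight ~ 0).
FLAT_PRIOR_THRESHOLD = 1e7

#: BIC difference treated as strong evidence (inclusive).
STRONG_EVIDENCE_DELTA_BIC = 6.0

_CONDITION_ORDER = ("self", "agent")
_FEEDBACK_ORDER = ("low", "medium", "high", "none")
_EV_FACTORS = ("condition", "direction", "feedback_level")

_LOG_2PI = math.log(2.0 * math.pi)


# ---------------------------------------------------------------------------
# Core formulas


def posterior_weight(prior_sd: float, evidence_sd: float):
    """Relative weight of the prior in the posterior mode.

    w = sigma_evidence^2 / (sigma_prior^2 + sigma_evidence^2); strictly in
    (0, 1) for finite positive SDs, increasing in evidence SD and decreasing
    in prior SD.  Accepts arrays.
    """
    prior_sd = np.asarray(prior_sd, dtype=float)
    evidence_sd = np.asarray(evidence_sd, dtype=float)
    if np.any(prior_sd <= 0) or np.any(evidence_sd <= 0):
        raise ValueError("prior_sd and evidence_sd must be strictly positive")
    # compute in a scale-free way to avoid overflow for very wide priors
    ratio = (prior_sd / evidence_sd) ** 2
    w = 1.0 / (1.0 + ratio)
    return w if w.ndim else float(w)


def predict_estimate(params, true_stop, direction=1):
    """Mean and SD of the report distribution for one factor cell.

    ``params`` is an :class:`~selfprior.tasks.ObserverParams`-like object with
    scalar ``prior_mean_px``, ``prior_sd_px``, ``evidence_sd_px``,
    ``prior_shift_px`` and ``evidence_shift_px``.  Returns ``(mean, sd)``.
    """
    w = posterior_weight(params.prior_sd_px, params.evidence_sd_px)
    mean = w * (params.prior_mean_px + params.prior_shift_px) + (1.0 - w) * (
        np.asarray(true_stop, dtype=float) + np.asarray(direction) * params.evidence_shift_px
    )
    sd = (1.0 - w) * params.evidence_sd_px
    return mean, sd


def compute_bic(neg_log_lik: float, k: int, n: int) -> float:
    """BIC = k ln(n) + 2 * negative log-likelihood (lower is better)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if k < 0:
        raise ValueError("k must be >= 0")
    return k * math.log(n) + 2.0 * neg_log_lik


# ---------------------------------------------------------------------------
# Model specifications (parameter tying)


@dataclass(frozen=True)
class ModelSpec:
    """A parameter-tying scheme over the factors present in the data.

    ``tie_evidence_across`` lists factors over which the evidence SD is
    shared; ``tie_prior_across`` may contain ``"condition"`` to share one
    prior between self and agent trials.  When ``include_shifts`` is set the
    prior mean is ``target + shift_prior`` and the evidence mean is
    ``true_stop + direction * shift_evidence`` (the direction coupling can be
    switched off).
    """

    name: str
    tie_evidence_across: frozenset = field(default_factory=frozenset)
    tie_prior_across: frozenset = field(default_factory=frozenset)
    include_shifts: bool = False
    fix_prior_mean_at_target: bool = True
    evidence_shift_direction_coupled: bool = True

    def __post_init__(self):
        object.__setattr__(self, "tie_evidence_across", frozenset(self.tie_evidence_across))
        object.__setattr__(self, "tie_prior_across", frozenset(self.tie_prior_across))
        bad = self.tie_evidence_across - set(_EV_FACTORS)
        if bad:
            raise ConfigError(f"unknown factors in tie_evidence_across: {sorted(bad)}")
        if self.tie_prior_across - {"condition"}:
            raise ConfigError("tie_prior_across may only contain 'condition'")
        if not self.fix_prior_mean_at_target and not self.include_shifts:
            raise ConfigError(
                "a free prior mean is parameterised as target + shift_prior; "
                "set include_shifts=True"
            )


MODEL_PRESETS: dict[str, ModelSpec] = {
    # Separate prior and evidence SD per condition (4 parameters on
    # self+agent data with a single motion direction).
    "exp1_full": ModelSpec(
        "exp1_full", tie_evidence_across=frozenset({"direction", "feedback_level"})
    ),
    # One evidence SD shared across conditions (3 parameters).
    "exp1_shared_evidence": ModelSpec(
        "exp1_shared_evidence",
        tie_evidence_across=frozenset({"condition", "direction", "feedback_level"}),
    ),
    # One prior shared across conditions (3 parameters).
    "exp1_shared_prior": ModelSpec(
        "exp1_shared_prior",
        tie_evidence_across=frozenset({"direction", "feedback_level"}),
        tie_prior_across=frozenset({"condition"}),
    ),
    # Bidirectional task with free prior/evidence shifts; evidence SD per
    # condition x direction (10 parameters on two conditions x two directions).
    "exp2_full_shift": ModelSpec(
        "exp2_full_shift",
        tie_evidence_across=frozenset({"feedback_level"}),
        include_shifts=True,
    ),
    # As above but evidence SD tied across directions (8 parameters).
    "exp2_shared_evidence_direction": ModelSpec(
        "exp2_shared_evidence_direction",
        tie_evidence_across=frozenset({"direction", "feedback_level"}),
        include_shifts=True,
    ),
}


def get_model_spec(spec: str | ModelSpec) -> ModelSpec:
    if isinstance(spec, ModelSpec):
        return spec
    try:
        return MODEL_PRESETS[spec]
    except KeyError:
        raise ConfigError(f"unknown model preset {spec!r}; known: {sorted(MODEL_PRESETS)}")


def _ordered_levels(values: Iterable, order: Sequence) -> list:
    present = set(values)
    out = [v for v in order if v in present]
    out += sorted(present - set(out), key=str)
    return out


def data_levels(trials: pd.DataFrame) -> dict[str, list]:
    """Factor levels present in a trial table (condition, direction, feedback)."""
    return {
        "condition": _ordered_levels(trials["condition"], _CONDITION_ORDER),
        "direction": sorted(int(d) for d in set(trials["direction"])),
        "feedback_level": _ordered_levels(trials["feedback_level"], _FEEDBACK_ORDER),
    }


def count_free_params(model_spec: str | ModelSpec, levels: Mapping[str, Sequence]) -> int:
    """Exact number of free parameters implied by a spec and the data levels."""
    spec = get_model_spec(model_spec)
    for f in _EV_FACTORS:
        if f not in levels:
            raise ConfigError(f"data_levels is missing factor {f!r}")
        if len(levels[f]) == 0:
            raise ConfigError(f"factor {f!r} has no levels")
    n_cond = len(levels["condition"])
    n_prior = 1 if "condition" in spec.tie_prior_across else n_cond
    n_ev = 1
    for f in _EV_FACTORS:
        if f not in spec.tie_evidence_across:
            n_ev *= len(levels[f])
    n_shift = 2 * n_cond if spec.include_shifts else 0
    return n_prior + n_ev + n_shift


def _prior_cell(spec: ModelSpec, condition: str) -> str:
    return "*" if "condition" in spec.tie_prior_across else condition


def _ev_cell(spec: ModelSpec, condition, direction, feedback) -> tuple:
    return (
        "*" if "condition" in spec.tie_evidence_across else condition,
        "*" if "direction" in spec.tie_evidence_across else int(direction),
        "*" if "feedback_level" in spec.tie_evidence_across else feedback,
    )


def _ev_label(cell: tuple, levels: Mapping[str, Sequence]) -> str:
    cond, d, fb = cell
    parts = [str(cond)]
    if d != "*" and len(levels["direction"]) > 1:
        parts.append(f"dir={d:+d}")
    if fb != "*" and len(levels["feedback_level"]) > 1:
        parts.append(f"fb={fb}")
    return f"evidence_sd[{','.join(parts)}]"


def _prior_label(cell: str) -> str:
    return f"prior_sd[{cell}]"


# ---------------------------------------------------------------------------
# Likelihood machinery


class _Design:
    """Per-trial index arrays mapping trials to parameter cells."""

    def __init__(self, spec: ModelSpec, trials: pd.DataFrame):
        self.spec = spec
        self.levels = data_levels(trials)

        conds = self.levels["condition"]
        prior_cells = ["*"] if "condition" in spec.tie_prior_across else list(conds)
        cond_arr = trials["condition"].to_numpy()
        dir_arr = trials["direction"].to_numpy()
        fb_arr = trials["feedback_level"].to_numpy()
        trial_cells = [_ev_cell(spec, c, d, f) for c, d, f in zip(cond_arr, dir_arr, fb_arr)]
        ev_cells = list(dict.fromkeys(trial_cells))
        # stable ordering: by (condition, direction, feedback) with order lists
        def _cell_key(cell):
            c, d, fb = cell
            ck = -1 if c == "*" else conds.index(c)
            dk = -1 if d == "*" else self.levels["direction"].index(d)
            fk = -1 if fb == "*" else self.levels["feedback_level"].index(fb)
            return (ck, dk, fk)

        ev_cells.sort(key=_cell_key)
        self.prior_cells = prior_cells
        self.ev_cells = ev_cells
        self.conds = conds

        prior_pos = {c: i for i, c in enumerate(prior_cells)}
        ev_pos = {c: i for i, c in enumerate(ev_cells)}
        cond_pos = {c: i for i, c in enumerate(conds)}

        self.prior_idx = np.array(
            [prior_pos[_prior_cell(spec, c)] for c in cond_arr], dtype=np.intp
        )
        self.ev_idx = np.array([ev_pos[cell] for cell in trial_cells], dtype=np.intp)
        self.cond_idx = np.array([cond_pos[c] for c in cond_arr], dtype=np.intp)

        self.target = np.asarray(trials["target_x_px"], dtype=float)
        self.truth = np.asarray(trials["true_stop_x_px"], dtype=float)
        self.estimate = np.asarray(trials["estimate_x_px"], dtype=float)
        if spec.evidence_shift_direction_coupled:
            self.dir_sign = np.asarray(trials["direction"], dtype=float)
        else:
            self.dir_sign = np.ones(len(trials))
        if np.any(~np.isfinite(self.target)):
            raise InputError("observer models require a finite target_x_px on every trial")
        self.n = len(trials)
        self.n_prior = len(prior_cells)
        self.n_ev = len(ev_cells)
        self.n_shift = 2 * len(conds) if spec.include_shifts else 0
        self.k = self.n_prior + self.n_ev + self.n_shift

    # -- parameter vector layout: [log sp | log se | shift_p | shift_e] -----

    def labels(self) -> list[str]:
        out = [_prior_label(c) for c in self.prior_cells]
        out += [_ev_label(c, self.levels) for c in self.ev_cells]
        if self.spec.include_shifts:
            out += [f"shift_prior[{c}]" for c in self.conds]
            out += [f"shift_evidence[{c}]" for c in self.conds]
        return out

    def pack(self, params: Mapping[str, float]) -> np.ndarray:
        theta = []
        for lbl in self.labels():
            if lbl.startswith("shift"):
                theta.append(float(params.get(lbl, 0.0)))
            else:
                theta.append(math.log(float(params[lbl])))
        return np.array(theta)

    def unpack(self, theta: np.ndarray) -> dict[str, float]:
        out = {}
        for lbl, v in zip(self.labels(), theta):
            out[lbl] = float(v) if lbl.startswith("shift") else float(math.exp(v))
        return out

    def _split(self, theta: np.ndarray):
        np_, ne = self.n_prior, self.n_ev
        sp = np.exp(theta[:np_])
        se = np.exp(theta[np_ : np_ + ne])
        if self.spec.include_shifts:
            nc = len(self.conds)
            shp = theta[np_ + ne : np_ + ne + nc]
            she = theta[np_ + ne + nc :]
        else:
            shp = she = np.zeros(len(self.conds))
        return sp, se, shp, she

    def _moments(self, theta: np.ndarray):
        sp, se, shp, she = self._split(theta)
        sp_t = sp[self.prior_idx]
        se_t = se[self.ev_idx]
        ratio = (sp_t / se_t) ** 2
        w = 1.0 / (1.0 + ratio)
        a = self.target + shp[self.cond_idx]
        b = self.truth + self.dir_sign * she[self.cond_idx]
        mean = w * a + (1.0 - w) * b
        sd = (1.0 - w) * se_t
        return w, a, b, mean, sd, se_t

    def nll(self, theta: np.ndarray, floor: float = 0.0) -> float:
        _, _, _, mean, sd, _ = self._moments(theta)
        if floor:
            sd = np.maximum(sd, floor)
        resid = self.estimate - mean
        if np.any(sd <= 0):
            if np.all(resid[sd <= 0] == 0):
                sd = np.where(sd <= 0, 1.0, sd)  # zero-noise cells matched exactly
            else:
                return math.inf
        return float(np.sum(np.log(sd)) + 0.5 * self.n * _LOG_2PI + 0.5 * np.sum((resid / sd) ** 2))

    def nll_grad(self, theta: np.ndarray):
        """Objective and analytic gradient (with a small SD floor for safety)."""
        w, a, b, mean, sd, se_t = self._moments(theta)
        sd = np.maximum(sd, 1e-12)
        resid = self.estimate - mean
        f = float(np.sum(np.log(sd)) + 0.5 * self.n * _LOG_2PI + 0.5 * np.sum((resid / sd) ** 2))
        inv_sd = 1.0 / sd
        d_m = -resid * inv_sd**2            # d nll / d mean
        d_s = inv_sd - resid**2 * inv_sd**3  # d nll / d sd
        common = d_m * (a - b) - d_s * se_t  # d nll / d w
        ww = 2.0 * w * (1.0 - w)
        g_logsp = np.bincount(self.prior_idx, weights=-common * ww, minlength=self.n_prior)
        g_logse = np.bincount(
            self.ev_idx, weights=common * ww + d_s * (1.0 - w) * se_t, minlength=self.n_ev
        )
        parts = [g_logsp, g_logse]
        if self.spec.include_shifts:
            nc = len(self.conds)
            parts.append(np.bincount(self.cond_idx, weights=d_m * w, minlength=nc))
            parts.append(
                np.bincount(self.cond_idx, weights=d_m * (1.0 - w) * self.dir_sign, minlength=nc)
            )
        return f, np.concatenate(parts)


def neg_log_likelihood(
    params: Mapping[str, float], model_spec: str | ModelSpec, trials: pd.DataFrame
) -> float:
    """Negative log-likelihood (nats) of a trial table under flat-dict params.

    ``params`` maps parameter labels (as produced by a fit, e.g.
    ``"prior_sd[self]"``) to values; shifts excluded by the model spec default to 0.
    Returns ``inf`` (not an exception) when a zero-SD cell mismatches its data.
    """
    spec = get_model_spec(model_spec)
    design = _Design(spec, _usable(trials))
    return design.nll(design.pack(params))


def _usable(trials: pd.DataFrame) -> pd.DataFrame:
    if "excluded" in trials.columns:
        return trials.loc[~trials["excluded"].astype(bool)]
    return trials


# ---------------------------------------------------------------------------
# Fitted result container


@dataclass
class FitResult:
    """Maximum-likelihood fit of one :class:`ModelSpec` to one trial table."""

    model: str
    params: dict[str, float]
    neg_log_lik: float
    n_trials: int
    k: int
    bic: float
    converged: bool
    n_restarts_used: int
    levels: dict = field(default_factory=dict)
    spec: ModelSpec | None = None
    ci_95: dict | None = None

    def _resolve(self, label: str) -> float:
        if label not in self.params:
            raise KeyError(f"{label!r} not among fitted parameters {sorted(self.params)}")
        return self.params[label]

    def prior_sd(self, condition: str = "self") -> float:
        cell = _prior_cell(self.spec, condition)
        return self._resolve(_prior_label(cell))

    def evidence_sd(self, condition: str = "self", direction=None, feedback_level=None) -> float:
        if direction is None:
            direction = self.levels["direction"][0]
        if feedback_level is None:
            feedback_level = self.levels["feedback_level"][0]
        cell = _ev_cell(self.spec, condition, direction, feedback_level)
        return self._resolve(_ev_label(cell, self.levels))

    def shift_prior(self, condition: str = "self") -> float:
        return self.params.get(f"shift_prior[{condition}]", 0.0)

    def shift_evidence(self, condition: str = "self") -> float:
        return self.params.get(f"shift_evidence[{condition}]", 0.0)

    def weight(self, condition: str = "self", direction=None, feedback_level=None) -> float:
        return posterior_weight(
            self.prior_sd(condition), self.evidence_sd(condition, direction, feedback_level)
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("spec")
        if d["ci_95"] is not None:
            d["ci_95"] = {k: list(v) for k, v in d["ci_95"].items()}
        return d


# ---------------------------------------------------------------------------
# Estimator


class BayesianObserver(BaseEstimator):
    """Maximum-likelihood Bayesian observer fit (scikit-learn style).

    Parameters
    ----------
    model_spec : str or ModelSpec, default "exp1_full"
        Parameter-tying scheme (preset name or explicit spec).
    n_restarts : int, default 8
        Number of optimisation starts.  The first start is data-driven (from
        the error regression in each cell); the rest draw SDs log-uniformly
        in [1, 1e4] px.
    min_sd, max_sd : float
        Box bounds on SDs (px).  Fits hugging ``max_sd`` are not errors; very
        wide priors are later classified as flat.
    shift_bound : float
        Symmetric bound (px) on shift parameters.
    tol : float
        Convergence tolerance on the negative log-likelihood (nats).
    init_params : dict or None
        Optional warm start (a fitted ``params`` dict); used as the sole
        start when ``n_restarts == 1``.
    random_state : int or None
        Seed for the random restarts.

    Attributes (after ``fit``)
    --------------------------
    params_ : dict mapping parameter labels to fitted values (SDs in px)
    nll_, k_, n_trials_, bic_, converged_, n_restarts_used_
    result_ : :class:`FitResult`
    """

    def __init__(
        self,
        model_spec="exp1_full",
        n_restarts: int = 8,
        min_sd: float = 0.1,
        max_sd: float = 1e9,
        shift_bound: float = 2000.0,
        tol: float = 1e-8,
        init_params: dict | None = None,
        random_state: int | None = None,
    ):
        self.model_spec = model_spec
        self.n_restarts = n_restarts
        self.min_sd = min_sd
        self.max_sd = max_sd
        self.shift_bound = shift_bound
        self.tol = tol
        self.init_params = init_params
        self.random_state = random_state

    # -- starts -------------------------------------------------------------

    def _data_start(self, design: _Design) -> np.ndarray:
        """Start derived from per-cell error regressions.

        In each cell the model implies estimation error = -w * performance
        error with residual SD (1 - w) * sigma_evidence, so a no-intercept
        regression gives near-optimal starting values.
        """
        perf = design.truth - design.target
        est_err = design.estimate - design.truth
        lo, hi = self.min_sd * 1.01, self.max_sd * 0.99

        def _cell_fit(mask):
            x, y = perf[mask], est_err[mask]
            if len(x) < 3 or np.ptp(x) == 0:
                return 0.5, 50.0
            sxx = float(np.dot(x, x))
            w_hat = float(np.clip(-np.dot(x, y) / sxx, 1e-3, 1.0 - 1e-3))
            resid = y + w_hat * x
            s = float(np.std(resid))
            return w_hat, max(s, 1e-3)

        se0 = np.empty(design.n_ev)
        for i in range(design.n_ev):
            w_hat, s = _cell_fit(design.ev_idx == i)
            se0[i] = np.clip(s / (1.0 - w_hat), lo, hi)
        sp0 = np.empty(design.n_prior)
        for i in range(design.n_prior):
            mask = design.prior_idx == i
            w_hat, _ = _cell_fit(mask)
            se_mean = float(np.mean(se0[np.unique(design.ev_idx[mask])]))
            sp0[i] = np.clip(se_mean * math.sqrt((1.0 - w_hat) / w_hat), lo, hi)
        theta = np.concatenate([np.log(sp0), np.log(se0), np.zeros(design.n_shift)])
        return theta

    def _random_start(self, design: _Design, rng: np.random.Generator) -> np.ndarray:
        logs = rng.uniform(math.log(1.0), math.log(1e4), design.n_prior + design.n_ev)
        shifts = rng.normal(0.0, 30.0, design.n_shift)
        shifts = np.clip(shifts, -self.shift_bound * 0.9, self.shift_bound * 0.9)
        return np.concatenate([logs, shifts])

    #: NLL tolerance (nats) below which a prior SD is resolved to the upper
    #: bound.  Once the weight is ~0 the likelihood is an almost-flat plateau
    #: in sigma_prior; a difference of less than half a nat for one parameter
    #: is statistically uninterpretable (below the one-sigma likelihood
    #: region), so the flat boundary is taken as the canonical representative.
    _PLATEAU_TOL = 0.5

    def _snap_flat_priors(self, design: _Design, theta: np.ndarray, fun: float):
        """Resolve prior SDs sitting on the flat-likelihood plateau to max_sd.

        When a prior contributes (essentially) no bias, any sufficiently
        large SD fits the data indistinguishably well and the optimiser may
        stop anywhere on the plateau.  Classification of flat priors needs
        the canonical (boundary) value.
        """
        hi = math.log(self.max_sd)
        for i in range(design.n_prior):
            if theta[i] >= hi:
                continue
            cand = theta.copy()
            cand[i] = hi
            f = design.nll(cand, floor=1e-12)
            if f <= fun + self._PLATEAU_TOL:
                theta, fun = cand, min(f, fun)
        return theta, fun

    # -- fitting ------------------------------------------------------------

    def fit(self, trials: pd.DataFrame, y=None):
        spec = get_model_spec(self.model_spec)
        df = _usable(trials)
        if len(df) < 2:
            raise InputError("need at least 2 usable trials")
        design = _Design(spec, df)
        if len(df) < design.k + 2:
            raise FitError(f"need at least k+2 = {design.k + 2} usable trials, got {len(df)}")
        perf = design.truth - design.target
        if np.ptp(perf) == 0:
            raise FitError("degenerate data: performance errors have zero variance")

        bounds = (
            [(math.log(self.min_sd), math.log(self.max_sd))] * (design.n_prior + design.n_ev)
            + [(-self.shift_bound, self.shift_bound)] * design.n_shift
        )

        starts: list[np.ndarray] = []
        if self.init_params is not None:
            starts.append(design.pack(self.init_params))
        if self.init_params is None or self.n_restarts > 1:
            starts.append(self._data_start(design))
        rng = derive_rng(self.random_state if self.random_state is not None else 0, "fit-restarts")
        while len(starts) < self.n_restarts:
            starts.append(self._random_start(design, rng))
        starts = starts[: max(self.n_restarts, 1)]

        best = None
        for theta0 in starts:
            res = optimize.minimize(
                design.nll_grad,
                np.clip(theta0, [b[0] for b in bounds], [b[1] for b in bounds]),
                jac=True,
                method="L-BFGS-B",
                bounds=bounds,
                options={"maxiter": 500, "ftol": self.tol * 1e-2, "gtol": 1e-8},
            )
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not np.isfinite(best.fun):
            raise FitError("all optimisation restarts failed to produce a finite likelihood")

        best_x, best_fun = self._snap_flat_priors(design, best.x, best.fun)
        best.x, best.fun = best_x, best_fun

        self.design_ = design
        self.params_ = design.unpack(best.x)
        self.nll_ = float(best.fun)
        self.k_ = design.k
        self.n_trials_ = design.n
        self.bic_ = compute_bic(self.nll_, self.k_, self.n_trials_)
        self.converged_ = bool(best.success)
        self.n_restarts_used_ = len(starts)
        self.result_ = FitResult(
            model=spec.name,
            params=self.params_,
            neg_log_lik=self.nll_,
            n_trials=self.n_trials_,
            k=self.k_,
            bic=self.bic_,
            converged=self.converged_,
            n_restarts_used=self.n_restarts_used_,
            levels=design.levels,
            spec=spec,
        )
        return self

    def predict(self, trials: pd.DataFrame) -> np.ndarray:
        """Predicted mean report for each trial under the fitted parameters."""
        if not hasattr(self, "params_"):
            raise FitError("estimator is not fitted")
        design = _Design(get_model_spec(self.model_spec), trials)
        _, _, _, mean, _, _ = design._moments(design.pack(self.params_))
        return mean


def fit_model(trials: pd.DataFrame, model_spec="exp1_full", **options) -> FitResult:
    """Functional wrapper around :class:`BayesianObserver`."""
    return BayesianObserver(model_spec=model_spec, **options).fit(trials).result_


# ---------------------------------------------------------------------------
# Model selection, bootstrap, flat classification


def compare_models(fits_by_participant: Mapping[str, Mapping[str, FitResult]]) -> dict:
    """BIC model selection across participants.

    Returns a report with the per-participant winner (lowest BIC), and for
    every model pair the group-mean BIC difference, how many participants
    favour each model, and whether the group difference reaches the
    strong-evidence threshold (|mean dBIC| >= 6, inclusive).
    """
    participants = list(fits_by_participant)
    if not participants:
        raise InputError("no participants")
    model_names = sorted(fits_by_participant[participants[0]])
    for p in participants:
        if sorted(fits_by_participant[p]) != model_names:
            raise InputError(f"participant {p!r} was not fitted under every candidate model")

    winners = {
        p: min(model_names, key=lambda m: fits_by_participant[p][m].bic) for p in participants
    }
    pairs = {}
    for i, a in enumerate(model_names):
        for b in model_names[i + 1 :]:
            deltas = np.array(
                [fits_by_participant[p][b].bic - fits_by_participant[p][a].bic for p in participants]
            )
            mean_delta = float(np.mean(deltas))
            if mean_delta == 0.0:
                verdict = "indistinguishable"
            else:
                strong = abs(mean_delta) >= STRONG_EVIDENCE_DELTA_BIC
                verdict = ("strong" if strong else "weak") + " evidence for " + (
                    a if mean_delta > 0 else b
                )
            pairs[f"{a} vs {b}"] = {
                "mean_delta_bic": mean_delta,  # BIC(b) - BIC(a); positive favours a
                "n_favoring_first": int(np.sum(deltas > 0)),
                "n_favoring_second": int(np.sum(deltas < 0)),
                "strong_evidence": bool(abs(mean_delta) >= STRONG_EVIDENCE_DELTA_BIC),
                "verdict": verdict,
            }
    group_winner = min(
        model_names, key=lambda m: np.mean([fits_by_participant[p][m].bic for p in participants])
    )
    return {
        "models": model_names,
        "per_participant_winner": winners,
        "pairwise": pairs,
        "group_winner": group_winner,
    }


def bootstrap_cis(
    trials: pd.DataFrame,
    model_spec="exp1_full",
    B: int = 5000,
    alpha: float = 0.05,
    seed: int | None = None,
    base_fit: FitResult | None = None,
    n_restarts: int = 8,
) -> dict[str, tuple[float, float]]:
    """Percentile bootstrap confidence intervals for the fitted parameters.

    Trials are resampled with replacement within participant x condition
    cells (preserving the design); each replicate is refitted warm-started at
    the original optimum.  Deterministic given ``seed``.  Raises
    :class:`StatisticError` when more than half the replicate fits fail.
    """
    if B < 2:
        raise ConfigError("B must be >= 2")
    spec = get_model_spec(model_spec)
    df = _usable(trials).reset_index(drop=True)
    if base_fit is None:
        base_fit = fit_model(df, spec, n_restarts=n_restarts, random_state=seed)

    group_cols = [c for c in ("participant_id", "condition") if c in df.columns]
    groups = [idx.to_numpy() for _, idx in df.groupby(group_cols, sort=True).groups.items()] if group_cols else [np.arange(len(df))]

    rng = derive_rng(seed if seed is not None else 0, "bootstrap")
    draws: dict[str, list[float]] = {k: [] for k in base_fit.params}
    failures = 0
    est = BayesianObserver(
        model_spec=spec, n_restarts=1, init_params=base_fit.params, random_state=seed
    )
    for _ in range(B):
        idx = np.concatenate([rng.choice(g, size=len(g), replace=True) for g in groups])
        rep = df.iloc[idx]
        try:
            fit = est.fit(rep).result_
        except (FitError, InputError):
            failures += 1
            continue
        if not math.isfinite(fit.neg_log_lik):
            failures += 1
            continue
        for k, v in fit.params.items():
            draws[k].append(v)
    if failures > B / 2:
        raise StatisticError(f"bootstrap failed: {failures}/{B} replicate fits did not converge")

    lo_q, hi_q = 100 * alpha / 2, 100 * (1 - alpha / 2)
    cis = {}
    for k, vals in draws.items():
        lo, hi = np.percentile(vals, [lo_q, hi_q])
        point = base_fit.params[k]
        cis[k] = (float(min(lo, point)), float(max(hi, point)))
    base_fit.ci_95 = cis
    return cis


def classify_flat(fit: FitResult, threshold: float = FLAT_PRIOR_THRESHOLD) -> dict[str, bool]:
    """Flag each fitted prior as flat when its SD strictly exceeds ``threshold``.

    A flat prior contributes essentially no bias: at the threshold the
    posterior weight is below 1e-13 for any evidence SD up to 1e3 px.
    """
    out = {}
    for label, value in fit.params.items():
        if label.startswith("prior_sd"):
            out[label[len("prior_sd[") : -1]] = bool(value > threshold)
    return out
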