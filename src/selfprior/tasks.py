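"""Synthetic cohorts and trial tables for the visuomotor estimation tasks.

The simulated paradigm: a ball sweeps across the screen and the participant
stops it under a target (Stop task), releases it to drop onto a target
(Release task, with three visual-uncertainty levels), or stops it with no
target present (No-Target task).  After the ball vanishes the participant
reports its final position with a cursor.  In Agent blocks the computer
replays the participant's own stopping positions (permuted, truncated to
+/-2 SD, sweeps limited to 1-4) and the participant merely observes and
reports.

Reports are generated from the Bayesian observer model: a reliability-
weighted mix of the prior mean (the goal) and noisy evidence about the true
outcome.  The cohort generator realises the population structure the
analysis is designed to detect: self priors narrower than true performance
(by a per-participant "exaggeration" ratio), agent priors matched to
performance or flat, a negative partial correlation between self prior width
and trait optimism (controlling for performance), and feedback phases that
shrink performance and evidence noise but never the prior.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import as_rng, derive_rng
from .errors import ConfigError, InputError
from .observer import posterior_weight

__all__ = [
    "TRIAL_COLUMNS",
    "PARTICIPANT_COLUMNS",
    "FLAT_PRIOR_SD",
    "DistSpec",
    "TaskConfig",
    "ObserverParams",
    "AgentPriorMode",
    "CohortSpec",
    "Participant",
    "Cohort",
    "SessionDesign",
    "make_cohort",
    "simulate_stop_block",
    "simulate_release_block",
    "simulate_no_target_block",
    "simulate_agent_replay",
    "simulate_session",
    "phase_generative_params",
    "level_evidence_sds",
    "participants_table",
]

#: Exact column order of the trial-table CSV dialect.
TRIAL_COLUMNS = [
    "participant_id",
    "condition",
    "phase",
    "block_index",
    "direction",
    "feedback_level",
    "target_x_px",
    "true_stop_x_px",
    "estimate_x_px",
    "sweeps",
    "reaction_time_s",
    "estimation_time_s",
    "excluded",
    "excluded_reason",
]

PARTICIPANT_COLUMNS = [
    "participant_id",
    "performance_sd_px",
    "self_prior_sd_px",
    "agent_prior_sd_px",
    "agent_prior_flat",
    "optimism_score",
]

#: Generative SD used for a flat (uninformative) agent prior, px.
FLAT_PRIOR_SD = 1e9

_TASK_KINDS = {
    "stop",
    "release",
    "no_target_stop",
    "no_target_release",
    "multi_target_stop",
    "implicit_target_stop",
}
_RELEASE_KINDS = {"release", "no_target_release"}
_FEEDBACK_LEVELS = ("low", "medium", "high")

# Timing model for the report phase (log-normal, seconds); the exclusion
# rules only need plausible positive times with occasional slow outliers.
_EST_TIME_LOG_MU, _EST_TIME_LOG_SD = math.log(1.4), 0.20
_RT_LOG_MU, _RT_LOG_SD = math.log(0.35), 0.22
_OUTLIER_PROB = 0.02
_OUTLIER_RANGE = (3.0, 5.0)

#: Default multipliers turning a base evidence SD into per-uncertainty-level
#: SDs for the Release task (strictly increasing low < medium < high).
DEFAULT_LEVEL_FACTORS = {"low": 0.7, "medium": 1.2, "high": 2.2}


# ---------------------------------------------------------------------------
# Configuration types


@dataclass(frozen=True)
class DistSpec:
    """A Gaussian distribution spec (mean, SD) for per-participant draws."""

    mean: float
    sd: float

    def __post_init__(self):
        if self.sd < 0:
            raise ConfigError("distribution SD must be >= 0")

    def draw(self, rng: np.random.Generator, size=None):
        return rng.normal(self.mean, self.sd, size)


@dataclass(frozen=True)
class TaskConfig:
    """Geometry and schedule of one task variant.

    Coordinates are in screen pixels, x = 0 at the left edge and increasing
    rightward; motion direction is encoded +1 (rightward) / -1 (leftward).
    """

    task_kind: str = "stop"
    screen_width_px: int = 1024
    refresh_hz: float = 85.0
    sweep_speed_px_s: float = 1200.0
    target_x_px: float | tuple = 512.0
    fall_frames: int | None = None
    fall_lateral_speed_px_s: float | None = None
    trials_per_block: int = 52
    n_blocks_per_phase: int = 2
    feedback_levels: tuple = ()
    bidirectional: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.task_kind not in _TASK_KINDS:
            raise ConfigError(f"unknown task_kind {self.task_kind!r}")
        if self.refresh_hz <= 0 or self.sweep_speed_px_s <= 0:
            raise ConfigError("refresh_hz and sweep_speed_px_s must be strictly positive")
        if self.trials_per_block < 1:
            raise ConfigError("trials_per_block must be >= 1")
        for t in np.atleast_1d(np.asarray(self.target_x_px, dtype=float)):
            if not np.isnan(t) and not (0 <= t <= self.screen_width_px):
                raise ConfigError(f"target position {t} outside [0, {self.screen_width_px}]")
        if self.task_kind in _RELEASE_KINDS:
            if self.fall_frames is None or self.fall_frames < 1:
                raise ConfigError("release tasks require fall_frames >= 1")
            if not self.fall_lateral_speed_px_s or self.fall_lateral_speed_px_s <= 0:
                raise ConfigError("release tasks require a positive fall_lateral_speed_px_s")
        elif self.fall_frames is not None:
            raise ConfigError("fall_frames only applies to release tasks")
        bad = set(self.feedback_levels) - set(_FEEDBACK_LEVELS)
        if bad:
            raise ConfigError(f"unknown feedback levels {sorted(bad)}")

    @property
    def px_per_refresh(self) -> float:
        """Ball displacement per screen refresh (px)."""
        return self.sweep_speed_px_s / self.refresh_hz

    @property
    def fall_duration_s(self) -> float:
        if self.task_kind not in _RELEASE_KINDS:
            raise ConfigError("fall duration only defined for release tasks")
        return self.fall_frames / self.refresh_hz

    @property
    def fall_lateral_displacement_px(self) -> float:
        """Constant lateral displacement of the ball during its descent (px)."""
        return self.fall_duration_s * self.fall_lateral_speed_px_s


@dataclass(frozen=True)
class ObserverParams:
    """Generative (or fitted) observer parameters for one condition.

    ``evidence_sd_px`` is a scalar, or a dict keyed by feedback level for the
    Release task.  ``performance_sd_px`` and ``momentum_shift_px`` are purely
    generative (SD of true stops around the target; directional report shift
    in no-target tasks).  ``prior_mean_px=None`` means "centred on the trial's
    target".
    """

    prior_sd_px: float
    evidence_sd_px: float | Mapping[str, float]
    prior_mean_px: float | None = None
    prior_shift_px: float = 0.0
    evidence_shift_px: float = 0.0
    performance_sd_px: float | None = None
    momentum_shift_px: float = 0.0

    def __post_init__(self):
        if self.prior_sd_px <= 0:
            raise ConfigError("prior_sd_px must be > 0 (use a large value for flat)")
        for v in self._evidence_values():
            if v <= 0:
                raise ConfigError("evidence_sd_px must be > 0")
        if self.performance_sd_px is not None and self.performance_sd_px <= 0:
            raise ConfigError("performance_sd_px must be > 0")

    def _evidence_values(self):
        if isinstance(self.evidence_sd_px, Mapping):
            return list(self.evidence_sd_px.values())
        return [self.evidence_sd_px]

    def evidence_sd(self, feedback_level: str = "none") -> float:
        if isinstance(self.evidence_sd_px, Mapping):
            try:
                return float(self.evidence_sd_px[feedback_level])
            except KeyError:
                raise ConfigError(f"no evidence SD for feedback level {feedback_level!r}")
        return float(self.evidence_sd_px)


@dataclass(frozen=True)
class AgentPriorMode:
    """How agent (observation) priors relate to true performance.

    ``matched``: agent prior SD ~ ratio x performance SD.  ``flat_with_prob``:
    with probability ``flat_prob`` the participant forms no usable
    observation prior (flat, SD 1e9); otherwise matched.
    """

    kind: str = "flat_with_prob"
    flat_prob: float = 0.25
    matched_ratio: DistSpec = field(default_factory=lambda: DistSpec(1.0, 0.15))

    def __post_init__(self):
        if self.kind not in {"matched", "flat_with_prob"}:
            raise ConfigError(f"unknown agent prior mode {self.kind!r}")
        if not 0.0 <= self.flat_prob <= 1.0:
            raise ConfigError("flat_prob must be in [0, 1]")


@dataclass(frozen=True)
class CohortSpec:
    """Population-level generative settings for a synthetic cohort."""

    n_participants: int = 20
    performance_sd_dist: DistSpec = field(default_factory=lambda: DistSpec(40.0, 10.0))
    self_exaggeration_dist: DistSpec = field(default_factory=lambda: DistSpec(0.6, 0.1))
    agent_prior_mode: AgentPriorMode = field(default_factory=AgentPriorMode)
    optimism_partial_rho: float = -0.5
    feedback_perf_sd_factor: float = 0.8
    feedback_evid_sd_factor: float = 0.75
    evidence_sd_dist: DistSpec = field(default_factory=lambda: DistSpec(30.0, 8.0))
    evidence_self_ratio: float = 0.85
    momentum_shift_dist: DistSpec = field(default_factory=lambda: DistSpec(18.0, 4.0))
    momentum_self_ratio: float = 0.6
    seed: int = 0

    def __post_init__(self):
        if self.n_participants < 2:
            raise ConfigError("n_participants must be >= 2")
        if not -1.0 <= self.optimism_partial_rho <= 1.0:
            raise ConfigError("optimism_partial_rho must be in [-1, 1]")
        for f in (self.feedback_perf_sd_factor, self.feedback_evid_sd_factor,
                  self.evidence_self_ratio, self.momentum_self_ratio):
            if f <= 0:
                raise ConfigError("multiplicative factors must be strictly positive")


@dataclass(frozen=True)
class Participant:
    participant_id: str
    performance_sd_px: float
    optimism_score: int
    self_params: ObserverParams
    agent_params: ObserverParams
    agent_prior_flat: bool


@dataclass(frozen=True)
class Cohort:
    spec: CohortSpec
    participants: tuple[Participant, ...]

    def __iter__(self):
        return iter(self.participants)

    def __len__(self):
        return len(self.participants)


@dataclass(frozen=True)
class SessionDesign:
    """Phase/block layout for a simulated session of one task."""

    task: TaskConfig
    phases: tuple = ("before", "during", "after")
    blocks_per_phase: int = 2
    include_agent: bool = True

    def __post_init__(self):
        if self.blocks_per_phase < 1:
            raise ConfigError("blocks_per_phase must be >= 1")
        bad = set(self.phases) - {"before", "during", "after"}
        if bad:
            raise ConfigError(f"unknown phases {sorted(bad)}")


# ---------------------------------------------------------------------------
# Cohort generation


def make_cohort(spec: CohortSpec) -> Cohort:
    """Draw per-participant generative observer parameters and optimism scores.

    Each participant's draws come from a stream keyed by their id, so cohort
    composition does not perturb individual participants.  Optimism scores
    (0-24) are built from the residual of log self-exaggeration after
    regressing out performance SD, mixed with independent noise so that over
    large cohorts partial corr(self prior SD, optimism | performance SD)
    approaches ``optimism_partial_rho``.
    """
    n = spec.n_participants
    ids = [f"p{i:03d}" for i in range(n)]
    perf = np.empty(n)
    exagg = np.empty(n)
    agent_flat = np.zeros(n, dtype=bool)
    agent_ratio = np.empty(n)
    evid = np.empty(n)
    momentum = np.empty(n)
    eps = np.empty(n)

    for i, pid in enumerate(ids):
        rng = derive_rng(spec.seed, pid, "cohort")
        perf[i] = max(float(spec.performance_sd_dist.draw(rng)), 5.0)
        exagg[i] = max(float(spec.self_exaggeration_dist.draw(rng)), 0.05)
        u_flat = rng.random()
        agent_ratio[i] = max(float(spec.agent_prior_mode.matched_ratio.draw(rng)), 0.2)
        # floor near the stimulus granularity (the ball moves ~14 px per
        # refresh): evidence noise below that is not physically attainable
        evid[i] = max(float(spec.evidence_sd_dist.draw(rng)), 10.0)
        momentum[i] = float(spec.momentum_shift_dist.draw(rng))
        eps[i] = rng.standard_normal()
        if spec.agent_prior_mode.kind == "flat_with_prob":
            agent_flat[i] = u_flat < spec.agent_prior_mode.flat_prob

    # optimism: residualise log exaggeration on performance SD, standardise,
    # mix with noise at the target partial correlation, map onto 0..24
    log_ex = np.log(exagg)
    X = np.column_stack([np.ones(n), perf])
    beta, *_ = np.linalg.lstsq(X, log_ex, rcond=None)
    resid = log_ex - X @ beta
    sd_resid = float(np.std(resid))
    z = resid / sd_resid if sd_resid > 1e-12 else np.zeros(n)
    rho = spec.optimism_partial_rho
    latent = rho * z + math.sqrt(max(0.0, 1.0 - rho**2)) * eps
    scores = np.clip(np.rint(12.0 + 4.0 * latent), 0, 24).astype(int)

    participants = []
    for i, pid in enumerate(ids):
        self_prior = exagg[i] * perf[i]
        agent_prior = FLAT_PRIOR_SD if agent_flat[i] else agent_ratio[i] * perf[i]
        self_p = ObserverParams(
            prior_sd_px=self_prior,
            evidence_sd_px=spec.evidence_self_ratio * evid[i],
            performance_sd_px=perf[i],
            momentum_shift_px=spec.momentum_self_ratio * momentum[i],
        )
        agent_p = ObserverParams(
            prior_sd_px=agent_prior,
            evidence_sd_px=evid[i],
            performance_sd_px=perf[i],
            momentum_shift_px=momentum[i],
        )
        participants.append(
            Participant(
                participant_id=pid,
                performance_sd_px=float(perf[i]),
                optimism_score=int(scores[i]),
                self_params=self_p,
                agent_params=agent_p,
                agent_prior_flat=bool(agent_flat[i]),
            )
        )
    return Cohort(spec=spec, participants=tuple(participants))


def participants_table(cohort: Cohort) -> pd.DataFrame:
    rows = []
    for p in cohort:
        rows.append(
            {
                "participant_id": p.participant_id,
                "performance_sd_px": p.performance_sd_px,
                "self_prior_sd_px": p.self_params.prior_sd_px,
                "agent_prior_sd_px": (
                    float("nan") if p.agent_prior_flat else p.agent_params.prior_sd_px
                ),
                "agent_prior_flat": p.agent_prior_flat,
                "optimism_score": p.optimism_score,
            }
        )
    return pd.DataFrame(rows, columns=PARTICIPANT_COLUMNS)


def level_evidence_sds(base_sd: float, factors: Mapping[str, float] = None) -> dict[str, float]:
    """Per-uncertainty-level evidence SDs for the Release task."""
    factors = dict(DEFAULT_LEVEL_FACTORS if factors is None else factors)
    sds = {lvl: base_sd * factors[lvl] for lvl in _FEEDBACK_LEVELS}
    if not sds["low"] < sds["medium"] < sds["high"]:
        raise ConfigError("evidence SDs must be strictly increasing low < medium < high")
    return sds


# ---------------------------------------------------------------------------
# Trial generation helpers


def _timings(rng: np.random.Generator, n: int, log_mu: float, log_sd: float) -> np.ndarray:
    t = rng.lognormal(log_mu, log_sd, n)
    outlier = rng.random(n) < _OUTLIER_PROB
    t[outlier] *= rng.uniform(*_OUTLIER_RANGE, int(outlier.sum()))
    return t


def _directions(rng: np.random.Generator, n: int, config: TaskConfig) -> np.ndarray:
    if config.bidirectional:
        return rng.choice(np.array([-1, 1]), n)
    return np.ones(n, dtype=int)


def _reports(
    rng: np.random.Generator,
    params: ObserverParams,
    truth: np.ndarray,
    target: np.ndarray,
    directions: np.ndarray,
    evidence_sd: np.ndarray,
) -> np.ndarray:
    """Posterior-mode reports: w*(prior) + (1-w)*(evidence sample)."""
    w = posterior_weight(params.prior_sd_px, evidence_sd)
    prior_mean = np.where(
        np.isnan(target), 0.0, target
    ) if params.prior_mean_px is None else params.prior_mean_px
    noise = rng.normal(0.0, 1.0, len(truth)) * evidence_sd
    return w * (prior_mean + params.prior_shift_px) + (1.0 - w) * (
        truth + directions * params.evidence_shift_px + noise
    )


def _frame(
    *,
    participant_id,
    condition,
    phase,
    block_index,
    directions,
    feedback_level,
    target,
    truth,
    estimate,
    sweeps,
    reaction_time,
    estimation_time,
) -> pd.DataFrame:
    n = len(truth)
    return pd.DataFrame(
        {
            "participant_id": np.repeat(participant_id, n),
            "condition": np.repeat(condition, n),
            "phase": np.repeat(phase, n),
            "block_index": np.repeat(int(block_index), n),
            "direction": np.asarray(directions, dtype=int),
            "feedback_level": feedback_level,
            "target_x_px": np.asarray(target, dtype=float),
            "true_stop_x_px": np.asarray(truth, dtype=float),
            "estimate_x_px": np.asarray(estimate, dtype=float),
            "sweeps": np.asarray(sweeps, dtype=int),
            "reaction_time_s": np.asarray(reaction_time, dtype=float),
            "estimation_time_s": np.asarray(estimation_time, dtype=float),
            "excluded": np.zeros(n, dtype=bool),
            "excluded_reason": np.repeat("", n),
        },
        columns=TRIAL_COLUMNS,
    )


# ---------------------------------------------------------------------------
# Block simulators


def simulate_stop_block(
    config: TaskConfig,
    params: ObserverParams,
    condition: str = "self",
    phase: str = "before",
    seed=None,
    *,
    participant_id: str = "p000",
    block_index: int = 0,
    target_x_px: float | None = None,
) -> pd.DataFrame:
    """One block of the Stop task (also the multi-/implicit-target variants).

    True stops are Normal(target, performance SD); reports follow the
    weighted-prior model with the condition's evidence SD.
    """
    if config.task_kind not in {"stop", "multi_target_stop", "implicit_target_stop"}:
        raise ConfigError(f"not a stop-task config: {config.task_kind!r}")
    if params.performance_sd_px is None:
        raise ConfigError("generation requires performance_sd_px")
    rng = as_rng(seed)
    n = config.trials_per_block
    target_val = float(target_x_px if target_x_px is not None else np.atleast_1d(
        np.asarray(config.target_x_px, dtype=float))[0])
    target = np.full(n, target_val)
    dirs = _directions(rng, n, config)
    truth = rng.normal(target_val, params.performance_sd_px, n)
    sd = np.full(n, params.evidence_sd("none"))
    estimate = _reports(rng, params, truth, target, dirs, sd)
    sweeps = np.clip(1 + rng.poisson(1.0, n), 1, 8)
    est_time = _timings(rng, n, _EST_TIME_LOG_MU, _EST_TIME_LOG_SD)
    rt = np.full(n, np.nan)
    if condition == "agent":
        rt = _timings(rng, n, _RT_LOG_MU, _RT_LOG_SD)
    return _frame(
        participant_id=participant_id,
        condition=condition,
        phase=phase,
        block_index=block_index,
        directions=dirs,
        feedback_level=np.repeat("none", n),
        target=target,
        truth=truth,
        estimate=estimate,
        sweeps=sweeps,
        reaction_time=rt,
        estimation_time=est_time,
    )


def simulate_release_block(
    config: TaskConfig,
    params: ObserverParams,
    condition: str = "self",
    phase: str = "before",
    seed=None,
    *,
    participant_id: str = "p000",
    block_index: int = 0,
) -> pd.DataFrame:
    """One block of the Release task with interleaved uncertainty levels.

    The three feedback levels appear equally often per block.  The landing
    position is the release position plus the constant lateral displacement
    ``fall_frames / refresh_hz * fall_lateral_speed_px_s``; participants aim
    so that landings are Normal(target, performance SD).
    """
    if config.task_kind != "release":
        raise ConfigError(f"not a release config: {config.task_kind!r}")
    if params.performance_sd_px is None:
        raise ConfigError("generation requires performance_sd_px")
    if not isinstance(params.evidence_sd_px, Mapping):
        raise ConfigError("release task requires evidence_sd_px keyed by feedback level")
    levels = config.feedback_levels or _FEEDBACK_LEVELS
    sds = {lvl: params.evidence_sd(lvl) for lvl in levels}
    ordered = [sds[lvl] for lvl in _FEEDBACK_LEVELS if lvl in sds]
    if any(a >= b for a, b in zip(ordered, ordered[1:])):
        raise ConfigError("evidence SDs must increase strictly with uncertainty level")
    rng = as_rng(seed)
    n = config.trials_per_block
    if n % len(levels):
        raise ConfigError("trials_per_block must be divisible by the number of feedback levels")
    level_arr = rng.permutation(np.repeat(np.array(levels), n // len(levels)))
    target_val = float(np.atleast_1d(np.asarray(config.target_x_px, dtype=float))[0])
    target = np.full(n, target_val)
    dirs = np.ones(n, dtype=int)  # release sweeps are rightward
    truth = rng.normal(target_val, params.performance_sd_px, n)  # landing positions
    sd = np.array([sds[lvl] for lvl in level_arr])
    estimate = _reports(rng, params, truth, target, dirs, sd)
    sweeps = np.clip(1 + rng.poisson(1.0, n), 1, 8)
    est_time = _timings(rng, n, _EST_TIME_LOG_MU, _EST_TIME_LOG_SD)
    rt = _timings(rng, n, _RT_LOG_MU, _RT_LOG_SD) if condition == "agent" else np.full(n, np.nan)
    return _frame(
        participant_id=participant_id,
        condition=condition,
        phase=phase,
        block_index=block_index,
        directions=dirs,
        feedback_level=level_arr,
        target=target,
        truth=truth,
        estimate=estimate,
        sweeps=sweeps,
        reaction_time=rt,
        estimation_time=est_time,
    )


def simulate_no_target_block(
    config: TaskConfig,
    params: ObserverParams,
    condition: str = "self",
    phase: str = "before",
    seed=None,
    *,
    participant_id: str = "p000",
    block_index: int = 0,
) -> pd.DataFrame:
    """One block of the No-Target task.

    Stops are uniform over the screen; reports carry a directional
    (representational-momentum) shift plus evidence noise, with no prior.
    """
    if not config.task_kind.startswith("no_target"):
        raise ConfigError(f"not a no-target config: {config.task_kind!r}")
    rng = as_rng(seed)
    n = config.trials_per_block
    dirs = _directions(rng, n, config)
    truth = rng.uniform(0.0, config.screen_width_px, n)
    sd = params.evidence_sd("none") if not isinstance(params.evidence_sd_px, Mapping) else (
        params.evidence_sd("medium"))
    estimate = truth + dirs * params.momentum_shift_px + rng.normal(0.0, sd, n)
    sweeps = np.clip(1 + rng.poisson(1.0, n), 1, 8)
    est_time = _timings(rng, n, _EST_TIME_LOG_MU, _EST_TIME_LOG_SD)
    rt = _timings(rng, n, _RT_LOG_MU, _RT_LOG_SD) if condition == "agent" else np.full(n, np.nan)
    return _frame(
        participant_id=participant_id,
        condition=condition,
        phase=phase,
        block_index=block_index,
        directions=dirs,
        feedback_level=np.repeat("none", n),
        target=np.full(n, np.nan),
        truth=truth,
        estimate=estimate,
        sweeps=sweeps,
        reaction_time=rt,
        estimation_time=est_time,
    )


def simulate_agent_replay(
    self_trials: pd.DataFrame,
    config: TaskConfig,
    agent_params: ObserverParams,
    seed=None,
) -> pd.DataFrame:
    """Agent block replaying a self block's stop positions.

    Positions are permuted and truncated (clamped) to the self block's
    mean +/- 2 SD; sweep counts are redrawn from {1..4}; reports are
    regenerated from the agent observer parameters; reaction times are
    populated for the attention-control button press.
    """
    if len(self_trials) == 0:
        raise InputError("self_trials is empty")
    if not (self_trials["condition"] == "self").all():
        raise InputError("simulate_agent_replay requires condition == 'self' trials")
    if len(self_trials) < 2:
        raise InputError("need at least 2 self trials to define the truncation band")
    rng = as_rng(seed)
    n = len(self_trials)
    vals = self_trials["true_stop_x_px"].to_numpy(dtype=float)
    mean, sd = float(np.mean(vals)), float(np.std(vals, ddof=1))
    clamped = np.clip(vals, mean - 2.0 * sd, mean + 2.0 * sd)
    perm = rng.permutation(n)

    out = self_trials.iloc[perm].reset_index(drop=True).copy()
    truth = clamped[perm]
    target = out["target_x_px"].to_numpy(dtype=float)
    dirs = out["direction"].to_numpy(dtype=int)
    if isinstance(agent_params.evidence_sd_px, Mapping):
        sd_arr = np.array([agent_params.evidence_sd(lvl) for lvl in out["feedback_level"]])
    else:
        sd_arr = np.full(n, agent_params.evidence_sd("none"))
    out["condition"] = "agent"
    out["true_stop_x_px"] = truth
    out["estimate_x_px"] = _reports(rng, agent_params, truth, target, dirs, sd_arr)
    out["sweeps"] = rng.integers(1, 5, n)
    out["reaction_time_s"] = _timings(rng, n, _RT_LOG_MU, _RT_LOG_SD)
    out["estimation_time_s"] = _timings(rng, n, _EST_TIME_LOG_MU, _EST_TIME_LOG_SD)
    out["excluded"] = False
    out["excluded_reason"] = ""
    return out[TRIAL_COLUMNS]


# ---------------------------------------------------------------------------
# Sessions


def _phase_params(p: Participant, spec: CohortSpec, phase: str):
    """Effective generative parameters in one phase.

    Feedback (during) and its aftermath shrink performance and evidence SDs
    by the cohort factors; the prior SD is never rescaled.
    """
    if phase == "before":
        return p.self_params, p.agent_params
    fp, fe = spec.feedback_perf_sd_factor, spec.feedback_evid_sd_factor

    def scale(params: ObserverParams) -> ObserverParams:
        if isinstance(params.evidence_sd_px, Mapping):
            ev = {k: v * fe for k, v in params.evidence_sd_px.items()}
        else:
            ev = params.evidence_sd_px * fe
        return replace(
            params,
            evidence_sd_px=ev,
            performance_sd_px=(
                None if params.performance_sd_px is None else params.performance_sd_px * fp
            ),
        )

    return scale(p.self_params), scale(p.agent_params)


def phase_generative_params(cohort: Cohort, design: SessionDesign) -> pd.DataFrame:
    """Per participant x phase effective generative SDs (metadata table)."""
    rows = []
    for p in cohort:
        for phase in design.phases:
            sp, ap = _phase_params(p, cohort.spec, phase)
            rows.append(
                {
                    "participant_id": p.participant_id,
                    "phase": phase,
                    "performance_sd_px": sp.performance_sd_px,
                    "self_prior_sd_px": sp.prior_sd_px,
                    "agent_prior_sd_px": ap.prior_sd_px,
                    "self_evidence_sd_px": sp.evidence_sd("none")
                    if not isinstance(sp.evidence_sd_px, Mapping)
                    else float("nan"),
                    "agent_evidence_sd_px": ap.evidence_sd("none")
                    if not isinstance(ap.evidence_sd_px, Mapping)
                    else float("nan"),
                }
            )
    return pd.DataFrame(rows)


def simulate_session(cohort: Cohort, design: SessionDesign, seed: int | None = None) -> pd.DataFrame:
    """Simulate a full session (all participants, phases and blocks).

    Self blocks always precede their agent replays.  Returns the concatenated
    trial table in the documented column order; byte-identical for identical
    (cohort spec, design, seed).
    """
    root = cohort.spec.seed if seed is None else seed
    task = design.task
    frames = []
    for p in cohort:
        for phase in design.phases:
            self_p, agent_p = _phase_params(p, cohort.spec, phase)
            for b in range(design.blocks_per_phase):
                rng_self = derive_rng(root, p.participant_id, phase, b, "self")
                if task.task_kind == "release":
                    self_block = simulate_release_block(
                        task, self_p, "self", phase, rng_self,
                        participant_id=p.participant_id, block_index=b,
                    )
                elif task.task_kind.startswith("no_target"):
                    self_block = simulate_no_target_block(
                        task, self_p, "self", phase, rng_self,
                        participant_id=p.participant_id, block_index=b,
                    )
                else:
                    self_block = simulate_stop_block(
                        task, self_p, "self", phase, rng_self,
                        participant_id=p.participant_id, block_index=b,
                    )
                frames.append(self_block)
                if design.include_agent:
                    rng_agent = derive_rng(root, p.participant_id, phase, b, "agent")
                    if task.task_kind.startswith("no_target"):
                        agent_block = simulate_no_target_block(
                            task, agent_p, "agent", phase, rng_agent,
                            participant_id=p.participant_id, block_index=b,
                        )
                    else:
                        agent_block = simulate_agent_replay(
                            self_block, task, agent_p, rng_agent
                        )
                    frames.append(agent_block)
    return pd.concat(frames, ignore_index=True)
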