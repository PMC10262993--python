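"""Adaptive 2-down-1-up 3AFC staircase and simulated-listener oracles.

The staircase tracks the voice difference (in semitones) between target and
reference: two consecutive correct responses shrink the difference by the
current step, one incorrect response grows it.  This transformed up-down rule
converges on the stimulus level at which the listener's psychometric function
passes through ~70.7% correct.

Schedule: the run starts at 12 st with 2 st steps; the step is divided by
sqrt(2) when the 15th trial is reached (if no division has happened yet) and
whenever the difference falls below twice the current step, with a
configurable floor.  A run ends after 12 reversals (converged) or 150 trials,
and fails outright if the last 15 or more responses were all incorrect.  The
just-noticeable difference (JND) is the mean of the last 10 reversal levels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "StaircaseConfig",
    "StaircaseState",
    "JNDResult",
    "WeibullListener",
    "LogisticListener",
    "StepListener",
    "ProbeSummary",
    "staircase_update",
    "run_staircase",
    "convergence_probe",
]

RUNNING = "running"
CONVERGED = "converged"
MAX_TRIALS = "max_trials"
FAILED = "failed"

GUESS_3AFC = 1.0 / 3.0
P_2D1U = math.sqrt(0.5)  # 70.7%: convergence point of the 2-down-1-up rule


@dataclass(frozen=True)
class StaircaseConfig:
    start_diff_st: float = 12.0
    initial_step_st: float = 2.0
    n_down: int = 2
    n_up: int = 1
    step_divisor: float = math.sqrt(2.0)
    step_update_trial: int = 15
    step_update_ratio: float = 2.0
    max_reversals: int = 12
    max_trials: int = 150
    n_reversals_for_jnd: int = 10
    fail_consecutive_incorrect: int = 15
    step_floor_st: float = 0.1
    #: if True, the step is divided at most once in the whole run (first
    #: trigger only, trial-count or ratio rule).  Default False re-applies the
    #: ratio rule each time "diff < ratio*step" becomes newly true, which lets
    #: the step refine enough to resolve sub-semitone thresholds.
    single_division: bool = False

    def __post_init__(self) -> None:
        if self.n_reversals_for_jnd > self.max_reversals:
            raise ValueError("n_reversals_for_jnd must be <= max_reversals")
        for name in ("start_diff_st", "initial_step_st", "step_divisor", "step_floor_st"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class StaircaseState:
    diff_st: float
    step_st: float
    trial_index: int = 0
    consecutive_correct: int = 0
    consecutive_incorrect: int = 0
    reversal_levels: list[float] = field(default_factory=list)
    last_direction: str | None = None  # "down" | "up" | None
    status: str = RUNNING
    step_divided: bool = False  # any division happened yet (trial-count rule)
    ratio_was_true: bool = False  # "diff < ratio*step" held after the last trial

    @classmethod
    def initial(cls, cfg: StaircaseConfig) -> "StaircaseState":
        s = cls(diff_st=cfg.start_diff_st, step_st=cfg.initial_step_st)
        s.ratio_was_true = s.diff_st < cfg.step_update_ratio * s.step_st
        return s


@dataclass
class JNDResult:
    jnd_st: float | None
    reversal_levels: list[float]
    n_trials: int
    status: str


@dataclass
class ProbeSummary:
    """Across-run summary of simulated staircases against one oracle."""

    mean_jnd_st: float
    sd_jnd_st: float
    pct_correct_at_mean: float
    n_runs: int
    n_failed: int


# --------------------------------------------------------------------------
# oracle listeners


def _scale_from_threshold(threshold: float, inv_base: float) -> float:
    return threshold / inv_base


@dataclass(frozen=True)
class WeibullListener:
    """3AFC observer with a Weibull psychometric function on the semitone axis.

    P(correct | d) = guess + (1 - guess - lapse) * (1 - exp(-(d/alpha)**slope)),
    with alpha chosen so that P(threshold_st) equals the 2-down-1-up
    convergence level (70.7% by default).
    """

    threshold_st: float
    slope: float = 1.5
    guess: float = GUESS_3AFC
    lapse: float = 0.0
    criterion: float = P_2D1U

    def _alpha(self) -> float:
        f = (self.criterion - self.guess) / (1.0 - self.guess - self.lapse)
        return self.threshold_st / (-math.log1p(-f)) ** (1.0 / self.slope)

    def p_correct(self, diff_st: float) -> float:
        if diff_st <= 0:
            return self.guess
        f = 1.0 - math.exp(-((diff_st / self._alpha()) ** self.slope))
        return self.guess + (1.0 - self.guess - self.lapse) * f

    def quantile(self, p: float) -> float:
        """Stimulus difference at which P(correct) = p (closed form)."""
        f = (p - self.guess) / (1.0 - self.guess - self.lapse)
        if not 0.0 < f < 1.0:
            raise ValueError("p outside the attainable range of the psychometric function")
        return self._alpha() * (-math.log1p(-f)) ** (1.0 / self.slope)


@dataclass(frozen=True)
class LogisticListener:
    """3AFC observer, logistic in log2(difference); slope per octave-log unit."""

    threshold_st: float
    slope: float = 4.0
    guess: float = GUESS_3AFC
    lapse: float = 0.0
    criterion: float = P_2D1U

    def _mid(self) -> float:
        # location so that p(threshold) == criterion
        f = (self.criterion - self.guess) / (1.0 - self.guess - self.lapse)
        return math.log2(self.threshold_st) - math.log(f / (1.0 - f)) / self.slope

    def p_correct(self, diff_st: float) -> float:
        if diff_st <= 0:
            return self.guess
        z = self.slope * (math.log2(diff_st) - self._mid())
        return self.guess + (1.0 - self.guess - self.lapse) / (1.0 + math.exp(-z))

    def quantile(self, p: float) -> float:
        f = (p - self.guess) / (1.0 - self.guess - self.lapse)
        if not 0.0 < f < 1.0:
            raise ValueError("p outside the attainable range of the psychometric function")
        return 2.0 ** (self._mid() + math.log(f / (1.0 - f)) / self.slope)


@dataclass(frozen=True)
class StepListener:
    """Degenerate observer: always correct above the threshold, guessing below."""

    threshold_st: float
    guess: float = GUESS_3AFC

    def p_correct(self, diff_st: float) -> float:
        return 1.0 if diff_st >= self.threshold_st else self.guess


# --------------------------------------------------------------------------
# core update rule


def _divide_step(state: StaircaseState, cfg: StaircaseConfig) -> None:
    state.step_st = max(cfg.step_floor_st, state.step_st / cfg.step_divisor)
    state.step_divided = True


def staircase_update(state: StaircaseState, correct: bool, cfg: StaircaseConfig) -> StaircaseState:
    """Advance the staircase by one trial response; returns a new state.

    Two consecutive correct responses move the difference down one step; an
    incorrect response moves it up one step.  The level in force before a
    direction flip is recorded as a reversal.  The difference is clamped at
    0 st (a negative voice difference is meaningless).
    """
    if state.status != RUNNING:
        raise RuntimeError(f"cannot update a staircase with status {state.status!r}")
    s = replace(state, reversal_levels=list(state.reversal_levels))
    s.trial_index += 1

    move: str | None = None
    if correct:
        s.consecutive_correct += 1
        s.consecutive_incorrect = 0
        if s.consecutive_correct >= cfg.n_down:
            move = "down"
            s.consecutive_correct = 0
    else:
        s.consecutive_incorrect += 1
        s.consecutive_correct = 0
        if s.consecutive_incorrect % cfg.n_up == 0:
            move = "up"

    if move is not None:
        if s.last_direction is not None and move != s.last_direction:
            s.reversal_levels.append(s.diff_st)
        s.last_direction = move
        if move == "down":
            s.diff_st = max(0.0, s.diff_st - s.step_st)
        else:
            s.diff_st = s.diff_st + s.step_st
        # divide the step when the ratio condition becomes *newly* true; it
        # re-arms once the difference climbs back above ratio*step again
        ratio_now = s.diff_st < cfg.step_update_ratio * s.step_st
        may_divide = not (cfg.single_division and s.step_divided)
        if ratio_now and not s.ratio_was_true and s.step_st > cfg.step_floor_st and may_divide:
            _divide_step(s, cfg)
        s.ratio_was_true = s.diff_st < cfg.step_update_ratio * s.step_st

    if s.trial_index == cfg.step_update_trial and not s.step_divided:
        _divide_step(s, cfg)
        s.ratio_was_true = s.diff_st < cfg.step_update_ratio * s.step_st

    if s.consecutive_incorrect >= cfg.fail_consecutive_incorrect:
        s.status = FAILED
    elif len(s.reversal_levels) >= cfg.max_reversals:
        s.status = CONVERGED
    elif s.trial_index >= cfg.max_trials:
        s.status = MAX_TRIALS
    return s


def _finish(state: StaircaseState, cfg: StaircaseConfig) -> JNDResult:
    jnd = None
    if state.status in (CONVERGED, MAX_TRIALS) and len(state.reversal_levels) >= cfg.n_reversals_for_jnd:
        jnd = float(np.mean(state.reversal_levels[-cfg.n_reversals_for_jnd:]))
    return JNDResult(jnd, list(state.reversal_levels), state.trial_index, state.status)


def run_staircase(
    listener,
    cfg: StaircaseConfig | None = None,
    seed: int | np.random.Generator | None = 0,
    trace: list | None = None,
) -> JNDResult:
    """Simulate one adaptive run against an oracle listener.

    Each trial draws correctness as Bernoulli(listener.p_correct(diff)).
    If ``trace`` is a list, a per-trial record (trial, diff, step, correct,
    n_reversals) is appended to it.
    """
    cfg = cfg or StaircaseConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    state = StaircaseState.initial(cfg)
    while state.status == RUNNING:
        diff, step = state.diff_st, state.step_st
        correct = bool(rng.random() < listener.p_correct(diff))
        state = staircase_update(state, correct, cfg)
        if trace is not None:
            trace.append(
                {
                    "trial": state.trial_index,
                    "diff_st": diff,
                    "step_st": step,
                    "correct": correct,
                    "n_reversals": len(state.reversal_levels),
                }
            )
    return _finish(state, cfg)


def convergence_probe(
    listener,
    cfg: StaircaseConfig | None = None,
    n_seeds: int = 500,
    seed: int | np.random.Generator | None = 0,
) -> ProbeSummary:
    """Run many seeded staircases and locate the oracle's percent-correct at
    the across-run mean JND.

    For the 2-down-1-up rule the expected value is ~70.7%.
    """
    if n_seeds < 1:
        raise ValueError("n_seeds must be >= 1")
    cfg = cfg or StaircaseConfig()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    jnds = []
    n_failed = 0
    for child in rng.spawn(n_seeds):
        res = run_staircase(listener, cfg, seed=child)
        if res.jnd_st is None:
            n_failed += 1
        else:
            jnds.append(res.jnd_st)
    if not jnds:
        raise RuntimeError("all staircase runs failed; no JNDs to summarize")
    mean_jnd = float(np.mean(jnds))
    sd_jnd = float(np.std(jnds, ddof=1)) if len(jnds) > 1 else 0.0
    pct = 100.0 * listener.p_correct(mean_jnd)
    return ProbeSummary(mean_jnd, sd_jnd, pct, len(jnds), n_failed)
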