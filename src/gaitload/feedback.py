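"""Per-step haptic feedback, adaptive goal progression, session rules.

The vibration code partitions the percent-change line for the current goal
g (a positive percent-reduction magnitude):

* two vibrations  — step EMG above 95% of baseline (pct > -5)
* one vibration   — reduction between 5% and the goal (-g < pct <= -5)
* no vibrations   — reduction at or beyond the goal (pct <= -g)

Goals progress 10 -> 20 -> 30 (%) between trials when any 50-step moving
average within the trial meets the current goal; 30 is the ceiling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "FeedbackState",
    "StepFeedback",
    "SessionRules",
    "SessionLog",
    "percent_change",
    "vibration_count",
    "moving_average",
    "update_goal",
    "assess_qualification",
    "run_session",
    "SESSION_RULES",
]

GOAL_START = 10
GOAL_STEP = 10
GOAL_MAX = 30
TWO_VIB_BOUNDARY = -5.0  # pct above this -> 2 vibrations ("95% of baseline")


@dataclass(frozen=True)
class FeedbackState:
    baseline_value: float  # stance-mean gastrocnemius EMG of the baseline trial
    goal: int = GOAL_START  # percent-reduction magnitude, in {10, 20, 30}
    trial_index: int = 0

    def __post_init__(self) -> None:
        if self.baseline_value <= 0:
            raise ValueError("baseline_value must be > 0")
        if self.goal not in (10, 20, 30):
            raise ValueError(f"goal must be one of 10/20/30, got {self.goal}")


@dataclass(frozen=True)
class StepFeedback:
    step_index: int
    percent_change: float  # negative = reduction
    vibrations: int  # 0, 1 or 2


@dataclass(frozen=True)
class SessionRules:
    session: int
    min_trials: int
    max_trials: int
    qualification_pct: float  # required reduction magnitude, percent
    window: int = 50
    start_goal: int = GOAL_START


SESSION_RULES = {
    1: SessionRules(session=1, min_trials=3, max_trials=5, qualification_pct=10.0),
    2: SessionRules(session=2, min_trials=2, max_trials=5, qualification_pct=20.0),
}


def percent_change(step_mean: float, baseline_value: float) -> float:
    """Percent change of a step's stance-mean EMG from baseline."""
    if baseline_value <= 0:
        raise ValueError("baseline_value must be > 0")
    return 100.0 * (step_mean - baseline_value) / baseline_value


def vibration_count(pct: float, goal: int) -> int:
    if goal not in (10, 20, 30):
        raise ValueError(f"goal must be one of 10/20/30, got {goal}")
    if pct > TWO_VIB_BOUNDARY:
        return 2
    if pct > -goal:
        return 1
    return 0


def moving_average(x, window: int) -> np.ndarray:
    """Moving averages of all full windows (empty when len(x) < window)."""
    if window < 1:
        raise ValueError("window must be >= 1")
    x = np.asarray(x, dtype=float)
    if x.size < window:
        return np.empty(0)
    c = np.concatenate(([0.0], np.cumsum(x)))
    return (c[window:] - c[:-window]) / window


def update_goal(state: FeedbackState, trial_pcts, window: int = 50) -> FeedbackState:
    """Advance the adaptive goal at a trial boundary.

    If any within-trial moving average over ``window`` steps meets the
    current goal (<= -goal), the goal steps up by 10 points, capped at 30.
    The trial index always increments.
    """
    avgs = moving_average(trial_pcts, window)
    goal = state.goal
    if avgs.size and float(avgs.min()) <= -goal:
        goal = min(goal + GOAL_STEP, GOAL_MAX)
    return replace(state, goal=goal, trial_index=state.trial_index + 1)


def assess_qualification(
    session: int, all_trial_pcts, window: int = 50
) -> tuple[bool, float | None]:
    """Check the session's early-finish criterion over completed trials.

    Windows never span trial boundaries. Returns (qualified, best moving
    average found); best is None when no trial contains a full window.
    """
    threshold = SESSION_RULES[session].qualification_pct
    best: float | None = None
    for pcts in all_trial_pcts:
        avgs = moving_average(pcts, window)
        if avgs.size:
            m = float(avgs.min())
            best = m if best is None else min(best, m)
    return (best is not None and best <= -threshold), best


@dataclass
class SessionLog:
    """Replay record of one feedback session."""

    session: int
    steps: list[StepFeedback] = field(default_factory=list)
    step_trial: list[int] = field(default_factory=list)
    step_goal: list[int] = field(default_factory=list)
    goal_trajectory: list[int] = field(default_factory=list)  # goal in effect per trial
    qualified: bool = False
    best_window_avg: float | None = None
    n_trials: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step_index": [s.step_index for s in self.steps],
                "trial": self.step_trial,
                "percent_change": [s.percent_change for s in self.steps],
                "vibrations": [s.vibrations for s in self.steps],
                "goal": self.step_goal,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def run_session(
    trials,
    state0: FeedbackState,
    rules: SessionRules,
) -> SessionLog:
    """Replay a feedback session over per-trial step stance means.

    Deterministic. Feedback is emitted per step with the goal in force for
    that trial; the goal updates only at trial boundaries. The session stops
    early once the qualification criterion is met and at least
    ``rules.min_trials`` trials have run, and always stops after
    ``rules.max_trials``.
    """
    if not 1 <= len(trials) <= rules.max_trials:
        raise ValueError(
            f"expected 1..{rules.max_trials} trials, got {len(trials)}"
        )
    state = state0
    log = SessionLog(session=rules.session)
    completed_pcts: list[np.ndarray] = []
    step_counter = 0
    for trial in trials:
        trial = np.asarray(trial, dtype=float)
        if trial.size == 0:
            warnings.warn("empty trial skipped", stacklevel=2)
            continue
        pcts = np.array(
            [percent_change(v, state.baseline_value) for v in trial]
        )
        log.goal_trajectory.append(state.goal)
        for p in pcts:
            log.steps.append(
                StepFeedback(step_counter, float(p), vibration_count(float(p), state.goal))
            )
            log.step_trial.append(state.trial_index)
            log.step_goal.append(state.goal)
            step_counter += 1
        completed_pcts.append(pcts)
        log.n_trials += 1
        qualified, best = assess_qualification(
            rules.session, completed_pcts, rules.window
        )
        log.qualified, log.best_window_avg = qualified, best
        state = update_goal(state, pcts, rules.window)
        if qualified and log.n_trials >= rules.min_trials:
            break
    return log
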