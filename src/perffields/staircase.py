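"""Grid-based QUEST adaptive staircase for contrast thresholds.

A Bayesian staircase maintains a discrete posterior over candidate log10
contrast thresholds of an assumed Weibull psychometric function

    p(correct | c, alpha) = gamma + (1 - gamma - delta) *
                            (1 - exp(-10 ** (beta * (log10 c - log10 alpha))))

and, after each trial, multiplies the posterior by the likelihood of the
observed outcome.  The next test contrast is placed where the assumed
psychometric function of the current MAP threshold crosses the criterion
accuracy (mode-placement rule).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class Psychometric:
    """Assumed Weibull shape: slope ``beta``, guess rate ``gamma``, lapse ``delta``."""

    beta: float = 3.0
    gamma: float = 0.5
    delta: float = 0.01


@dataclass(frozen=True)
class QuestState:
    """Immutable staircase state.

    ``grid``: strictly increasing support of candidate log10 thresholds;
    ``posterior``: probability mass over the grid (sums to 1);
    ``history``: tuple of (log10 contrast tested, correct) pairs.
    """

    grid: np.ndarray
    posterior: np.ndarray
    psychometric: Psychometric
    criterion: float
    history: tuple[tuple[float, bool], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(self.posterior < 0) or abs(self.posterior.sum() - 1.0) > 1e-9:
            raise ValueError("posterior must be a normalized probability mass")


def weibull_p(log_contrast, log_threshold, psychometric: Psychometric) -> np.ndarray:
    """Probability correct under the assumed Weibull, in log10-contrast form."""
    g, d, b = psychometric.gamma, psychometric.delta, psychometric.beta
    x = np.asarray(log_contrast, dtype=float) - np.asarray(log_threshold, dtype=float)
    return g + (1.0 - g - d) * (1.0 - np.exp(-(10.0 ** (b * x))))


def criterion_offset(psychometric: Psychometric, criterion: float) -> float:
    """log10-contrast offset from threshold at which accuracy equals the criterion."""
    g, d, b = psychometric.gamma, psychometric.delta, psychometric.beta
    if not g < criterion < 1.0 - d:
        raise ValueError("criterion must lie strictly between chance and the lapse ceiling")
    q = -np.log(1.0 - (criterion - g) / (1.0 - g - d))
    return float(np.log10(q) / b)


def quest_init(
    prior_mean: float,
    prior_sd: float,
    psychometric: Psychometric = Psychometric(),
    criterion: float = 0.75,
    n_grid: int = 201,
    grid_halfspan_sd: float = 3.0,
) -> QuestState:
    """Fresh staircase with a Gaussian prior over log10 thresholds.

    The grid spans ``prior_mean +/- grid_halfspan_sd * prior_sd`` with
    ``n_grid`` points.
    """
    if prior_sd <= 0:
        raise ValueError("prior_sd must be positive")
    criterion_offset(psychometric, criterion)  # validates the criterion
    grid = np.linspace(
        prior_mean - grid_halfspan_sd * prior_sd,
        prior_mean + grid_halfspan_sd * prior_sd,
        n_grid,
    )
    prior = np.exp(-0.5 * ((grid - prior_mean) / prior_sd) ** 2)
    prior /= prior.sum()
    return QuestState(grid=grid, posterior=prior, psychometric=psychometric, criterion=criterion)


def quest_update(state: QuestState, tested_log_contrast: float, correct: bool) -> QuestState:
    """Posterior update after one trial outcome at a tested log10 contrast."""
    p = weibull_p(tested_log_contrast, state.grid, state.psychometric)
    like = p if correct else 1.0 - p
    post = state.posterior * like
    total = post.sum()
    if total <= 0:  # pragma: no cover - impossible with gamma > 0, delta < 1
        raise FloatingPointError("posterior mass vanished")
    post = post / total
    post = post / post.sum()  # second pass keeps the mass within 1e-12 of 1
    return QuestState(
        grid=state.grid,
        posterior=post,
        psychometric=state.psychometric,
        criterion=state.criterion,
        history=state.history + ((float(tested_log_contrast), bool(correct)),),
    )


def quest_mode(state: QuestState) -> float:
    """MAP estimate of the log10 threshold; grid ties break toward lower contrast."""
    return float(state.grid[int(np.argmax(state.posterior))])


def quest_recommend(state: QuestState) -> float:
    """Next log10 contrast to test: the criterion point of the MAP threshold."""
    return quest_mode(state) + criterion_offset(state.psychometric, state.criterion)


def run_quest(
    respond,
    n_trials: int,
    prior_mean: float,
    prior_sd: float,
    psychometric: Psychometric = Psychometric(),
    criterion: float = 0.75,
    min_log_contrast: float | None = None,
    max_log_contrast: float = 0.0,
) -> QuestState:
    """Run a staircase against a response callback.

    ``respond(log10_contrast) -> bool`` produces each trial's outcome.  Test
    contrasts are clipped to ``[min_log_contrast, max_log_contrast]``
    (defaulting to the grid floor and 0, i.e. full contrast).
    """
    state = quest_init(prior_mean, prior_sd, psychometric, criterion)
    lo = float(state.grid[0]) if min_log_contrast is None else min_log_contrast
    for _ in range(n_trials):
        c = float(np.clip(quest_recommend(state), lo, max_log_contrast))
        state = quest_update(state, c, respond(c))
    return state


def transcript(state: QuestState) -> pd.DataFrame:
    """Staircase transcript: one row per trial with the running MAP estimate."""
    rows = []
    mode_trace = quest_replay_modes(state)
    for i, ((log_c, ok), mode) in enumerate(zip(state.history, mode_trace), start=1):
        rows.append(
            {"trial": i, "log10_contrast": log_c, "correct": ok, "posterior_mode": mode}
        )
    return pd.DataFrame(rows, columns=["trial", "log10_contrast", "correct", "posterior_mode"])


def quest_replay_modes(state: QuestState) -> list[float]:
    """MAP threshold after each historical trial (recomputed from the prior)."""
    # The prior is recoverable because updates only multiply likelihoods.
    post = state.posterior.copy()
    for log_c, ok in reversed(state.history):
        p = weibull_p(log_c, state.grid, state.psychometric)
        like = p if ok else 1.0 - p
        post = post / like
        post /= post.sum()
    modes = []
    for log_c, ok in state.history:
        p = weibull_p(log_c, state.grid, state.psychometric)
        like = p if ok else 1.0 - p
        post = post * like
        post /= post.sum()
        modes.append(float(state.grid[int(np.argmax(post))]))
    return modes
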