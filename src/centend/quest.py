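"""QUEST Bayesian adaptive staircase for the discrimination tasks.

QUEST maintains a posterior over the observer's threshold on a discrete
grid and places each comparison stimulus at the current best estimate
(posterior mode by default).  The assumed psychometric family is a
cumulative Gaussian on the linear stimulus axis,

    psi(x; T) = gamma + (1 - gamma - delta) * Phi(beta * (x - T)),

with assumed slope beta and small symmetric floor/ceiling offsets gamma
and delta.  The response being modelled is "comparison judged longer",
whose probability genuinely runs from ~0 to ~1 across the comparison
range (this is a judgement of which interval was longer, not a
correct/incorrect score), so gamma is a lapse-like floor near 0 — not the
0.5 guess rate used for performance-scored tasks — and the tracked
threshold T is the point of subjective equality.  The posterior is stored
in log space so long sessions cannot underflow, and every update
renormalizes.

Placing every trial exactly at the posterior estimate samples one point
of the psychometric function, which cannot identify both its location and
its slope; sessions therefore alternate placements through a deterministic
cycle of offsets around the recommendation (default +/-1.57 assumed SDs,
the information-optimal symmetric two-point design for estimating the
slope), so the session log supports the later cumulative-Gaussian fit.

Defaults mirror the study's staircases: the spatial session starts from a
prior of 12.0 +/- 3.6 cm around the 10 cm standard, the temporal one from
1.7 +/- 0.52 s around the 1.535 s standard, and a session never stops
before 50 trials.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm

from .observers import ObserverParams, simulate_discrimination_choice

__all__ = [
    "QuestConfig",
    "QuestState",
    "default_config",
    "quest_init",
    "quest_recommend",
    "quest_update",
    "quest_should_stop",
    "run_discrimination_session",
]


@dataclass(frozen=True)
class QuestConfig:
    """Staircase configuration: threshold prior, grid, assumed psychometric
    parameters, placement rule and stopping rule."""

    guess: float
    prior_sd: float
    grid_min: float
    grid_max: float
    grid_n: int = 201
    beta: float = 1.0
    delta: float = 0.01
    gamma: float = 0.01
    recommendation_rule: str = "mode"  # "mode" | "mean" | "quantile"
    quantile: float = 0.5
    min_trials: int = 50
    max_trials: int = 60
    sd_stop: float | None = None
    #: Deterministic cycle of offsets (stimulus units) added to the
    #: recommendation on successive session trials, spreading placements
    #: across the transition region; empty for pure QUEST placement.
    placement_offsets: tuple[float, ...] = ()
    #: Optional extra uniform jitter half-width (stimulus units).
    placement_jitter: float = 0.0

    def __post_init__(self) -> None:
        if not self.grid_min < self.guess < self.grid_max:
            raise ValueError("guess must lie strictly inside the grid")
        if self.grid_n < 3:
            raise ValueError("grid_n must be >= 3")
        if not self.prior_sd > 0:
            raise ValueError("prior_sd must be positive")
        if not self.beta > 0:
            raise ValueError("beta must be positive")
        if not (0 <= self.gamma < 1 and 0 <= self.delta < 1 and self.gamma + self.delta < 1):
            raise ValueError("need 0 <= gamma, delta and gamma + delta < 1")
        if self.recommendation_rule not in ("mode", "mean", "quantile"):
            raise ValueError(f"unknown rule: {self.recommendation_rule!r}")
        if not 0.0 < self.quantile < 1.0:
            raise ValueError("quantile must be in (0, 1)")
        if not 1 <= self.min_trials <= self.max_trials:
            raise ValueError("need 1 <= min_trials <= max_trials")
        if self.sd_stop is not None and not self.sd_stop > 0:
            raise ValueError("sd_stop must be positive when set")
        if self.placement_jitter < 0:
            raise ValueError("placement_jitter must be >= 0")

    @property
    def grid(self) -> np.ndarray:
        return np.linspace(self.grid_min, self.grid_max, self.grid_n)


@dataclass(frozen=True)
class QuestState:
    """Log posterior over the threshold grid plus the trial history."""

    log_posterior: np.ndarray
    history: tuple[tuple[float, bool], ...] = ()

    @property
    def n_trials(self) -> int:
        return len(self.history)

    def posterior(self) -> np.ndarray:
        """Normalized posterior probabilities on the grid."""
        p = np.exp(self.log_posterior - logsumexp(self.log_posterior))
        return p / p.sum()

    def posterior_mean(self, config: QuestConfig) -> float:
        return float(np.dot(self.posterior(), config.grid))

    def posterior_sd(self, config: QuestConfig) -> float:
        p = self.posterior()
        g = config.grid
        m = float(np.dot(p, g))
        return float(np.sqrt(np.dot(p, (g - m) ** 2)))


def default_config(condition: str) -> QuestConfig:
    """The study's staircase for one condition (space or time)."""
    if condition == "space":
        return QuestConfig(
            guess=12.0, prior_sd=3.6, grid_min=2.0, grid_max=22.0, grid_n=201,
            beta=1.0 / (0.1 * 10.0), placement_offsets=(-1.57, 1.57),
        )
    if condition == "time":
        return QuestConfig(
            guess=1.7, prior_sd=0.52, grid_min=0.2, grid_max=3.2, grid_n=301,
            beta=1.0 / (0.1 * 1.535), placement_offsets=(-0.241, 0.241),
        )
    raise ValueError(f"unknown condition: {condition!r}")


def quest_init(config: QuestConfig) -> QuestState:
    """Fresh state: discretized normal prior N(guess, prior_sd) on the grid."""
    g = config.grid
    logp = -0.5 * ((g - config.guess) / config.prior_sd) ** 2
    logp -= logsumexp(logp)
    return QuestState(log_posterior=logp)


def _psi(x: float, grid: np.ndarray, config: QuestConfig) -> np.ndarray:
    """Assumed P(comparison judged longer) at intensity x, per grid threshold."""
    core = norm.cdf(config.beta * (x - grid))
    return config.gamma + (1.0 - config.gamma - config.delta) * core


def quest_recommend(state: QuestState, config: QuestConfig) -> float:
    """Next comparison intensity under the configured placement rule.

    The mode rule returns the grid value with maximal posterior mass, ties
    broken toward the value nearest the prior guess; mean and quantile
    rules snap their estimate to the nearest grid value.  The result is
    always within the grid bounds.
    """
    p = state.posterior()
    g = config.grid
    if config.recommendation_rule == "mode":
        maxp = p.max()
        cand = g[p >= maxp * (1.0 - 1e-12)]
        return float(cand[np.argmin(np.abs(cand - config.guess))])
    if config.recommendation_rule == "mean":
        est = float(np.dot(p, g))
    else:
        cdf = np.cumsum(p)
        est = float(g[np.searchsorted(cdf, config.quantile)])
    return float(g[np.argmin(np.abs(g - est))])


def quest_update(
    state: QuestState, intensity: float, response: bool, config: QuestConfig
) -> QuestState:
    """Bayes update: multiply by psi (comparison judged longer) or 1 - psi.

    Returns a new state; updates commute, as products of likelihoods must.
    """
    if not np.isfinite(intensity):
        raise ValueError("intensity must be finite")
    if not config.grid_min <= intensity <= config.grid_max:
        raise ValueError(
            f"intensity {intensity} outside grid [{config.grid_min}, {config.grid_max}]"
        )
    psi = _psi(float(intensity), config.grid, config)
    lik = psi if response else 1.0 - psi
    logp = state.log_posterior + np.log(np.clip(lik, 1e-300, None))
    logp -= logsumexp(logp)
    return QuestState(
        log_posterior=logp,
        history=state.history + ((float(intensity), bool(response)),),
    )


def quest_should_stop(state: QuestState, config: QuestConfig) -> bool:
    """True once the trial floor is reached and either the ceiling is hit
    or the posterior SD has fallen below ``sd_stop`` (when configured)."""
    n = state.n_trials
    if n < config.min_trials:
        return False
    if n >= config.max_trials:
        return True
    if config.sd_stop is not None:
        return state.posterior_sd(config) <= config.sd_stop
    return False


def run_discrimination_session(
    config: QuestConfig,
    observer: ObserverParams,
    standard: float,
    seed: int = 0,
):
    """Simulate one adaptive discrimination session against ``observer``.

    Each trial: recommend a comparison, randomize whether it occupies the
    first or second interval, draw the observer's choice, update the
    posterior.  Returns a tidy DataFrame trial log with columns
    ``trial_index, standard, comparison, comparison_position, choice,
    comparison_judged_longer``.
    """
    import pandas as pd

    if not standard > 0:
        raise ValueError("standard must be positive")
    rng = np.random.default_rng(seed)
    state = quest_init(config)
    records = []
    grid = config.grid
    offsets = config.placement_offsets
    while not quest_should_stop(state, config):
        x = quest_recommend(state, config)
        if offsets:
            x += offsets[len(records) % len(offsets)]
        if config.placement_jitter > 0:
            x += rng.uniform(-config.placement_jitter, config.placement_jitter)
        x = float(grid[np.argmin(np.abs(grid - x))])  # snap/clip to grid
        position = int(rng.integers(1, 3))  # interval holding the comparison
        longer = simulate_discrimination_choice(observer, standard, x, rng)
        choice = position if longer else (3 - position)
        records.append(
            {"trial_index": len(records), "standard": float(standard),
             "comparison": float(x), "comparison_position": position,
             "choice": choice, "comparison_judged_longer": bool(longer)}
        )
        state = quest_update(state, x, longer, config)
    return pd.DataFrame(records)
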