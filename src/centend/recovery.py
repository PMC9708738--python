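"""Parameter-recovery experiments: simulate observers with known
generative parameters, run the analysis pipeline, and tabulate how well
the estimators recover them.

Two experiments are provided:

* :func:`recover_regression_index` — static-mean observers across a grid
  of prior weights w; the regression index should recover w (its OLS
  estimator is unbiased under the linear generative model) and the mean
  offset should recover the generative response bias b.
* :func:`recover_weber_fraction` — QUEST discrimination sessions against
  observers with known discrimination noise, followed by the
  cumulative-Gaussian fit; tabulates the relative error of the recovered
  Weber fraction.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import quest
from .central_tendency import summarize
from .observers import ObserverParams, simulate_reproduction
from .psychometric import fit_cumulative_gaussian, weber_fraction
from .schedules import (
    SPACE_STANDARD,
    TIME_STANDARD,
    default_reproduction_schedule,
    participant_task_seed,
)

__all__ = ["recover_regression_index", "recover_weber_fraction"]

DEFAULT_W_GRID = tuple(np.round(np.arange(0.1, 0.95, 0.1), 2))


def recover_regression_index(
    w_values=DEFAULT_W_GRID,
    n_participants: int = 200,
    condition: str = "space",
    noise_cv: float = 0.12,
    sigma_m: float = 0.3,
    bias: float = -0.053,
    seed: int = 0,
) -> pd.DataFrame:
    """Regression-index / offset recovery over a grid of prior weights.

    Each cell simulates ``n_participants`` static-mean observers on the
    default 66-trial reproduction schedule with constant sensory noise
    ``noise_cv * mean stimulus`` and a common generative bias ``b``.
    Returns one row per w with the mean and SD of the recovered regression
    index, its bias against w, and the mean recovered offset.
    """
    sched0 = default_reproduction_schedule(condition, seed=0)
    s_bar = sched0.mean_level
    sigma_s = noise_cv * s_bar
    rows = []
    pid = 0
    for w in w_values:
        ri_vals = np.empty(n_participants)
        offset_vals = np.empty(n_participants)
        for i in range(n_participants):
            obs = ObserverParams(
                w_prior=float(w), prior_mode="static_mean",
                sigma_s=sigma_s, sigma_m=sigma_m, bias=bias,
            )
            ps = participant_task_seed(seed, pid, condition, "reproduction")
            sched = default_reproduction_schedule(condition, seed=ps)
            stim, resp = simulate_reproduction(obs, sched, seed=ps + 1)
            summ = summarize((stim, resp))
            ri_vals[i] = summ.regression_index
            offset_vals[i] = summ.offset
            pid += 1
        rows.append(
            {"w": float(w), "n": n_participants,
             "mean_ri": float(np.mean(ri_vals)), "sd_ri": float(np.std(ri_vals, ddof=1)),
             "ri_bias": float(np.mean(ri_vals) - w),
             "ri_rmse": float(np.sqrt(np.mean((ri_vals - w) ** 2))),
             "generative_bias": float(bias),
             "mean_offset": float(np.mean(offset_vals)),
             "offset_bias": float(np.mean(offset_vals) - bias)}
        )
    return pd.DataFrame(rows)


def recover_weber_fraction(
    n_sessions: int = 100,
    condition: str = "space",
    true_wf: float = 0.1,
    lapse: float = 0.02,
    seed: int = 0,
) -> pd.DataFrame:
    """Weber-fraction recovery through the full staircase + fit pipeline.

    Runs ``n_sessions`` QUEST discrimination sessions (default stopping
    rule, so >= 50 trials each) against an observer whose discrimination
    noise is ``true_wf * standard``, fits each session log, and returns
    one row per session with the fitted Weber fraction and its relative
    error.  Non-converged fits are kept and flagged, never dropped.
    """
    standard = SPACE_STANDARD if condition == "space" else TIME_STANDARD
    sigma_d = true_wf * standard
    obs = ObserverParams(sigma_s=0.0, sigma_d=sigma_d, lapse=lapse)
    cfg = quest.default_config(condition)
    rows = []
    for i in range(n_sessions):
        ss = participant_task_seed(seed, i, condition, "discrimination")
        log = quest.run_discrimination_session(cfg, obs, standard, seed=ss)
        fit = fit_cumulative_gaussian(log)
        wf = weber_fraction(fit.sigma, standard) if fit.converged else np.nan
        rows.append(
            {"session": i, "n_trials": int(len(log)), "true_wf": float(true_wf),
             "fitted_mu": fit.mu, "fitted_sigma": fit.sigma,
             "fitted_wf": wf, "converged": fit.converged,
             "rel_error": abs(wf - true_wf) / true_wf if fit.converged else np.nan}
        )
    return pd.DataFrame(rows)
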