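"""Parametric observers embodying the Bayesian context-dependency model.

Every analysis stage in the package can be exercised without human data by
simulating observers whose reproduction responses regress toward a prior.
The generative model for a reproduction trial with stimulus S is

    m = S + eps_s                    sensory measurement
    p = w * mu_prior + (1 - w) * m   prior-weighted percept
    R = p + b + eps_m                motor response

where eps_s is zero-mean Gaussian sensory noise — either a constant scale
sigma_s (typical for length) or scalar variability k * S (the standard
assumption for interval timing) — w in [0, 1] is the weight on the prior,
b a constant response bias (the generative analogue of the measured
Offset) and eps_m zero-mean Gaussian motor noise.  Under the static-mean
prior (mu_prior = mean of the stimulus set) the expected response slope is
1 - w, so the regression index recovers w exactly; a running-mean prior
(mean of all previous measurements) is available for trial-history
simulations.

Discrimination responses follow the same cumulative-Gaussian law that the
analysis side fits: P(comparison judged longer) =
lapse/2 + (1 - lapse) * Phi((c - s) / sigma_d).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .schedules import StimulusSchedule

__all__ = [
    "ObserverParams",
    "simulate_reproduction",
    "simulate_discrimination_choice",
    "discrimination_choice_probability",
    "simulate_pointing",
    "simulate_rhythm",
    "simulate_cohort",
    "default_cohort_spec",
    "POINTING_POSITIONS",
    "RHYTHM_TARGET_INTERVAL",
    "RHYTHM_N_INTERVALS",
    "POINTING_N_TRIALS",
]

#: Touchscreen active area (cm) and the five pointing-target positions:
#: four corners 2 cm in from the frame, plus the centre.
_SCREEN_CM = (43.69, 24.07)
POINTING_POSITIONS = (
    (2.0, 2.0),
    (_SCREEN_CM[0] - 2.0, 2.0),
    (2.0, _SCREEN_CM[1] - 2.0),
    (_SCREEN_CM[0] - 2.0, _SCREEN_CM[1] - 2.0),
    (_SCREEN_CM[0] / 2.0, _SCREEN_CM[1] / 2.0),
)
POINTING_N_TRIALS = 50

#: Rhythm task defaults: 50 dot appearances, the first 4 watched only,
#: leaving 46 paced presses and 45 analyzed inter-press intervals.  The
#: pacing interval itself is a package choice (1 s).
RHYTHM_TARGET_INTERVAL = 1.0
RHYTHM_N_INTERVALS = 45


@dataclass(frozen=True)
class ObserverParams:
    """Generative parameters of one simulated participant (one condition).

    Exactly one of ``sigma_s`` (constant sensory noise, stimulus units) and
    ``weber_coeff`` (scalar variability, sd = k * S) must be set.
    """

    w_prior: float = 0.5
    prior_mode: str = "static_mean"  # or "running_mean"
    sigma_s: float | None = None
    weber_coeff: float | None = None
    sigma_m: float = 0.0
    bias: float = 0.0
    lapse: float = 0.0
    sigma_d: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.w_prior <= 1.0:
            raise ValueError("w_prior must be in [0, 1]")
        if self.prior_mode not in ("static_mean", "running_mean"):
            raise ValueError(f"unknown prior_mode: {self.prior_mode!r}")
        if (self.sigma_s is None) == (self.weber_coeff is None):
            raise ValueError("set exactly one of sigma_s and weber_coeff")
        for name in ("sigma_s", "weber_coeff", "sigma_m", "sigma_d"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.lapse <= 0.5:
            raise ValueError("lapse must be in [0, 0.5]")

    def sensory_sd(self, stimulus) -> np.ndarray:
        """Sensory noise SD at the given stimulus magnitude(s)."""
        s = np.asarray(stimulus, dtype=float)
        if self.sigma_s is not None:
            return np.full_like(s, self.sigma_s)
        return self.weber_coeff * s


def simulate_reproduction(
    params: ObserverParams, schedule: StimulusSchedule, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one reproduction session; returns (stimuli, responses).

    Responses are clipped at zero (negative lengths or durations are
    meaningless); clipping is counted and warned about since it bends the
    linear generative model.
    """
    if schedule.task != "reproduction":
        raise ValueError(f"expected a reproduction schedule, got {schedule.task!r}")
    rng = np.random.default_rng(seed)
    stimuli = schedule.magnitudes
    eps_s = rng.normal(0.0, 1.0, stimuli.size) * params.sensory_sd(stimuli)
    m = stimuli + eps_s
    if params.prior_mode == "static_mean":
        mu_p = np.full(stimuli.size, schedule.mean_level)
    else:
        # running mean of previous measurements; first trial uses its own
        csum = np.cumsum(m)
        mu_p = np.empty(stimuli.size)
        mu_p[0] = m[0]
        mu_p[1:] = csum[:-1] / np.arange(1, stimuli.size)
    percept = params.w_prior * mu_p + (1.0 - params.w_prior) * m
    responses = percept + params.bias + rng.normal(0.0, params.sigma_m, stimuli.size)
    n_clipped = int(np.sum(responses < 0))
    if n_clipped:
        warnings.warn(
            f"{n_clipped} response(s) clipped at 0; the linear generative "
            "model is distorted at this noise level",
            stacklevel=2,
        )
        responses = np.clip(responses, 0.0, None)
    return stimuli, responses


def discrimination_choice_probability(
    params: ObserverParams, standard: float, comparison: float
) -> float:
    """P(comparison judged longer) under the observer's psychometric law."""
    if not (standard > 0 and comparison > 0):
        raise ValueError("magnitudes must be positive")
    if params.sigma_d > 0:
        core = norm.cdf((comparison - standard) / params.sigma_d)
    else:
        # deterministic step observer; an exact tie is a fair coin
        if comparison == standard:
            core = 0.5
        else:
            core = 1.0 if comparison > standard else 0.0
    return params.lapse / 2.0 + (1.0 - params.lapse) * core


def simulate_discrimination_choice(
    params: ObserverParams, standard: float, comparison: float, seed
) -> bool:
    """One seeded Bernoulli draw: True iff the comparison is judged longer.

    ``seed`` may be an integer or an existing :class:`numpy.random.Generator`
    (so a session can thread a single stream through its trials).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p = discrimination_choice_probability(params, standard, comparison)
    return bool(rng.random() < p)


def simulate_pointing(
    params: ObserverParams, n_trials: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Pointing control task: targets cycle over the five screen positions;
    touches are target + isotropic 2-D Gaussian motor noise (sigma_m)."""
    n_trials = int(n_trials)
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    pos = np.asarray(POINTING_POSITIONS, dtype=float)
    targets = pos[np.arange(n_trials) % pos.shape[0]]
    touches = targets + rng.normal(0.0, params.sigma_m, size=targets.shape)
    return targets, touches


def simulate_rhythm(
    params: ObserverParams,
    n_intervals: int = RHYTHM_N_INTERVALS,
    target_interval: float = RHYTHM_TARGET_INTERVAL,
    seed: int = 0,
) -> np.ndarray:
    """Rhythm control task: inter-press intervals = target + motor noise."""
    n_intervals = int(n_intervals)
    if n_intervals < 2:
        raise ValueError("n_intervals must be >= 2")
    if not target_interval > 0:
        raise ValueError("target_interval must be positive")
    rng = np.random.default_rng(seed)
    intervals = target_interval + rng.normal(0.0, params.sigma_m, n_intervals)
    return np.clip(intervals, 1e-6, None)


# ---------------------------------------------------------------------------
# Cohort simulation

def default_cohort_spec() -> dict:
    """Two age cohorts at the study's sample sizes (25 young, 21 older).

    Group-level parameter distributions echo the study conditions: constant
    sensory noise for length, scalar variability for duration, a constant
    underestimation bias, and discrimination noise set so the Weber
    fractions land near 0.09/0.18 (young) and 0.13/0.25 (older) in the
    space/time conditions.  Between-participant spread follows the
    reported group SDs.
    """
    def g(mean, sd, low=None, high=None):
        d = {"dist": "normal", "mean": mean, "sd": sd}
        if low is not None:
            d["low"] = low
        if high is not None:
            d["high"] = high
        return d

    return {
        "groups": [
            {
                "name": "YA",
                "n": 25,
                "space": {
                    "w_prior": g(0.426, 0.195, 0.0, 1.0),
                    "sigma_s": g(1.96, 0.35, 0.05),
                    "sigma_m": g(0.17, 0.05, 0.02),
                    "bias": g(-0.053, 0.128),
                    "lapse": 0.02,
                    "sigma_d": g(0.93, 0.43, 0.05),
                },
                "time": {
                    "w_prior": g(0.320, 0.193, 0.0, 1.0),
                    "weber_coeff": g(0.20, 0.05, 0.01),
                    "sigma_m": g(0.065, 0.02, 0.01),
                    "bias": g(-0.054, 0.092),
                    "lapse": 0.02,
                    "sigma_d": g(0.272, 0.086, 0.01),
                },
            },
            {
                "name": "OA",
                "n": 21,
                "space": {
                    "w_prior": g(0.467, 0.168, 0.0, 1.0),
                    "sigma_s": g(2.24, 0.60, 0.05),
                    "sigma_m": g(0.21, 0.07, 0.02),
                    "bias": g(-0.121, 0.114),
                    "lapse": 0.02,
                    "sigma_d": g(1.33, 0.74, 0.05),
                },
                "time": {
                    "w_prior": g(0.294, 0.294, 0.0, 1.0),
                    "weber_coeff": g(0.18, 0.06, 0.01),
                    "sigma_m": g(0.085, 0.03, 0.01),
                    "bias": g(-0.120, 0.092),
                    "lapse": 0.02,
                    "sigma_d": g(0.381, 0.198, 0.01),
                },
            },
        ]
    }


def _draw_param(spec, rng: np.random.Generator, field: str) -> float:
    if isinstance(spec, (int, float)):
        return float(spec)
    if not isinstance(spec, dict):
        raise ValueError(f"malformed distribution for {field!r}: {spec!r}")
    dist = spec.get("dist", "normal")
    if dist == "constant":
        return float(spec["value"])
    if dist == "uniform":
        return float(rng.uniform(spec["low"], spec["high"]))
    if dist == "normal":
        try:
            v = float(rng.normal(spec["mean"], spec["sd"]))
        except KeyError as e:
            raise ValueError(f"malformed distribution for {field!r}: missing {e}") from e
        lo = spec.get("low", -np.inf)
        hi = spec.get("high", np.inf)
        return float(np.clip(v, lo, hi))
    raise ValueError(f"unknown distribution {dist!r} for {field!r}")


def _draw_observer(cond_spec: dict, rng: np.random.Generator) -> ObserverParams:
    allowed = {
        "w_prior", "prior_mode", "sigma_s", "weber_coeff",
        "sigma_m", "bias", "lapse", "sigma_d",
    }
    unknown = set(cond_spec) - allowed
    if unknown:
        raise ValueError(f"unknown observer field(s): {sorted(unknown)}")
    kwargs = {}
    for field, spec in cond_spec.items():
        if field == "prior_mode":
            kwargs[field] = str(spec)
        else:
            kwargs[field] = _draw_param(spec, rng, field)
    return ObserverParams(**kwargs)


def simulate_cohort(cohort_spec: dict | None = None, seed: int = 0):
    """Simulate the full six-task dataset for a cohort of observers.

    Returns a dict of tidy :class:`pandas.DataFrame` trial logs keyed by
    task (``reproduction``, ``discrimination``, ``pointing``, ``rhythm``)
    plus a ``participants`` table with each participant's drawn generative
    parameters.  Deterministic for a fixed seed; participant substreams are
    independent, so changing one group's size never perturbs the draws of
    the other participants.
    """
    import pandas as pd

    from . import quest
    from .schedules import (
        SPACE_STANDARD, TIME_STANDARD, default_reproduction_schedule,
        draw_nuisance, participant_task_seed,
    )

    if cohort_spec is None:
        cohort_spec = default_cohort_spec()
    groups = cohort_spec.get("groups")
    if not groups:
        raise ValueError("cohort spec missing 'groups'")
    for gi, grp in enumerate(groups):
        for key in ("name", "n", "space", "time"):
            if key not in grp:
                raise ValueError(f"group {gi} missing field {key!r}")

    standards = {"space": SPACE_STANDARD, "time": TIME_STANDARD}
    rows: dict[str, list] = {t: [] for t in ("reproduction", "discrimination", "pointing", "rhythm")}
    participant_rows = []
    pid = 0
    for gi, grp in enumerate(groups):
        if int(grp["n"]) < 1:
            raise ValueError(f"group {grp['name']!r} has non-positive n")
        for _ in range(int(grp["n"])):
            param_rng = np.random.default_rng(
                participant_task_seed(seed, pid, "space", "pointing") + 7
            )
            for condition in ("space", "time"):
                obs = _draw_observer(grp[condition], param_rng)
                participant_rows.append(
                    {"participant": pid, "group": grp["name"], "condition": condition,
                     **{k: getattr(obs, k) for k in (
                         "w_prior", "prior_mode", "sigma_s", "weber_coeff",
                         "sigma_m", "bias", "lapse", "sigma_d")}}
                )
                # reproduction
                rs = participant_task_seed(seed, pid, condition, "reproduction")
                sched = draw_nuisance(
                    default_reproduction_schedule(condition, seed=rs), seed=rs + 1
                )
                stim, resp = simulate_reproduction(obs, sched, seed=rs + 2)
                for i, (s, r) in enumerate(zip(stim, resp)):
                    rows["reproduction"].append(
                        {"participant": pid, "group": grp["name"], "condition": condition,
                         "task": "reproduction", "trial_index": i,
                         "set_index": sched.trials[i][0], "stimulus": s,
                         "nuisance": sched.nuisance[i], "response": r}
                    )
                # discrimination (QUEST-driven session)
                ds = participant_task_seed(seed, pid, condition, "discrimination")
                cfg = quest.default_config(condition)
                log = quest.run_discrimination_session(
                    cfg, obs, standards[condition], seed=ds
                )
                for rec in log.to_dict("records"):
                    rows["discrimination"].append(
                        {"participant": pid, "group": grp["name"], "condition": condition,
                         "task": "discrimination", **rec}
                    )
                # control task (pointing for space, rhythm for time)
                cs = participant_task_seed(
                    seed, pid, condition, "pointing" if condition == "space" else "rhythm"
                )
                if condition == "space":
                    targets, touches = simulate_pointing(obs, POINTING_N_TRIALS, seed=cs)
                    for i in range(targets.shape[0]):
                        rows["pointing"].append(
                            {"participant": pid, "group": grp["name"], "condition": "space",
                             "task": "pointing", "trial_index": i,
                             "x_s": targets[i, 0], "y_s": targets[i, 1],
                             "x_r": touches[i, 0], "y_r": touches[i, 1]}
                        )
                else:
                    intervals = simulate_rhythm(obs, seed=cs)
                    for i, iv in enumerate(intervals):
                        rows["rhythm"].append(
                            {"participant": pid, "group": grp["name"], "condition": "time",
                             "task": "rhythm", "trial_index": i, "interval": iv}
                        )
            pid += 1

    out = {task: pd.DataFrame(r) for task, r in rows.items()}
    out["participants"] = pd.DataFrame(participant_rows)
    return out
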