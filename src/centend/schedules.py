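"""Stimulus schedules for the six space/time perception tasks.

The experiment has two conditions (space: segment lengths in cm; time:
interval durations in s), each with a reproduction task, a discrimination
task, and a control task (pointing for space, rhythm synchronization for
time).  Reproduction schedules are block-randomized: the full level set is
presented once per set, shuffled within each set.  Discrimination schedules
are adaptive and are produced by the staircase at run time, so here a
discrimination "schedule" only carries the standard magnitude and the
nuisance onset delays.

Units are fixed: centimeters for space, seconds for time.  There is no unit
conversion anywhere in the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StimulusSchedule",
    "build_levels",
    "build_reproduction_schedule",
    "draw_nuisance",
    "default_levels",
    "default_reproduction_schedule",
    "participant_task_seed",
    "SPACE_LEVEL_RANGE",
    "TIME_LEVEL_RANGE",
    "N_LEVELS",
    "N_SETS",
    "SPACE_STANDARD",
    "TIME_STANDARD",
    "NUISANCE_RANGES",
    "PRESENTATION_DURATIONS",
]

CONDITIONS = ("space", "time")
TASKS = ("reproduction", "discrimination", "pointing", "rhythm")

#: Reproduction level ranges: 11 lengths 6..14 cm (0.8 cm steps) and 11
#: intervals 1.270..1.8 s (0.053 s steps).
SPACE_LEVEL_RANGE = (6.0, 14.0)
TIME_LEVEL_RANGE = (1.270, 1.8)
N_LEVELS = 11
N_SETS = 6

#: Discrimination standards.  Each equals the mean of the corresponding
#: reproduction level set, so the prior acquired in one task is centred on
#: the standard of the other.
SPACE_STANDARD = 10.0
TIME_STANDARD = 1.535

#: Per-trial nuisance draws, uniform in the printed range.  Space
#: reproduction: horizontal start position of the first dot (cm from the
#: left border).  Time reproduction / discrimination: onset delay of the
#: first dot from trial start (s).  The pointing and space-discrimination
#: tasks have no nuisance parameter.
NUISANCE_RANGES = {
    ("space", "reproduction"): (0.2, 1.7),
    ("time", "reproduction"): (1.0, 2.0),
    ("time", "discrimination"): (1.0, 1.8),
}

#: Stimulus presentation durations (s); metadata only, no computational role.
PRESENTATION_DURATIONS = {"space": 0.4, "time": 0.2}


@dataclass(frozen=True)
class StimulusSchedule:
    """Ordered trial magnitudes plus nuisance draws for one task/condition.

    ``trials`` is a tuple of ``(set_index, magnitude)`` pairs; each
    contiguous block of ``len(levels)`` trials is a permutation of
    ``levels``.  ``nuisance`` is ``None`` until :func:`draw_nuisance` fills
    it, and never alters the magnitudes.
    """

    condition: str
    task: str
    levels: tuple[float, ...]
    trials: tuple[tuple[int, float], ...]
    units: str
    seed: int
    nuisance: tuple[float, ...] | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition: {self.condition!r}")
        if self.task not in TASKS:
            raise ValueError(f"unknown task: {self.task!r}")
        lv = np.asarray(self.levels, dtype=float)
        if lv.size == 0:
            raise ValueError("levels must be non-empty")
        if lv.size > 1:
            diffs = np.diff(lv)
            if not np.all(diffs > 0):
                raise ValueError("levels must be strictly increasing")
            if not np.allclose(diffs, diffs[0], rtol=1e-9, atol=0.0):
                raise ValueError("levels must be equally spaced")
        if self.nuisance is not None and len(self.nuisance) != len(self.trials):
            raise ValueError("nuisance length must match number of trials")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def magnitudes(self) -> np.ndarray:
        """Trial magnitudes in presentation order, as a float array."""
        return np.array([m for _, m in self.trials], dtype=float)

    @property
    def mean_level(self) -> float:
        return float(np.mean(self.levels))


def build_levels(min_mag: float, max_mag: float, n_levels: int) -> np.ndarray:
    """Equally spaced stimulus levels, inclusive of both endpoints.

    For the default space set this is 6, 6.8, ..., 14 cm; for time,
    1.270, 1.323, ..., 1.8 s (step 0.053 s).
    """
    n_levels = int(n_levels)
    if n_levels < 1:
        raise ValueError(f"n_levels must be >= 1, got {n_levels}")
    if min_mag > max_mag:
        raise ValueError(f"min_mag {min_mag} exceeds max_mag {max_mag}")
    if n_levels == 1:
        if min_mag != max_mag:
            raise ValueError("a single level requires min_mag == max_mag")
        return np.array([float(min_mag)])
    return np.linspace(min_mag, max_mag, n_levels)


def default_levels(condition: str) -> np.ndarray:
    """The 11-level reproduction set for ``condition``."""
    if condition == "space":
        return build_levels(*SPACE_LEVEL_RANGE, N_LEVELS)
    if condition == "time":
        return build_levels(*TIME_LEVEL_RANGE, N_LEVELS)
    raise ValueError(f"unknown condition: {condition!r}")


def build_reproduction_schedule(
    levels,
    n_sets: int = N_SETS,
    seed: int = 0,
    condition: str = "space",
) -> StimulusSchedule:
    """Block-randomized reproduction schedule: ``n_sets`` seeded permutations
    of ``levels``, concatenated.  Deterministic for a fixed seed."""
    levels = np.asarray(levels, dtype=float)
    if levels.size == 0:
        raise ValueError("levels must be non-empty")
    n_sets = int(n_sets)
    if n_sets < 1:
        raise ValueError(f"n_sets must be >= 1, got {n_sets}")
    rng = np.random.default_rng(seed)
    trials: list[tuple[int, float]] = []
    for s in range(n_sets):
        order = rng.permutation(levels.size)
        trials.extend((s, float(levels[j])) for j in order)
    units = "cm" if condition == "space" else "s"
    return StimulusSchedule(
        condition=condition,
        task="reproduction",
        levels=tuple(float(x) for x in levels),
        trials=tuple(trials),
        units=units,
        seed=int(seed),
        metadata={"presentation_duration_s": PRESENTATION_DURATIONS[condition]},
    )


def default_reproduction_schedule(condition: str, seed: int = 0) -> StimulusSchedule:
    """The 66-trial (6 sets x 11 levels) reproduction schedule."""
    return build_reproduction_schedule(
        default_levels(condition), N_SETS, seed, condition=condition
    )


def draw_nuisance(schedule: StimulusSchedule, seed: int) -> StimulusSchedule:
    """Return a copy of ``schedule`` with per-trial uniform nuisance draws.

    The range is the task's printed one (see :data:`NUISANCE_RANGES`); a
    ``nuisance_range`` entry in ``schedule.metadata`` overrides it.  Draws
    are recorded only — trial magnitudes are untouched.
    """
    if not schedule.trials:
        raise ValueError("schedule has no trials")
    key = (schedule.condition, schedule.task)
    rng_range = schedule.metadata.get("nuisance_range", NUISANCE_RANGES.get(key))
    if rng_range is None:
        raise ValueError(f"no nuisance range defined for {key}")
    lo, hi = rng_range
    if lo > hi:
        raise ValueError(f"invalid nuisance range {rng_range}")
    rng = np.random.default_rng(seed)
    draws = rng.uniform(lo, hi, size=len(schedule.trials))
    return StimulusSchedule(
        condition=schedule.condition,
        task=schedule.task,
        levels=schedule.levels,
        trials=schedule.trials,
        units=schedule.units,
        seed=schedule.seed,
        nuisance=tuple(float(x) for x in draws),
        metadata=dict(schedule.metadata),
    )


def participant_task_seed(master_seed: int, participant: int, condition: str, task: str) -> int:
    """Derive an independent substream seed for one participant x task.

    Built on :class:`numpy.random.SeedSequence` spawn keys so adding a
    participant never perturbs the draws of the others.  The result is a
    plain non-negative integer below 2**31, usable anywhere a seed is taken.
    """
    ci = CONDITIONS.index(condition)
    ti = TASKS.index(task)
    ss = np.random.SeedSequence(
        entropy=int(master_seed), spawn_key=(int(participant), ci, ti)
    )
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))
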