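"""Reproduction-task analysis: Offset, regression index, and the
per-stimulus accuracy/precision error decomposition.

Given one participant's reproduction trials (stimulus S, response R):

* ``Offset = mean(R) - mean(S)`` — a constant under/overestimation bias,
  independent of stimulus history.
* Responses are offset-corrected, ``R' = R - Offset``, before every other
  metric, so the remaining errors reflect context dependency rather than a
  global shift.
* The regression index ``RI = 1 - slope`` of the OLS fit of R' on S:
  0 for veridical responding, 1 for complete regression to the mean of the
  stimulus set.
* Per stimulus level i: ``bias_cd_i = (mean(R'_i) - S_i) / mean(S)``,
  ``cv_i = sd(R'_i) / mean(S)`` (population SD, N denominator) and
  ``rmse_i = sqrt(bias_cd_i^2 + cv_i^2)``.

With a balanced design the signed bias_cd_i average to exactly zero after
offset correction, so the aggregate accuracy error is the mean of
|bias_cd_i| (an RMS aggregate is available as an alternative).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ReproductionTrial",
    "CentralTendencySummary",
    "compute_offset",
    "offset_correct",
    "fit_response_line",
    "regression_index",
    "per_stimulus_errors",
    "summarize",
]


@dataclass(frozen=True)
class ReproductionTrial:
    """One reproduction trial: shown magnitude S and reproduced magnitude R."""

    stimulus: float
    response: float

    def __post_init__(self) -> None:
        if not self.stimulus > 0:
            raise ValueError("stimulus must be positive")
        if self.response < 0 or not np.isfinite(self.response):
            raise ValueError("response must be finite and non-negative")


@dataclass(frozen=True)
class CentralTendencySummary:
    """The full metric suite for one participant x condition."""

    offset: float
    slope: float
    intercept: float
    regression_index: float
    levels: tuple[float, ...]
    response_means: tuple[float, ...]  # per-level mean of corrected responses
    bias_cd: tuple[float, ...]
    cv: tuple[float, ...]
    rmse: tuple[float, ...]
    aggregate_bias: float
    aggregate_cv: float
    aggregate_rmse: float
    mean_stimulus: float
    n_trials: int


def _as_sr(trials) -> tuple[np.ndarray, np.ndarray]:
    """Accept a list of ReproductionTrial, a (S, R) pair of arrays, or an
    object with ``stimulus``/``response`` columns (e.g. a DataFrame)."""
    if hasattr(trials, "columns"):
        s = np.asarray(trials["stimulus"], dtype=float)
        r = np.asarray(trials["response"], dtype=float)
    elif isinstance(trials, tuple) and len(trials) == 2:
        s = np.asarray(trials[0], dtype=float)
        r = np.asarray(trials[1], dtype=float)
    else:
        s = np.array([t.stimulus for t in trials], dtype=float)
        r = np.array([t.response for t in trials], dtype=float)
    if s.shape != r.shape or s.ndim != 1:
        raise ValueError("stimuli and responses must be 1-D and equal length")
    if s.size == 0:
        raise ValueError("no trials")
    if not (np.isfinite(s).all() and np.isfinite(r).all()):
        raise ValueError("non-finite stimulus or response")
    if np.any(s <= 0):
        raise ValueError("stimuli must be positive")
    return s, r


def compute_offset(trials) -> float:
    """mean(response) - mean(stimulus) over the whole session."""
    s, r = _as_sr(trials)
    return float(np.mean(r) - np.mean(s))


def offset_correct(trials, offset: float) -> tuple[np.ndarray, np.ndarray]:
    """Subtract ``offset`` from every response; stimuli unchanged.

    When ``offset`` is the session's own value, mean(R') == mean(S) exactly.
    """
    if not np.isfinite(offset):
        raise ValueError("offset must be finite")
    s, r = _as_sr(trials)
    return s, r - float(offset)


def fit_response_line(trials) -> tuple[float, float]:
    """OLS fit of (corrected) responses on stimuli: returns (slope, intercept)."""
    s, r = _as_sr(trials)
    if np.unique(s).size < 2:
        raise ValueError("need >= 2 distinct stimulus values for a slope")
    slope, intercept = np.polyfit(s, r, 1)
    return float(slope), float(intercept)


def regression_index(slope: float) -> float:
    """1 - slope: 0 = veridical, 1 = complete regression to the mean."""
    if not np.isfinite(slope):
        raise ValueError("slope must be finite")
    return 1.0 - float(slope)


def per_stimulus_errors(
    trials, mean_stimulus: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Per-level accuracy (bias_cd), precision (cv) and combined (rmse) errors.

    ``trials`` should already be offset-corrected.  Returns
    ``(levels, response_means, bias_cd, cv, rmse)``; all three error arrays
    are normalized by ``mean_stimulus`` and therefore dimensionless.
    """
    if not mean_stimulus > 0:
        raise ValueError("mean_stimulus must be positive")
    s, r = _as_sr(trials)
    levels = np.unique(s)
    r_means = np.empty(levels.size)
    r_sds = np.empty(levels.size)
    for i, lv in enumerate(levels):
        ri = r[s == lv]
        r_means[i] = np.mean(ri)
        r_sds[i] = np.std(ri)  # population SD, N denominator
    bias_cd = (r_means - levels) / mean_stimulus
    cv = r_sds / mean_stimulus
    rmse = np.sqrt(bias_cd**2 + cv**2)
    return levels, r_means, bias_cd, cv, rmse


def summarize(trials, aggregate: str = "absolute_mean") -> CentralTendencySummary:
    """Run the full pipeline on one participant x condition's raw trials.

    Offset -> offset correction -> OLS line -> regression index ->
    per-stimulus errors -> aggregates.  ``aggregate`` selects how bias_cd
    is pooled across levels: ``"absolute_mean"`` (mean of |bias_cd_i|,
    default) or ``"rms"`` (root mean square); cv and rmse aggregate as
    plain means either way (cv_i and rmse_i are non-negative).
    """
    if aggregate not in ("absolute_mean", "rms"):
        raise ValueError(f"unknown aggregate rule: {aggregate!r}")
    s, r = _as_sr(trials)
    offset = compute_offset((s, r))
    s, r_corr = offset_correct((s, r), offset)
    slope, intercept = fit_response_line((s, r_corr))
    ri = regression_index(slope)
    s_bar = float(np.mean(s))
    levels, r_means, bias_cd, cv, rmse = per_stimulus_errors((s, r_corr), s_bar)
    if aggregate == "absolute_mean":
        agg_bias = float(np.mean(np.abs(bias_cd)))
    else:
        agg_bias = float(np.sqrt(np.mean(bias_cd**2)))
    return CentralTendencySummary(
        offset=offset,
        slope=slope,
        intercept=intercept,
        regression_index=ri,
        levels=tuple(levels),
        response_means=tuple(r_means),
        bias_cd=tuple(bias_cd),
        cv=tuple(cv),
        rmse=tuple(rmse),
        aggregate_bias=agg_bias,
        aggregate_cv=float(np.mean(cv)),
        aggregate_rmse=float(np.mean(rmse)),
        mean_stimulus=s_bar,
        n_trials=int(s.size),
    )
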