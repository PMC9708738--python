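"""Cumulative-Gaussian psychometric fitting and the Weber fraction.

The discrimination tasks are two-interval forced choice against a fixed
standard (10 cm for space, 1.535 s for time).  The probability of judging
the comparison longer is modelled as

    P(c) = lambda/2 + (1 - lambda) * Phi((c - mu) / sigma)

where mu is the point of subjective equality, sigma the differential
threshold (the SD of the underlying cumulative Gaussian) and lambda a
small lapse rate splitting stimulus-independent errors equally between the
two responses.  Perceptual acuity is then the Weber fraction
sigma / standard.

Fitting is maximum likelihood with a fixed, deterministic multi-start grid
(no random restarts), so fits are bit-reproducible.  Non-identifiable data
(a single comparison level, or responses all in one category) yield
``converged=False`` with a diagnostic instead of a silent number.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.stats import norm

__all__ = [
    "DiscriminationTrial",
    "PsychometricFit",
    "psychometric_p",
    "fit_cumulative_gaussian",
    "weber_fraction",
    "negative_log_likelihood",
]

_SIGMA_STARTS = (0.02, 0.05, 0.1, 0.2, 0.4)  # fractions of the stimulus span
_LAPSE_MAX = 0.1


@dataclass(frozen=True)
class DiscriminationTrial:
    """One 2IFC trial: the fixed standard, the comparison shown, and
    whether the comparison was judged longer."""

    standard: float
    comparison: float
    comparison_judged_longer: bool

    def __post_init__(self) -> None:
        if not (self.standard > 0 and self.comparison > 0):
            raise ValueError("magnitudes must be positive")


@dataclass(frozen=True)
class PsychometricFit:
    """MLE of the cumulative-Gaussian psychometric function."""

    mu: float
    sigma: float
    lapse: float
    log_likelihood: float
    n_trials: int
    converged: bool
    message: str = ""

    @property
    def threshold(self) -> float:
        """The differential threshold: the fitted SD."""
        return self.sigma


def psychometric_p(c, mu: float, sigma: float, lapse: float) -> np.ndarray:
    """P(comparison judged longer) at comparison magnitude(s) ``c``."""
    c = np.asarray(c, dtype=float)
    return lapse / 2.0 + (1.0 - lapse) * norm.cdf((c - mu) / sigma)


def negative_log_likelihood(
    params, comparisons: np.ndarray, longer: np.ndarray, lapse: float | None
) -> float:
    """Bernoulli NLL; ``params`` is (mu, sigma) or (mu, sigma, lapse)."""
    if lapse is None:
        mu, sigma, lam = params
    else:
        mu, sigma = params
        lam = lapse
    if sigma <= 0 or not 0.0 <= lam <= 0.5:
        return np.inf
    p = psychometric_p(comparisons, mu, sigma, lam)
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return float(-np.sum(np.where(longer, np.log(p), np.log1p(-p))))


def _extract(trials) -> tuple[np.ndarray, np.ndarray]:
    if hasattr(trials, "columns"):
        c = np.asarray(trials["comparison"], dtype=float)
        y = np.asarray(trials["comparison_judged_longer"]).astype(bool)
    else:
        c = np.array([t.comparison for t in trials], dtype=float)
        y = np.array([t.comparison_judged_longer for t in trials], dtype=bool)
    if c.size == 0:
        raise ValueError("no trials")
    if np.any(c <= 0) or not np.isfinite(c).all():
        raise ValueError("comparisons must be positive and finite")
    return c, y


def fit_cumulative_gaussian(trials, lapse_policy: float | str = 0.01) -> PsychometricFit:
    """Fit mu, sigma (and optionally lambda) by maximum likelihood.

    ``lapse_policy``: a float fixes the lapse rate at that value (default
    0.01; 0.0 gives the plain cumulative Gaussian); the string ``"free"``
    estimates it within [0, 0.1].

    Deterministic: optimization restarts from a fixed grid of starting
    points and keeps the best optimum.
    """
    c, y = _extract(trials)
    n = c.size
    if lapse_policy == "free":
        fixed_lapse = None
    else:
        fixed_lapse = float(lapse_policy)
        if not 0.0 <= fixed_lapse <= _LAPSE_MAX:
            raise ValueError(f"fixed lapse must be in [0, {_LAPSE_MAX}]")

    uniq = np.unique(c)
    if uniq.size < 2:
        return PsychometricFit(
            mu=np.nan, sigma=np.nan,
            lapse=fixed_lapse if fixed_lapse is not None else np.nan,
            log_likelihood=np.nan, n_trials=n, converged=False,
            message="non-identifiable: a single comparison level",
        )
    if y.all() or not y.any():
        return PsychometricFit(
            mu=np.nan, sigma=np.nan,
            lapse=fixed_lapse if fixed_lapse is not None else np.nan,
            log_likelihood=np.nan, n_trials=n, converged=False,
            message="non-identifiable: all responses in one category",
        )

    span = float(uniq[-1] - uniq[0])
    lo, hi = float(uniq[0]), float(uniq[-1])
    mu_starts = np.quantile(c, [0.1, 0.25, 0.5, 0.75, 0.9])
    sigma_starts = [max(f * span, 1e-6) for f in _SIGMA_STARTS]
    mu_bounds = (lo - 2.0 * span, hi + 2.0 * span)
    sigma_bounds = (1e-9 * max(span, 1.0), 50.0 * span)

    best = None
    for mu0 in mu_starts:
        for s0 in sigma_starts:
            if fixed_lapse is None:
                x0 = [mu0, s0, 0.02]
                bounds = [mu_bounds, sigma_bounds, (0.0, _LAPSE_MAX)]
            else:
                x0 = [mu0, s0]
                bounds = [mu_bounds, sigma_bounds]
            res = optimize.minimize(
                negative_log_likelihood,
                x0,
                args=(c, y, fixed_lapse),
                method="L-BFGS-B",
                bounds=bounds,
            )
            if best is None or res.fun < best.fun:
                best = res
    assert best is not None
    if fixed_lapse is None:
        mu, sigma, lam = best.x
    else:
        (mu, sigma), lam = best.x, fixed_lapse
    return PsychometricFit(
        mu=float(mu),
        sigma=float(sigma),
        lapse=float(lam),
        log_likelihood=-float(best.fun),
        n_trials=n,
        converged=bool(best.success),
        message=str(best.message),
    )


def weber_fraction(threshold: float, standard: float) -> float:
    """Differential threshold divided by the standard magnitude."""
    if not standard > 0:
        raise ValueError("standard must be positive")
    if threshold < 0 or not np.isfinite(threshold):
        raise ValueError("threshold must be finite and non-negative")
    return float(threshold) / float(standard)
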