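"""End-to-end analysis of trial-log datasets.

Takes the tidy per-task trial logs (simulated by
:func:`centend.observers.simulate_cohort` or read from disk) and produces
the per-participant measure tables and group statistics: psychometric
fits and Weber fractions from the discrimination logs, the Offset /
regression-index / BiasCD-CV-RMSE suite from the reproduction logs,
control-task summaries, between- and within-group tests, and a
long-format export suitable for external mixed-model tools.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .central_tendency import summarize
from .control import rhythm_variability, summarize_pointing
from .psychometric import fit_cumulative_gaussian, weber_fraction
from .stats import mann_whitney, one_sample_t

__all__ = [
    "fit_summaries",
    "central_tendency_summaries",
    "control_summaries",
    "group_comparisons",
    "long_format",
    "analyze",
]


def fit_summaries(discrimination: pd.DataFrame, lapse_policy: float | str = 0.01) -> pd.DataFrame:
    """One row per participant x condition: psychometric fit and Weber
    fraction.  Non-converged fits are flagged, never dropped."""
    rows = []
    for (pid, cond), sub in discrimination.groupby(["participant", "condition"]):
        fit = fit_cumulative_gaussian(sub, lapse_policy=lapse_policy)
        standard = float(sub["standard"].iloc[0])
        rows.append(
            {"participant": pid, "group": sub["group"].iloc[0], "condition": cond,
             "mu": fit.mu, "sigma": fit.sigma, "lapse": fit.lapse,
             "wf": weber_fraction(fit.sigma, standard) if fit.converged else np.nan,
             "n_trials": fit.n_trials, "converged": fit.converged,
             "message": fit.message}
        )
    return pd.DataFrame(rows)


def central_tendency_summaries(reproduction: pd.DataFrame, aggregate: str = "absolute_mean") -> pd.DataFrame:
    """One row per participant x condition: the reproduction metric suite."""
    rows = []
    for (pid, cond), sub in reproduction.groupby(["participant", "condition"]):
        s = summarize(sub, aggregate=aggregate)
        rows.append(
            {"participant": pid, "group": sub["group"].iloc[0], "condition": cond,
             "offset": s.offset, "slope": s.slope, "ri": s.regression_index,
             "agg_bias": s.aggregate_bias, "agg_cv": s.aggregate_cv,
             "agg_rmse": s.aggregate_rmse, "n_trials": s.n_trials}
        )
    return pd.DataFrame(rows)


def control_summaries(pointing: pd.DataFrame | None, rhythm: pd.DataFrame | None) -> pd.DataFrame:
    """Per-participant control metrics: median pointing error (cm) and
    rhythm variability (s)."""
    rows = []
    if pointing is not None and len(pointing):
        for pid, sub in pointing.groupby("participant"):
            rows.append(
                {"participant": pid, "group": sub["group"].iloc[0],
                 "metric": "pointing_error",
                 "value": summarize_pointing(sub[["x_s", "y_s"]].to_numpy(),
                                             sub[["x_r", "y_r"]].to_numpy())}
            )
    if rhythm is not None and len(rhythm):
        for pid, sub in rhythm.groupby("participant"):
            rows.append(
                {"participant": pid, "group": sub["group"].iloc[0],
                 "metric": "rhythm_variability",
                 "value": rhythm_variability(sub["interval"].to_numpy())}
            )
    return pd.DataFrame(rows)


def group_comparisons(
    ct: pd.DataFrame, fits: pd.DataFrame, controls: pd.DataFrame
) -> pd.DataFrame:
    """The study's test battery on the derived measures.

    One-sample t-tests (with Cohen's d) of the regression index and the
    Offset against 0, per group x condition; Mann-Whitney between-group
    comparisons of the Weber fraction per condition and of the control
    metrics.
    """
    rows = []
    for metric in ("ri", "offset"):
        for (grp, cond), sub in ct.groupby(["group", "condition"]):
            r = one_sample_t(sub[metric].to_numpy())
            rows.append(
                {"metric": metric, "group": grp, "condition": cond,
                 "method": r.method, "statistic": r.statistic, "df": r.df,
                 "p_value": r.p_value, "effect_size": r.effect_size,
                 "n1": r.n1, "n2": None}
            )
    groups = sorted(ct["group"].unique())
    if len(groups) == 2:
        g1, g2 = groups
        conv = fits[fits["converged"]]
        for cond, sub in conv.groupby("condition"):
            x = sub.loc[sub["group"] == g1, "wf"].dropna().to_numpy()
            y = sub.loc[sub["group"] == g2, "wf"].dropna().to_numpy()
            if len(x) and len(y):
                r = mann_whitney(x, y)
                rows.append(
                    {"metric": "wf", "group": f"{g1}-{g2}", "condition": cond,
                     "method": r.method, "statistic": r.statistic, "df": None,
                     "p_value": r.p_value, "effect_size": r.z,
                     "n1": r.n1, "n2": r.n2}
                )
        for metric, sub in controls.groupby("metric"):
            x = sub.loc[sub["group"] == g1, "value"].to_numpy()
            y = sub.loc[sub["group"] == g2, "value"].to_numpy()
            cond = "space" if metric == "pointing_error" else "time"
            if len(x) and len(y):
                r = mann_whitney(x, y)
                rows.append(
                    {"metric": metric, "group": f"{g1}-{g2}", "condition": cond,
                     "method": r.method, "statistic": r.statistic, "df": None,
                     "p_value": r.p_value, "effect_size": r.z,
                     "n1": r.n1, "n2": r.n2}
                )
    return pd.DataFrame(rows)


def long_format(ct: pd.DataFrame, fits: pd.DataFrame) -> pd.DataFrame:
    """Long-format metric table (participant, group, condition, metric,
    value) for external mixed-effect modelling."""
    frames = []
    for metric in ("offset", "ri", "agg_bias", "agg_cv", "agg_rmse"):
        f = ct[["participant", "group", "condition"]].copy()
        f["metric"] = metric
        f["value"] = ct[metric].to_numpy()
        frames.append(f)
    conv = fits[fits["converged"]]
    f = conv[["participant", "group", "condition"]].copy()
    f["metric"] = "wf"
    f["value"] = conv["wf"].to_numpy()
    frames.append(f)
    out = pd.concat(frames, ignore_index=True)
    return out.sort_values(["metric", "condition", "participant"], ignore_index=True)


def analyze(data: dict, lapse_policy: float | str = 0.01) -> dict:
    """Full analysis of a simulated (or schema-conforming) dataset.

    ``data`` maps task name -> tidy trial-log frame; returns a dict of
    result frames: ``fits``, ``central_tendency``, ``controls``,
    ``comparisons``, ``long``.
    """
    fits = fit_summaries(data["discrimination"], lapse_policy=lapse_policy)
    ct = central_tendency_summaries(data["reproduction"])
    controls = control_summaries(data.get("pointing"), data.get("rhythm"))
    comparisons = group_comparisons(ct, fits, controls)
    return {
        "fits": fits,
        "central_tendency": ct,
        "controls": controls,
        "comparisons": comparisons,
        "long": long_format(ct, fits),
    }
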