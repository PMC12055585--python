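"""Cox proportional-hazards contrasts and Kaplan-Meier summaries.

Backed by lifelines (Efron tie handling, the default there).  Fits are
returned as tidy tables with one row per non-reference level: hazard ratio,
Wald 95% CI, p, group sizes and event counts.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError

from .association import bh_adjust

logger = logging.getLogger(__name__)


def cox_fit(time, event, group, reference: str) -> pd.DataFrame:
    """Multi-level Cox proportional-hazards fit against a reference group.

    Groups with zero events are dropped with a warning.  Complete separation
    surfaces as a ConvergenceError with a diagnostic message.
    """
    df = pd.DataFrame({
        "time": np.asarray(time, dtype=float),
        "event": np.asarray(event, dtype=bool).astype(int),
        "group": np.asarray(group, dtype=object),
    })
    if (df.time < 0).any():
        raise ValueError("survival times must be nonnegative")
    levels = [g for g in pd.unique(df.group)]
    if reference not in levels:
        raise ValueError(f"reference level {reference!r} not present")

    events_per = df.groupby("group")["event"].sum()
    dead_levels = [g for g in levels if events_per.get(g, 0) == 0]
    for g in dead_levels:
        logger.warning("dropping group %r with zero events", g)
    df = df[~df.group.isin(dead_levels)]
    levels = [g for g in levels if g not in dead_levels]
    if reference not in levels or len(levels) < 2:
        raise ValueError("need the reference plus at least one comparison "
                         "group, each with at least one event")

    X = pd.get_dummies(df.group, dtype=float)
    terms = [g for g in levels if g != reference]
    design = pd.concat([df[["time", "event"]].reset_index(drop=True),
                        X[terms].reset_index(drop=True)], axis=1)
    cph = CoxPHFitter()
    try:
        cph.fit(design, duration_col="time", event_col="event")
    except ConvergenceError as exc:
        raise ConvergenceError(
            f"Cox fit failed to converge (possible complete separation "
            f"between groups {levels}): {exc}") from exc

    rows = []
    for term in terms:
        beta = cph.params_[term]
        se = cph.standard_errors_[term]
        rows.append({
            "term": term,
            "reference": reference,
            "n": int((df.group == term).sum()),
            "events": int(events_per[term]),
            "hr": float(np.exp(beta)),
            "ci_low": float(np.exp(beta - 1.96 * se)),
            "ci_high": float(np.exp(beta + 1.96 * se)),
            "p": float(cph.summary.loc[term, "p"]),
        })
    return pd.DataFrame(rows)


def km_curve(time, event, group) -> pd.DataFrame:
    """Product-limit survival estimates as a tidy per-group table.

    Columns: group, time, survival, n_risk, n_event.
    """
    df = pd.DataFrame({
        "time": np.asarray(time, dtype=float),
        "event": np.asarray(event, dtype=bool).astype(int),
        "group": np.asarray(group, dtype=object),
    })
    out = []
    for g, sub in df.groupby("group", sort=True):
        kmf = KaplanMeierFitter()
        kmf.fit(sub.time, sub.event, label=str(g))
        tab = kmf.event_table
        surv = kmf.survival_function_.iloc[:, 0]
        for t in tab.index:
            out.append({
                "group": g, "time": float(t),
                "survival": float(surv.loc[t]),
                "n_risk": int(tab.loc[t, "at_risk"]),
                "n_event": int(tab.loc[t, "observed"]),
            })
    return pd.DataFrame(out)


def univariate_screen(features: pd.DataFrame, time, event,
                      min_altered: int = 5) -> pd.DataFrame:
    """One Cox fit per binary alteration feature, BH-corrected.

    ``features`` is cases x features (binary).  Features altered in fewer
    than ``min_altered`` cases are skipped (logged).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    rows = []
    for feat in features.columns:
        x = features[feat].astype(int).to_numpy()
        if x.sum() < min_altered:
            logger.info("skipping %s: only %d altered cases", feat, x.sum())
            continue
        group = np.where(x == 1, "altered", "wildtype")
        try:
            fit = cox_fit(time, event, group, reference="wildtype")
        except (ValueError, ConvergenceError) as exc:
            logger.warning("skipping %s: %s", feat, exc)
            continue
        row = fit.iloc[0].to_dict()
        row["term"] = feat
        rows.append(row)
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
    return out


def plot_km(time, event, group, ax=None):
    """Kaplan-Meier curves per group on a matplotlib axis."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    df = pd.DataFrame({"time": time, "event": np.asarray(event, dtype=bool),
                       "group": group})
    for g, sub in df.groupby("group", sort=True):
        kmf = KaplanMeierFitter()
        kmf.fit(sub.time, sub.event.astype(int), label=str(g))
        kmf.plot_survival_function(ax=ax)
    ax.set_xlabel("time (months)")
    ax.set_ylabel("overall survival")
    return ax
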