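"""Parsing and summary of interval-timing switch-task behavior.

The task: mice initiate a trial, poke a first nosepoke, and on 18-s
trials are rewarded only if they abandon it and switch to a second
nosepoke after their internal estimate of the 6-s criterion elapses.
The *switch response time* is the moment the animal departs the first
nosepoke before arriving at the second — operationally, the last
first-nosepoke exit preceding the first second-nosepoke entry.
*Traversal time* is first-exit to second-entry; *nosepoke duration* is
entry-to-exit of the switch poke itself.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ddm import GammaFit, fit_gamma, gamma_sample_r2

__all__ = [
    "BehaviorValidationError",
    "read_event_log",
    "validate_events",
    "extract_switch_times",
    "response_distributions",
    "ResponseDistributions",
    "fit_behavior_gamma",
    "session_summary",
    "cohens_d",
]

REQUIRED_COLUMNS = ["mouse_id", "session_id", "trial_id", "trial_type",
                    "event_type", "time_s"]
EVENT_TYPES = {"trial_start", "back_np_in", "first_np_in", "first_np_out",
               "second_np_in", "second_np_out", "reward",
               "laser_on", "laser_off"}
_PORTS = {"first_np": ("first_np_in", "first_np_out"),
          "second_np": ("second_np_in", "second_np_out")}


class BehaviorValidationError(ValueError):
    """Raised with the full list of problems found in an event log."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("invalid event log:\n  " + "\n  ".join(problems))


def validate_events(df: pd.DataFrame) -> list[str]:
    """Collect (not raise) all structural problems in an event table."""
    problems: list[str] = []
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        return [f"missing columns: {', '.join(missing)}"]
    bad = ~df["event_type"].isin(EVENT_TYPES)
    for line in df.index[bad]:
        problems.append(f"row {line}: unknown event_type "
                        f"{df.loc[line, 'event_type']!r}")
    for (mouse, sess, trial), g in df.groupby(
            ["mouse_id", "session_id", "trial_id"], sort=False):
        t = g["time_s"].to_numpy()
        if np.any(np.diff(t) < 0):
            line = g.index[1:][np.diff(t) < 0][0]
            problems.append(f"row {line}: non-monotone times in trial "
                            f"{mouse}/{sess}/{trial}")
        for port, (ev_in, ev_out) in _PORTS.items():
            seq = g.loc[g["event_type"].isin([ev_in, ev_out])]
            expect_in = True
            for line, ev in seq["event_type"].items():
                if (ev == ev_in) != expect_in:
                    problems.append(
                        f"row {line}: unpaired {port} entry/exit in trial "
                        f"{mouse}/{sess}/{trial}")
                    break
                expect_in = not expect_in
    return problems


def read_event_log(path) -> pd.DataFrame:
    """Read and validate a delimited event log.

    Expects a header with mouse_id, session_id, trial_id, trial_type,
    event_type, time_s.  Raises :class:`BehaviorValidationError` listing
    every malformed row with its line index; an empty file yields an
    empty, well-formed table.
    """
    df = pd.read_csv(path)
    if df.empty:
        return pd.DataFrame(columns=REQUIRED_COLUMNS)
    problems = validate_events(df)
    if problems:
        raise BehaviorValidationError(problems)
    return df


def extract_switch_times(events: pd.DataFrame) -> pd.DataFrame:
    """One switch record per analysable long trial.

    The switch time is the LAST first-nosepoke exit preceding the FIRST
    second-nosepoke entry.  Short trials and error trials (no
    first-exit-then-second-entry pattern) produce no record.
    """
    records = []
    if events.empty:
        return pd.DataFrame(columns=["mouse_id", "session_id", "trial_id",
                                     "switch_time_s", "traversal_time_s",
                                     "nosepoke_duration_s", "laser_on"])
    for (mouse, sess, trial), g in events.groupby(
            ["mouse_id", "session_id", "trial_id"], sort=False):
        if g["trial_type"].iloc[0] != "long":
            continue
        second_in = g.loc[g["event_type"] == "second_np_in", "time_s"]
        if second_in.empty:
            continue
        t2 = float(second_in.min())
        exits = g.loc[(g["event_type"] == "first_np_out")
                      & (g["time_s"] <= t2), "time_s"]
        if exits.empty:
            continue  # error trial: arrived second without leaving first
        t_switch = float(exits.max())
        entries = g.loc[(g["event_type"] == "first_np_in")
                        & (g["time_s"] <= t_switch), "time_s"]
        dur = t_switch - float(entries.max()) if not entries.empty else np.nan
        laser = bool((g["event_type"] == "laser_on").any())
        records.append((mouse, sess, trial, t_switch, t2 - t_switch,
                        dur, laser))
    return pd.DataFrame(records,
                        columns=["mouse_id", "session_id", "trial_id",
                                 "switch_time_s", "traversal_time_s",
                                 "nosepoke_duration_s", "laser_on"])


@dataclass
class ResponseDistributions:
    """Normalised histogram densities and empirical CDFs per event class."""

    bin_centers: np.ndarray
    density: dict[str, np.ndarray]
    cdf: dict[str, np.ndarray]
    empty: set[str]


def response_distributions(events: pd.DataFrame,
                           switch_records: pd.DataFrame | None = None,
                           bin_width: float = 1.0,
                           t_max: float = 25.0) -> ResponseDistributions:
    """Pooled response-time distributions for first pokes, switch
    responses, and second pokes.

    Each density integrates to 1 over the histogram support; classes
    with no events are returned empty and flagged.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if switch_records is None:
        switch_records = extract_switch_times(events)
    long_trials = events.loc[events["trial_type"] == "long"]
    classes = {
        "first_np": long_trials.loc[
            long_trials["event_type"] == "first_np_in"].groupby(
            ["mouse_id", "session_id", "trial_id"])["time_s"].min().to_numpy(),
        "switch": switch_records["switch_time_s"].to_numpy(),
        "second_np": long_trials.loc[
            long_trials["event_type"] == "second_np_in"].groupby(
            ["mouse_id", "session_id", "trial_id"])["time_s"].min().to_numpy(),
    }
    edges = np.arange(0.0, t_max + bin_width, bin_width)
    centers = (edges[:-1] + edges[1:]) / 2.0
    density, cdf, empty = {}, {}, set()
    for name, x in classes.items():
        if x.size == 0:
            density[name] = np.zeros(centers.size)
            cdf[name] = np.zeros(centers.size)
            empty.add(name)
            continue
        hist, _ = np.histogram(x, bins=edges)
        density[name] = hist / (x.size * bin_width)
        cdf[name] = np.cumsum(hist) / x.size
    return ResponseDistributions(centers, density, cdf, empty)


def fit_behavior_gamma(switch_times, bin_width: float = 0.5,
                       t_max: float = 25.0,
                       r2_method: str = "cdf") -> GammaFit:
    """Gamma MLE of behavioral switch times with goodness of fit."""
    fit = fit_gamma(switch_times)
    r2 = gamma_sample_r2(switch_times, fit, bin_width=bin_width,
                         t_max=t_max, method=r2_method)
    return GammaFit(alpha=fit.alpha, beta=fit.beta, n=fit.n, r2=r2)


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Cohen's d: mean difference over pooled standard deviation."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = x.size, y.size
    pooled = np.sqrt(((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1))
                     / (nx + ny - 2))
    if pooled == 0:
        return 0.0
    return float((x.mean() - y.mean()) / pooled)


def session_summary(records: pd.DataFrame,
                    group_col: str = "laser_on") -> pd.DataFrame:
    """Group-level summary of switch times.

    Per condition: per-mouse mean switch times, their group median and
    IQR, Cohen's d against the first condition, and rank-based test
    p-values (signed-rank when mice are paired across both conditions,
    rank-sum otherwise).
    """
    if group_col not in records.columns:
        raise ValueError(f"missing grouping column {group_col!r}")
    groups = list(records[group_col].drop_duplicates())
    if len(groups) < 2:
        raise ValueError("need at least two conditions for a comparison")
    per_mouse = (records.groupby(["mouse_id", group_col])["switch_time_s"]
                 .mean().unstack(group_col))
    ref = groups[0]
    rows = []
    for g in groups:
        vals = per_mouse[g].dropna().to_numpy()
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        if g == ref:
            d, p = 0.0, 1.0
        else:
            # scalar label lookups: group labels may be booleans, which
            # pandas would misread as a mask in a list indexer
            a = pd.concat([per_mouse[ref], per_mouse[g]], axis=1,
                          keys=["ref", "grp"]).dropna()
            d = cohens_d(a["grp"].to_numpy(), a["ref"].to_numpy())
            paired = len(a) == len(per_mouse[g].dropna()) == len(
                per_mouse[ref].dropna())
            if paired and len(a) > 1 and not np.allclose(a["grp"],
                                                         a["ref"]):
                p = float(stats.wilcoxon(a["grp"], a["ref"]).pvalue)
            elif len(a) > 1:
                p = float(stats.mannwhitneyu(
                    per_mouse[g].dropna(), per_mouse[ref].dropna()).pvalue)
            else:
                p = np.nan
        rows.append((g, len(vals), med, q1, q3, d, p))
    return pd.DataFrame(rows, columns=[group_col, "n_mice", "median_s",
                                       "q1_s", "q3_s", "cohens_d",
                                       "p_value"])
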