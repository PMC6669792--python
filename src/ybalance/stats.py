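"""Per-subject aggregation and condition comparison.

The analysis design is one within-subject factor (taping condition,
three levels) measured on every subject.  Per-trial complexity values
are first averaged over the five trials of each cell, then compared with
a repeated-measures ANOVA and Tukey post-hoc pairwise tests.

Two ANOVA modes are provided:

* ``within_subject`` (default) — the classical one-within-factor
  decomposition ``SS_total = SS_subject + SS_condition + SS_error`` with
  ``F = MS_condition / MS_error`` on ``(c-1, (c-1)(n-1))`` degrees of
  freedom;
* ``one_way`` — cells treated as independent groups, ``(c-1, c n - c)``
  degrees of freedom.  Published balance-taping comparisons sometimes
  report this df pattern, so it is kept for replication.

Tukey-adjusted p-values come from the studentized-range distribution
with the ANOVA's own mean-square error and error df, family size =
number of conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sst

__all__ = [
    "ConditionComparison",
    "aggregate_trials",
    "summarize",
    "rm_anova",
    "tukey_posthoc",
    "compare_conditions",
]

MEASURE_COLUMNS = ["subject", "condition", "channel", "measure", "value"]

CANONICAL_CONDITIONS = ("NT", "ST", "KT")


def condition_order(conditions) -> list:
    """Fixed NT/ST/KT ordering for the standard labels; appearance order
    for any others."""
    known = [c for c in CANONICAL_CONDITIONS if c in conditions]
    other = [c for c in conditions if c not in CANONICAL_CONDITIONS]
    return known + other


@dataclass
class ConditionComparison:
    """Full comparison for one (channel, measure): per-condition mean and
    SE, ANOVA F/df/p and Tukey pairwise adjusted p-values."""

    channel: str
    measure: str
    conditions: tuple
    means: dict
    ses: dict
    n: int
    F: float
    df1: int
    df2: int
    p_anova: float
    tukey: dict  # (cond_a, cond_b) -> adjusted p


def aggregate_trials(records: pd.DataFrame) -> pd.DataFrame:
    """Average per-trial measure values within each
    (subject, condition, channel, measure) cell.

    ``records`` needs columns subject, condition, channel, measure,
    trial, value.  Cells average whatever trials are present; a study
    where a cell is empty simply lacks that row (downstream ANOVA then
    drops the subject listwise for that channel, with a warning).
    """
    required = {"subject", "condition", "channel", "measure", "value"}
    missing = required - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns {sorted(missing)}")
    out = (
        records.groupby(["subject", "condition", "channel", "measure"], sort=False)["value"]
        .mean()
        .reset_index()
    )
    return out


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Per-condition mean and standard error (sd / sqrt(n)) for each
    (channel, measure).  Requires at least two subjects per cell."""
    rows = []
    ordered = table.copy()
    ordered["condition"] = pd.Categorical(
        ordered["condition"], categories=condition_order(ordered["condition"].unique()), ordered=True
    )
    ordered = ordered.sort_values("condition", kind="stable")
    for (channel, measure, condition), grp in ordered.groupby(
        ["channel", "measure", "condition"], sort=False, observed=True
    ):
        v = grp["value"].to_numpy()
        if v.size < 2:
            raise ValueError(
                f"SE undefined with n={v.size} subjects for {channel}/{measure}/{condition}"
            )
        rows.append(
            {
                "channel": channel,
                "measure": measure,
                "condition": condition,
                "n": v.size,
                "mean": v.mean(),
                "se": v.std(ddof=1) / np.sqrt(v.size),
            }
        )
    return pd.DataFrame(rows)


def _cell_matrix(table: pd.DataFrame, channel: str, measure: str) -> tuple[np.ndarray, list, list]:
    """Complete-case subject x condition matrix for one channel/measure."""
    sub = table[(table["channel"] == channel) & (table["measure"] == measure)]
    if sub.empty:
        raise ValueError(f"no data for channel={channel!r}, measure={measure!r}")
    wide = sub.pivot_table(index="subject", columns="condition", values="value", sort=False)
    wide = wide[condition_order(list(wide.columns))]
    conditions = list(wide.columns)
    complete = wide.dropna()
    if len(complete) < len(wide):
        warnings.warn(
            f"{len(wide) - len(complete)} subject(s) dropped listwise for "
            f"{channel}/{measure} (incomplete cells)"
        )
    if len(complete) < 3:
        raise ValueError(f"need >= 3 complete subjects, have {len(complete)}")
    return complete.to_numpy(), list(complete.index), conditions


def _anova_from_matrix(y: np.ndarray, mode: str) -> tuple[float, int, int, float, float]:
    """(F, df1, df2, p, ms_error) for an n-subjects x c-conditions matrix."""
    n, c = y.shape
    grand = y.mean()
    ss_cond = n * ((y.mean(axis=0) - grand) ** 2).sum()
    df1 = c - 1
    if mode == "within_subject":
        ss_subj = c * ((y.mean(axis=1) - grand) ** 2).sum()
        ss_total = ((y - grand) ** 2).sum()
        ss_err = ss_total - ss_subj - ss_cond
        df2 = (c - 1) * (n - 1)
    elif mode == "one_way":
        ss_err = ((y - y.mean(axis=0)) ** 2).sum()
        df2 = c * n - c
    else:
        raise ValueError(f"unknown ANOVA mode {mode!r}")
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    if ms_err <= 0:
        # all residual variance absorbed; conventionally F -> inf (or 0/0 -> 0)
        f = 0.0 if ms_cond == 0 else np.inf
        p = 1.0 if ms_cond == 0 else 0.0
        return f, df1, df2, p, max(ms_err, 0.0)
    f = ms_cond / ms_err
    p = float(sst.f.sf(f, df1, df2))
    return float(f), df1, df2, p, float(ms_err)


def _greenhouse_geisser_eps(y: np.ndarray) -> float:
    """Greenhouse-Geisser sphericity correction factor from the
    double-centered covariance of the condition columns."""
    c = y.shape[1]
    s = np.cov(y, rowvar=False)
    s = s - s.mean(axis=0) - s.mean(axis=1)[:, None] + s.mean()
    num = np.trace(s) ** 2
    den = (c - 1) * (s**2).sum()
    return float(num / den) if den > 0 else 1.0


def rm_anova(
    table: pd.DataFrame,
    channel: str,
    measure: str,
    mode: str = "within_subject",
    gg_correction: bool = False,
) -> tuple[float, int, int, float]:
    """ANOVA across conditions for one channel/measure.

    Returns ``(F, df1, df2, p)``.  ``gg_correction`` applies the
    Greenhouse-Geisser epsilon to the df before computing p (within-
    subject mode only); off by default.
    """
    y, _, _ = _cell_matrix(table, channel, measure)
    f, df1, df2, p, _ = _anova_from_matrix(y, mode)
    if gg_correction and mode == "within_subject" and np.isfinite(f):
        eps = _greenhouse_geisser_eps(y)
        p = float(sst.f.sf(f, eps * df1, eps * df2))
    return f, df1, df2, p


def tukey_posthoc(
    table: pd.DataFrame, channel: str, measure: str, mode: str = "within_subject"
) -> dict:
    """Tukey-adjusted pairwise p-values for all condition pairs.

    Uses the studentized-range distribution with the ANOVA's MS_error
    and error df; the family size is the number of conditions.
    """
    y, _, conditions = _cell_matrix(table, channel, measure)
    n, c = y.shape
    _, _, df2, _, ms_err = _anova_from_matrix(y, mode)
    means = y.mean(axis=0)
    out = {}
    for i in range(c):
        for j in range(i + 1, c):
            if ms_err == 0:
                p = 1.0 if means[i] == means[j] else 0.0
            else:
                q = abs(means[i] - means[j]) / np.sqrt(ms_err / n)
                p = float(sst.studentized_range.sf(q, c, df2))
            out[(conditions[i], conditions[j])] = min(p, 1.0)
    return out


def compare_conditions(
    table: pd.DataFrame,
    mode: str = "within_subject",
    gg_correction: bool = False,
    posthoc: bool = True,
) -> list[ConditionComparison]:
    """Run summarize + ANOVA (+ Tukey unless ``posthoc=False``) for every
    (channel, measure)."""
    summary = summarize(table)
    results = []
    for (channel, measure), grp in summary.groupby(["channel", "measure"], sort=False):
        f, df1, df2, p = rm_anova(table, channel, measure, mode, gg_correction)
        tk = tukey_posthoc(table, channel, measure, mode) if posthoc else {}
        conds = tuple(grp["condition"])
        results.append(
            ConditionComparison(
                channel=channel,
                measure=measure,
                conditions=conds,
                means=dict(zip(grp["condition"], grp["mean"])),
                ses=dict(zip(grp["condition"], grp["se"])),
                n=int(grp["n"].iloc[0]),
                F=f,
                df1=df1,
                df2=df2,
                p_anova=p,
                tukey=tk,
            )
        )
    return results
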