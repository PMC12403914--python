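"""State/region-stratified occurrence rates, group summaries, and
behavior-electrophysiology regression.

Rates default to events/min (the unit on the occurrence-rate figures this
pipeline feeds); an ``unit='per_sec'`` flag covers the per-second
convention.  Omnibus ANOVA machinery is intentionally out of scope — the
stratified outputs carry the metadata an external correction needs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .errors import ValidationError
from .io import StateInterval


def _membership(times: np.ndarray, intervals: list[StateInterval]
                ) -> np.ndarray:
    """Boolean mask: time t belongs to some half-open [start, end)."""
    mask = np.zeros(times.size, dtype=bool)
    for s in intervals:
        mask |= (times >= s.start_s) & (times < s.end_s)
    return mask


def occurrence_rates(events: pd.DataFrame, states: list[StateInterval],
                     by=("region", "kind"), state_labels=("NREM",),
                     unit: str = "per_min") -> pd.DataFrame:
    """Event rates per stratum within the requested sleep state(s).

    Counts events whose ``peak_time_s`` falls inside intervals of the
    requested state; the denominator is the total analyzed time in that
    state.  ``events`` is one session's table (shared time base with
    ``states``); multi-animal cohorts concatenate per-session outputs.
    """
    if unit not in ("per_min", "per_sec"):
        raise ValidationError(f"unknown unit {unit!r}")
    by = list(by)
    rows = []
    for label in ([state_labels] if isinstance(state_labels, str)
                  else state_labels):
        ivs = [s for s in states if s.label == label]
        minutes = sum(s.duration_s for s in ivs) / 60.0
        if minutes <= 0:
            warnings.warn(f"no analyzed time in state {label}; omitted")
            continue
        if len(events):
            inside = events[_membership(
                events["peak_time_s"].to_numpy(float), ivs)]
        else:
            inside = events
        groups = (inside.groupby(by, dropna=False).size()
                  if len(inside) else pd.Series(dtype=int))
        seen = set(groups.index)
        all_strata = (set(map(tuple, events[by].drop_duplicates()
                              .itertuples(index=False))) if len(events)
                      else set())
        for key in sorted(seen | {k if isinstance(k, tuple) else (k,)
                                  for k in all_strata}):
            key_t = key if isinstance(key, tuple) else (key,)
            count = int(groups.get(key_t if len(by) > 1 else key_t[0], 0))
            denom = minutes if unit == "per_min" else minutes * 60.0
            rows.append(dict(zip(by, key_t), state=label,
                             analyzed_min=minutes, count=count,
                             rate=count / denom))
    return pd.DataFrame(rows, columns=by + ["state", "analyzed_min",
                                            "count", "rate"])


@dataclass
class RegressionResult:
    """Simple linear regression of behavior on one electrophysiological
    measure (R^2 = r^2 by construction)."""

    predictor: str
    n: int
    slope: float
    intercept: float
    r: float
    r_squared: float
    p_value: float
    stderr: float


def regress_behavior(x, y, predictor: str = "x") -> RegressionResult:
    """OLS of completion time ``y`` on measure ``x``; Pearson r and the
    two-sided p-value from the t distribution with n-2 df."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ValidationError("x and y must be paired")
    if x.size < 3:
        raise ValidationError(f"need >= 3 paired observations, got {x.size}")
    if np.ptp(x) == 0:
        raise ValidationError("constant predictor: regression is degenerate")
    res = sstats.linregress(x, y)
    return RegressionResult(predictor=predictor, n=int(x.size),
                            slope=float(res.slope),
                            intercept=float(res.intercept),
                            r=float(res.rvalue),
                            r_squared=float(res.rvalue ** 2),
                            p_value=float(res.pvalue),
                            stderr=float(res.stderr))


def summarize_groups(rates: pd.DataFrame, contrast=("FAD+", "FAD-"),
                     group_col: str = "group", value_col: str = "rate",
                     by=("region", "state", "kind"),
                     animal_col: str = "animal") -> pd.DataFrame:
    """Per-stratum group means, SEMs and Welch t statistics for a two-group
    contrast.  Strata with fewer than 2 animals in either group are
    omitted with a warning (ready for external omnibus testing)."""
    g1, g2 = contrast
    by = list(by)
    rows = []
    for key, sub in rates.groupby(by, dropna=False):
        key_t = key if isinstance(key, tuple) else (key,)
        a = sub.loc[sub[group_col] == g1, value_col].to_numpy(float)
        b = sub.loc[sub[group_col] == g2, value_col].to_numpy(float)
        if a.size < 2 or b.size < 2:
            warnings.warn(f"stratum {key_t}: fewer than 2 animals per group; "
                          "omitted")
            continue
        t, p = sstats.ttest_ind(a, b, equal_var=False)
        # Welch-Satterthwaite degrees of freedom
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        if va + vb > 0:
            df = (va + vb) ** 2 / (va ** 2 / (a.size - 1)
                                   + vb ** 2 / (b.size - 1))
        else:
            df = a.size + b.size - 2.0
            t, p = 0.0, 1.0
        rows.append(dict(zip(by, key_t),
                         **{f"mean_{g1}": a.mean(), f"sem_{g1}":
                            a.std(ddof=1) / np.sqrt(a.size),
                            f"mean_{g2}": b.mean(), f"sem_{g2}":
                            b.std(ddof=1) / np.sqrt(b.size),
                            "mean_diff": a.mean() - b.mean(),
                            "welch_t": float(t), "welch_df": float(df),
                            "p_value": float(p),
                            f"n_{g1}": a.size, f"n_{g2}": b.size}))
    return pd.DataFrame(rows)
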