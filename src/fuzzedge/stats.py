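"""Descriptive statistics, alpha-cut uncertainty intervals and Student-t
confidence intervals over sets of metric values.

A metric observed over several detection methods is treated as a fuzzy
number centered at the sample mean with spread equal to the sample standard
deviation; its alpha-cut at level alpha is the interval

    [mean - std * sqrt(1 - alpha), mean + std * sqrt(1 - alpha)],

degenerate at the mean for alpha = 1 and widest (mean +- std) at alpha = 0.
This is the alpha-cut of a triangular membership built on mean +- std.
The 95% confidence interval uses the two-sided Student-t quantile with
n - 1 degrees of freedom.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as _sps

__all__ = [
    "StatsSummary",
    "AlphaCutTable",
    "describe_values",
    "alpha_cut_intervals",
    "t_confidence_interval",
    "summarize_metric_table",
]

DEFAULT_ALPHAS = (0.0, 0.25, 0.5, 0.75, 1.0)


@dataclass
class StatsSummary:
    n: int
    mean: float
    sample_std: float
    sample_variance: float


@dataclass
class AlphaCutTable:
    rows: list[tuple[float, float, float]]  # (alpha, lower, upper)


def describe_values(values: Sequence[float]) -> StatsSummary:
    """Mean and sample (n-1 denominator) std/variance; zero spread for n = 1."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("describe_values needs at least one value")
    mean = float(v.mean())
    if v.size == 1:
        return StatsSummary(1, mean, 0.0, 0.0)
    var = float(v.var(ddof=1))
    return StatsSummary(int(v.size), mean, math.sqrt(var), var)


def alpha_cut_intervals(
    summary: StatsSummary, alphas: Sequence[float] = DEFAULT_ALPHAS
) -> AlphaCutTable:
    """Nested intervals mean +- std*sqrt(1-alpha) for each alpha in [0, 1]."""
    rows = []
    for a in alphas:
        if not 0 <= a <= 1:
            raise ValueError(f"alpha must be in [0, 1], got {a}")
        half = summary.sample_std * math.sqrt(1.0 - a)
        rows.append((float(a), summary.mean - half, summary.mean + half))
    return AlphaCutTable(rows)


def t_confidence_interval(
    values: Sequence[float], level: float = 0.95
) -> tuple[float, float]:
    """Two-sided Student-t confidence interval for the mean."""
    v = np.asarray(list(values), dtype=float)
    if v.size < 2:
        raise ValueError("t interval needs n >= 2")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    s = describe_values(v)
    tq = float(_sps.t.ppf(0.5 * (1 + level), df=s.n - 1))
    half = tq * s.sample_std / math.sqrt(s.n)
    return (s.mean - half, s.mean + half)


def summarize_metric_table(
    table,
    metrics: Sequence[str],
    group: str | None = None,
    alphas: Sequence[float] = DEFAULT_ALPHAS,
    level: float = 0.95,
):
    """Table-shaped summary of a metrics DataFrame.

    For each group (or the whole table) and each metric column, returns rows
    for mean/std/variance, the alpha-cut intervals and the t confidence
    interval, as a tidy DataFrame.
    """
    import pandas as pd

    frames = []
    groups = [(None, table)] if group is None else list(table.groupby(group))
    for gname, sub in groups:
        for metric in metrics:
            vals = sub[metric].to_numpy(dtype=float)
            s = describe_values(vals)
            rows = [
                ("mean", s.mean, s.mean),
                ("std", s.sample_std, s.sample_std),
                ("variance", s.sample_variance, s.sample_variance),
            ]
            for a, lo, hi in alpha_cut_intervals(s, alphas).rows:
                rows.append((f"alpha={a:.2f}", lo, hi))
            if s.n >= 2:
                lo, hi = t_confidence_interval(vals, level)
                rows.append((f"ci{int(round(level * 100))}", lo, hi))
            df = pd.DataFrame(rows, columns=["statistic", "lower", "upper"])
            df.insert(0, "metric", metric)
            if gname is not None:
                df.insert(0, group, gname)
            frames.append(df)
    return pd.concat(frames, ignore_index=True)
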