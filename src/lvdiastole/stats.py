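"""Reporting layer: per-subject summaries, mean ± SEM, paired t-tests.

Values are summarised as mean ± SEM (SD/sqrt(n)) and conditions are compared
with the classical two-sided paired t-test on per-subject differences, p from
the t distribution with n - 1 degrees of freedom. No multiplicity correction
is applied (a documented limitation). Degenerate all-equal differences are
reported with the t statistic flagged undefined rather than a fabricated p.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class SubjectSummary:
    subject: str
    condition: str
    metrics: dict[str, float]

    def __post_init__(self) -> None:
        for k, v in self.metrics.items():
            if not np.isfinite(v):
                raise ValueError(f"metric {k!r} of subject {self.subject!r} is not finite")


@dataclass
class ComparisonResult:
    metric: str
    n: int
    mean_diff: float
    sem_diff: float
    t: float | None
    df: int
    p: float | None
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.df != self.n - 1:
            raise ValueError("df must equal n - 1")
        if self.p is not None and not 0 <= self.p <= 1:
            raise ValueError("p must lie in [0, 1]")


def summarize(values) -> tuple[float, float]:
    """Mean and SEM (= SD/sqrt(n), sample SD with ddof=1) of per-subject values."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("summary needs at least 2 values")
    return float(np.mean(x)), float(np.std(x, ddof=1) / np.sqrt(x.size))


def paired_t(a, b, metric: str = "") -> ComparisonResult:
    """Two-sided paired t-test of subject-aligned samples ``a`` vs ``b``.

    The statistic is mean(d) / (SD(d)/sqrt(n)) with d = a - b, referred to a
    t distribution on n - 1 df. All-equal differences (zero variance) yield a
    degenerate result with t and p withheld.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    n = a.size
    if n < 2:
        raise ValueError("paired t-test needs at least 2 pairs")
    d = a - b
    mean = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    sem = sd / np.sqrt(n)
    df = n - 1
    if sd == 0.0:
        return ComparisonResult(metric, n, mean, 0.0, None, df, None, degenerate=True)
    t = mean / sem
    p = float(2.0 * sps.t.sf(abs(t), df))
    return ComparisonResult(metric, n, mean, float(sem), float(t), df, p)


def compare_conditions(
    summaries: pd.DataFrame, condition_a: str, condition_b: str, metrics: list[str] | None = None
) -> list[ComparisonResult]:
    """Paired comparisons across subjects between two condition labels.

    ``summaries`` has columns ``subject``, ``condition`` and one column per
    metric. Subjects must appear under both conditions; unmatched subject ids
    raise an error listing them.
    """
    for col in ("subject", "condition"):
        if col not in summaries.columns:
            raise ValueError(f"summaries table lacks required column {col!r}")
    a = summaries[summaries["condition"] == condition_a].set_index("subject")
    b = summaries[summaries["condition"] == condition_b].set_index("subject")
    if a.empty or b.empty:
        missing = condition_a if a.empty else condition_b
        raise ValueError(f"no rows for condition {missing!r}; need at least 2 conditions")
    unmatched = sorted(set(a.index) ^ set(b.index))
    if unmatched:
        raise ValueError(f"unmatched subject ids between conditions: {unmatched}")
    subjects = sorted(a.index)
    if metrics is None:
        metrics = [c for c in summaries.columns if c not in ("subject", "condition")]
    return [
        paired_t(
            a.loc[subjects, m].to_numpy(dtype=float),
            b.loc[subjects, m].to_numpy(dtype=float),
            metric=m,
        )
        for m in metrics
    ]


def comparison_table(results: list[ComparisonResult]) -> pd.DataFrame:
    """Flat report table: metric, n, difference ± SEM, t, df, p (full precision)."""
    return pd.DataFrame(
        [
            {
                "metric": r.metric,
                "n": r.n,
                "mean_diff": r.mean_diff,
                "sem_diff": r.sem_diff,
                "t": np.nan if r.t is None else r.t,
                "df": r.df,
                "p": np.nan if r.p is None else r.p,
                "degenerate": r.degenerate,
            }
            for r in results
        ]
    )
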