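"""Welch two-sample statistics and per-condition summaries.

Comparisons between imaging conditions use per-object (per-cell) means as
the observations, one value per cell, compared with a Welch-corrected
two-tailed two-sample t-test.  The Welch statistic makes no equal-variance
assumption:

    t  = (m_a - m_b) / sqrt(s_a^2/n_a + s_b^2/n_b)
    df = (s_a^2/n_a + s_b^2/n_b)^2 /
         [ (s_a^2/n_a)^2/(n_a - 1) + (s_b^2/n_b)^2/(n_b - 1) ]

with the Welch-Satterthwaite degrees of freedom reported unrounded.
Inputs may be raw samples or (mean, SD, n) summaries; both give identical
results because the statistic depends on the data only through those
summaries (SD is the ddof=1 sample standard deviation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SampleSummary",
    "WelchResult",
    "welch_t",
    "condition_table",
    "bonferroni",
]


@dataclass(frozen=True)
class SampleSummary:
    """Sufficient statistics of one sample: mean, SD (ddof=1) and n."""

    mean: float
    sd: float
    n: int

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("SD must be non-negative")
        if self.n < 2:
            raise ValueError("need n >= 2 observations")

    @classmethod
    def from_sample(cls, x) -> "SampleSummary":
        x = np.asarray(x, dtype=float)
        if x.size < 2:
            raise ValueError("need n >= 2 observations")
        return cls(float(x.mean()), float(x.std(ddof=1)), int(x.size))


@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p_value: float

    def summary(self) -> str:
        return (
            f"Welch two-sample t-test: t = {self.t:.3f}, "
            f"df = {self.df:.1f}, two-tailed p = {self.p_value:.3g}"
        )


def _as_summary(x) -> SampleSummary:
    if isinstance(x, SampleSummary):
        return x
    return SampleSummary.from_sample(x)


def welch_t(a, b) -> WelchResult:
    """Welch-corrected two-tailed two-sample t-test.

    ``a`` and ``b`` are raw samples (array-like) or
    :class:`SampleSummary` objects, mixed freely.  Zero pooled variance
    makes the statistic undefined and raises.
    """
    sa, sb = _as_summary(a), _as_summary(b)
    va, vb = sa.sd**2 / sa.n, sb.sd**2 / sb.n
    pooled = va + vb
    if pooled == 0:
        raise ValueError("zero variance in both samples: t undefined")
    t = (sa.mean - sb.mean) / np.sqrt(pooled)
    df = pooled**2 / (va**2 / (sa.n - 1) + vb**2 / (sb.n - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return WelchResult(float(t), float(df), float(min(p, 1.0)))


def condition_table(
    per_object: pd.DataFrame,
    group_col: str = "condition",
    value_col: str = "mean",
) -> pd.DataFrame:
    """Per-condition summary (mean, SD, n) over per-object observations.

    Matches box-plot reporting where each data point is one object (cell):
    the condition mean is the unweighted mean of per-object means,
    regardless of object sizes.  Single-object conditions carry NaN SD.
    """
    if per_object.empty:
        raise ValueError("no observations")
    rows = []
    for cond, grp in per_object.groupby(group_col, sort=True):
        v = grp[value_col].to_numpy(dtype=float)
        rows.append(
            {
                group_col: cond,
                "mean": float(v.mean()),
                "sd": float(v.std(ddof=1)) if v.size > 1 else float("nan"),
                "n": int(v.size),
            }
        )
    return pd.DataFrame(rows)


def bonferroni(p_values, n_comparisons: int | None = None) -> np.ndarray:
    """Optional Bonferroni adjustment (off by default in reports)."""
    p = np.asarray(p_values, dtype=float)
    m = n_comparisons if n_comparisons is not None else p.size
    return np.minimum(p * m, 1.0)
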