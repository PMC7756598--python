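"""O'Brien's ordinary-least-squares (OLS) global test.

The classical comparator for multiple-endpoint problems when a common
standardized effect in a common direction is anticipated: per-endpoint t
statistics are summed and scaled by the sample correlation structure,

    T_OLS = sum_k t_k / sqrt(1' R 1),

with R the sample correlation matrix (pooled within-group for a two-group
design, the correlation of within-subject differences for a paired design).
A one-sided upper-tail p-value is taken from a t reference distribution with
df = N - 2 (two-group, N total) or n - 1 (paired) by default; the df is
configurable because the small-sample reference for this statistic is an
approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import _corr_matrix, _split_two_group

__all__ = ["OlsResult", "ols_test"]


@dataclass(frozen=True)
class OlsResult:
    """O'Brien OLS global test outcome (one-sided, upper tail)."""

    statistic: float
    p_value: float
    df: int
    per_endpoint_t: np.ndarray


def _paired_t(X: np.ndarray, labels) -> np.ndarray:
    n = X.shape[0]
    if n < 2:
        raise ValueError("paired design needs at least 2 subjects")
    sd = X.std(axis=0, ddof=1)
    if (sd == 0).any():
        i = int(np.argmax(sd == 0))
        raise ValueError(f"endpoint {labels[i]!r} has zero variance")
    return X.mean(axis=0) / (sd / np.sqrt(n))


def _two_group_t(g1: np.ndarray, g2: np.ndarray, labels) -> np.ndarray:
    n1, n2 = g1.shape[0], g2.shape[0]
    if n1 < 2 or n2 < 2:
        raise ValueError("two-group design needs at least 2 observations per group")
    s1 = g1.var(axis=0, ddof=1)
    s2 = g2.var(axis=0, ddof=1)
    sp2 = ((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2)
    if (sp2 == 0).any():
        i = int(np.argmax(sp2 == 0))
        raise ValueError(f"endpoint {labels[i]!r} has zero pooled variance")
    return (g2.mean(axis=0) - g1.mean(axis=0)) / np.sqrt(
        sp2 * (1.0 / n1 + 1.0 / n2)
    )


def ols_test(
    data: pd.DataFrame,
    design: str = "two-group",
    *,
    correlation_estimator: str = "pearson",
    df: int | None = None,
    group_col: str = "group",
) -> OlsResult:
    """O'Brien's OLS global test on an endpoint data table.

    Pooled-variance two-sample t statistics (two-group) or one-sample t
    statistics on differences (paired) are combined as
    ``T_OLS = sum(t_k) / sqrt(1'R1)``; a one-sided p-value comes from
    ``t(df)``, df defaulting to N-2 (two-group) or n-1 (paired).
    """
    if design == "two-group":
        g1, g2, labels = _split_two_group(data, group_col)
        t_stats = _two_group_t(g1, g2, labels)
        pooled = np.vstack([g1 - g1.mean(axis=0), g2 - g2.mean(axis=0)])
        default_df = g1.shape[0] + g2.shape[0] - 2
        corr_source = pooled
    elif design == "paired":
        X = data.to_numpy(float)
        labels = list(data.columns)
        t_stats = _paired_t(X, labels)
        default_df = X.shape[0] - 1
        corr_source = X
    else:
        raise ValueError(f"unknown design {design!r}; use 'paired' or 'two-group'")

    m = len(t_stats)
    if m == 1:
        R = np.ones((1, 1))
    else:
        R = _corr_matrix(corr_source, correlation_estimator, labels)
    ones = np.ones(m)
    denom_sq = float(ones @ R @ ones)
    if denom_sq <= 0:
        raise ValueError(
            "1'R1 is not positive; the sample correlation matrix is degenerate"
        )
    statistic = float(t_stats.sum() / np.sqrt(denom_sq))
    dof = int(df) if df is not None else int(default_df)
    if dof < 1:
        raise ValueError(f"degrees of freedom must be >= 1, got {dof}")
    p_value = float(sps.t.sf(statistic, dof))
    return OlsResult(
        statistic=statistic,
        p_value=p_value,
        df=dof,
        per_endpoint_t=np.asarray(t_stats, dtype=float),
    )
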