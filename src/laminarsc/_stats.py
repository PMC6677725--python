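"""Small statistical helpers shared across analysis stages."""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = ["welch_t_pvalue", "welch_t_pvalues_columns"]


def welch_t_pvalue(a: np.ndarray, b: np.ndarray) -> float:
    """Two-tailed unequal-variance t test.

    Degenerate zero-variance samples are handled by an exact-equality rule:
    when both samples have zero variance the difference is called significant
    (p=0) iff the means differ, otherwise p=1.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.std() == 0.0 and b.std() == 0.0:
        return 0.0 if a.mean() != b.mean() else 1.0
    p = stats.ttest_ind(a, b, equal_var=False).pvalue
    return 1.0 if np.isnan(p) else float(p)


def welch_t_pvalues_columns(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorized two-tailed Welch t test of each column of ``A`` against the
    1-D sample ``b`` (used for per-1-ms-bin tests against a pooled baseline)."""
    A = np.asarray(A, float)
    b = np.asarray(b, float)
    n1 = A.shape[0]
    n2 = b.size
    m1 = A.mean(axis=0)
    v1 = A.var(axis=0, ddof=1) if n1 > 1 else np.zeros(A.shape[1])
    m2 = b.mean()
    v2 = b.var(ddof=1) if n2 > 1 else 0.0

    se2 = v1 / n1 + v2 / n2
    p = np.empty(A.shape[1])
    degenerate = se2 == 0.0
    p[degenerate] = np.where(m1[degenerate] != m2, 0.0, 1.0)
    ok = ~degenerate
    if np.any(ok):
        t = (m1[ok] - m2) / np.sqrt(se2[ok])
        with np.errstate(divide="ignore", invalid="ignore"):
            df = se2[ok] ** 2 / (
                (v1[ok] / n1) ** 2 / max(n1 - 1, 1) + (v2 / n2) ** 2 / max(n2 - 1, 1)
            )
        df = np.where(np.isfinite(df) & (df > 0), df, 1.0)
        p[ok] = 2.0 * stats.t.sf(np.abs(t), df)
    return p
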