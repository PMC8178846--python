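"""Two-group differential expression with a Bayesian-regularized t-statistic.

The statistic shrinks each gene's pooled variance toward a local
"background" variance estimated from genes of similar overall mean
expression, then refers the moderated t to a Student distribution with
inflated degrees of freedom.  With ``nu0 = 0`` the statistic reduces
exactly to the ordinary pooled-variance two-sample t-test, which is the
testable anchor of the construction.

For gene g with group means m_A, m_B, pooled sample variance s^2 on
``n - 2`` degrees of freedom (n = n_A + n_B) and background variance
sigma0^2 (mean pooled variance over a rank window of genes with the
nearest overall mean expression):

    v     = (nu0 * sigma0^2 + (n - 2) * s^2) / (nu0 + n - 2)
    t_reg = (m_A - m_B) / sqrt(v * (1/n_A + 1/n_B))
    p     = two-sided Student t with df = nu0 + n - 2
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from dormsig.data_model import ExpressionMatrix

DEFAULT_WINDOW = 101
DEFAULT_NU0 = 10.0


def _windowed_mean(x: np.ndarray, window: int) -> np.ndarray:
    """Mean of x over a centered window of ranks, truncated at the ends.

    For index i the window is ranks [i - h, i + h] intersected with
    [0, len(x) - 1], h = window // 2, so edge windows contain fewer
    elements rather than wrapping.
    """
    n = len(x)
    h = window // 2
    csum = np.concatenate(([0.0], np.cumsum(x)))
    lo = np.maximum(np.arange(n) - h, 0)
    hi = np.minimum(np.arange(n) + h, n - 1)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)


def regularized_ttest(
    matrix: ExpressionMatrix | pd.DataFrame,
    group_a: Sequence[str],
    group_b: Sequence[str],
    window: int = DEFAULT_WINDOW,
    nu0: float = DEFAULT_NU0,
) -> pd.DataFrame:
    """Regularized two-sample t-test of group A minus group B, per gene.

    Parameters
    ----------
    matrix
        ExpressionMatrix or raw genes x samples DataFrame (log2 scale).
    group_a, group_b
        Disjoint sample-id sets, each with >= 2 samples.  ``log2fc`` is
        oriented as mean(A) - mean(B); by convention A is the
        residual-lesion-style group.
    window
        Odd rank-window width for the background variance.
    nu0
        Prior degrees of freedom; 0 recovers the ordinary pooled t-test.

    Returns
    -------
    DataFrame indexed by gene id with columns mean_A, mean_B, log2fc,
    t_reg, p, q, pooled_sd, background_sd.
    """
    values = matrix.values if isinstance(matrix, ExpressionMatrix) else matrix
    group_a, group_b = list(group_a), list(group_b)
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs at least 2 samples")
    if set(group_a) & set(group_b):
        raise ValueError("groups overlap")
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    if window > values.shape[0]:
        raise ValueError("window exceeds number of genes")
    if nu0 < 0:
        raise ValueError("nu0 must be nonnegative")

    a = values[group_a].to_numpy(dtype=float)
    b = values[group_b].to_numpy(dtype=float)
    n_a, n_b = a.shape[1], b.shape[1]
    n = n_a + n_b
    df_raw = n - 2

    mean_a = a.mean(axis=1)
    mean_b = b.mean(axis=1)
    s2 = (
        a.var(axis=1, ddof=1) * (n_a - 1) + b.var(axis=1, ddof=1) * (n_b - 1)
    ) / df_raw

    overall_mean = np.concatenate([a, b], axis=1).mean(axis=1)
    order = np.argsort(overall_mean, kind="stable")
    sigma0_sq = np.empty_like(s2)
    sigma0_sq[order] = _windowed_mean(s2[order], window)

    v = (nu0 * sigma0_sq + df_raw * s2) / (nu0 + df_raw)
    if (v <= 0).any():
        gene = values.index[np.argmax(v <= 0)]
        raise ValueError(
            f"zero posterior variance for gene {gene!r}; "
            "increase nu0 or check for constant data"
        )
    t_reg = (mean_a - mean_b) / np.sqrt(v * (1.0 / n_a + 1.0 / n_b))
    df_post = nu0 + df_raw
    p = 2.0 * stats.t.sf(np.abs(t_reg), df=df_post)

    return pd.DataFrame(
        {
            "mean_A": mean_a,
            "mean_B": mean_b,
            "log2fc": mean_a - mean_b,
            "t_reg": t_reg,
            "p": p,
            "q": bh_fdr(p),
            "pooled_sd": np.sqrt(s2),
            "background_sd": np.sqrt(sigma0_sq),
        },
        index=values.index.copy(),
    )


def bh_fdr(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, aligned to the input order.

    q_(i) = min_{j >= i} p_(j) * G / j over the ascending p-order, capped
    at 1.  Ties share the q of their shared rank position.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    g = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * g / np.arange(1, g + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(g)
    q[order] = q_sorted
    return q


def write_de_table(result: pd.DataFrame, path) -> None:
    """Persist a DE table as tab-delimited text (gene id in first column)."""
    out = result.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.10g")
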