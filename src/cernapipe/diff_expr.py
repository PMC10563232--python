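"""Differential expression: MA-plot random-sampling test, BH, fold filter.

The test is the classic two-library MA-plot statistic: per feature, counts
are pooled within each group, M = log2 c1 - log2 c2 and
A = (log2 c1 + log2 c2)/2 are formed, and under the random-sampling null
(each library a binomial draw of its total) the delta method gives

    z = (M - log2(N1/N2)) / sqrt(Var),
    Var = [(1 - c1/N1)/c1 + (1 - c2/N2)/c2] / ln(2)^2,

with a two-sided standard-normal p-value.  Counts of zero receive a +0.5
continuity correction before the logs.  P-values are Benjamini-Hochberg
adjusted to Q values, and a feature is called differential only when
Q < ``q_threshold`` AND the ratio of group means of the normalized matrix
(FPKM or TPM) passes the fold threshold in either direction.

With biological replicates the pooled binomial null understates the true
variance (overdispersion), so many null features reach small Q; the fold
filter is what keeps calls specific.  This mirrors the dual
Q-and-fold-change criterion the method was designed around.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionMatrix

logger = logging.getLogger(__name__)

_LN2_SQ = math.log(2.0) ** 2


def _mars_arrays(
    c1: np.ndarray, c2: np.ndarray, n1: float, n2: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized MA statistic; returns (m, a, z, p) arrays."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")
    c1 = np.asarray(c1, dtype=float)
    c2 = np.asarray(c2, dtype=float)
    if (c1 < 0).any() or (c2 < 0).any():
        raise ValueError("counts must be non-negative")
    uninformative = (c1 == 0) & (c2 == 0)
    c1c = np.where(c1 == 0, 0.5, c1)
    c2c = np.where(c2 == 0, 0.5, c2)
    l1 = np.log2(c1c)
    l2 = np.log2(c2c)
    m = l1 - l2
    a = (l1 + l2) / 2.0
    var = ((1.0 - c1c / n1) / c1c + (1.0 - c2c / n2) / c2c) / _LN2_SQ
    var = np.maximum(var, 1e-300)
    z = (m - math.log2(n1 / n2)) / np.sqrt(var)
    z = np.where(uninformative, 0.0, z)
    p = np.where(uninformative, 1.0, 2.0 * stats.norm.sf(np.abs(z)))
    p = np.minimum(p, 1.0)
    return m, a, z, p


def mars_test(c1: int, c2: int, n1: int, n2: int) -> tuple[float, float, float, float]:
    """MA-plot random-sampling test for one feature.

    Returns (M, A, z, p).  ``c1``/``c2`` are the pooled counts of the two
    libraries with totals ``n1``/``n2``.  A feature with both counts zero is
    uninformative: z = 0, p = 1.
    """
    if c1 > n1 or c2 > n2:
        raise ValueError("counts cannot exceed library totals")
    if c1 == 0 and c2 == 0:
        logger.warning("mars_test called with c1=c2=0; feature is uninformative")
    m, a, z, p = _mars_arrays(np.array([c1]), np.array([c2]), float(n1), float(n2))
    return float(m[0]), float(a[0]), float(z[0]), float(p[0])


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, output in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_differential(
    counts: ExpressionMatrix,
    norm_matrix: ExpressionMatrix,
    design: pd.DataFrame,
    group1: str = "TPS",
    group2: str = "MPS",
    q_threshold: float = 0.05,
    fc_threshold: float = 2.0,
) -> pd.DataFrame:
    """Differential calls over all features of ``counts``.

    Replicates are pooled by summing counts within each group for the
    MA-plot test; the fold change divides the ``group2`` mean of the
    normalized matrix by the ``group1`` mean (e.g. MPS/TPS).  Returns a
    DataFrame indexed by feature id with columns pooled_c1, pooled_c2,
    m_value, a_value, z, p, q, mean_norm_g1, mean_norm_g2, fold_change and
    call in {up, down, ns}.
    """
    for g in (group1, group2):
        if (design["group"] == g).sum() == 0:
            raise ValueError(f"design has no samples for group {g!r}")
    if list(counts.feature_ids) != list(norm_matrix.feature_ids):
        norm = norm_matrix.data.reindex(counts.data.index)
        if norm.isna().any().any():
            raise ValueError("counts and normalized matrix must share features")
    else:
        norm = norm_matrix.data
    samples1 = design.loc[design["group"] == group1, "sample_id"].tolist()
    samples2 = design.loc[design["group"] == group2, "sample_id"].tolist()
    missing = [s for s in samples1 + samples2 if s not in counts.sample_ids]
    if missing:
        raise ValueError(f"design samples absent from count matrix: {missing}")

    c1 = counts.data[samples1].sum(axis=1).to_numpy()
    c2 = counts.data[samples2].sum(axis=1).to_numpy()
    n1 = float(counts.data[samples1].to_numpy().sum())
    n2 = float(counts.data[samples2].to_numpy().sum())
    m, a, z, p = _mars_arrays(c1, c2, n1, n2)
    q = bh_adjust(p)

    mean1 = norm[samples1].mean(axis=1).to_numpy()
    mean2 = norm[samples2].mean(axis=1).to_numpy()
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = mean2 / mean1
    fold = np.where((mean1 == 0) & (mean2 == 0), np.nan, fold)  # 0/0 -> ns
    fold = np.where((mean1 == 0) & (mean2 > 0), np.inf, fold)

    sig = q < q_threshold
    with np.errstate(invalid="ignore"):
        up = sig & (fold >= fc_threshold)
        down = sig & (fold <= 1.0 / fc_threshold)
    call = np.where(up, "up", np.where(down, "down", "ns"))

    return pd.DataFrame(
        {
            "pooled_c1": c1.astype(int),
            "pooled_c2": c2.astype(int),
            "m_value": m,
            "a_value": a,
            "z": z,
            "p": p,
            "q": q,
            "mean_norm_g1": mean1,
            "mean_norm_g2": mean2,
            "fold_change": fold,
            "call": call,
        },
        index=pd.Index(counts.feature_ids, name="feature_id"),
    )
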