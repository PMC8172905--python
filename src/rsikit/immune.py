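"""Immune-association statistics.

Covers the downstream statistics applied to immune-cell fraction tables
(deconvolution output is consumed as input, never recomputed): macrophage
polarisation as log2(M1/M2), Spearman correlation matrices with pairwise-
complete observations, two-group Mann-Whitney comparisons, one-way ANOVA
across k groups, and the |logFC| / adjusted-p filter applied to externally
produced differential-expression or proteomic result tables.

Correlation p-values are reported raw (no multiplicity adjustment); callers
comparing many pairs should adjust downstream.
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "validate_immune_fractions",
    "m1_m2_log_ratio",
    "LogRatioResult",
    "spearman_with_p",
    "spearman_matrix",
    "group_compare",
    "anova_across_groups",
    "filter_differential",
]

M1_COLUMN = "Macrophages M1"
M2_COLUMN = "Macrophages M2"


def validate_immune_fractions(t: pd.DataFrame, tol: float = 1e-6) -> pd.DataFrame:
    """Check an immune-fraction table: fractions >= 0, per-sample sum <= 1+tol."""
    frac = t.select_dtypes("number")
    if (frac.to_numpy() < 0).any():
        raise ValidationError("immune fractions must be non-negative")
    sums = frac.sum(axis=1)
    if (sums > 1 + tol).any():
        bad = t.index[sums > 1 + tol].tolist()
        raise ValidationError(f"immune fractions sum above 1: samples {bad}")
    return t


@dataclass
class LogRatioResult:
    """log2(M1/M2) per sample, with structural-zero exclusions counted."""

    values: pd.Series
    n_excluded: int
    excluded_samples: list[str]


def m1_m2_log_ratio(
    t: pd.DataFrame, m1_col: str = M1_COLUMN, m2_col: str = M2_COLUMN
) -> LogRatioResult:
    """Macrophage polarisation: log2(M1/M2) per sample.

    Samples where either fraction is zero carry no ratio information
    (deconvolution zeros are structural — the cell type is called absent)
    and are excluded rather than pseudo-counted; exclusions are counted.
    """
    for col in (m1_col, m2_col):
        if col not in t.columns:
            raise ValidationError(f"column {col!r} missing from fraction table")
    m1, m2 = t[m1_col], t[m2_col]
    ok = (m1 > 0) & (m2 > 0)
    excluded = t.index[~ok].tolist()
    values = np.log2(m1[ok] / m2[ok])
    values.name = "log2_m1_m2"
    return LogRatioResult(values, len(excluded), [str(s) for s in excluded])


# Null distributions of Spearman's rho (as sum of squared rank differences)
# for untied samples of size n; computed lazily, keyed by n.
_EXACT_NULL_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}
_EXACT_N_MAX = 10


def _exact_null_d2(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Distinct values and counts of sum(d^2) over all n! rank permutations."""
    if n not in _EXACT_NULL_CACHE:
        base = np.arange(1, n + 1)
        counts: dict[int, int] = {}
        chunk: list[tuple[int, ...]] = []
        perms = itertools.permutations(range(1, n + 1))
        while True:
            chunk = list(itertools.islice(perms, 200_000))
            if not chunk:
                break
            arr = np.asarray(chunk, dtype=np.int64)
            d2 = ((arr - base) ** 2).sum(axis=1)
            vals, cnts = np.unique(d2, return_counts=True)
            for v, c in zip(vals, cnts):
                counts[int(v)] = counts.get(int(v), 0) + int(c)
        keys = np.array(sorted(counts))
        _EXACT_NULL_CACHE[n] = (keys, np.array([counts[k] for k in keys]))
    return _EXACT_NULL_CACHE[n]


def spearman_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho with an exact permutation p for small untied samples.

    For n <= 10 with no ties the two-sided p is exact (enumeration of the
    null distribution of rho); otherwise the asymptotic t approximation is
    used. Returns (rho, p).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = x.size
    rho = float(stats.spearmanr(x, y).statistic)
    untied = len(np.unique(x)) == n and len(np.unique(y)) == n
    if n <= _EXACT_N_MAX and untied and n >= 3:
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        d2_obs = int(((rx - ry) ** 2).sum())
        d2_vals, d2_counts = _exact_null_d2(n)
        # rho = 1 - 6 d2 / (n(n^2-1)): extreme rho <=> extreme d2 on both tails
        mid = n * (n * n - 1) / 6.0  # d2 at rho = 0
        dev = abs(d2_obs - mid)
        extreme = np.abs(d2_vals - mid) >= dev - 1e-9
        p = float(d2_counts[extreme].sum() / d2_counts.sum())
        return rho, min(p, 1.0)
    if n <= _EXACT_N_MAX and not untied:
        logger.warning("ties at n=%d: falling back to asymptotic Spearman p", n)
    p = float(stats.spearmanr(x, y).pvalue)
    return rho, p


def spearman_matrix(
    X: pd.DataFrame, Y: pd.DataFrame | None = None, min_pairs: int = 4
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Column-pairwise Spearman correlation between two tables.

    Missing values are handled pairwise-complete; cells with fewer than
    ``min_pairs`` complete pairs are flagged missing. Returns (rho, p, n)
    frames indexed by X columns with Y columns as columns.
    """
    if Y is None:
        Y = X
    rho = pd.DataFrame(np.nan, index=X.columns, columns=Y.columns)
    pval = rho.copy()
    npairs = pd.DataFrame(0, index=X.columns, columns=Y.columns)
    for cx in X.columns:
        for cy in Y.columns:
            pair = pd.concat([X[cx], Y[cy]], axis=1, join="inner").dropna()
            npairs.loc[cx, cy] = len(pair)
            if len(pair) < min_pairs:
                continue
            r, p = spearman_with_p(pair.iloc[:, 0].to_numpy(),
                                   pair.iloc[:, 1].to_numpy())
            rho.loc[cx, cy] = r
            pval.loc[cx, cy] = p
    return rho, pval, npairs


def group_compare(
    values: pd.Series | np.ndarray, labels: pd.Series | np.ndarray
) -> tuple[float, float]:
    """Two-sided Mann-Whitney U between the two label groups.

    Exact enumeration when both groups have n <= 8 (and no ties); the
    tie-corrected normal approximation otherwise. Returns (U, p).
    """
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    levels = pd.unique(labels)
    if len(levels) != 2:
        raise ValidationError(f"expected exactly 2 groups, got {len(levels)}")
    a = values[labels == levels[0]]
    b = values[labels == levels[1]]
    if a.size == 0 or b.size == 0:
        raise ValidationError("both groups must be non-empty")
    n_a, n_b = a.size, b.size
    ranks = stats.rankdata(values)
    u_obs = float(ranks[labels == levels[0]].sum() - n_a * (n_a + 1) / 2)
    if n_a <= 8 and n_b <= 8:
        # exact enumeration over all C(n_a+n_b, n_a) group assignments;
        # valid with ties since it permutes the observed (averaged) ranks
        mu = n_a * n_b / 2.0
        idx = np.fromiter(
            itertools.chain.from_iterable(
                itertools.combinations(range(n_a + n_b), n_a)
            ),
            dtype=np.intp,
        ).reshape(-1, n_a)
        u_all = ranks[idx].sum(axis=1) - n_a * (n_a + 1) / 2
        p = float(np.mean(np.abs(u_all - mu) >= abs(u_obs - mu) - 1e-9))
        return u_obs, p
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return u_obs, float(res.pvalue)


def anova_across_groups(
    values: pd.Series | np.ndarray, labels: pd.Series | np.ndarray
) -> tuple[float, float]:
    """Classical one-way ANOVA F test across k >= 2 groups (each n >= 2)."""
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    groups = [values[labels == lv] for lv in pd.unique(labels)]
    if len(groups) < 2:
        raise ValidationError("ANOVA needs >= 2 groups")
    if any(g.size < 2 for g in groups):
        raise ValidationError("every ANOVA group needs >= 2 observations")
    res = stats.f_oneway(*groups)
    return float(res.statistic), float(res.pvalue)


def filter_differential(
    rows: pd.DataFrame, fc_thresh: float = 1.0, alpha: float = 0.05
) -> pd.DataFrame:
    """Retain differential rows with |logFC| strictly above ``fc_thresh``
    and adjusted p strictly below ``alpha``.

    Both inequalities are strict, so boundary rows (|logFC| == 1 or
    adj_p == 0.05) are dropped. Expects columns ``logFC`` and ``adj_p``.
    """
    if not rows["adj_p"].between(0, 1).all():
        raise ValidationError("adj_p must lie in [0, 1]")
    keep = (rows["logFC"].abs() > fc_thresh) & (rows["adj_p"] < alpha)
    return rows.loc[keep].copy()
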