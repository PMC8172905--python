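"""Rank-based radiosensitivity-index (RSI) scoring and stratification.

Per sample, the ten signature genes are ranked among themselves by
expression (ascending; the highest-expressed gene gets rank 10, ties get
average ranks) and the RSI is the weighted sum of those ranks with the
published coefficients. RSI proxies the survival fraction at 2 Gy, so a low
RSI suggests high radiosensitivity. Samples are stratified into RSI-Low
(score < threshold) and RSI-High (score >= threshold); the published
threshold is 0.46.

Ranking is within the signature genes only and is therefore invariant to
any strictly monotone per-sample transform of expression; it is unbounded
(no clipping) and deterministic.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata, spearmanr

from .errors import ScoringError, ValidationError
from .io import ExpressionMatrix
from .signatures import WeightedSignature

__all__ = [
    "RSI_THRESHOLD",
    "rank_transform",
    "compute_rsi",
    "stratify",
    "score_matrix",
    "qc_signature",
    "SignatureQCReport",
]

#: Published RSI stratification threshold (RSI-Low iff score < threshold).
RSI_THRESHOLD = 0.46


def rank_transform(
    m: ExpressionMatrix, sig: WeightedSignature, tie_policy: str = "average"
) -> pd.DataFrame:
    """Within-sample ranks of the signature genes (genes x samples).

    Ranks are ascending over the signature genes only: with n genes the
    highest expression gets rank n. Ties receive average ranks, so the ranks
    of every sample sum to n(n+1)/2. Missing or absent signature genes raise
    :class:`ScoringError` naming the gene and sample.
    """
    if tie_policy != "average":
        raise ValueError("only the 'average' tie policy is supported")
    missing = [g for g in sig.genes if g not in m.data.index]
    if missing:
        raise ScoringError(f"signature genes absent from matrix: {missing}")
    sub = m.data.loc[list(sig.genes)]
    if sub.isna().any().any():
        gene = sub.index[sub.isna().any(axis=1)][0]
        sample = sub.columns[sub.isna().any(axis=0)][0]
        raise ScoringError(
            f"missing expression for signature gene {gene!r} (e.g. sample {sample!r})"
        )
    ranks = rankdata(sub.to_numpy(), method="average", axis=0)
    return pd.DataFrame(ranks, index=sub.index, columns=sub.columns)


def compute_rsi(ranks: pd.DataFrame, sig: WeightedSignature) -> pd.DataFrame:
    """RSI per sample: the coefficient-weighted sum of within-sample ranks.

    Returns a ScoreTable-style frame with columns ``sample_id`` and ``rsi``.
    """
    if list(ranks.index) != list(sig.genes):
        ranks = ranks.loc[list(sig.genes)]
    scores = sig.coef_array @ ranks.to_numpy()
    return pd.DataFrame({"sample_id": ranks.columns, "rsi": scores})


def stratify(scores: pd.DataFrame, threshold: float = RSI_THRESHOLD) -> pd.DataFrame:
    """Label each sample RSI-Low (score < threshold) or RSI-High (>=).

    The threshold used is recorded in the returned table. Non-finite scores
    raise :class:`ValidationError`.
    """
    if not np.isfinite(scores["rsi"]).all():
        bad = scores.loc[~np.isfinite(scores["rsi"]), "sample_id"].tolist()
        raise ValidationError(f"non-finite RSI for samples: {bad}")
    out = scores.copy()
    out["category"] = np.where(out["rsi"] < threshold, "RSI-Low", "RSI-High")
    out["threshold"] = threshold
    return out


def score_matrix(
    m: ExpressionMatrix,
    sig: WeightedSignature,
    threshold: float = RSI_THRESHOLD,
) -> pd.DataFrame:
    """Convenience: rank, score and stratify a matrix in one call."""
    return stratify(compute_rsi(rank_transform(m, sig), sig), threshold)


@dataclass
class SignatureQCReport:
    """Cross-platform signature QC summary.

    Per dataset: the mean and sd of each gene's within-sample rank, the
    gene-gene Spearman correlation matrix and the score mean/sd; plus the
    per-gene absolute difference of rank means between the two datasets.
    Large deltas signal that the signature ranks genes differently on the
    two platforms.
    """

    rank_summary: dict[str, pd.DataFrame]
    spearman: dict[str, pd.DataFrame]
    score_stats: dict[str, dict[str, float]]
    rank_mean_delta: pd.Series


def qc_signature(
    m1: ExpressionMatrix,
    m2: ExpressionMatrix,
    sig: WeightedSignature,
    names: tuple[str, str] = ("dataset1", "dataset2"),
) -> SignatureQCReport:
    """Rank-distribution, co-correlation and score-variability QC metrics
    for one signature across two expression datasets."""
    rank_summary, spear, score_stats, rank_means = {}, {}, {}, {}
    for name, m in zip(names, (m1, m2)):
        ranks = rank_transform(m, sig)
        rank_summary[name] = pd.DataFrame(
            {"rank_mean": ranks.mean(axis=1), "rank_sd": ranks.std(axis=1, ddof=1)}
        )
        rank_means[name] = ranks.mean(axis=1)
        rho = spearmanr(m.data.loc[list(sig.genes)].to_numpy(), axis=1).statistic
        rho = np.atleast_2d(rho)
        spear[name] = pd.DataFrame(rho, index=sig.genes, columns=sig.genes)
        scores = compute_rsi(ranks, sig)["rsi"]
        score_stats[name] = {"mean": float(scores.mean()),
                             "sd": float(scores.std(ddof=1))}
    delta = (rank_means[names[0]] - rank_means[names[1]]).abs()
    return SignatureQCReport(rank_summary, spear, score_stats, delta)
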