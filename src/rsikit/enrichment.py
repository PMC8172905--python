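"""Single-sample gene-set enrichment (GSVA-style statistic).

The per-sample enrichment statistic follows the kernel-CDF pathway: each
gene's expression is converted to a kernel-estimated cumulative density
against its own cross-sample distribution (Gaussian kernel, bandwidth
sd/4), the resulting scores are turned into centred rank statistics within
each sample, and a weighted Kolmogorov-Smirnov random walk down the
sample's gene ordering yields the enrichment score. In ``max_diff`` mode
the score is the maximum positive deviation plus the minimum negative
deviation of the walk.

Cohort-level calling z-transforms the raw scores (population sd) and flags
a sample as enriched when its z exceeds a threshold; 0.35 is the default
T-cell-inflamed activity threshold (a nearby 0.32 variant also circulates —
see docs/methods.md).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ValidationError
from .io import ExpressionMatrix
from .signatures import GeneSet

logger = logging.getLogger(__name__)

__all__ = [
    "ENRICHMENT_Z_THRESHOLD",
    "kernel_expression_statistic",
    "gsva_score",
    "z_and_call",
    "enrich_matrix",
]

#: Default z-score threshold for calling a sample enriched.
ENRICHMENT_Z_THRESHOLD = 0.35


def kernel_expression_statistic(
    m: ExpressionMatrix, bandwidth_factor: float = 4.0
) -> pd.DataFrame:
    """Gaussian-kernel cumulative-density statistic per gene and sample.

    For gene i with cross-sample values x_i and bandwidth h_i = sd_i /
    ``bandwidth_factor``, the statistic for sample j is the mean of
    ``Phi((x_ij - x_ik) / h_i)`` over samples k — a smoothed within-gene
    CDF, invariant to adding a constant to the gene's row. A constant gene
    has no distribution to estimate; its statistic is defined as 0.5 for
    every sample and logged.
    """
    X = m.values.astype(float)
    n_genes, n_samples = X.shape
    if n_samples < 3:
        raise ValidationError("kernel statistic needs >= 3 samples")
    out = np.empty_like(X)
    sds = X.std(axis=1, ddof=1)
    for i in range(n_genes):
        if sds[i] == 0 or not np.isfinite(sds[i]):
            logger.info("gene %s constant across samples; statistic set to 0.5",
                        m.gene_ids[i])
            out[i] = 0.5
            continue
        h = sds[i] / bandwidth_factor
        diffs = (X[i][:, None] - X[i][None, :]) / h
        out[i] = norm.cdf(diffs).mean(axis=1)
    return pd.DataFrame(out, index=m.gene_ids, columns=m.sample_ids)


def _walk_es(order: np.ndarray, in_set: np.ndarray, weights: np.ndarray,
             mode: str) -> float:
    """Weighted KS random walk over one sample's gene ordering."""
    p = order.size
    inset_ordered = in_set[order]
    w = weights[order] * inset_ordered
    denom_in = w.sum()
    n_out = p - int(in_set.sum())
    step = np.where(
        inset_ordered,
        w / denom_in if denom_in > 0 else 0.0,
        -1.0 / n_out if n_out > 0 else 0.0,
    )
    walk = np.cumsum(step)
    if mode == "max_diff":
        return float(max(walk.max(), 0.0) + min(walk.min(), 0.0))
    # largest absolute deviation, signed
    return float(walk[np.argmax(np.abs(walk))])


def gsva_score(
    stats: pd.DataFrame,
    gs: GeneSet,
    tau: float = 1.0,
    mode: str = "max_diff",
) -> pd.Series:
    """Per-sample enrichment score for one gene set.

    Within each sample, genes are ordered by decreasing kernel statistic;
    the centred rank statistic ``|p/2 - rank|`` (rank 1 = top) weights the
    in-set increments (raised to ``tau``; ``tau=0`` gives the unweighted KS
    walk) while out-of-set genes decrement uniformly. Genes of ``gs`` absent
    from ``stats`` are dropped with a warning; an empty intersection raises.
    """
    if mode not in ("max_diff", "max_abs"):
        raise ValueError(f"unknown mode {mode!r}")
    present = [g for g in gs.genes if g in stats.index]
    absent = sorted(set(gs.genes) - set(present))
    if absent:
        logger.warning("gene set %s: %d genes absent from matrix: %s",
                       gs.name, len(absent), absent)
    if not present:
        raise ValidationError(f"gene set {gs.name} has no genes in the matrix")
    genes = np.asarray(stats.index)
    in_set = np.isin(genes, present)
    Z = stats.to_numpy()
    p = len(genes)
    es = np.empty(Z.shape[1])
    for j in range(Z.shape[1]):
        order = np.argsort(-Z[:, j], kind="stable")
        ranks = np.empty(p)
        ranks[order] = np.arange(1, p + 1)
        centred = np.abs(p / 2.0 - ranks)
        weights = centred ** tau if tau != 0 else np.ones(p)
        es[j] = _walk_es(order, in_set, weights, mode)
    return pd.Series(es, index=stats.columns, name=gs.name)


@dataclass
class EnrichmentResult:
    """Per-sample enrichment scores, cohort z-scores and calls."""

    table: pd.DataFrame  # sample_id, es, z, enriched, threshold
    threshold: float
    fraction_enriched: float


def z_and_call(
    es: pd.Series, z_threshold: float = ENRICHMENT_Z_THRESHOLD
) -> EnrichmentResult:
    """Z-transform raw scores across the cohort (population sd) and call a
    sample enriched when z > threshold."""
    if es.size < 2:
        raise ValidationError("z-transform needs >= 2 samples")
    sd = float(es.std(ddof=0))
    if sd == 0:
        raise ValidationError("enrichment scores have zero variance")
    z = (es - es.mean()) / sd
    enriched = z > z_threshold
    table = pd.DataFrame(
        {"sample_id": es.index, "es": es.to_numpy(), "z": z.to_numpy(),
         "enriched": enriched.to_numpy(), "threshold": z_threshold}
    )
    return EnrichmentResult(table, z_threshold, float(enriched.mean()))


def enrich_matrix(
    m: ExpressionMatrix,
    gs: GeneSet,
    tau: float = 1.0,
    mode: str = "max_diff",
    z_threshold: float = ENRICHMENT_Z_THRESHOLD,
    bandwidth_factor: float = 4.0,
) -> EnrichmentResult:
    """Convenience: kernel statistic, set score and cohort call in one go."""
    stats = kernel_expression_statistic(m, bandwidth_factor)
    return z_and_call(gsva_score(stats, gs, tau, mode), z_threshold)
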