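"""Synthetic cohorts with the statistical structure the pipeline assumes.

The generator emulates a pan-cancer bulk-expression cohort: log-scale
expression with Gaussian gene-level noise, immune subtype labels C1-C6,
Dirichlet immune-cell fractions whose M1 component is coupled to the RSI,
and exponential survival whose hazard depends on the latent RSI group.
IFN-gamma-dominant (C2) samples receive configurable expression shifts on
five RSI classifier genes and on the T-cell-inflamed (TCIA) genes, so the
direction of every downstream association (C2 at lower RSI, TCIA enriched
at lower RSI, M1 polarisation anticorrelated with RSI, RSI-dependent
survival) is planted and recoverable.

Because the RSI mixes positive and negative rank coefficients, the sign
pattern of the C2 shift is a calibrated constant (:data:`DEFAULT_RSI_SHIFT_SIGNS`):
upward shifts on JUN, CDK1, IRF1 and STAT1 and a downward shift on ABL1
guarantee that C2 samples score lower on average (the sign-weighted
coefficient sum is -0.122); analysis/00_calibrate_shift_directions.py
verifies the direction empirically.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import ExpressionMatrix, ProbeMap
from .rsi import RSI_THRESHOLD, score_matrix
from .signatures import GeneSet, WeightedSignature, rsi_signature, tcia_gene_set

__all__ = [
    "SyntheticConfig",
    "SyntheticCohort",
    "DEFAULT_RSI_SHIFT_SIGNS",
    "IMMUNE_SUBTYPES",
    "generate",
    "truth_report",
    "split_to_probes",
    "null_config",
]

IMMUNE_SUBTYPES = ("C1", "C2", "C3", "C4", "C5", "C6")

#: Calibrated sign of the C2 expression shift per RSI classifier gene
#: (upward where the source cohorts show higher expression in RSI-Low
#: tumours; ABL1 shifted down so the net rank effect lowers the RSI).
DEFAULT_RSI_SHIFT_SIGNS: dict[str, float] = {
    "JUN": 1.0, "CDK1": 1.0, "IRF1": 1.0, "STAT1": 1.0, "ABL1": -1.0,
}


def _lm22_cell_types() -> list[str]:
    text = resources.files("rsikit.data").joinpath("lm22_cell_types.txt").read_text()
    return [line for line in text.splitlines() if line.strip()]


@dataclass(frozen=True)
class SyntheticConfig:
    """Generating parameters for one synthetic cohort.

    Effect sizes are in units of the noise sd; ``beta_m1`` adds
    ``beta_m1 * (rsi_threshold - RSI)`` of M1 mass to samples below the RSI
    threshold before renormalising the immune simplex; survival is
    exponential with the hazard multiplied by ``hazard_ratio_high`` for the
    latent RSI-High group.
    """

    n_samples: int = 600
    n_background_genes: int = 500
    subtype_proportions: dict[str, float] = field(
        default_factory=lambda: {"C1": 0.35, "C2": 0.25, "C3": 0.15,
                                 "C4": 0.10, "C5": 0.05, "C6": 0.10}
    )
    delta_rsi: float = 1.5
    rsi_shift_signs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_RSI_SHIFT_SIGNS)
    )
    delta_tcia: float = 2.0
    noise_sd: float = 1.0
    dirichlet_concentration: float = 1.0
    beta_m1: float = 0.1
    baseline_hazard: float = 0.1
    hazard_ratio_high: float = 0.5
    censoring_rate: float = 0.3
    rsi_threshold: float = RSI_THRESHOLD
    seed: int = 0

    def validate(self) -> None:
        props = self.subtype_proportions
        if set(props) - set(IMMUNE_SUBTYPES):
            raise ValidationError(f"unknown subtypes: {set(props) - set(IMMUNE_SUBTYPES)}")
        if abs(sum(props.values()) - 1.0) > 1e-9:
            raise ValidationError("subtype proportions must sum to 1")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be > 0")
        if self.dirichlet_concentration <= 0:
            raise ValidationError("Dirichlet concentration must be > 0")
        if self.baseline_hazard <= 0 or self.hazard_ratio_high <= 0:
            raise ValidationError("hazard parameters must be > 0")
        if not 0 <= self.censoring_rate < 1:
            raise ValidationError("censoring_rate must be in [0, 1)")
        if self.beta_m1 < 0:
            raise ValidationError("beta_m1 must be >= 0")


@dataclass
class SyntheticCohort:
    """Expression, labels, immune fractions and survival for one cohort."""

    expression: ExpressionMatrix
    subtypes: pd.Series
    immune_fractions: pd.DataFrame
    survival: pd.DataFrame  # sample_id, time, event
    truth: pd.DataFrame
    config: SyntheticConfig


def generate(
    config: SyntheticConfig,
    signature: WeightedSignature | None = None,
    tcia: GeneSet | None = None,
) -> SyntheticCohort:
    """Draw one cohort from the generating model (bitwise reproducible)."""
    config.validate()
    sig = signature or rsi_signature()
    gs = tcia or tcia_gene_set()
    rng = np.random.default_rng(config.seed)
    unknown = set(config.rsi_shift_signs) - set(sig.genes)
    if unknown:
        raise ValidationError(f"shift signs for genes outside the signature: {unknown}")

    n = config.n_samples
    sample_ids = [f"S{i:04d}" for i in range(n)]
    genes = list(sig.genes)
    genes += [g for g in gs.genes if g not in genes]
    genes += [f"BG{i:04d}" for i in range(config.n_background_genes)]

    subtype_names = list(config.subtype_proportions)
    subtypes = rng.choice(
        subtype_names, size=n, p=list(config.subtype_proportions.values())
    )
    is_c2 = subtypes == "C2"

    base = rng.normal(7.0, 2.0, size=len(genes))
    # signature genes share one baseline: their within-sample ranks are then
    # exchangeable under the null, so the RSI spans its permutation range and
    # both threshold groups are populated for any seed
    base[: len(sig.genes)] = 7.0
    X = base[:, None] + rng.normal(0.0, config.noise_sd, size=(len(genes), n))
    gene_index = {g: i for i, g in enumerate(genes)}
    for g, sign in config.rsi_shift_signs.items():
        X[gene_index[g], is_c2] += sign * config.delta_rsi * config.noise_sd
    for g in gs.genes:
        X[gene_index[g], is_c2] += config.delta_tcia * config.noise_sd

    expression = ExpressionMatrix(pd.DataFrame(X, index=genes, columns=sample_ids))
    rsi_table = score_matrix(expression, sig, config.rsi_threshold)
    rsi = rsi_table["rsi"].to_numpy()
    rsi_group = rsi_table["category"].to_numpy()

    cell_types = _lm22_cell_types()
    alpha = np.full(len(cell_types), config.dirichlet_concentration)
    fractions = rng.dirichlet(alpha, size=n)
    m1_idx = cell_types.index("Macrophages M1")
    below = rsi < config.rsi_threshold
    fractions[below, m1_idx] += config.beta_m1 * (config.rsi_threshold - rsi[below])
    fractions /= fractions.sum(axis=1, keepdims=True)
    immune = pd.DataFrame(fractions, index=sample_ids, columns=cell_types)
    immune.index.name = "sample_id"

    high = rsi_group == "RSI-High"
    hazard = config.baseline_hazard * np.where(high, config.hazard_ratio_high, 1.0)
    t_event = rng.exponential(1.0 / hazard)
    if config.censoring_rate > 0:
        # censoring rate calibrated against the baseline hazard; the realised
        # censored fraction varies with the group mix
        lam_c = config.baseline_hazard * config.censoring_rate / (1 - config.censoring_rate)
        t_cens = rng.exponential(1.0 / lam_c, size=n)
    else:
        t_cens = np.full(n, np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    survival = pd.DataFrame({"sample_id": sample_ids, "time": time, "event": event})

    truth = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "subtype": subtypes,
            "is_c2": is_c2,
            "rsi": rsi,
            "rsi_group": rsi_group,
            "hazard": hazard,
            "seed": config.seed,
        }
    )
    return SyntheticCohort(expression, pd.Series(subtypes, index=sample_ids,
                                                 name="subtype"),
                           immune, survival, truth, config)


def truth_report(cohort: SyntheticCohort) -> pd.DataFrame:
    """Ground-truth table (one row per sample) for recovery scoring."""
    return cohort.truth.copy()


def split_to_probes(
    m: ExpressionMatrix, n_probes: int = 2, seed: int = 0
) -> tuple[ExpressionMatrix, ProbeMap]:
    """Expand a gene-level matrix into probe-level rows for testing probe
    collapse: probe 1 keeps the gene value, further probes subtract
    positive noise, so a per-sample maximum collapse recovers the input."""
    rng = np.random.default_rng(seed)
    rows, ids, mapping = [], [], {}
    for g in m.gene_ids:
        base = m.data.loc[g].to_numpy()
        for k in range(n_probes):
            pid = f"{g}_p{k}"
            mapping[pid] = g
            ids.append(pid)
            rows.append(base if k == 0 else base - rng.exponential(1.0, base.size))
    probes = ExpressionMatrix(pd.DataFrame(rows, index=ids, columns=m.sample_ids))
    return probes, ProbeMap(mapping)


def null_config(**overrides) -> SyntheticConfig:
    """A no-signal configuration (all effects off) for null calibration."""
    cfg = SyntheticConfig(delta_rsi=0.0, delta_tcia=0.0, beta_m1=0.0,
                          hazard_ratio_high=1.0)
    return replace(cfg, **overrides) if overrides else cfg
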