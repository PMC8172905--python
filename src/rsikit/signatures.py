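"""Weighted gene signatures and gene-set registries.

A :class:`WeightedSignature` is an ordered gene list with per-gene linear
coefficients; the shipped RSI instance carries the ten radiosensitivity
genes and their published coefficients. Plain (unweighted) gene sets — such
as the 18-gene T-cell-inflamed activity (TCIA) list — load from GMT or YAML
and are user-overridable: referenced lists are configuration, not code.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .errors import ValidationError

__all__ = ["WeightedSignature", "GeneSet", "rsi_signature", "tcia_gene_set",
           "read_gene_sets_gmt", "read_signature_yaml"]


@dataclass(frozen=True)
class WeightedSignature:
    """Ordered gene list with per-gene real coefficients c_g."""

    name: str
    genes: tuple[str, ...]
    coefficients: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.coefficients):
            raise ValidationError("genes and coefficients differ in length")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("signature genes must be unique")

    def __len__(self) -> int:
        return len(self.genes)

    @property
    def coef_array(self) -> np.ndarray:
        return np.asarray(self.coefficients, dtype=float)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.genes, self.coefficients))


@dataclass(frozen=True)
class GeneSet:
    """Named unweighted gene set (|genes| >= 2, unique)."""

    name: str
    genes: tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"gene set {self.name}: duplicate genes")
        if len(self.genes) < 2:
            raise ValidationError(f"gene set {self.name}: needs >= 2 genes")


def read_signature_yaml(path: str | Path) -> WeightedSignature:
    """Load a weighted signature from a YAML registry entry
    (``name`` plus a ``genes: {symbol: coefficient}`` mapping)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    genes = doc["genes"]
    return WeightedSignature(
        name=str(doc.get("name", Path(path).stem)),
        genes=tuple(genes),
        coefficients=tuple(float(genes[g]) for g in genes),
    )


def read_gene_sets_gmt(path: str | Path) -> dict[str, GeneSet]:
    """Parse a GMT file (name, description, then tab-separated genes)."""
    sets: dict[str, GeneSet] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValidationError(f"malformed GMT line: {line[:60]!r}")
        name, desc, genes = fields[0], fields[1], tuple(fields[2:])
        sets[name] = GeneSet(name=name, genes=genes, description=desc)
    return sets


def rsi_signature() -> WeightedSignature:
    """The ten-gene RSI signature with its published rank coefficients."""
    with resources.as_file(
        resources.files("rsikit.data").joinpath("rsi_signature.yaml")
    ) as p:
        return read_signature_yaml(p)


def tcia_gene_set() -> GeneSet:
    """The default 18-gene T-cell-inflamed activity (TCIA) gene set."""
    with resources.as_file(
        resources.files("rsikit.data").joinpath("tcia_genes.gmt")
    ) as p:
        return read_gene_sets_gmt(p)["TCIA"]
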