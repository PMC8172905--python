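"""Expression-matrix I/O, probe collapsing and gene-symbol canonicalisation.

The in-memory container is :class:`ExpressionMatrix`, a thin wrapper around a
genes x samples :class:`pandas.DataFrame` of log-scale expression values.
TSV (header row = sample ids, first column = gene/probe id) is the reference
dialect; CSV and GCT 1.2 are supported for interoperability.
"""
from __future__ import annotations

import io as _io
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "ProbeMap",
    "AliasTable",
    "read_expression",
    "write_expression",
    "collapse_probes",
    "canonicalise_genes",
    "default_alias_table",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log-scale expression values.

    Row ids may be probes (before :func:`collapse_probes`) or gene symbols
    (after). Sample ids must be unique; row ids must be unique only after
    probe collapse.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        cols = self.data.columns
        if cols.duplicated().any():
            dupes = sorted(set(cols[cols.duplicated()]))
            raise ValidationError(f"duplicate sample ids: {dupes}")
        if self.data.shape[1] and self.data.isna().all(axis=0).any():
            bad = self.data.columns[self.data.isna().all(axis=0)].tolist()
            raise ValidationError(f"samples with all-missing values: {bad}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = list(genes)
        missing = [g for g in genes if g not in self.data.index]
        if missing:
            raise ValidationError(f"genes absent from matrix: {missing}")
        return ExpressionMatrix(self.data.loc[genes].copy())


@dataclass
class ProbeMap:
    """Many-to-one probe id -> gene symbol mapping."""

    mapping: dict[str, str]

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ProbeMap":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls(dict(zip(df.iloc[:, 0], df.iloc[:, 1])))


@dataclass
class AliasTable:
    """Legacy symbol -> canonical symbol mapping (a function; canonical
    symbols appear only on the right-hand side)."""

    mapping: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        canonical = set(self.mapping.values())
        bad = canonical & set(self.mapping.keys())
        if bad:
            raise ValidationError(f"canonical symbols used as aliases: {sorted(bad)}")

    def resolve(self, symbol: str) -> str:
        return self.mapping.get(symbol, symbol)


def default_alias_table() -> AliasTable:
    """Alias table shipped with the package (covers common legacy symbols
    such as c-JUN, PKC, Rel A, cABL, CD8, PD1, PDL1)."""
    ref = resources.files("rsikit.data").joinpath("gene_aliases.tsv")
    df = pd.read_csv(_io.StringIO(ref.read_text()), sep="\t", dtype=str)
    return AliasTable(dict(zip(df["alias"], df["canonical"])))


def _parse_gct(path: str | Path) -> pd.DataFrame:
    with open(path) as fh:
        version = fh.readline().strip()
        if version != "#1.2":
            raise ValidationError(f"unsupported GCT version line: {version!r}")
        sizes = fh.readline().split()
        n_rows, n_cols = int(sizes[0]), int(sizes[1])
        body = pd.read_csv(fh, sep="\t", index_col=0)
    body = body.drop(columns=["Description"], errors="ignore")
    if body.shape != (n_rows, n_cols):
        raise ValidationError(
            f"GCT size line {(n_rows, n_cols)} does not match body {body.shape}"
        )
    return body


def _check_duplicate_header(path: Path, sep: str, skip: int = 0) -> None:
    # pandas silently mangles duplicate column names, so inspect the raw header
    with open(path) as fh:
        for _ in range(skip):
            fh.readline()
        line = fh.readline()
        while line.startswith("#"):
            line = fh.readline()
    cols = line.rstrip("\n").split(sep)[1:]
    seen = [c for c in set(cols) if cols.count(c) > 1]
    if seen:
        raise ValidationError(f"duplicate sample ids: {sorted(seen)}")


def read_expression(path: str | Path, format: str | None = None) -> ExpressionMatrix:
    """Read an expression matrix from TSV, CSV or GCT 1.2.

    The first column holds gene/probe ids and the header row holds sample
    ids. Non-numeric cells become missing values. ``format`` defaults to the
    file extension.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "gct":
        _check_duplicate_header(path, "\t", skip=2)
        df = _parse_gct(path)
    elif fmt in ("tsv", "csv", "txt"):
        sep = "," if fmt == "csv" else "\t"
        _check_duplicate_header(path, sep)
        df = pd.read_csv(path, sep=sep, index_col=0, comment="#")
    else:
        raise ValidationError(f"unknown expression format: {fmt!r}")
    df = df.apply(pd.to_numeric, errors="coerce")
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df)


def write_expression(
    m: ExpressionMatrix, path: str | Path, format: str | None = None
) -> None:
    """Write a matrix as TSV/CSV (with a one-line provenance comment) or GCT 1.2."""
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt == "gct":
        with open(path, "w") as fh:
            fh.write("#1.2\n")
            fh.write(f"{m.shape[0]}\t{m.shape[1]}\n")
            out = m.data.copy()
            out.insert(0, "Description", "na")
            out.index.name = "Name"
            out.to_csv(fh, sep="\t")
    elif fmt in ("tsv", "csv"):
        sep = "," if fmt == "csv" else "\t"
        with open(path, "w") as fh:
            fh.write("# rsikit expression matrix, log-scale, genes x samples\n")
            m.data.to_csv(fh, sep=sep, index_label="gene_id")
    else:
        raise ValidationError(f"unknown expression format: {fmt!r}")


def collapse_probes(
    m: ExpressionMatrix, pm: ProbeMap, on_missing: str = "error"
) -> ExpressionMatrix:
    """Collapse probe-level rows to gene level by the per-sample maximum.

    Multiple probes mapping to one gene are reduced cell-wise to their
    maximum expression value; missing cells are ignored in the maximum and a
    gene missing in all probes for a sample stays missing. Probes absent
    from ``pm`` raise by default (``on_missing="drop"`` removes them).
    """
    if on_missing not in ("error", "drop"):
        raise ValueError("on_missing must be 'error' or 'drop'")
    known = m.data.index.isin(pm.mapping)
    if not known.all():
        unknown = sorted(set(m.data.index[~known]))
        if on_missing == "error":
            raise ValidationError(f"probes absent from probe map: {unknown}")
        logger.warning("dropping %d unmapped probes", len(unknown))
    kept = m.data.loc[known]
    genes = kept.index.map(pm.mapping.get)
    collapsed = kept.groupby(genes).max()  # skipna by default
    collapsed.index.name = m.data.index.name
    return ExpressionMatrix(collapsed)


def canonicalise_genes(
    names: Iterable[str], at: AliasTable | Mapping[str, str] | None = None
) -> list[str]:
    """Replace legacy symbols by canonical HGNC-style symbols.

    Unknown symbols pass through unchanged with a logged warning (warn-only
    contract: canonicalisation never fails).
    """
    if at is None:
        at = default_alias_table()
    if not isinstance(at, AliasTable):
        at = AliasTable(dict(at))
    out = []
    for name in names:
        resolved = at.resolve(name)
        if resolved == name and name not in at.mapping.values():
            logger.warning("symbol %r not in alias table; passed through", name)
        out.append(resolved)
    return out
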