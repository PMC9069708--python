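"""Expression tables: TSV I/O, RPKM normalization, and the background filter.

Matrices are genes x samples. Sample columns are named
``<celltype>_<age>_rep<k>`` (e.g. ``IHC_young_rep1``) and parsed into
(cell_type, age, replicate) descriptors on read. Values are either raw read
counts or RPKM (reads per kilobase of transcript per million mapped reads);
the ``kind`` flag records which. A gene is regarded as expressed in a
(cell_type, age) group when its mean replicate RPKM exceeds a background
cutoff (default 0.1 RPKM, strict inequality).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, FormatError

_SAMPLE_RE = re.compile(r"^(?P<cell>[A-Za-z0-9]+)_(?P<age>[A-Za-z0-9]+)_rep(?P<rep>\d+)$")

GENE_COLUMN = "gene_symbol"


@dataclass(frozen=True)
class SampleDescriptor:
    cell_type: str
    age: str
    replicate: int

    @property
    def name(self) -> str:
        return f"{self.cell_type}_{self.age}_rep{self.replicate}"


def parse_sample_name(name: str) -> SampleDescriptor:
    m = _SAMPLE_RE.match(name)
    if m is None:
        raise FormatError(
            f"sample name {name!r} does not match '<celltype>_<age>_rep<k>'"
        )
    return SampleDescriptor(m.group("cell"), m.group("age"), int(m.group("rep")))


@dataclass(frozen=True)
class Thresholds:
    """Classification thresholds for background and differential expression.

    background_rpkm: genes with mean replicate RPKM above this are expressed.
    log2fc_min: minimum |log2 fold change| (inclusive) for a DEG call.
    fdr_max: maximum BH-adjusted p (inclusive) for a DEG call.
    """

    background_rpkm: float = 0.1
    log2fc_min: float = 1.0
    fdr_max: float = 0.10

    def __post_init__(self) -> None:
        for name in ("background_rpkm", "log2fc_min", "fdr_max"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"threshold {name} must be positive")


@dataclass
class ExpressionMatrix:
    """Genes x samples table of counts or RPKM with parsed sample descriptors."""

    values: pd.DataFrame  # index: gene symbols; columns: sample names
    kind: Literal["counts", "rpkm"]
    gene_lengths: pd.Series | None = None  # bp, indexed by gene symbol
    samples: list[SampleDescriptor] = field(default_factory=list)

    def __post_init__(self) -> None:
        idx = self.values.index
        if idx.duplicated().any():
            dupes = sorted(set(idx[idx.duplicated()]))
            raise FormatError(f"duplicate gene symbols: {', '.join(map(str, dupes))}")
        if (self.values.to_numpy() < 0).any():
            raise FormatError("expression values must be non-negative")
        if not self.samples:
            self.samples = [parse_sample_name(c) for c in self.values.columns]

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    def group_columns(self, cell_type: str, age: str) -> list[str]:
        cols = [
            s.name
            for s in self.samples
            if s.cell_type == cell_type and s.age == age
        ]
        if not cols:
            raise ConfigurationError(f"no samples for group ({cell_type}, {age})")
        return cols

    def group_values(self, cell_type: str, age: str) -> pd.DataFrame:
        return self.values[self.group_columns(cell_type, age)]

    def cell_types(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.cell_type, None)
        return list(seen)

    def ages(self) -> list[str]:
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.age, None)
        return list(seen)


def read_matrix(path, kind: Literal["counts", "rpkm"] = "rpkm") -> ExpressionMatrix:
    """Read a TSV expression matrix (first column gene symbols, header row).

    Raises FormatError on an empty file, duplicate gene symbols, or any
    non-numeric cell (reported with its row and column).
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file") from None
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected gene column plus >=1 sample column")
    gene_col = df.columns[0]
    genes = df[gene_col]
    body = df.drop(columns=[gene_col])
    numeric = body.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & body.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric value {body.iat[r, c]!r} at gene "
            f"{genes.iloc[r]!r}, column {body.columns[c]!r}"
        )
    if numeric.isna().to_numpy().any():
        raise FormatError(f"{path}: missing values are not allowed")
    numeric.index = pd.Index(genes, name=GENE_COLUMN)
    return ExpressionMatrix(values=numeric, kind=kind)


def write_matrix(matrix: ExpressionMatrix, path) -> None:
    out = matrix.values.copy()
    out.index.name = GENE_COLUMN
    out.to_csv(path, sep="\t")


def compute_rpkm(
    counts: ExpressionMatrix,
    library_sizes: Mapping[str, float] | pd.Series,
) -> ExpressionMatrix:
    """RPKM = count * 1e9 / (gene_length_bp * library_size)."""
    if counts.kind != "counts":
        raise ConfigurationError("compute_rpkm expects a counts matrix")
    if counts.gene_lengths is None:
        raise ConfigurationError("gene lengths are required to compute RPKM")
    lengths = counts.gene_lengths.reindex(counts.genes)
    if lengths.isna().any():
        missing = list(lengths.index[lengths.isna()])
        raise ConfigurationError(
            f"missing gene lengths for: {', '.join(map(str, missing[:10]))}"
            + ("..." if len(missing) > 10 else "")
        )
    lib = pd.Series(dict(library_sizes) if not isinstance(library_sizes, pd.Series) else library_sizes)
    lib = lib.reindex(counts.values.columns)
    if lib.isna().any() or (lib <= 0).any():
        raise ConfigurationError("library sizes must be positive and cover every sample")
    rpkm = counts.values * 1e9
    rpkm = rpkm.div(lengths.to_numpy(), axis=0).div(lib.to_numpy(), axis=1)
    return ExpressionMatrix(
        values=rpkm, kind="rpkm", gene_lengths=counts.gene_lengths, samples=list(counts.samples)
    )


def filter_expressed(
    matrix: ExpressionMatrix,
    group: tuple[str, str],
    thresholds: Thresholds = Thresholds(),
    mode: Literal["mean", "any"] = "mean",
) -> tuple[set[str], int]:
    """Genes expressed in one (cell_type, age) group, plus the count.

    ``mean`` (default): mean replicate RPKM > background_rpkm (strict).
    ``any``: any single replicate exceeds the cutoff.
    """
    if matrix.kind != "rpkm":
        raise ConfigurationError("filter_expressed operates on RPKM values")
    vals = matrix.group_values(*group)
    if mode == "mean":
        over = vals.mean(axis=1) > thresholds.background_rpkm
    elif mode == "any":
        over = (vals > thresholds.background_rpkm).any(axis=1)
    else:
        raise ConfigurationError(f"unknown expressed mode {mode!r}")
    expressed = set(matrix.genes[over])
    return expressed, len(expressed)


def write_gene_set(genes: Iterable[str], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in sorted(genes):
            fh.write(f"{g}\n")
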