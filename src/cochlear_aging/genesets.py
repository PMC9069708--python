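"""Ranked top-N gene lists, cross-table set logic, and over-representation.

Operates on DEG tables produced by :func:`cochlear_aging.degs.classify_deg`
(indexed by gene, with ``log2fc`` and ``status`` columns). "Top" lists are
ranked by fold-change magnitude: common lists between two cell types use the
smaller of the two |log2fc| values (a gene is only as interesting as its
weaker change), single-table lists use |log2fc|; ties break lexicographically
on the gene symbol. Over-representation of a category within a hit list uses
the upper-tail hypergeometric probability.
"""

from __future__ import annotations

from collections.abc import Mapping
from typing import Iterable, Literal, Sequence

import pandas as pd
from scipy import stats

from .errors import ConfigurationError, FormatError
from .degs import bh_fdr

__all__ = [
    "GeneAnnotation",
    "rank_top_common",
    "concordant_subset",
    "exclusive_top",
    "hypergeom_enrichment",
    "enrich_categories",
    "write_ranked_list",
]

Direction = Literal["up", "down"]


class GeneAnnotation(Mapping):
    """Total gene -> category-set lookup; unknown genes map to the empty set.

    Categories follow the field's functional groupings (aging/longevity,
    oxidative stress, transcription factor, autophagy, DNA damage/repair,
    stereocilia, ion channel, synapse, ...); any non-empty string is valid.
    """

    def __init__(self, mapping: Mapping[str, Iterable[str]]):
        self._map: dict[str, frozenset[str]] = {}
        for gene, cats in mapping.items():
            cats = frozenset(cats)
            if any(not c or not isinstance(c, str) for c in cats):
                raise FormatError(f"empty or non-string category for gene {gene!r}")
            self._map[gene] = cats

    @classmethod
    def from_tsv(cls, path) -> "GeneAnnotation":
        """Two-column TSV: gene <tab> category (one pair per line)."""
        pairs: dict[str, set[str]] = {}
        with open(path, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 2:
                    raise FormatError(f"{path}:{lineno}: expected 2 tab-separated fields")
                pairs.setdefault(fields[0], set()).add(fields[1])
        return cls(pairs)

    def __getitem__(self, gene: str) -> frozenset[str]:
        return self._map.get(gene, frozenset())

    def __iter__(self):
        return iter(self._map)

    def __len__(self) -> int:
        return len(self._map)

    def category_members(self, category: str) -> set[str]:
        return {g for g, cats in self._map.items() if category in cats}

    def categories(self) -> set[str]:
        return set().union(*self._map.values()) if self._map else set()


def _require_direction(direction: str) -> None:
    if direction not in ("up", "down"):
        raise ConfigurationError(f"direction must be 'up' or 'down', got {direction!r}")


def rank_top_common(
    deg_a: pd.DataFrame, deg_b: pd.DataFrame, direction: Direction, n: int
) -> list[str]:
    """Genes with the given status in both tables, ranked by the smaller
    |log2fc| of the pair (descending), ties lexicographic; at most n."""
    _require_direction(direction)
    if n <= 0:
        raise ConfigurationError("n must be positive")
    common = sorted(
        set(deg_a.index[deg_a["status"] == direction])
        & set(deg_b.index[deg_b["status"] == direction])
    )
    key = {
        g: min(abs(deg_a.at[g, "log2fc"]), abs(deg_b.at[g, "log2fc"])) for g in common
    }
    common.sort(key=lambda g: (-key[g], g))
    return common[:n]


def concordant_subset(
    gene_list: Sequence[str], reference_deg: pd.DataFrame, direction: Direction
) -> list[str]:
    """Members whose status in the reference table equals ``direction``,
    input order preserved."""
    _require_direction(direction)
    ref = reference_deg["status"] if len(reference_deg) else pd.Series(dtype=object)
    return [g for g in gene_list if g in ref.index and ref[g] == direction]


def exclusive_top(
    deg_this: pd.DataFrame,
    deg_other: pd.DataFrame,
    direction: Direction,
    n: int,
    mode: Literal["exclusive", "intersection"] = "exclusive",
) -> list[str]:
    """Top-n genes changed in one table relative to another, by |log2fc|.

    ``exclusive`` (default): status == direction here and ns/not_expressed
    (or absent) in the other table — cell-type-specific changes.
    ``intersection``: direction in both tables — e.g. overlap between an
    aging DEG table and an independent (noise-exposure) DEG table.
    """
    _require_direction(direction)
    if n <= 0:
        raise ConfigurationError("n must be positive")
    mine = deg_this.index[deg_this["status"] == direction]
    other_status = deg_other["status"] if len(deg_other) else pd.Series(dtype=object)
    if mode == "exclusive":
        keep = [
            g
            for g in mine
            if g not in other_status.index
            or other_status[g] in ("ns", "not_expressed")
        ]
    elif mode == "intersection":
        keep = [g for g in mine if g in other_status.index and other_status[g] == direction]
    else:
        raise ConfigurationError(f"unknown mode {mode!r}")
    keep.sort(key=lambda g: (-abs(deg_this.at[g, "log2fc"]), g))
    return keep[:n]


def hypergeom_enrichment(
    hits: set[str], category: set[str], universe: set[str]
) -> tuple[float, int]:
    """Upper-tail hypergeometric P(X >= overlap) and the overlap count.

    X ~ Hypergeom(|universe|, |category|, |hits|): drawing |hits| genes
    without replacement, X of them in the category.
    """
    if not universe:
        raise ConfigurationError("universe must be non-empty")
    if not hits <= universe:
        raise ConfigurationError("hits must be a subset of the universe")
    if not category <= universe:
        raise ConfigurationError("category must be a subset of the universe")
    overlap = len(hits & category)
    p = float(stats.hypergeom.sf(overlap - 1, len(universe), len(category), len(hits)))
    return p, overlap


def enrich_categories(
    hits: set[str], annotation: GeneAnnotation, universe: set[str]
) -> pd.DataFrame:
    """Per-category over-representation with BH FDR across categories.

    Categories are restricted to their members inside the universe. Columns:
    category, overlap, category_size, p, fdr; sorted by p then category.
    """
    rows = []
    for cat in sorted(annotation.categories()):
        members = annotation.category_members(cat) & universe
        if not members:
            continue
        p, overlap = hypergeom_enrichment(hits, members, universe)
        rows.append(
            {"category": cat, "overlap": overlap, "category_size": len(members), "p": p}
        )
    df = pd.DataFrame(rows, columns=["category", "overlap", "category_size", "p"])
    if len(df):
        df["fdr"] = bh_fdr(df["p"].to_numpy())
        df = df.sort_values(["p", "category"]).reset_index(drop=True)
    else:
        df["fdr"] = []
    return df


def write_ranked_list(genes: Sequence[str], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("rank\tgene\n")
        for i, g in enumerate(genes, 1):
            fh.write(f"{i}\t{g}\n")
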