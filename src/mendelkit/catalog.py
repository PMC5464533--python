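"""Gene and disease catalogs (HGNC/OMIM/CGD-like) with search and panels.

Catalogs are plain TSV files. Gene catalog: columns ``symbol``, ``name``.
Disease catalog: columns ``disease_name``, ``source`` (omim|cgd),
``inheritance`` (AD/AR/XL/other or empty), ``genes`` (semicolon-separated
symbols). Gene identity is by uppercase symbol string.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

from .errors import CatalogError

__all__ = [
    "GeneEntry",
    "DiseaseEntry",
    "GenePanel",
    "GeneCatalog",
    "DiseaseCatalog",
    "load_gene_catalog",
    "load_disease_catalog",
    "search_diseases",
    "panel_from_diseases",
    "known_disease_genes",
]


@dataclass(frozen=True)
class GeneEntry:
    symbol: str
    name: str


@dataclass(frozen=True)
class DiseaseEntry:
    disease_name: str
    source: str  # "omim" | "cgd"
    gene_symbols: tuple[str, ...]
    inheritance: Optional[str] = None


@dataclass(frozen=True)
class GenePanel:
    label: str
    symbols: frozenset

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.symbols


@dataclass
class GeneCatalog:
    entries: dict = field(default_factory=dict)  # symbol -> GeneEntry

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.entries

    def lookup(self, symbol: str) -> GeneEntry:
        return self.entries[symbol.upper()]

    def search(self, query: str) -> list[GeneEntry]:
        """Case-insensitive substring search over symbols and names."""
        q = query.strip().lower()
        if not q:
            return []
        return sorted(
            (e for e in self.entries.values()
             if q in e.symbol.lower() or q in e.name.lower()),
            key=lambda e: e.symbol,
        )


@dataclass
class DiseaseCatalog:
    entries: list = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


def load_gene_catalog(path) -> GeneCatalog:
    """Load a two-column (symbol, name) TSV; duplicate symbols are an error."""
    frame = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"symbol", "name"}
    if not required.issubset(frame.columns):
        raise CatalogError(
            f"gene catalog {path!r} must have columns {sorted(required)}, "
            f"found {list(frame.columns)}"
        )
    catalog = GeneCatalog()
    for row in frame.itertuples(index=False):
        symbol = row.symbol.strip().upper()
        if symbol in catalog.entries:
            raise CatalogError(f"duplicate gene symbol {symbol!r} in {path!r}")
        catalog.entries[symbol] = GeneEntry(symbol=symbol, name=row.name)
    return catalog


def load_disease_catalog(path) -> DiseaseCatalog:
    """Load a disease TSV (disease_name, source, inheritance, genes)."""
    frame = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"disease_name", "source", "inheritance", "genes"}
    if not required.issubset(frame.columns):
        raise CatalogError(
            f"disease catalog {path!r} must have columns {sorted(required)}, "
            f"found {list(frame.columns)}"
        )
    catalog = DiseaseCatalog()
    for row in frame.itertuples(index=False):
        genes = tuple(
            g.strip().upper() for g in row.genes.split(";") if g.strip()
        )
        if not genes:
            raise CatalogError(
                f"disease {row.disease_name!r} in {path!r} lists no genes"
            )
        catalog.entries.append(DiseaseEntry(
            disease_name=row.disease_name,
            source=row.source.strip().lower(),
            gene_symbols=genes,
            inheritance=row.inheritance.strip() or None,
        ))
    return catalog


def search_diseases(catalog: DiseaseCatalog, query: str) -> list[DiseaseEntry]:
    """Find diseases by name substring or by exact gene symbol.

    Matching is case-insensitive: a disease is returned when the query is a
    substring of its name or equals one of its gene symbols. Results are
    sorted by disease name; an empty query returns nothing.
    """
    q = query.strip().lower()
    if not q:
        return []
    hits = [
        e for e in catalog
        if q in e.disease_name.lower()
        or any(q == g.lower() for g in e.gene_symbols)
    ]
    return sorted(hits, key=lambda e: e.disease_name)


def panel_from_diseases(selection: Iterable[DiseaseEntry]) -> GenePanel:
    """Union of gene symbols over the selected diseases."""
    selection = list(selection)
    if not selection:
        raise CatalogError("cannot build a gene panel from an empty selection")
    symbols = frozenset(g for e in selection for g in e.gene_symbols)
    label = "; ".join(e.disease_name for e in selection[:3])
    if len(selection) > 3:
        label += f" (+{len(selection) - 3} more)"
    return GenePanel(label=label, symbols=symbols)


def known_disease_genes(*catalogs: DiseaseCatalog) -> GenePanel:
    """All gene symbols across the supplied disease catalogs (OMIM+CGD-like)."""
    symbols = frozenset(
        g for catalog in catalogs for e in catalog for g in e.gene_symbols
    )
    if not symbols:
        warnings.warn("disease catalogs are empty; known-gene panel is empty",
                      stacklevel=2)
    return GenePanel(label="known disease genes", symbols=symbols)
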