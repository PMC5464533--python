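"""Shared variant data model.

A :class:`VariantSet` holds the raw meta-header lines, the sample list and an
ordered list of :class:`VariantRecord`. Records keep INFO values typed
according to the header declarations: fields declared with Number 0 or 1 are
scalars, every other Number is canonically a tuple (even when it has one
element), and a missing element (``.``) is ``None``. This canonical form makes
``parse ∘ write`` an exact identity and makes per-alt annotation of
multiallelic records unambiguous.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

#: Natural human-genome chromosome order: 1..22, X, Y, MT; anything else after.
CHROM_RANK = {str(i): i for i in range(1, 23)}
CHROM_RANK.update({"X": 23, "Y": 24, "MT": 25})

_CHR_PREFIX = re.compile(r"^chr", re.IGNORECASE)
ALLELE_RE = re.compile(r"^[ACGTN*]+$")

ZYG_HOM_REF = "hom_ref"
ZYG_HET = "het"
ZYG_HOM_ALT = "hom_alt"
ZYG_HEMI = "hemi"
ZYG_MISSING = "missing"


def strip_chr_prefix(chrom: str) -> str:
    """Remove a leading ``chr``/``Chr``/``CHR`` from a chromosome label."""
    return _CHR_PREFIX.sub("", chrom)


def chrom_sort_key(chrom: str) -> tuple:
    """Sort key placing 1..22, X, Y, MT first, unknown contigs after, by name."""
    rank = CHROM_RANK.get(chrom)
    if rank is None:
        return (26, chrom)
    return (rank, "")


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's call at one site.

    ``allele_indices`` is ``None`` for a missing genotype (``./.`` or any
    partially missing call); a single index encodes a hemizygous call.
    """

    allele_indices: Optional[tuple[int, ...]]
    phased: bool = False
    depth: Optional[int] = None
    genotype_quality: Optional[int] = None

    @property
    def is_missing(self) -> bool:
        return self.allele_indices is None

    @property
    def carries_alt(self) -> bool:
        return self.allele_indices is not None and any(
            i > 0 for i in self.allele_indices
        )

    def zygosity(self) -> str:
        """Classify the call: hom_ref / het / hom_alt / hemi / missing.

        A single-allele call counts as hemizygous when it carries an alternate
        allele and as hom_ref when it is the reference allele.
        """
        idx = self.allele_indices
        if idx is None:
            return ZYG_MISSING
        if len(idx) == 1:
            return ZYG_HEMI if idx[0] > 0 else ZYG_HOM_REF
        if all(i == 0 for i in idx):
            return ZYG_HOM_REF
        first = idx[0]
        if first > 0 and all(i == first for i in idx):
            return ZYG_HOM_ALT
        return ZYG_HET


@dataclass
class VariantRecord:
    """One VCF data line.

    ``chrom`` carries no ``chr`` prefix after sanity checking. ``info`` is an
    ordered mapping key -> typed value (``True`` for flags, scalar, or tuple
    for multi-valued fields). ``calls`` maps sample name -> GenotypeCall in
    header sample order.
    """

    chrom: str
    pos: int
    ids: tuple[str, ...]
    ref: str
    alts: tuple[str, ...]
    qual: Optional[float]
    filter_status: Optional[tuple[str, ...]]
    info: dict
    calls: dict
    line: Optional[int] = field(default=None, compare=False)

    @property
    def key(self) -> tuple:
        """Identity of the variant: (chrom, pos, ref, alts)."""
        return (self.chrom, self.pos, self.ref, self.alts)

    @property
    def sort_key(self) -> tuple:
        return (chrom_sort_key(self.chrom), self.pos, self.ref, self.alts)

    def allele_string(self, index: int) -> str:
        """Map a genotype allele index to its allele sequence."""
        return self.ref if index == 0 else self.alts[index - 1]

    def per_alt_value(self, key: str, alt_index: int):
        """INFO value applying to the ``alt_index``-th alternate allele.

        Tuples are indexed per-alt; a scalar applies to every alt; missing
        entries and absent keys return ``None``.
        """
        value = self.info.get(key)
        if isinstance(value, tuple):
            return value[alt_index] if alt_index < len(value) else None
        return value

    def copy(self) -> "VariantRecord":
        return replace(
            self, ids=self.ids, info=dict(self.info), calls=dict(self.calls)
        )


# Recognized VCF INFO scalar types and their converters.
_INFO_CASTS = {
    "Integer": int,
    "Float": float,
    "String": str,
    "Character": str,
}

_INFO_META_RE = re.compile(
    r"^##INFO=<ID=(?P<id>[^,>]+),Number=(?P<number>[^,>]+),Type=(?P<type>[^,>]+)"
)


@dataclass(frozen=True)
class InfoDefinition:
    key: str
    number: str  # "0", "1", "A", "R", "G", "." or an integer literal
    type: str

    @property
    def is_flag(self) -> bool:
        return self.type == "Flag" or self.number == "0"

    @property
    def is_scalar(self) -> bool:
        return self.number == "1"

    def convert_token(self, token: str):
        if token == ".":
            return None
        cast = _INFO_CASTS.get(self.type, str)
        try:
            return cast(token)
        except ValueError:
            return token


@dataclass
class VariantSet:
    """An in-memory VCF: meta-header lines, sample names, ordered records."""

    meta: list[str] = field(default_factory=list)
    samples: list[str] = field(default_factory=list)
    records: list[VariantRecord] = field(default_factory=list)

    def info_definitions(self) -> dict[str, InfoDefinition]:
        defs: dict[str, InfoDefinition] = {}
        for line in self.meta:
            m = _INFO_META_RE.match(line)
            if m:
                defs[m.group("id")] = InfoDefinition(
                    m.group("id"), m.group("number"), m.group("type")
                )
        return defs

    def ensure_info_definition(
        self, key: str, number: str, type_: str, description: str = ""
    ) -> None:
        """Append an ##INFO declaration if ``key`` is not declared yet."""
        if key in self.info_definitions():
            return
        self.meta.append(
            f'##INFO=<ID={key},Number={number},Type={type_},'
            f'Description="{description}">'
        )

    def sorted_records(self) -> list[VariantRecord]:
        return sorted(self.records, key=lambda r: r.sort_key)

    def subset_samples(self, names: Iterable[str]) -> "VariantSet":
        """Project onto a subset of samples (records keep all sites)."""
        names = list(names)
        missing = [n for n in names if n not in self.samples]
        if missing:
            raise KeyError(f"unknown sample(s): {', '.join(missing)}")
        records = []
        for rec in self.records:
            new = rec.copy()
            new.calls = {n: rec.calls[n] for n in names}
            records.append(new)
        return VariantSet(meta=list(self.meta), samples=names, records=records)
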