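"""Annotate a target VCF from reference panels.

Two panel kinds are supported:

* ``vcf-panel`` — a coordinate-sorted, sites-only VCF (population frequency
  panel, dbSNP-like catalog, known-mutation list). Matching is allele-exact:
  chrom, pos and ref must be equal and the target alt must appear among the
  panel row's alts.
* ``score-table`` — a tab-separated table with columns
  ``#chrom pos ref alt <score>...`` (dbNSFP-like per-allele pathogenicity
  scores), matched on (chrom, pos, ref, alt).

Panels are bgzip-compressed and tabix-indexed (via pysam) so lookups are
sublinear in panel size; a plain-text panel is compressed and indexed in
place on first use. Copied fields are namespaced ``<panel>_<field>`` in the
target INFO column and stored per-alt, so multiallelic target records are
annotated without being decomposed. A name collision with an existing INFO
key is a hard error, never a silent overwrite.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import pysam
import yaml

from .errors import AnnotationError, PanelError
from .records import (
    InfoDefinition,
    VariantRecord,
    VariantSet,
    chrom_sort_key,
    strip_chr_prefix,
)
from .vcf_core import _parse_info  # shared INFO tokenizer

__all__ = [
    "ReferencePanel",
    "AnnotationConfig",
    "PanelIndex",
    "PanelRow",
    "build_index",
    "annotate_with_panel",
    "annotate_scores",
    "annotate_all",
    "dbsnp_build_of",
]

VCF_PANEL = "vcf-panel"
SCORE_TABLE = "score-table"

#: Default INFO key in which the dbSNP-like panel's first-build lives after
#: annotation by a panel named ``dbsnp`` with copy field ``build``.
DBSNP_BUILD_FIELD = "dbsnp_build"


@dataclass(frozen=True)
class ReferencePanel:
    """A named annotation source with field-copy rules.

    ``name`` becomes the INFO prefix for every copied field and must match
    ``[a-z0-9_]+``. ``id_fill`` unions the panel's variant identifiers (rs
    numbers) into the target ID column on match.
    """

    name: str
    kind: str
    path: Union[str, os.PathLike]
    copy_fields: tuple[str, ...]
    id_fill: bool = False

    def __post_init__(self):
        import re

        if not re.fullmatch(r"[a-z0-9_]+", self.name):
            raise PanelError(
                f"panel name {self.name!r} must match [a-z0-9_]+"
            )
        if self.kind not in (VCF_PANEL, SCORE_TABLE):
            raise PanelError(f"unknown panel kind {self.kind!r}")
        if not self.copy_fields:
            raise PanelError(f"panel {self.name!r} has no copy_fields")


@dataclass
class AnnotationConfig:
    """Ordered list of panels; prefixes must be unique."""

    panels: list[ReferencePanel] = field(default_factory=list)

    def __post_init__(self):
        names = [p.name for p in self.panels]
        if len(set(names)) != len(names):
            raise PanelError(f"duplicate panel names in config: {names}")

    @classmethod
    def from_yaml(cls, path) -> "AnnotationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        base = os.path.dirname(os.path.abspath(path))
        panels = []
        for entry in raw.get("panels", []):
            panel_path = entry["path"]
            if not os.path.isabs(panel_path):
                panel_path = os.path.join(base, panel_path)
            panels.append(ReferencePanel(
                name=entry["name"],
                kind=entry["kind"],
                path=panel_path,
                copy_fields=tuple(entry["copy_fields"]),
                id_fill=bool(entry.get("id_fill", False)),
            ))
        return cls(panels=panels)


@dataclass(frozen=True)
class PanelRow:
    chrom: str
    pos: int
    ids: tuple[str, ...]
    ref: str
    alts: tuple[str, ...]
    values: dict  # field name -> scalar or per-alt tuple


def _check_sorted(rows: Sequence[tuple[str, int]], path) -> None:
    previous = None
    for i, (chrom, pos) in enumerate(rows, start=1):
        key = (chrom_sort_key(chrom), pos)
        if previous is not None and key < previous:
            raise PanelError(
                f"panel {path!r} is not coordinate-sorted: row {i} "
                f"({chrom}:{pos}) is out of order"
            )
        previous = key


class PanelIndex:
    """Tabix-backed random access to one reference panel.

    ``query(chrom, start, end)`` returns all rows overlapping the 1-based
    closed interval, parsed into :class:`PanelRow`.
    """

    def __init__(self, panel: ReferencePanel):
        self.panel = panel
        self._gz_path = self._prepare(panel)
        self._tabix = pysam.TabixFile(self._gz_path)
        if panel.kind == VCF_PANEL:
            header = [l for l in self._tabix.header]
            self._info_defs = VariantSet(meta=header).info_definitions()
            self._columns: list[str] = []
        else:
            header = [l for l in self._tabix.header if l.startswith("#")]
            if not header:
                raise PanelError(
                    f"score table {panel.path!r} lacks a '#chrom pos ref alt "
                    "...' header line"
                )
            self._columns = header[-1].lstrip("#").split("\t")
            self._info_defs = {}

    @staticmethod
    def _prepare(panel: ReferencePanel) -> str:
        path = str(panel.path)
        if path.endswith(".gz"):
            gz_path = path
        else:
            gz_path = path + ".gz"
            if not os.path.exists(gz_path) or (
                os.path.getmtime(gz_path) < os.path.getmtime(path)
            ):
                PanelIndex._verify_sorted_text(path)
                pysam.tabix_compress(path, gz_path, force=True)
        if not os.path.exists(gz_path + ".tbi") or (
            os.path.getmtime(gz_path + ".tbi") < os.path.getmtime(gz_path)
        ):
            try:
                if panel.kind == VCF_PANEL:
                    pysam.tabix_index(gz_path, preset="vcf", force=True)
                else:
                    pysam.tabix_index(
                        gz_path, seq_col=0, start_col=1, end_col=1,
                        meta_char="#", force=True, zerobased=False,
                    )
            except OSError as exc:
                raise PanelError(
                    f"cannot index panel {panel.path!r}: {exc}"
                ) from exc
        return gz_path

    @staticmethod
    def _verify_sorted_text(path: str) -> None:
        coords = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    continue
                cols = line.split("\t", 2)
                if len(cols) < 2:
                    continue
                coords.append((cols[0], int(cols[1])))
        _check_sorted(coords, path)

    def _parse_row(self, line: str) -> PanelRow:
        cols = line.rstrip("\n").split("\t")
        if self.panel.kind == VCF_PANEL:
            chrom, pos_s, ids_s, ref, alt_s = cols[:5]
            info = _parse_info(cols[7] if len(cols) > 7 else ".",
                               self._info_defs)
            return PanelRow(
                chrom=strip_chr_prefix(chrom),
                pos=int(pos_s),
                ids=() if ids_s == "." else tuple(ids_s.split(";")),
                ref=ref,
                alts=() if alt_s == "." else tuple(alt_s.split(",")),
                values=info,
            )
        named = dict(zip(self._columns, cols))
        values = {}
        for col in self._columns[4:]:
            raw = named.get(col, ".")
            if raw in (".", ""):
                continue
            try:
                values[col] = float(raw)
            except ValueError:
                values[col] = raw
        return PanelRow(
            chrom=strip_chr_prefix(named["chrom"]),
            pos=int(named["pos"]),
            ids=(),
            ref=named["ref"],
            alts=(named["alt"],),
            values=values,
        )

    def query(self, chrom: str, start: int, end: int) -> list[PanelRow]:
        """All panel rows whose position lies in the closed interval."""
        try:
            lines = self._tabix.fetch(chrom, start - 1, end)
        except ValueError:  # contig absent from the index
            return []
        return [self._parse_row(line) for line in lines]

    def close(self) -> None:
        self._tabix.close()


def build_index(panel: ReferencePanel) -> PanelIndex:
    """Bgzip-compress (if needed), tabix-index and open a reference panel."""
    return PanelIndex(panel)


def _panel_value_for_alt(row: PanelRow, field_name: str, alt: str):
    """Value of ``field_name`` applying to ``alt`` within a panel row."""
    value = row.values.get(field_name)
    if value is None:
        return None
    if isinstance(value, tuple):
        try:
            return value[row.alts.index(alt)]
        except (ValueError, IndexError):
            return None
    return value


def _attach(record: VariantRecord, key: str, per_alt: list) -> None:
    if all(v is None for v in per_alt):
        return
    if key in record.info:
        raise AnnotationError(
            f"INFO key {key!r} already present at "
            f"{record.chrom}:{record.pos}; refusing to overwrite"
        )
    record.info[key] = tuple(per_alt)


def _declare_copied(vs: VariantSet, panel: ReferencePanel) -> None:
    for f in panel.copy_fields:
        vs.ensure_info_definition(
            f"{panel.name}_{f}", "A", "String",
            f"copied from panel {panel.name}",
        )


def _annotate_vcf_panel(
    target: VariantSet, panel: ReferencePanel, index: PanelIndex
) -> VariantSet:
    out = VariantSet(meta=list(target.meta), samples=list(target.samples))
    _declare_copied(out, panel)
    if panel.id_fill:
        pass  # IDs live in the ID column; no INFO declaration needed
    for rec in target.records:
        rows = [
            row for row in index.query(rec.chrom, rec.pos, rec.pos)
            if row.pos == rec.pos and row.ref == rec.ref
        ]
        new = rec.copy()
        matched_rows = []
        per_alt_rows: list[Optional[PanelRow]] = []
        for alt in rec.alts:
            hit = next((row for row in rows if alt in row.alts), None)
            per_alt_rows.append(hit)
            if hit is not None and hit not in matched_rows:
                matched_rows.append(hit)
        if matched_rows:
            for f in panel.copy_fields:
                per_alt = [
                    None if row is None else _panel_value_for_alt(row, f, alt)
                    for row, alt in zip(per_alt_rows, rec.alts)
                ]
                _attach(new, f"{panel.name}_{f}", per_alt)
            if panel.id_fill:
                merged = list(new.ids)
                for row in matched_rows:
                    for rsid in row.ids:
                        if rsid not in merged:
                            merged.append(rsid)
                new.ids = tuple(merged)
        out.records.append(new)
    return out


def _annotate_score_table(
    target: VariantSet, panel: ReferencePanel, index: PanelIndex
) -> VariantSet:
    out = VariantSet(meta=list(target.meta), samples=list(target.samples))
    _declare_copied(out, panel)
    for rec in target.records:
        rows = [
            row for row in index.query(rec.chrom, rec.pos, rec.pos)
            if row.pos == rec.pos and row.ref == rec.ref
        ]
        new = rec.copy()
        by_alt = {}
        for row in rows:
            by_alt.setdefault(row.alts[0], row)
        if any(alt in by_alt for alt in rec.alts):
            for f in panel.copy_fields:
                per_alt = [
                    by_alt[alt].values.get(f) if alt in by_alt else None
                    for alt in rec.alts
                ]
                _attach(new, f"{panel.name}_{f}", per_alt)
        out.records.append(new)
    return out


def annotate_with_panel(
    target: VariantSet, panel: ReferencePanel,
    index: Optional[PanelIndex] = None,
) -> VariantSet:
    """Annotate a target set from a sites-only reference VCF.

    For each target alt allele a panel row matches iff chrom, pos and ref
    are equal and the alt appears among the row's alts; each copy field is
    written to INFO as ``<panel>_<field>`` with per-alt alignment.
    Non-matching records are returned unchanged.
    """
    if panel.kind != VCF_PANEL:
        raise PanelError(f"panel {panel.name!r} is not a VCF panel")
    own = index is None
    index = index or build_index(panel)
    try:
        return _annotate_vcf_panel(target, panel, index)
    finally:
        if own:
            index.close()


def annotate_scores(
    target: VariantSet, panel: ReferencePanel,
    index: Optional[PanelIndex] = None,
) -> VariantSet:
    """Annotate from a per-allele score table, matching (chrom,pos,ref,alt).

    Scores absent from the table are omitted, never zero-filled.
    """
    if panel.kind != SCORE_TABLE:
        raise PanelError(f"panel {panel.name!r} is not a score table")
    own = index is None
    index = index or build_index(panel)
    try:
        return _annotate_score_table(target, panel, index)
    finally:
        if own:
            index.close()


def annotate_all(target: VariantSet, cfg: AnnotationConfig) -> VariantSet:
    """Apply every panel of the configuration in sequence.

    Because each panel writes only keys under its own unique prefix, the
    result is independent of panel order. A failure in any panel aborts the
    whole annotation, naming the panel.
    """
    names = [p.name for p in cfg.panels]
    if len(set(names)) != len(names):
        raise PanelError(f"duplicate panel names: {names}")
    current = target
    for panel in cfg.panels:
        try:
            if panel.kind == VCF_PANEL:
                current = annotate_with_panel(current, panel)
            else:
                current = annotate_scores(current, panel)
        except AnnotationError:
            raise
        except Exception as exc:
            raise AnnotationError(
                f"annotation failed in panel {panel.name!r}: {exc}"
            ) from exc
    return current


def dbsnp_build_of(
    record: VariantRecord, field_name: str = DBSNP_BUILD_FIELD
) -> Optional[int]:
    """First dbSNP build containing the variant, or None when unannotated.

    For multiallelic records annotated per-alt, the earliest present build is
    returned. A non-integer build value is an annotation-format error.
    """
    value = record.info.get(field_name)
    if value is None:
        return None
    values = value if isinstance(value, tuple) else (value,)
    builds = []
    for v in values:
        if v is None:
            continue
        if isinstance(v, bool) or not isinstance(v, (int, float, str)):
            raise AnnotationError(f"non-integer dbSNP build value {v!r}")
        try:
            builds.append(int(v))
        except (TypeError, ValueError):
            raise AnnotationError(f"non-integer dbSNP build value {v!r}")
    return min(builds) if builds else None
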