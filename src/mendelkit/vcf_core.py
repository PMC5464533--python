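"""Read, validate, normalize, write and summarize VCF data.

The reader is deliberately tolerant: it transcribes data lines into the data
model even when they violate the VCF contract (out-of-range genotype allele
indices, odd allele strings, undeclared INFO keys), because reporting those
problems is :func:`validate_vcf`'s job. The normalization step
(:func:`sanity_check`) mirrors the preprocessing applied to every uploaded
patient file: drop records in which no sample carries an alternate allele,
strip ``chr`` prefixes, delete stale effect-predictor INFO tags (EFF/ANN) and
sort by chromosome and position.
"""

from __future__ import annotations

import gzip
import io
import math
import os
from collections import Counter
from dataclasses import dataclass, field
from typing import Optional, Union

from .errors import VcfFormatError
from .records import (
    ALLELE_RE,
    GenotypeCall,
    InfoDefinition,
    VariantRecord,
    VariantSet,
    strip_chr_prefix,
)

__all__ = [
    "parse_vcf",
    "write_vcf",
    "validate_vcf",
    "sanity_check",
    "summarize",
    "SummaryStats",
    "FieldStats",
    "ValidationIssue",
    "ValidationReport",
    "GenotypeCall",
    "VariantRecord",
    "VariantSet",
]

#: INFO keys written by effect predictors that stale annotations may carry.
PRIOR_ANNOTATION_KEYS = ("EFF", "ANN")

_GZIP_MAGIC = b"\x1f\x8b"
_ZIP_MAGIC = b"PK"
_RAR_MAGIC = b"Rar!"


def _open_text(path) -> io.TextIOBase:
    with open(path, "rb") as fh:
        magic = fh.read(4)
    if magic[:2] == _GZIP_MAGIC:  # plain gzip and bgzip share the magic
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    if magic[:2] == _ZIP_MAGIC or magic == _RAR_MAGIC:
        raise OSError(f"unsupported compression format for {path!r}; "
                      "use plain or gzip/bgzip VCF")
    return open(path, "rt", encoding="utf-8")


def _parse_gt(token: str) -> tuple[Optional[tuple[int, ...]], bool]:
    phased = "|" in token
    parts = token.replace("|", "/").split("/")
    if any(p in ("", ".") for p in parts):
        return None, False
    try:
        return tuple(int(p) for p in parts), phased
    except ValueError:
        return None, False


def _parse_optional_int(token: str) -> Optional[int]:
    if token in (".", ""):
        return None
    try:
        return int(token)
    except ValueError:
        return None


def _parse_info(text: str, defs: dict[str, InfoDefinition]) -> dict:
    info: dict = {}
    if text == ".":
        return info
    for item in text.split(";"):
        if not item:
            continue
        if "=" not in item:
            info[item] = True
            continue
        key, _, raw = item.partition("=")
        definition = defs.get(key)
        if definition is None:
            info[key] = raw
        elif definition.is_flag:
            info[key] = True
        elif definition.is_scalar:
            info[key] = definition.convert_token(raw)
        else:
            info[key] = tuple(definition.convert_token(t) for t in raw.split(","))
    return info


def _parse_record(
    line: str,
    lineno: int,
    samples: list[str],
    defs: dict[str, InfoDefinition],
) -> VariantRecord:
    cols = line.rstrip("\n").split("\t")
    if len(cols) < 8:
        raise VcfFormatError(
            f"line {lineno}: expected at least 8 tab-separated columns, "
            f"found {len(cols)}"
        )
    chrom, pos_s, ids_s, ref, alt_s, qual_s, filt_s, info_s = cols[:8]
    try:
        pos = int(pos_s)
    except ValueError:
        raise VcfFormatError(f"line {lineno}: POS {pos_s!r} is not an integer")
    ids = () if ids_s == "." else tuple(ids_s.split(";"))
    alts = () if alt_s == "." else tuple(alt_s.split(","))
    qual = None if qual_s == "." else float(qual_s)
    filt = None if filt_s == "." else tuple(filt_s.split(";"))
    info = _parse_info(info_s, defs)

    calls: dict[str, GenotypeCall] = {}
    if samples:
        if len(cols) < 9 + len(samples):
            raise VcfFormatError(
                f"line {lineno}: {len(samples)} samples declared but only "
                f"{max(0, len(cols) - 9)} genotype columns present"
            )
        fmt_keys = cols[8].split(":")
        for name, raw in zip(samples, cols[9:]):
            values = dict(zip(fmt_keys, raw.split(":")))
            indices, phased = _parse_gt(values.get("GT", "."))
            calls[name] = GenotypeCall(
                allele_indices=indices,
                phased=phased,
                depth=_parse_optional_int(values.get("DP", ".")),
                genotype_quality=_parse_optional_int(values.get("GQ", ".")),
            )
    return VariantRecord(
        chrom=chrom, pos=pos, ids=ids, ref=ref, alts=alts, qual=qual,
        filter_status=filt, info=info, calls=calls, line=lineno,
    )


def parse_vcf(path: Union[str, os.PathLike]) -> VariantSet:
    """Parse a plain or gzip/bgzip-compressed VCF file into a VariantSet.

    The file must begin with ``##fileformat=VCF``; INFO values are typed
    according to the header ``##INFO`` declarations when present and kept as
    strings otherwise. Sample order is preserved. Zip/rar archives are
    rejected with an I/O error.
    """
    vs = VariantSet()
    defs: dict[str, InfoDefinition] = {}
    saw_column_header = False
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if lineno == 1:
                if not line.startswith("##fileformat=VCF"):
                    raise VcfFormatError(
                        f"line 1: file does not start with '##fileformat=VCF' "
                        f"(got {line[:40]!r})"
                    )
            if not line:
                continue
            if line.startswith("##"):
                if saw_column_header:
                    raise VcfFormatError(
                        f"line {lineno}: meta-header line after #CHROM header"
                    )
                vs.meta.append(line)
                continue
            if line.startswith("#"):
                cols = line.split("\t")
                if cols[:8] != ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL",
                                "FILTER", "INFO"]:
                    raise VcfFormatError(
                        f"line {lineno}: malformed #CHROM header line"
                    )
                vs.samples = cols[9:]
                saw_column_header = True
                defs = vs.info_definitions()
                continue
            if not saw_column_header:
                raise VcfFormatError(
                    f"line {lineno}: data line before #CHROM header"
                )
            vs.records.append(_parse_record(line, lineno, vs.samples, defs))
    if not saw_column_header:
        raise VcfFormatError("missing #CHROM header line")
    return vs


def _format_scalar(value) -> str:
    if value is None:
        return "."
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _format_info(info: dict) -> str:
    if not info:
        return "."
    parts = []
    for key, value in info.items():
        if value is True:
            parts.append(key)
        elif isinstance(value, tuple):
            parts.append(f"{key}=" + ",".join(_format_scalar(v) for v in value))
        else:
            parts.append(f"{key}={_format_scalar(value)}")
    return ";".join(parts)


def _format_call(call: GenotypeCall, keys: list[str]) -> str:
    fields = []
    for key in keys:
        if key == "GT":
            if call.allele_indices is None:
                fields.append("./.")
            else:
                sep = "|" if call.phased else "/"
                fields.append(sep.join(str(i) for i in call.allele_indices))
        elif key == "DP":
            fields.append("." if call.depth is None else str(call.depth))
        elif key == "GQ":
            fields.append(
                "." if call.genotype_quality is None
                else str(call.genotype_quality)
            )
    return ":".join(fields)


def _infer_info_declarations(vs: VariantSet) -> None:
    """Declare every INFO key used by the records, inferring Number/Type.

    Needed so that a programmatically built VariantSet round-trips with the
    same value types after write + parse.
    """
    defs = vs.info_definitions()
    seen: dict[str, list] = {}
    for rec in vs.records:
        for key, value in rec.info.items():
            if key in defs:
                continue
            seen.setdefault(key, []).append(value)
    for key, values in seen.items():
        flat = []
        multi = False
        for v in values:
            if isinstance(v, tuple):
                multi = True
                flat.extend(v)
            else:
                flat.append(v)
        present = [v for v in flat if v is not None]
        if all(v is True for v in present) and present:
            number, type_ = "0", "Flag"
        elif all(isinstance(v, int) and not isinstance(v, bool) for v in present):
            number, type_ = (".", "Integer") if multi else ("1", "Integer")
        elif all(isinstance(v, (int, float)) and not isinstance(v, bool)
                 for v in present):
            number, type_ = (".", "Float") if multi else ("1", "Float")
        else:
            number, type_ = (".", "String") if multi else ("1", "String")
        vs.ensure_info_definition(key, number, type_)


def write_vcf(vs: VariantSet, path: Union[str, os.PathLike]) -> None:
    """Write a VariantSet as a VCF 4.2 file (gzip-compressed for ``.gz``).

    Undeclared INFO keys get inferred ``##INFO`` declarations so that
    ``parse_vcf(write_vcf(vs))`` reproduces the records exactly.
    """
    _infer_info_declarations(vs)
    meta = list(vs.meta)
    if not any(l.startswith("##fileformat=") for l in meta):
        meta.insert(0, "##fileformat=VCFv4.2")
    header_cols = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER",
                   "INFO"]
    if vs.samples:
        header_cols += ["FORMAT"] + vs.samples

    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for line in meta:
            fh.write(line + "\n")
        fh.write("\t".join(header_cols) + "\n")
        for rec in vs.records:
            cols = [
                rec.chrom,
                str(rec.pos),
                ";".join(rec.ids) if rec.ids else ".",
                rec.ref,
                ",".join(rec.alts) if rec.alts else ".",
                _format_scalar(rec.qual),
                ";".join(rec.filter_status) if rec.filter_status else ".",
                _format_info(rec.info),
            ]
            if vs.samples:
                keys = ["GT"]
                if any(rec.calls[s].depth is not None for s in vs.samples):
                    keys.append("DP")
                if any(rec.calls[s].genotype_quality is not None
                       for s in vs.samples):
                    keys.append("GQ")
                cols.append(":".join(keys))
                cols += [_format_call(rec.calls[s], keys) for s in vs.samples]
            fh.write("\t".join(cols) + "\n")


@dataclass(frozen=True)
class ValidationIssue:
    severity: str  # "error" | "warning"
    code: str
    message: str
    line: Optional[int] = None


@dataclass
class ValidationReport:
    issues: list[ValidationIssue] = field(default_factory=list)

    @property
    def is_clean(self) -> bool:
        return not self.issues

    def errors(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "error"]

    def warnings(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "warning"]


def validate_vcf(vs: VariantSet) -> ValidationReport:
    """Check a parsed VariantSet and report problems without raising.

    Reported: unsorted adjacent record pairs, duplicate (chrom,pos,ref,alt),
    genotype allele indices out of range, alleles outside {A,C,G,T,N,*}, and
    INFO keys with no header declaration.
    """
    report = ValidationReport()
    defs = vs.info_definitions()
    seen_keys: set[tuple] = set()
    previous: Optional[VariantRecord] = None
    for rec in vs.records:
        where = rec.line
        if previous is not None and rec.sort_key < previous.sort_key:
            report.issues.append(ValidationIssue(
                "warning", "unsorted",
                f"record {rec.chrom}:{rec.pos} out of order after "
                f"{previous.chrom}:{previous.pos}", where,
            ))
        if rec.key in seen_keys:
            report.issues.append(ValidationIssue(
                "error", "duplicate",
                f"duplicate variant {rec.chrom}:{rec.pos} "
                f"{rec.ref}>{','.join(rec.alts)}", where,
            ))
        seen_keys.add(rec.key)
        for allele in (rec.ref, *rec.alts):
            if not ALLELE_RE.match(allele):
                report.issues.append(ValidationIssue(
                    "error", "bad_allele",
                    f"allele {allele!r} at {rec.chrom}:{rec.pos} is not a "
                    "string over A,C,G,T,N,*", where,
                ))
        for sample, call in rec.calls.items():
            if call.allele_indices is None:
                continue
            for idx in call.allele_indices:
                if idx < 0 or idx > len(rec.alts):
                    report.issues.append(ValidationIssue(
                        "error", "allele_index_out_of_range",
                        f"sample {sample} at {rec.chrom}:{rec.pos} has allele "
                        f"index {idx} but only {len(rec.alts)} ALT allele(s)",
                        where,
                    ))
        for key in rec.info:
            if key not in defs:
                report.issues.append(ValidationIssue(
                    "warning", "undeclared_info",
                    f"INFO key {key!r} at {rec.chrom}:{rec.pos} has no "
                    "##INFO declaration", where,
                ))
        previous = rec
    return report


def sanity_check(vs: VariantSet) -> VariantSet:
    """Normalize a VariantSet for annotation. Idempotent.

    Drops records in which every sample call is hom-ref or missing (records
    with no sample columns are retained), strips ``chr`` prefixes from
    chromosome names, deletes stale EFF/ANN annotation keys, and sorts by
    (chromosome in natural order, position, ref, alts).
    """
    records = []
    for rec in vs.records:
        if rec.calls and not any(c.carries_alt for c in rec.calls.values()):
            continue
        new = rec.copy()
        new.chrom = strip_chr_prefix(new.chrom)
        for key in PRIOR_ANNOTATION_KEYS:
            new.info.pop(key, None)
        records.append(new)
    records.sort(key=lambda r: r.sort_key)
    return VariantSet(meta=list(vs.meta), samples=list(vs.samples),
                      records=records)


@dataclass
class FieldStats:
    """Min/max/mean of a numeric field over its present values."""

    minimum: float
    maximum: float
    mean: float
    n: int


def _field_stats(values: list) -> Optional[FieldStats]:
    present = [v for v in values if v is not None]
    if not present:
        return None
    return FieldStats(
        minimum=min(present),
        maximum=max(present),
        mean=math.fsum(present) / len(present),
        n=len(present),
    )


@dataclass
class SummaryStats:
    total_variants: int
    novel_variants: int
    qual: Optional[FieldStats]
    depth: dict[str, Optional[FieldStats]]
    zygosity: dict[str, Counter]

    def to_dict(self) -> dict:
        def fs(stats):
            if stats is None:
                return None
            return {"min": stats.minimum, "max": stats.maximum,
                    "mean": stats.mean, "n": stats.n}

        return {
            "total_variants": self.total_variants,
            "novel_variants": self.novel_variants,
            "qual": fs(self.qual),
            "depth": {s: fs(d) for s, d in self.depth.items()},
            "zygosity": {s: dict(c) for s, c in self.zygosity.items()},
        }


def summarize(vs: VariantSet) -> SummaryStats:
    """Compute per-file metrics: totals, novel count, QUAL/DP stats, zygosity.

    A variant is *novel* when its ID column is empty (no external identifier,
    e.g. no dbSNP rs number). Statistics are computed over present values
    only; a field that is missing everywhere is reported as absent, not 0.
    """
    quals = [rec.qual for rec in vs.records]
    depth: dict[str, Optional[FieldStats]] = {}
    zygosity: dict[str, Counter] = {}
    for sample in vs.samples:
        depth[sample] = _field_stats(
            [rec.calls[sample].depth for rec in vs.records]
        )
        zygosity[sample] = Counter(
            rec.calls[sample].zygosity() for rec in vs.records
        )
    return SummaryStats(
        total_variants=len(vs.records),
        novel_variants=sum(1 for rec in vs.records if not rec.ids),
        qual=_field_stats(quals),
        depth=depth,
        zygosity=zygosity,
    )
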