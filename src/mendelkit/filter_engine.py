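"""Declarative variant filtering and Mendelian inheritance models.

``apply_filters`` evaluates a :class:`FilterSpec` as a conjunction of
criteria over annotated records; every active criterion must pass for a
record to survive. Allele-level criteria (population frequency, dbSNP build,
pathogenicity scores) are evaluated per alternate allele; a multiallelic
record survives when any of its alts survives them all.

A note on the frequency criterion: it excludes variants whose panel
frequency EXCEEDS the cutoff, keeping rare and panel-absent variants. This
is the behaviour required for Mendelian analysis (the pathogenic variant is
rare essentially by definition), even though "exclude variants with
frequency lower than X%" phrasings circulate for this kind of filter.

``filter_inheritance`` implements five segregation models over a trio (or a
proband alone, with graceful degradation): autosomal-recessive homozygous,
autosomal-recessive compound-heterozygous, autosomal-dominant heterozygous,
de novo, and X-linked hemizygous.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Union

import yaml

from .annotate import DBSNP_BUILD_FIELD
from .catalog import GenePanel
from .errors import FilterConfigError, PedigreeError
from .records import (
    GenotypeCall,
    VariantRecord,
    VariantSet,
    ZYG_HET,
    ZYG_HEMI,
    ZYG_HOM_ALT,
)

__all__ = [
    "FilterSpec",
    "Pedigree",
    "CandidateReport",
    "apply_filters",
    "genes_in_common",
    "filter_inheritance",
    "INHERITANCE_MODELS",
    "AR_HOM",
    "AR_COMPHET",
    "AD_HET",
    "DE_NOVO",
    "XL_HEMI",
]

#: INFO field conventions (gene symbol and consequence severity are consumed
#: from the input, produced upstream by an effect predictor or the synthetic
#: generator).
GENE_FIELD = "gene"
IMPACT_FIELD = "impact"
FUNCTIONAL_FIELD = "functional_class"
FREQUENCY_SUFFIX = "AF"

AR_HOM = "AR_HOM"
AR_COMPHET = "AR_COMPHET"
AD_HET = "AD_HET"
DE_NOVO = "DE_NOVO"
XL_HEMI = "XL_HEMI"
INHERITANCE_MODELS = (AR_HOM, AR_COMPHET, AD_HET, DE_NOVO, XL_HEMI)

VALID_ZYGOSITY = frozenset({ZYG_HOM_ALT, ZYG_HET, ZYG_HEMI})
VALID_IMPACTS = frozenset({"HIGH", "MODERATE", "LOW", "MODIFIER"})


@dataclass
class FilterSpec:
    """The full set of filter-analysis options as a declarative value.

    Every field is inactive when ``None`` (or empty); an inactive criterion
    excludes nothing. ``max_dbsnp_build`` EXCLUDES variants first catalogued
    in that dbSNP build or earlier. ``max_panel_frequency`` maps panel name
    to a frequency cutoff in [0,1]; ``score_thresholds`` maps an annotated
    score field to ``(direction, cutoff)`` with direction ``"le"`` or
    ``"ge"``. ``keep_unannotated_frequency`` keeps variants absent from a
    frequency panel (the default; panel absence is evidence of rarity).
    """

    zygosity: Optional[frozenset] = None
    impacts: Optional[frozenset] = None
    functional_classes: Optional[frozenset] = None
    min_depth: Optional[int] = None
    require_depth: bool = False
    min_qual: Optional[float] = None
    max_dbsnp_build: Optional[int] = None
    max_panel_frequency: dict = field(default_factory=dict)
    regions: Optional[tuple] = None  # ((chrom, start, end), ...) 1-based closed
    gene_panel: Optional[GenePanel] = None
    score_thresholds: dict = field(default_factory=dict)
    keep_unannotated_frequency: bool = True

    def __post_init__(self):
        if self.zygosity is not None:
            self.zygosity = frozenset(self.zygosity)
            bad = self.zygosity - VALID_ZYGOSITY
            if bad:
                raise FilterConfigError(f"invalid zygosity values: {sorted(bad)}")
        if self.impacts is not None:
            self.impacts = frozenset(self.impacts)
        if self.functional_classes is not None:
            self.functional_classes = frozenset(self.functional_classes)
        if self.min_depth is not None and self.min_depth < 0:
            raise FilterConfigError("min_depth must be >= 0")
        for panel, cutoff in self.max_panel_frequency.items():
            if not 0.0 <= cutoff <= 1.0:
                raise FilterConfigError(
                    f"frequency cutoff for panel {panel!r} must lie in [0,1], "
                    f"got {cutoff}"
                )
        if self.regions is not None:
            self.regions = tuple(
                (str(c), int(s), int(e)) for c, s, e in self.regions
            )
            for chrom, start, end in self.regions:
                if start > end:
                    raise FilterConfigError(
                        f"region {chrom}:{start}-{end} has start > end"
                    )
        for name, (direction, _) in self.score_thresholds.items():
            if direction not in ("le", "ge"):
                raise FilterConfigError(
                    f"score threshold direction for {name!r} must be 'le' or "
                    f"'ge', got {direction!r}"
                )

    def merged_with(self, overrides: Optional[dict]) -> "FilterSpec":
        """A copy with the given field overrides applied."""
        if not overrides:
            return replace(self)
        return replace(self, **overrides)

    # -- plain-text (YAML) serialization ------------------------------------

    def to_dict(self) -> dict:
        out: dict = {}
        for name in ("zygosity", "impacts", "functional_classes"):
            value = getattr(self, name)
            if value is not None:
                out[name] = sorted(value)
        for name in ("min_depth", "min_qual", "max_dbsnp_build"):
            value = getattr(self, name)
            if value is not None:
                out[name] = value
        if self.require_depth:
            out["require_depth"] = True
        if self.max_panel_frequency:
            out["max_panel_frequency"] = dict(self.max_panel_frequency)
        if self.regions is not None:
            out["regions"] = [list(r) for r in self.regions]
        if self.gene_panel is not None:
            out["gene_panel"] = {
                "label": self.gene_panel.label,
                "symbols": sorted(self.gene_panel.symbols),
            }
        if self.score_thresholds:
            out["score_thresholds"] = {
                k: list(v) for k, v in self.score_thresholds.items()
            }
        out["keep_unannotated_frequency"] = self.keep_unannotated_frequency
        return out

    @classmethod
    def from_dict(cls, raw: dict) -> "FilterSpec":
        kwargs = dict(raw)
        for name in ("zygosity", "impacts", "functional_classes"):
            if kwargs.get(name) is not None:
                kwargs[name] = frozenset(kwargs[name])
        if kwargs.get("regions") is not None:
            kwargs["regions"] = tuple(tuple(r) for r in kwargs["regions"])
        if kwargs.get("gene_panel") is not None:
            gp = kwargs["gene_panel"]
            kwargs["gene_panel"] = GenePanel(
                label=gp.get("label", "panel"),
                symbols=frozenset(gp["symbols"]),
            )
        if kwargs.get("score_thresholds"):
            kwargs["score_thresholds"] = {
                k: (v[0], float(v[1]))
                for k, v in kwargs["score_thresholds"].items()
            }
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "FilterSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class Pedigree:
    """Sample roles binding multi-sample data to inheritance models."""

    proband: str
    mother: Optional[str] = None
    father: Optional[str] = None
    affected_siblings: tuple = ()
    unaffected_members: tuple = ()
    sex_of_proband: str = "unknown"  # "male" | "female" | "unknown"

    def __post_init__(self):
        core = [self.proband]
        core += [n for n in (self.mother, self.father) if n]
        core += list(self.affected_siblings)
        # parents may double as unaffected members (dominant-model checks);
        # everything else must be distinct
        unaffected = list(self.unaffected_members)
        names = core + [n for n in unaffected
                        if n not in (self.mother, self.father)]
        if len(set(names)) != len(names) or len(set(unaffected)) != len(unaffected):
            raise PedigreeError(f"pedigree sample names are not distinct: {names}")

    @classmethod
    def from_ped_file(cls, path, proband: Optional[str] = None) -> "Pedigree":
        """Build a pedigree from a PED-like whitespace-separated file.

        Columns: family, sample, father, mother, sex (1=male, 2=female),
        affected (2=affected, 1=unaffected). The proband defaults to the
        first affected sample that has at least one parent listed, else the
        first affected sample.
        """
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                cols = line.split()
                if len(cols) < 6:
                    raise PedigreeError(
                        f"pedigree line {line!r} has fewer than 6 columns"
                    )
                rows.append(cols[:6])
        by_name = {r[1]: r for r in rows}
        affected = [r for r in rows if r[5] == "2"]
        if proband is None:
            with_parents = [r for r in affected
                            if r[2] in by_name or r[3] in by_name]
            if with_parents:
                proband = with_parents[0][1]
            elif affected:
                proband = affected[0][1]
            else:
                raise PedigreeError(f"no affected sample in {path!r}")
        if proband not in by_name:
            raise PedigreeError(f"proband {proband!r} not in {path!r}")
        row = by_name[proband]
        father = row[2] if row[2] in by_name else None
        mother = row[3] if row[3] in by_name else None
        sex = {"1": "male", "2": "female"}.get(row[4], "unknown")
        siblings = []
        unaffected = []
        for r in rows:
            if r[1] in (proband, mother, father):
                continue
            (siblings if r[5] == "2" else unaffected).append(r[1])
        for parent in (mother, father):
            if parent and by_name[parent][5] != "2":
                unaffected.append(parent)
        return cls(
            proband=proband, mother=mother, father=father,
            affected_siblings=tuple(siblings),
            unaffected_members=tuple(unaffected),
            sex_of_proband=sex,
        )


@dataclass
class CandidateReport:
    """Surviving variants with per-record filter provenance."""

    records: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)  # record.key -> (names,)
    input_count: int = 0
    output_count: int = 0
    sample: Optional[str] = None
    excluded_no_gene: int = 0
    stage_counts: list = field(default_factory=list)

    def genes(self) -> set:
        return {
            rec.info[GENE_FIELD] for rec in self.records
            if GENE_FIELD in rec.info
        }

    def by_gene(self) -> dict:
        grouped: dict = {}
        for rec in self.records:
            grouped.setdefault(rec.info.get(GENE_FIELD), []).append(rec)
        return grouped

    def contains(self, chrom, pos, ref=None, alt=None) -> bool:
        for rec in self.records:
            if rec.chrom != str(chrom) or rec.pos != int(pos):
                continue
            if ref is not None and rec.ref != ref:
                continue
            if alt is not None and alt not in rec.alts:
                continue
            return True
        return False


def _frequency_field(panel: str) -> str:
    return f"{panel}_{FREQUENCY_SUFFIX}"


def _referenced_fields(spec: FilterSpec) -> list[str]:
    fields = []
    if spec.impacts is not None:
        fields.append(IMPACT_FIELD)
    if spec.functional_classes is not None:
        fields.append(FUNCTIONAL_FIELD)
    if spec.max_dbsnp_build is not None:
        fields.append(DBSNP_BUILD_FIELD)
    fields += [_frequency_field(p) for p in spec.max_panel_frequency]
    if spec.gene_panel is not None:
        fields.append(GENE_FIELD)
    fields += list(spec.score_thresholds)
    return fields


def _record_level_pass(rec: VariantRecord, spec: FilterSpec,
                       call: Optional[GenotypeCall]) -> bool:
    if spec.zygosity is not None:
        if call is None or call.zygosity() not in spec.zygosity:
            return False
    if spec.impacts is not None:
        if rec.info.get(IMPACT_FIELD) not in spec.impacts:
            return False
    if spec.functional_classes is not None:
        if rec.info.get(FUNCTIONAL_FIELD) not in spec.functional_classes:
            return False
    if spec.min_depth is not None:
        depth = call.depth if call is not None else None
        if depth is None:
            if spec.require_depth:
                return False
        elif depth < spec.min_depth:
            return False
    if spec.min_qual is not None:
        if rec.qual is not None and rec.qual < spec.min_qual:
            return False
    if spec.regions is not None:
        if not any(rec.chrom == c and s <= rec.pos <= e
                   for c, s, e in spec.regions):
            return False
    if spec.gene_panel is not None:
        gene = rec.info.get(GENE_FIELD)
        if gene is None or gene not in spec.gene_panel:
            return False
    return True


def _alt_level_pass(rec: VariantRecord, spec: FilterSpec, alt_index: int) -> bool:
    if spec.max_dbsnp_build is not None:
        build = rec.per_alt_value(DBSNP_BUILD_FIELD, alt_index)
        if build is not None and int(build) <= spec.max_dbsnp_build:
            return False
    for panel, cutoff in spec.max_panel_frequency.items():
        freq = rec.per_alt_value(_frequency_field(panel), alt_index)
        if freq is None:
            if not spec.keep_unannotated_frequency:
                return False
        elif float(freq) > cutoff:
            return False
    for name, (direction, cutoff) in spec.score_thresholds.items():
        score = rec.per_alt_value(name, alt_index)
        if score is None:
            continue
        score = float(score)
        if direction == "le" and score > cutoff:
            return False
        if direction == "ge" and score < cutoff:
            return False
    return True


def record_passes(rec: VariantRecord, spec: FilterSpec,
                  sample: Optional[str]) -> bool:
    """Whether one record satisfies every active criterion of the spec."""
    call = rec.calls.get(sample) if sample is not None else None
    if not _record_level_pass(rec, spec, call):
        return False
    if not rec.alts:
        return _alt_level_pass(rec, spec, 0)
    return any(_alt_level_pass(rec, spec, i) for i in range(len(rec.alts)))


def _active_criteria(spec: FilterSpec) -> tuple:
    names = []
    if spec.zygosity is not None:
        names.append("zygosity")
    if spec.impacts is not None:
        names.append("impact")
    if spec.functional_classes is not None:
        names.append("functional_class")
    if spec.min_depth is not None:
        names.append("min_depth")
    if spec.min_qual is not None:
        names.append("min_qual")
    if spec.max_dbsnp_build is not None:
        names.append("dbsnp_build")
    for panel in spec.max_panel_frequency:
        names.append(f"frequency:{panel}")
    if spec.regions is not None:
        names.append("regions")
    if spec.gene_panel is not None:
        names.append("gene_panel")
    for name in spec.score_thresholds:
        names.append(f"score:{name}")
    return tuple(names)


def apply_filters(vs: VariantSet, spec: FilterSpec,
                  sample: Optional[str] = None) -> CandidateReport:
    """Filter a variant set for one sample; survivors pass every criterion.

    Raises :class:`FilterConfigError` when the spec references an annotation
    field that no record carries (a sign the input was never annotated).
    """
    if sample is not None and vs.samples and sample not in vs.samples:
        raise FilterConfigError(f"sample {sample!r} not present in the input")
    if vs.records:
        present = set()
        for rec in vs.records:
            present.update(rec.info)
        for name in _referenced_fields(spec):
            if name not in present:
                raise FilterConfigError(
                    f"filter references annotation field {name!r} which is "
                    "absent from every record"
                )
    active = _active_criteria(spec)
    report = CandidateReport(sample=sample, input_count=len(vs.records))
    for rec in vs.records:
        if record_passes(rec, spec, sample):
            report.records.append(rec)
            report.provenance[rec.key] = active
        if spec.gene_panel is not None and GENE_FIELD not in rec.info:
            report.excluded_no_gene += 1
    report.output_count = len(report.records)
    return report


def genes_in_common(reports: dict) -> GenePanel:
    """Genes holding >=1 surviving variant in EVERY individual's report."""
    if not reports:
        raise FilterConfigError("genes_in_common needs at least one report")
    gene_sets = [report.genes() for report in reports.values()]
    common = frozenset(set.intersection(*gene_sets))
    return GenePanel(label="genes in common", symbols=common)


# ---------------------------------------------------------------------------
# Inheritance models
# ---------------------------------------------------------------------------

_ABSENT = GenotypeCall(allele_indices=(0, 0))  # non-carrier pseudo-call


def _iter_family(family: Union[VariantSet, dict], ped: Pedigree):
    """Yield (proband record, {sample: call}) for every proband record.

    ``family`` is either one multi-sample VariantSet or a mapping
    sample -> single-sample VariantSet. In the mapping form a sample whose
    set lacks the record is treated as a non-carrier (its own file omits
    hom-ref sites); a sample not supplied at all is simply not in the dict.
    """
    members = [ped.proband]
    members += [m for m in (ped.mother, ped.father) if m]
    members += list(ped.affected_siblings) + list(ped.unaffected_members)
    if isinstance(family, VariantSet):
        available = [m for m in members if m in family.samples]
        if ped.proband not in family.samples:
            raise PedigreeError(
                f"proband {ped.proband!r} is not a sample of the input"
            )
        for rec in family.records:
            yield rec, {m: rec.calls[m] for m in available}
    else:
        if ped.proband not in family:
            raise PedigreeError(f"no variant set supplied for proband "
                                f"{ped.proband!r}")
        lookups = {}
        for member in members:
            if member == ped.proband or member not in family:
                continue
            vs = family[member]
            calls = {}
            for rec in vs.records:
                name = member if member in rec.calls else (
                    vs.samples[0] if len(vs.samples) == 1 else None
                )
                if name is None:
                    raise PedigreeError(
                        f"cannot locate sample {member!r} in its variant set"
                    )
                calls[rec.key] = rec.calls[name]
            lookups[member] = calls
        proband_vs = family[ped.proband]
        for rec in proband_vs.records:
            name = ped.proband if ped.proband in rec.calls else (
                proband_vs.samples[0] if len(proband_vs.samples) == 1 else None
            )
            if name is None:
                raise PedigreeError(
                    f"cannot locate sample {ped.proband!r} in its variant set"
                )
            calls = {ped.proband: rec.calls[name]}
            for member, lookup in lookups.items():
                calls[member] = lookup.get(rec.key, _ABSENT)
            yield rec, calls


def _demonstrably_carries(call: Optional[GenotypeCall]) -> bool:
    return call is not None and call.carries_alt


def _demonstrably_clear(call: Optional[GenotypeCall]) -> bool:
    """Call present and demonstrably free of alternate alleles."""
    return call is not None and not call.is_missing and not call.carries_alt


def filter_inheritance(
    family: Union[VariantSet, dict],
    ped: Pedigree,
    model: str,
) -> CandidateReport:
    """Keep variants (or genes, for compound het) segregating under a model.

    * AR_HOM — proband homozygous-alt; each supplied parent heterozygous.
    * AR_COMPHET — gene with >=2 distinct proband-het variants; with both
      parents, at least one variant transmitted by the mother only and one
      by the father only (trans configuration); genes failing the check are
      dropped. Without both parents the gene is kept with a
      ``phase-unverified`` provenance flag.
    * AD_HET — proband heterozygous; every affected relative demonstrably
      carries the variant; no unaffected member carries it.
    * DE_NOVO — proband heterozygous; both parents required, and both must
      demonstrably carry no alternate allele.
    * XL_HEMI — X chromosome, male proband hemizygous or homozygous-alt;
      mother heterozygous when supplied.

    A missing genotype fails a positive requirement (carriage or het status
    that must be demonstrated) and passes a negative one.
    """
    if model not in INHERITANCE_MODELS:
        raise FilterConfigError(
            f"unknown inheritance model {model!r}; "
            f"expected one of {INHERITANCE_MODELS}"
        )
    if model == XL_HEMI and ped.sex_of_proband != "male":
        raise PedigreeError(
            "XL_HEMI requires a male proband (sex is "
            f"{ped.sex_of_proband!r})"
        )

    pairs = list(_iter_family(family, ped))
    if model == DE_NOVO:
        supplied = {s for _, calls in pairs for s in calls} if pairs else set()
        has_parents = (
            ped.mother and ped.father
            and (not pairs or {ped.mother, ped.father} <= supplied)
        )
        if not has_parents:
            raise PedigreeError("DE_NOVO requires genotypes for both parents")

    report = CandidateReport(sample=ped.proband, input_count=len(pairs))
    tag = f"inheritance:{model}"

    if model == AR_COMPHET:
        _comphet(pairs, ped, report, tag)
    else:
        for rec, calls in pairs:
            if _single_site_pass(rec, calls, ped, model):
                report.records.append(rec)
                report.provenance[rec.key] = (tag,)
    report.output_count = len(report.records)
    return report


def _single_site_pass(rec, calls, ped: Pedigree, model: str) -> bool:
    proband = calls.get(ped.proband)
    if proband is None:
        return False
    mother = calls.get(ped.mother) if ped.mother else None
    father = calls.get(ped.father) if ped.father else None
    zyg = proband.zygosity()

    if model == AR_HOM:
        if zyg != ZYG_HOM_ALT:
            return False
        for parent in (mother, father):
            if parent is not None and parent.zygosity() != ZYG_HET:
                return False
        return True

    if model == AD_HET:
        if zyg != ZYG_HET:
            return False
        for sib in ped.affected_siblings:
            if sib in calls and not _demonstrably_carries(calls[sib]):
                return False
        for member in ped.unaffected_members:
            if member in calls and _demonstrably_carries(calls[member]):
                return False
        return True

    if model == DE_NOVO:
        if zyg != ZYG_HET:
            return False
        return _demonstrably_clear(mother) and _demonstrably_clear(father)

    if model == XL_HEMI:
        if rec.chrom != "X":
            return False
        if zyg not in (ZYG_HEMI, ZYG_HOM_ALT):
            return False
        if mother is not None and mother.zygosity() != ZYG_HET:
            return False
        return True

    raise AssertionError(model)


def _comphet(pairs, ped: Pedigree, report: CandidateReport, tag: str) -> None:
    by_gene: dict = {}
    for rec, calls in pairs:
        gene = rec.info.get(GENE_FIELD)
        if gene is None:
            report.excluded_no_gene += 1
            continue
        proband = calls.get(ped.proband)
        if proband is not None and proband.zygosity() == ZYG_HET:
            by_gene.setdefault(gene, []).append((rec, calls))

    both_parents = bool(ped.mother and ped.father)
    for gene, items in sorted(by_gene.items()):
        distinct = {rec.key for rec, _ in items}
        if len(distinct) < 2:
            continue
        flags = (tag,)
        if both_parents:
            maternal_only = False
            paternal_only = False
            for rec, calls in items:
                mother = calls.get(ped.mother)
                father = calls.get(ped.father)
                if mother is None or father is None:
                    continue
                m_carries = _demonstrably_carries(mother)
                f_carries = _demonstrably_carries(father)
                if m_carries and _demonstrably_clear(father):
                    maternal_only = True
                if f_carries and _demonstrably_clear(mother):
                    paternal_only = True
            if not (maternal_only and paternal_only):
                continue
        else:
            flags = (tag, "phase-unverified")
        for rec, _ in items:
            report.records.append(rec)
            report.provenance[rec.key] = flags
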