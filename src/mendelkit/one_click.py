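"""The 1-Click preset: a fixed filter specification plus pipeline.

The preset encodes the tool's suggested defaults for a first-pass candidate
list: drop variants catalogued in dbSNP build 129 or earlier (the last build
predating large-scale inclusion of pathogenic SNVs), drop calls with read
depth below 10, keep only HIGH/MODERATE-impact variants, keep only genes with
surviving variants in every selected individual, drop variants more common
than 1% in the 1000 Genomes-, dbSNP- and ESP-like panels, and — deliberately
— apply no pathogenicity-score thresholds, so no candidate is lost to a
misclassifying score. The result is then optionally intersected with an
inheritance model and with known disease genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

from .catalog import (
    DiseaseCatalog,
    GenePanel,
    known_disease_genes,
    panel_from_diseases,
)
from .errors import FilterConfigError
from .filter_engine import (
    GENE_FIELD,
    CandidateReport,
    FilterSpec,
    Pedigree,
    apply_filters,
    filter_inheritance,
    genes_in_common,
)
from .records import VariantSet, chrom_sort_key

__all__ = ["OneClickOptions", "default_spec", "one_click"]


def default_spec() -> FilterSpec:
    """The 1-Click filter defaults.

    dbSNP build <= 129 excluded, read depth >= 10, impact HIGH or MODERATE,
    frequency <= 1% in the ``1000g``, ``dbsnp`` and ``esp`` panels
    (panel-absent variants kept), and no pathogenicity-score thresholds.
    """
    return FilterSpec(
        max_dbsnp_build=129,
        min_depth=10,
        impacts=frozenset({"HIGH", "MODERATE"}),
        max_panel_frequency={"1000g": 0.01, "dbsnp": 0.01, "esp": 0.01},
        keep_unannotated_frequency=True,
    )


@dataclass
class OneClickOptions:
    """Options for a 1-Click run over one or more individuals."""

    individuals: tuple  # sample names, >= 1
    inheritance_model: Optional[str] = None
    restrict_to_known_disease_genes: bool = True
    disease_selection: Optional[list] = None  # list of DiseaseEntry
    overrides: Optional[dict] = None  # partial FilterSpec fields
    disease_catalogs: tuple = ()  # DiseaseCatalog sources for the known-gene panel

    def __post_init__(self):
        self.individuals = tuple(self.individuals)
        if not self.individuals:
            raise FilterConfigError("1-Click needs at least one individual")


def _restrict(report: CandidateReport, panel: GenePanel,
              stage: str) -> CandidateReport:
    kept = [
        rec for rec in report.records
        if rec.info.get(GENE_FIELD) in panel
    ]
    out = CandidateReport(
        records=kept,
        provenance={
            rec.key: report.provenance.get(rec.key, ()) + (stage,)
            for rec in kept
        },
        input_count=report.input_count,
        output_count=len(kept),
        sample=report.sample,
        excluded_no_gene=report.excluded_no_gene,
        stage_counts=list(report.stage_counts),
    )
    return out


def one_click(
    data: Union[VariantSet, dict],
    ped: Optional[Pedigree],
    opts: OneClickOptions,
) -> CandidateReport:
    """Run the full preset pipeline and return the final candidate report.

    Stages, in fixed order: per-individual filtering with the default spec
    (plus any overrides) → intersection on genes common to all individuals →
    optional inheritance-model filter → optional restriction to known
    disease genes or to a selected disease's gene panel. The report records
    every stage's input/output counts; candidates are ordered by gene
    symbol, then locus.
    """
    spec = default_spec().merged_with(opts.overrides)

    def vs_for(sample: str) -> VariantSet:
        if isinstance(data, VariantSet):
            return data
        if sample not in data:
            raise FilterConfigError(f"no variant set supplied for {sample!r}")
        return data[sample]

    stage_counts: list[tuple[str, int, int]] = []

    reports = {}
    for sample in opts.individuals:
        vs = vs_for(sample)
        reports[sample] = apply_filters(vs, spec, sample)
        stage_counts.append((
            f"filter:{sample}",
            reports[sample].input_count,
            reports[sample].output_count,
        ))

    proband = opts.individuals[0]
    current = reports[proband]

    if len(opts.individuals) > 1:
        common = genes_in_common(reports)
        before = current.output_count
        current = _restrict(current, common, "genes_in_common")
        stage_counts.append(("genes_in_common", before, current.output_count))

    if opts.inheritance_model is not None:
        if ped is None:
            raise FilterConfigError(
                "an inheritance model requires a pedigree"
            )
        family: Union[VariantSet, dict]
        if isinstance(data, VariantSet):
            family = VariantSet(
                meta=list(data.meta), samples=list(data.samples),
                records=current.records,
            )
        else:
            family = dict(data)
            family[ped.proband] = VariantSet(
                meta=list(vs_for(ped.proband).meta),
                samples=list(vs_for(ped.proband).samples),
                records=current.records,
            )
        before = current.output_count
        inh = filter_inheritance(family, ped, opts.inheritance_model)
        surviving_keys = {rec.key for rec in inh.records}
        kept = [rec for rec in current.records if rec.key in surviving_keys]
        current = CandidateReport(
            records=kept,
            provenance={
                rec.key: current.provenance.get(rec.key, ())
                + inh.provenance.get(rec.key, ())
                for rec in kept
            },
            input_count=current.input_count,
            output_count=len(kept),
            sample=current.sample,
            excluded_no_gene=current.excluded_no_gene,
        )
        stage_counts.append((
            f"inheritance:{opts.inheritance_model}", before,
            current.output_count,
        ))

    panel: Optional[GenePanel] = None
    stage_name = None
    if opts.disease_selection:
        panel = panel_from_diseases(opts.disease_selection)
        stage_name = "disease_panel"
    elif opts.restrict_to_known_disease_genes:
        panel = known_disease_genes(*opts.disease_catalogs)
        stage_name = "known_disease_genes"
    if panel is not None:
        before = current.output_count
        current = _restrict(current, panel, stage_name)
        stage_counts.append((stage_name, before, current.output_count))

    current.records.sort(
        key=lambda r: (
            str(r.info.get(GENE_FIELD, "")),
            chrom_sort_key(r.chrom),
            r.pos,
            r.ref,
            r.alts,
        )
    )
    current.stage_counts = stage_counts
    return current
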