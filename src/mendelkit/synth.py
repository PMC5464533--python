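"""Deterministic synthetic families, reference panels and catalogs.

The generator emulates the data a rare-disease prioritization run consumes:
a trio VCF (male proband, mother, father) with Mendelian-consistent
background genotypes, population frequency panels (1000 Genomes- and
ESP-like), a dbSNP-like panel carrying rs identifiers and first-build
numbers, a dbNSFP-like per-allele score table, and HGNC/OMIM-like gene and
disease catalogs. One causal ("culprit") variant — or a compound-het pair —
is planted so that it segregates exactly under the configured inheritance
model, is absent from every panel, has HIGH impact and read depth >= 10 in
all family members; the :class:`PlantedTruth` it returns is the ground truth
against which recovery is measured.

Everything is drawn from a single seeded generator: the same configuration
always produces byte-identical files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .annotate import SCORE_TABLE, VCF_PANEL, AnnotationConfig, ReferencePanel
from .errors import SynthConfigError
from .filter_engine import (
    AD_HET,
    AR_COMPHET,
    AR_HOM,
    GENE_FIELD,
    IMPACT_FIELD,
    INHERITANCE_MODELS,
    XL_HEMI,
    Pedigree,
)
from .records import GenotypeCall, VariantRecord, VariantSet, chrom_sort_key
from .vcf_core import write_vcf

__all__ = [
    "SynthConfig",
    "PlantedTruth",
    "SynthDataset",
    "generate_dataset",
    "make_panels",
    "make_family",
]

_BASES = ("A", "C", "G", "T")
_IMPACTS = ("HIGH", "MODERATE", "LOW", "MODIFIER")
_SCORE_COLUMNS = ("sift_score", "polyphen2_score", "cadd_phred")

PROBAND, MOTHER, FATHER = "PROBAND", "MOTHER", "FATHER"

#: Inheritance label used in the disease catalog for each model.
_MODEL_INHERITANCE = {
    AR_HOM: "AR",
    AR_COMPHET: "AR",
    AD_HET: "AD",
    XL_HEMI: "XL",
    "DE_NOVO": "AD",
}

_GENE_SPAN = 900_000


@dataclass
class SynthConfig:
    """Study conditions for one synthetic family.

    Background allele frequencies mix common (AF ~ U(0.05, 0.5)) and rare
    (AF ~ U(1e-4, 0.01)) variants; ~95% of common variants carry dbSNP-like
    builds of 129 or lower while rare variants are mostly uncatalogued, so
    the preset filters have a realistic, large effect. Depths are
    Poisson-distributed around an exome-like mean with a small low-coverage
    fraction exercising the depth filter.
    """

    seed: int = 0
    n_background_variants: int = 20_000
    n_genes: int = 1_000
    chroms: tuple = tuple(str(i) for i in range(1, 23)) + ("X",)
    model: str = AR_HOM
    frac_common: float = 0.30
    common_af: tuple = (0.05, 0.5)
    rare_af: tuple = (0.0001, 0.01)
    p_old_build_common: float = 0.95  # P(build <= 129 | common)
    p_dbsnp_rare: float = 0.10  # P(catalogued at all | rare); build > 129
    mean_depth: float = 60.0
    frac_low_depth: float = 0.05
    impact_probs: dict = field(default_factory=lambda: {
        "HIGH": 0.05, "MODERATE": 0.15, "LOW": 0.40, "MODIFIER": 0.40,
    })
    esp_coverage: float = 0.85  # fraction of background sites in the ESP panel
    score_coverage: float = 0.40  # fraction of sites in the score table
    n_diseases: int = 80

    def __post_init__(self):
        if self.model not in INHERITANCE_MODELS:
            raise SynthConfigError(f"unknown model {self.model!r}")
        for name in ("n_background_variants", "n_genes", "n_diseases"):
            if getattr(self, name) <= 0:
                raise SynthConfigError(f"{name} must be positive")
        if self.model == XL_HEMI and "X" not in self.chroms:
            raise SynthConfigError(
                "XL_HEMI requires chromosome X among the configured "
                "chromosomes"
            )


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth of the planted causal variant(s)."""

    gene: str
    model: str
    variants: tuple  # ((chrom, pos, ref, alt), ...) — two for compound het
    expected_genotypes: dict  # sample -> tuple of GT strings, variant-aligned


@dataclass(frozen=True)
class _Gene:
    symbol: str
    chrom: str
    start: int
    end: int


@dataclass
class _Site:
    chrom: str
    pos: int
    ref: str
    alt: str
    af: float
    gene: str
    impact: str
    in_esp: bool
    dbsnp_id: Optional[str]
    dbsnp_build: Optional[int]
    scores: Optional[dict]
    qual: float
    calls: dict  # sample -> GenotypeCall
    causal: bool = False


def _gt_string(call: GenotypeCall) -> str:
    if call.allele_indices is None:
        return "./."
    return "/".join(str(i) for i in call.allele_indices)


class SynthDataset:
    """In-memory synthetic dataset; see module docstring for contents."""

    def __init__(self, cfg: SynthConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.genes = self._make_genes(cfg)
        self.sites = self._make_background(cfg, rng)
        self.truth, causal_sites = self._plant_culprit(cfg, rng)
        self.sites.extend(causal_sites)
        self.sites.sort(key=lambda s: (chrom_sort_key(s.chrom), s.pos, s.alt))
        self.catalog_rows = self._make_catalogs(cfg, rng)
        self.pedigree = Pedigree(
            proband=PROBAND, mother=MOTHER, father=FATHER,
            unaffected_members=(MOTHER, FATHER), sex_of_proband="male",
        )

    # -- construction -------------------------------------------------------

    @staticmethod
    def _make_genes(cfg: SynthConfig) -> list[_Gene]:
        genes = []
        per_chrom: dict[str, int] = {}
        for i in range(cfg.n_genes):
            chrom = cfg.chroms[i % len(cfg.chroms)]
            idx = per_chrom.get(chrom, 0)
            per_chrom[chrom] = idx + 1
            start = 1 + idx * 1_000_000
            genes.append(_Gene(
                symbol=f"SYNG{i + 1:04d}", chrom=chrom, start=start,
                end=start + _GENE_SPAN - 1,
            ))
        return genes

    def _draw_trio(self, rng, af: float, on_x: bool) -> dict:
        """Mendelian-consistent trio genotypes for a male proband.

        Parental alleles are i.i.d. Bernoulli(af); if the family would carry
        no alternate allele at all, one uniformly chosen parental allele is
        flipped (multi-sample VCFs only list variant sites). The child then
        inherits one allele from each parent (maternal only on X).
        """
        mother = list((rng.random(2) < af).astype(int))
        father = list((rng.random(1 if on_x else 2) < af).astype(int))
        pool = len(mother) + len(father)
        if not any(mother) and not any(father):
            k = int(rng.integers(pool))
            if k < len(mother):
                mother[k] = 1
            else:
                father[k - len(mother)] = 1
        maternal = mother[int(rng.integers(2))]
        if on_x:
            child = (maternal,)
            father_gt = (father[0],)
        else:
            child = tuple(sorted((maternal, father[int(rng.integers(2))])))
            father_gt = tuple(sorted(father))
        return {
            PROBAND: child,
            MOTHER: tuple(sorted(mother)),
            FATHER: father_gt,
        }

    def _call(self, rng, indices, low_depth_ok=True) -> GenotypeCall:
        cfg = self.cfg
        if low_depth_ok and rng.random() < cfg.frac_low_depth:
            depth = int(rng.integers(0, 10))
        else:
            depth = int(rng.poisson(cfg.mean_depth))
        return GenotypeCall(
            allele_indices=indices,
            depth=depth,
            genotype_quality=int(rng.integers(20, 100)),
        )

    def _make_background(self, cfg: SynthConfig, rng) -> list[_Site]:
        counts = np.bincount(
            rng.integers(0, cfg.n_genes, size=cfg.n_background_variants),
            minlength=cfg.n_genes,
        )
        impacts = list(cfg.impact_probs)
        impact_p = np.array([cfg.impact_probs[i] for i in impacts], dtype=float)
        impact_p = impact_p / impact_p.sum()
        sites: list[_Site] = []
        rs_serial = 1000
        for gene, count in zip(self.genes, counts):
            if count == 0:
                continue
            offsets = np.sort(rng.choice(_GENE_SPAN, size=count, replace=False))
            on_x = gene.chrom == "X"
            for offset in offsets:
                pos = gene.start + int(offset)
                ref, alt = rng.choice(4, size=2, replace=False)
                common = rng.random() < cfg.frac_common
                lo, hi = cfg.common_af if common else cfg.rare_af
                af = round(float(rng.uniform(lo, hi)), 6)
                if common:
                    if rng.random() < cfg.p_old_build_common:
                        build = int(rng.integers(36, 130))
                    else:
                        build = int(rng.integers(130, 151))
                elif rng.random() < cfg.p_dbsnp_rare:
                    build = int(rng.integers(130, 151))
                else:
                    build = None
                rs_serial += 1
                scores = None
                if rng.random() < cfg.score_coverage:
                    scores = {}
                    draws = {
                        "sift_score": round(float(rng.random()), 3),
                        "polyphen2_score": round(float(rng.random()), 3),
                        "cadd_phred": round(float(rng.uniform(0, 40)), 2),
                    }
                    for col, value in draws.items():
                        if rng.random() >= 0.1:
                            scores[col] = value
                gts = self._draw_trio(rng, af, on_x)
                sites.append(_Site(
                    chrom=gene.chrom,
                    pos=pos,
                    ref=_BASES[int(ref)],
                    alt=_BASES[int(alt)],
                    af=af,
                    gene=gene.symbol,
                    impact=impacts[int(rng.choice(len(impacts), p=impact_p))],
                    in_esp=bool(rng.random() < cfg.esp_coverage),
                    dbsnp_id=f"rs{rs_serial}" if build is not None else None,
                    dbsnp_build=build,
                    scores=scores,
                    qual=round(float(rng.uniform(50, 3000)), 2),
                    calls={
                        s: self._call(rng, gt) for s, gt in gts.items()
                    },
                ))
        return sites

    def _plant_culprit(self, cfg: SynthConfig, rng):
        if cfg.model == XL_HEMI:
            candidates = [g for g in self.genes if g.chrom == "X"]
            if not candidates:
                raise SynthConfigError("no genes on chromosome X")
        else:
            candidates = [g for g in self.genes if g.chrom != "X"]
        gene = candidates[int(rng.integers(len(candidates)))]
        used = {s.pos for s in self.sites if s.chrom == gene.chrom}

        def fresh_pos() -> int:
            while True:
                pos = gene.start + int(rng.integers(_GENE_SPAN))
                if pos not in used:
                    used.add(pos)
                    return pos

        model_gts = {
            AR_HOM: [{PROBAND: (1, 1), MOTHER: (0, 1), FATHER: (0, 1)}],
            AR_COMPHET: [
                {PROBAND: (0, 1), MOTHER: (0, 1), FATHER: (0, 0)},
                {PROBAND: (0, 1), MOTHER: (0, 0), FATHER: (0, 1)},
            ],
            AD_HET: [{PROBAND: (0, 1), MOTHER: (0, 0), FATHER: (0, 0)}],
            "DE_NOVO": [{PROBAND: (0, 1), MOTHER: (0, 0), FATHER: (0, 0)}],
            XL_HEMI: [{PROBAND: (1,), MOTHER: (0, 1), FATHER: (0,)}],
        }[cfg.model]

        causal_sites = []
        variants = []
        expected: dict[str, list[str]] = {PROBAND: [], MOTHER: [], FATHER: []}
        for gts in model_gts:
            pos = fresh_pos()
            ref, alt = rng.choice(4, size=2, replace=False)
            calls = {
                s: GenotypeCall(
                    allele_indices=gt,
                    depth=int(rng.integers(20, 100)),
                    genotype_quality=99,
                )
                for s, gt in gts.items()
            }
            causal_sites.append(_Site(
                chrom=gene.chrom, pos=pos,
                ref=_BASES[int(ref)], alt=_BASES[int(alt)],
                af=0.0, gene=gene.symbol, impact="HIGH",
                in_esp=False, dbsnp_id=None, dbsnp_build=None, scores=None,
                qual=round(float(rng.uniform(1000, 3000)), 2),
                calls=calls, causal=True,
            ))
            variants.append(
                (gene.chrom, pos, _BASES[int(ref)], _BASES[int(alt)])
            )
            for s in (PROBAND, MOTHER, FATHER):
                expected[s].append(_gt_string(calls[s]))
        truth = PlantedTruth(
            gene=gene.symbol,
            model=cfg.model,
            variants=tuple(variants),
            expected_genotypes={s: tuple(v) for s, v in expected.items()},
        )
        return truth, causal_sites

    def _make_catalogs(self, cfg: SynthConfig, rng) -> list[dict]:
        symbols = [g.symbol for g in self.genes]
        rows = []
        for i in range(cfg.n_diseases - 1):
            k = int(rng.integers(1, 5))
            genes = sorted(
                symbols[int(j)]
                for j in rng.choice(len(symbols), size=k, replace=False)
            )
            rows.append({
                "disease_name": f"Synthetic disorder {i + 1:03d}",
                "source": "omim" if i % 2 == 0 else "cgd",
                "inheritance": str(rng.choice(["AD", "AR", "XL"])),
                "genes": genes,
            })
        extra = sorted(
            symbols[int(j)] for j in rng.choice(len(symbols), size=2,
                                                replace=False)
        )
        causal_genes = sorted({self.truth.gene, *extra})
        rows.append({
            "disease_name": f"Synthetic {cfg.model} culprit disorder",
            "source": "omim",
            "inheritance": _MODEL_INHERITANCE[cfg.model],
            "genes": causal_genes,
        })
        return rows

    # -- materialization ----------------------------------------------------

    def trio_variantset(self) -> VariantSet:
        vs = VariantSet(samples=[PROBAND, MOTHER, FATHER])
        vs.meta.append("##fileformat=VCFv4.2")
        vs.ensure_info_definition(GENE_FIELD, "1", "String", "gene symbol")
        vs.ensure_info_definition(IMPACT_FIELD, "1", "String",
                                  "predicted consequence severity")
        for site in self.sites:
            vs.records.append(VariantRecord(
                chrom=site.chrom, pos=site.pos, ids=(),
                ref=site.ref, alts=(site.alt,), qual=site.qual,
                filter_status=("PASS",),
                info={GENE_FIELD: site.gene, IMPACT_FIELD: site.impact},
                calls=dict(site.calls),
            ))
        return vs

    def _panel_variantset(self, which: str) -> VariantSet:
        vs = VariantSet()
        vs.meta.append("##fileformat=VCFv4.2")
        vs.ensure_info_definition("AF", "A", "Float", "allele frequency")
        if which == "dbsnp":
            vs.ensure_info_definition("build", "1", "Integer",
                                      "first dbSNP build")
        for site in self.sites:
            if site.causal:
                continue
            if which == "esp" and not site.in_esp:
                continue
            if which == "dbsnp" and site.dbsnp_build is None:
                continue
            info: dict = {"AF": (site.af,)}
            ids: tuple = ()
            if which == "dbsnp":
                info["build"] = site.dbsnp_build
                ids = (site.dbsnp_id,)
            vs.records.append(VariantRecord(
                chrom=site.chrom, pos=site.pos, ids=ids,
                ref=site.ref, alts=(site.alt,), qual=None,
                filter_status=None, info=info, calls={},
            ))
        return vs

    def score_table_text(self) -> str:
        lines = ["#" + "\t".join(("chrom", "pos", "ref", "alt")
                                 + _SCORE_COLUMNS)]
        for site in self.sites:
            if site.causal or site.scores is None:
                continue
            row = [site.chrom, str(site.pos), site.ref, site.alt]
            for col in _SCORE_COLUMNS:
                value = site.scores.get(col)
                row.append("." if value is None else repr(value))
            lines.append("\t".join(row))
        return "\n".join(lines) + "\n"

    def gene_catalog_text(self) -> str:
        lines = ["symbol\tname"]
        for g in self.genes:
            lines.append(f"{g.symbol}\tsynthetic gene {g.symbol} "
                         f"on chromosome {g.chrom}")
        return "\n".join(lines) + "\n"

    def disease_catalog_text(self) -> str:
        lines = ["disease_name\tsource\tinheritance\tgenes"]
        for row in self.catalog_rows:
            lines.append("\t".join([
                row["disease_name"], row["source"], row["inheritance"],
                ";".join(row["genes"]),
            ]))
        return "\n".join(lines) + "\n"

    def ped_text(self) -> str:
        return (
            f"FAM1\t{PROBAND}\t{FATHER}\t{MOTHER}\t1\t2\n"
            f"FAM1\t{MOTHER}\t0\t0\t2\t1\n"
            f"FAM1\t{FATHER}\t0\t0\t1\t1\n"
        )

    def truth_text(self) -> str:
        lines = ["gene\tmodel\tchrom\tpos\tref\talt\tproband_gt\tmother_gt"
                 "\tfather_gt"]
        for i, (chrom, pos, ref, alt) in enumerate(self.truth.variants):
            lines.append("\t".join([
                self.truth.gene, self.truth.model, chrom, str(pos), ref, alt,
                self.truth.expected_genotypes[PROBAND][i],
                self.truth.expected_genotypes[MOTHER][i],
                self.truth.expected_genotypes[FATHER][i],
            ]))
        return "\n".join(lines) + "\n"


def generate_dataset(cfg: SynthConfig) -> SynthDataset:
    """Generate the full synthetic dataset for one configuration."""
    return SynthDataset(cfg)


@dataclass
class SynthPanels:
    """Paths of the generated reference panels and catalogs."""

    annotation_config: AnnotationConfig
    frequency_panels: dict  # name -> path
    score_table: str
    gene_catalog: str
    disease_catalog: str


def make_panels(cfg: SynthConfig, outdir) -> SynthPanels:
    """Write frequency/dbSNP panels, score table and catalogs to ``outdir``.

    The returned annotation configuration copies ``AF`` from the 1000
    Genomes- and ESP-like panels, ``AF`` + ``build`` (with rsID fill) from
    the dbSNP-like panel, and the three pathogenicity scores from the
    dbNSFP-like table.
    """
    dataset = generate_dataset(cfg)
    os.makedirs(outdir, exist_ok=True)
    paths = {}
    for name in ("1000g", "esp", "dbsnp"):
        path = os.path.join(outdir, f"{name}.vcf")
        write_vcf(dataset._panel_variantset(name), path)
        paths[name] = path
    score_path = os.path.join(outdir, "dbnsfp.tsv")
    with open(score_path, "w") as fh:
        fh.write(dataset.score_table_text())
    gene_path = os.path.join(outdir, "genes.tsv")
    with open(gene_path, "w") as fh:
        fh.write(dataset.gene_catalog_text())
    disease_path = os.path.join(outdir, "diseases.tsv")
    with open(disease_path, "w") as fh:
        fh.write(dataset.disease_catalog_text())
    config = AnnotationConfig(panels=[
        ReferencePanel("1000g", VCF_PANEL, paths["1000g"], ("AF",)),
        ReferencePanel("esp", VCF_PANEL, paths["esp"], ("AF",)),
        ReferencePanel("dbsnp", VCF_PANEL, paths["dbsnp"], ("AF", "build"),
                       id_fill=True),
        ReferencePanel("dbnsfp", SCORE_TABLE, score_path, _SCORE_COLUMNS),
    ])
    return SynthPanels(
        annotation_config=config,
        frequency_panels=paths,
        score_table=score_path,
        gene_catalog=gene_path,
        disease_catalog=disease_path,
    )


def make_family(cfg: SynthConfig, outdir=None):
    """Build the trio VariantSet, pedigree and planted truth.

    When ``outdir`` is given, also writes ``trio.vcf``, ``trio.ped`` and
    ``truth.tsv`` there.
    """
    dataset = generate_dataset(cfg)
    trio = dataset.trio_variantset()
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        write_vcf(trio, os.path.join(outdir, "trio.vcf"))
        with open(os.path.join(outdir, "trio.ped"), "w") as fh:
            fh.write(dataset.ped_text())
        with open(os.path.join(outdir, "truth.tsv"), "w") as fh:
            fh.write(dataset.truth_text())
    return trio, dataset.pedigree, dataset.truth
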