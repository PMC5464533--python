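# Methods

## The prioritization model

mendelkit treats rare-disease variant prioritization as a sequence of
set-reducing operations on an annotated call set. The underlying
assumptions are the standard ones of clinical Mendelian analysis:

1. the causal variant is present in the patient's calls (sequencing and
   calling found it);
2. it is rare — essentially absent from population panels, and not part
   of the pre-clinical dbSNP catalog (first build ≤ 129, the last release
   predating large-scale inclusion of pathogenic SNVs);
3. it has a protein-relevant consequence (HIGH or MODERATE impact as
   assigned by an upstream effect predictor);
4. it segregates in the family according to the suspected inheritance
   model;
5. for a first pass, it lies in a gene already associated with a
   Mendelian disorder (this restriction is on by default and must be
   disabled for novel-gene discovery).

Each assumption maps to one filter; filters are conjunctive and
individually optional. The pipeline never ranks candidates by
pathogenicity score: scores are annotations a user may threshold on, but
by default no candidate is lost to a misclassifying score.

### Filter semantics

- **Frequency.** A variant is excluded when its panel allele frequency
  *exceeds* the cutoff (default 1% in each of the 1000 Genomes-, dbSNP-
  and ESP-like panels). Variants absent from a panel are kept by
  default (`keep_unannotated_frequency`): absence from a population
  panel is evidence of rarity, and dropping unannotated variants would
  discard precisely the novel variants the analysis seeks. One
  occasionally sees this filter phrased in the opposite direction
  ("exclude variants with frequency lower than 1%"); that reading would
  remove every rare variant and is incompatible with recovering rare
  pathogenic alleles, so mendelkit implements the exclusion of *common*
  variants and documents the choice here.
- **Read depth.** `min_depth` (default 10 in the preset) applies to the
  analyzed sample's DP. Calls lacking DP pass the criterion by default,
  because many VCF dialects omit per-call depth; `require_depth=True`
  switches to a strict mode that drops them.
- **dbSNP build.** A variant is excluded when a first-build annotation
  is present and ≤ `max_dbsnp_build`. Unannotated variants pass.
- **Allele-level evaluation.** Frequency, build and score criteria are
  evaluated per alternate allele; a multiallelic record survives when
  any single alt passes them all. Records are never decomposed into
  biallelic lines, preserving the uploaded file's structure.
- **QUAL.** Like depth: a missing QUAL passes `min_qual`.

### Inheritance models

Five segregation models run over a pedigree (proband, optional parents,
optional affected siblings and unaffected members). Rules degrade
gracefully when relatives are absent:

- **AR_HOM** — proband homozygous-alt; each *supplied* parent must be
  heterozygous (an obligate carrier).
- **AR_COMPHET** — a gene qualifies with ≥ 2 distinct heterozygous
  proband variants; with both parents supplied, at least one variant
  must be demonstrably transmitted by the mother only and one by the
  father only (trans configuration inferred from transmission, not from
  phase annotations). Without both parents the gene is kept but flagged
  `phase-unverified`.
- **AD_HET** — proband heterozygous; every affected relative must
  demonstrably carry the variant; no unaffected member may carry it.
  Parents supplied as unaffected members therefore exclude inherited
  hets — the dominant de-novo situation proper is split into its own
  model so that dominant *inherited* analysis (affected parent) remains
  expressible.
- **DE_NOVO** — proband heterozygous; genotypes for both parents are
  required and both must be demonstrably free of the alternate allele.
- **XL_HEMI** — X-chromosome variant in a male proband (an error is
  raised when the proband's sex is not known to be male), hemizygous
  (`1`) or effectively homozygous-alt (`1/1`, since upstream callers
  disagree on male-X representation); the mother, when supplied, must be
  heterozygous.

**Missing genotypes.** A missing call (`./.`) fails every *positive*
requirement (carriage or carrier status that must be demonstrated) and
passes every *negative* one (a missing call is not evidence of
carriage). This is the conservative choice for positive evidence and
the permissive one for exclusion, and it is mirrored exactly by the
brute-force oracles in the test suite.

**Separate per-sample files.** When the family arrives as one VCF per
person rather than one multi-sample VCF, a record absent from a
relative's file is treated as hom-ref for that relative, because the
normalization step removes hom-ref-only lines from single-sample files.

## Normalization ("sanity check")

Input files are normalized before annotation: records in which no
sample carries an alternate allele are dropped (records with zero
sample columns are retained — the rule is about genotyped patient
files, not sites-only panels); `chr`/`Chr`/`CHR` prefixes are stripped;
stale `EFF` and `ANN` INFO keys from previous effect-predictor runs are
deleted (`ANN` is the successor key of the same tool family); records
are sorted by chromosome in natural human order (1–22, X, Y, MT,
then unknown contigs lexicographically), position, ref, alts. The
operation is idempotent.

## Annotation

Panels are bgzip-compressed and tabix-indexed (via pysam); a plain-text
panel is compressed and indexed in place on first use, after a
sortedness check that names the first out-of-order row. Matching is
allele-exact — chrom, pos and ref equal, target alt among the panel
row's alts — because position-only matching would attach wrong-allele
frequencies to multiallelic sites. Copied values are written to INFO as
`<panel>_<field>` with per-alt alignment (`.` for unmatched alts);
writing to an already-present key is a hard error so that every one of
the potentially hundreds of annotation fields stays traceable to its
source. Because prefixes are unique, panel application commutes and the
merged result is deterministic regardless of order or chunking.

Gene symbol (`gene`) and consequence severity (`impact`) are consumed
from INFO fields of the input; they are produced upstream by an effect
predictor or by the synthetic generator. The dbSNP-like panel exposes a
per-variant integer `build` field (copied to `dbsnp_build`); for
multiallelic records `dbsnp_build_of` returns the earliest per-alt
build, while the filter uses each alt's own value.

## VCF data model and numerical conventions

INFO values are typed from the header declarations; fields with Number
other than 0/1 are canonically tuples (even with one element) and `.`
elements are `None` — this makes write∘parse an exact identity on the
data model. Floats are serialized with `repr`, which round-trips
exactly. Missing QUAL/DP/GQ/GT map to absent values, never 0, so
threshold filters cannot silently drop records that merely lack an
annotation. Summary statistics are computed over present values only; a
field missing everywhere is reported absent. A "novel" variant is one
with an empty ID column. Genotype concordance between two call sets
matches on (chrom, pos), compares unordered multisets of allele
*strings* (robust to different ALT-column encodings), ignores phase, and
excludes positions with a missing genotype on either side from the
denominator; the percentage is rounded to one decimal for display only.

## The synthetic-data generator

The generator emulates the inputs of a real prioritization run at
desk scale. Its defaults are the study conditions used throughout the
tests:

- 20,000 background variants over 1,000 genes (tutorial scale; gene
  loci are laid out on chromosomes 1–22 and X in 1 Mb slots);
- allele frequencies: 30% common sites with AF ~ U(0.05, 0.5), 70% rare
  with AF ~ U(10⁻⁴, 0.01) — a caricature of the real site-frequency
  spectrum that preserves the property the filters exploit (common
  variants are catalogued, rare ones mostly are not);
- dbSNP-like catalog: 95% of common variants carry builds ≤ 129, the
  rest builds 130–150; 10% of rare variants are catalogued, all with
  builds > 129;
- read depth ~ Poisson(60) per call (exome-like coverage), with a 5%
  low-depth fraction (DP < 10) to exercise the depth filter; genotype
  qualities U(20, 99), QUAL U(50, 3000);
- impact labels drawn per site: 5% HIGH, 15% MODERATE, 40% LOW, 40%
  MODIFIER;
- the ESP-like panel covers 85% of sites; the score table covers 40%,
  with 10% of individual scores missing.

Background trio genotypes draw parental alleles i.i.d. Bernoulli(AF);
if a site would be alt-free in the whole family, one uniformly chosen
parental allele is flipped to alt, because multi-sample VCFs only list
variant sites. This conditioning slightly distorts Hardy–Weinberg
proportions at rare sites but leaves Mendelian transmission exact: the
child inherits one random allele from each parent (maternal only on X —
the proband is male, and males are hemizygous single-allele on X).

The planted culprit satisfies its model's segregation exactly
(compound het: one variant per parent of origin, in one gene), is
absent from every panel and the score table, has HIGH impact, QUAL ≥
1000 and DP ≥ 20 in all members. The disease catalog (80 entries, 1–4
genes each, alternating OMIM-/CGD-like sources) always contains one
disorder listing the causal gene under the matching inheritance label.
All draws come from one seeded generator, so a configuration produces
byte-identical files on every run.

What the generator does **not** emulate — and what passing tests
therefore do not demonstrate about real data: linkage disequilibrium
and haplotype structure, indels and multiallelic background sites,
genotyping error and Mendelian inconsistencies, batch effects between
panels, population stratification of frequencies, and realistic gene
length/variant density distributions. Recovery rates on this generator
are a correctness check of the filter logic, not a clinical sensitivity
estimate.

## Design choices that were genuinely open

- **Chromosome order** for "sort by chromosome name" is natural
  (1–22, X, Y, MT), matching human-genome convention, rather than
  lexicographic.
- **Multi-sample hom-ref rule:** a record is dropped only when *no*
  sample carries an alternate allele; dropping any record containing
  one `0/0` call would destroy trio analysis.
- **Disease search ranking** is alphabetical by disease name; matching
  is case-insensitive substring on names and exact on gene symbols.
- **Pipeline order** in the preset is fixed: per-individual filters,
  then the common-genes intersection, then the inheritance model, then
  the disease-gene restriction; the stage counts recorded in the report
  make the order auditable.
- **Known-disease-gene restriction** defaults to on (the preset's
  purpose is a clinician-ready list) but is a flag, since novel-gene
  discovery requires the unrestricted path.
- A **partially missing genotype** (`./1`) is treated as fully missing.

## Limitations

- No indel left-alignment/normalization; records are compared and
  joined as written.
- Archive formats (.zip/.rar) are rejected; plain, gzip and bgzip VCF
  only.
- FORMAT fields other than GT/DP/GQ are not carried through the data
  model.
- The compound-het trans check uses transmission only; phased genotypes
  are not used to resolve cis/trans when parents are absent.
- Panel queries require coordinate-sorted panels; the annotation step
  buffers the target in memory (per-chromosome scale inputs are fine;
  whole-genome inputs should be chunked by chromosome, which the
  chunking-invariance of annotation makes safe).
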