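# mendelkit

Annotation, filtering and prioritization of candidate disease-causing
variants from VCF files, for rare-disease (Mendelian) genome and exome
analysis.

Clinicians and researchers diagnosing a suspected Mendelian disorder start
from 20,000–5,000,000 called variants per patient and need a short list of
candidates worth manual scrutiny. mendelkit implements the computational
core of that workflow as a plain Python library with a thin CLI:

- **VCF handling** (`mendelkit.vcf_core`) — parse/write plain or
  gzip/bgzip VCF 4.1/4.2, a `vcf-validator`-style checker, a "sanity
  check" normalization (drop records where no sample carries an alternate
  allele, strip `chr` prefixes, delete stale `EFF`/`ANN` effect tags, sort
  by chromosome and position), and per-file summary metrics (totals, novel
  variants, depth/quality min–max–mean, zygosity counts).
- **Annotation** (`mendelkit.annotate`) — join a patient VCF against
  bgzip-compressed, tabix-indexed reference panels: population frequency
  panels (1000 Genomes-, ESP-like), a dbSNP-like catalog with rs IDs and
  first-build numbers, and dbNSFP-like per-allele pathogenicity score
  tables. Matching is allele-exact; copied fields are namespaced
  `<panel>_<field>` in INFO, multiallelic records are annotated per-alt.
- **Catalogs** (`mendelkit.catalog`) — HGNC-like gene and OMIM/CGD-like
  disease tables with search and gene-panel extraction.
- **Filter engine** (`mendelkit.filter_engine`) — declarative
  `FilterSpec` (zygosity, impact, depth, quality, dbSNP build, panel
  frequency, regions, gene panels, score thresholds) evaluated as a
  conjunction, plus five inheritance models over a pedigree:
  autosomal-recessive homozygous, autosomal-recessive
  compound-heterozygous (with trans verification through parental
  transmission), autosomal-dominant heterozygous, de novo, and X-linked
  hemizygous.
- **1-Click preset** (`mendelkit.one_click`) — the one-call pipeline:
  exclude variants catalogued in dbSNP build ≤ 129, require read depth
  ≥ 10, keep HIGH/MODERATE impact, keep genes shared by all selected
  individuals, exclude variants with panel frequency above 1%, then
  optionally apply an inheritance model and restrict to known disease
  genes. No pathogenicity-score threshold is applied by default.
- **Comparison** (`mendelkit.compare`) — shared positions and genotype
  concordance between two call sets (phase-blind, allele-string based),
  including private-variant extraction for tumor/germline pairs.
- **Synthetic data** (`mendelkit.synth`) — a deterministic generator of
  trios, panels and catalogs with a planted causal variant per
  inheritance model, used both as test ground truth and as tutorial data.

## Worked example

Generate a tutorial study (an autosomal-recessive trio with 20,000
background variants over 1,000 genes and one planted causal variant),
annotate it, and run the 1-Click preset:

```bash
mendelkit synth --model ar_hom --seed 11 --n-variants 20000 \
    --n-genes 1000 --out study
# planted AR_HOM culprit in gene SYNG0065 at 19:2129710 G>A

mendelkit annotate study/trio.vcf --config panels.yaml -o annotated.vcf
# annotated 20001 records with 4 panel(s) -> annotated.vcf

mendelkit one-click annotated.vcf --ped study/trio.ped --model ar_hom \
    --diseases study/diseases.tsv -o report.tsv
```

where `panels.yaml` lists the generated panels:

```yaml
panels:
  - {name: 1000g, kind: vcf-panel, path: study/1000g.vcf, copy_fields: [AF]}
  - {name: esp, kind: vcf-panel, path: study/esp.vcf, copy_fields: [AF]}
  - {name: dbsnp, kind: vcf-panel, path: study/dbsnp.vcf,
     copy_fields: [AF, build], id_fill: true}
  - {name: dbnsfp, kind: score-table, path: study/dbnsfp.tsv,
     copy_fields: [sift_score, polyphen2_score, cadd_phred]}
```

The `one-click` command prints the stage-by-stage reduction as JSON:

```json
{"stages": [{"stage": "filter:PROBAND", "in": 20001, "out": 2596},
            {"stage": "inheritance:AR_HOM", "in": 2596, "out": 1},
            {"stage": "known_disease_genes", "in": 1, "out": 1}],
 "candidates": 1}
```

The preset filters cut 20,001 records to 2,596 (mostly by removing
common, catalogued and low-impact variants); requiring recessive
segregation in the trio leaves exactly one candidate, which is the
planted culprit:

```
gene      chrom  pos      ref  alt  PROBAND_GT  PROBAND_DP  impact  frequencies  provenance
SYNG0065  19     2129710  G    A    1/1         71          HIGH    .            impact,min_depth,dbsnp_build,frequency:1000g,frequency:dbsnp,frequency:esp,inheritance:AR_HOM,known_disease_genes
```

The empty `frequencies` column and the provenance list say why it
survived: it appears in no population panel, has no dbSNP build, HIGH
impact, adequate depth, recessive segregation, and lies in a catalogued
disease gene. The same pipeline is available as library calls
(`make_panels` / `make_family` → `annotate_all` → `one_click`).

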