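"""Shared fixtures and hypothesis strategies."""

from __future__ import annotations

import pytest
from hypothesis import strategies as st

from mendelkit.annotate import annotate_all
from mendelkit.catalog import load_disease_catalog, load_gene_catalog
from mendelkit.records import GenotypeCall, VariantRecord, VariantSet
from mendelkit.synth import SynthConfig, generate_dataset, make_family, make_panels
from mendelkit.vcf_core import sanity_check

# ---------------------------------------------------------------------------
# hypothesis strategies for the data model
# ---------------------------------------------------------------------------

_CHROMS = ["1", "2", "10", "22", "X", "MT", "chr5", "CHR7", "ctgU1"]
_BASES = "ACGT"

_alleles = st.text(alphabet=_BASES, min_size=1, max_size=4)
_floats = st.floats(allow_nan=False, allow_infinity=False, width=64)
_words = st.text(alphabet="abcdefgXYZ0123456789", min_size=1, max_size=6)

# INFO keys have a fixed type each so that type inference on write is
# consistent across records of one set.
_info_entry = st.one_of(
    st.tuples(st.just("n_count"), st.integers(-1000, 1000)),
    st.tuples(st.just("x_score"), _floats),
    st.tuples(st.just("label"), _words),
    st.tuples(st.just("seen"), st.just(True)),
    st.tuples(
        st.just("per_alt"),
        st.lists(st.one_of(st.none(), _floats), min_size=1, max_size=3)
        .map(tuple),
    ),
    st.tuples(st.just("EFF"), _words),
    st.tuples(st.just("ANN"), _words),
)


@st.composite
def genotype_calls(draw, n_alts: int) -> GenotypeCall:
    kind = draw(st.integers(0, 3))
    if kind == 0:
        indices = None
    elif kind == 1:
        indices = (draw(st.integers(0, n_alts)),)
    else:
        indices = tuple(
            draw(st.lists(st.integers(0, n_alts), min_size=2, max_size=2))
        )
    phased = (
        draw(st.booleans()) if indices is not None and len(indices) > 1
        else False
    )
    return GenotypeCall(
        allele_indices=indices,
        phased=phased,
        depth=draw(st.one_of(st.none(), st.integers(0, 500))),
        genotype_quality=draw(st.one_of(st.none(), st.integers(0, 99))),
    )


@st.composite
def variant_records(draw, samples: tuple[str, ...]) -> VariantRecord:
    alts = tuple(draw(st.lists(_alleles, min_size=1, max_size=2)))
    info = dict(draw(st.lists(_info_entry, max_size=4)))
    return VariantRecord(
        chrom=draw(st.sampled_from(_CHROMS)),
        pos=draw(st.integers(1, 2_000_000)),
        ids=tuple(draw(st.lists(_words, max_size=2))),
        ref=draw(_alleles),
        alts=alts,
        qual=draw(st.one_of(st.none(), _floats)),
        filter_status=draw(st.sampled_from([None, ("PASS",), ("q10", "s50")])),
        info=info,
        calls={s: draw(genotype_calls(len(alts))) for s in samples},
    )


@st.composite
def variant_sets(draw, max_records: int = 12) -> VariantSet:
    samples = draw(st.sampled_from([(), ("S1",), ("S1", "S2")]))
    records = draw(
        st.lists(variant_records(samples), max_size=max_records)
    )
    return VariantSet(meta=["##fileformat=VCFv4.2"], samples=list(samples),
                      records=records)


# ---------------------------------------------------------------------------
# a small shared synthetic study (module-scale; the acceptance suite builds
# its own full-size ones)
# ---------------------------------------------------------------------------

SMALL_CFG = dict(seed=42, n_background_variants=2_000, n_genes=200)


@pytest.fixture(scope="session")
def small_cfg() -> SynthConfig:
    return SynthConfig(model="AR_HOM", **SMALL_CFG)


@pytest.fixture(scope="session")
def small_study(small_cfg, tmp_path_factory):
    """Annotated AR_HOM trio plus panels, catalogs and planted truth."""
    outdir = tmp_path_factory.mktemp("synth_ar_hom")
    panels = make_panels(small_cfg, outdir)
    trio, ped, truth = make_family(small_cfg, outdir)
    annotated = annotate_all(sanity_check(trio), panels.annotation_config)
    return {
        "cfg": small_cfg,
        "panels": panels,
        "trio": trio,
        "annotated": annotated,
        "ped": ped,
        "truth": truth,
        "gene_catalog": load_gene_catalog(panels.gene_catalog),
        "disease_catalog": load_disease_catalog(panels.disease_catalog),
        "dataset": generate_dataset(small_cfg),
    }
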