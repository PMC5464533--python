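"""Declarative filtering and inheritance-model behaviour."""

import pytest

from mendelkit.catalog import GenePanel
from mendelkit.errors import FilterConfigError, PedigreeError
from mendelkit.filter_engine import (
    AD_HET,
    AR_COMPHET,
    AR_HOM,
    DE_NOVO,
    XL_HEMI,
    CandidateReport,
    FilterSpec,
    Pedigree,
    apply_filters,
    filter_inheritance,
    genes_in_common,
)
from mendelkit.records import GenotypeCall, VariantRecord, VariantSet

TRIO = ("CHILD", "MUM", "DAD")


def _rec(chrom="1", pos=100, gts=((0, 1),), info=None, qual=None, dp=None,
         samples=("S1",), alts=("G",)):
    calls = {}
    for i, s in enumerate(samples):
        gt = gts[i] if i < len(gts) else (0, 0)
        depth = dp[i] if isinstance(dp, (list, tuple)) else dp
        calls[s] = GenotypeCall(allele_indices=gt, depth=depth)
    return VariantRecord(chrom, pos, (), "A", tuple(alts), qual, None,
                         dict(info or {}), calls)


def _vs(records, samples=("S1",)):
    return VariantSet(meta=["##fileformat=VCFv4.2"], samples=list(samples),
                      records=records)


class TestApplyFilters:
    def test_empty_spec_is_identity(self):
        vs = _vs([_rec(pos=p) for p in (1, 2, 3)])
        report = apply_filters(vs, FilterSpec(), "S1")
        assert report.records == vs.records
        assert report.input_count == report.output_count == 3

    def test_dbsnp_build_boundary(self):
        vs = _vs([
            _rec(pos=1, info={"dbsnp_build": (129,)}),
            _rec(pos=2, info={"dbsnp_build": (130,)}),
            _rec(pos=3, info={}),
        ])
        report = apply_filters(vs, FilterSpec(max_dbsnp_build=129), "S1")
        assert [r.pos for r in report.records] == [2, 3]

    def test_depth_boundary_and_missing_dp(self):
        vs = _vs([
            _rec(pos=1, dp=9),
            _rec(pos=2, dp=10),
            _rec(pos=3, dp=None),
        ])
        report = apply_filters(vs, FilterSpec(min_depth=10), "S1")
        assert [r.pos for r in report.records] == [2, 3]
        strict = apply_filters(
            vs, FilterSpec(min_depth=10, require_depth=True), "S1")
        assert [r.pos for r in strict.records] == [2]

    def test_frequency_excludes_common_keeps_rare_and_absent(self):
        vs = _vs([
            _rec(pos=1, info={"1000g_AF": (0.2,)}),
            _rec(pos=2, info={"1000g_AF": (0.005,)}),
            _rec(pos=3, info={}),
        ])
        spec = FilterSpec(max_panel_frequency={"1000g": 0.01})
        report = apply_filters(vs, spec, "S1")
        assert [r.pos for r in report.records] == [2, 3]
        drop_absent = FilterSpec(max_panel_frequency={"1000g": 0.01},
                                 keep_unannotated_frequency=False)
        assert [r.pos for r in apply_filters(vs, drop_absent, "S1").records] \
            == [2]

    def test_multiallelic_survives_if_any_alt_survives(self):
        vs = _vs([
            _rec(pos=1, alts=("G", "T"), info={"1000g_AF": (0.3, 0.001)}),
            _rec(pos=2, alts=("G", "T"), info={"1000g_AF": (0.3, 0.2)}),
        ])
        spec = FilterSpec(max_panel_frequency={"1000g": 0.01})
        assert [r.pos for r in apply_filters(vs, spec, "S1").records] == [1]

    def test_zygosity_impact_gene_and_region(self):
        panel = GenePanel("p", frozenset({"G1"}))
        vs = _vs([
            _rec(pos=1, gts=((1, 1),), info={"impact": "HIGH", "gene": "G1"}),
            _rec(pos=2, gts=((0, 1),), info={"impact": "HIGH", "gene": "G1"}),
            _rec(pos=3, gts=((1, 1),), info={"impact": "LOW", "gene": "G1"}),
            _rec(pos=4, gts=((1, 1),), info={"impact": "HIGH", "gene": "G2"}),
            _rec(pos=900, gts=((1, 1),),
                 info={"impact": "HIGH", "gene": "G1"}),
        ])
        spec = FilterSpec(
            zygosity={"hom_alt"}, impacts={"HIGH"}, gene_panel=panel,
            regions=(("1", 1, 500),),
        )
        assert [r.pos for r in apply_filters(vs, spec, "S1").records] == [1]

    def test_score_threshold_directions(self):
        vs = _vs([
            _rec(pos=1, info={"dbnsfp_sift_score": (0.01,)}),
            _rec(pos=2, info={"dbnsfp_sift_score": (0.8,)}),
            _rec(pos=3, info={}),
        ])
        spec = FilterSpec(score_thresholds={
            "dbnsfp_sift_score": ("le", 0.05)})
        assert [r.pos for r in apply_filters(vs, spec, "S1").records] == \
            [1, 3]

    def test_unreferenced_field_raises_config_error(self):
        vs = _vs([_rec(pos=1, info={"impact": "HIGH"})])
        with pytest.raises(FilterConfigError, match="gene"):
            apply_filters(
                vs, FilterSpec(gene_panel=GenePanel("p", frozenset({"X"}))),
                "S1")

    def test_tightening_is_monotone(self):
        vs = _vs([
            _rec(pos=p, dp=d, info={"1000g_AF": (f,)})
            for p, d, f in [(1, 50, 0.001), (2, 9, 0.001), (3, 50, 0.3),
                            (4, 12, 0.02)]
        ])
        loose = apply_filters(
            vs, FilterSpec(min_depth=5,
                           max_panel_frequency={"1000g": 0.5}), "S1")
        tight = apply_filters(
            vs, FilterSpec(min_depth=10,
                           max_panel_frequency={"1000g": 0.01}), "S1")
        assert {r.pos for r in tight.records} <= \
            {r.pos for r in loose.records}

    def test_unknown_sample_rejected(self):
        vs = _vs([_rec()])
        with pytest.raises(FilterConfigError, match="NOPE"):
            apply_filters(vs, FilterSpec(), "NOPE")


class TestGenesInCommon:
    def _report(self, genes):
        records = [
            _rec(pos=i + 1, info={"gene": g}) for i, g in enumerate(genes)
        ]
        return CandidateReport(records=records, input_count=len(records),
                               output_count=len(records))

    def test_single_individual(self):
        panel = genes_in_common({"a": self._report(["A", "B"])})
        assert panel.symbols == {"A", "B"}

    def test_two_individuals_intersection(self):
        panel = genes_in_common({
            "a": self._report(["A", "B"]),
            "b": self._report(["B", "C"]),
        })
        assert panel.symbols == {"B"}

    def test_five_individuals_equal_bruteforce(self):
        import numpy as np

        rng = np.random.default_rng(3)
        universe = [f"G{i}" for i in range(30)]
        gene_sets = []
        reports = {}
        for i in range(5):
            picks = {universe[int(j)] for j in
                     rng.choice(30, size=12, replace=False)}
            gene_sets.append(picks)
            reports[f"ind{i}"] = self._report(sorted(picks))
        expected = set.intersection(*gene_sets)
        assert genes_in_common(reports).symbols == expected

    def test_empty_map_is_error(self):
        with pytest.raises(FilterConfigError):
            genes_in_common({})


def _trio_vs(rows, chrom="1"):
    """rows: list of (pos, gene, child_gt, mum_gt, dad_gt)."""
    records = []
    for pos, gene, child, mum, dad in rows:
        records.append(_rec(
            chrom=chrom, pos=pos, gts=(child, mum, dad),
            info={"gene": gene}, samples=TRIO,
        ))
    return _vs(records, samples=TRIO)


PED = Pedigree(proband="CHILD", mother="MUM", father="DAD",
               unaffected_members=("MUM", "DAD"), sex_of_proband="male")


class TestInheritance:
    def test_ar_hom_textbook_trio(self):
        vs = _trio_vs([(100, "G1", (1, 1), (0, 1), (0, 1)),
                       (200, "G1", (1, 1), (1, 1), (0, 1)),
                       (300, "G1", (0, 1), (0, 1), (0, 1))])
        report = filter_inheritance(vs, PED, AR_HOM)
        assert [r.pos for r in report.records] == [100]

    def test_ar_hom_proband_only_degrades(self):
        vs = _vs([_rec(pos=1, gts=((1, 1),), samples=("CHILD",)),
                  _rec(pos=2, gts=((0, 1),), samples=("CHILD",))],
                 samples=("CHILD",))
        ped = Pedigree(proband="CHILD")
        assert [r.pos for r in
                filter_inheritance(vs, ped, AR_HOM).records] == [1]

    def test_comphet_trans_kept_cis_dropped(self):
        trans = _trio_vs([
            (100, "G1", (0, 1), (0, 1), (0, 0)),
            (200, "G1", (0, 1), (0, 0), (0, 1)),
        ])
        report = filter_inheritance(trans, PED, AR_COMPHET)
        assert {r.pos for r in report.records} == {100, 200}

        cis = _trio_vs([
            (100, "G1", (0, 1), (0, 1), (0, 0)),
            (200, "G1", (0, 1), (0, 1), (0, 0)),
        ])
        assert filter_inheritance(cis, PED, AR_COMPHET).records == []

    def test_comphet_without_parents_flags_phase(self):
        vs = _vs([
            _rec(pos=100, gts=((0, 1),), info={"gene": "G1"},
                 samples=("CHILD",)),
            _rec(pos=200, gts=((0, 1),), info={"gene": "G1"},
                 samples=("CHILD",)),
        ], samples=("CHILD",))
        ped = Pedigree(proband="CHILD")
        report = filter_inheritance(vs, ped, AR_COMPHET)
        assert len(report.records) == 2
        assert all("phase-unverified" in report.provenance[r.key]
                   for r in report.records)

    def test_comphet_single_het_not_enough(self):
        vs = _trio_vs([(100, "G1", (0, 1), (0, 1), (0, 0))])
        assert filter_inheritance(vs, PED, AR_COMPHET).records == []

    def test_de_novo_definition(self):
        vs = _trio_vs([
            (100, "G1", (0, 1), (0, 0), (0, 0)),
            (200, "G1", (0, 1), (0, 0), (0, 1)),
            (300, "G1", (0, 1), None, (0, 0)),  # unverifiable parent
        ])
        report = filter_inheritance(vs, PED, DE_NOVO)
        assert [r.pos for r in report.records] == [100]

    def test_de_novo_requires_both_parents(self):
        vs = _vs([_rec(pos=1, gts=((0, 1),), samples=("CHILD",))],
                 samples=("CHILD",))
        with pytest.raises(PedigreeError):
            filter_inheritance(vs, Pedigree(proband="CHILD"), DE_NOVO)

    def test_ad_het_unaffected_carrier_excluded(self):
        vs = _trio_vs([
            (100, "G1", (0, 1), (0, 0), (0, 0)),
            (200, "G1", (0, 1), (0, 1), (0, 0)),  # unaffected mum carries
            (300, "G1", (1, 1), (0, 0), (0, 0)),  # not het
        ])
        report = filter_inheritance(vs, PED, AD_HET)
        assert [r.pos for r in report.records] == [100]

    def test_ad_het_affected_sibling_must_carry(self):
        samples = ("CHILD", "SIB")
        ped = Pedigree(proband="CHILD", affected_siblings=("SIB",))
        vs = _vs([
            _rec(pos=1, gts=((0, 1), (0, 1)), samples=samples),
            _rec(pos=2, gts=((0, 1), (0, 0)), samples=samples),
            _rec(pos=3, gts=((0, 1), None), samples=samples),  # unproven
        ], samples=samples)
        report = filter_inheritance(vs, ped, AD_HET)
        assert [r.pos for r in report.records] == [1]

    def test_xl_hemi_rules(self):
        vs = _trio_vs([
            (100, "G1", (1,), (0, 1), (0,)),
            (200, "G1", (1, 1), (0, 1), (0,)),  # effectively hom alt
            (300, "G1", (1,), (1, 1), (0,)),  # mother hom, not het
            (400, "G1", (0,), (0, 1), (0,)),  # hemi ref
        ], chrom="X")
        report = filter_inheritance(vs, PED, XL_HEMI)
        assert [r.pos for r in report.records] == [100, 200]
        autosomal = _trio_vs([(100, "G1", (1,), (0, 1), (0,))], chrom="5")
        assert filter_inheritance(autosomal, PED, XL_HEMI).records == []

    def test_xl_hemi_requires_male_proband(self):
        vs = _trio_vs([(100, "G1", (1,), (0, 1), (0,))], chrom="X")
        ped = Pedigree(proband="CHILD", mother="MUM", father="DAD")
        with pytest.raises(PedigreeError, match="male"):
            filter_inheritance(vs, ped, XL_HEMI)

    def test_per_sample_vcfs_equal_multisample(self):
        multi = _trio_vs([
            (100, "G1", (1, 1), (0, 1), (0, 1)),
            (200, "G1", (1, 1), (0, 1), (1, 1)),
            (300, "G1", (1, 1), (0, 1), (0, 0)),
        ])
        from_multi = filter_inheritance(multi, PED, AR_HOM)
        split = {}
        for name in TRIO:
            single = multi.subset_samples([name])
            # mimic per-sample uploads: each file lists only non-ref sites
            single.records = [
                r for r in single.records if r.calls[name].carries_alt
            ]
            split[name] = single
        from_split = filter_inheritance(split, PED, AR_HOM)
        assert [r.pos for r in from_multi.records] == \
            [r.pos for r in from_split.records] == [100]


class TestPedigreeFile:
    def test_roundtrip_roles(self, tmp_path):
        path = tmp_path / "t.ped"
        path.write_text(
            "FAM1 CHILD DAD MUM 1 2\n"
            "FAM1 MUM 0 0 2 1\n"
            "FAM1 DAD 0 0 1 1\n"
            "FAM1 SIB DAD MUM 2 2\n"
        )
        ped = Pedigree.from_ped_file(path)
        assert ped.proband == "CHILD"
        assert (ped.mother, ped.father) == ("MUM", "DAD")
        assert ped.affected_siblings == ("SIB",)
        assert set(ped.unaffected_members) == {"MUM", "DAD"}
        assert ped.sex_of_proband == "male"

    def test_no_affected_sample_is_error(self, tmp_path):
        path = tmp_path / "t.ped"
        path.write_text("FAM1 A 0 0 1 1\n")
        with pytest.raises(PedigreeError):
            Pedigree.from_ped_file(path)


class TestSpecSerialization:
    def test_yaml_roundtrip(self, tmp_path):
        spec = FilterSpec(
            zygosity={"het", "hom_alt"},
            impacts={"HIGH", "MODERATE"},
            min_depth=10,
            max_dbsnp_build=129,
            max_panel_frequency={"1000g": 0.01, "esp": 0.01},
            regions=(("1", 100, 200),),
            gene_panel=GenePanel("p", frozenset({"A", "B"})),
            score_thresholds={"dbnsfp_sift_score": ("le", 0.05)},
        )
        path = tmp_path / "spec.yaml"
        spec.to_yaml(path)
        back = FilterSpec.from_yaml(path)
        assert back.zygosity == spec.zygosity
        assert back.impacts == spec.impacts
        assert back.max_panel_frequency == spec.max_panel_frequency
        assert back.regions == spec.regions
        assert back.gene_panel.symbols == spec.gene_panel.symbols
        assert back.score_thresholds == spec.score_thresholds

    def test_invalid_values_rejected(self):
        with pytest.raises(FilterConfigError):
            FilterSpec(max_panel_frequency={"1000g": 1.5})
        with pytest.raises(FilterConfigError):
            FilterSpec(min_depth=-1)
        with pytest.raises(FilterConfigError):
            FilterSpec(regions=(("1", 200, 100),))
        with pytest.raises(FilterConfigError):
            FilterSpec(zygosity={"banana"})
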