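"""MOI-stratified privacy filters, protein-changing stage, funnel report."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from moiscan.moi_filter import (
    ALL_CASES,
    DEFAULT_PROTEIN_CHANGING_TERMS,
    CandidateSet,
    FilterConfig,
    Moi,
    Stage,
    apply_protein_changing_filter,
    apply_tier2_filter,
    build_funnel_report,
    filter_dominant_individual,
    filter_recessive_individual,
    filter_recessive_shared,
    manual_review_frame,
    run_moi_pipeline,
)
from moiscan.vcf_model import CohortManifest, GenotypeClass, QualLabel, Role

from conftest import make_manifest, make_table

GC = GenotypeClass
P = QualLabel.PASS
MISSENSE = ("missense_variant",)
SYN = ("synonymous_variant",)


@pytest.fixture
def manifest():
    # 2 cases, 2 tier1, 2 tier2 -> columns [c1, c2, t1a, t1b, t2a, t2b]
    return make_manifest(n_cases=2, n_tier1=2, n_tier2=2, pops=["PopA"])


class TestRecessiveShared:
    def test_planted_shared_hom_variant_returned(self, manifest):
        table = make_table(manifest, [
            ("1", 100, "A", "C", P, MISSENSE,
             [GC.HOM_ALT, GC.HOM_ALT, GC.HOM_REF, GC.HET, GC.HOM_REF, GC.HOM_REF]),
        ])
        out = filter_recessive_shared(table, manifest, FilterConfig())
        assert out.keys() == [("1", 100, "A", "C")]
        assert out.stage is Stage.PRIVATE_TIER1

    def test_one_het_case_excludes(self, manifest):
        table = make_table(manifest, [
            ("1", 100, "A", "C", P, MISSENSE,
             [GC.HOM_ALT, GC.HET, GC.HOM_REF, GC.HOM_REF, GC.HOM_REF, GC.HOM_REF]),
        ])
        assert len(filter_recessive_shared(table, manifest, FilterConfig())) == 0

    def test_missing_case_genotype_excludes(self, manifest):
        table = make_table(manifest, [
            ("1", 100, "A", "C", P, MISSENSE,
             [GC.HOM_ALT, GC.MISSING, GC.HOM_REF, GC.HOM_REF, GC.HOM_REF, GC.HOM_REF]),
        ])
        assert len(filter_recessive_shared(table, manifest, FilterConfig())) == 0

    def test_control_homalt_excludes(self, manifest):
        table = make_table(manifest, [
            ("1", 100, "A", "C", P, MISSENSE,
             [GC.HOM_ALT, GC.HOM_ALT, GC.HOM_ALT, GC.HOM_REF, GC.HOM_REF, GC.HOM_REF]),
        ])
        assert len(filter_recessive_shared(table, manifest, FilterConfig())) == 0

    def test_no_shared_variant_yields_empty_set(self, manifest):
        """Cohorts without a shared homozygous variant give the negative result."""
        table = make_table(manifest, [
            ("1", 100, "A", "C", P, MISSENSE,
             [GC.HOM_ALT, GC.HOM_REF, GC.HOM_REF, GC.HOM_REF, GC.HOM_REF, GC.HOM_REF]),
            ("1", 200, "A", "C", P, MISSENSE,
             [GC.HOM_REF, GC.HOM_ALT, GC.HOM_REF, GC.HOM_REF, GC.HOM_REF, GC.HOM_REF]),
        ])
        assert len(filter_recessive_shared(table, manifest, FilterConfig())) == 0

    def test_empty_table_is_not_an_error(self, manifest):
        table = make_table(manifest, [])
        assert len(filter_recessive_shared(table, manifest, FilterConfig())) == 0


class TestRecessiveIndividual:
    def test_het_carriers_in_controls_allowed_by_default(self, manifest):
        # control het carriers must not defeat a case-private homozygote
        table = make_table(manifest, [
            ("1", 100, "A", "C", P, MISSENSE,
             [GC.HOM_ALT, GC.HOM_REF, GC.HET, GC.HOM_REF, GC.HET, GC.HET]),
        ])
        out = filter_recessive_individual(table, "case_1", manifest, FilterConfig())
        assert out.keys() == [("1", 100, "A", "C")]
        # and the tier-2 stage keeps it too (het unbounded there as well)
        pc = apply_protein_changing_filter(out, FilterConfig())
        final = apply_tier2_filter(pc, manifest, FilterConfig())
        assert final.keys() == [("1", 100, "A", "C")]

    def test_control_homalt_excludes(self, manifest):
        table = make_table(manifest, [
            ("1", 100, "A", "C", P, MISSENSE,
             [GC.HOM_ALT, GC.HOM_REF, GC.HOM_ALT, GC.HOM_REF, GC.HOM_REF, GC.HOM_REF]),
        ])
        out = filter_recessive_individual(table, "case_1", manifest, FilterConfig())
        assert len(out) == 0

    def test_other_cases_are_ignored(self, manifest):
        table = make_table(manifest, [
            ("1", 100, "A", "C", P, MISSENSE,
             [GC.HOM_ALT, GC.HOM_ALT, GC.HOM_REF, GC.HOM_REF, GC.HOM_REF, GC.HOM_REF]),
        ])
        out = filter_recessive_individual(table, "case_1", manifest, FilterConfig())
        assert len(out) == 1

    def test_het_threshold_enforced_when_set(self, manifest):
        cfg = FilterConfig(recessive_max_control_het_tier1=0)
        table = make_table(manifest, [
            ("1", 100, "A", "C", P, MISSENSE,
             [GC.HOM_ALT, GC.HOM_REF, GC.HET, GC.HOM_REF, GC.HOM_REF, GC.HOM_REF]),
        ])
        assert len(filter_recessive_individual(table, "case_1", manifest, cfg)) == 0

    def test_unknown_case_id_hard_error(self, manifest):
        table = make_table(manifest, [])
        with pytest.raises(KeyError):
            filter_recessive_individual(table, "nope", manifest, FilterConfig())
        with pytest.raises(ValueError):
            filter_recessive_individual(table, "ctrl1_0001", manifest, FilterConfig())


class TestDominantIndividual:
    def test_case_private_het_retained(self, manifest):
        table = make_table(manifest, [
            ("1", 100, "A", "C", P, MISSENSE,
             [GC.HET, GC.HOM_REF, GC.HOM_REF, GC.HOM_REF, GC.HOM_REF, GC.HOM_REF]),
        ])
        out = filter_dominant_individual(table, "case_1", manifest, FilterConfig())
        assert out.keys() == [("1", 100, "A", "C")]

    def test_single_control_het_excludes(self, manifest):
        table = make_table(manifest, [
            ("1", 100, "A", "C", P, MISSENSE,
             [GC.HET, GC.HOM_REF, GC.HET, GC.HOM_REF, GC.HOM_REF, GC.HOM_REF]),
        ])
        assert len(filter_dominant_individual(table, "case_1", manifest, FilterConfig())) == 0

    def test_digenic_pattern_two_final_candidates(self, manifest):
        table = make_table(manifest, [
            ("1", 100, "A", "C", P, MISSENSE,
             [GC.HET, GC.HOM_REF, GC.HOM_REF, GC.HOM_REF, GC.HOM_REF, GC.HOM_REF]),
            ("2", 200, "G", "T", P, MISSENSE,
             [GC.HET, GC.HOM_REF, GC.HOM_REF, GC.HOM_REF, GC.HOM_REF, GC.HOM_REF]),
        ])
        stages = run_moi_pipeline(table, manifest, FilterConfig(), Moi.DOMINANT_INDIVIDUAL, "case_1")
        final = stages[Stage.POST_TIER2]
        assert len(final) == 2
        assert len(final.gene_symbols()) == 2

    def test_quality_gate_applied(self, manifest):
        table = make_table(manifest, [
            ("1", 100, "A", "C", QualLabel.FAIL, MISSENSE,
             [GC.HET, GC.HOM_REF, GC.HOM_REF, GC.HOM_REF, GC.HOM_REF, GC.HOM_REF]),
            ("1", 200, "A", "C", QualLabel.UNLABELED, MISSENSE,
             [GC.HET, GC.HOM_REF, GC.HOM_REF, GC.HOM_REF, GC.HOM_REF, GC.HOM_REF]),
        ])
        assert len(filter_dominant_individual(table, "case_1", manifest, FilterConfig())) == 0
        relaxed = FilterConfig(include_unlabeled=True)
        out = filter_dominant_individual(table, "case_1", manifest, relaxed)
        assert out.keys() == [("1", 200, "A", "C")]


class TestProteinChangingFilter:
    def test_missense_kept_synonymous_removed(self, manifest):
        table = make_table(manifest, [
            ("1", 100, "A", "C", P, MISSENSE, [GC.HET] + [GC.HOM_REF] * 5),
            ("1", 200, "A", "C", P, SYN, [GC.HET] + [GC.HOM_REF] * 5),
            ("1", 300, "A", "C", P, None, [GC.HET] + [GC.HOM_REF] * 5),
        ])
        cset = filter_dominant_individual(table, "case_1", manifest, FilterConfig())
        out = apply_protein_changing_filter(cset, FilterConfig())
        assert out.keys() == [("1", 100, "A", "C")]

    def test_inframe_deletion_is_protein_changing(self, manifest):
        table = make_table(manifest, [
            ("1", 100, "ACCCGAGCCCGAG", "A", P, ("disruptive_inframe_deletion",),
             [GC.HET] + [GC.HOM_REF] * 5),
        ])
        cset = filter_dominant_individual(table, "case_1", manifest, FilterConfig())
        out = apply_protein_changing_filter(cset, FilterConfig())
        assert len(out) == 1

    def test_requires_private_stage(self, manifest):
        cset = CandidateSet("case_1", Moi.DOMINANT_INDIVIDUAL, Stage.ALL, [], manifest.samples)
        with pytest.raises(ValueError, match="PRIVATE_TIER1"):
            apply_protein_changing_filter(cset, FilterConfig())


class TestTier2Filter:
    def test_tier2_homalt_removes_recessive_candidate(self, manifest):
        table = make_table(manifest, [
            ("1", 100, "A", "C", P, MISSENSE,
             [GC.HOM_ALT, GC.HOM_REF, GC.HOM_REF, GC.HOM_REF, GC.HOM_ALT, GC.HOM_REF]),
        ])
        cset = filter_recessive_individual(table, "case_1", manifest, FilterConfig())
        pc = apply_protein_changing_filter(cset, FilterConfig())
        assert len(pc) == 1
        assert len(apply_tier2_filter(pc, manifest, FilterConfig())) == 0

    def test_empty_tier2_cohort_is_identity(self):
        manifest = make_manifest(n_cases=1, n_tier1=2, n_tier2=0)
        table = make_table(manifest, [
            ("1", 100, "A", "C", P, MISSENSE, [GC.HET, GC.HOM_REF, GC.HOM_REF]),
        ])
        cset = filter_dominant_individual(table, "case_1", manifest, FilterConfig())
        pc = apply_protein_changing_filter(cset, FilterConfig())
        out = apply_tier2_filter(pc, manifest, FilterConfig())
        assert out.keys() == pc.keys()

    def test_manual_review_export(self, manifest, tmp_path):
        table = make_table(manifest, [
            ("1", 100, "A", "C", P, MISSENSE, [GC.HET] + [GC.HOM_REF] * 5),
        ])
        cset = filter_dominant_individual(table, "case_1", manifest, FilterConfig())
        pc = apply_protein_changing_filter(cset, FilterConfig())
        review = tmp_path / "review.tsv"
        apply_tier2_filter(pc, manifest, FilterConfig(), review_path=review)
        text = review.read_text().splitlines()
        assert text[0].split("\t") == ["chrom", "pos", "ref", "alt", "case", "genotype", "gene"]
        assert text[1].split("\t")[:6] == ["1", "100", "A", "C", "case_1", "HET"]


class TestFunnelReport:
    def test_counts_and_gene_column(self, manifest):
        table = make_table(manifest, [
            ("1", 100, "A", "C", P, MISSENSE, [GC.HET] + [GC.HOM_REF] * 5),
            ("1", 200, "A", "C", P, SYN, [GC.HET] + [GC.HOM_REF] * 5),
            ("1", 300, "A", "C", P, MISSENSE, [GC.HET, GC.HOM_REF, GC.HET,
                                               GC.HOM_REF, GC.HOM_REF, GC.HOM_REF]),
        ])
        stages = run_moi_pipeline(table, manifest, FilterConfig(), Moi.DOMINANT_INDIVIDUAL, "case_1")
        report = build_funnel_report({("case_1", Moi.DOMINANT_INDIVIDUAL): stages})
        frame = report.to_frame()
        row = frame.iloc[0]
        assert (row["all_variants"], row["private_variants_tier1"],
                row["private_protein_changing_tier1"], row["remaining_post_tier2"]) == (3, 2, 1, 1)
        assert row["candidate_genes"] == "G100"

    def test_empty_pipeline_prints_none(self, manifest):
        table = make_table(manifest, [])
        stages = run_moi_pipeline(table, manifest, FilterConfig(), Moi.RECESSIVE_SHARED)
        report = build_funnel_report({(ALL_CASES, Moi.RECESSIVE_SHARED): stages})
        row = report.to_frame().iloc[0]
        assert row["candidate_genes"] == "None"
        assert row["all_variants"] == 0

    def test_missing_stage_hard_error(self, manifest):
        table = make_table(manifest, [])
        stages = run_moi_pipeline(table, manifest, FilterConfig(), Moi.RECESSIVE_SHARED)
        del stages[Stage.POST_TIER2]
        with pytest.raises(ValueError, match="POST_TIER2"):
            build_funnel_report({(ALL_CASES, Moi.RECESSIVE_SHARED): stages})

    def test_tsv_column_order(self, manifest, tmp_path):
        table = make_table(manifest, [])
        stages = run_moi_pipeline(table, manifest, FilterConfig(), Moi.RECESSIVE_SHARED)
        report = build_funnel_report({(ALL_CASES, Moi.RECESSIVE_SHARED): stages})
        path = tmp_path / "funnel.tsv"
        report.to_tsv(path)
        header = path.read_text().splitlines()[0].split("\t")
        assert header == list(report.COLUMNS)


class TestFunnelMonotonicity:
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_stage_counts_never_increase(self, seed):
        rng = np.random.default_rng(seed)
        manifest = make_manifest(n_cases=3, n_tier1=4, n_tier2=4, pops=["PopA", "PopB"])
        n_s = len(manifest.samples)
        n_v = int(rng.integers(1, 40))
        rows = []
        for i in range(n_v):
            terms = [MISSENSE, SYN, None][int(rng.integers(0, 3))]
            qual = [P, QualLabel.FAIL][int(rng.integers(0, 2))]
            classes = rng.integers(0, 4, size=n_s)
            rows.append(("1", 100 + i, "A", "C", qual, terms, list(classes)))
        table = make_table(manifest, rows)
        for moi, cid in [
            (Moi.RECESSIVE_SHARED, None),
            (Moi.RECESSIVE_INDIVIDUAL, "case_1"),
            (Moi.DOMINANT_INDIVIDUAL, "case_2"),
        ]:
            stages = run_moi_pipeline(table, manifest, FilterConfig(), moi, cid)
            counts = [len(stages[s]) for s in Stage]
            assert counts == sorted(counts, reverse=True)
            # nesting, not just counts
            keys = [set(map(tuple, stages[s].keys())) for s in Stage]
            assert keys[0] >= keys[1] >= keys[2] >= keys[3]


class TestFilterConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = FilterConfig(recessive_max_control_het_tier1=5, dominant_max_control_alt_alleles_tier1=1)
        p = tmp_path / "cfg.yaml"
        cfg.to_yaml(p)
        assert FilterConfig.from_yaml(p) == cfg

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            FilterConfig(recessive_max_control_homalt_tier1=-1)

    def test_default_term_set_covers_reported_candidate_types(self):
        # the 8-candidate spectrum: 7 missense + 1 inframe deletion
        assert "missense_variant" in DEFAULT_PROTEIN_CHANGING_TERMS
        assert "disruptive_inframe_deletion" in DEFAULT_PROTEIN_CHANGING_TERMS
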