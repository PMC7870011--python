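import itertools

import pytest

from canosa.filters import (
    FilterConfig,
    adhoc_filter,
    caller_level_filter,
    clonal_prefilter,
    consequence_filter,
    load_whitelist,
    population_db_filter,
    run_cascade,
)
from canosa.genomic_io import (
    GenomicInterval,
    SampleSupport,
    Segment,
    VariantRecord,
)


def mkvar(chrom="1", pos=1000, ref="A", alt="G", consequence="non_synonymous_coding",
          **support):
    """support kwargs like normal_WGS=(var_reads, depth)."""
    sup = {
        tuple(key.split("_")): SampleSupport(*val) for key, val in support.items()
    }
    return VariantRecord(
        chrom=chrom, pos=pos, ref=ref, alt=alt, consequence=consequence, support=sup
    )


class TestCallerLevelWes:
    def test_low_tumor_vaf_removed(self):
        v = mkvar(primary_WES=(4, 200), normal_WES=(0, 100))  # VAF 2.0%
        decision = caller_level_filter(v, "WES")
        assert not decision.keep
        assert "tumor_vaf_low" in decision.reasons

    def test_clean_variant_retained(self):
        v = mkvar(primary_WES=(30, 60), normal_WES=(0, 50))
        assert caller_level_filter(v, "WES").keep

    def test_boundary_values_are_removals(self):
        # printed bounds are inclusive: VAF 2.5%, 4 reads, 10x all removed
        v = mkvar(primary_WES=(4, 160), normal_WES=(0, 50))
        reasons = caller_level_filter(v, "WES").reasons
        assert {"tumor_vaf_low", "tumor_var_reads_low"} <= set(reasons)
        v = mkvar(primary_WES=(5, 10), normal_WES=(0, 50))
        assert "tumor_cov_low" in caller_level_filter(v, "WES").reasons

    def test_normal_contamination_removed(self):
        v = mkvar(primary_WES=(30, 60), normal_WES=(12, 100))  # normal VAF 12%
        assert "normal_vaf_high" in caller_level_filter(v, "WES").reasons

    def test_conjunctive_normal_rule_switch(self):
        cfg = FilterConfig(conjunctive_normal_rule=True)
        v = mkvar(primary_WES=(30, 60), normal_WES=(12, 100))
        assert caller_level_filter(v, "WES", cfg).keep  # cov 100 > 10
        v = mkvar(primary_WES=(30, 60), normal_WES=(2, 8))
        assert not caller_level_filter(v, "WES", cfg).keep

    def test_missing_normal_entry_names_sample(self):
        v = mkvar(primary_WES=(30, 60))
        with pytest.raises(ValueError, match="normal.WES"):
            caller_level_filter(v, "WES")


class TestCallerLevelWgs:
    def test_low_tumor_vaf_removed(self):
        v = mkvar(primary_WGS=(30, 333), normal_WGS=(0, 60))  # VAF 9%
        decision = caller_level_filter(v, "WGS")
        assert not decision.keep
        assert "tumor_vaf_low" in decision.reasons

    def test_related_sample_rule_skipped_without_related(self):
        v = mkvar(primary_WGS=(30, 60), normal_WGS=(0, 60))
        assert caller_level_filter(v, "WGS").keep

    def test_related_sample_low_vaf_removes(self):
        v = mkvar(
            primary_WGS=(30, 60), normal_WGS=(0, 60), metastasis_WGS=(6, 60)
        )  # related VAF 10% <= 15%
        assert "related_vaf_low" in caller_level_filter(v, "WGS").reasons

    def test_wes_read_support_checked_from_wgs_ruleset(self):
        v = mkvar(
            primary_WGS=(30, 60), normal_WGS=(0, 60), primary_WES=(15, 100),
            normal_WES=(0, 100),
        )
        assert "tumor_var_reads_low_wes" in caller_level_filter(v, "WGS").reasons

    def test_normal_two_reads_removes(self):
        v = mkvar(primary_WGS=(30, 60), normal_WGS=(2, 300))
        assert "normal_support_wgs" in caller_level_filter(v, "WGS").reasons


class TestConsequenceFilter:
    @pytest.mark.parametrize(
        "consequence,kept",
        [
            ("stop_gained", True),
            ("splice_site, synonymous_coding", True),
            ("non_synonymous_coding", True),
            ("intergenic", False),
            ("synonymous_coding", False),  # only whitelisted in combination
            ("", False),
        ],
    )
    def test_exact_string_membership(self, consequence, kept):
        v = mkvar(consequence=consequence)
        assert consequence_filter(v).keep is kept

    def test_whitelist_is_nonempty_and_deduplicated(self):
        wl = load_whitelist()
        assert len(wl) == 20


class TestPopulationDb:
    def test_exact_allele_match_removed(self):
        v = mkvar(pos=500)
        assert not population_db_filter(v, {("1", 500, "A", "G")}).keep

    def test_same_position_different_alt_retained(self):
        v = mkvar(pos=500, alt="T")
        db = {("1", 500, "A", "G")}
        assert population_db_filter(v, db).keep
        # the allele-level decision is what distinguishes this from
        # position-level matching, which would remove it
        assert ("1", 500) == (v.chrom, v.pos)

    def test_empty_database_retains_all(self):
        assert population_db_filter(mkvar(), set()).keep


class TestAdhocFilter:
    def test_scaffold_removed(self):
        v = mkvar(chrom="AAEX03025384.1", primary_WGS=(30, 60), normal_WGS=(0, 60))
        assert "non_canonical_chrom" in adhoc_filter(v).reasons

    def test_rna_support_satisfies_tumor_requirement(self):
        v = mkvar(primary_RNA=(9, 150), normal_WGS=(0, 60))  # VAF 6%
        assert adhoc_filter(v).keep

    def test_normal_five_reads_removed(self):
        v = mkvar(primary_WGS=(30, 60), normal_WGS=(5, 60))
        assert "normal_support_wgs" in adhoc_filter(v).reasons

    def test_seven_reads_but_low_vaf_insufficient(self):
        v = mkvar(primary_WGS=(7, 250), normal_WGS=(0, 60))  # VAF 2.8%
        assert "no_tumor_support" in adhoc_filter(v).reasons


class TestClonalPrefilter:
    def _segments(self):
        loh = [Segment(GenomicInterval("1", 5000, 6000), 0.3, 10, "LOH")]
        cna = [Segment(GenomicInterval("2", 0, 10_000), 1.0, 10, "CN")]
        return loh, cna

    def _clean(self, **overrides):
        base = dict(
            normal_WGS=(0, 60),
            normal_WES=(0, 100),
            primary_WES=(40, 100),
            metastasis_WES=(40, 100),
        )
        base.update(overrides)
        return mkvar(**base)

    def test_any_normal_read_removes(self):
        loh, cna = self._segments()
        v = self._clean(normal_WGS=(1, 60))
        assert "normal_support_wgs" in clonal_prefilter(v, loh, cna).reasons

    def test_wes_depth_below_80_removes(self):
        loh, cna = self._segments()
        v = self._clean(primary_WES=(40, 75))
        assert "wes_depth_low_primary" in clonal_prefilter(v, loh, cna).reasons

    def test_locus_in_loh_space_removed(self):
        loh, cna = self._segments()
        v = self._clean()
        v.pos = 5500
        assert "in_loh_space" in clonal_prefilter(v, loh, cna).reasons

    def test_locus_in_copy_altered_space_removed(self):
        loh, cna = self._segments()
        v = self._clean()
        v.chrom, v.pos = "2", 500
        assert "copy_altered_space" in clonal_prefilter(v, loh, cna).reasons

    def test_clean_variant_retained(self):
        loh, cna = self._segments()
        assert clonal_prefilter(self._clean(), loh, cna).keep


class TestCascade:
    def _toy_set(self):
        variants = []
        # mixture of survivors and stage-specific casualties
        for i in range(8):
            variants.append(
                mkvar(pos=10_000 + i, primary_WGS=(30, 60), normal_WGS=(0, 60))
            )
        variants.append(mkvar(pos=20_000, primary_WGS=(3, 60), normal_WGS=(0, 60)))
        variants.append(
            mkvar(pos=20_001, primary_WGS=(30, 60), normal_WGS=(0, 60),
                  consequence="intergenic")
        )
        variants.append(mkvar(pos=20_002, primary_WGS=(30, 60), normal_WGS=(0, 60)))
        variants.append(
            mkvar(chrom="scaffold_1", pos=20_003, primary_WGS=(30, 60),
                  normal_WGS=(0, 60))
        )
        variants.append(mkvar(pos=20_004, primary_WGS=(30, 60), normal_WGS=(6, 60)))
        return variants, {("1", 20_002, "A", "G")}

    def test_survivors_match_brute_force(self):
        variants, db = self._toy_set()
        retained, report = run_cascade(variants, FilterConfig(), db)

        def brute(v):
            dec = caller_level_filter(v, "WGS")
            if not dec.keep:
                return False
            if not consequence_filter(v).keep:
                return False
            if v.key in db:
                return False
            return adhoc_filter(v).keep

        expected = [v.key for v in variants if brute(v)]
        assert [v.key for v in retained] == expected
        assert report.stages[0].n_input == len(variants)
        for stage in report.stages:
            assert stage.n_input == stage.n_removed + stage.n_retained

    def test_empty_input(self):
        retained, report = run_cascade([], FilterConfig(), set())
        assert retained == []
        assert all(s.n_input == 0 for s in report.stages)

    def test_idempotence(self):
        variants, db = self._toy_set()
        once, _ = run_cascade(variants, FilterConfig(), db)
        twice, _ = run_cascade(once, FilterConfig(), db)
        assert [v.key for v in twice] == [v.key for v in once]

    def test_relaxing_thresholds_never_shrinks_retained_set(self):
        variants, db = self._toy_set()
        baseline_cfg = FilterConfig()
        baseline, _ = run_cascade(variants, baseline_cfg, db)
        for field, relaxed in [
            ("wgs_tumor_vaf_max", 0.05),
            ("adhoc_var_reads_min", 5),
            ("adhoc_vaf_min", 0.02),
            ("adhoc_normal_reads_max", 6),
        ]:
            cfg = FilterConfig(**{field: relaxed})
            retained, _ = run_cascade(variants, cfg, db)
            assert set(v.key for v in baseline) <= set(v.key for v in retained)
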