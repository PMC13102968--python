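import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dnmpipe.config import ConfigurationError, FilterParams
from dnmpipe.validation import (
    AlleleCounts,
    DE_NOVO,
    FAILED,
    INHERITED,
    InputError,
    PedigreeError,
    QualityClass,
    SiteEvidence,
    UNSUPPORTED,
    VALIDATED,
    ab_filters,
    classify_read,
    combine_platform_verdicts,
    filter_clusters,
    homopolymer_filter,
    recurrence_filter,
    select_candidates,
    validate_indel,
    validate_sex_chromosome,
    validate_snv_platform,
)

PARAMS = FilterParams()


def _pedigree():
    return pd.DataFrame(
        {
            "family": ["F1"] * 3,
            "individual": ["F1_fa", "F1_mo", "F1_c1"],
            "father": ["0", "0", "F1_fa"],
            "mother": ["0", "0", "F1_mo"],
            "sex": [1, 2, 1],
            "phenotype": [1, 1, 2],
            "role": ["father", "mother", "child"],
            "father_age": [np.nan, np.nan, 30.0],
            "mother_age": [np.nan, np.nan, 28.0],
        }
    )


def _genotypes(child_gt="0/1", child_gq=30, father_gt="0/0", mother_gt="0/0"):
    return pd.DataFrame(
        {
            "family": ["F1"] * 3,
            "chrom": ["chr1"] * 3,
            "pos": [100] * 3,
            "ref": ["A"] * 3,
            "alt": ["G"] * 3,
            "sample": ["F1_fa", "F1_mo", "F1_c1"],
            "gt": [father_gt, mother_gt, child_gt],
            "gq": [50, 50, child_gq],
        }
    )


class TestSelectCandidates:
    def test_basic_candidate(self):
        out = select_candidates(_genotypes(), _pedigree())
        assert len(out) == 1
        assert out.iloc[0]["child"] == "F1_c1"
        assert out.iloc[0]["var_class"] == "snv"

    def test_low_gq_rejected(self):
        out = select_candidates(_genotypes(child_gq=19), _pedigree())
        assert len(out) == 0

    def test_gq_exactly_20_kept(self):
        out = select_candidates(_genotypes(child_gq=20), _pedigree())
        assert len(out) == 1

    def test_parent_carrier_rejected(self):
        out = select_candidates(_genotypes(father_gt="0/1"), _pedigree())
        assert len(out) == 0

    def test_missing_child_raises(self):
        geno = _genotypes()
        geno = geno[geno["sample"] != "F1_c1"]
        with pytest.raises(PedigreeError):
            select_candidates(geno, _pedigree())


class TestClusterFilter:
    def brute_force(self, positions, window=1000, k=3):
        """Independent oracle: scan all windows left-aligned on a candidate
        position (sufficient: any qualifying interval can be shifted until
        its left edge touches its leftmost contained position)."""
        positions = np.asarray(positions)
        excluded = np.zeros(len(positions), dtype=bool)
        for i, p in enumerate(positions):
            for lo in positions:
                hi = lo + window
                inside = (positions >= lo) & (positions <= hi)
                if lo <= p <= hi and inside.sum() >= k:
                    excluded[i] = True
                    break
        return excluded

    def test_three_in_800bp_all_excluded(self):
        assert filter_clusters([100, 500, 900]).all()

    def test_pair_kept(self):
        assert not filter_clusters([100, 900]).any()

    def test_spread_triple_kept(self):
        assert not filter_clusters([0, 600, 1200]).any()

    @given(
        st.lists(st.integers(min_value=0, max_value=5000), min_size=0, max_size=12)
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force(self, positions):
        got = filter_clusters(positions)
        want = self.brute_force(positions)
        assert (got == want).all()


class TestClassifyRead:
    def test_high(self):
        assert classify_read(25, 60, "hifi") is QualityClass.HIGH

    def test_low(self):
        assert classify_read(15, 60, "ont") is QualityClass.LOW

    def test_mapq_excluded_long_read(self):
        assert classify_read(30, 58, "hifi") is QualityClass.MAPQ_EXCLUDED

    def test_short_read_never_mapq_excluded(self):
        assert classify_read(30, 0, "illumina") is QualityClass.HIGH

    def test_discard(self):
        assert classify_read(9, 60, "hifi") is QualityClass.DISCARD

    def test_boundaries(self):
        assert classify_read(20, 60, "hifi") is QualityClass.LOW
        assert classify_read(21, 60, "hifi") is QualityClass.HIGH
        assert classify_read(10, 60, "hifi") is QualityClass.LOW
        assert classify_read(30, 59, "ont") is QualityClass.HIGH

    def test_unknown_platform(self):
        with pytest.raises(ConfigurationError):
            classify_read(30, 60, "454")


def _evidence(counts) -> SiteEvidence:
    ev = SiteEvidence()
    for (sample, platform), c in counts.items():
        ev.counts[(sample, platform)] = AlleleCounts(*c)
    return ev


class TestPlatformValidation:
    # counts are (high_alt, low_alt, high_ref, low_ref, other)
    def test_parent_single_hq_alt_inherited_hifi(self):
        ev = _evidence({
            ("fa", "hifi"): (1, 0, 20, 0, 0),
            ("mo", "hifi"): (0, 0, 20, 0, 0),
            ("ch", "hifi"): (10, 0, 10, 0, 0),
        })
        assert validate_snv_platform(ev, "hifi", "fa", "mo", "ch") == INHERITED

    def test_parent_two_lq_alt_inherited_hifi(self):
        ev = _evidence({
            ("fa", "hifi"): (0, 2, 20, 0, 0),
            ("mo", "hifi"): (0, 0, 20, 0, 0),
            ("ch", "hifi"): (10, 0, 10, 0, 0),
        })
        assert validate_snv_platform(ev, "hifi", "fa", "mo", "ch") == INHERITED

    def test_parent_one_lq_alt_passes_hifi(self):
        ev = _evidence({
            ("fa", "hifi"): (0, 1, 20, 0, 0),
            ("mo", "hifi"): (0, 0, 20, 0, 0),
            ("ch", "hifi"): (10, 0, 10, 0, 0),
        })
        assert validate_snv_platform(ev, "hifi", "fa", "mo", "ch") == DE_NOVO

    def test_ont_looser_ceilings(self):
        ev = _evidence({
            ("fa", "ont"): (1, 2, 20, 0, 0),
            ("mo", "ont"): (0, 0, 20, 0, 0),
            ("ch", "ont"): (10, 0, 10, 0, 0),
        })
        assert validate_snv_platform(ev, "ont", "fa", "mo", "ch") == DE_NOVO

    def test_ont_two_hq_alt_inherited(self):
        ev = _evidence({
            ("fa", "ont"): (2, 0, 20, 0, 0),
            ("ch", "ont"): (10, 0, 10, 0, 0),
        })
        assert validate_snv_platform(ev, "ont", "fa", "mo", "ch") == INHERITED

    def test_child_without_alt_unsupported(self):
        ev = _evidence({
            ("fa", "hifi"): (0, 0, 20, 0, 0),
            ("mo", "hifi"): (0, 0, 20, 0, 0),
            ("ch", "hifi"): (0, 0, 20, 0, 0),
        })
        assert validate_snv_platform(ev, "hifi", "fa", "mo", "ch") == UNSUPPORTED

    def test_missing_child_evidence_unsupported(self):
        ev = _evidence({("fa", "hifi"): (0, 0, 20, 0, 0)})
        assert validate_snv_platform(ev, "hifi", "fa", "mo", "ch") == UNSUPPORTED


class TestCombineVerdicts:
    def test_two_platforms_validate(self):
        v = {"hifi": DE_NOVO, "illumina": DE_NOVO, "ont": UNSUPPORTED}
        assert combine_platform_verdicts(v) == VALIDATED

    def test_any_inherited_wins(self):
        v = {"hifi": DE_NOVO, "ont": INHERITED, "illumina": DE_NOVO}
        assert combine_platform_verdicts(v) == INHERITED

    def test_single_support_fails(self):
        v = {"hifi": DE_NOVO, "ont": UNSUPPORTED, "illumina": UNSUPPORTED}
        assert combine_platform_verdicts(v) == FAILED

    def test_cellline_only_needs_illumina_support(self):
        v = {"hifi": DE_NOVO, "ont": DE_NOVO, "illumina": DE_NOVO}
        assert (
            combine_platform_verdicts(v, cellline_only=True, illumina_child_hq_alt=1)
            == FAILED
        )
        assert (
            combine_platform_verdicts(v, cellline_only=True, illumina_child_hq_alt=2)
            == VALIDATED
        )


class TestRecurrence:
    def _carriers(self, samples_families):
        return pd.DataFrame(
            [("chr1", 100, s, f) for s, f in samples_families],
            columns=["chrom", "pos", "sample", "family"],
        )

    def test_nontr_one_unrelated_fails(self):
        carriers = self._carriers([("X1", "F9")])
        assert not recurrence_filter("F1", "chr1", 100, carriers, False)

    def test_tr_one_unrelated_passes_two_fail(self):
        one = self._carriers([("X1", "F9")])
        two = self._carriers([("X1", "F9"), ("X2", "F8")])
        assert recurrence_filter("F1", "chr1", 100, one, True)
        assert not recurrence_filter("F1", "chr1", 100, two, True)

    def test_nobody_else_passes(self):
        assert recurrence_filter("F1", "chr1", 100, self._carriers([]), False)

    def test_family_members_ignored(self):
        carriers = self._carriers([("F1_c2", "F1")])
        assert recurrence_filter("F1", "chr1", 100, carriers, False)


class TestAbFilters:
    def _ev(self, ab_per_platform):
        counts = {}
        for platform, ab in ab_per_platform.items():
            alt = int(round(ab * 100))
            counts[("ch", platform)] = (alt, 0, 100 - alt, 0, 0)
        return _evidence(counts)

    def test_tr_low_ab_fails(self):
        ev = self._ev({"hifi": 0.04, "ont": 0.04, "illumina": 0.04})
        ok, reason = ab_filters(ev, "ch", True, False)
        assert not ok and reason == "tr_ab"

    def test_rm_and_tr_requires_point_one(self):
        ev = self._ev({"hifi": 0.09, "ont": 0.09, "illumina": 0.09})
        ok, _ = ab_filters(ev, "ch", True, True)
        assert not ok

    def test_rm_non_tr_point_oh_eight(self):
        ev = self._ev({"hifi": 0.09, "ont": 0.09, "illumina": 0.09})
        ok, _ = ab_filters(ev, "ch", False, True)
        assert ok

    def test_no_reads_fails(self):
        ok, reason = ab_filters(SiteEvidence(), "ch", False, False)
        assert not ok and reason == "no_evidence"

    def test_plain_variant_unfiltered(self):
        ev = self._ev({"hifi": 0.02})
        ok, _ = ab_filters(ev, "ch", False, False)
        assert ok


class TestHomopolymer:
    def test_subunit_involved_fails(self):
        assert not homopolymer_filter("A", "T", "A", 5)

    def test_non_subunit_passes(self):
        assert homopolymer_filter("C", "T", "A", 5)

    def test_far_from_homopolymer_passes(self):
        assert homopolymer_filter("A", "T", None, 0)

    def test_short_run_passes(self):
        assert not homopolymer_filter("A", "T", "A", 4)
        assert homopolymer_filter("A", "T", "A", 3)


def _indel_reads(rows):
    return pd.DataFrame(
        rows,
        columns=["sample", "platform", "allele", "mapping_quality",
                 "flank_left", "flank_right"],
    )


class TestIndelValidation:
    def test_mapq59_reads_not_counted(self):
        reads = _indel_reads(
            [
                ("ch", "hifi", "alt", 59, 50, 50),
                ("ch", "illumina", "alt", 60, 50, 50),
            ]
        )
        assert validate_indel(reads, "fa", "mo", "ch", None) == FAILED

    def test_sibling_read_inherited(self):
        reads = _indel_reads(
            [
                ("ch", "hifi", "alt", 60, 50, 50),
                ("ch", "illumina", "alt", 60, 50, 50),
                ("sib", "ont", "alt", 60, 50, 50),
            ]
        )
        assert validate_indel(reads, "fa", "mo", "ch", "sib") == INHERITED

    def test_hifi_only_fails(self):
        reads = _indel_reads([("ch", "hifi", "alt", 60, 50, 50)])
        assert validate_indel(reads, "fa", "mo", "ch", None) == FAILED

    def test_both_platforms_validated(self):
        reads = _indel_reads(
            [
                ("ch", "hifi", "alt", 60, 50, 50),
                ("ch", "illumina", "alt", 60, 50, 50),
            ]
        )
        assert validate_indel(reads, "fa", "mo", "ch", None) == VALIDATED

    def test_short_flank_not_counted(self):
        reads = _indel_reads(
            [
                ("ch", "hifi", "alt", 60, 9, 50),
                ("ch", "hifi", "alt", 60, 50, 50),
                ("ch", "illumina", "alt", 60, 50, 50),
            ]
        )
        assert validate_indel(reads, "fa", "mo", "ch", None) == VALIDATED

    def test_multiallelic_noise_fails(self):
        rows = [
            ("ch", "hifi", "alt", 60, 50, 50),
            ("ch", "illumina", "alt", 60, 50, 50),
        ]
        rows += [("ch", "hifi", f"other:{s}", 60, 50, 50) for s in ("AA", "AT", "GC")]
        assert validate_indel(_indel_reads(rows), "fa", "mo", "ch", None) == FAILED


class TestSexChromosome:
    def test_male_x_partial_ab_fails(self):
        ev = _evidence({
            ("mo", "hifi"): (0, 0, 20, 0, 0),
            ("ch", "hifi"): (9, 0, 1, 0, 0),
            ("ch", "illumina"): (9, 0, 1, 0, 0),
        })
        assert (
            validate_sex_chromosome(ev, "chrX", 1, "fa", "mo", "ch") == FAILED
        )

    def test_male_y_clean_validated(self):
        ev = _evidence({
            ("fa", "hifi"): (0, 0, 20, 0, 0),
            ("ch", "hifi"): (10, 0, 0, 0, 0),
            ("ch", "illumina"): (10, 0, 0, 0, 0),
        })
        assert (
            validate_sex_chromosome(ev, "chrY", 1, "fa", "mo", "ch") == VALIDATED
        )

    def test_male_y_present_in_father_inherited(self):
        ev = _evidence({
            ("fa", "hifi"): (2, 0, 20, 0, 0),
            ("ch", "hifi"): (10, 0, 0, 0, 0),
            ("ch", "illumina"): (10, 0, 0, 0, 0),
        })
        assert (
            validate_sex_chromosome(ev, "chrY", 1, "fa", "mo", "ch") == INHERITED
        )

    def test_female_x_uses_autosomal_rules(self):
        # heterozygous-looking AB passes for a female (no AB=1 rule)
        ev = _evidence({
            ("fa", "hifi"): (0, 0, 20, 0, 0),
            ("mo", "hifi"): (0, 0, 20, 0, 0),
            ("ch", "hifi"): (5, 0, 5, 0, 0),
            ("fa", "illumina"): (0, 0, 20, 0, 0),
            ("mo", "illumina"): (0, 0, 20, 0, 0),
            ("ch", "illumina"): (5, 0, 5, 0, 0),
        })
        assert (
            validate_sex_chromosome(ev, "chrX", 2, "fa", "mo", "ch") == VALIDATED
        )

    def test_chry_in_female_rejected(self):
        with pytest.raises(InputError):
            validate_sex_chromosome(SiteEvidence(), "chrY", 2, "fa", "mo", "ch")


class TestCascadeProperties:
    def test_order_stability(self, pipeline_result):
        """The kept set equals the conjunction of the independent filter
        columns regardless of evaluation order."""
        cand = pipeline_result.candidates
        predicates = [
            ~cand["cluster_excluded"],
            cand["combined_verdict"] == VALIDATED,
            cand["recurrence_pass"].astype(bool),
            cand["ab_pass"].astype(bool),
            cand["homopolymer_pass"].astype(bool),
        ]
        for perm in ([0, 1, 2, 3, 4], [4, 3, 2, 1, 0], [2, 0, 4, 1, 3]):
            acc = np.ones(len(cand), dtype=bool)
            for i in perm:
                acc &= predicates[i].to_numpy()
            assert (acc == cand["kept"].to_numpy()).all()

    def test_sensitivity_on_clean_bundle(self, clean_bundle, clean_result):
        truth = clean_bundle.truth
        constitutional = truth[
            (truth["origin"] == "germline") & (truth["var_class"] == "snv")
        ]
        kept = clean_result.classified[["child", "chrom", "pos"]]
        found = constitutional.merge(kept, on=["child", "chrom", "pos"])
        assert len(found) / len(constitutional) >= 0.95

    def test_no_inherited_variant_validated(self, clean_result):
        """Candidates flagged inherited by any platform never validate."""
        cand = clean_result.candidates
        inherited = cand[cand["combined_verdict"] == INHERITED]
        assert not inherited["kept"].any()
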