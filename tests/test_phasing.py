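import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dnmpipe.bundle import simulate_cohort
from dnmpipe.config import ArtifactRates, FilterParams, SimulationConfig
from dnmpipe.phasing import (
    PhaseCall,
    TrioGenotypeIndex,
    find_informative_snps,
    haplotype_of,
    phase_all,
    phase_variant,
    phase_with_fallback,
    score_read,
)

PARAMS = FilterParams()


def _genotype_index(rows):
    df = pd.DataFrame(
        rows, columns=["family", "chrom", "pos", "sample", "gt"]
    )
    return TrioGenotypeIndex(df)


class TestFindInformativeSnps:
    def _rows(self, pos, fa, mo, ch):
        return [
            ("F1", "chr1", pos, "fa", fa),
            ("F1", "chr1", pos, "mo", mo),
            ("F1", "chr1", pos, "ch", ch),
        ]

    def test_maternal_het_informative(self):
        idx = _genotype_index(self._rows(5000, "0/0", "0/1", "0/1"))
        out = find_informative_snps(idx, "F1", "fa", "mo", "ch", "chr1", 10_000)
        assert len(out) == 1
        assert out.iloc[0]["alt_parent"] == "maternal"
        assert out.iloc[0]["distance"] == 5000

    def test_homalt_parent_informative(self):
        idx = _genotype_index(self._rows(5000, "1/1", "0/0", "0/1"))
        out = find_informative_snps(idx, "F1", "fa", "mo", "ch", "chr1", 10_000)
        assert len(out) == 1
        assert out.iloc[0]["alt_parent"] == "paternal"

    def test_both_parents_het_ambiguous(self):
        idx = _genotype_index(self._rows(5000, "0/1", "0/1", "0/1"))
        out = find_informative_snps(idx, "F1", "fa", "mo", "ch", "chr1", 10_000)
        assert len(out) == 0

    def test_outside_window_excluded(self):
        idx = _genotype_index(self._rows(51_000, "0/0", "0/1", "0/1"))
        out = find_informative_snps(idx, "F1", "fa", "mo", "ch", "chr1", 10_000)
        assert len(out) == 0  # 41 kbp away > 40 kbp half-window

    def test_dnm_site_itself_excluded(self):
        idx = _genotype_index(self._rows(10_000, "0/0", "0/1", "0/1"))
        out = find_informative_snps(idx, "F1", "fa", "mo", "ch", "chr1", 10_000)
        assert len(out) == 0


def _informative(*rows):
    df = pd.DataFrame(rows, columns=["pos", "alt_parent"])
    df["distance"] = 1
    return df


class TestScoreRead:
    def test_single_paternal_snp(self):
        info = _informative((9000, "paternal"))
        score = score_read(np.array([9000]), np.array(["alt"]), info, 10_000)
        assert score == -1.0
        assert haplotype_of(score) == "paternal"

    def test_hand_computed_weighted_mean(self):
        # paternal at d=1000, maternal at d=2000:
        # (-1/1000 + 1/2000) / (1/1000 + 1/2000) = -1/3
        info = _informative((9000, "paternal"), (12_000, "maternal"))
        score = score_read(
            np.array([9000, 12_000]), np.array(["alt", "alt"]), info, 10_000
        )
        assert score == pytest.approx(-1 / 3)
        assert haplotype_of(score) == "paternal"

    def test_ref_allele_flips_tag(self):
        # seeing the REF at a maternal-alt SNP places the read paternally
        info = _informative((9000, "maternal"))
        score = score_read(np.array([9000]), np.array(["ref"]), info, 10_000)
        assert score == -1.0

    def test_no_snps_unassigned(self):
        info = _informative((9000, "paternal"))
        score = score_read(np.array([]), np.array([]), info, 10_000)
        assert np.isnan(score)
        assert haplotype_of(score) == "unassigned"

    def test_zero_score_unassigned(self):
        info = _informative((9000, "paternal"), (11_000, "maternal"))
        score = score_read(
            np.array([9000, 11_000]), np.array(["alt", "alt"]), info, 10_000
        )
        assert score == 0.0
        assert haplotype_of(score) == "unassigned"

    @given(
        st.lists(
            st.tuples(
                st.integers(min_value=1, max_value=39_999),
                st.booleans(),
                st.booleans(),
            ),
            min_size=1,
            max_size=8,
            unique_by=lambda t: t[0],
        )
    )
    @settings(max_examples=150, deadline=None)
    def test_antisymmetry(self, snps):
        """Flipping every SNP's parental tag negates the score."""
        dnm = 40_000
        info = _informative(
            *((dnm + d, "paternal" if pat else "maternal") for d, pat, _ in snps)
        )
        flipped = _informative(
            *((dnm + d, "maternal" if pat else "paternal") for d, pat, _ in snps)
        )
        pos = np.array([dnm + d for d, _, _ in snps])
        alleles = np.array(["alt" if a else "ref" for _, _, a in snps])
        s1 = score_read(pos, alleles, info, dnm)
        s2 = score_read(pos, alleles, flipped, dnm)
        assert s1 == pytest.approx(-s2)


def _calls(*rows):
    return pd.DataFrame(rows, columns=["read_id", "carries_alt", "haplotype"])


class TestPhaseVariant:
    def test_unanimous_paternal(self):
        calls = _calls(*[(i, True, "paternal") for i in range(5)])
        assert phase_variant(calls, "hifi").parent_of_origin == "paternal"

    def test_split_is_conflict(self):
        calls = _calls(
            *[(i, True, "paternal") for i in range(3)],
            *[(i + 3, True, "maternal") for i in range(2)],
        )
        assert phase_variant(calls, "hifi").parent_of_origin == "conflict"

    def test_all_unassigned_is_unphased(self):
        calls = _calls((1, True, "unassigned"), (2, False, "paternal"))
        assert phase_variant(calls, "hifi").parent_of_origin == "unphased"


class TestFallback:
    def test_ont_rescues_unphased_hifi(self):
        final = phase_with_fallback(
            PhaseCall("unphased", "hifi"), PhaseCall("paternal", "ont"), True
        )
        assert final.parent_of_origin == "paternal"
        assert final.source == "ont"

    def test_hifi_preferred_on_disagreement(self):
        final = phase_with_fallback(
            PhaseCall("paternal", "hifi"), PhaseCall("maternal", "ont"), True
        )
        assert final.parent_of_origin == "paternal"
        assert final.source == "hifi"

    def test_conflict_in_both_excluded(self):
        final = phase_with_fallback(
            PhaseCall("conflict", "hifi"), PhaseCall("conflict", "ont"), True
        )
        assert final.exclude

    def test_no_snps_just_unphased(self):
        final = phase_with_fallback(
            PhaseCall("unphased", "hifi"), PhaseCall("unphased", "ont"), False
        )
        assert final.parent_of_origin == "unphased"
        assert not final.exclude


@pytest.fixture(scope="module")
def phased_truth():
    cfg = SimulationConfig(
        n_families=12, quad_fraction=0.0, genome_length=10_000_000,
        n_chromosomes=1, germline_rate=1.2e-6, pzm_rate=0.0,
        germline_indel_rate=0.0, pzm_indel_rate=0.0,
        artifact_rates=ArtifactRates(0.0, 0.0), panel_sites_per_child=10,
        snp_observation_error=0.0, seed=77,
    )
    bundle = simulate_cohort(cfg, members="children", with_background=False)
    variants = bundle.truth[["family", "child", "chrom", "pos", "var_class"]]
    phased, _hap = phase_all(
        variants, bundle.reads, bundle.snp_obs, bundle.genotypes,
        bundle.pedigree, PARAMS,
    )
    return bundle, phased


class TestCohortPhasing:
    def test_phasing_fraction_at_default_snp_density(self, phased_truth):
        _, phased = phased_truth
        frac = phased["parent_of_origin"].isin(["paternal", "maternal"]).mean()
        assert frac >= 0.97

    def test_accuracy_perfect_without_snp_error(self, phased_truth):
        bundle, phased = phased_truth
        merged = phased.merge(
            bundle.truth[["child", "chrom", "pos", "parent"]],
            on=["child", "chrom", "pos"],
        )
        assigned = merged[merged["parent_of_origin"].isin(["paternal", "maternal"])]
        assert (assigned["parent_of_origin"] == assigned["parent"]).all()

    def test_accuracy_degrades_gracefully_with_snp_error(self):
        accs = []
        for err in (0.0, 0.2):
            cfg = SimulationConfig(
                n_families=8, quad_fraction=0.0, genome_length=5_000_000,
                n_chromosomes=1, germline_rate=1.2e-6, pzm_rate=0.0,
                germline_indel_rate=0.0, pzm_indel_rate=0.0,
                artifact_rates=ArtifactRates(0.0, 0.0), panel_sites_per_child=10,
                snp_observation_error=err, seed=78,
            )
            bundle = simulate_cohort(cfg, members="children", with_background=False)
            variants = bundle.truth[["family", "child", "chrom", "pos", "var_class"]]
            phased, _ = phase_all(
                variants, bundle.reads, bundle.snp_obs, bundle.genotypes,
                bundle.pedigree, PARAMS,
            )
            merged = phased.merge(
                bundle.truth[["child", "chrom", "pos", "parent"]],
                on=["child", "chrom", "pos"],
            )
            assigned = merged[
                merged["parent_of_origin"].isin(["paternal", "maternal"])
            ]
            accs.append((assigned["parent_of_origin"] == assigned["parent"]).mean())
        assert accs[0] >= accs[1]
        assert accs[0] == 1.0
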