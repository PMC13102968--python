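import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dnmpipe.spectra import (
    build_spectrum,
    dinucleotide_category,
    find_mnms,
    parental_age_regression,
    parental_bias_tests,
    paternal_fraction_ztest,
    spectrum_enrichment,
    titv,
)


def _variants(rows):
    return pd.DataFrame(
        rows, columns=["child", "chrom", "pos", "ref", "alt", "context_5p", "context_3p"]
    )


class TestSpectrum:
    def test_cpg_transition(self):
        assert dinucleotide_category("C", "T", "G", "A") == "CpG>TpG"

    def test_strand_collapse_oracle(self):
        """G>A with 5' C equals C>T at a CpG on the complementary strand."""
        assert dinucleotide_category("G", "A", "T", "C") == dinucleotide_category(
            "C", "T", "G", "A"
        )

    @given(
        st.sampled_from("ACGT"),
        st.sampled_from("ACGT"),
        st.sampled_from("ACGT"),
        st.sampled_from("ACGT"),
    )
    @settings(max_examples=100, deadline=None)
    def test_strand_invariance_property(self, ref, alt, c5, c3):
        if ref == alt:
            return
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        forward = dinucleotide_category(ref, alt, c3, c5)
        reverse = dinucleotide_category(comp[ref], comp[alt], comp[c5], comp[c3])
        assert forward == reverse

    def test_counts_conserved(self):
        vs = _variants(
            [
                ("c1", "chr1", 10, "C", "T", "A", "G"),
                ("c1", "chr1", 50, "A", "C", "T", "A"),
                ("c1", "chr1", 90, "G", "A", "C", "T"),  # CpG on the reverse strand
            ]
        )
        spec = build_spectrum(vs)
        assert spec.sum() == 3
        assert spec["CpG>TpG"] == 2  # one direct, one on the reverse strand

    def test_empty_input(self):
        assert build_spectrum(_variants([])).sum() == 0

    def test_order_invariance(self):
        rows = [
            ("c1", "chr1", 10, "C", "T", "A", "G"),
            ("c1", "chr1", 50, "A", "C", "T", "A"),
        ]
        a = build_spectrum(_variants(rows))
        b = build_spectrum(_variants(rows[::-1]))
        pd.testing.assert_series_equal(a, b)


class TestEnrichment:
    def test_identical_tables_no_enrichment(self):
        spec = pd.Series({"CpG>TpG": 50, "ApA>CpA": 30, "ApT>GpT": 20})
        out = spectrum_enrichment(spec, spec.copy())
        assert np.allclose(out["q_value"], 1.0)
        assert not out["significant"].any()

    def test_simulated_deficit_detected(self):
        """A generated CpG>TpG deficit in class B is detected at q < 0.05."""
        rng = np.random.default_rng(0)
        cats = ["CpG>TpG", "ApA>CpA", "ApT>GpT", "CpA>TpA"]
        p_a = np.array([0.4, 0.2, 0.2, 0.2])
        p_b = np.array([0.2, 0.27, 0.27, 0.26])  # deficit in the first category
        a = pd.Series(rng.multinomial(1000, p_a), index=cats)
        b = pd.Series(rng.multinomial(1000, p_b), index=cats)
        out = spectrum_enrichment(a, b).set_index("category")
        assert out.loc["CpG>TpG", "q_value"] < 0.05
        assert out.loc["CpG>TpG", "direction"] == "enriched_in_a"

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            spectrum_enrichment(pd.Series(dtype=int), pd.Series({"x": 1}))

    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0), min_size=1, max_size=20))
    @settings(max_examples=100, deadline=None)
    def test_bh_monotone_in_p_rank(self, pvals):
        from statsmodels.stats.multitest import multipletests

        q = multipletests(pvals, method="fdr_bh")[1]
        order = np.argsort(pvals)
        assert (np.diff(np.asarray(q)[order]) >= -1e-12).all()


class TestTiTv:
    def _vs(self, pairs):
        return pd.DataFrame(
            [("c", "chr1", i, r, a) for i, (r, a) in enumerate(pairs)],
            columns=["child", "chrom", "pos", "ref", "alt"],
        )

    def test_two_to_one(self):
        assert titv(self._vs([("A", "G"), ("C", "T"), ("A", "C")])) == pytest.approx(2.0)

    def test_all_transitions_undefined(self):
        assert titv(self._vs([("A", "G"), ("C", "T")])) is None

    def test_generated_spectra_recover_knobs(self, clean_bundle):
        truth = clean_bundle.truth
        snvs = truth[(truth["var_class"] == "snv") & (truth["origin"] == "germline")]
        assert titv(snvs) == pytest.approx(2.10, rel=0.25)


class TestMnM:
    def _vs(self, positions, child="c1", chrom="chr1"):
        return pd.DataFrame(
            [(child, chrom, p) for p in positions], columns=["child", "chrom", "pos"]
        )

    def test_pair_within_500(self):
        clusters, pairs = find_mnms(self._vs([100, 550]))
        assert len(clusters) == 1
        assert pairs.iloc[0]["distance"] == 450
        assert pairs.iloc[0]["distance_bin"] == "101-500"

    def test_adjacent_pair_bin_one(self):
        _, pairs = find_mnms(self._vs([100, 101]))
        assert pairs.iloc[0]["distance_bin"] == "1"

    def test_distance_501_no_cluster(self):
        clusters, pairs = find_mnms(self._vs([100, 601]))
        assert clusters == [] and len(pairs) == 0

    def test_transitive_chaining(self):
        clusters, _ = find_mnms(self._vs([100, 550, 1000]))
        assert len(clusters) == 1
        assert clusters[0].positions == [100, 550, 1000]

    def test_different_children_not_chained(self):
        vs = pd.concat([self._vs([100]), self._vs([200], child="c2")])
        clusters, pairs = find_mnms(vs)
        assert clusters == [] and len(pairs) == 0

    @given(
        st.lists(st.integers(min_value=0, max_value=3000), min_size=0, max_size=14)
    )
    @settings(max_examples=150, deadline=None)
    def test_matches_transitive_closure_oracle(self, positions):
        positions = sorted(set(positions))
        clusters, pairs = find_mnms(self._vs(positions))
        # oracle: union-find over all pairs <= 500 bp apart
        parent = {p: p for p in positions}

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        for a in positions:
            for b in positions:
                if a < b and b - a <= 500:
                    parent[find(b)] = find(a)
        groups = {}
        for p in positions:
            groups.setdefault(find(p), []).append(p)
        want = sorted([sorted(g) for g in groups.values() if len(g) > 1])
        got = sorted([c.positions for c in clusters])
        assert got == want
        # pair table covers exactly the consecutive pairs within 500 bp
        want_pairs = sum(
            1 for a, b in zip(positions, positions[1:]) if b - a <= 500
        )
        assert len(pairs) == want_pairs

    def test_bin_totals_conserved(self):
        _, pairs = find_mnms(self._vs([100, 101, 120, 400, 1000, 1090]))
        assert pairs["distance_bin"].value_counts().sum() == len(pairs)


class TestAgeRegression:
    def test_exact_linear_fit(self):
        per_child = pd.DataFrame(
            {
                "father_age": [20.0, 30.0, 40.0, 50.0],
                "mother_age": [20.0, 30.0, 40.0, 50.0],
                "paternal_count": [40, 60, 80, 100],
                "maternal_count": [10, 15, 20, 25],
            }
        )
        fit = parental_age_regression(per_child)
        assert fit.paternal_slope == pytest.approx(2.0)
        assert fit.maternal_slope == pytest.approx(0.5)
        assert fit.paternal_ci[0] <= fit.paternal_slope <= fit.paternal_ci[1]

    def test_permuted_ages_null(self):
        rng = np.random.default_rng(1)
        slopes = []
        for _ in range(20):
            ages = rng.normal(30, 5, size=40)
            counts = rng.poisson(60, size=40)
            per_child = pd.DataFrame(
                {
                    "father_age": rng.permutation(ages),
                    "mother_age": ages,
                    "paternal_count": counts,
                    "maternal_count": counts,
                }
            )
            slopes.append(parental_age_regression(per_child).paternal_slope)
        assert np.mean(slopes) == pytest.approx(0.0, abs=0.3)

    def test_degenerate_design_rejected(self):
        per_child = pd.DataFrame(
            {
                "father_age": [30.0, 30.0, 30.0],
                "mother_age": [28.0, 29.0, 30.0],
                "paternal_count": [1, 2, 3],
                "maternal_count": [1, 2, 3],
            }
        )
        with pytest.raises(ValueError):
            parental_age_regression(per_child)

    def test_too_few_children_rejected(self):
        with pytest.raises(ValueError):
            parental_age_regression(
                pd.DataFrame(
                    {
                        "father_age": [30.0],
                        "mother_age": [28.0],
                        "paternal_count": [1],
                        "maternal_count": [1],
                    }
                )
            )


class TestParentalBias:
    def test_published_chrx_ratio(self):
        per_child = pd.DataFrame(
            {"paternal_count": [166], "maternal_count": [48]}
        )
        out = parental_bias_tests(per_child)
        assert out["ratio"] == pytest.approx(166 / 48)

    def test_identical_counts_null(self):
        per_child = pd.DataFrame(
            {"paternal_count": [5, 7, 9], "maternal_count": [5, 7, 9]}
        )
        out = parental_bias_tests(per_child)
        assert out["ratio"] == pytest.approx(1.0)
        assert out["wilcoxon_p"] == pytest.approx(1.0)

    def test_power_at_study_parameters(self):
        """73 children at a 0.799 paternal fraction: Wilcoxon significant in
        >= 95% of replicates."""
        rng = np.random.default_rng(2)
        n_sig = 0
        n_rep = 40
        for _ in range(n_rep):
            total = rng.poisson(80, size=73)
            pat = rng.binomial(total, 0.799)
            per_child = pd.DataFrame(
                {"paternal_count": pat, "maternal_count": total - pat}
            )
            if parental_bias_tests(per_child)["wilcoxon_p"] < 0.05:
                n_sig += 1
        assert n_sig / n_rep >= 0.95

    def test_two_proportion_ztest(self):
        stat, p = paternal_fraction_ztest(800, 200, 500, 500)
        assert p < 1e-6
        stat, p = paternal_fraction_ztest(500, 500, 500, 500)
        assert p == pytest.approx(1.0)
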