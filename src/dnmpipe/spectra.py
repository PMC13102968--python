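"""Mutation spectra, Ti/Tv, multinucleotide clusters and cohort statistics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
PURINE_KEEP = {"A", "C"}  # categories are keyed on an A or C reference base
TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}

MNM_DISTANCE_BINS = ((1, 1, "1"), (2, 10, "2-10"), (11, 50, "11-50"),
                     (51, 100, "51-100"), (101, 500, "101-500"))


def dinucleotide_category(ref: str, alt: str, context_3p: str, context_5p: str) -> str:
    """Strand-collapsed dinucleotide category, e.g. ``CpG>TpG``.

    The mutated base is written 5' of its 3' neighbour; G/T references are
    complemented (the 3' neighbour then comes from the complement of the 5'
    context).
    """
    ref, alt = ref.upper(), alt.upper()
    if ref not in COMPLEMENT or alt not in COMPLEMENT:
        return "other"
    if ref in PURINE_KEEP:
        nxt = context_3p.upper()
    else:
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
        nxt = COMPLEMENT.get(context_5p.upper(), "N")
    if nxt not in COMPLEMENT:
        return "other"
    return f"{ref}p{nxt}>{alt}p{nxt}"


def build_spectrum(variants: pd.DataFrame) -> pd.Series:
    """Counts per dinucleotide category.

    Expects columns ref, alt, context_5p, context_3p; rows with unknown
    context land in ``other``.
    """
    if variants.empty:
        return pd.Series(dtype=int)
    cats = [
        dinucleotide_category(r, a, c3, c5)
        for r, a, c5, c3 in zip(
            variants["ref"], variants["alt"], variants["context_5p"],
            variants["context_3p"],
        )
    ]
    return pd.Series(cats).value_counts().sort_index()


def spectrum_enrichment(
    spectrum_a: pd.Series, spectrum_b: pd.Series, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-category 2x2 chi-squared (category vs rest, class A vs B) with
    Benjamini-Hochberg correction across categories."""
    from statsmodels.stats.multitest import multipletests

    total_a, total_b = int(spectrum_a.sum()), int(spectrum_b.sum())
    if total_a == 0 or total_b == 0:
        raise ValueError("both spectra must have nonzero totals")
    cats = sorted(set(spectrum_a.index) | set(spectrum_b.index))
    records = []
    for cat in cats:
        a = int(spectrum_a.get(cat, 0))
        b = int(spectrum_b.get(cat, 0))
        if a == 0 and b == 0:
            continue
        table = np.array([[a, total_a - a], [b, total_b - b]], dtype=float)
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            p = 1.0
        else:
            # plain Pearson chi-squared (no Yates correction), so identical
            # spectra give p = 1 exactly
            _, p, _, _ = stats.chi2_contingency(table, correction=False)
        frac_a = a / total_a
        frac_b = b / total_b
        records.append(
            {
                "category": cat,
                "count_a": a,
                "count_b": b,
                "fraction_a": frac_a,
                "fraction_b": frac_b,
                "direction": "enriched_in_a" if frac_a > frac_b else "enriched_in_b",
                "p_value": float(p),
            }
        )
    out = pd.DataFrame(records)
    if len(out):
        out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
        out["significant"] = out["q_value"] < alpha
    return out


def titv(variants: pd.DataFrame) -> float | None:
    """Transition/transversion ratio over SNV rows; None when no
    transversions are present."""
    snvs = variants[variants.get("var_class", "snv") == "snv"] if "var_class" in variants.columns else variants
    if snvs.empty:
        return None
    is_ti = np.array(
        [(r.upper(), a.upper()) in TRANSITIONS for r, a in zip(snvs["ref"], snvs["alt"])]
    )
    n_tv = int((~is_ti).sum())
    if n_tv == 0:
        return None
    return float(is_ti.sum() / n_tv)


# ---------------------------------------------------------------------------
# multinucleotide mutations


@dataclass
class MnMCluster:
    child: str
    chrom: str
    positions: list[int]
    member_ids: list[int]  # row indices into the input frame

    @property
    def pairwise_distances(self) -> list[int]:
        return [
            self.positions[i + 1] - self.positions[i]
            for i in range(len(self.positions) - 1)
        ]


def find_mnms(
    variants: pd.DataFrame, max_distance: int = 500
) -> tuple[list[MnMCluster], pd.DataFrame]:
    """Chain same-child variants with consecutive distances <= 500 bp.

    Returns maximal chains (transitive closure on sorted positions) and a
    pair table with distance-bin labels for spectrum comparison.
    """
    clusters: list[MnMCluster] = []
    pair_rows = []
    for (child, chrom), grp in variants.groupby(["child", "chrom"], sort=True):
        grp = grp.sort_values("pos")
        pos = grp["pos"].to_numpy(dtype=np.int64)
        idx = grp.index.to_numpy()
        if len(pos) < 2:
            continue
        gaps = np.diff(pos)
        start = 0
        for i in range(len(pos)):
            last = i == len(pos) - 1
            if last or gaps[i] > max_distance:
                if i > start:
                    clusters.append(
                        MnMCluster(
                            child=child,
                            chrom=chrom,
                            positions=[int(p) for p in pos[start : i + 1]],
                            member_ids=list(idx[start : i + 1]),
                        )
                    )
                start = i + 1
        for i in np.nonzero(gaps <= max_distance)[0]:
            d = int(gaps[i])
            pair_rows.append(
                {
                    "child": child,
                    "chrom": chrom,
                    "pos_a": int(pos[i]),
                    "pos_b": int(pos[i + 1]),
                    "distance": d,
                    "distance_bin": _distance_bin(d),
                }
            )
    return clusters, pd.DataFrame(
        pair_rows,
        columns=["child", "chrom", "pos_a", "pos_b", "distance", "distance_bin"],
    )


def _distance_bin(d: int) -> str:
    for lo, hi, label in MNM_DISTANCE_BINS:
        if lo <= d <= hi:
            return label
    return "unbinned"


# ---------------------------------------------------------------------------
# parental-age and parental-bias statistics


@dataclass
class AgeEffectFit:
    paternal_slope: float
    paternal_ci: tuple[float, float]
    paternal_p: float
    maternal_slope: float
    maternal_ci: tuple[float, float]
    maternal_p: float
    paternal_intercept: float
    maternal_intercept: float


def parental_age_regression(per_child: pd.DataFrame) -> AgeEffectFit:
    """Two separate OLS fits: paternal-haplotype count on paternal age and
    maternal count on maternal age.

    ``per_child`` columns: father_age, mother_age, paternal_count,
    maternal_count; needs >= 3 children with age variation.
    """
    import statsmodels.api as sm

    if len(per_child) < 3:
        raise ValueError("need at least 3 children")
    fits = {}
    for parent, age_col, count_col in (
        ("paternal", "father_age", "paternal_count"),
        ("maternal", "mother_age", "maternal_count"),
    ):
        ages = per_child[age_col].to_numpy(dtype=float)
        if np.ptp(ages) == 0:
            raise ValueError(f"degenerate design: constant {age_col}")
        y = per_child[count_col].to_numpy(dtype=float)
        model = sm.OLS(y, sm.add_constant(ages)).fit()
        ci = model.conf_int()[1]
        fits[parent] = (
            float(model.params[1]),
            (float(ci[0]), float(ci[1])),
            float(model.pvalues[1]),
            float(model.params[0]),
        )
    return AgeEffectFit(
        paternal_slope=fits["paternal"][0],
        paternal_ci=fits["paternal"][1],
        paternal_p=fits["paternal"][2],
        maternal_slope=fits["maternal"][0],
        maternal_ci=fits["maternal"][1],
        maternal_p=fits["maternal"][2],
        paternal_intercept=fits["paternal"][3],
        maternal_intercept=fits["maternal"][3],
    )


def parental_bias_tests(per_child: pd.DataFrame) -> dict:
    """Cohort paternal:maternal ratio with a two-sided Wilcoxon signed-rank
    test of per-child counts.

    ``per_child`` columns: paternal_count, maternal_count.
    """
    pat = per_child["paternal_count"].to_numpy(dtype=float)
    mat = per_child["maternal_count"].to_numpy(dtype=float)
    total_pat, total_mat = float(pat.sum()), float(mat.sum())
    out = {
        "paternal_total": int(total_pat),
        "maternal_total": int(total_mat),
        "ratio": total_pat / total_mat if total_mat else np.inf,
    }
    diffs = pat - mat
    if np.all(diffs == 0) or len(diffs) == 0:
        out["wilcoxon_p"] = 1.0
    else:
        res = stats.wilcoxon(pat, mat, zero_method="wilcox", alternative="two-sided")
        out["wilcoxon_p"] = float(res.pvalue)
    return out


def paternal_fraction_ztest(
    pat_a: int, mat_a: int, pat_b: int, mat_b: int
) -> tuple[float, float]:
    """Two-sided two-proportion Z-test comparing paternal fractions of two
    variant classes (e.g. germline vs postzygotic)."""
    from statsmodels.stats.proportion import proportions_ztest

    stat, p = proportions_ztest(
        count=np.array([pat_a, pat_b]), nobs=np.array([pat_a + mat_a, pat_b + mat_b])
    )
    return float(stat), float(p)
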