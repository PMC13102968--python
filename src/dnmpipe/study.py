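"""Published cohort summary counts and the arithmetic identities over them.

These constants are the printed cohort-level totals of the 73-child,
42-family study this pipeline reimplements; the functions recompute the
derived per-child and fractional quantities from them.
"""

from __future__ import annotations

COHORT = {
    "n_children": 73,
    "n_families": 42,
    "n_quads": 31,
    "n_trios": 11,
    "n_individuals": 157,
    "validated_autosomal_snvs": 6030,
    "classified_germline_snvs": 5145,
    "classified_postzygotic_snvs": 917,
    "autosomal_insertions": 182,
    "autosomal_deletions": 351,
    "postzygotic_indels": 129,
    "mean_callable_gbp": 2.66,
    "autosome_gbp": 2.90,
    "germline_rate": 1.30e-8,
    "postzygotic_rate": 0.23e-8,
}


def mean_snvs_per_child() -> float:
    """Validated autosomal SNVs per child, one decimal."""
    return round(COHORT["validated_autosomal_snvs"] / COHORT["n_children"], 1)


def mean_indels_per_child() -> float:
    total = COHORT["autosomal_insertions"] + COHORT["autosomal_deletions"]
    return round(total / COHORT["n_children"], 1)


def mean_pzm_snvs_per_child() -> float:
    return round(COHORT["classified_postzygotic_snvs"] / COHORT["n_children"], 1)


def pzm_snv_fraction_pct() -> float:
    """Percentage of classified SNVs that are postzygotic."""
    pzm = COHORT["classified_postzygotic_snvs"]
    total = pzm + COHORT["classified_germline_snvs"]
    return round(100 * pzm / total, 1)


def pzm_indel_fraction_pct() -> float:
    total = COHORT["autosomal_insertions"] + COHORT["autosomal_deletions"]
    return round(100 * COHORT["postzygotic_indels"] / total, 1)


def callable_fraction_pct() -> float:
    return round(100 * COHORT["mean_callable_gbp"] / COHORT["autosome_gbp"], 1)


def combined_rate() -> float:
    """Germline plus postzygotic substitution rate per bp per generation."""
    return COHORT["germline_rate"] + COHORT["postzygotic_rate"]
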