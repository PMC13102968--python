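"""Germline vs. postzygotic origin classification.

Combines per-platform haplotype composition (a postzygotic mutation shows a
third haplotype: reference reads alongside alt reads on one parental
haplotype), a cross-platform allele-balance concordance chi-squared test,
and a pooled one-sided exact binomial test against AB = 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from dnmpipe.config import FilterParams

GERMLINE = "germline"
POSTZYGOTIC = "postzygotic"
AMBIGUOUS = "ambiguous"
NOT_EVALUABLE = "not_evaluable"


@dataclass(frozen=True)
class OriginCall:
    hifi_verdict: str
    ont_verdict: str
    ab_prediction: str
    final: str
    rationale: str
    concordance_p: float = float("nan")
    pooled_p: float = float("nan")
    pooled_ab: float = float("nan")


def haplotype_origin_call(
    ref_on_hap: int, alt_on_hap: int, params: FilterParams | None = None
) -> str:
    """Verdict from read composition on the assigned parental haplotype."""
    params = params or FilterParams()
    if ref_on_hap >= params.hap_pzm_min_ref and alt_on_hap >= params.hap_min_alt:
        return POSTZYGOTIC
    if ref_on_hap == 0 and alt_on_hap >= params.hap_min_alt:
        return GERMLINE
    return AMBIGUOUS


def ab_concordance_test(
    platform_counts: list[tuple[int, int]], params: FilterParams | None = None
) -> tuple[bool | None, float]:
    """Chi-squared homogeneity test of (alt, ref) across platforms.

    Zero-coverage platforms are dropped; with fewer than two informative
    platforms the test is not evaluable (returns ``(None, nan)``).
    """
    params = params or FilterParams()
    table = [(alt, ref) for alt, ref in platform_counts if alt + ref > 0]
    if len(table) < 2:
        return None, float("nan")
    arr = np.asarray(table, dtype=float)
    if (arr.sum(axis=0) == 0).any():
        # a degenerate margin (all-alt or all-ref everywhere) is trivially concordant
        return True, 1.0
    _, p, _, _ = stats.chi2_contingency(arr)
    return bool(p > params.alpha_concordance), float(p)


def pooled_ab_test(
    pooled_alt: int, pooled_total: int, params: FilterParams | None = None
) -> tuple[str, float]:
    """One-sided exact binomial: is the pooled AB significantly below 0.5?"""
    params = params or FilterParams()
    if pooled_total <= 0:
        return NOT_EVALUABLE, float("nan")
    p = float(stats.binomtest(pooled_alt, pooled_total, 0.5, alternative="less").pvalue)
    return (POSTZYGOTIC if p < params.alpha_pooled else GERMLINE), p


def resolve_origin(hifi_verdict: str, ont_verdict: str, ab_prediction: str) -> tuple[str, str]:
    """Fixed precedence: agreeing unambiguous haplotypes win; disagreement
    and double-ambiguity fall back to the AB prediction; with no usable
    signal anywhere the variant is assumed germline."""
    unambiguous = [v for v in (hifi_verdict, ont_verdict) if v in (GERMLINE, POSTZYGOTIC)]
    ab_usable = ab_prediction in (GERMLINE, POSTZYGOTIC)
    if len(unambiguous) == 2:
        if unambiguous[0] == unambiguous[1]:
            return unambiguous[0], "haplotypes_agree"
        if ab_usable:
            return ab_prediction, "haplotypes_disagree_ab"
        return GERMLINE, "haplotypes_disagree_default"
    if len(unambiguous) == 1:
        return unambiguous[0], "single_platform_haplotype"
    if ab_usable:
        return ab_prediction, "ab_only"
    return GERMLINE, "default_germline"


def classify_indel_origin(
    discordant_reads_on_hap: int, params: FilterParams | None = None
) -> str:
    """Indels are noisier: postzygotic only beyond a discordant-read count."""
    params = params or FilterParams()
    if discordant_reads_on_hap >= params.indel_pzm_min_discordant:
        return POSTZYGOTIC
    return GERMLINE


# ---------------------------------------------------------------------------
# cohort-level classification


def classify_all(
    phased: pd.DataFrame,
    hap_table: pd.DataFrame,
    evidence_counts: pd.DataFrame,
    params: FilterParams | None = None,
) -> pd.DataFrame:
    """Classify every phased variant row; adds origin columns.

    ``hap_table`` is the per-read haplotype table from the phasing stage;
    ``evidence_counts`` the per-site/sample/platform allele-count table from
    validation (used for the AB tests).
    """
    params = params or FilterParams()
    hap_groups = (
        {
            key: grp
            for key, grp in hap_table.groupby(["child", "chrom", "pos"], sort=False)
        }
        if len(hap_table)
        else {}
    )
    ev = evidence_counts.set_index(["sample", "chrom", "pos", "platform"]).sort_index() if len(evidence_counts) else None

    records = []
    for var in phased.itertuples(index=False):
        assigned = var.parent_of_origin
        counts = _child_platform_counts(ev, var.child, var.chrom, int(var.pos))
        concordant, p_conc = ab_concordance_test(list(counts.values()), params)
        if concordant is None:
            ab_pred, p_pool, pooled_ab = NOT_EVALUABLE, float("nan"), float("nan")
        elif not concordant:
            # discordant AB: no confident prediction, presumed germline
            ab_pred, p_pool, pooled_ab = GERMLINE, float("nan"), _pooled_ab(counts)
        else:
            alt = sum(a for a, _ in counts.values())
            total = sum(a + r for a, r in counts.values())
            ab_pred, p_pool = pooled_ab_test(alt, total, params)
            pooled_ab = alt / total if total else float("nan")

        if getattr(var, "var_class", "snv") != "snv":
            hifi_v = ont_v = NOT_EVALUABLE
            n_disc = _discordant_indel_reads(
                hap_groups.get((var.child, var.chrom, int(var.pos))), assigned
            )
            final, rationale = classify_indel_origin(n_disc, params), "indel_rule"
        elif assigned in ("paternal", "maternal"):
            hifi_v, ont_v = _haplotype_verdicts(
                hap_groups.get((var.child, var.chrom, int(var.pos))), assigned, params
            )
            final, rationale = resolve_origin(hifi_v, ont_v, ab_pred)
        else:
            hifi_v = ont_v = NOT_EVALUABLE
            final, rationale = resolve_origin(NOT_EVALUABLE, NOT_EVALUABLE, ab_pred)
        records.append(
            (hifi_v, ont_v, ab_pred, final, rationale, p_conc, p_pool, pooled_ab)
        )
    res = pd.DataFrame(
        records,
        columns=[
            "hifi_hap_verdict",
            "ont_hap_verdict",
            "ab_prediction",
            "origin",
            "origin_rationale",
            "concordance_p",
            "pooled_p",
            "pooled_ab",
        ],
    )
    out = phased.copy().reset_index(drop=True)
    return pd.concat([out, res], axis=1)


def _child_platform_counts(ev, child: str, chrom: str, pos: int) -> dict[str, tuple[int, int]]:
    counts: dict[str, tuple[int, int]] = {}
    if ev is None:
        return counts
    for platform in ("hifi", "ont", "illumina"):
        try:
            row = ev.loc[(child, chrom, pos, platform)]
        except KeyError:
            continue
        if isinstance(row, pd.DataFrame):
            row = row.iloc[0]
        alt = int(row["high_alt"] + row["low_alt"])
        ref = int(row["high_ref"] + row["low_ref"])
        counts[platform] = (alt, ref)
    return counts


def _pooled_ab(counts: dict[str, tuple[int, int]]) -> float:
    alt = sum(a for a, _ in counts.values())
    total = sum(a + r for a, r in counts.values())
    return alt / total if total else float("nan")


def _haplotype_verdicts(
    grp: pd.DataFrame | None, assigned: str, params: FilterParams
) -> tuple[str, str]:
    if grp is None or grp.empty:
        return AMBIGUOUS, AMBIGUOUS
    verdicts = []
    for platform in ("hifi", "ont"):
        on_hap = grp[(grp["platform"] == platform) & (grp["haplotype"] == assigned)]
        if on_hap.empty:
            verdicts.append(AMBIGUOUS)
            continue
        alt = int(on_hap["carries_alt"].sum())
        ref = int((~on_hap["carries_alt"]).sum())
        verdicts.append(haplotype_origin_call(ref, alt, params))
    return verdicts[0], verdicts[1]


def _discordant_indel_reads(grp: pd.DataFrame | None, assigned: str) -> int:
    if grp is None or grp.empty or assigned not in ("paternal", "maternal"):
        return 0
    on_hap = grp[grp["haplotype"] == assigned]
    return int((~on_hap["carries_alt"]).sum())
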