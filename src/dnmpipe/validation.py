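"""Candidate selection and the tri-platform DNM validation cascade.

Every filter is a pure predicate of (candidate, evidence); the cascade's
outcome is the conjunction of the individual verdict columns, so filter
order never changes the final validated set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

from dnmpipe.config import ConfigurationError, FilterParams
from dnmpipe.intervals import positions_in_bed


class PedigreeError(ValueError):
    """Trio membership cannot be resolved."""


class InputError(ValueError):
    """Biologically impossible input (e.g. chrY candidate in a female)."""


class QualityClass(str, Enum):
    HIGH = "HIGH"
    LOW = "LOW"
    DISCARD = "DISCARD"
    MAPQ_EXCLUDED = "MAPQ_EXCLUDED"


DE_NOVO = "DE_NOVO"
INHERITED = "INHERITED"
UNSUPPORTED = "UNSUPPORTED"
VALIDATED = "VALIDATED"
FAILED = "FAILED"

LONG_READ_PLATFORMS = frozenset({"hifi", "ont"})
PLATFORMS = ("hifi", "ont", "illumina")


# ---------------------------------------------------------------------------
# read partitioning


def classify_read(
    base_quality: float,
    mapping_quality: float,
    platform: str,
    params: FilterParams | None = None,
) -> QualityClass:
    """Partition one read by base/mapping quality.

    Long reads below the mapping-quality floor are excluded outright; short
    reads are never filtered on mapping quality.
    """
    params = params or FilterParams()
    if platform not in PLATFORMS:
        raise ConfigurationError(f"unknown platform {platform!r}")
    if platform in LONG_READ_PLATFORMS and mapping_quality < params.long_read_min_mapq:
        return QualityClass.MAPQ_EXCLUDED
    if base_quality > params.high_bq_exclusive:
        return QualityClass.HIGH
    if base_quality >= params.low_bq_min:
        return QualityClass.LOW
    return QualityClass.DISCARD


def classify_reads_frame(reads: pd.DataFrame, params: FilterParams) -> pd.DataFrame:
    """Vectorised read partitioning; adds a ``qclass`` column."""
    bq = reads["base_quality"].to_numpy(dtype=float)
    mapq = reads["mapping_quality"].to_numpy(dtype=float)
    platform = reads["platform"].to_numpy()
    long_read = np.isin(platform, list(LONG_READ_PLATFORMS))
    qclass = np.where(
        bq > params.high_bq_exclusive,
        QualityClass.HIGH.value,
        np.where(bq >= params.low_bq_min, QualityClass.LOW.value,
                 QualityClass.DISCARD.value),
    )
    qclass = np.where(
        long_read & (mapq < params.long_read_min_mapq),
        QualityClass.MAPQ_EXCLUDED.value,
        qclass,
    )
    out = reads.copy()
    out["qclass"] = qclass
    return out


# ---------------------------------------------------------------------------
# evidence containers


@dataclass
class AlleleCounts:
    high_alt: int = 0
    low_alt: int = 0
    high_ref: int = 0
    low_ref: int = 0
    other: int = 0

    @property
    def alt(self) -> int:
        return self.high_alt + self.low_alt

    @property
    def ref(self) -> int:
        return self.high_ref + self.low_ref

    @property
    def retained(self) -> int:
        return self.alt + self.ref

    @property
    def ab(self) -> float:
        denom = self.alt + self.ref
        return self.alt / denom if denom else float("nan")


@dataclass
class SiteEvidence:
    """Filtered allele counts per (sample, platform) at one candidate site."""

    counts: dict[tuple[str, str], AlleleCounts] = field(default_factory=dict)

    def get(self, sample: str, platform: str) -> AlleleCounts:
        return self.counts.get((sample, platform), AlleleCounts())


def build_evidence_counts(
    reads: pd.DataFrame,
    params: FilterParams,
    child_roles: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Aggregate retained reads into per-site/sample/platform allele counts.

    Child HiFi evidence is restricted to blood-derived reads whenever blood
    reads exist for that sample at that site (cell-line-only samples keep
    their cell-line HiFi reads); parental blood and cell-line reads are
    pooled.
    """
    if reads.empty:
        return pd.DataFrame(
            columns=["family", "chrom", "pos", "sample", "platform",
                     "high_alt", "low_alt", "high_ref", "low_ref", "other"]
        )
    ev = classify_reads_frame(reads, params)
    ev = ev[ev["qclass"].isin([QualityClass.HIGH.value, QualityClass.LOW.value])]
    if child_roles:
        is_child = ev["sample"].map(lambda s: child_roles.get(s) == "child")
        hifi_cl = (ev["platform"] == "hifi") & (ev["tissue"] != "blood") & is_child
        if hifi_cl.any():
            has_blood = ev[
                (ev["platform"] == "hifi") & (ev["tissue"] == "blood")
            ].groupby(["sample", "chrom", "pos"]).size()
            keys = pd.MultiIndex.from_frame(ev.loc[hifi_cl, ["sample", "chrom", "pos"]])
            drop = hifi_cl.copy()
            drop.loc[hifi_cl] = keys.isin(has_blood.index)
            ev = ev[~drop]
    is_alt = ev["allele"] == "alt"
    is_ref = ev["allele"] == "ref"
    is_high = ev["qclass"] == QualityClass.HIGH.value
    ev = ev.assign(
        high_alt=(is_alt & is_high).astype(int),
        low_alt=(is_alt & ~is_high).astype(int),
        high_ref=(is_ref & is_high).astype(int),
        low_ref=(is_ref & ~is_high).astype(int),
        other=(~is_alt & ~is_ref).astype(int),
    )
    grouped = (
        ev.groupby(["family", "chrom", "pos", "sample", "platform"], sort=False)[
            ["high_alt", "low_alt", "high_ref", "low_ref", "other"]
        ]
        .sum()
        .reset_index()
    )
    return grouped


def site_evidence(
    counts: pd.DataFrame, family: str, chrom: str, pos: int
) -> SiteEvidence:
    rows = counts[
        (counts["family"] == family)
        & (counts["chrom"] == chrom)
        & (counts["pos"] == pos)
    ]
    ev = SiteEvidence()
    for row in rows.itertuples(index=False):
        ev.counts[(row.sample, row.platform)] = AlleleCounts(
            row.high_alt, row.low_alt, row.high_ref, row.low_ref, row.other
        )
    return ev


# ---------------------------------------------------------------------------
# candidate selection


def select_candidates(
    genotypes: pd.DataFrame,
    pedigree: pd.DataFrame,
    params: FilterParams | None = None,
) -> pd.DataFrame:
    """Sites where both parents are 0/0 and the child carries an alt allele
    with genotype quality >= the floor."""
    params = params or FilterParams()
    children = pedigree[pedigree["role"] == "child"]
    if genotypes.empty:
        return pd.DataFrame(
            columns=["family", "child", "chrom", "pos", "ref", "alt", "var_class", "gq"]
        )
    present = set(genotypes["sample"])
    for child in children.itertuples(index=False):
        fam_has_data = (genotypes["family"] == child.family).any()
        if fam_has_data and child.individual not in present:
            raise PedigreeError(f"child {child.individual} absent from genotype records")

    child_rows = genotypes.merge(
        children[["individual", "father", "mother"]],
        left_on="sample",
        right_on="individual",
    )
    child_rows = child_rows[
        child_rows["gt"].isin(["0/1", "1/1"]) & (child_rows["gq"] >= params.min_child_gq)
    ]
    site_key = ["family", "chrom", "pos", "ref", "alt"]
    parent_gt = genotypes[site_key + ["sample", "gt"]]
    merged = child_rows.merge(
        parent_gt.rename(columns={"sample": "father", "gt": "father_gt"}),
        on=site_key + ["father"],
        how="left",
    ).merge(
        parent_gt.rename(columns={"sample": "mother", "gt": "mother_gt"}),
        on=site_key + ["mother"],
        how="left",
    )
    keep = (merged["father_gt"] == "0/0") & (merged["mother_gt"] == "0/0")
    out = merged.loc[
        keep, ["family", "sample", "chrom", "pos", "ref", "alt", "gq"]
    ].rename(columns={"sample": "child"})
    ref_len = out["ref"].str.len()
    alt_len = out["alt"].str.len()
    out["var_class"] = np.where(
        (ref_len == 1) & (alt_len == 1), "snv", np.where(alt_len > ref_len, "ins", "del")
    )
    return out.sort_values(["family", "child", "chrom", "pos"]).reset_index(drop=True)


def annotate_candidates(
    candidates: pd.DataFrame, tracks: dict[str, pd.DataFrame]
) -> pd.DataFrame:
    """Attach annotation flags (TR, RepeatMasker, SD, homopolymer context)."""
    out = candidates.copy()
    chroms = out["chrom"].to_numpy()
    pos = out["pos"].to_numpy(dtype=np.int64)
    for flag, name in (
        ("in_tandem_repeat", "tandem_repeat"),
        ("in_repeatmasker", "repeatmasker"),
        ("in_segdup", "segdup"),
    ):
        bed = tracks.get(name)
        if bed is None or bed.empty or len(out) == 0:
            out[flag] = False
        else:
            out[flag] = positions_in_bed(chroms, pos, bed)
    out["hp_base"] = None
    out["hp_length"] = 0
    hp = tracks.get("homopolymer")
    if hp is not None and not hp.empty and len(out):
        padded = hp.copy()
        padded["start"] = padded["start"] - 1  # in or within 1 bp
        padded["end"] = padded["end"] + 1
        for i in range(len(out)):
            sel = (
                (padded["chrom"] == chroms[i])
                & (padded["start"] < pos[i])
                & (pos[i] <= padded["end"])
            )
            if sel.any():
                row = padded[sel].iloc[0]
                out.iloc[i, out.columns.get_loc("hp_base")] = row.get("base", "A")
                out.iloc[i, out.columns.get_loc("hp_length")] = int(
                    row["end"] - row["start"] - 2
                )
    return out


# ---------------------------------------------------------------------------
# cluster filter


def filter_clusters(
    positions: np.ndarray | list[int], params: FilterParams | None = None
) -> np.ndarray:
    """Boolean exclusion mask for sorted-or-not SNV positions of one child
    and chromosome: a site is excluded iff some window of ``cluster_window_bp``
    containing it holds >= ``cluster_min_snvs`` candidate positions.

    Equivalent to scanning consecutive k-tuples of the sorted positions
    (k = cluster_min_snvs): the tuple spans <= window iff such a window
    exists.
    """
    params = params or FilterParams()
    pos = np.asarray(positions, dtype=np.int64)
    n = len(pos)
    k = params.cluster_min_snvs
    excluded = np.zeros(n, dtype=bool)
    if n < k:
        return excluded
    order = np.argsort(pos, kind="stable")
    sorted_pos = pos[order]
    span_ok = sorted_pos[k - 1 :] - sorted_pos[: n - k + 1] <= params.cluster_window_bp
    excl_sorted = np.zeros(n, dtype=bool)
    for i in np.nonzero(span_ok)[0]:
        excl_sorted[i : i + k] = True
    excluded[order] = excl_sorted
    return excluded


def apply_cluster_filter(
    candidates: pd.DataFrame, params: FilterParams
) -> pd.DataFrame:
    """Adds ``cluster_excluded`` (SNVs only; indels are never cluster-filtered)."""
    out = candidates.copy()
    out["cluster_excluded"] = False
    snvs = out[out["var_class"] == "snv"]
    for (_, _), grp in snvs.groupby(["child", "chrom"], sort=False):
        mask = filter_clusters(grp["pos"].to_numpy(), params)
        out.loc[grp.index[mask], "cluster_excluded"] = True
    return out


# ---------------------------------------------------------------------------
# per-platform read validation


def validate_snv_platform(
    evidence: SiteEvidence,
    platform: str,
    father: str,
    mother: str,
    child: str,
    params: FilterParams | None = None,
) -> str:
    """DE_NOVO / INHERITED / UNSUPPORTED verdict for one platform."""
    params = params or FilterParams()
    hq_max, lq_max = params.parent_ceiling(platform)
    child_counts = evidence.get(child, platform)
    usable = child_counts.retained > 0
    for parent in (father, mother):
        pc = evidence.get(parent, platform)
        if pc.high_alt > hq_max or pc.low_alt > lq_max:
            return INHERITED
    if not usable or child_counts.alt < params.child_min_alt_reads:
        return UNSUPPORTED
    return DE_NOVO


def combine_platform_verdicts(
    verdicts: dict[str, str],
    params: FilterParams | None = None,
    cellline_only: bool = False,
    illumina_child_hq_alt: int = 0,
) -> str:
    """Inherited in any platform wins; otherwise two supporting platforms
    validate. Cell-line-only children additionally need elevated blood
    Illumina support."""
    params = params or FilterParams()
    if any(v == INHERITED for v in verdicts.values()):
        return INHERITED
    n_support = sum(v == DE_NOVO for v in verdicts.values())
    if n_support < params.min_supporting_platforms:
        return FAILED
    if cellline_only and illumina_child_hq_alt < params.cellline_only_illumina_hq_alt:
        return FAILED
    return VALIDATED


# ---------------------------------------------------------------------------
# cohort-level filters


def recurrence_scan(
    reads: pd.DataFrame, params: FilterParams
) -> pd.DataFrame:
    """Per (chrom, pos): HiFi alt-read carrier samples for the recurrence
    filter. Restricted to retained high-quality reads by default."""
    hifi = reads[(reads["platform"] == "hifi") & (reads["allele"] == "alt")]
    if hifi.empty:
        return pd.DataFrame(columns=["chrom", "pos", "sample", "family"])
    hifi = classify_reads_frame(hifi, params)
    if params.recurrence_high_quality_only:
        hifi = hifi[hifi["qclass"] == QualityClass.HIGH.value]
    else:
        hifi = hifi[
            hifi["qclass"].isin([QualityClass.HIGH.value, QualityClass.LOW.value])
        ]
    return hifi[["chrom", "pos", "sample", "family"]].drop_duplicates()


def recurrence_filter(
    family: str,
    chrom: str,
    pos: int,
    carriers: pd.DataFrame,
    in_tandem_repeat: bool,
    params: FilterParams | None = None,
) -> bool:
    """True (pass) iff the de novo allele is observed in no more unrelated
    samples than allowed (0 outside TRs, 1 inside)."""
    params = params or FilterParams()
    at_site = carriers[(carriers["chrom"] == chrom) & (carriers["pos"] == pos)]
    n_unrelated = (at_site["family"] != family).sum()
    allowance = (
        params.tr_recurrence_allowance
        if in_tandem_repeat
        else params.nontr_recurrence_allowance
    )
    return n_unrelated <= allowance


def ab_filters(
    evidence: SiteEvidence,
    child: str,
    in_tandem_repeat: bool,
    in_repeatmasker: bool,
    params: FilterParams | None = None,
) -> tuple[bool, str]:
    """Mean-AB floors for TR and RepeatMasker variants; others pass."""
    params = params or FilterParams()
    abs_ = [
        evidence.get(child, p).ab
        for p in PLATFORMS
        if evidence.get(child, p).retained > 0
    ]
    if not abs_:
        return False, "no_evidence"
    mean_ab = float(np.mean(abs_))
    if in_tandem_repeat and not (mean_ab > params.tr_min_mean_ab):
        return False, "tr_ab"
    if in_repeatmasker:
        floor = params.rm_tr_min_ab if in_tandem_repeat else params.rm_min_ab
        if mean_ab < floor:
            return False, "repeatmasker_ab"
    return True, ""


def homopolymer_filter(
    ref: str,
    alt: str,
    hp_base: str | None,
    hp_length: int,
    params: FilterParams | None = None,
) -> bool:
    """True (pass) unless the variant sits in/adjacent to a homopolymer of
    qualifying length and either allele involves the homopolymer base."""
    params = params or FilterParams()
    if hp_base is None or hp_length < params.homopolymer_min_len:
        return True
    return not (hp_base in ref or hp_base in alt)


# ---------------------------------------------------------------------------
# indels


def validate_indel(
    reads: pd.DataFrame,
    father: str,
    mother: str,
    child: str,
    sibling: str | None,
    params: FilterParams | None = None,
) -> str:
    """Indel verdict from span-filtered reads at one site.

    Reads count only at maximal mapping quality with both flanks covering
    the site. Any parental or sibling support in any platform marks the
    variant inherited; child support must be present in both HiFi and
    Illumina.
    """
    params = params or FilterParams()
    ok = reads[
        (reads["mapping_quality"] >= params.indel_min_mapq)
        & (reads["flank_left"] >= params.indel_min_flank_bp)
        & (reads["flank_right"] >= params.indel_min_flank_bp)
    ]
    checkers = [father, mother] + ([sibling] if sibling else [])
    support = ok[ok["allele"] == "alt"]
    if support["sample"].isin(checkers).any():
        return INHERITED
    trio_reads = ok[ok["sample"].isin([father, mother, child])]
    n_other = trio_reads.loc[
        trio_reads["allele"].str.startswith("other:"), "allele"
    ].nunique()
    if n_other > params.indel_max_other_alleles:
        return FAILED
    child_support = support[support["sample"] == child]
    platforms = set(child_support["platform"])
    if {"hifi", "illumina"}.issubset(platforms):
        return VALIDATED
    return FAILED


# ---------------------------------------------------------------------------
# sex chromosomes


def validate_sex_chromosome(
    evidence: SiteEvidence,
    chrom: str,
    child_sex: int,
    father: str,
    mother: str,
    child: str,
    params: FilterParams | None = None,
) -> str:
    """Hemizygous validation: male X checked against the mother only, Y
    against the father only, with a strict AB = 1 requirement; female X uses
    the autosomal rules."""
    params = params or FilterParams()
    female = child_sex == 2
    if chrom.endswith("Y") and female:
        raise InputError("chrY candidate in a female child")
    if female:
        verdicts = {
            p: validate_snv_platform(evidence, p, father, mother, child, params)
            for p in PLATFORMS
        }
        return combine_platform_verdicts(verdicts, params)
    checked_parent = mother if chrom.endswith("X") else father
    verdicts = {}
    for p in PLATFORMS:
        hq_max, lq_max = params.parent_ceiling(p)
        pc = evidence.get(checked_parent, p)
        cc = evidence.get(child, p)
        if pc.high_alt > hq_max or pc.low_alt > lq_max:
            verdicts[p] = INHERITED
        elif cc.retained == 0 or cc.alt < params.child_min_alt_reads:
            verdicts[p] = UNSUPPORTED
        else:
            verdicts[p] = DE_NOVO
    combined = combine_platform_verdicts(verdicts, params)
    if combined != VALIDATED:
        return combined
    alt = sum(evidence.get(child, p).alt for p in PLATFORMS)
    ref = sum(evidence.get(child, p).ref for p in PLATFORMS)
    ab = alt / (alt + ref) if (alt + ref) else 0.0
    if ab < 1.0 - params.sex_ab_epsilon:
        return FAILED
    return combined
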