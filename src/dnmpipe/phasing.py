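"""Read-backed parent-of-origin assignment via inheritance scores.

Each child long read covering a DNM is scored as the distance-weighted mean
of +/-1 tags over the informative SNPs it carries (weight 1/d by default);
negative scores are paternal, positive maternal, zero or no SNPs leaves the
read unassigned. HiFi calls take precedence, ONT fills in, and variants
whose DNM-allele reads land on both haplotypes in every informative
platform are excluded as likely sequencing errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from dnmpipe.config import FilterParams

PATERNAL = "paternal"
MATERNAL = "maternal"
UNPHASED = "unphased"
CONFLICT = "conflict"

_SIGN = {PATERNAL: -1.0, MATERNAL: 1.0}


@dataclass(frozen=True)
class PhaseCall:
    parent_of_origin: str  # paternal | maternal | unphased | conflict
    source: str  # hifi | ont | none
    exclude: bool = False


# ---------------------------------------------------------------------------
# informative SNPs


class TrioGenotypeIndex:
    """Per-(family, chrom) positional index over the long genotype table."""

    def __init__(self, genotypes: pd.DataFrame):
        self._store: dict[tuple[str, str], pd.DataFrame] = {}
        if genotypes.empty:
            return
        for (family, chrom), grp in genotypes.groupby(["family", "chrom"], sort=False):
            pivot = grp.pivot_table(
                index="pos", columns="sample", values="gt", aggfunc="first"
            ).sort_index()
            self._store[(family, chrom)] = pivot

    def window(
        self, family: str, chrom: str, lo: int, hi: int
    ) -> pd.DataFrame | None:
        pivot = self._store.get((family, chrom))
        if pivot is None:
            return None
        return pivot.loc[lo:hi]


def find_informative_snps(
    index: TrioGenotypeIndex,
    family: str,
    father: str,
    mother: str,
    child: str,
    chrom: str,
    dnm_pos: int,
    params: FilterParams | None = None,
) -> pd.DataFrame:
    """SNPs within the phasing window whose parental origin is forced:
    one parent 0/0, the other 0/1 or 1/1, child 0/1."""
    params = params or FilterParams()
    half = params.phase_window_bp // 2
    window = index.window(family, chrom, dnm_pos - half, dnm_pos + half)
    empty = pd.DataFrame(columns=["pos", "alt_parent", "distance"])
    if window is None or window.empty:
        return empty
    for col in (father, mother, child):
        if col not in window.columns:
            return empty
    f = window[father].to_numpy()
    m = window[mother].to_numpy()
    c = window[child].to_numpy()
    pos = window.index.to_numpy(dtype=np.int64)
    het_child = c == "0/1"
    carrier_is_father = (f != "0/0") & np.isin(f, ["0/1", "1/1"]) & (m == "0/0")
    carrier_is_mother = (m != "0/0") & np.isin(m, ["0/1", "1/1"]) & (f == "0/0")
    informative = het_child & (carrier_is_father | carrier_is_mother) & (pos != dnm_pos)
    out = pd.DataFrame(
        {
            "pos": pos[informative],
            "alt_parent": np.where(
                carrier_is_father[informative], PATERNAL, MATERNAL
            ),
        }
    )
    out["distance"] = np.abs(out["pos"] - dnm_pos).clip(lower=1)
    return out


# ---------------------------------------------------------------------------
# read scoring


def score_read(
    snp_positions: np.ndarray,
    snp_alleles: np.ndarray,
    informative: pd.DataFrame,
    dnm_pos: int,
    params: FilterParams | None = None,
) -> float:
    """Inheritance score of one read; NaN when no informative SNP is seen."""
    params = params or FilterParams()
    if informative.empty or len(snp_positions) == 0:
        return float("nan")
    info_pos = informative["pos"].to_numpy(dtype=np.int64)
    order = np.argsort(info_pos)
    info_pos = info_pos[order]
    info_parent = informative["alt_parent"].to_numpy()[order]
    idx = np.searchsorted(info_pos, snp_positions)
    valid = (idx < len(info_pos)) & (info_pos[np.clip(idx, 0, len(info_pos) - 1)] == snp_positions)
    if not valid.any():
        return float("nan")
    parent = info_parent[idx[valid]]
    obs_alt = np.asarray(snp_alleles)[valid] == "alt"
    sign = np.where(parent == PATERNAL, -1.0, 1.0)
    sign = np.where(obs_alt, sign, -sign)
    d = np.abs(snp_positions[valid] - dnm_pos).clip(min=1).astype(float)
    w = 1.0 / d**params.phase_weight_power
    return float(np.sum(sign * w) / np.sum(w))


def haplotype_of(score: float) -> str:
    if np.isnan(score) or score == 0:
        return "unassigned"
    return PATERNAL if score < 0 else MATERNAL


def phase_variant(read_calls: pd.DataFrame, source: str) -> PhaseCall:
    """Collapse per-read haplotypes: unanimous DNM-allele reads phase the
    variant; split reads are a conflict; no assignable alt reads leave it
    unphased."""
    alt = read_calls[read_calls["carries_alt"]]
    haps = set(alt["haplotype"]) - {"unassigned"}
    if haps == {PATERNAL}:
        return PhaseCall(PATERNAL, source)
    if haps == {MATERNAL}:
        return PhaseCall(MATERNAL, source)
    if len(haps) == 2:
        return PhaseCall(CONFLICT, source)
    return PhaseCall(UNPHASED, source)


def phase_with_fallback(
    hifi_call: PhaseCall, ont_call: PhaseCall, has_informative_snps: bool
) -> PhaseCall:
    """HiFi assignment preferred; ONT fills unphased/conflicted HiFi calls;
    a variant that conflicts in every informative platform is excluded."""
    if hifi_call.parent_of_origin in (PATERNAL, MATERNAL):
        return hifi_call
    if ont_call.parent_of_origin in (PATERNAL, MATERNAL):
        return ont_call
    saw_conflict = CONFLICT in (hifi_call.parent_of_origin, ont_call.parent_of_origin)
    if has_informative_snps and saw_conflict:
        return PhaseCall(CONFLICT, "none", exclude=True)
    return PhaseCall(UNPHASED, "none")


# ---------------------------------------------------------------------------
# cohort-level phasing


def phase_all(
    variants: pd.DataFrame,
    reads: pd.DataFrame,
    snp_obs: pd.DataFrame,
    genotypes: pd.DataFrame,
    pedigree: pd.DataFrame,
    params: FilterParams | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Phase every variant row (family, child, chrom, pos).

    Returns the variants with ``parent_of_origin``, ``phase_source`` and
    ``phase_exclude`` columns, plus a per-read haplotype table used by the
    origin classifier.
    """
    params = params or FilterParams()
    gindex = TrioGenotypeIndex(genotypes)
    trio = pedigree.set_index("individual")[["father", "mother"]].to_dict("index")

    phase_reads = reads[
        reads["platform"].isin(["hifi", "ont"])
        & (reads["mapping_quality"] >= params.long_read_min_mapq)
        & (reads["base_quality"] >= params.high_bq_exclusive)
        & reads["allele"].isin(["ref", "alt"])
    ]
    # child HiFi phasing reads must come from blood when blood data exist
    hifi_blood = phase_reads[
        (phase_reads["platform"] == "hifi") & (phase_reads["tissue"] == "blood")
    ]
    has_blood_keys = set(
        map(tuple, hifi_blood[["sample", "chrom", "pos"]].drop_duplicates().to_numpy())
    )
    blood_elsewhere = np.array(
        [
            (s, c, p) in has_blood_keys
            for s, c, p in zip(
                phase_reads["sample"], phase_reads["chrom"], phase_reads["pos"]
            )
        ],
        dtype=bool,
    )
    drop = (
        (phase_reads["platform"] == "hifi").to_numpy()
        & (phase_reads["tissue"] != "blood").to_numpy()
        & blood_elsewhere
    )
    phase_reads = phase_reads[~drop]

    read_groups = {
        key: grp
        for key, grp in phase_reads.groupby(["sample", "chrom", "pos"], sort=False)
    }
    obs_index = _ObsIndex(snp_obs)

    results = []
    hap_rows = []
    for var in variants.itertuples(index=False):
        father = trio[var.child]["father"]
        mother = trio[var.child]["mother"]
        informative = find_informative_snps(
            gindex, var.family, father, mother, var.child, var.chrom, int(var.pos),
            params,
        )
        has_snps = not informative.empty
        calls = {}
        for platform in ("hifi", "ont"):
            grp = read_groups.get((var.child, var.chrom, int(var.pos)))
            if grp is not None:
                grp = grp[grp["platform"] == platform]
            if grp is None or grp.empty:
                calls[platform] = PhaseCall(UNPHASED, platform)
                continue
            scores = _score_group(grp, obs_index, informative, int(var.pos), params)
            read_calls = pd.DataFrame(
                {
                    "read_id": grp["read_id"].to_numpy(),
                    "carries_alt": (grp["allele"] == "alt").to_numpy(),
                    "haplotype": [haplotype_of(s) for s in scores],
                }
            )
            calls[platform] = phase_variant(read_calls, platform)
            for rid, alt_flag, hap in read_calls.itertuples(index=False):
                hap_rows.append(
                    (
                        var.family,
                        var.child,
                        var.chrom,
                        int(var.pos),
                        platform,
                        rid,
                        bool(alt_flag),
                        hap,
                    )
                )
        final = phase_with_fallback(calls["hifi"], calls["ont"], has_snps)
        results.append(
            (final.parent_of_origin, final.source, final.exclude, len(informative))
        )
    out = variants.copy().reset_index(drop=True)
    if results:
        res = pd.DataFrame(
            results,
            columns=["parent_of_origin", "phase_source", "phase_exclude", "n_informative_snps"],
        )
    else:
        res = pd.DataFrame(
            columns=["parent_of_origin", "phase_source", "phase_exclude", "n_informative_snps"]
        )
    out = pd.concat([out, res], axis=1)
    hap_table = pd.DataFrame(
        hap_rows,
        columns=[
            "family", "child", "chrom", "pos", "platform", "read_id",
            "carries_alt", "haplotype",
        ],
    )
    return out, hap_table


class _ObsIndex:
    """SNP observations sorted by read id for fast per-site slicing."""

    def __init__(self, snp_obs: pd.DataFrame):
        if snp_obs is None or len(snp_obs) == 0:
            self.rid = np.array([], dtype=object)
            self.pos = np.array([], dtype=np.int64)
            self.allele = np.array([], dtype=object)
            return
        rid = snp_obs["read_id"].to_numpy()
        order = np.argsort(rid, kind="stable")
        self.rid = rid[order]
        self.pos = snp_obs["snp_pos"].to_numpy(dtype=np.int64)[order]
        self.allele = snp_obs["allele"].to_numpy()[order]

    def gather(self, read_ids: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(local read index, snp position, observed allele) for given reads."""
        if len(self.rid) == 0 or len(read_ids) == 0:
            return (
                np.array([], dtype=np.int64),
                np.array([], dtype=np.int64),
                np.array([], dtype=object),
            )
        lo = np.searchsorted(self.rid, read_ids, side="left")
        hi = np.searchsorted(self.rid, read_ids, side="right")
        counts = hi - lo
        ridx = np.repeat(np.arange(len(read_ids)), counts)
        flat = np.concatenate(
            [np.arange(a, b) for a, b in zip(lo, hi)]
        ) if counts.sum() else np.array([], dtype=np.int64)
        return ridx, self.pos[flat], self.allele[flat]


def _score_group(
    grp: pd.DataFrame,
    obs_index: _ObsIndex,
    informative: pd.DataFrame,
    dnm_pos: int,
    params: FilterParams,
) -> np.ndarray:
    """Vectorised inheritance scores for all reads of one site/platform."""
    n = len(grp)
    scores = np.full(n, np.nan)
    if informative.empty:
        return scores
    ridx, pos, allele = obs_index.gather(grp["read_id"].to_numpy())
    if len(ridx) == 0:
        return scores
    info_pos = informative["pos"].to_numpy(dtype=np.int64)
    order = np.argsort(info_pos)
    info_pos = info_pos[order]
    info_parent = informative["alt_parent"].to_numpy()[order]
    idx = np.searchsorted(info_pos, pos)
    valid = (idx < len(info_pos)) & (
        info_pos[np.clip(idx, 0, len(info_pos) - 1)] == pos
    )
    if not valid.any():
        return scores
    ridx, pos, allele, idx = ridx[valid], pos[valid], allele[valid], idx[valid]
    sign = np.where(info_parent[idx] == PATERNAL, -1.0, 1.0)
    sign = np.where(allele == "alt", sign, -sign)
    w = 1.0 / np.abs(pos - dnm_pos).clip(min=1).astype(float) ** params.phase_weight_power
    num = np.zeros(n)
    den = np.zeros(n)
    np.add.at(num, ridx, sign * w)
    np.add.at(den, ridx, w)
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = np.where(den > 0, num / den, np.nan)
    return scores
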