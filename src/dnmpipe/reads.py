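"""Tri-platform read-evidence simulation for synthetic cohorts.

Reads are sampled haplotype-aware: each child read derives from one parental
haplotype; alt-carrying reads are dropped at the rate implied by the
configured constitutional allele-balance mean, so germline hets show the
expected sub-0.5 AB while keeping parental haplotypes clean. The latent
haplotype is kept in a private ``_hap`` column (never written to disk) and
only surfaces through informative-SNP observations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from dnmpipe.cohort import BASES, alt_read_dropout
from dnmpipe.config import ConfigurationError, PlatformProfile, SimulationConfig

READ_COLUMNS = [
    "family",
    "sample",
    "chrom",
    "pos",
    "var_id",
    "platform",
    "tissue",
    "read_id",
    "allele",
    "base_quality",
    "mapping_quality",
    "flank_left",
    "flank_right",
    "_hap",
]

SNP_COLUMNS = ["family", "chrom", "pos", "alt_parent", "anchor_var_id"]
SNP_OBS_COLUMNS = ["family", "anchor_var_id", "read_id", "snp_pos", "allele"]
GENOTYPE_COLUMNS = ["family", "chrom", "pos", "ref", "alt", "sample", "gt", "gq"]
PANEL_COLUMNS = ["family", "child", "chrom", "pos", "callable"]

OTHER_PARENT = {"paternal": "maternal", "maternal": "paternal"}


_SCALAR_COLS = ("family", "sample", "chrom", "pos", "var_id", "platform", "tissue")
_ARRAY_COLS = ("allele", "base_quality", "mapping_quality", "flank_left",
               "flank_right", "_hap")


class _ReadBuffer:
    """Column-wise accumulator: per-group scalars expanded lazily with
    ``np.repeat``; read ids are sequential integers."""

    def __init__(self) -> None:
        self.scalars: dict[str, list] = {c: [] for c in _SCALAR_COLS}
        self.arrays: dict[str, list] = {c: [] for c in _ARRAY_COLS}
        self.sizes: list[int] = []
        self.counter = 0

    def add(
        self,
        family: str,
        sample: str,
        chrom: str,
        pos: int,
        var_id: str,
        profile: PlatformProfile,
        allele: np.ndarray,
        bq: np.ndarray,
        mapq: np.ndarray,
        flank_left: np.ndarray,
        flank_right: np.ndarray,
        hap: np.ndarray,
    ) -> np.ndarray:
        n = len(allele)
        ids = np.arange(self.counter, self.counter + n, dtype=np.int64)
        self.counter += n
        for col, value in zip(
            _SCALAR_COLS, (family, sample, chrom, pos, var_id, profile.name,
                           profile.tissue)
        ):
            self.scalars[col].append(value)
        for col, arr in zip(
            _ARRAY_COLS, (allele, bq, mapq, flank_left, flank_right, hap)
        ):
            self.arrays[col].append(arr)
        self.sizes.append(n)
        return ids

    def frame(self) -> pd.DataFrame:
        if not self.sizes:
            return pd.DataFrame(
                {c: np.array([], dtype=object) for c in READ_COLUMNS}
            ).astype({"pos": np.int64, "read_id": np.int64})
        sizes = np.asarray(self.sizes, dtype=np.int64)
        data: dict[str, np.ndarray] = {}
        for col in _SCALAR_COLS:
            dtype = np.int64 if col == "pos" else object
            data[col] = np.repeat(np.asarray(self.scalars[col], dtype=dtype), sizes)
        start = self.counter - int(sizes.sum())
        data["read_id"] = np.arange(start, self.counter, dtype=np.int64)
        for col in _ARRAY_COLS:
            data[col] = np.concatenate(self.arrays[col])
        return pd.DataFrame({c: data[c] for c in READ_COLUMNS})


def _draw_discrete(
    pairs: tuple[tuple[int, float], ...], n: int, rng: np.random.Generator
) -> np.ndarray:
    values = np.array([v for v, _ in pairs])
    probs = np.array([p for _, p in pairs])
    return rng.choice(values, size=n, p=probs)


def _geometry(
    profile: PlatformProfile, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    u = rng.integers(0, profile.read_span_bp, size=n)
    return u, profile.read_span_bp - 1 - u


def simulate_reads(
    truth: pd.DataFrame,
    pedigree: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
    members: str = "family",
) -> pd.DataFrame:
    """Simulate per-read evidence at every truth site.

    ``members`` is ``"family"`` (child, parents and sibling) or
    ``"children"`` (carrier child only; used for phasing-only studies).
    """
    for required in ("hifi", "ont", "illumina"):
        config.profile(required)  # raises for missing platform
    delta = alt_read_dropout(config)
    fam_index = _family_index(pedigree)
    buf = _ReadBuffer()
    for var in truth.itertuples(index=False):
        fam = fam_index[var.family]
        if members == "children":
            samples = [(var.child, True)]
        else:
            samples = [(var.child, True), (fam["father"], False), (fam["mother"], False)]
            for sib in fam["children"]:
                if sib != var.child:
                    samples.append((sib, False))
        for sample, is_carrier in samples:
            for profile in config.platform_profiles:
                n = rng.poisson(profile.mean_depth)
                if n == 0:
                    continue
                if is_carrier:
                    allele, bq, hap, keep = _carrier_reads(
                        var, profile, n, delta, rng
                    )
                    n = int(keep.sum())
                    if n == 0:
                        continue
                else:
                    allele, bq = _noncarrier_reads(profile, n, rng)
                    hap = np.full(n, "", dtype=object)
                mapq = _draw_discrete(profile.mapping_quality_probs, n, rng)
                fl, fr = _geometry(profile, n, rng)
                buf.add(
                    var.family,
                    sample,
                    var.chrom,
                    int(var.pos),
                    var.var_id,
                    profile,
                    allele,
                    bq,
                    mapq,
                    fl,
                    fr,
                    hap,
                )
    return buf.frame()


def _carrier_reads(
    var,
    profile: PlatformProfile,
    n: int,
    delta: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    frac = float(var.mosaic_fraction)
    carrier_parent = var.parent if var.parent in OTHER_PARENT else "paternal"
    on_carrier_hap = rng.random(n) < 0.5
    carries_alt = on_carrier_hap & (rng.random(n) < frac)
    dropped = carries_alt & (rng.random(n) < delta)
    keep = ~dropped
    m = int(keep.sum())
    carries_alt = carries_alt[keep]
    on_carrier_hap = on_carrier_hap[keep]
    allele = np.where(carries_alt, "alt", "ref").astype(object)
    bq = _draw_discrete(profile.base_quality_probs, m, rng)
    # sequencing noise on non-alt reads
    noise = ~carries_alt
    err = noise & (rng.random(m) < profile.error_rate)
    other = noise & ~err & (rng.random(m) < profile.other_allele_rate)
    if err.any():
        allele[err] = "alt"
        bq[err] = _draw_discrete(
            profile.error_base_quality_probs, int(err.sum()), rng
        )
    if other.any():
        allele[other] = np.array(
            [f"other:{b}" for b in rng.choice(BASES, size=int(other.sum()))],
            dtype=object,
        )
        bq[other] = _draw_discrete(
            profile.error_base_quality_probs, int(other.sum()), rng
        )
    hap = np.where(
        on_carrier_hap, carrier_parent, OTHER_PARENT[carrier_parent]
    ).astype(object)
    return allele, bq, hap, keep


def _noncarrier_reads(
    profile: PlatformProfile, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    allele = np.full(n, "ref", dtype=object)
    bq = _draw_discrete(profile.base_quality_probs, n, rng)
    err = rng.random(n) < profile.error_rate
    other = ~err & (rng.random(n) < profile.other_allele_rate)
    if err.any():
        allele[err] = "alt"
        bq[err] = _draw_discrete(profile.error_base_quality_probs, int(err.sum()), rng)
    if other.any():
        allele[other] = np.array(
            [f"other:{b}" for b in rng.choice(BASES, size=int(other.sum()))],
            dtype=object,
        )
        bq[other] = _draw_discrete(
            profile.error_base_quality_probs, int(other.sum()), rng
        )
    return allele, bq


def simulate_background_alt_reads(
    truth: pd.DataFrame,
    pedigree: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Sparse HiFi alt reads in cohort members outside each variant's family.

    Equivalent to full read simulation followed by discarding non-alt reads
    (Poisson thinning), which is all the recurrence filter consumes.
    """
    profile = config.profile("hifi")
    lam = profile.mean_depth * profile.error_rate
    others_by_family: dict[str, np.ndarray] = {}
    all_samples = pedigree["individual"].to_numpy()
    fam_of = pedigree.set_index("individual")["family"].to_dict()
    for fam in pedigree["family"].unique():
        others_by_family[fam] = all_samples[
            np.array([fam_of[s] != fam for s in all_samples])
        ]
    buf = _ReadBuffer()
    buf.counter = 10_000_000  # distinct id space from family reads
    for var in truth.itertuples(index=False):
        others = others_by_family[var.family]
        counts = rng.poisson(lam, size=len(others))
        for sample, k in zip(others[counts > 0], counts[counts > 0]):
            bq = _draw_discrete(profile.error_base_quality_probs, int(k), rng)
            mapq = _draw_discrete(profile.mapping_quality_probs, int(k), rng)
            fl, fr = _geometry(profile, int(k), rng)
            buf.add(
                fam_of[sample],
                sample,
                var.chrom,
                int(var.pos),
                var.var_id,
                profile,
                np.full(int(k), "alt", dtype=object),
                bq,
                mapq,
                fl,
                fr,
                np.full(int(k), "", dtype=object),
            )
    return buf.frame()


# ---------------------------------------------------------------------------
# informative SNPs


def simulate_informative_snps(
    truth: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Poisson-process informative SNPs in a window around each truth DNM."""
    half = config.snp_window_bp // 2
    rows = {c: [] for c in SNP_COLUMNS}
    for var in truth.itertuples(index=False):
        lo = max(1, int(var.pos) - half)
        hi = min(config.genome_length, int(var.pos) + half)
        n = rng.poisson(config.snp_density * max(hi - lo, 0))
        if n == 0:
            continue
        pos = np.unique(rng.integers(lo, hi + 1, size=n))
        pos = pos[pos != int(var.pos)]
        n = len(pos)
        if n == 0:
            continue
        parents = np.where(rng.random(n) < 0.5, "paternal", "maternal").astype(object)
        rows["family"].append(np.full(n, var.family, dtype=object))
        rows["chrom"].append(np.full(n, var.chrom, dtype=object))
        rows["pos"].append(pos.astype(np.int64))
        rows["alt_parent"].append(parents)
        rows["anchor_var_id"].append(np.full(n, var.var_id, dtype=object))
    data = {
        c: (np.concatenate(v) if v else np.array([], dtype=object))
        for c, v in rows.items()
    }
    return pd.DataFrame(data)


def simulate_snp_observations(
    reads: pd.DataFrame,
    snps: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per-read observations of informative SNPs on child long reads."""
    long_platforms = {
        p.name for p in config.platform_profiles if p.long_read
    }
    phaseable = reads[
        reads["platform"].isin(long_platforms) & (reads["_hap"] != "")
    ]
    if snps.empty or phaseable.empty:
        return pd.DataFrame(columns=SNP_OBS_COLUMNS)
    snp_groups = {
        key: grp for key, grp in snps.groupby(["family", "anchor_var_id"], sort=False)
    }
    out = {c: [] for c in SNP_OBS_COLUMNS}
    err = config.snp_observation_error
    for (family, var_id), grp in phaseable.groupby(["family", "var_id"], sort=False):
        snp_grp = snp_groups.get((family, var_id))
        if snp_grp is None:
            continue
        snp_pos = snp_grp["pos"].to_numpy(dtype=np.int64)
        snp_parent = snp_grp["alt_parent"].to_numpy()
        pos = grp["pos"].to_numpy(dtype=np.int64)
        starts = pos - grp["flank_left"].to_numpy(dtype=np.int64)
        ends = pos + grp["flank_right"].to_numpy(dtype=np.int64)
        covered = (snp_pos[None, :] >= starts[:, None]) & (
            snp_pos[None, :] <= ends[:, None]
        )
        ridx, sidx = np.nonzero(covered)
        if len(ridx) == 0:
            continue
        read_ids = grp["read_id"].to_numpy()[ridx]
        haps = grp["_hap"].to_numpy()[ridx]
        alleles = np.where(haps == snp_parent[sidx], "alt", "ref").astype(object)
        flips = rng.random(len(ridx)) < err
        if flips.any():
            alleles[flips] = np.where(alleles[flips] == "alt", "ref", "alt")
        out["family"].append(np.full(len(ridx), family, dtype=object))
        out["anchor_var_id"].append(np.full(len(ridx), var_id, dtype=object))
        out["read_id"].append(read_ids)
        out["snp_pos"].append(snp_pos[sidx])
        out["allele"].append(alleles)
    data = {
        c: (np.concatenate(v) if v else np.array([], dtype=object))
        for c, v in out.items()
    }
    return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# genotypes and callable panel


def genotypes_from_truth(
    truth: pd.DataFrame,
    snps: pd.DataFrame,
    pedigree: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Family VCF genotype records at truth sites and informative SNP sites.

    The carrier child is 0/1 at its truth sites; at an informative SNP the
    alt-contributing parent and the anchor child are 0/1, everyone else 0/0.
    """
    members = pedigree[["family", "individual", "role"]]
    frames = []
    if len(truth):
        m = truth[["family", "child", "chrom", "pos", "ref", "alt"]].merge(
            members, on="family"
        )
        m["gt"] = np.where(m["individual"] == m["child"], "0/1", "0/0")
        frames.append(m)
    if len(snps):
        uniq = snps.drop_duplicates(subset=["family", "chrom", "pos"]).copy()
        uniq["anchor_child"] = [a.rsplit("_", 2)[0] for a in uniq["anchor_var_id"]]
        s = uniq[["family", "chrom", "pos", "alt_parent", "anchor_child"]].merge(
            members, on="family"
        )
        carrier = (
            ((s["role"] == "father") & (s["alt_parent"] == "paternal"))
            | ((s["role"] == "mother") & (s["alt_parent"] == "maternal"))
            | (s["individual"] == s["anchor_child"])
        )
        s["gt"] = np.where(carrier, "0/1", "0/0")
        s["ref"] = "A"
        s["alt"] = "G"
        frames.append(s)
    if not frames:
        return pd.DataFrame(columns=GENOTYPE_COLUMNS)
    df = pd.concat(
        [f[["family", "chrom", "pos", "ref", "alt", "individual", "gt"]] for f in frames],
        ignore_index=True,
    ).rename(columns={"individual": "sample"})
    df["gq"] = rng.integers(40, 99, size=len(df))
    return df.sort_values(["family", "chrom", "pos", "sample"]).reset_index(drop=True)


def simulate_callable_panel(
    pedigree: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Monte-Carlo callability panel: uniform sites scored per trio.

    A panel site is callable when father, mother and child each have at
    least one HiFi read with mapping quality >= 59 and base quality >= 20,
    mirroring the mask definition at full resolution.
    """
    profile = config.profile("hifi")
    p_map = sum(p for q, p in profile.mapping_quality_probs if q >= 59)
    p_bq = sum(p for q, p in profile.base_quality_probs if q >= 20)
    p_hq = p_map * p_bq
    children = pedigree[pedigree["role"] == "child"]
    if config.genome_length == 0:
        return pd.DataFrame(columns=PANEL_COLUMNS)
    frames = []
    n_sites = config.panel_sites_per_child
    for child in children.itertuples(index=False):
        chroms = rng.choice(np.array(config.chromosomes), size=n_sites)
        pos = rng.integers(1, config.genome_length + 1, size=n_sites)
        ok = np.ones(n_sites, dtype=bool)
        for _member in range(3):  # father, mother, child
            depth = rng.poisson(profile.mean_depth, size=n_sites)
            hq = rng.binomial(depth, p_hq)
            ok &= hq >= 1
        frames.append(
            pd.DataFrame(
                {
                    "family": child.family,
                    "child": child.individual,
                    "chrom": chroms,
                    "pos": pos,
                    "callable": ok,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=PANEL_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def _family_index(pedigree: pd.DataFrame) -> dict[str, dict]:
    index: dict[str, dict] = {}
    for fam, grp in pedigree.groupby("family", sort=False):
        father = grp.loc[grp["role"] == "father", "individual"]
        mother = grp.loc[grp["role"] == "mother", "individual"]
        if father.empty or mother.empty:
            raise ConfigurationError(f"family {fam}: missing parent")
        index[fam] = {
            "father": father.iloc[0],
            "mother": mother.iloc[0],
            "children": list(grp.loc[grp["role"] == "child", "individual"]),
        }
    return index
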