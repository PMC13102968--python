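"""Callable-genome masks and mutation-rate estimation."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from dnmpipe.config import FilterParams
from dnmpipe.intervals import bed_total_bp, intersect_bed, merge_bed, positions_in_bed


@dataclass
class CallableMask:
    """Merged half-open intervals where DNM discovery was possible for one trio."""

    child: str
    intervals: pd.DataFrame  # chrom, start, end

    @property
    def total_bp(self) -> int:
        return bed_total_bp(self.intervals)

    def stratify(self, tracks: dict[str, pd.DataFrame]) -> dict[str, int]:
        return {
            name: bed_total_bp(intersect_bed(self.intervals, bed))
            for name, bed in tracks.items()
        }


@dataclass
class RateEstimate:
    stratum: str
    count: int
    denominator_bp: float
    rate: float
    ci_low: float
    ci_high: float
    per_sample: pd.DataFrame | None = field(default=None, repr=False)


def compute_callable_mask(
    sites: pd.DataFrame,
    child: str,
    child_sex: int = 2,
    params: FilterParams | None = None,
) -> CallableMask:
    """Per-site callability: both parents 0/0 and every required trio member
    has >= 1 high-quality read (MAPQ floor, base quality >= 20).

    ``sites`` columns: chrom, pos (1-based), father_gt, mother_gt,
    father_hq, mother_hq, child_hq. On the male X only the mother's data
    count (father may carry an alt); on the Y only the father's.
    """
    if sites.empty:
        return CallableMask(child, pd.DataFrame(columns=["chrom", "start", "end"]))
    chrom = sites["chrom"].astype(str)
    male = child_sex == 1
    on_x = chrom.str.endswith("X") & male
    on_y = chrom.str.endswith("Y") & male
    diploid = ~(on_x | on_y)
    gt_ok = (sites["father_gt"] == "0/0") & (sites["mother_gt"] == "0/0")
    cov_ok = (
        (sites["father_hq"] >= 1) & (sites["mother_hq"] >= 1) & (sites["child_hq"] >= 1)
    )
    callable_ = (diploid & gt_ok & cov_ok) | (
        on_x & (sites["mother_hq"] >= 1) & (sites["child_hq"] >= 1)
    ) | (on_y & (sites["father_hq"] >= 1) & (sites["child_hq"] >= 1))
    rows = []
    for c, grp in sites[callable_].groupby("chrom", sort=True):
        pos = np.sort(grp["pos"].to_numpy(dtype=np.int64))
        for s, e in _runs_to_intervals(pos):
            rows.append((c, s, e))
    return CallableMask(child, merge_bed(pd.DataFrame(rows, columns=["chrom", "start", "end"])))


def _runs_to_intervals(sorted_pos: np.ndarray) -> list[tuple[int, int]]:
    """1-based site runs -> half-open 0-based intervals."""
    if len(sorted_pos) == 0:
        return []
    breaks = np.nonzero(np.diff(sorted_pos) > 1)[0]
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [len(sorted_pos) - 1]])
    return [(int(sorted_pos[s] - 1), int(sorted_pos[e])) for s, e in zip(starts, ends)]


def stratify_mask(
    mask: CallableMask, tracks: dict[str, pd.DataFrame]
) -> dict[str, int]:
    """Callable bp per annotation track (interval intersection)."""
    return mask.stratify(tracks)


SD_IDENTITY_BINS = (("90-95", 90.0, 95.0), ("95-98", 95.0, 98.0),
                    ("98-99", 98.0, 99.0), (">99", 99.0, 101.0))


def stratify_segdup_identity(
    mask: CallableMask, segdup: pd.DataFrame
) -> dict[str, int]:
    out = {}
    for label, lo, hi in SD_IDENTITY_BINS:
        sub = segdup[(segdup["pct_identity"] >= lo) & (segdup["pct_identity"] < hi)]
        out[label] = bed_total_bp(intersect_bed(mask.intervals, sub[["chrom", "start", "end"]]))
    return out


def poisson_ci(count: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (Garwood) confidence interval for a Poisson count."""
    alpha = 1 - level
    lo = 0.0 if count == 0 else float(stats.chi2.ppf(alpha / 2, 2 * count) / 2)
    hi = float(stats.chi2.ppf(1 - alpha / 2, 2 * count + 2) / 2)
    return lo, hi


def mutation_rate(
    count: int,
    callable_bp: float,
    ploidy: int = 2,
    level: float = 0.95,
    stratum: str = "autosomes",
    per_sample: pd.DataFrame | None = None,
) -> RateEstimate:
    """Rate per bp per generation: count over ploidy x callable bp, with an
    exact Poisson interval on the count."""
    if callable_bp <= 0:
        raise ValueError("callable_bp must be > 0")
    denom = ploidy * callable_bp
    lo, hi = poisson_ci(count, level)
    return RateEstimate(
        stratum=stratum,
        count=int(count),
        denominator_bp=denom,
        rate=count / denom,
        ci_low=lo / denom,
        ci_high=hi / denom,
        per_sample=per_sample,
    )


# ---------------------------------------------------------------------------
# panel-based callable estimation (synthetic cohorts)


def callable_from_panel(
    panel: pd.DataFrame,
    total_genome_bp: float,
    tracks: dict[str, pd.DataFrame] | None = None,
) -> pd.DataFrame:
    """Estimate per-child callable bp (total and per track) from a sampled
    callability panel; Monte-Carlo stand-in for the full per-site mask."""
    track_items = list((tracks or {}).items())
    track_bp = {
        name: bed_total_bp(bed[["chrom", "start", "end"]]) for name, bed in track_items
    }
    if panel.empty:
        return pd.DataFrame(columns=["child", "family", "callable_bp"])
    chroms = panel["chrom"].to_numpy()
    pos = panel["pos"].to_numpy(dtype=np.int64)
    work = panel[["child", "family", "callable"]].copy()
    # per-track callable fractions are pooled over the cohort: per-child
    # panel slices inside a small track are too sparse to invert stably
    pooled_frac: dict[str, float] = {}
    for name, bed in track_items:
        in_track = positions_in_bed(chroms, pos, bed[["chrom", "start", "end"]])
        pooled_frac[name] = (
            float(work.loc[in_track, "callable"].mean()) if in_track.any() else 1.0
        )
    rows = []
    for (child, family), grp in work.groupby(["child", "family"], sort=True):
        row = {
            "child": child,
            "family": family,
            "callable_bp": grp["callable"].mean() * total_genome_bp,
        }
        for name, _ in track_items:
            row[f"callable_bp_{name}"] = pooled_frac[name] * track_bp[name]
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stratified and parent-specific rates


def cohort_rate(
    variants: pd.DataFrame,
    callable_table: pd.DataFrame,
    origin: str = "germline",
    var_class: str = "snv",
    stratum: str = "autosomes",
    level: float = 0.95,
) -> RateEstimate:
    """Cohort-level rate: summed counts over summed diploid denominators,
    with a per-sample rate vector attached."""
    sel = variants
    if origin is not None and "origin" in sel.columns:
        sel = sel[sel["origin"] == origin]
    if var_class is not None and "var_class" in sel.columns:
        sel = sel[sel["var_class"] == var_class]
    counts = sel.groupby("child").size() if len(sel) else pd.Series(dtype=int)
    per_sample = callable_table[["child", "callable_bp"]].copy()
    per_sample["count"] = per_sample["child"].map(counts).fillna(0).astype(int)
    per_sample["rate"] = per_sample["count"] / (2 * per_sample["callable_bp"])
    total_count = int(per_sample["count"].sum())
    total_bp = float(per_sample["callable_bp"].sum())
    return mutation_rate(
        total_count, total_bp, ploidy=2, level=level, stratum=stratum,
        per_sample=per_sample,
    )


def stratified_rates(
    variants: pd.DataFrame,
    callable_table: pd.DataFrame,
    tracks: dict[str, pd.DataFrame],
    origin: str = "germline",
    level: float = 0.95,
) -> pd.DataFrame:
    """Per-track rates with per-sample vectors and BH-corrected two-sided
    t-tests of the per-sample (stratum - genome-wide) rate differences."""
    from statsmodels.stats.multitest import multipletests

    sel = variants[variants["origin"] == origin] if "origin" in variants.columns else variants
    if "var_class" in sel.columns:
        sel = sel[sel["var_class"] == "snv"]
    genome = cohort_rate(sel, callable_table, origin=None, var_class=None)
    genome_rates = genome.per_sample.set_index("child")["rate"]

    records = []
    pvals = []
    for name, bed in tracks.items():
        col = f"callable_bp_{name}"
        if col not in callable_table.columns:
            continue
        if len(sel):
            in_track = positions_in_bed(
                sel["chrom"].to_numpy(), sel["pos"].to_numpy(dtype=np.int64),
                bed[["chrom", "start", "end"]],
            )
            counts = sel[in_track].groupby("child").size()
        else:
            counts = pd.Series(dtype=int)
        tbl = callable_table[["child", col]].rename(columns={col: "callable_bp"}).copy()
        tbl = tbl[tbl["callable_bp"] > 0]
        tbl["count"] = tbl["child"].map(counts).fillna(0).astype(int)
        tbl["rate"] = tbl["count"] / (2 * tbl["callable_bp"])
        total = int(tbl["count"].sum())
        denom = 2 * float(tbl["callable_bp"].sum())
        lo, hi = poisson_ci(total, level)
        diffs = tbl["rate"].to_numpy() - genome_rates.reindex(tbl["child"]).to_numpy()
        if len(diffs) >= 2 and np.nanstd(diffs) > 0:
            _, p = stats.ttest_1samp(diffs, 0.0, nan_policy="omit")
        else:
            p = np.nan
        pvals.append(p)
        records.append(
            {
                "stratum": name,
                "count": total,
                "denominator_bp": denom,
                "rate": total / denom if denom else np.nan,
                "ci_low": lo / denom if denom else np.nan,
                "ci_high": hi / denom if denom else np.nan,
                "genome_rate": genome.rate,
                "p_value": p,
            }
        )
    out = pd.DataFrame(records)
    if len(out):
        finite = np.isfinite(out["p_value"].to_numpy(dtype=float))
        qvals = np.full(len(out), np.nan)
        if finite.any():
            qvals[finite] = multipletests(
                out.loc[finite, "p_value"], method="fdr_bh"
            )[1]
        out["q_value"] = qvals
    return out


def parent_specific_rates(
    phased_variants: pd.DataFrame,
    callable_table: pd.DataFrame,
    level: float = 0.95,
) -> dict[str, RateEstimate | int]:
    """Haplotype-specific rates: each parent contributes one haplotype, so
    the denominator is the callable bp (ploidy 1) summed over samples.
    Unphased variants are excluded and reported as a remainder."""
    total_bp = float(callable_table["callable_bp"].sum())
    out: dict[str, RateEstimate | int] = {}
    for parent in ("paternal", "maternal"):
        n = int((phased_variants["parent_of_origin"] == parent).sum())
        out[parent] = mutation_rate(n, total_bp, ploidy=1, level=level, stratum=parent)
    out["unphased"] = int(
        (~phased_variants["parent_of_origin"].isin(["paternal", "maternal"])).sum()
    )
    return out
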