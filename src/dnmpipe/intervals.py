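"""Half-open genomic interval arithmetic (0-based, BED convention)."""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

BED_COLUMNS = ["chrom", "start", "end"]


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping or touching half-open intervals on one chromosome."""
    ivs = sorted((int(s), int(e)) for s, e in intervals if e > s)
    merged: list[tuple[int, int]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def intersect_intervals(
    a: Sequence[tuple[int, int]], b: Sequence[tuple[int, int]]
) -> list[tuple[int, int]]:
    """Intersection of two merged, sorted interval lists."""
    out: list[tuple[int, int]] = []
    i = j = 0
    a = merge_intervals(a)
    b = merge_intervals(b)
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            out.append((s, e))
        if a[i][1] <= b[j][1]:
            i += 1
        else:
            j += 1
    return out


def total_bp(intervals: Iterable[tuple[int, int]]) -> int:
    return sum(e - s for s, e in merge_intervals(intervals))


def merge_bed(bed: pd.DataFrame) -> pd.DataFrame:
    """Merge a BED-like frame (chrom, start, end) per chromosome."""
    rows = []
    for chrom, grp in bed.groupby("chrom", sort=True):
        for s, e in merge_intervals(zip(grp["start"], grp["end"])):
            rows.append((chrom, s, e))
    return pd.DataFrame(rows, columns=BED_COLUMNS)


def intersect_bed(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    rows = []
    b_groups = {chrom: grp for chrom, grp in b.groupby("chrom", sort=True)}
    for chrom, grp in a.groupby("chrom", sort=True):
        other = b_groups.get(chrom)
        if other is None:
            continue
        for s, e in intersect_intervals(
            list(zip(grp["start"], grp["end"])), list(zip(other["start"], other["end"]))
        ):
            rows.append((chrom, s, e))
    return pd.DataFrame(rows, columns=BED_COLUMNS)


def bed_total_bp(bed: pd.DataFrame) -> int:
    return int(sum(total_bp(zip(g["start"], g["end"])) for _, g in bed.groupby("chrom")))


def positions_in_bed(
    chroms: np.ndarray, positions: np.ndarray, bed: pd.DataFrame
) -> np.ndarray:
    """Boolean membership of 1-based positions in a BED frame."""
    hit = np.zeros(len(positions), dtype=bool)
    pos0 = np.asarray(positions, dtype=np.int64) - 1  # to 0-based
    for chrom, grp in bed.groupby("chrom", sort=True):
        sel = np.asarray(chroms) == chrom
        if not sel.any():
            continue
        ivs = merge_intervals(zip(grp["start"], grp["end"]))
        if not ivs:
            continue
        starts = np.array([s for s, _ in ivs], dtype=np.int64)
        ends = np.array([e for _, e in ivs], dtype=np.int64)
        p = pos0[sel]
        idx = np.searchsorted(starts, p, side="right") - 1
        ok = (idx >= 0) & (p < ends[np.clip(idx, 0, len(ends) - 1)])
        hit[sel] = ok
    return hit
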