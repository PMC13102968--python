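"""Synthetic pedigrees, genome annotation layout and truth variants."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from dnmpipe.config import ConfigurationError, SimulationConfig

PEDIGREE_COLUMNS = [
    "family",
    "individual",
    "father",
    "mother",
    "sex",
    "phenotype",
    "role",
    "father_age",
    "mother_age",
]

TRUTH_COLUMNS = [
    "var_id",
    "family",
    "child",
    "chrom",
    "pos",
    "ref",
    "alt",
    "var_class",
    "origin",
    "parent",
    "mosaic_fraction",
    "region",
    "pct_identity",
    "context_5p",
    "context_3p",
]

BASES = np.array(["A", "C", "G", "T"])
TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
TRANSVERSIONS = {
    "A": ["C", "T"],
    "G": ["C", "T"],
    "C": ["A", "G"],
    "T": ["A", "G"],
}

SD_IDENTITY_CYCLE = (92.0, 96.0, 98.5, 99.5)
_TRACK_BLOCKS = 20  # blocks per track per chromosome


# ---------------------------------------------------------------------------
# genome layout


@dataclass
class GenomeLayout:
    """Deterministic carving of the synthetic genome into annotation tracks.

    Each chromosome is divided into ``_TRACK_BLOCKS`` segments; each track
    occupies a slice at the head of every segment, in declaration order, so
    tracks are disjoint by construction. Intervals are half-open 0-based.
    """

    config: SimulationConfig
    tracks: dict[str, pd.DataFrame]  # name -> chrom,start,end[,extra]

    @classmethod
    def build(cls, config: SimulationConfig) -> "GenomeLayout":
        length = config.genome_length
        seg = max(length // _TRACK_BLOCKS, 1)
        tracks: dict[str, list] = {t.name: [] for t in config.region_tracks}
        sd_counter = 0
        for chrom in config.chromosomes:
            for b in range(_TRACK_BLOCKS):
                offset = b * seg
                if offset >= length:
                    break
                cursor = offset
                for track in config.region_tracks:
                    width = int(round(track.genome_fraction * seg))
                    if width <= 0:
                        continue
                    start, end = cursor, min(cursor + width, length)
                    if end <= start:
                        continue
                    row = [chrom, start, end]
                    if track.name == "segdup":
                        row.append(SD_IDENTITY_CYCLE[sd_counter % len(SD_IDENTITY_CYCLE)])
                        sd_counter += 1
                    elif track.name == "homopolymer":
                        row.append("ACGT"[b % 4])
                    tracks[track.name].append(row)
                    cursor = end
        frames: dict[str, pd.DataFrame] = {}
        for track in config.region_tracks:
            cols = ["chrom", "start", "end"]
            if track.name == "segdup":
                cols.append("pct_identity")
            elif track.name == "homopolymer":
                cols.append("base")
            frames[track.name] = pd.DataFrame(tracks[track.name], columns=cols)
        layout = cls(config=config, tracks=frames)
        layout._complement = layout._build_complement()
        return layout

    def _build_complement(self) -> pd.DataFrame:
        """Genome minus all tracks: the 'unique' sampling compartment."""
        from dnmpipe.intervals import merge_intervals

        rows = []
        for chrom in self.config.chromosomes:
            covered = []
            for df in self.tracks.values():
                sub = df[df["chrom"] == chrom]
                covered.extend(zip(sub["start"], sub["end"]))
            cursor = 0
            for s, e in merge_intervals(covered):
                if s > cursor:
                    rows.append((chrom, cursor, s))
                cursor = max(cursor, e)
            if cursor < self.config.genome_length:
                rows.append((chrom, cursor, self.config.genome_length))
        return pd.DataFrame(rows, columns=["chrom", "start", "end"])

    def _flat(self, name: str | None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        df = self._complement if name is None else self.tracks[name]
        return (
            df["chrom"].to_numpy(),
            df["start"].to_numpy(dtype=np.int64),
            df["end"].to_numpy(dtype=np.int64),
        )

    def sample_positions(
        self, name: str | None, n: int, rng: np.random.Generator
    ) -> tuple[np.ndarray, np.ndarray]:
        """Sample 1-based positions uniformly within a track (None = the
        complement of all tracks)."""
        if n == 0:
            return np.array([], dtype=object), np.array([], dtype=np.int64)
        chrom_arr, starts, ends = self._flat(name)
        lengths = ends - starts
        cum = np.concatenate([[0], np.cumsum(lengths)])
        offsets = rng.integers(0, cum[-1], size=n)
        idx = np.searchsorted(cum, offsets, side="right") - 1
        pos = starts[idx] + (offsets - cum[idx]) + 1  # 1-based
        return chrom_arr[idx], pos

    def label_positions(self, chroms: np.ndarray, positions: np.ndarray) -> np.ndarray:
        """First matching track name per position, else 'unique'."""
        from dnmpipe.intervals import positions_in_bed

        labels = np.full(len(positions), "unique", dtype=object)
        for name, df in self.tracks.items():
            unlabeled = labels == "unique"
            if not unlabeled.any():
                break
            hit = positions_in_bed(chroms, positions, df)
            labels[unlabeled & hit] = name
        return labels


# ---------------------------------------------------------------------------
# pedigree


def simulate_pedigree(
    config: SimulationConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Generate a pedigree table of quads and trios with parental ages.

    ``father_age``/``mother_age`` on child rows are ages at that child's
    birth; parent rows carry NaN.
    """
    if config.n_families < 1:
        raise ConfigurationError("n_families must be >= 1")
    n_quads = int(round(config.quad_fraction * config.n_families))
    n_quads = min(n_quads, config.n_families)
    rows = []
    for i in range(config.n_families):
        fam = f"F{i + 1:03d}"
        father = f"{fam}_fa"
        mother = f"{fam}_mo"
        n_children = 2 if i < n_quads else 1
        father_base = _truncated_age(config, rng)
        mother_base = _truncated_age(config, rng)
        rows.append([fam, father, "0", "0", 1, 1, "father", np.nan, np.nan])
        rows.append([fam, mother, "0", "0", 2, 1, "mother", np.nan, np.nan])
        # symmetric birth offsets keep the cohort mean age on target
        offsets = [0.0] if n_children == 1 else [-1.5, 1.5]
        for k in range(n_children):
            child = f"{fam}_c{k + 1}"
            sex = int(rng.integers(1, 3))
            rows.append(
                [
                    fam,
                    child,
                    father,
                    mother,
                    sex,
                    2,
                    "child",
                    father_base + offsets[k],
                    mother_base + offsets[k],
                ]
            )
    return pd.DataFrame(rows, columns=PEDIGREE_COLUMNS)


def _truncated_age(config: SimulationConfig, rng: np.random.Generator) -> float:
    for _ in range(1000):
        age = rng.normal(config.parental_age_mean, config.parental_age_sd)
        if age >= config.parental_age_min:
            return float(age)
    return float(config.parental_age_min)


# ---------------------------------------------------------------------------
# mosaic fraction model


def mosaic_fraction_params(config: SimulationConfig) -> tuple[float, float]:
    """Beta(a, b) parameters for the postzygotic cell fraction.

    The configured ``mosaic_ab_mean`` is a target mean allele balance;
    sampled alt fractions follow AB(f) = a*f / (1 - b*f) where ``delta`` is
    the alt-read loss implied by the constitutional AB mean, so the Beta is
    parameterised on the cell-fraction scale.
    """
    g = config.germline_ab_mean
    delta = (1 - 2 * g) / (1 - g)
    a_lin = 0.5 * (1 - delta)
    b_lin = 0.5 * delta
    m = config.mosaic_ab_mean
    f_mean = m / (a_lin + b_lin * m)
    f_mean = min(max(f_mean, 1e-3), 0.99)
    kappa = config.mosaic_ab_concentration
    return f_mean * kappa, (1 - f_mean) * kappa


def alt_read_dropout(config: SimulationConfig) -> float:
    """Fraction of alt-carrying reads lost, reproducing the sub-0.5 AB mean."""
    g = config.germline_ab_mean
    return (1 - 2 * g) / (1 - g)


# ---------------------------------------------------------------------------
# truth variants


def simulate_truth_variants(
    config: SimulationConfig,
    pedigree: pd.DataFrame,
    rng: np.random.Generator,
    layout: GenomeLayout | None = None,
) -> pd.DataFrame:
    """Draw per-child germline and postzygotic truth variants.

    Germline SNV counts are Poisson per parental haplotype: the paternal
    mean is ``paternal_fraction * base + scaled_slope * (father_age - ref)``
    (analogously maternal), with ``base = rate * 2 * genome`` so the cohort
    mean matches the configured rate at the mean parental ages. Age slopes
    are scaled by genome size relative to ``reference_genome_bp``.
    """
    if layout is None:
        layout = GenomeLayout.build(config)
    total_bp = config.total_genome_bp
    if total_bp == 0:
        return pd.DataFrame(columns=TRUTH_COLUMNS)
    scale = total_bp / config.reference_genome_bp
    ref_age = config.parental_age_mean
    a_beta, b_beta = mosaic_fraction_params(config)

    children = pedigree[pedigree["role"] == "child"]
    rows: list[list] = []
    for child in children.itertuples(index=False):
        lam_pat = (
            config.paternal_fraction * config.germline_rate * 2 * total_bp
            + scale * config.paternal_age_slope * (child.father_age - ref_age)
        )
        lam_mat = (
            (1 - config.paternal_fraction) * config.germline_rate * 2 * total_bp
            + scale * config.maternal_age_slope * (child.mother_age - ref_age)
        )
        if lam_pat < 0 or lam_mat < 0:
            warnings.warn(
                f"negative expected DNM count for {child.individual}; clamped to 0",
                stacklevel=2,
            )
        counts = {
            ("germline", "snv", "paternal"): rng.poisson(max(lam_pat, 0.0)),
            ("germline", "snv", "maternal"): rng.poisson(max(lam_mat, 0.0)),
        }
        lam_pzm = config.pzm_rate * 2 * total_bp
        n_pzm = rng.poisson(lam_pzm)
        n_pzm_pat = rng.binomial(n_pzm, config.pzm_paternal_fraction)
        counts[("postzygotic", "snv", "paternal")] = n_pzm_pat
        counts[("postzygotic", "snv", "maternal")] = n_pzm - n_pzm_pat
        for origin, rate in (
            ("germline", config.germline_indel_rate),
            ("postzygotic", config.pzm_indel_rate),
        ):
            n_ind = rng.poisson(rate * 2 * total_bp)
            n_pat = rng.binomial(
                n_ind,
                config.paternal_fraction
                if origin == "germline"
                else config.pzm_paternal_fraction,
            )
            counts[(origin, "indel", "paternal")] = n_pat
            counts[(origin, "indel", "maternal")] = n_ind - n_pat

        for (origin, kind, parent), n in counts.items():
            if n == 0:
                continue
            track_names = [t.name for t in config.region_tracks]
            weights = np.array(
                [
                    t.genome_fraction
                    * (t.germline_multiplier if origin == "germline" else t.pzm_multiplier)
                    for t in config.region_tracks
                ]
                + [1 - sum(t.genome_fraction for t in config.region_tracks)]
            )
            weights = weights / weights.sum()
            choice = rng.choice(len(weights), size=n, p=weights)
            for c in choice:
                track = track_names[c] if c < len(track_names) else None
                chroms, positions = layout.sample_positions(track, 1, rng)
                chrom, pos = chroms[0], int(positions[0])
                if origin == "postzygotic":
                    frac = float(min(rng.beta(a_beta, b_beta), 0.995))
                else:
                    frac = 1.0
                if kind == "snv":
                    ref, alt, c5, c3 = _draw_substitution(config, origin, rng)
                    var_class = "snv"
                else:
                    ref, alt, var_class = _draw_indel(rng)
                    c5, c3 = rng.choice(BASES), rng.choice(BASES)
                pct_id = np.nan
                if track == "segdup":
                    sd = layout.tracks["segdup"]
                    in_iv = (
                        (sd["chrom"] == chrom)
                        & (sd["start"] < pos)
                        & (pos <= sd["end"])
                    )
                    if in_iv.any():
                        pct_id = float(sd.loc[in_iv, "pct_identity"].iloc[0])
                rows.append(
                    [
                        f"{child.individual}_{chrom}_{pos}",
                        child.family,
                        child.individual,
                        chrom,
                        pos,
                        ref,
                        alt,
                        var_class,
                        origin,
                        parent,
                        frac,
                        track or "unique",
                        pct_id,
                        c5,
                        c3,
                    ]
                )
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    if len(truth):
        truth = truth.drop_duplicates(subset=["child", "chrom", "pos"], keep="first")
        truth = truth.sort_values(["family", "child", "chrom", "pos"]).reset_index(
            drop=True
        )
    return truth


def simulate_germline_counts(
    config: SimulationConfig, pedigree: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Per-child germline SNV counts by parent, without variant placement.

    Uses the same per-haplotype Poisson model as ``simulate_truth_variants``;
    suitable for age-effect and parental-bias analyses at full genome scale.
    """
    total_bp = config.total_genome_bp
    scale = total_bp / config.reference_genome_bp
    ref_age = config.parental_age_mean
    children = pedigree[pedigree["role"] == "child"]
    base = config.germline_rate * 2 * total_bp
    lam_pat = np.maximum(
        config.paternal_fraction * base
        + scale
        * config.paternal_age_slope
        * (children["father_age"].to_numpy() - ref_age),
        0.0,
    )
    lam_mat = np.maximum(
        (1 - config.paternal_fraction) * base
        + scale
        * config.maternal_age_slope
        * (children["mother_age"].to_numpy() - ref_age),
        0.0,
    )
    return pd.DataFrame(
        {
            "family": children["family"].to_numpy(),
            "child": children["individual"].to_numpy(),
            "father_age": children["father_age"].to_numpy(),
            "mother_age": children["mother_age"].to_numpy(),
            "paternal_count": rng.poisson(lam_pat),
            "maternal_count": rng.poisson(lam_mat),
        }
    )


def _draw_substitution(
    config: SimulationConfig, origin: str, rng: np.random.Generator
) -> tuple[str, str, str, str]:
    titv = config.germline_titv if origin == "germline" else config.pzm_titv
    ref = str(rng.choice(BASES))
    if rng.random() < titv / (1 + titv):
        alt = TRANSITION[ref]
    else:
        alt = str(rng.choice(TRANSVERSIONS[ref]))
    c5 = str(rng.choice(BASES))
    c3 = str(rng.choice(BASES))
    if ref == "C" and rng.random() < config.cpg_fraction:
        c3 = "G"
    elif ref == "G" and rng.random() < config.cpg_fraction:
        c5 = "C"
    return ref, alt, c5, c3


def _draw_indel(rng: np.random.Generator) -> tuple[str, str, str]:
    size = int(rng.geometric(0.25))
    seq = "".join(rng.choice(BASES, size=size))
    anchor = str(rng.choice(BASES))
    if rng.random() < 182 / (182 + 351):
        return anchor, anchor + seq, "ins"
    return anchor + seq, anchor, "del"
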