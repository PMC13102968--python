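"""Cohort bundle assembly, artifact injection and on-disk round-tripping."""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from dnmpipe import reads as readsim
from dnmpipe.cohort import (
    GenomeLayout,
    TRUTH_COLUMNS,
    TRANSITION,
    simulate_pedigree,
    simulate_truth_variants,
)
from dnmpipe.config import SimulationConfig


@dataclass
class CohortBundle:
    """All in-memory artifacts of one simulated cohort."""

    config: SimulationConfig
    pedigree: pd.DataFrame
    truth: pd.DataFrame
    genotypes: pd.DataFrame
    reads: pd.DataFrame
    snps: pd.DataFrame
    snp_obs: pd.DataFrame
    panel: pd.DataFrame
    tracks: dict[str, pd.DataFrame] = field(default_factory=dict)

    def check_consistency(self) -> None:
        """Cross-reference invariants between bundle tables."""
        samples = set(self.pedigree["individual"])
        for table, col in (
            (self.genotypes, "sample"),
            (self.reads, "sample"),
        ):
            if len(table) and not set(table[col]).issubset(samples):
                raise ValueError(f"unknown {col} identifiers in bundle table")
        if len(self.snp_obs) and len(self.reads):
            if not set(self.snp_obs["read_id"]).issubset(set(self.reads["read_id"])):
                raise ValueError("snp_obs references unknown read ids")


def simulate_cohort(
    config: SimulationConfig,
    seed: int | None = None,
    members: str = "family",
    with_background: bool = True,
) -> CohortBundle:
    """Run the full generator: pedigree, truth, artifacts, reads, SNPs, panel."""
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    layout = GenomeLayout.build(config)
    pedigree = simulate_pedigree(config, rng)
    truth = simulate_truth_variants(config, pedigree, rng, layout)
    truth = inject_artifact_truth(truth, pedigree, config, rng, layout)
    reads = readsim.simulate_reads(truth, pedigree, config, rng, members=members)
    if with_background and members == "family":
        background = readsim.simulate_background_alt_reads(truth, pedigree, config, rng)
        reads = pd.concat([reads, background], ignore_index=True)
        reads = inject_recurrent_reads(reads, truth, pedigree, config, rng)
    snps = readsim.simulate_informative_snps(truth, config, rng)
    snp_obs = readsim.simulate_snp_observations(reads, snps, config, rng)
    genotypes = readsim.genotypes_from_truth(truth, snps, pedigree, rng)
    panel = readsim.simulate_callable_panel(pedigree, config, rng)
    return CohortBundle(
        config=config,
        pedigree=pedigree,
        truth=truth,
        genotypes=genotypes,
        reads=reads,
        snps=snps,
        snp_obs=snp_obs,
        panel=panel,
        tracks=layout.tracks,
    )


# ---------------------------------------------------------------------------
# artifacts


def inject_artifact_truth(
    truth: pd.DataFrame,
    pedigree: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
    layout: GenomeLayout,
) -> pd.DataFrame:
    """Add dropped-haplotype runs and recurrent-error sites to the truth table.

    Both artifact classes present like constitutional hets in the child's
    reads (a dropped parental haplotype hides the parental support; a
    recurrent error mimics real alt reads) and are flagged in ``origin`` so
    downstream filters can be scored against them.
    """
    rates = config.artifact_rates
    if (
        config.genome_length < 2000
        or (rates.dropped_haplotype_runs == 0 and rates.recurrent_errors == 0)
    ):
        return truth
    children = pedigree[pedigree["role"] == "child"]
    rows: list[list] = []
    for child in children.itertuples(index=False):
        for _ in range(rng.poisson(rates.dropped_haplotype_runs)):
            chrom = str(rng.choice(np.array(config.chromosomes)))
            anchor = int(rng.integers(1, max(config.genome_length - 1000, 2)))
            k = 3 + int(rng.poisson(0.3))
            offsets = np.sort(rng.choice(np.arange(1, 900), size=k, replace=False))
            offsets[0] = 0
            for off in offsets:
                pos = anchor + int(off)
                ref = str(rng.choice(list(TRANSITION)))
                rows.append(
                    _artifact_row(
                        child, chrom, pos, ref, TRANSITION[ref],
                        "artifact_dropped_hap", layout,
                    )
                )
        for _ in range(rng.poisson(rates.recurrent_errors)):
            chrom = str(rng.choice(np.array(config.chromosomes)))
            pos = int(rng.integers(1, config.genome_length + 1))
            ref = str(rng.choice(list(TRANSITION)))
            rows.append(
                _artifact_row(
                    child, chrom, pos, ref, TRANSITION[ref],
                    "artifact_recurrent", layout,
                )
            )
    if not rows:
        return truth
    artifacts = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    combined = pd.concat([truth, artifacts], ignore_index=True)
    combined = combined.drop_duplicates(subset=["child", "chrom", "pos"], keep="first")
    return combined.sort_values(["family", "child", "chrom", "pos"]).reset_index(
        drop=True
    )


def _artifact_row(child, chrom, pos, ref, alt, origin, layout: GenomeLayout) -> list:
    region = layout.label_positions(
        np.array([chrom], dtype=object), np.array([pos], dtype=np.int64)
    )[0]
    return [
        f"{child.individual}_{chrom}_{pos}",
        child.family,
        child.individual,
        chrom,
        pos,
        ref,
        alt,
        "snv",
        origin,
        "paternal",
        1.0,
        region,
        np.nan,
        "A",
        "A",
    ]


def inject_recurrent_reads(
    reads: pd.DataFrame,
    truth: pd.DataFrame,
    pedigree: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Give each recurrent-error site high-quality HiFi alt reads in >=1
    unrelated sample, so the cross-sample recurrence scan can catch it."""
    recurrent = truth[truth["origin"] == "artifact_recurrent"]
    if recurrent.empty:
        return reads
    profile = config.profile("hifi")
    buf = readsim._ReadBuffer()
    buf.counter = 20_000_000
    individuals = pedigree["individual"].to_numpy()
    fam_of = pedigree.set_index("individual")["family"].to_dict()
    for var in recurrent.itertuples(index=False):
        unrelated = [s for s in individuals if fam_of[s] != var.family]
        n_samples = 1 + int(rng.random() < 0.3)
        picks = rng.choice(np.array(unrelated), size=n_samples, replace=False)
        for sample in picks:
            n = 2
            buf.add(
                fam_of[sample],
                sample,
                var.chrom,
                int(var.pos),
                var.var_id,
                profile,
                np.full(n, "alt", dtype=object),
                np.full(n, 30, dtype=np.int64),
                np.full(n, 60, dtype=np.int64),
                *readsim._geometry(profile, n, rng),
                np.full(n, "", dtype=object),
            )
    return pd.concat([reads, buf.frame()], ignore_index=True)


# ---------------------------------------------------------------------------
# on-disk bundle


_PUBLIC_READ_COLUMNS = [c for c in readsim.READ_COLUMNS if not c.startswith("_")]


def write_bundle(bundle: CohortBundle, directory: str | Path) -> dict[str, Path]:
    """Write PED, per-family VCFs, BED tracks and TSV tables.

    VCF positions are 1-based; BED intervals half-open 0-based. The latent
    read haplotype column is withheld.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    ped_path = directory / "cohort.ped"
    bundle.pedigree[
        ["family", "individual", "father", "mother", "sex", "phenotype"]
    ].to_csv(ped_path, sep="\t", header=False, index=False)
    paths["pedigree"] = ped_path
    ages_path = directory / "parental_ages.tsv"
    bundle.pedigree.to_csv(ages_path, sep="\t", index=False)
    paths["ages"] = ages_path

    vcf_dir = directory / "vcf"
    vcf_dir.mkdir(exist_ok=True)
    for fam, grp in bundle.pedigree.groupby("family", sort=True):
        fam_gt = bundle.genotypes[bundle.genotypes["family"] == fam]
        vcf_path = vcf_dir / f"{fam}.vcf"
        _write_family_vcf(vcf_path, fam_gt, list(grp["individual"]), bundle.config)
        paths[f"vcf:{fam}"] = vcf_path

    tracks_dir = directory / "tracks"
    tracks_dir.mkdir(exist_ok=True)
    for name, df in bundle.tracks.items():
        bed_path = tracks_dir / f"{name}.bed"
        df.to_csv(bed_path, sep="\t", header=False, index=False)
        paths[f"track:{name}"] = bed_path

    for name, df in (
        ("reads", bundle.reads[_PUBLIC_READ_COLUMNS] if len(bundle.reads) else
         pd.DataFrame(columns=_PUBLIC_READ_COLUMNS)),
        ("informative_snps", bundle.snps),
        ("snp_observations", bundle.snp_obs),
        ("truth", bundle.truth),
        ("panel", bundle.panel),
    ):
        path = directory / f"{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        paths[name] = path
    return paths


_VCF_HEADER = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype Quality">
"""


def _write_family_vcf(
    path: Path, genotypes: pd.DataFrame, samples: list[str], config: SimulationConfig
) -> None:
    buf = io.StringIO()
    buf.write(_VCF_HEADER)
    for chrom in config.chromosomes:
        buf.write(f"##contig=<ID={chrom},length={config.genome_length}>\n")
    buf.write(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        + "\t".join(samples)
        + "\n"
    )
    if len(genotypes):
        genotypes = genotypes.drop_duplicates(
            subset=["chrom", "pos", "ref", "alt", "sample"], keep="first"
        )
        by_sample = genotypes.set_index(["chrom", "pos", "ref", "alt", "sample"])
        sites = genotypes[["chrom", "pos", "ref", "alt"]].drop_duplicates()
        sites = sites.sort_values(["chrom", "pos"])
        for site in sites.itertuples(index=False):
            fields = [site.chrom, str(site.pos), ".", site.ref, site.alt, ".", "PASS",
                      ".", "GT:GQ"]
            for sample in samples:
                try:
                    row = by_sample.loc[(site.chrom, site.pos, site.ref, site.alt, sample)]
                    fields.append(f"{row['gt']}:{int(row['gq'])}")
                except KeyError:
                    fields.append("./.:0")
            buf.write("\t".join(fields) + "\n")
    path.write_text(buf.getvalue())


def read_bundle(directory: str | Path, config: SimulationConfig | None = None) -> CohortBundle:
    """Load a bundle written by :func:`write_bundle`."""
    directory = Path(directory)
    pedigree = pd.read_csv(directory / "parental_ages.tsv", sep="\t")
    pedigree["father"] = pedigree["father"].astype(str)
    pedigree["mother"] = pedigree["mother"].astype(str)
    truth = pd.read_csv(directory / "truth.tsv", sep="\t")
    reads = pd.read_csv(directory / "reads.tsv", sep="\t")
    if len(reads):
        reads["_hap"] = ""
    else:
        reads = pd.DataFrame(columns=readsim.READ_COLUMNS)
    snps = pd.read_csv(directory / "informative_snps.tsv", sep="\t")
    snp_obs = pd.read_csv(directory / "snp_observations.tsv", sep="\t")
    panel = pd.read_csv(directory / "panel.tsv", sep="\t")
    genotypes = read_vcf_dir(directory / "vcf", pedigree)
    tracks = {}
    for bed in sorted((directory / "tracks").glob("*.bed")):
        cols = ["chrom", "start", "end"]
        if bed.stat().st_size == 0:
            tracks[bed.stem] = pd.DataFrame(columns=cols)
            continue
        df = pd.read_csv(bed, sep="\t", header=None)
        if df.shape[1] > 3:
            extra = "pct_identity" if bed.stem == "segdup" else "base"
            cols = cols + [extra]
        df.columns = cols[: df.shape[1]]
        tracks[bed.stem] = df
    if config is None:
        config = SimulationConfig()
    return CohortBundle(
        config=config,
        pedigree=pedigree,
        truth=truth,
        genotypes=genotypes,
        reads=reads,
        snps=snps,
        snp_obs=snp_obs,
        panel=panel,
        tracks=tracks,
    )


def read_vcf_dir(vcf_dir: str | Path, pedigree: pd.DataFrame) -> pd.DataFrame:
    """Parse per-family VCFs back into the long genotype table via cyvcf2."""
    from cyvcf2 import VCF

    fam_of = pedigree.set_index("individual")["family"].to_dict()
    rows = []
    for vcf_path in sorted(Path(vcf_dir).glob("*.vcf")):
        vcf = VCF(str(vcf_path))
        samples = vcf.samples
        for variant in vcf:
            gts = variant.genotypes  # [[a, b, phased], ...]
            gqs = variant.format("GQ")
            for i, sample in enumerate(samples):
                a, b = gts[i][0], gts[i][1]
                if a < 0 or b < 0:
                    continue
                gt = f"{a}/{b}"
                gq = int(gqs[i][0]) if gqs is not None else 0
                rows.append(
                    [
                        fam_of[sample],
                        variant.CHROM,
                        int(variant.POS),
                        variant.REF,
                        variant.ALT[0] if variant.ALT else ".",
                        sample,
                        gt,
                        gq,
                    ]
                )
        vcf.close()
    df = pd.DataFrame(rows, columns=readsim.GENOTYPE_COLUMNS)
    return df.sort_values(["family", "chrom", "pos", "sample"]).reset_index(drop=True)
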