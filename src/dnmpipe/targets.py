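"""Acceptance-target computations: cohort arithmetic identities and
parameter-recovery runs on synthetic cohorts.

Each ``t*`` function recomputes its quantity from scratch at run time; the
recovery targets simulate cohorts under the default generator configuration
and push them through the real pipeline stages.
"""

from __future__ import annotations

import numpy as np

from dnmpipe import phasing, study
from dnmpipe.bundle import simulate_cohort
from dnmpipe.cohort import simulate_germline_counts, simulate_pedigree
from dnmpipe.config import ArtifactRates, FilterParams, SimulationConfig
from dnmpipe.pipeline import run_pipeline
from dnmpipe.spectra import parental_age_regression


# ---------------------------------------------------------------------------
# cohort arithmetic (t1-t7)


def arithmetic_targets() -> dict[str, dict]:
    n = study.COHORT["n_children"]
    return {
        "t1": {"value": study.mean_snvs_per_child(), "n": n},
        "t2": {"value": study.mean_indels_per_child(), "n": n},
        "t3": {"value": study.mean_pzm_snvs_per_child(), "n": n},
        "t4": {"value": study.pzm_snv_fraction_pct(), "n": n},
        "t5": {"value": study.pzm_indel_fraction_pct(), "n": n},
        "t6": {"value": study.callable_fraction_pct(), "n": n},
        "t7": {"value": study.combined_rate(), "n": n},
    }


# ---------------------------------------------------------------------------
# rate recovery (t8, t9): full pipeline over replicate cohorts


def rate_recovery(
    seed: int, n_cohorts: int = 100, config: SimulationConfig | None = None
) -> dict:
    """Mean germline and postzygotic SNV rates over replicate cohorts run
    end-to-end (simulate -> validate -> phase -> classify -> rates)."""
    config = config or SimulationConfig()
    params = FilterParams()
    germ, pzm = [], []
    for i in range(n_cohorts):
        bundle = simulate_cohort(config, seed=seed + i)
        result = run_pipeline(bundle, params)
        germ.append(result.summary["germline_rate"])
        pzm.append(result.summary["postzygotic_rate"])
    germ_arr, pzm_arr = np.asarray(germ), np.asarray(pzm)
    return {
        "germline_rate_mean": float(germ_arr.mean()),
        "germline_rate_se": float(germ_arr.std(ddof=1) / np.sqrt(n_cohorts)),
        "pzm_rate_mean": float(pzm_arr.mean()),
        "pzm_rate_se": float(pzm_arr.std(ddof=1) / np.sqrt(n_cohorts)),
        "n_cohorts": n_cohorts,
        "n_children_per_cohort": int(
            (config.n_families + round(config.quad_fraction * config.n_families))
        ),
    }


# ---------------------------------------------------------------------------
# phasing ratio recovery (t10)


def phasing_ratio_recovery(
    seed: int, min_dnms: int = 10_000, n_chunks: int = 8
) -> dict:
    """Paternal:maternal ratio of phased germline SNVs from germline-only
    replicate cohorts pushed through the phasing stage.

    The simulation is split into independent chunks to bound memory; counts
    are pooled across chunks.
    """
    base = SimulationConfig()
    # expected total = 73 children * rate * 2L; solve L for >= min_dnms (+10%)
    genome_total = int(np.ceil(1.1 * min_dnms / (73 * base.germline_rate * 2)))
    params = FilterParams()
    n_pat = n_mat = n_total = 0
    for chunk in range(n_chunks):
        config = base.evolve(
            genome_length=genome_total // n_chunks,
            n_chromosomes=1,
            pzm_rate=0.0,
            germline_indel_rate=0.0,
            pzm_indel_rate=0.0,
            artifact_rates=ArtifactRates(0.0, 0.0),
            panel_sites_per_child=10,
        )
        bundle = simulate_cohort(
            config, seed=seed + chunk, members="children", with_background=False
        )
        variants = bundle.truth[["family", "child", "chrom", "pos", "var_class"]]
        phased, _ = phasing.phase_all(
            variants, bundle.reads, bundle.snp_obs, bundle.genotypes,
            bundle.pedigree, params,
        )
        n_pat += int((phased["parent_of_origin"] == "paternal").sum())
        n_mat += int((phased["parent_of_origin"] == "maternal").sum())
        n_total += int(len(phased))
    n = n_pat + n_mat
    p_hat = n_pat / n
    se_p = np.sqrt(p_hat * (1 - p_hat) / n)
    ratio = n_pat / n_mat
    # delta-method SE of the odds p/(1-p)
    se_ratio = se_p / (1 - p_hat) ** 2
    return {
        "ratio": float(ratio),
        "ratio_se": float(se_ratio),
        "n_phased": n,
        "phased_fraction": float(n / n_total) if n_total else float("nan"),
    }


# ---------------------------------------------------------------------------
# postzygotic AB recovery (t11)


def pzm_ab_recovery(seed: int, min_pzms: int = 5000, n_chunks: int = 4) -> dict:
    """Mean pooled allele balance of variants the classifier labels
    postzygotic, from PZM-only cohorts (default mosaic configuration and
    platform depths) run through validation and classification."""
    base = SimulationConfig()
    n_children = 73
    pzm_rate = min_pzms * 1.1 / (n_children * 2 * base.total_genome_bp)
    abs_all = []
    for chunk in range(n_chunks):
        config = base.evolve(
            germline_rate=0.0,
            paternal_age_slope=0.0,
            maternal_age_slope=0.0,
            pzm_rate=pzm_rate / n_chunks,
            germline_indel_rate=0.0,
            pzm_indel_rate=0.0,
            artifact_rates=ArtifactRates(0.0, 0.0),
            panel_sites_per_child=10,
        )
        bundle = simulate_cohort(config, seed=seed + chunk)
        result = run_pipeline(bundle, FilterParams())
        labelled = result.classified[
            (result.classified["origin"] == "postzygotic")
            & (result.classified["var_class"] == "snv")
        ]
        ab = labelled["pooled_ab"].to_numpy(dtype=float)
        abs_all.append(ab[np.isfinite(ab)])
    ab = np.concatenate(abs_all)
    return {
        "mean_ab": float(ab.mean()),
        "se": float(ab.std(ddof=1) / np.sqrt(len(ab))),
        "n": int(len(ab)),
    }


# ---------------------------------------------------------------------------
# paternal age slope recovery (t12)


def age_slope_recovery(seed: int, n_cohorts: int = 100) -> dict:
    """Mean paternal-age regression slope over replicate cohorts simulated
    at full genome scale (truth counts; regression on paternal counts)."""
    config = SimulationConfig(genome_length=1_330_000_000, n_chromosomes=2)
    slopes_p, slopes_m = [], []
    for i in range(n_cohorts):
        rng = np.random.default_rng(seed + 1_000_000 + i)
        pedigree = simulate_pedigree(config, rng)
        counts = simulate_germline_counts(config, pedigree, rng)
        fit = parental_age_regression(counts)
        slopes_p.append(fit.paternal_slope)
        slopes_m.append(fit.maternal_slope)
    arr = np.asarray(slopes_p)
    return {
        "paternal_slope_mean": float(arr.mean()),
        "paternal_slope_se": float(arr.std(ddof=1) / np.sqrt(n_cohorts)),
        "maternal_slope_mean": float(np.mean(slopes_m)),
        "n_cohorts": n_cohorts,
    }


# ---------------------------------------------------------------------------
# assembly


def compute_all_targets(
    seed: int,
    n_rate_cohorts: int = 100,
    n_age_cohorts: int = 100,
    min_phased_dnms: int = 10_000,
    min_pzms: int = 5000,
) -> tuple[dict[str, dict], dict]:
    """All acceptance-target values plus a diagnostics blob."""
    out = arithmetic_targets()
    diag: dict = {}

    rr = rate_recovery(seed, n_cohorts=n_rate_cohorts)
    out["t8"] = {"value": rr["germline_rate_mean"], "n": rr["n_cohorts"]}
    out["t9"] = {"value": rr["pzm_rate_mean"], "n": rr["n_cohorts"]}
    diag["rate_recovery"] = rr

    pr = phasing_ratio_recovery(seed + 777, min_dnms=min_phased_dnms)
    out["t10"] = {"value": pr["ratio"], "n": pr["n_phased"]}
    diag["phasing_ratio"] = pr

    ab = pzm_ab_recovery(seed + 888, min_pzms=min_pzms)
    out["t11"] = {"value": ab["mean_ab"], "n": ab["n"]}
    diag["pzm_ab"] = ab

    sl = age_slope_recovery(seed + 999, n_cohorts=n_age_cohorts)
    out["t12"] = {"value": sl["paternal_slope_mean"], "n": sl["n_cohorts"]}
    diag["age_slope"] = sl
    return out, diag
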