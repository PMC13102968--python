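"""End-to-end orchestration: simulate -> validate -> phase -> classify ->
rates -> spectra, with a machine-readable run manifest."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from dnmpipe import __version__, classify, phasing, rates as rates_mod, spectra, validation
from dnmpipe.bundle import CohortBundle, simulate_cohort, write_bundle
from dnmpipe.config import FilterParams, SimulationConfig


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineResult:
    bundle: CohortBundle
    candidates: pd.DataFrame
    validated: pd.DataFrame
    classified: pd.DataFrame
    callable_table: pd.DataFrame
    summary: dict
    manifest: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# validation stage


def run_validation(
    bundle: CohortBundle,
    params: FilterParams,
    counts: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Apply the full filter cascade; returns candidates with per-filter
    columns and a ``kept`` flag."""
    pedigree = bundle.pedigree
    roles = pedigree.set_index("individual")["role"].to_dict()
    trio = pedigree.set_index("individual")[["father", "mother", "family", "sex"]].to_dict("index")
    candidates = validation.select_candidates(bundle.genotypes, pedigree, params)
    candidates = validation.annotate_candidates(candidates, bundle.tracks)
    candidates = validation.apply_cluster_filter(candidates, params)

    if counts is None:
        counts = validation.build_evidence_counts(bundle.reads, params, roles)
    ev_groups = (
        {k: g for k, g in counts.groupby(["family", "chrom", "pos"], sort=False)}
        if len(counts)
        else {}
    )
    carriers = validation.recurrence_scan(bundle.reads, params)

    # raw reads at candidate sites (indel span filtering needs per-read rows)
    if len(candidates):
        keys = candidates[["family", "chrom", "pos"]].drop_duplicates()
        site_reads = bundle.reads.merge(keys, on=["family", "chrom", "pos"])
        read_groups = {
            k: g for k, g in site_reads.groupby(["family", "chrom", "pos"], sort=False)
        }
    else:
        read_groups = {}

    blood_hifi = set(
        bundle.reads.loc[
            (bundle.reads["platform"] == "hifi") & (bundle.reads["tissue"] == "blood"),
            "sample",
        ].unique()
    )

    siblings: dict[str, str | None] = {}
    for fam, grp in pedigree[pedigree["role"] == "child"].groupby("family"):
        kids = list(grp["individual"])
        for kid in kids:
            others = [k for k in kids if k != kid]
            siblings[kid] = others[0] if others else None

    records = []
    for cand in candidates.itertuples(index=False):
        father = trio[cand.child]["father"]
        mother = trio[cand.child]["mother"]
        key = (cand.family, cand.chrom, int(cand.pos))
        grp = ev_groups.get(key)
        ev = validation.SiteEvidence()
        if grp is not None:
            for row in grp.itertuples(index=False):
                ev.counts[(row.sample, row.platform)] = validation.AlleleCounts(
                    row.high_alt, row.low_alt, row.high_ref, row.low_ref, row.other
                )
        is_sex_chrom = cand.chrom.endswith(("X", "Y"))
        if cand.var_class == "snv":
            if is_sex_chrom:
                combined = validation.validate_sex_chromosome(
                    ev, cand.chrom, trio[cand.child]["sex"], father, mother,
                    cand.child, params,
                )
                verdicts = {}
            else:
                verdicts = {
                    p: validation.validate_snv_platform(
                        ev, p, father, mother, cand.child, params
                    )
                    for p in validation.PLATFORMS
                }
                combined = validation.combine_platform_verdicts(
                    verdicts,
                    params,
                    cellline_only=cand.child not in blood_hifi,
                    illumina_child_hq_alt=ev.get(cand.child, "illumina").high_alt,
                )
            rec_pass = validation.recurrence_filter(
                cand.family, cand.chrom, int(cand.pos), carriers,
                cand.in_tandem_repeat, params,
            )
            ab_pass, ab_reason = validation.ab_filters(
                ev, cand.child, cand.in_tandem_repeat, cand.in_repeatmasker, params
            )
            hp_pass = validation.homopolymer_filter(
                cand.ref, cand.alt, cand.hp_base, cand.hp_length, params
            )
            tr_indel_excluded = False
        else:
            reads_here = read_groups.get(key)
            if cand.in_tandem_repeat:
                combined = validation.FAILED
                tr_indel_excluded = True
            elif reads_here is None:
                combined = validation.FAILED
                tr_indel_excluded = False
            else:
                combined = validation.validate_indel(
                    reads_here, father, mother, cand.child, siblings.get(cand.child),
                    params,
                )
                tr_indel_excluded = False
            verdicts = {}
            rec_pass, ab_pass, ab_reason, hp_pass = True, True, "", True
        records.append(
            {
                "platform_hifi": verdicts.get("hifi", ""),
                "platform_ont": verdicts.get("ont", ""),
                "platform_illumina": verdicts.get("illumina", ""),
                "combined_verdict": combined,
                "recurrence_pass": rec_pass,
                "ab_pass": ab_pass,
                "ab_reason": ab_reason,
                "homopolymer_pass": hp_pass,
                "tr_indel_excluded": tr_indel_excluded,
            }
        )
    res = pd.DataFrame(records)
    out = candidates.reset_index(drop=True)
    if len(res):
        out = pd.concat([out, res], axis=1)
        out["kept"] = (
            ~out["cluster_excluded"]
            & (out["combined_verdict"] == validation.VALIDATED)
            & out["recurrence_pass"]
            & out["ab_pass"]
            & out["homopolymer_pass"]
        )
    else:
        for col in [
            "platform_hifi", "platform_ont", "platform_illumina", "combined_verdict",
            "recurrence_pass", "ab_pass", "ab_reason", "homopolymer_pass",
            "tr_indel_excluded", "kept",
        ]:
            out[col] = pd.Series(dtype=object)
    return out


# ---------------------------------------------------------------------------
# full run


def run_pipeline(
    bundle: CohortBundle, params: FilterParams | None = None
) -> PipelineResult:
    params = params or FilterParams()
    stages: dict[str, float] = {}

    def _timed(stage, fn):
        t0 = time.perf_counter()
        try:
            out = fn()
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise StageError(stage, exc) from exc
        stages[stage] = round(time.perf_counter() - t0, 3)
        return out

    counts = validation.build_evidence_counts(
        bundle.reads, params, bundle.pedigree.set_index("individual")["role"].to_dict()
    )
    candidates = _timed("validate", lambda: run_validation(bundle, params, counts))
    kept = candidates[candidates["kept"] == True].copy()  # noqa: E712

    def _phase():
        return phasing.phase_all(
            kept, bundle.reads, bundle.snp_obs, bundle.genotypes, bundle.pedigree,
            params,
        )

    phased, hap_table = _timed("phase", _phase)
    phased = phased[~phased["phase_exclude"].astype(bool)].reset_index(drop=True)

    classified = _timed(
        "classify", lambda: classify.classify_all(phased, hap_table, counts, params)
    )

    def _rates():
        return rates_mod.callable_from_panel(
            bundle.panel, bundle.config.total_genome_bp, bundle.tracks
        )

    callable_table = _timed("rates", _rates)
    summary = _timed(
        "summarize",
        lambda: summarize(bundle, candidates, classified, callable_table, params),
    )
    return PipelineResult(
        bundle=bundle,
        candidates=candidates,
        validated=kept,
        classified=classified,
        callable_table=callable_table,
        summary=summary,
        manifest={"stage_seconds": stages},
    )


def summarize(
    bundle: CohortBundle,
    candidates: pd.DataFrame,
    classified: pd.DataFrame,
    callable_table: pd.DataFrame,
    params: FilterParams,
) -> dict:
    children = bundle.pedigree[bundle.pedigree["role"] == "child"]
    snvs = classified[classified["var_class"] == "snv"]
    indels = classified[classified["var_class"] != "snv"]
    phased_frac = (
        float(snvs["parent_of_origin"].isin(["paternal", "maternal"]).mean())
        if len(snvs)
        else float("nan")
    )
    per_child_df = children[["individual", "family", "father_age", "mother_age"]].rename(
        columns={"individual": "child"}
    ).reset_index(drop=True)
    if len(classified):
        is_snv = classified["var_class"] == "snv"
        germ = classified["origin"] == "germline"
        pzm = classified["origin"] == "postzygotic"
        tallies = {
            "germline_snvs": germ & is_snv,
            "postzygotic_snvs": pzm & is_snv,
            "germline_indels": germ & ~is_snv,
            "postzygotic_indels": pzm & ~is_snv,
            "paternal_count": (classified["parent_of_origin"] == "paternal") & germ & is_snv,
            "maternal_count": (classified["parent_of_origin"] == "maternal") & germ & is_snv,
        }
        for name, mask in tallies.items():
            counts = classified.loc[mask].groupby("child").size()
            per_child_df[name] = (
                per_child_df["child"].map(counts).fillna(0).astype(int)
            )
    else:
        for name in (
            "germline_snvs", "postzygotic_snvs", "germline_indels",
            "postzygotic_indels", "paternal_count", "maternal_count",
        ):
            per_child_df[name] = 0
    per_child = per_child_df.to_dict(orient="records")

    out: dict = {
        "n_children": int(len(children)),
        "n_candidates": int(len(candidates)),
        "n_validated": int(len(classified)),
        "n_germline_snvs": int((snvs["origin"] == "germline").sum()) if len(snvs) else 0,
        "n_postzygotic_snvs": int((snvs["origin"] == "postzygotic").sum()) if len(snvs) else 0,
        "n_indels": int(len(indels)),
        "phased_fraction_snv": phased_frac,
        "per_child": per_child,
    }

    if len(callable_table):
        germ = rates_mod.cohort_rate(snvs, callable_table, origin="germline")
        pzm = rates_mod.cohort_rate(snvs, callable_table, origin="postzygotic")
        out["germline_rate"] = germ.rate
        out["germline_rate_ci"] = [germ.ci_low, germ.ci_high]
        out["postzygotic_rate"] = pzm.rate
        out["postzygotic_rate_ci"] = [pzm.ci_low, pzm.ci_high]
        out["combined_rate"] = germ.rate + pzm.rate
        parent = rates_mod.parent_specific_rates(
            snvs[snvs["origin"] == "germline"], callable_table
        )
        out["paternal_rate"] = parent["paternal"].rate
        out["maternal_rate"] = parent["maternal"].rate
        out["n_unphased_germline"] = parent["unphased"]

    if len(per_child_df):
        bias = spectra.parental_bias_tests(per_child_df)
        out["paternal_maternal_ratio"] = bias["ratio"]
        out["wilcoxon_p"] = bias["wilcoxon_p"]
        ages_ok = per_child_df["father_age"].nunique() > 1 and len(per_child_df) >= 3
        if ages_ok:
            fit = spectra.parental_age_regression(per_child_df)
            out["paternal_age_slope"] = fit.paternal_slope
            out["maternal_age_slope"] = fit.maternal_slope

    for origin in ("germline", "postzygotic"):
        sub = snvs[snvs["origin"] == origin] if len(snvs) else snvs
        if len(sub) and {"ref", "alt"}.issubset(sub.columns):
            out[f"titv_{origin}"] = spectra.titv(sub)
    if len(snvs):
        clusters, pairs = spectra.find_mnms(snvs)
        out["n_mnm_clusters"] = len(clusters)
        out["n_mnm_pairs"] = int(len(pairs))
    return out


def run_all(
    config: SimulationConfig,
    out_dir: str | Path,
    seed: int | None = None,
    params: FilterParams | None = None,
    write_inputs: bool = False,
) -> PipelineResult:
    """Simulate a cohort, run the pipeline and write all outputs + manifest."""
    params = params or FilterParams()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    bundle = simulate_cohort(config, seed=seed)
    sim_seconds = round(time.perf_counter() - t0, 3)
    if write_inputs:
        write_bundle(bundle, out_dir / "bundle")
    result = run_pipeline(bundle, params)

    outputs = {
        "candidates.tsv": result.candidates,
        "classified.tsv": result.classified,
        "callable.tsv": result.callable_table,
    }
    hashes = {}
    for name, df in outputs.items():
        path = out_dir / name
        df.to_csv(path, sep="\t", index=False)
        hashes[name] = hashlib.sha256(path.read_bytes()).hexdigest()
    summary_path = out_dir / "summary.json"
    summary_path.write_text(json.dumps(result.summary, indent=2, default=_json_default))
    hashes["summary.json"] = hashlib.sha256(summary_path.read_bytes()).hexdigest()

    manifest = {
        "version": __version__,
        "seed": int(config.seed if seed is None else seed),
        "config": config.to_dict(),
        "stage_seconds": {"simulate": sim_seconds, **result.manifest["stage_seconds"]},
        "output_hashes": hashes,
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=_json_default)
    )
    result.manifest = manifest
    return result


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


# ---------------------------------------------------------------------------
# truth comparison


def compare_to_truth(result: PipelineResult, truth: pd.DataFrame | None = None) -> dict:
    """Recovery report against the generator's truth table."""
    if truth is None:
        truth = result.bundle.truth
    if truth is None or len(truth) == 0:
        raise ValueError("truth table missing")
    key = ["child", "chrom", "pos"]
    merged = truth.merge(
        result.classified[key + ["origin", "parent_of_origin"]],
        on=key,
        how="left",
        suffixes=("_true", "_called"),
    )
    real = merged[~merged["origin_true"].str.startswith("artifact")]
    recovered = real["origin_called"].notna()

    report: dict = {"n_truth": int(len(real))}
    for origin in ("germline", "postzygotic"):
        for var_class in ("snv", "ins", "del"):
            sel = (real["origin_true"] == origin) & (real["var_class"] == var_class)
            if sel.sum():
                report[f"sensitivity_{origin}_{var_class}"] = float(
                    recovered[sel].mean()
                )
    artifacts = merged[merged["origin_true"].str.startswith("artifact")]
    report["n_artifacts_injected"] = int(len(artifacts))
    report["n_artifacts_leaked"] = int(artifacts["origin_called"].notna().sum())

    called = real[recovered]
    if len(called):
        confusion = (
            called.groupby(["origin_true", "origin_called"]).size().unstack(fill_value=0)
        )
        report["origin_confusion"] = {
            str(k): {str(kk): int(vv) for kk, vv in v.items()}
            for k, v in confusion.to_dict(orient="index").items()
        }
        phased = called[called["parent_of_origin"].isin(["paternal", "maternal"])]
        if len(phased):
            report["phasing_accuracy"] = float(
                (phased["parent_of_origin"] == phased["parent"]).mean()
            )
            report["phased_fraction"] = float(len(phased) / len(called))
    if "germline_rate" in result.summary:
        gen = result.bundle.config.germline_rate
        report["germline_rate_bias"] = float(
            (result.summary["germline_rate"] - gen) / gen
        )
    return report
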