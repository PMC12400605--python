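"""End-to-end driver chaining all analysis stages for both scan scenarios.

On synthetic input the driver simulates the dataset, writes and reloads it
through the package's own formats, runs the scan for two overlapping
scenarios (A: all populations; B: without the northernmost group), calls
signature regions, compares them across tests and scenarios, runs the LD
analyses and the haplotype-block comparison, and scores everything against
the generator's truth ledger.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import haplotypes as hb
from . import ldnet, signatures
from .config import PipelineConfig
from .io import load_vcf_dosages, read_population_table
from .scan import (
    OmegaModel,
    PopulationAlleleCounts,
    ScanScores,
    bf_scan,
    consolidate_runs,
    estimate_omega,
    pod_threshold,
    population_allele_counts,
    xtx_scan,
)
from .simulate import (
    SimConfig,
    simulate_frequencies,
    simulate_genotypes,
    simulate_haplotype_panel,
    write_dataset,
)

log = logging.getLogger(__name__)


def _scan_covariate_pair(c: np.ndarray) -> dict[str, np.ndarray]:
    """Primary gradient covariate plus an orthogonal quadratic contrast.

    The second covariate plays the role of a second environmental axis with
    no planted effect (curvature of the gradient), standardized divisor-P.
    """
    q = c * c
    q = q - q.mean()
    q = q - (q @ c) / (c @ c) * c  # orthogonalize against the gradient
    q = (q - q.mean()) / q.std()
    return {"pc1": c, "pc2": q}


def scan_scenario(
    counts: PopulationAlleleCounts,
    covariates: dict[str, np.ndarray],
    n_runs: int,
    pod_size: int,
    pod_quantile: float,
    seed: int,
) -> tuple[ScanScores, OmegaModel, float]:
    """Estimate the null model and consolidate replicate scan runs.

    The scan statistics are closed-form and identical across runs; runs
    differ in their POD seeds, and the returned threshold is the mean of
    the per-run POD thresholds.
    """
    model = estimate_omega(counts)
    runs = []
    thresholds = []
    sizes = counts.sample_sizes()
    for r in range(n_runs):
        sc = xtx_scan(counts, model)
        for name, c in covariates.items():
            sc.values[f"bf_{name}_db"] = bf_scan(counts, model, c, name=name).values[name]
        runs.append(sc)
        pod = pod_threshold(
            model, sample_sizes=sizes, n_pod=pod_size, q=pod_quantile,
            seed=seed + 1000 + r, calibrate_xtx=sc.values["xtx"],
        )
        thresholds.append(pod.threshold)
    return consolidate_runs(runs), model, float(np.mean(thresholds))


def _truth_recovery(
    truth: pd.DataFrame, regions: pd.DataFrame, klass: str
) -> dict[str, float]:
    """Fraction of planted loci of a class covered by called regions, and
    the fraction of regions containing a planted locus of any class."""
    planted = truth[truth["class"] == klass]
    covered = 0
    for _, snp in planted.iterrows():
        sel = regions[regions["chrom"] == snp["chrom"]]
        if ((sel["start"] <= snp["pos"]) & (sel["end"] >= snp["pos"])).any():
            covered += 1
    any_planted = truth[truth["class"] != "neutral"]
    hit = 0
    for _, r in regions.iterrows():
        sel = any_planted[any_planted["chrom"] == r["chrom"]]
        if ((sel["pos"] >= r["start"]) & (sel["pos"] <= r["end"])).any():
            hit += 1
    return {
        "recall": covered / max(len(planted), 1),
        "precision": hit / max(len(regions), 1),
        "n_regions": int(len(regions)),
    }


def signal_recovery_experiment(
    seed: int = 0,
    sim: SimConfig | None = None,
    pod_size: int = 100_000,
    bf_threshold_db: float = 10.0,
) -> dict:
    """Planted-signal recovery at the default study conditions.

    Simulates the default synthetic dataset (P=6, J=20,000, 50 inbred
    individuals per population, 1% differentiated loci at lambda=5, 1%
    associated loci), runs the scan, and reports per-SNP detection rates:
    the fraction of differentiated loci above the calibrated POD threshold,
    the fraction of associated loci with BF above the deciban cut, and the
    corresponding neutral-locus exceedance rates.
    """
    cfg = replace(sim if sim is not None else SimConfig(), seed=seed)
    freqs, truth = simulate_frequencies(cfg)
    gt = simulate_genotypes(freqs, cfg)
    from .simulate import population_of_samples

    pac = population_allele_counts(
        gt, population_of_samples(gt), haploid=cfg.selfing_f >= 1.0
    )
    model = estimate_omega(pac)
    xtx = xtx_scan(pac, model).values["xtx"]
    pod = pod_threshold(
        model, pac.sample_sizes(), n_pod=pod_size, seed=seed + 1, calibrate_xtx=xtx
    )
    bf = bf_scan(pac, model, cfg.covariate).values["bf_db"]
    cls = pac.snps.merge(truth, on=["chrom", "pos"])["class"].to_numpy()
    neutral, diff, assoc = (cls == "neutral"), (cls == "differentiated"), (cls == "associated")
    return {
        "n_snps": int(pac.n_snps),
        "pod_threshold": float(pod.threshold),
        "xtx_power": float((xtx[diff] > pod.threshold).mean()),
        "xtx_neutral_exceedance": float((xtx[neutral] > pod.threshold).mean()),
        "bf_power": float((bf[assoc] > bf_threshold_db).mean()),
        "bf_neutral_rate": float((bf[neutral] > bf_threshold_db).mean()),
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage for both scenarios and return the summary bundle."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    sim = replace(config.sim, seed=config.seed)
    truth = None
    if config.vcf is None:
        freqs, truth = simulate_frequencies(sim)
        gt_mem = simulate_genotypes(freqs, sim)
        paths = write_dataset(out / "data", gt_mem, truth=truth)
        gt = load_vcf_dosages(paths["vcf"], maf_floor=0.0)
        pops = read_population_table(paths["populations"])
    else:
        gt = load_vcf_dosages(config.vcf, maf_floor=0.0)
        pops = read_population_table(config.populations)

    het = (gt.dosages == 1).mean()
    log.info("panel heterozygosity (all calls): %.4f", het)

    c = sim.covariate
    covariate_full = _scan_covariate_pair(c)
    pop_names = sorted(pops["population"].unique())

    haploid = config.vcf is None and sim.selfing_f >= 1.0
    counts_all = population_allele_counts(
        gt, pops, maf_floor=config.maf_scan, haploid=haploid
    )

    scenario_pops = {"A": pop_names, "B": pop_names[1:]}
    summary: dict = {"seed": config.seed, "heterozygosity": float(het)}
    per_scenario: dict[str, dict] = {}
    for scen, names in scenario_pops.items():
        counts = counts_all.take_pops(names)
        keep = [pop_names.index(n) for n in names]
        covs = {}
        for cname, vec in covariate_full.items():
            v = vec[keep]
            covs[cname] = (v - v.mean()) / v.std()
        scores, model, threshold = scan_scenario(
            counts, covs, config.n_runs, config.pod_size, config.pod_quantile,
            seed=config.seed,
        )
        table = scores.table()
        table.to_csv(out / f"scan_{scen}.tsv", sep="\t", index=False)
        regions_x = signatures.call_signatures(
            table, "xtx", threshold, config.merge_dist, config.pad,
            gt.chrom_lengths, test="XtX", scenario=scen,
        )
        regions_bf = {
            f"BF_{cname.upper()}": signatures.call_signatures(
                table, f"bf_{cname}_db", config.bf_threshold_db, config.merge_dist,
                config.pad, gt.chrom_lengths, test=f"BF_{cname.upper()}", scenario=scen,
            )
            for cname in covs
        }
        combined = signatures.combine_tests(regions_x, regions_bf)
        all_regions = pd.concat([regions_x, *regions_bf.values()], ignore_index=True)
        all_regions.to_csv(out / f"regions_{scen}.tsv", sep="\t", index=False)
        per_scenario[scen] = {
            "counts": counts,
            "model": model,
            "threshold": threshold,
            "regions_x": regions_x,
            "regions_bf": regions_bf,
        }
        summary[f"scenario_{scen}"] = {
            "n_pops": len(names),
            "n_snps": counts.n_snps,
            "pod_threshold": threshold,
            "n_xtx_regions": int(len(regions_x)),
            **{f"n_{k.lower()}_regions": int(len(v)) for k, v in regions_bf.items()},
            "n_both": int((combined["klass"] == "both").sum()),
        }
        if truth is not None:
            summary[f"scenario_{scen}"]["xtx_truth"] = _truth_recovery(
                truth, regions_x, "differentiated"
            )
            summary[f"scenario_{scen}"]["bf_truth"] = _truth_recovery(
                truth, regions_bf["BF_PC1"], "associated"
            )

    summary["scenario_overlap"] = signatures.overlap_sets(
        per_scenario["A"]["regions_x"], per_scenario["B"]["regions_x"]
    )

    # --- LD analyses (scenario A peaks) ---
    bg = ldnet.background_ld(gt, n_pairs=50_000, maf_floor=config.maf_ld, seed=config.seed)
    summary["background_ld"] = {"mean_r2": bg.mean_r2, "bs_p95": bg.bs_p95}
    peaks_df = pd.concat(
        [per_scenario["A"]["regions_x"], *per_scenario["A"]["regions_bf"].values()],
        ignore_index=True,
    )
    maf = gt.maf()
    peak_idx = []
    for _, r in peaks_df.iterrows():
        hit = np.flatnonzero((gt.chrom == r["chrom"]) & (gt.pos == r["peak_pos"]))
        if len(hit) and maf[hit[0]] >= config.maf_ld:
            peak_idx.append(hit[0])
    peak_idx = np.unique(peak_idx)[:80]
    if len(peak_idx) >= 2:
        ldm = ldnet.pairwise_r2(gt, peak_idx, maf_floor=config.maf_ld)
        net = ldnet.build_ld_network(
            ldm, bg, multiple=config.ld_multiple, min_dist=config.min_cluster_span
        )
        summary["ld_network"] = {
            "n_peaks": int(len(peak_idx)),
            "edge_threshold": net.threshold,
            "n_components": len(net.components),
            "n_reported_clusters": len(net.clusters),
        }
        iu = np.triu_indices(len(peak_idx), k=1)
        rand = ldnet.random_snp_r2_samples(
            gt, n_samples=5, snps_per_sample=500, maf_floor=config.maf_ld,
            seed=config.seed, max_pairs=len(iu[0]),
        )
        t_obs, p = ldnet.permutation_ld_test(
            ldm.r2[iu], np.concatenate(rand), n_perm=min(config.n_perm, 200),
            seed=config.seed,
        )
        summary["ld_peaks_vs_random"] = {"t": t_obs, "p": p}
    decay = ldnet.ld_decay(gt, str(gt.chrom[0]), max_dist=500_000, seed=config.seed)
    decay.to_csv(out / "ld_decay.tsv", sep="\t", index=False)

    # --- haplotype blocks on a simulated region panel ---
    panel = simulate_haplotype_panel(sim, n_snps=120)
    # block calling operates on a signature-sized window (about half a
    # copy-process block length), as it would on a called region
    window = slice(0, 12)
    blocks = hb.blocks_in_region(panel.haplotypes[:, window], region_id="sim_region")
    freq_table = hb.block_frequencies(blocks, panel.populations)
    lats = dict(zip(
        [f"pop{i + 1}" for i in range(sim.n_pops)],
        np.linspace(49.55, 27.70, sim.n_pops),
    ))
    grad = hb.gradient_correlation(freq_table, lats) if len(blocks) else pd.Series(dtype=float)
    freq_table.to_csv(out / "block_frequencies.tsv", sep="\t")
    summary["haplotype_blocks"] = {
        "n_blocks": len(blocks),
        "mean_abs_gradient_r": float(np.nanmean(np.abs(grad))) if len(grad) else float("nan"),
    }

    summary["runtime_s"] = round(time.time() - t0, 2)
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
    return summary
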