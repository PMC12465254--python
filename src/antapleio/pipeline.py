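"""Configured end-to-end runs producing deterministic TSV/JSON outputs.

A run either simulates a panel (``simulate:`` section) or loads one
(``input:`` section with vcf/metadata/phenotypes/climate paths), then
executes the requested stages:

``blue``     per-trait BLUEs, variance components and heritability
``gwas``     mixed-model scans, region calling, favorable alleles, FAF
``scan``     windowed pi / Fst / pi-ratio and sweep candidates
``classify`` pleiotropy classification and class-wise PVE
``haplo``    overlap regions, tagSNP haplotypes, effect tests
``climate``  climate populations and haplotype-climate tests

All numeric output is written with a fixed ``%.6g`` format so identical
configs and seeds give byte-identical files.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from antapleio import (
    allele_effects,
    geo_climate,
    gwas_mlm,
    haplotype_regions,
    io_core,
    pheno_models,
    selection_scan,
    synth,
)

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.6g"
DEFAULT_STAGES = ("blue", "gwas", "scan", "classify")


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=FLOAT_FMT)
    logger.info("wrote %s (%d records)", path, len(df))


def build_simulation_config(section: dict, seed: int) -> synth.SimulationConfig:
    section = dict(section or {})
    plan = section.pop("qtl_plan", None)
    cfg_kwargs = {k: v for k, v in section.items() if k != "qtls"}
    cfg = synth.SimulationConfig(seed=seed, **cfg_kwargs)
    if plan:
        rng = np.random.default_rng(seed + 1)
        cfg = synth.SimulationConfig(
            seed=seed,
            qtls=synth.default_qtl_plan(cfg.n_variants, rng=rng, **plan),
            **cfg_kwargs,
        )
    return cfg


def run_pipeline(config: dict, seed: int | None = None, output_dir=None) -> dict:
    """Execute the configured stages; returns the run summary dict."""
    seed = int(config.get("seed", 0) if seed is None else seed)
    out = Path(output_dir or config.get("output_dir", "antapleio_out"))
    out.mkdir(parents=True, exist_ok=True)
    stages = list(config.get("stages", DEFAULT_STAGES))
    summary: dict = {"seed": seed, "stages": stages}

    # ---- data ----
    if "simulate" in config:
        cfg = build_simulation_config(config["simulate"], seed)
        ds = synth.simulate_dataset(cfg)
        G, pheno, climate = ds.genotypes, ds.phenotypes, ds.climate
        synth.write_dataset(ds, out / "dataset", overwrite=True)
        summary["n_qtls"] = len(cfg.qtls)
    elif "input" in config:
        inp = config["input"]
        G = io_core.read_genotypes(inp["vcf"], inp["metadata"])
        pheno = io_core.read_phenotypes(inp["phenotypes"])
        climate = io_core.read_climate(inp["climate"]) if "climate" in inp else None
    else:
        raise ValueError("config needs a 'simulate' or 'input' section")

    fil = config.get("filter", {})
    G = io_core.filter_variants(
        G,
        maf_min=fil.get("maf_min", 0.05),
        site_missing_max=fil.get("site_missing_max", 0.2),
        sample_missing_max=fil.get("sample_missing_max", 0.1),
    )
    summary["n_samples"] = G.n_samples
    summary["n_variants"] = G.n_variants

    gwas_cfg = config.get("gwas", {})
    traits = list(gwas_cfg.get("traits", ["GP3D", "TKW"]))
    threshold = float(gwas_cfg.get("threshold_log10p", 5.0))

    blues: dict[str, pd.Series] = {}
    if {"blue", "gwas", "classify", "haplo", "climate"} & set(stages):
        vc_summary = {}
        for trait in traits:
            vc = pheno_models.estimate_variance_components(pheno, trait)
            blues[trait] = pheno_models.fit_blue(pheno, trait, vc=vc)
            vc_summary[trait] = {
                "sigma2_g": vc.sigma2_g,
                "sigma2_gl": vc.sigma2_gl,
                "sigma2_gy": vc.sigma2_gy,
                "sigma2_e": vc.sigma2_e,
                "H2": pheno_models.estimate_h2(vc),
            }
        blue_df = pd.DataFrame(blues)
        blue_df.index.name = "accession"
        _write(blue_df.sort_index(), out / "blues.tsv", index=True)
        summary["variance_components"] = vc_summary

    assoc: dict[str, pd.DataFrame] = {}
    regions: dict[str, list] = {}
    if {"gwas", "classify", "haplo"} & set(stages):
        grm = gwas_mlm.compute_grm(G)
        pcs = gwas_mlm.compute_pca(G, k=int(gwas_cfg.get("n_pcs", 1)))
        merge_bp = int(gwas_cfg.get("merge_bp", 1_000_000))
        for trait in traits:
            assoc[trait] = gwas_mlm.mlm_scan(G, blues[trait], grm=grm, pcs=pcs)
            _write(assoc[trait], out / f"assoc_{trait}.tsv")
            regions[trait] = gwas_mlm.call_regions(
                assoc[trait], threshold_log10p=threshold, merge_bp=merge_bp,
                trait=trait,
            )
        reg_df = pd.concat(
            [gwas_mlm.regions_to_frame(regions[t]) for t in traits],
            ignore_index=True,
        )
        _write(reg_df, out / "regions.tsv")
        bed = reg_df.assign(start0=reg_df["start"] - 1)[
            ["chrom", "start0", "end", "trait", "n_snps"]
        ]
        bed.to_csv(out / "regions.bed", sep="\t", index=False, header=False)
        summary["n_regions"] = {t: len(regions[t]) for t in traits}

        fav = allele_effects.assign_favorable_alleles(assoc, threshold_log10p=threshold)
        if len(fav):
            shift = allele_effects.compute_faf_shift(G, fav)
            _write(shift, out / "faf_shift.tsv")
            _write(allele_effects.faf_summary(shift), out / "faf_summary.tsv")
            counts = allele_effects.count_favorable_alleles(G, fav)
            _write(counts, out / "favorable_allele_counts.tsv", index=True)
        summary["n_mta"] = {t: int((assoc[t]["neg_log10_p"] > threshold).sum())
                            for t in traits}

    if "scan" in stages:
        scan_cfg = config.get("scan", {})
        window = int(scan_cfg.get("window_bp", 200_000))
        step = int(scan_cfg.get("step_bp", 100_000))
        ia = G.group_indices(scan_cfg.get("group_a", "landrace"))
        ib = G.group_indices(scan_cfg.get("group_b", "cultivar"))
        pi_a = selection_scan.windowed_pi(G, ia, window, step)
        pi_b = selection_scan.windowed_pi(G, ib, window, step)
        fst_w, fst_gw = selection_scan.windowed_fst(G, ia, ib, window, step)
        ratio = selection_scan.pi_ratio(pi_a, pi_b)
        for name, df in (("pi_a", pi_a), ("pi_b", pi_b), ("fst", fst_w),
                         ("pi_ratio", ratio)):
            _write(df, out / f"windows_{name}.tsv")
        cands = selection_scan.sweep_candidates(
            {"fst": fst_w, "pi_ratio": ratio},
            top_frac=float(scan_cfg.get("top_frac", 0.05)),
        )
        sweep_rows = [
            {"chrom": r.chrom, "start0": r.start - 1, "end": r.end,
             "statistics": ",".join(r.statistics)}
            for r in cands["union"]
        ]
        pd.DataFrame(sweep_rows, columns=["chrom", "start0", "end", "statistics"]) \
            .to_csv(out / "sweeps.bed", sep="\t", index=False, header=False)
        summary["genome_wide_fst"] = round(fst_gw, 6)
        summary["n_sweep_regions"] = len(cands["union"])
        if regions:
            all_regions = [r for t in regions for r in regions[t]]
            _, ov = selection_scan.overlap_with_sweeps(all_regions, cands["union"])
            summary["regions_overlapping_sweeps"] = ov

    if "classify" in stages and len(traits) >= 2:
        cls_cfg = config.get("classify", {})
        gp_trait = next((t for t in traits if t in io_core.DORMANCY_TRAITS), None)
        size_trait = next((t for t in traits if t in io_core.SIZE_TRAITS), None)
        if gp_trait and size_trait:
            mta_gp = assoc[gp_trait].index[
                assoc[gp_trait]["neg_log10_p"] > threshold]
            mta_size = assoc[size_trait].index[
                assoc[size_trait]["neg_log10_p"] > threshold]
            if len(mta_gp) or len(mta_size):
                cl = allele_effects.classify_pleiotropy(
                    G, blues[gp_trait], blues[size_trait], mta_gp, mta_size,
                    alpha=float(cls_cfg.get("alpha", 0.05)),
                )
                _write(cl, out / "classification.tsv")
                cs = allele_effects.classification_summary(
                    G, blues[gp_trait], blues[size_trait], mta_gp, mta_size,
                    alpha=float(cls_cfg.get("alpha", 0.05)),
                )
                _write(cs, out / "class_summary.tsv")
                pve = {}
                for cls_name in allele_effects.CLASSES:
                    snps = cl.loc[cl["snp_class"] == cls_name, "variant"]
                    if len(snps) == 0:
                        continue
                    for trait, blue in ((gp_trait, blues[gp_trait]),
                                        (size_trait, blues[size_trait])):
                        res = allele_effects.pve_of_set(G, snps, blue)
                        pve[f"{cls_name}_{trait}"] = round(res.pve, 6)
                summary["pve_by_class"] = pve
                (out / "pve.json").write_text(
                    json.dumps(pve, indent=2, sort_keys=True) + "\n")

    if "haplo" in stages:
        gp_regs = [r for t in traits if t in io_core.DORMANCY_TRAITS
                   for r in regions.get(t, [])]
        size_regs = [r for t in traits if t in io_core.SIZE_TRAITS
                     for r in regions.get(t, [])]
        overlaps = haplotype_regions.overlap_trait_regions(gp_regs, size_regs)
        summary["n_overlap_regions"] = len(overlaps)
        hap_rows = []
        for ov in overlaps:
            gp_trait = next(t for t in traits if t in io_core.DORMANCY_TRAITS)
            sig = assoc[gp_trait][
                (assoc[gp_trait]["chrom"] == ov.chrom)
                & (assoc[gp_trait]["pos"].between(ov.start, ov.end))
                & (assoc[gp_trait]["neg_log10_p"] > threshold)
            ]
            if sig.empty:
                continue
            tags = haplotype_regions.select_tag_snps(G, sig.index, sig["p"])
            asg = haplotype_regions.call_haplotypes(G, tags, region_id=ov.region_id)
            for acc, lab in asg.labels.items():
                if lab:
                    hap_rows.append({"accession": acc, "region": ov.region_id,
                                     "haplotype": lab})
        if hap_rows:
            _write(pd.DataFrame(hap_rows), out / "haplotypes.tsv")

    if "climate" in stages and climate is not None:
        cl_cfg = config.get("climate", {})
        joined = geo_climate.attach_climate(G.metadata, climate)
        pops, centers = geo_climate.cluster_climate_pops(
            joined, k=int(cl_cfg.get("k", 3)), seed=seed)
        pop_df = pops.to_frame()
        _write(pop_df, out / "climate_pops.tsv", index=True)
        _write(centers, out / "climate_centers.tsv", index=True)
        summary["climate_pops"] = {int(k): int(v)
                                   for k, v in pops.value_counts().items()}

    (out / "run_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, default=str) + "\n"
    )
    logger.info("run complete: %s", out / "run_summary.json")
    return summary
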