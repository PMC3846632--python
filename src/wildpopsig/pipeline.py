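"""End-to-end orchestration: simulate -> normalize -> call -> structure ->
linkage -> enrichment -> phenotype/food-preference, with a summary metrics
file and full config serialization for reproducibility."""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import calling, enrichment, linkage, normalize, phenotype, simulate, structure
from .config import RunConfig

__all__ = ["run_pipeline"]

log = logging.getLogger("wildpopsig.pipeline")


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.time()
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception:
                log.exception("stage %s: failed", name)
                raise RuntimeError(f"pipeline stage {name!r} failed") from None
            log.info("stage %s: done in %.1fs", name, time.time() - t0)
            return out

        return wrapped

    return deco


def run_pipeline(config: RunConfig, write_raw_scans: bool = False) -> dict:
    """Run every stage on freshly simulated data; returns the metrics dict.

    All outputs land under ``config.output_dir``; the config itself is
    serialized there so any run can be reproduced from the directory alone.
    Identical config + seed gives identical outputs.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "run_config.yaml")
    sim = config.sim
    metrics: dict = {"master_seed": config.master_seed}

    # --- simulate -----------------------------------------------------------
    dna_scan, truth, rna_scan, phen, choice, msat = _simulate(sim, outdir, write_raw_scans)

    # --- normalize ----------------------------------------------------------
    dna_norm = _normalize(dna_scan, config, outdir, "dna")
    rna_norm = _normalize(rna_scan, config, outdir, "rna")

    # --- polymorphism calling ----------------------------------------------
    ratio = calling.ratio_to_mean(dna_norm)
    calls = calling.call_polymorphic(
        ratio, config.minor_threshold, config.major_threshold
    )
    spectrum = calling.occurrence_spectrum(calls)
    spectrum.to_csv(outdir / "occurrence_spectrum.tsv", sep="\t")
    calls.per_strain_counts().to_csv(outdir / "per_strain_call_counts.tsv", sep="\t")
    bins = calling.hotspot_bins(
        calls, truth.strains["site"], sim.chromosome_lengths
    )
    bins.to_csv(outdir / "hotspot_bins.tsv", sep="\t", index=False)
    _profile, regions = calling.moving_average_profile(
        dna_norm, window=config.ma_window, ma_threshold=config.ma_threshold
    )
    bed = regions.assign(start=regions["start"] - 1)[  # BED is 0-based half-open
        ["chrom", "start", "end", "array", "sign", "n_probes"]
    ]
    bed.to_csv(outdir / "ma_region_calls.bed", sep="\t", index=False, header=False)
    metrics["n_ma_regions"] = int(len(regions))
    poly_genes = set(calls.polymorphic_genes)
    metrics["n_polymorphic_genes"] = len(poly_genes)
    occupied = spectrum.index.to_numpy()
    metrics["pct_private_1_3"] = float(
        spectrum.loc[spectrum.index.intersection([1, 2, 3]), "percent"].sum()
    ) if len(occupied) else 0.0

    # --- population structure ----------------------------------------------
    if poly_genes:
        dist = structure.distance_matrix(ratio, poly_genes)
        tree = structure.neighbor_joining(dist)
        (outdir / "nj_dna.nwk").write_text(tree.to_newick() + "\n")
        scores, varexp = structure.pca(ratio, poly_genes)
        scores.to_csv(outdir / "pca_scores.tsv", sep="\t")
        metrics["pca_var_explained_pc1_pc2"] = float(varexp[:2].sum())
        for chrom in sim.chromosome_lengths:
            sub = set(ratio.coords.index[(ratio.coords["chrom"] == chrom)]) & poly_genes
            if len(sub) >= 2:
                t = structure.neighbor_joining(structure.distance_matrix(ratio, sub))
                (outdir / f"nj_dna_{chrom}.nwk").write_text(t.to_newick() + "\n")
    else:
        log.warning("no polymorphic genes called; skipping trees and PCA")
    msn = structure.minimum_spanning_network(msat)
    msn.edges.to_csv(outdir / "msn_edges.tsv", sep="\t", index=False)
    msn.nodes.to_csv(outdir / "msn_nodes.tsv", sep="\t")
    metrics["msn_main_weight"] = msn.main_tree_weight()

    # --- linkage ------------------------------------------------------------
    site_labels = truth.strains["site"]
    group_labels = truth.strains["group"]
    site_link = linkage.linkage_screen(
        ratio.values, site_labels,
        n_perm=config.n_permutations, target=config.fdr_target,
        seed=config.master_seed,
    )
    site_link.neglogp.to_csv(outdir / "linkage_site_neglogp.tsv", sep="\t")
    site_linked = set().union(
        *(site_link.linked_genes(lev) for lev in site_link.neglogp.columns)
    )
    metrics["n_site_linked_genes"] = len(site_linked)
    metrics["site_thresholds"] = {k: v for k, v in site_link.thresholds.items()}

    group_sets, overlaps, group_thr = linkage.group_contrasts(
        ratio, group_labels,
        n_perm=config.n_permutations, target=config.fdr_target,
        seed=config.master_seed + 1,
    )
    overlaps.to_csv(outdir / "group_overlaps.tsv", sep="\t")
    metrics["n_group_linked"] = {g: len(s) for g, s in group_sets.items()}
    metrics["group_thresholds"] = group_thr

    decomp = linkage.decompose_expression(
        rna_norm, ratio, group_labels,
        n_perm=min(config.n_permutations, 50), target=config.fdr_target,
        seed=config.master_seed + 2,
    )
    decomp.neglogp.to_csv(outdir / "expression_decomposition_neglogp.tsv", sep="\t")
    att = decomp.attribution
    metrics["expression_attribution_counts"] = {c: int(att[c].sum()) for c in att.columns}
    metrics["n_dna_only_genes"] = len(decomp.dna_only_genes)

    try:
        rna_ratio = structure.expression_tree_input(
            rna_norm, decomp.dna_only_genes, probe_filter=config.minor_threshold
        )
        rna_tree = structure.neighbor_joining(
            structure.distance_matrix(rna_ratio)
        )
        (outdir / "nj_rna.nwk").write_text(rna_tree.to_newick() + "\n")
    except ValueError as exc:  # no probes past the filter on tiny configs
        log.warning("RNA tree skipped: %s", exc)

    # --- enrichment ---------------------------------------------------------
    universe = set(ratio.values.index)
    classes = enrichment.AnnotationSet(
        terms={
            cls: set(truth.genes.index[truth.genes["gene_class"] == cls])
            for cls in truth.genes["gene_class"].unique()
            if cls != "other"
        },
        kind="gene-class",
    )
    class_rec = enrichment.enrich(
        site_linked & universe, classes, universe,
        min_overlap=config.enrichment_min_overlap,
        logp_threshold=config.enrichment_logp_threshold,
    )
    class_df = enrichment.records_to_frame(class_rec)
    class_df.to_csv(outdir / "enrichment_gene_class.tsv", sep="\t", index=False)
    metrics["n_enriched_classes"] = int(class_df["enriched"].sum())

    chrom_df = enrichment.chromosome_enrichment(poly_genes, ratio.coords)
    chrom_df.to_csv(outdir / "enrichment_chromosome.tsv", sep="\t")

    env_sets = simulate.generate_env_study_sets(sim, truth)
    env_rec = enrichment.enrich(
        site_linked & universe,
        enrichment.AnnotationSet(terms=env_sets, kind="env-study"),
        universe,
        min_overlap=config.enrichment_min_overlap,
        logp_threshold=config.enrichment_logp_threshold,
    )
    env_df = enrichment.records_to_frame(env_rec)
    env_df.to_csv(outdir / "enrichment_env_studies.tsv", sep="\t", index=False)
    metrics["n_enriched_env_studies"] = int(env_df["enriched"].sum())

    # --- phenotypes and food preference -------------------------------------
    results = phenotype.trait_tests(phen, site_labels, group_labels)
    pheno_df = pd.DataFrame(
        [(r.trait, r.anova_p, r.welch_p, r.h2, r.group_anova_p) for r in results],
        columns=["trait", "anova_p", "welch_p", "H2", "group_anova_p"],
    )
    pheno_df.to_csv(outdir / "phenotype_tests.tsv", sep="\t", index=False)
    metrics["heritability"] = {r.trait: round(r.h2, 6) for r in results}

    ci = phenotype.choice_summary(choice, site_labels)
    ci.to_csv(outdir / "choice_summary.tsv", sep="\t", index=False)
    metrics["mean_choice_index"] = {
        f"{r.bacterium_a}|{r.bacterium_b}|{r.site}": round(float(r.mean_ci), 6)
        for r in ci.itertuples()
    }

    with open(outdir / "metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True)
    log.info("pipeline complete: %s", outdir)
    return metrics


@_stage("simulate")
def _simulate(sim, outdir, write_raw_scans):
    dna_scan, truth = simulate.generate_genotype_arrays(sim)
    rna_scan = simulate.generate_expression_arrays(sim, truth)
    phen, choice, msat = simulate.generate_organismal_data(sim)
    truth.strains.to_csv(outdir / "strain_metadata.tsv", sep="\t")
    truth.genes.to_csv(outdir / "gene_annotation.tsv", sep="\t")
    phen.to_csv(outdir / "phenotypes.tsv", sep="\t", index=False)
    choice.to_csv(outdir / "food_choice.tsv", sep="\t", index=False)
    msat.to_csv(outdir / "microsatellites.tsv", sep="\t", index=False)
    if write_raw_scans:
        dna_scan.to_long().to_csv(outdir / "dna_scans.tsv", sep="\t", index=False)
        rna_scan.to_long().to_csv(outdir / "rna_scans.tsv", sep="\t", index=False)
    return dna_scan, truth, rna_scan, phen, choice, msat


@_stage("normalize")
def _normalize(scan, config, outdir, branch):
    norm = normalize.normalize_branch(
        scan, span=config.loess_span, iterations=config.loess_iterations,
        floor=config.background_floor,
    )
    norm.values.round(6).to_csv(outdir / f"normalized_{branch}.tsv", sep="\t")
    return norm
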