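"""Synthetic wild-population data with known ground truth.

Generates every input of the pipeline: two-color DNA hybridization scans
(one array per strain, co-hybridized against a common reference), two-color
expression scans (two replicates per strain spread over batches), replicate
phenotype tables, food-choice count tables and multilocus microsatellite
genotypes — together with the planted truth (which gene is polymorphic in
which strain, which genes are linked to isolation site or genetic group,
and which source of variation drives each gene's expression).

The channel model follows two-color array geometry: each channel is a
per-probe lognormal baseline times 2^(planted effect) times lognormal
noise, plus an additive background stored alongside so that background
subtraction can be exact. A smooth intensity-dependent dye bias is added
to the test channel so that LOESS within-array normalization has a real
trend to remove.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import (
    DEFAULT_EXPR_DRIVER_COUNTS,
    DEFAULT_N_SITE_LINKED_MINOR,
    DEFAULT_UNIVERSE_SIZE,
    GROUP_SITE,
    ConfigError,
    SimConfig,
)

__all__ = [
    "ScanSet",
    "SimTruth",
    "generate_genotype_arrays",
    "generate_expression_arrays",
    "generate_organismal_data",
    "write_inputs",
]


@dataclass
class ScanSet:
    """Raw two-color intensities for a set of arrays sharing one probe set.

    ``test`` and ``ref`` are probe x array matrices; ``probes`` carries the
    probe annotation (gene, chromosome, position, additive background) and
    ``arrays`` the array annotation (batch, strain).
    """

    probes: pd.DataFrame      # index probe_id; columns gene_id, chrom, pos, background
    arrays: pd.DataFrame      # index array_id; columns batch, strain
    test: pd.DataFrame        # probe x array
    ref: pd.DataFrame         # probe x array
    branch: str               # "dna" | "rna"

    def __post_init__(self) -> None:
        if (self.test.values < 0).any() or (self.ref.values < 0).any():
            raise ValueError("intensities must be nonnegative")
        if not self.test.columns.equals(self.ref.columns):
            raise ValueError("test and ref must cover the same arrays")
        if not self.test.index.equals(self.ref.index):
            raise ValueError("every array must report the same probe set")

    def to_long(self) -> pd.DataFrame:
        """Long layout: array-id, batch, strain, probe-id, channel-test, channel-ref."""
        long = self.test.stack().rename("channel_test").reset_index()
        long.columns = ["probe_id", "array_id", "channel_test"]
        long["channel_ref"] = self.ref.stack().values
        long["batch"] = self.arrays.loc[long["array_id"], "batch"].values
        long["strain"] = self.arrays.loc[long["array_id"], "strain"].values
        return long[["array_id", "batch", "strain", "probe_id", "channel_test", "channel_ref"]]


@dataclass
class SimTruth:
    """Planted ground truth used by every recovery test."""

    genes: pd.DataFrame            # index gene_id; chrom, start, end, gene_class
    strains: pd.DataFrame          # index strain_id; group, site
    poly_truth: pd.DataFrame       # gene x strain bool: strain carries the polymorphism
    expected_ratio: pd.DataFrame   # gene x strain expected log2 ratio to the strain mean
    raw_shift: pd.DataFrame | None = None  # uncentered per-(gene, strain) channel shift
    site_linked_genes: set[str] = field(default_factory=set)
    group_linked: dict[str, set[str]] = field(default_factory=dict)
    expr_driver: pd.Series | None = None   # gene -> batch|dna|site|group|genotype|none
    dna_only_genes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        gene_ids = set(self.genes.index)
        if not self.site_linked_genes <= gene_ids:
            raise ValueError("site-linked genes must be a subset of the gene universe")
        if self.poly_truth.shape != (len(self.genes), len(self.strains)):
            raise ValueError("poly_truth dimensions must match genes x strains")

    @property
    def polymorphic_genes(self) -> set[str]:
        return set(self.poly_truth.index[self.poly_truth.any(axis=1)])


# ---------------------------------------------------------------------------
# study design: strains, genes, planted polymorphisms
# ---------------------------------------------------------------------------

def _strain_table(config: SimConfig) -> pd.DataFrame:
    rows = []
    for group, count in config.strains_per_group.items():
        for i in range(1, count + 1):
            sid = f"{group}-{i:02d}"
            site = GROUP_SITE[group]
            rows.append((sid, group, site))
    df = pd.DataFrame(rows, columns=["strain_id", "group", "site"]).set_index("strain_id")
    if config.group_crossing_strain and "S3" in config.strains_per_group:
        # one S3-group strain was isolated at the orchard site
        df.loc["S3-01", "site"] = "Orsay"
    return df


def _gene_table(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    chroms = list(config.chromosome_lengths)
    weights = np.array([config.chrom_gene_weights.get(c, 1) for c in chroms], float)
    weights /= weights.sum()
    counts = np.floor(weights * config.n_genes).astype(int)
    for i in np.argsort(-(weights * config.n_genes - counts))[: config.n_genes - counts.sum()]:
        counts[i] += 1
    gene_len = 2_000
    recs = []
    for chrom, n_c in zip(chroms, counts):
        length = config.chromosome_lengths[chrom]
        hi = max(length - gene_len, 1)
        starts = np.sort(rng.integers(1, hi + 1, size=n_c))
        for s in starts:
            recs.append((chrom, int(s), int(s) + gene_len - 1))
    df = pd.DataFrame(recs, columns=["chrom", "start", "end"])
    df.index = pd.Index([f"gene_{i:05d}" for i in range(len(df))], name="gene_id")
    return df


def _assign_classes(genes: pd.DataFrame, config: SimConfig, rng: np.random.Generator) -> pd.Series:
    classes = np.full(len(genes), "other", dtype=object)
    order = rng.permutation(len(genes))
    pos = 0
    for cls, (count, _mult) in config.class_table.items():
        take = min(count, len(genes) - pos)
        classes[order[pos : pos + take]] = cls
        pos += take
    return pd.Series(classes, index=genes.index, name="gene_class")


def _hotspot_weight(genes: pd.DataFrame, config: SimConfig) -> np.ndarray:
    w = np.ones(len(genes))
    for chrom, start, end, rate in config.hotspot_regions:
        mask = (genes["chrom"] == chrom) & (genes["start"] >= start) & (genes["start"] < end)
        w[mask.values] *= rate
    return w


def _plant_design(config: SimConfig) -> SimTruth:
    """Strains, genes, classes and all planted genetic effects."""
    rng = np.random.default_rng(config.child_seed("design"))
    strains = _strain_table(config)
    genes = _gene_table(config, rng)
    genes["gene_class"] = _assign_classes(genes, config, rng)

    n_genes, n_strains = len(genes), len(strains)
    gene_ids = genes.index.to_numpy()
    strain_ids = strains.index.to_numpy()
    class_mult = np.array(
        [config.class_table.get(c, (0, 1.0))[1] if c != "other" else 1.0
         for c in genes["gene_class"]]
    )

    # which genes are polymorphic: hotspot regions carry elevated rate.
    # Independent Bernoulli inclusion keeps the in/out density ratio equal
    # to the configured multiplier (weighted sampling without replacement
    # would saturate the hotspots at this sampling fraction).
    w = _hotspot_weight(genes, config)
    p_incl = np.minimum(config.poly_fraction * n_genes * w / w.sum(), 1.0)
    poly_idx = np.where(rng.random(n_genes) < p_incl)[0]
    n_poly = len(poly_idx)

    carriers = np.zeros((n_genes, n_strains), dtype=bool)
    effect = np.zeros(n_genes)
    effect[poly_idx] = config.deletion_effect

    # split polymorphic genes: group-linked, private (1-3 carriers), multi-strain
    n_grp = int(round(config.group_linked_fraction * n_poly))
    n_priv = int(round(config.private_poly_fraction * n_poly))
    pool = rng.permutation(poly_idx)
    # group-linked genes drawn with gene-class enrichment weight
    if n_grp > 0 and len(pool):
        pw = class_mult[pool].astype(float)
        grp_sel = rng.choice(len(pool), size=n_grp, replace=False, p=pw / pw.sum())
        grp_genes = pool[np.sort(grp_sel)]
    else:
        grp_genes = np.array([], dtype=int)
    rest = np.setdiff1d(pool, grp_genes)
    rest = rng.permutation(rest)
    priv_genes = rest[:n_priv]
    multi_genes = rest[n_priv:]

    group_linked: dict[str, set[str]] = {}
    wild_groups = [g for g in config.strains_per_group if g != "out"]
    grp_assign = rng.integers(0, len(wild_groups), size=len(grp_genes))
    for gi, which in zip(grp_genes, grp_assign):
        grp = wild_groups[which]
        members = (strains["group"] == grp).to_numpy()
        carriers[gi, members] = True
        group_linked.setdefault(grp, set()).add(gene_ids[gi])

    for gi in priv_genes:
        k = rng.integers(1, 4)
        carriers[gi, rng.choice(n_strains, size=k, replace=False)] = True
    lo, hi = config.multi_carrier_range
    for gi in multi_genes:
        k = rng.integers(lo, hi + 1)
        carriers[gi, rng.choice(n_strains, size=k, replace=False)] = True

    # site-linked genes with minor (sub-threshold) hybridization shifts:
    # the whole site carries a shift too small for the ratio call but
    # detectable by the per-gene linear model on site
    nonpoly = np.setdiff1d(np.arange(n_genes), poly_idx)
    # default planted counts are calibrated to the default gene universe and
    # scale with n_genes; explicitly configured counts are taken verbatim
    scale = n_genes / DEFAULT_UNIVERSE_SIZE
    n_minor = config.n_site_linked_minor
    if n_minor is None:
        n_minor = int(round(DEFAULT_N_SITE_LINKED_MINOR * scale))
    n_minor = min(n_minor, len(nonpoly))
    if n_minor > 0:
        pw = class_mult[nonpoly].astype(float)
        minor_sel = rng.choice(len(nonpoly), size=n_minor, replace=False, p=pw / pw.sum())
        minor_genes = nonpoly[np.sort(minor_sel)]
    else:
        minor_genes = np.array([], dtype=int)
    site_of = strains["site"].to_numpy()
    for j, gi in enumerate(minor_genes):
        site = ("Orsay", "Santeuil")[j % 2]
        carriers[gi, site_of == site] = True
        effect[gi] = config.site_minor_effect

    raw = effect[:, None] * carriers
    expected = raw - raw.mean(axis=1, keepdims=True)

    site_linked = set(gene_ids[minor_genes]) | {g for s in group_linked.values() for g in s}

    # expression drivers: DNA-driven genes must be DNA-polymorphic
    driver = pd.Series("none", index=genes.index, name="expr_driver")
    if config.expr_driver_counts is None:
        counts = {k: int(round(v * scale)) for k, v in DEFAULT_EXPR_DRIVER_COUNTS.items()}
    else:
        counts = dict(config.expr_driver_counts)
    poly_pool = rng.permutation(poly_idx)
    n_dna = min(counts.get("dna", 0), len(poly_pool))
    dna_drv = poly_pool[:n_dna]
    driver.iloc[dna_drv] = "dna"
    remaining = rng.permutation(
        np.setdiff1d(np.arange(n_genes), dna_drv)
    )
    pos = 0
    for name in ("site", "group", "batch", "genotype"):
        k = counts.get(name, 0)
        driver.iloc[remaining[pos : pos + k]] = name
        pos += k

    poly_truth = pd.DataFrame(
        np.zeros((n_genes, n_strains), dtype=bool), index=genes.index, columns=strain_ids
    )
    poly_truth.values[poly_idx, :] = carriers[poly_idx, :]

    return SimTruth(
        genes=genes,
        strains=strains,
        poly_truth=poly_truth,
        expected_ratio=pd.DataFrame(expected, index=genes.index, columns=strain_ids),
        raw_shift=pd.DataFrame(raw, index=genes.index, columns=strain_ids),
        site_linked_genes=site_linked,
        group_linked=group_linked,
        expr_driver=driver,
        dna_only_genes=set(gene_ids[dna_drv]),
    )


def _probe_table(truth: SimTruth, config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    genes = truth.genes
    k = config.probes_per_gene
    gidx = np.repeat(np.arange(len(genes)), k)
    starts = genes["start"].to_numpy()[gidx]
    ends = genes["end"].to_numpy()[gidx]
    pos = rng.integers(starts, ends + 1)
    lo, hi = config.background_range
    df = pd.DataFrame(
        {
            "gene_id": genes.index.to_numpy()[gidx],
            "chrom": genes["chrom"].to_numpy()[gidx],
            "pos": pos,
            "background": rng.uniform(lo, hi, size=len(gidx)),
        }
    )
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    df.index = pd.Index([f"probe_{i:06d}" for i in range(len(df))], name="probe_id")
    return df


# ---------------------------------------------------------------------------
# array intensity generation
# ---------------------------------------------------------------------------

def _channel_noise_sd(config: SimConfig) -> float:
    # each channel gets noise_sd / sqrt(2) so the per-probe M-value noise
    # has standard deviation noise_sd
    return config.noise_sd / np.sqrt(2.0)


def generate_genotype_arrays(config: SimConfig) -> tuple[ScanSet, SimTruth]:
    """One two-channel DNA array per strain; carriers shifted by the deletion effect."""
    config.validate()
    truth = _plant_design(config)
    rng = np.random.default_rng(config.child_seed("dna"))
    probes = _probe_table(truth, config, rng)
    strains = truth.strains
    n_probes, n_strains = len(probes), len(strains)

    base = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=n_probes)
    a_std = (base - base.mean()) / max(base.std(), 1e-12)
    dye_bias = config.dye_bias_amplitude * (a_std**2 - 1.0) / 2.0

    gene_pos = truth.genes.index.get_indexer(probes["gene_id"])
    # channel shift is the raw (uncentered) planted effect: carriers move,
    # non-carriers hybridize at baseline
    probe_shift = truth.raw_shift.values[gene_pos, :]

    sd = _channel_noise_sd(config)
    eps_t = rng.normal(0.0, sd, size=(n_probes, n_strains)) if sd > 0 else 0.0
    eps_r = rng.normal(0.0, sd, size=(n_probes, n_strains)) if sd > 0 else 0.0
    bg = probes["background"].to_numpy()[:, None]
    test = 2.0 ** (base[:, None] + dye_bias[:, None] + probe_shift + eps_t) + bg
    ref = np.broadcast_to(2.0 ** (base[:, None] + eps_r) + bg, test.shape).copy()

    array_ids = [f"dna_{s}" for s in strains.index]
    arrays = pd.DataFrame(
        {
            "batch": [i % config.n_batches for i in range(n_strains)],
            "strain": strains.index,
        },
        index=pd.Index(array_ids, name="array_id"),
    )
    scan = ScanSet(
        probes=probes,
        arrays=arrays,
        test=pd.DataFrame(test, index=probes.index, columns=array_ids),
        ref=pd.DataFrame(ref, index=probes.index, columns=array_ids),
        branch="dna",
    )
    return scan, truth


def generate_expression_arrays(config: SimConfig, truth: SimTruth) -> ScanSet:
    """Two replicate expression arrays per strain, spread over batches."""
    if truth is None or truth.expr_driver is None:
        raise ConfigError("expression generation requires the genotype-stage truth")
    rng = np.random.default_rng(config.child_seed("rna"))
    probes = _probe_table(truth, config, np.random.default_rng(config.child_seed("dna")))
    strains = truth.strains
    n_probes = len(probes)
    n_strains = len(strains)
    n_rep = 2

    driver = truth.expr_driver
    dev = np.zeros((len(truth.genes), n_strains))

    site_labels = strains["site"].to_numpy()
    group_labels = strains["group"].to_numpy()
    for kind, labels in (("site", site_labels), ("group", group_labels)):
        sel = np.where(driver.to_numpy() == kind)[0]
        levels = np.unique(labels)
        means = rng.normal(0.0, config.expr_effect_sd, size=(len(sel), len(levels)))
        for j, lev in enumerate(levels):
            dev[np.ix_(sel, np.where(labels == lev)[0])] = means[:, [j]]
    sel = np.where(driver.to_numpy() == "genotype")[0]
    dev[sel, :] = rng.normal(0.0, config.expr_effect_sd, size=(len(sel), n_strains))
    sel = np.where(driver.to_numpy() == "dna")[0]
    dev[sel, :] = config.expr_dna_coefficient * truth.expected_ratio.values[sel, :]

    batch_sel = np.where(driver.to_numpy() == "batch")[0]

    base = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=n_probes)
    gene_pos = truth.genes.index.get_indexer(probes["gene_id"])
    sd = _channel_noise_sd(config)

    cols, batches, strain_col = [], [], []
    test_blocks, ref_blocks = [], []
    for rep in range(n_rep):
        batch = rep % config.n_batches
        batch_dev = np.zeros(len(truth.genes))
        # symmetric batch effect around zero for batch-driven genes
        batch_dev[batch_sel] = config.expr_batch_effect * (batch - (config.n_batches - 1) / 2.0)
        probe_dev = dev[gene_pos, :] + batch_dev[gene_pos, None]
        eps_t = rng.normal(0.0, sd, size=(n_probes, n_strains)) if sd > 0 else 0.0
        eps_r = rng.normal(0.0, sd, size=(n_probes, n_strains)) if sd > 0 else 0.0
        test_blocks.append(2.0 ** (base[:, None] + probe_dev + eps_t))
        ref_blocks.append(
            np.broadcast_to(2.0 ** (base[:, None] + eps_r), (n_probes, n_strains)).copy()
        )
        cols.extend(f"rna_{s}_r{rep + 1}" for s in strains.index)
        batches.extend([batch] * n_strains)
        strain_col.extend(strains.index)

    arrays = pd.DataFrame(
        {"batch": batches, "strain": strain_col},
        index=pd.Index(cols, name="array_id"),
    )
    probes_rna = probes.copy()
    probes_rna["background"] = 0.0  # no background correction on the RNA branch
    return ScanSet(
        probes=probes_rna,
        arrays=arrays,
        test=pd.DataFrame(np.hstack(test_blocks), index=probes.index, columns=cols),
        ref=pd.DataFrame(np.hstack(ref_blocks), index=probes.index, columns=cols),
        branch="rna",
    )


# ---------------------------------------------------------------------------
# organismal data: phenotypes, food choice, microsatellites
# ---------------------------------------------------------------------------

def generate_organismal_data(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Replicate phenotypes, food-choice counts and microsatellite genotypes.

    Phenotype replicate values are drawn around strain means that are
    themselves shifted by isolation site; choice counts are multinomial
    over (A, B, neither); microsatellite alleles follow group-specific
    frequencies at six loci (strains are clonal and homozygous, so one
    allele per locus defines the multilocus genotype).
    """
    config.validate()
    strains = _strain_table(config)

    rng = np.random.default_rng(config.child_seed("phenotype"))
    pheno_rows = []
    for trait, (mu_o, mu_s, mu_out, strain_sd, within_sd, n_rep) in config.phenotype_effects.items():
        site_mean = {"Orsay": mu_o, "Santeuil": mu_s, "out": mu_out}
        for sid, row in strains.iterrows():
            mean = site_mean[row["site"]] + rng.normal(0.0, strain_sd)
            for r in range(1, n_rep + 1):
                pheno_rows.append((sid, trait, r, mean + rng.normal(0.0, within_sd)))
    phenotypes = pd.DataFrame(
        pheno_rows, columns=["strain_id", "trait", "replicate", "value"]
    )

    rng = np.random.default_rng(config.child_seed("choice"))
    choice_rows = []
    for (bact_a, bact_b), prefs in config.choice_preferences.items():
        for sid, row in strains.iterrows():
            p = np.asarray(prefs[row["site"]], float)
            p = p / p.sum()
            for a in range(1, config.choice_assays_per_strain + 1):
                ca, cb, cn = rng.multinomial(config.choice_worms_per_assay, p)
                choice_rows.append((sid, bact_a, bact_b, a, int(ca), int(cb), int(cn)))
    choices = pd.DataFrame(
        choice_rows,
        columns=["strain_id", "bacterium_a", "bacterium_b", "assay", "count_a", "count_b", "count_neither"],
    )

    rng = np.random.default_rng(config.child_seed("msat"))
    n_all = config.msat_alleles_per_locus
    groups = list(config.strains_per_group)
    msat_rows = []
    for sid, row in strains.iterrows():
        g = groups.index(row["group"])
        alleles = []
        for locus in range(config.msat_n_loci):
            modal = (g + locus) % n_all
            p = np.full(n_all, (1.0 - config.msat_modal_freq) / (n_all - 1))
            p[modal] = config.msat_modal_freq
            alleles.append(int(rng.choice(n_all, p=p)))
        msat_rows.append([sid, row["group"], row["site"]] + alleles)
    msats = pd.DataFrame(
        msat_rows,
        columns=["strain_id", "group", "site"] + [f"locus_{i + 1}" for i in range(config.msat_n_loci)],
    )
    return phenotypes, choices, msats


def generate_env_study_sets(
    config: SimConfig,
    truth: SimTruth,
    n_studies: int = 19,
    genes_per_study: int = 300,
    class_fraction: float = 0.6,
) -> dict[str, set[str]]:
    """Synthetic stand-ins for externally supplied environment-study gene sets.

    Each study's differentially expressed genes are drawn with
    ``class_fraction`` of the set from the environment-responsive gene
    classes (chemoreceptors, lectins, F-box, ...) — the same classes that
    carry the planted site-linked polymorphisms — so the overlap analysis
    has a real gene-environment signature to find.
    """
    rng = np.random.default_rng(config.child_seed("design") + 17)
    is_class = (truth.genes["gene_class"] != "other").to_numpy()
    gene_ids = truth.genes.index.to_numpy()
    class_genes = gene_ids[is_class]
    other_genes = gene_ids[~is_class]
    sets = {}
    for i in range(1, n_studies + 1):
        n_cls = min(int(round(class_fraction * genes_per_study)), len(class_genes))
        n_oth = min(genes_per_study - n_cls, len(other_genes))
        pick = np.concatenate(
            [
                rng.choice(class_genes, size=n_cls, replace=False),
                rng.choice(other_genes, size=n_oth, replace=False),
            ]
        )
        sets[f"env_study_{i:02d}"] = set(pick)
    return sets


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_inputs(config: SimConfig, outdir: str | Path, write_scans: bool = True) -> SimTruth:
    """Write every simulated input (and truth sidecars) to ``outdir`` as TSV/BED."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dna, truth = generate_genotype_arrays(config)
    rna = generate_expression_arrays(config, truth)
    phen, choice, msat = generate_organismal_data(config)

    if write_scans:
        dna.to_long().to_csv(outdir / "dna_scans.tsv", sep="\t", index=False)
        rna.to_long().to_csv(outdir / "rna_scans.tsv", sep="\t", index=False)

    genes = truth.genes
    bed = pd.DataFrame(
        {
            "chrom": genes["chrom"],
            "start": genes["start"] - 1,  # BED is 0-based half-open
            "end": genes["end"],
            "name": genes.index,
        }
    )
    bed.to_csv(outdir / "genes.bed", sep="\t", index=False, header=False)
    genes.to_csv(outdir / "gene_annotation.tsv", sep="\t")
    dna.probes.to_csv(outdir / "probes.tsv", sep="\t")
    truth.strains.to_csv(outdir / "strain_metadata.tsv", sep="\t")
    phen.to_csv(outdir / "phenotypes.tsv", sep="\t", index=False)
    choice.to_csv(outdir / "food_choice.tsv", sep="\t", index=False)
    msat.to_csv(outdir / "microsatellites.tsv", sep="\t", index=False)

    truth.poly_truth.astype(int).to_csv(outdir / "truth_polymorphisms.tsv", sep="\t")
    pd.Series(sorted(truth.site_linked_genes), name="gene_id").to_csv(
        outdir / "truth_site_linked.tsv", sep="\t", index=False
    )
    truth.expr_driver.to_csv(outdir / "truth_expr_driver.tsv", sep="\t")
    return truth
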