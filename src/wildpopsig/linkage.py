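"""Per-gene linear-model screens with permutation-calibrated thresholds.

Each gene's hybridization (or expression) values are regressed on a
sample-level factor — isolation site or genetic group — optionally after
batch and a per-gene DNA-hybridization covariate, with F-tests from
sequential (Type I) sums of squares in the order batch -> dna -> factor
-> genotype. Significance thresholds are calibrated by permutation:
sample labels are shuffled jointly across all genes (preserving the
between-gene correlation structure) and the threshold is the smallest
-log10(p) at which the estimated ratio of permuted (false) positives to
observed positives falls below the target (0.05).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .calling import RatioMatrix
from .normalize import NormalizedMatrix

__all__ = [
    "PermutationCalibration",
    "LinkageResult",
    "ExpressionDecomposition",
    "fit_gene_models",
    "calibrate_threshold",
    "linkage_screen",
    "group_contrasts",
    "decompose_expression",
]

NEGLOG10_CAP = 300.0


def _neglog10(p: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        nl = -np.log10(np.maximum(p, 0.0))
    return np.minimum(nl, NEGLOG10_CAP)


def _dummies(labels: np.ndarray) -> np.ndarray:
    """Centered full-rank dummy design for a categorical factor."""
    levels = np.unique(labels)
    d = np.stack([(labels == lev).astype(float) for lev in levels[1:]], axis=1)
    return d - d.mean(axis=0, keepdims=True)


def _orth_basis(x: np.ndarray) -> np.ndarray:
    q, r = np.linalg.qr(x)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    return q[:, keep]


@dataclass
class PermutationCalibration:
    """Permutation-estimated FDR along the observed -log10(p) grid."""

    candidate_thresholds: np.ndarray   # sorted ascending
    est_fdr: np.ndarray                # mean permuted positives / observed positives
    chosen_threshold: float            # smallest candidate with est_fdr < target; inf if none
    target: float
    n_permutations: int
    seed: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"threshold": self.candidate_thresholds, "est_fdr": self.est_fdr}
        )


@dataclass
class LinkageResult:
    """Per-gene -log10(p) per factor-level contrast plus linked flags."""

    neglogp: pd.DataFrame               # gene x level
    thresholds: dict[str, float]
    calibrations: dict[str, PermutationCalibration]

    @property
    def linked(self) -> pd.DataFrame:
        out = {}
        for lev in self.neglogp.columns:
            out[lev] = self.neglogp[lev] >= self.thresholds[lev]
        return pd.DataFrame(out)

    def linked_genes(self, level: str) -> set[str]:
        flags = self.linked[level]
        return set(flags.index[flags])


@dataclass
class ExpressionDecomposition:
    """Per-gene attribution of expression variance to its drivers."""

    pvalues: pd.DataFrame               # gene x term (batch, dna, factor, genotype)
    neglogp: pd.DataFrame
    thresholds: dict[str, float]
    calibrations: dict[str, PermutationCalibration] = field(default_factory=dict)

    @property
    def attribution(self) -> pd.DataFrame:
        out = {}
        for term in self.neglogp.columns:
            out[term] = self.neglogp[term] >= self.thresholds[term]
        return pd.DataFrame(out)

    @property
    def dna_only_genes(self) -> set[str]:
        att = self.attribution
        if "dna" not in att.columns:
            return set()
        only = att["dna"] & ~att.drop(columns="dna").any(axis=1)
        return set(att.index[only])


# ---------------------------------------------------------------------------
# sequential per-gene OLS
# ---------------------------------------------------------------------------

def fit_gene_models(
    values: pd.DataFrame,
    factor: pd.Series,
    batch: pd.Series | None = None,
    dna: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Sequential (Type I) F-tests per gene in the order batch -> dna -> factor.

    ``values`` is gene x sample; ``factor`` and ``batch`` are per-sample
    labels; ``dna`` is an optional gene x sample covariate (the per-gene DNA
    hybridization ratio). Returns a frame with one p column per fitted term.
    Terms without residual degrees of freedom come back as NaN.
    """
    samples = values.columns
    y = values.values.astype(float)
    n = y.shape[1]
    flab = factor.reindex(samples).to_numpy()
    if len(np.unique(flab)) < 2:
        raise ValueError("factor needs at least 2 levels")
    r = y - y.mean(axis=1, keepdims=True)
    df_used = 1  # intercept
    ss = {}
    dfs = {}

    qb = None
    if batch is not None:
        blab = batch.reindex(samples).to_numpy()
        qb = _orth_basis(_dummies(blab))
        c = r @ qb
        ss["batch"] = (c**2).sum(axis=1)
        dfs["batch"] = qb.shape[1]
        r = r - c @ qb.T
        df_used += qb.shape[1]

    d_perp = None
    if dna is not None:
        d = dna.reindex(index=values.index, columns=samples).values.astype(float)
        d = d - d.mean(axis=1, keepdims=True)
        if qb is not None:
            d = d - (d @ qb) @ qb.T
        dd = (d**2).sum(axis=1)
        safe = dd > 1e-12
        coef = np.zeros(len(dd))
        coef[safe] = (r[safe] * d[safe]).sum(axis=1) / dd[safe]
        ss_d = coef**2 * dd
        ss_d[~safe] = np.nan  # no DNA variation for these genes: term skipped
        ss["dna"] = ss_d
        dfs["dna"] = 1
        r = r - coef[:, None] * d
        d_perp = d
        dd_safe = dd
        df_used += 1

    fdes = _dummies(flab)
    if qb is not None:
        fdes = fdes - qb @ (qb.T @ fdes)
    if d_perp is None:
        qf = _orth_basis(fdes)
        c = r @ qf
        ss["factor"] = (c**2).sum(axis=1)
        dfs["factor"] = qf.shape[1]
        r = r - c @ qf.T
        df_used += qf.shape[1]
    else:
        # factor design orthogonalized per gene against its DNA covariate
        proj = np.einsum("gn,nf->gf", d_perp, fdes)
        with np.errstate(invalid="ignore", divide="ignore"):
            proj = proj / np.where(dd_safe > 1e-12, dd_safe, np.nan)[:, None]
        proj = np.nan_to_num(proj)
        fg = fdes[None, :, :] - d_perp[:, :, None] * proj[:, None, :]
        gram = np.einsum("gnf,gne->gfe", fg, fg)
        rhs = np.einsum("gnf,gn->gf", fg, r)
        # guard singular grams (factor collinear with covariate)
        eye = np.eye(gram.shape[1])[None, :, :]
        coef = np.linalg.solve(gram + 1e-12 * eye, rhs[:, :, None])[:, :, 0]
        ss["factor"] = (coef * rhs).sum(axis=1)
        dfs["factor"] = fdes.shape[1]
        r = r - np.einsum("gnf,gf->gn", fg, coef)
        df_used += fdes.shape[1]

    df_resid = n - df_used
    ss_resid = (r**2).sum(axis=1)
    ss_total = ((y - y.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    degenerate = ss_resid <= 1e-12 * np.maximum(ss_total, 1e-300)
    out = {}
    for term, ss_t in ss.items():
        if df_resid <= 0:
            out[f"p_{term}"] = np.full(len(ss_t), np.nan)
            continue
        with np.errstate(invalid="ignore", divide="ignore"):
            f = (ss_t / dfs[term]) / (ss_resid / df_resid)
        p = stats.f.sf(f, dfs[term], df_resid)
        p = np.where(degenerate, np.where(ss_t > 0, 0.0, 1.0), p)
        out[f"p_{term}"] = p
    return pd.DataFrame(out, index=values.index)


def _oneway_f(y: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Vectorized one-way F-test p-values; y is gene x sample."""
    levels, inv = np.unique(labels, return_inverse=True)
    k = len(levels)
    n = y.shape[1]
    grand = y.mean(axis=1, keepdims=True)
    ssb = np.zeros(y.shape[0])
    for j in range(k):
        sel = inv == j
        nj = sel.sum()
        ssb += nj * (y[:, sel].mean(axis=1) - grand[:, 0]) ** 2
    sst = ((y - grand) ** 2).sum(axis=1)
    ssw = np.maximum(sst - ssb, 0.0)
    dfb, dfw = k - 1, n - k
    if dfw <= 0:
        return np.full(y.shape[0], np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = (ssb / dfb) / (ssw / dfw)
    p = stats.f.sf(f, dfb, dfw)
    # residual at floating-point zero: perfect separation, p underflows
    degenerate = ssw <= 1e-12 * np.maximum(sst, 1e-300)
    return np.where(degenerate, np.where(ssb > 0, 0.0, 1.0), p)


# ---------------------------------------------------------------------------
# permutation calibration
# ---------------------------------------------------------------------------

def _estimate_fdr(
    obs_nl: np.ndarray, perm_nl: np.ndarray, n_perm: int
) -> tuple[np.ndarray, np.ndarray]:
    """est_fdr along the observed -log10(p) grid (candidates ascending)."""
    cand = np.unique(obs_nl[np.isfinite(obs_nl)])
    obs_sorted = np.sort(obs_nl)
    perm_sorted = np.sort(perm_nl)
    n_obs = len(obs_nl) - np.searchsorted(obs_sorted, cand, side="left")
    n_perm_pos = (len(perm_nl) - np.searchsorted(perm_sorted, cand, side="left")) / n_perm
    with np.errstate(invalid="ignore", divide="ignore"):
        est = np.where(n_obs > 0, n_perm_pos / n_obs, np.inf)
    return cand, est


def calibrate_threshold(
    values: pd.DataFrame,
    factor: pd.Series,
    n_perm: int = 100,
    target: float = 0.05,
    seed: int = 0,
    observed_neglogp: np.ndarray | None = None,
) -> PermutationCalibration:
    """Permutation-calibrated -log10(p) threshold for the factor screen.

    Sample labels are shuffled jointly across all genes per permutation;
    the threshold is the smallest observed -log10(p) at which
    (mean permuted positives) / (observed positives) < ``target``. If no
    candidate qualifies the threshold is +inf (no genes linked).
    """
    if n_perm < 10:
        raise ValueError("need at least 10 permutations")
    samples = values.columns
    y = values.values.astype(float)
    labels = factor.reindex(samples).to_numpy()
    if observed_neglogp is None:
        observed_neglogp = _neglog10(_oneway_f(y, labels))
    rng = np.random.default_rng(seed)
    perm_nl = np.empty((n_perm, y.shape[0]))
    for b in range(n_perm):
        perm_nl[b] = _neglog10(_oneway_f(y, rng.permutation(labels)))
    cand, est = _estimate_fdr(observed_neglogp, perm_nl.ravel(), n_perm)
    ok = np.where(est < target)[0]
    chosen = float(cand[ok[0]]) if ok.size else float("inf")
    return PermutationCalibration(
        candidate_thresholds=cand,
        est_fdr=est,
        chosen_threshold=chosen,
        target=target,
        n_permutations=n_perm,
        seed=seed,
    )


def linkage_screen(
    values: pd.DataFrame,
    labels: pd.Series,
    levels: list[str] | None = None,
    n_perm: int = 100,
    target: float = 0.05,
    seed: int = 0,
) -> LinkageResult:
    """One-vs-rest linkage screen per factor level with per-level thresholds.

    For each level (by default every level except the out-group), genes are
    tested for a mean difference between that level's samples and all
    others, and a permutation threshold is calibrated for that contrast.
    """
    samples = values.columns
    lab = labels.reindex(samples)
    if levels is None:
        levels = [l for l in pd.unique(lab) if l != "out"]
    neglogp = {}
    thresholds: dict[str, float] = {}
    calibrations: dict[str, PermutationCalibration] = {}
    for i, lev in enumerate(levels):
        contrast = pd.Series(
            np.where(lab.to_numpy() == lev, lev, "rest"), index=samples
        )
        nl = _neglog10(_oneway_f(values.values.astype(float), contrast.to_numpy()))
        cal = calibrate_threshold(
            values, contrast, n_perm=n_perm, target=target,
            seed=seed + 7919 * i, observed_neglogp=nl,
        )
        neglogp[lev] = nl
        thresholds[lev] = cal.chosen_threshold
        calibrations[lev] = cal
    return LinkageResult(
        neglogp=pd.DataFrame(neglogp, index=values.index),
        thresholds=thresholds,
        calibrations=calibrations,
    )


def group_contrasts(
    r: RatioMatrix,
    groups: pd.Series,
    n_perm: int = 100,
    target: float = 0.05,
    seed: int = 0,
    out_label: str = "out",
) -> tuple[dict[str, set[str]], pd.DataFrame, dict[str, float]]:
    """Genes significant per genetic group versus the out-group.

    Each wild group is compared with the out-group strains only (the other
    groups' strains are excluded), at that group's own calibrated
    threshold. Returns the per-group gene sets, a pairwise overlap-count
    table, and the thresholds used.
    """
    lab = groups.reindex(r.values.columns)
    if (lab == out_label).sum() == 0:
        raise ValueError("out-group strains required")
    gene_sets: dict[str, set[str]] = {}
    thresholds: dict[str, float] = {}
    wild = [g for g in pd.unique(lab) if g != out_label]
    for i, grp in enumerate(wild):
        members = lab.index[(lab == grp) | (lab == out_label)]
        if (lab == grp).sum() < 2:
            import warnings

            warnings.warn(f"group {grp!r} has fewer than 2 strains; excluded")
            continue
        sub = r.values[members]
        contrast = lab.loc[members]
        nl = _neglog10(_oneway_f(sub.values.astype(float), contrast.to_numpy()))
        cal = calibrate_threshold(
            sub, contrast, n_perm=n_perm, target=target,
            seed=seed + 104729 * i, observed_neglogp=nl,
        )
        thresholds[grp] = cal.chosen_threshold
        gene_sets[grp] = set(r.values.index[nl >= cal.chosen_threshold])
    names = list(gene_sets)
    overlaps = pd.DataFrame(
        [[len(gene_sets[a] & gene_sets[b]) for b in names] for a in names],
        index=names,
        columns=names,
    )
    return gene_sets, overlaps, thresholds


def fdr_validation_experiment(
    seed: int,
    n_genes: int = 2_000,
    n_samples: int = 41,
    n_effects: int = 200,
    effect: float = 1.0,
    noise_sd: float = 0.25,
    n_perm: int = 100,
    target: float = 0.05,
) -> dict[str, float]:
    """Planted-truth check of the permutation FDR contract.

    Simulates a two-site ratio matrix (site sizes as balanced as
    ``n_samples`` allows) with ``n_effects`` genes carrying a between-site
    mean shift of ``effect``, calibrates the permutation threshold at
    ``target`` and counts false and true positives against the planted
    truth at the chosen threshold.
    """
    rng = np.random.default_rng(seed)
    n_a = n_samples // 2 + n_samples % 2
    labels = pd.Series(
        ["siteA"] * n_a + ["siteB"] * (n_samples - n_a),
        index=[f"s{i}" for i in range(n_samples)],
    )
    y = rng.normal(0.0, noise_sd, size=(n_genes, n_samples))
    y[:n_effects, labels.to_numpy() == "siteA"] += effect
    y -= y.mean(axis=1, keepdims=True)
    values = pd.DataFrame(y, index=[f"g{i}" for i in range(n_genes)], columns=labels.index)
    cal = calibrate_threshold(values, labels, n_perm=n_perm, target=target, seed=seed)
    nl = _neglog10(_oneway_f(values.values, labels.to_numpy()))
    positives = nl >= cal.chosen_threshold
    truth = np.zeros(n_genes, dtype=bool)
    truth[:n_effects] = True
    tp = int((positives & truth).sum())
    fp = int((positives & ~truth).sum())
    return {
        "threshold": cal.chosen_threshold,
        "true_positives": tp,
        "false_positives": fp,
        "fp_over_tp": fp / tp if tp else float("inf") if fp else 0.0,
        "sensitivity": tp / n_effects,
    }


# ---------------------------------------------------------------------------
# expression variance decomposition
# ---------------------------------------------------------------------------

def _decompose_ss(
    y: np.ndarray,
    strain_idx: np.ndarray,
    batch_idx: np.ndarray,
    dna_by_strain: np.ndarray,
    factor_design: np.ndarray,
    n_strains: int,
) -> dict[str, np.ndarray]:
    """Sequential sums of squares batch -> dna -> factor -> genotype.

    Relies on replicates of every strain being balanced across batches, so
    the batch term is orthogonal to all strain-constant terms and the
    strain-constant terms can be fitted in strain-mean space.
    """
    n = y.shape[1]
    yc = y - y.mean(axis=1, keepdims=True)

    n_batches = batch_idx.max() + 1
    ss_batch = np.zeros(y.shape[0])
    for b in range(n_batches):
        sel = batch_idx == b
        ss_batch += sel.sum() * yc[:, sel].mean(axis=1) ** 2

    counts = np.bincount(strain_idx, minlength=n_strains).astype(float)
    sums = np.zeros((y.shape[0], n_strains))
    for s in range(n_strains):
        sums[:, s] = yc[:, strain_idx == s].sum(axis=1)
    means = sums / counts[None, :]
    n_rep = counts[0]
    ss_between = (counts[None, :] * means**2).sum(axis=1)

    mc = means - means.mean(axis=1, keepdims=True)
    d = dna_by_strain - dna_by_strain.mean(axis=1, keepdims=True)
    dd = (d**2).sum(axis=1)
    safe = dd > 1e-12
    coef = np.zeros(len(dd))
    coef[safe] = (mc[safe] * d[safe]).sum(axis=1) / dd[safe]
    ss_dna = n_rep * coef**2 * dd
    mc2 = mc - coef[:, None] * d

    fdes = factor_design - factor_design.mean(axis=0, keepdims=True)
    proj = np.einsum("gs,sf->gf", d, fdes)
    with np.errstate(invalid="ignore", divide="ignore"):
        proj = np.nan_to_num(proj / np.where(safe, dd, np.nan)[:, None])
    fg = fdes[None, :, :] - d[:, :, None] * proj[:, None, :]
    gram = np.einsum("gsf,gse->gfe", fg, fg)
    rhs = np.einsum("gsf,gs->gf", fg, mc2)
    eye = np.eye(fg.shape[2])[None, :, :]
    fcoef = np.linalg.solve(gram + 1e-12 * eye, rhs[:, :, None])[:, :, 0]
    ss_factor = n_rep * (fcoef * rhs).sum(axis=1)

    ss_geno = np.maximum(ss_between - ss_dna - ss_factor, 0.0)
    ss_total = (yc**2).sum(axis=1)
    ss_resid = np.maximum(ss_total - ss_batch - ss_between, 0.0)

    df_factor = factor_design.shape[1]
    dfs = {
        "batch": n_batches - 1,
        "dna": 1,
        "factor": df_factor,
        "genotype": n_strains - 1 - 1 - df_factor,
    }
    df_resid = n - n_strains - (n_batches - 1)
    out = {}
    for term, ss_t in (
        ("batch", ss_batch),
        ("dna", ss_dna),
        ("factor", ss_factor),
        ("genotype", ss_geno),
    ):
        with np.errstate(invalid="ignore", divide="ignore"):
            f = (ss_t / dfs[term]) / (ss_resid / df_resid)
        p = stats.f.sf(f, dfs[term], df_resid)
        p = np.where(ss_resid <= 1e-300, np.where(ss_t > 0, 0.0, 1.0), p)
        if term == "dna":
            p = np.where(safe, p, np.nan)  # genes without DNA variation: flagged
        out[term] = p
    return out


def decompose_expression(
    rna: NormalizedMatrix,
    dna_ratio: RatioMatrix,
    factor: pd.Series,
    n_perm: int = 50,
    target: float = 0.05,
    seed: int = 0,
) -> ExpressionDecomposition:
    """Attribute expression variance to batch, DNA hybridization, site/group
    and genotype, each gated at its permutation-calibrated threshold.

    ``factor`` maps strain -> site or genetic group (selectable by the
    caller). The genotype term is estimable because every strain has
    replicate arrays; permutations shuffle whole arrays over the
    genotype/batch layout, which nullifies every term at once.
    """
    gene_of = rna.probes["gene_id"].reindex(rna.values.index)
    y = rna.values.groupby(gene_of).mean()
    genes = y.index
    strains = pd.unique(rna.arrays["strain"])
    strain_idx = (
        pd.Categorical(rna.arrays["strain"].reindex(y.columns), categories=strains).codes
    )
    batch_idx = rna.arrays["batch"].reindex(y.columns).to_numpy()
    dna = dna_ratio.values.reindex(index=genes, columns=strains)
    missing_dna = dna.isna().all(axis=1)
    dna = dna.fillna(0.0)
    flab = factor.reindex(pd.Index(strains)).to_numpy()
    fdes = _dummies(flab)

    def run(yv: np.ndarray) -> dict[str, np.ndarray]:
        return _decompose_ss(
            yv, strain_idx, batch_idx, dna.values, fdes, n_strains=len(strains)
        )

    obs = run(y.values.astype(float))
    obs_nl = {t: _neglog10(np.nan_to_num(p, nan=1.0)) for t, p in obs.items()}

    rng = np.random.default_rng(seed)
    perm_nl = {t: [] for t in obs}
    yv = y.values.astype(float)
    for _ in range(n_perm):
        perm = rng.permutation(yv.shape[1])
        res = run(yv[:, perm])
        for t, p in res.items():
            perm_nl[t].append(_neglog10(np.nan_to_num(p, nan=1.0)))

    thresholds: dict[str, float] = {}
    calibrations: dict[str, PermutationCalibration] = {}
    for t in obs:
        cand, est = _estimate_fdr(obs_nl[t], np.concatenate(perm_nl[t]), n_perm)
        ok = np.where(est < target)[0]
        chosen = float(cand[ok[0]]) if ok.size else float("inf")
        thresholds[t] = chosen
        calibrations[t] = PermutationCalibration(
            candidate_thresholds=cand,
            est_fdr=est,
            chosen_threshold=chosen,
            target=target,
            n_permutations=n_perm,
            seed=seed,
        )

    pmat = pd.DataFrame(obs, index=genes)
    pmat.loc[missing_dna, "dna"] = np.nan
    nlmat = pd.DataFrame(obs_nl, index=genes)
    nlmat.loc[missing_dna, "dna"] = 0.0
    return ExpressionDecomposition(
        pvalues=pmat,
        neglogp=nlmat,
        thresholds=thresholds,
        calibrations=calibrations,
    )
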