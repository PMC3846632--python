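"""Statistics for fitness and behavioral traits.

Per trait: a one-way ANOVA on strain (does genotype explain the
replicate-to-replicate variation), a two-sided unequal-variance (Welch)
t-test between isolation sites computed on strain means, broad-sense
heritability H2 from the one-way variance components, and Choice Index
summaries for the food-preference assays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TraitTestResult",
    "anova_strain",
    "welch_site_test",
    "heritability",
    "choice_index",
    "choice_summary",
    "trait_tests",
]


@dataclass
class TraitTestResult:
    trait: str
    anova_p: float          # strain effect on replicate values
    welch_p: float          # Orsay vs Santeuil, strain means
    h2: float               # broad-sense heritability, clamped to [0, 1]
    group_anova_p: float    # genetic-group effect on strain means


def _trait_values(table: pd.DataFrame, trait: str) -> pd.DataFrame:
    sub = table[table["trait"] == trait]
    if sub.empty:
        raise ValueError(f"no measurements for trait {trait!r}")
    return sub


def anova_strain(table: pd.DataFrame, trait: str) -> float:
    """One-way F-test p-value for the strain factor on replicate values."""
    sub = _trait_values(table, trait)
    groups = [g["value"].to_numpy() for _, g in sub.groupby("strain_id")]
    if len(groups) < 2:
        raise ValueError("need at least 2 strains")
    values = np.concatenate(groups)
    if np.allclose(values, values[0]):
        return 1.0
    stat = stats.f_oneway(*groups)
    return float(stat.pvalue)


def welch_site_test(
    table: pd.DataFrame, trait: str, site_labels: pd.Series,
    sites: tuple[str, str] = ("Orsay", "Santeuil"),
) -> float:
    """Two-sided Welch t-test between sites, with strain means as the unit
    of analysis (replicates within a strain are pseudo-replicates)."""
    sub = _trait_values(table, trait)
    strain_means = sub.groupby("strain_id")["value"].mean()
    site = site_labels.reindex(strain_means.index)
    a = strain_means[site == sites[0]].to_numpy()
    b = strain_means[site == sites[1]].to_numpy()
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each site needs at least 2 strains")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.pvalue)


def heritability(table: pd.DataFrame, trait: str) -> float:
    """Broad-sense H2 = Vg / (Vg + Ve) from one-way variance components.

    Vg = (MSB - MSW) / n0 with n0 the effective replicate count for
    unbalanced designs, Ve = MSW; the estimate is clamped to [0, 1].
    Among clonal homozygous lines the between-strain variance is entirely
    genetic, so this is the broad-sense heritability.
    """
    sub = _trait_values(table, trait)
    groups = [g["value"].to_numpy() for _, g in sub.groupby("strain_id")]
    a = len(groups)
    if a < 2:
        raise ValueError("need at least 2 strains")
    ns = np.array([len(g) for g in groups], dtype=float)
    if (ns <= 1).all():
        raise ValueError("no replication anywhere: H2 undefined")
    n_total = ns.sum()
    means = np.array([g.mean() for g in groups])
    grand = np.concatenate(groups).mean()
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    msb = ssb / (a - 1)
    dfw = n_total - a
    msw = ssw / dfw if dfw > 0 else 0.0
    n0 = (n_total - (ns**2).sum() / n_total) / (a - 1)
    vg = max((msb - msw) / n0, 0.0)
    ve = msw
    if vg + ve == 0:
        return 1.0 if np.ptp(means) > 0 else 0.0
    return float(np.clip(vg / (vg + ve), 0.0, 1.0))


def _group_anova(table: pd.DataFrame, trait: str, group_labels: pd.Series) -> float:
    sub = _trait_values(table, trait)
    strain_means = sub.groupby("strain_id")["value"].mean()
    grp = group_labels.reindex(strain_means.index)
    groups = [strain_means[grp == g].to_numpy() for g in grp.unique() if (grp == g).sum() >= 2]
    if len(groups) < 2:
        return float("nan")
    return float(stats.f_oneway(*groups).pvalue)


def trait_tests(
    table: pd.DataFrame,
    site_labels: pd.Series,
    group_labels: pd.Series,
) -> list[TraitTestResult]:
    """All four statistics for every trait in the table."""
    out = []
    for trait in table["trait"].unique():
        out.append(
            TraitTestResult(
                trait=trait,
                anova_p=anova_strain(table, trait),
                welch_p=welch_site_test(table, trait, site_labels),
                h2=heritability(table, trait),
                group_anova_p=_group_anova(table, trait, group_labels),
            )
        )
    return out


def choice_index(count_a: int, count_b: int, count_neither: int) -> float:
    """CI = (A - B) / (A + B + neither); +1 all on A, -1 all on B.

    Non-choosers stay in the denominator, so the three preference
    fractions of an assay are CI-consistent.
    """
    total = count_a + count_b + count_neither
    if total <= 0:
        raise ValueError("Choice Index undefined for zero worms")
    return (count_a - count_b) / total


def choice_summary(choices: pd.DataFrame, site_labels: pd.Series) -> pd.DataFrame:
    """Per (bacterial pair, site): mean CI over strains and preference
    percentages (A%, B%, neither%, summing to 100)."""
    df = choices.copy()
    df["site"] = site_labels.reindex(df["strain_id"]).to_numpy()
    totals = df[["count_a", "count_b", "count_neither"]].sum(axis=1)
    if (totals <= 0).any():
        raise ValueError("assay with zero worms")
    df["ci"] = (df["count_a"] - df["count_b"]) / totals
    per_strain = (
        df.groupby(["bacterium_a", "bacterium_b", "site", "strain_id"])
        .agg(ci=("ci", "mean"), a=("count_a", "sum"), b=("count_b", "sum"),
             neither=("count_neither", "sum"))
        .reset_index()
    )
    rows = []
    for (ba, bb, site), sub in per_strain.groupby(["bacterium_a", "bacterium_b", "site"]):
        tot = sub[["a", "b", "neither"]].to_numpy().sum()
        rows.append(
            {
                "bacterium_a": ba,
                "bacterium_b": bb,
                "site": site,
                "mean_ci": sub["ci"].mean(),
                "pct_a": 100.0 * sub["a"].sum() / tot,
                "pct_b": 100.0 * sub["b"].sum() / tot,
                "pct_neither": 100.0 * sub["neither"].sum() / tot,
            }
        )
    return pd.DataFrame(rows)
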