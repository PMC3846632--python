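"""Per-gene, per-strain polymorphism calls from normalized DNA hybridizations.

A gene's hybridization "ratio" for a strain is its log2 deviation from the
across-strain mean; strains whose ratio exceeds +-0.5 are called
polymorphic for that gene (minor tier), strains beyond +-1 are the major
tier. The module also builds occurrence spectra, nine-probe moving-average
profiles with region calls, and 100-kb hotspot maps.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .normalize import NormalizedMatrix

__all__ = [
    "RatioMatrix",
    "PolymorphismCallSet",
    "ratio_to_mean",
    "call_polymorphic",
    "occurrence_spectrum",
    "moving_average_profile",
    "hotspot_bins",
]

log = logging.getLogger(__name__)

CALL_NONE = "none"


@dataclass
class RatioMatrix:
    """Gene x strain log2 ratios to the across-strain mean (rows sum to 0)."""

    values: pd.DataFrame          # gene x strain
    coords: pd.DataFrame          # index gene_id; chrom, start, end (1-based inclusive)

    def __post_init__(self) -> None:
        rowsums = self.values.values.sum(axis=1)
        if len(rowsums) and np.abs(rowsums).max() > 1e-6 * max(1, self.values.shape[1]):
            raise ValueError("RatioMatrix rows must sum to zero")

    @property
    def strains(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class PolymorphismCallSet:
    """Signed two-tier calls per (gene, strain) plus the thresholds used."""

    ratios: pd.DataFrame          # gene x strain
    calls: pd.DataFrame           # gene x strain, values in {none, minor+, minor-, major+, major-}
    coords: pd.DataFrame
    minor_threshold: float = 0.5
    major_threshold: float = 1.0

    @property
    def any_call(self) -> pd.Series:
        """Per gene: True when any strain has a call (the gene is polymorphic)."""
        return (self.calls != CALL_NONE).any(axis=1)

    @property
    def polymorphic_genes(self) -> pd.Index:
        return self.calls.index[self.any_call]

    def per_strain_counts(self) -> pd.DataFrame:
        """Signed per-strain counts per tier (the per-strain bar heights)."""
        rows = {}
        c = self.calls
        for tier in ("minor", "major"):
            for sign in ("+", "-"):
                rows[f"{tier}{sign}"] = (c == f"{tier}{sign}").sum(axis=0)
        return pd.DataFrame(rows)


def ratio_to_mean(m: NormalizedMatrix, probe_to_gene: pd.Series | None = None) -> RatioMatrix:
    """Aggregate probes to genes (unweighted mean) and center each gene row.

    ``probe_to_gene`` defaults to the probe annotation carried by the
    normalized matrix. Strains with several arrays (expression replicates)
    must be averaged upstream; here columns are taken as strains.
    """
    if m.values.shape[1] < 2:
        raise ValueError("ratio to the across-strain mean needs at least 2 strains")
    if probe_to_gene is None:
        probe_to_gene = m.probes["gene_id"]
    gene_vals = m.values.groupby(probe_to_gene.reindex(m.values.index)).mean()
    missing = set()
    if "gene_id" in m.probes:
        missing = set(m.probes["gene_id"].unique()) - set(gene_vals.index)
    if missing:
        log.warning("%d genes had no probes and were excluded", len(missing))
    centered = gene_vals.sub(gene_vals.mean(axis=1), axis=0)
    coords = pd.DataFrame(index=centered.index)
    if {"gene_id", "chrom"} <= set(m.probes.columns):
        per_gene = m.probes.groupby("gene_id").agg(
            chrom=("chrom", "first"), start=("pos", "min"), end=("pos", "max")
        )
        coords = per_gene.reindex(centered.index)
    # map strains onto columns when arrays are one-per-strain
    strain_of = m.arrays["strain"]
    if strain_of.reindex(centered.columns).notna().all() and strain_of.is_unique:
        centered.columns = strain_of.reindex(centered.columns).values
    return RatioMatrix(values=centered, coords=coords)


def call_polymorphic(
    r: RatioMatrix, minor_threshold: float = 0.5, major_threshold: float = 1.0
) -> PolymorphismCallSet:
    """Strict-threshold calls: |ratio| > minor is a call, |ratio| > major is major."""
    if not 0 < minor_threshold <= major_threshold:
        raise ValueError("thresholds must satisfy 0 < minor <= major")
    v = r.values.values
    calls = np.full(v.shape, CALL_NONE, dtype=object)
    calls[v > minor_threshold] = "minor+"
    calls[v < -minor_threshold] = "minor-"
    calls[v > major_threshold] = "major+"
    calls[v < -major_threshold] = "major-"
    return PolymorphismCallSet(
        ratios=r.values,
        calls=pd.DataFrame(calls, index=r.values.index, columns=r.values.columns),
        coords=r.coords,
        minor_threshold=minor_threshold,
        major_threshold=major_threshold,
    )


def occurrence_spectrum(c: PolymorphismCallSet) -> pd.DataFrame:
    """How many strains each polymorphic gene is called in.

    Returns a frame indexed by the number of carrier strains with columns
    ``n_genes`` and ``percent`` (of all polymorphic genes; sums to 100).
    """
    n_called = (c.calls != CALL_NONE).sum(axis=1)
    n_called = n_called[n_called > 0]
    if n_called.empty:
        return pd.DataFrame(columns=["n_genes", "percent"]).rename_axis("n_strains")
    counts = n_called.value_counts().sort_index()
    return pd.DataFrame(
        {"n_genes": counts, "percent": 100.0 * counts / counts.sum()}
    ).rename_axis("n_strains")


def moving_average_profile(
    m: NormalizedMatrix,
    window: int = 9,
    ma_threshold: float = 0.25,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Centered probe-level moving average per strain along each chromosome.

    Windows are trimmed at chromosome ends (the average uses however many
    of the ``window`` probes fall inside the chromosome). Contiguous runs
    of the profile beyond +-``ma_threshold`` are emitted as region calls
    (chrom, start, end, array, sign, n_probes).
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    probes = m.probes.sort_values(["chrom", "pos"], kind="mergesort")
    vals = m.values.reindex(probes.index)
    prof = np.empty_like(vals.values)
    regions = []
    for chrom, idx in probes.groupby("chrom", sort=False).groups.items():
        pos = probes.index.get_indexer(idx)
        block = vals.values[pos, :]
        if len(pos) < window:
            warnings.warn(f"chromosome {chrom!r} has fewer probes than the window")
        sm = (
            pd.DataFrame(block)
            .rolling(window, center=True, min_periods=1)
            .mean()
            .values
        )
        prof[pos, :] = sm
        coords = probes.loc[idx, "pos"].to_numpy()
        for j, arr in enumerate(vals.columns):
            over = np.where(sm[:, j] > ma_threshold, 1, 0) - np.where(
                sm[:, j] < -ma_threshold, 1, 0
            )
            k = 0
            while k < len(over):
                if over[k] == 0:
                    k += 1
                    continue
                sgn = over[k]
                j2 = k
                while j2 + 1 < len(over) and over[j2 + 1] == sgn:
                    j2 += 1
                regions.append(
                    (chrom, int(coords[k]), int(coords[j2]), arr, "+" if sgn > 0 else "-", j2 - k + 1)
                )
                k = j2 + 1
    profile = pd.DataFrame(prof, index=probes.index, columns=vals.columns)
    region_df = pd.DataFrame(
        regions, columns=["chrom", "start", "end", "array", "sign", "n_probes"]
    )
    return profile, region_df


def hotspot_bins(
    c: PolymorphismCallSet,
    strain_groups: pd.Series,
    chromosome_lengths: dict[str, int],
    bin_size: int = 100_000,
) -> pd.DataFrame:
    """Polymorphic-gene counts per 100-kb bin, total and per strain group.

    A gene belongs to the bin containing its start. The total column counts
    genes with any call; per-group columns count genes whose ratio falls
    below minus the minor threshold in at least one member of the group
    (loss-of-hybridization signal).
    """
    coords = c.coords
    if coords[["chrom", "start"]].isna().any().any():
        raise ValueError("gene coordinates required for hotspot binning")
    for chrom, length in chromosome_lengths.items():
        over = coords[(coords["chrom"] == chrom) & (coords["start"] > length)]
        if len(over):
            raise ValueError(f"gene(s) beyond the length of chromosome {chrom}")
    rows = []
    called = c.any_call
    neg = c.ratios < -c.minor_threshold
    groups = strain_groups.reindex(c.ratios.columns)
    bin_of = (coords["start"] // bin_size).astype(int)
    for chrom, length in chromosome_lengths.items():
        n_bins = int(np.ceil(length / bin_size))
        on_chrom = coords["chrom"] == chrom
        for b in range(n_bins):
            sel = on_chrom & (bin_of == b)
            row = {
                "chrom": chrom,
                "bin_start": b * bin_size,
                "bin_end": min((b + 1) * bin_size, length),
                "n_polymorphic": int(called[sel].sum()),
            }
            for grp in groups.dropna().unique():
                members = groups.index[groups == grp]
                row[f"n_neg_{grp}"] = int(neg.loc[sel, members].any(axis=1).sum())
            rows.append(row)
    return pd.DataFrame(rows)
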