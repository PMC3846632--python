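"""Hypergeometric over-representation analysis with a fixed decision rule.

A selection of genes (e.g. those linked to an isolation site) is tested
against annotation terms (gene classes, chromosomes, environment-study
gene sets) with the exact hypergeometric upper tail; a term counts as
enriched only when the overlap is more than three genes AND -log10(p)
exceeds 2.5. No further multiple-testing correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

__all__ = [
    "AnnotationSet",
    "EnrichmentRecord",
    "hypergeom_tail",
    "enrich",
    "chromosome_enrichment",
]


@dataclass
class AnnotationSet:
    """term -> set of gene ids, with the kind of annotation it represents."""

    terms: dict[str, set[str]]
    kind: str = "gene-class"   # gene-class | anatomy | go | env-study | chromosome

    @classmethod
    def from_table(cls, df: pd.DataFrame, kind: str = "gene-class") -> "AnnotationSet":
        """Two-column (term, gene_id) long table -> AnnotationSet."""
        terms: dict[str, set[str]] = {}
        for term, sub in df.groupby(df.columns[0]):
            terms[str(term)] = set(sub[df.columns[1]])
        return cls(terms=terms, kind=kind)

    def to_table(self) -> pd.DataFrame:
        rows = [(t, g) for t, gs in self.terms.items() for g in sorted(gs)]
        return pd.DataFrame(rows, columns=["term", "gene_id"])


@dataclass
class EnrichmentRecord:
    term: str
    universe_size: int      # N
    term_size: int          # K
    selection_size: int     # n
    overlap: int            # k
    neglog10_p: float
    enriched: bool


def _log_binom(n: float, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Exact upper tail P(X >= k) of Hypergeometric(N, K, n), in log space.

    X counts annotated genes in a size-``n`` draw without replacement from
    a universe of ``N`` genes of which ``K`` are annotated.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= K, n <= N, got N={N}, K={K}, n={n}")
    if k < 0:
        raise ValueError("overlap k must be nonnegative")
    upper = min(K, n)
    if k == 0:
        return 1.0
    if k > upper:
        return 0.0
    i = np.arange(k, upper + 1, dtype=float)
    log_terms = _log_binom(K, i) + _log_binom(N - K, n - i) - _log_binom(N, float(n))
    return float(np.exp(logsumexp(log_terms)))


def enrich(
    selection: set[str],
    annotation: AnnotationSet,
    universe: set[str],
    min_overlap: int = 3,
    logp_threshold: float = 2.5,
) -> list[EnrichmentRecord]:
    """One record per annotation term; strict decision rule on both counts.

    A term is enriched only when overlap > ``min_overlap`` (strictly more
    than three genes by default) and -log10(p) > ``logp_threshold``.
    """
    if not selection <= universe:
        raise ValueError("selection must be a subset of the universe")
    records = []
    N = len(universe)
    n = len(selection)
    for term, genes in annotation.terms.items():
        term_genes = genes & universe
        K = len(term_genes)
        k = len(term_genes & selection)
        p = hypergeom_tail(N, K, n, k)
        nl = float(-np.log10(p)) if p > 0 else 300.0
        records.append(
            EnrichmentRecord(
                term=term,
                universe_size=N,
                term_size=K,
                selection_size=n,
                overlap=k,
                neglog10_p=nl,
                enriched=bool(k > min_overlap and nl > logp_threshold),
            )
        )
    return records


def records_to_frame(records: list[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.term, r.universe_size, r.term_size, r.selection_size, r.overlap,
             r.neglog10_p, r.enriched)
            for r in records
        ],
        columns=["term", "N", "K", "n", "overlap", "neglog10_p", "enriched"],
    )


def chromosome_enrichment(
    polymorphic_genes: set[str],
    coords: pd.DataFrame,
) -> pd.DataFrame:
    """Per-chromosome over- and under-representation of polymorphic genes.

    The universe is every gene with coordinates; each chromosome's gene
    set is the term. Both one-sided tails are reported (enrichment:
    P(X >= k); depletion: P(X <= k)).
    """
    if "chrom" not in coords.columns:
        raise ValueError("gene coordinates with a 'chrom' column are required")
    universe = set(coords.index)
    selection = polymorphic_genes & universe
    N, n = len(universe), len(selection)
    rows = []
    for chrom, sub in coords.groupby("chrom"):
        term_genes = set(sub.index)
        K = len(term_genes)
        k = len(term_genes & selection)
        p_over = hypergeom_tail(N, K, n, k)
        # depletion tail P(X <= k) = 1 - P(X >= k+1)
        p_under = 1.0 - hypergeom_tail(N, K, n, k + 1)
        rows.append((chrom, N, K, n, k, p_over, p_under))
    return pd.DataFrame(
        rows, columns=["chrom", "N", "K", "n", "overlap", "p_enriched", "p_depleted"]
    ).set_index("chrom")
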