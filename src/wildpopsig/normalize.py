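"""Two-color array normalization for the DNA and RNA branches.

The DNA branch runs background subtraction, LOESS within-array
normalization of M on A, and scale (MAD-equalizing) between-array
normalization. The RNA branch skips background correction and replaces
the scale step with quantile between-array normalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from statsmodels.nonparametric.smoothers_lowess import lowess

from .simulate import ScanSet

__all__ = [
    "NormalizedMatrix",
    "background_subtract",
    "loess_within_array",
    "scale_between_arrays",
    "quantile_between_arrays",
    "normalize_branch",
]


@dataclass
class NormalizedMatrix:
    """Probe x array matrix of within-array normalized M-values (log2 test/ref)."""

    values: pd.DataFrame          # probe x array
    arrays: pd.DataFrame          # index array_id; batch, strain
    probes: pd.DataFrame          # probe annotation (gene_id, chrom, pos)
    branch: str                   # "dna" | "rna"

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.values).all():
            raise ValueError("normalized matrix must be finite with no missing values")


def background_subtract(scan: ScanSet, floor: float = 0.5) -> ScanSet:
    """Subtract the per-probe background from both channels, flooring at ``floor``.

    The floor keeps subsequent log-ratios finite when the background
    estimate exceeds the foreground intensity.
    """
    if floor < 0:
        raise ValueError("floor must be nonnegative")
    bg = scan.probes["background"].to_numpy()[:, None]
    test = np.maximum(scan.test.values - bg, floor)
    ref = np.maximum(scan.ref.values - bg, floor)
    return ScanSet(
        probes=scan.probes.assign(background=0.0),
        arrays=scan.arrays,
        test=pd.DataFrame(test, index=scan.test.index, columns=scan.test.columns),
        ref=pd.DataFrame(ref, index=scan.ref.index, columns=scan.ref.columns),
        branch=scan.branch,
    )


def loess_within_array(
    scan: ScanSet,
    span: float = 0.3,
    iterations: int = 3,
) -> NormalizedMatrix:
    """Remove the intensity-dependent trend of M on A within each array.

    Per array, M = log2(test/ref) and A = (log2 test + log2 ref)/2; the
    returned values are M minus a robust locally weighted linear fit of
    M on A (``iterations`` robustness reweightings). When A is constant
    the fit is degenerate and the array is median-centered instead.
    """
    if not 0 < span <= 1:
        raise ValueError("span must lie in (0, 1]")
    if (scan.test.values <= 0).any() or (scan.ref.values <= 0).any():
        raise ValueError("both channels must be positive; run background_subtract first")
    lt = np.log2(scan.test.values)
    lr = np.log2(scan.ref.values)
    m = lt - lr
    a = 0.5 * (lt + lr)
    out = np.empty_like(m)
    for j in range(m.shape[1]):
        aj, mj = a[:, j], m[:, j]
        spread = aj.max() - aj.min()
        if spread <= 0:
            warnings.warn(
                f"array {scan.test.columns[j]!r}: constant A; median-centering instead of LOESS"
            )
            out[:, j] = mj - np.median(mj)
            continue
        # delta collapses near-duplicate abscissae; interpolation error is
        # far below the probe noise scale
        fit = lowess(
            mj,
            aj,
            frac=span,
            it=iterations,
            delta=0.003 * spread,
            return_sorted=False,
        )
        out[:, j] = mj - fit
    return NormalizedMatrix(
        values=pd.DataFrame(out, index=scan.test.index, columns=scan.test.columns),
        arrays=scan.arrays,
        probes=scan.probes,
        branch=scan.branch,
    )


def _mad(x: np.ndarray) -> float:
    return float(np.median(np.abs(x - np.median(x))))


def scale_between_arrays(m: NormalizedMatrix) -> NormalizedMatrix:
    """Equalize array spreads: divide each array by its MAD, rescale by the
    geometric mean of all arrays' MADs (DNA branch)."""
    vals = m.values.values
    mads = np.array([_mad(vals[:, j]) for j in range(vals.shape[1])])
    zero = np.where(mads == 0)[0]
    if zero.size:
        names = list(m.values.columns[zero])
        raise ValueError(f"zero-MAD array(s), cannot scale-normalize: {names}")
    target = np.exp(np.mean(np.log(mads)))
    out = vals / mads[None, :] * target
    return NormalizedMatrix(
        values=pd.DataFrame(out, index=m.values.index, columns=m.values.columns),
        arrays=m.arrays,
        probes=m.probes,
        branch=m.branch,
    )


def quantile_between_arrays(m: NormalizedMatrix) -> NormalizedMatrix:
    """Force every array onto the common (mean) distribution (RNA branch).

    Each value is replaced by the mean of like-ranked values across
    arrays; ties receive the average over their tied ranks.
    """
    vals = m.values.values
    n = vals.shape[0]
    mean_sorted = np.mean(np.sort(vals, axis=0), axis=1)
    out = np.empty_like(vals)
    grid = np.arange(1, n + 1, dtype=float)
    for j in range(vals.shape[1]):
        ranks = rankdata(vals[:, j], method="average")
        out[:, j] = np.interp(ranks, grid, mean_sorted)
    return NormalizedMatrix(
        values=pd.DataFrame(out, index=m.values.index, columns=m.values.columns),
        arrays=m.arrays,
        probes=m.probes,
        branch=m.branch,
    )


def normalize_branch(
    scan: ScanSet,
    span: float = 0.3,
    iterations: int = 3,
    floor: float = 0.5,
) -> NormalizedMatrix:
    """Full normalization for one branch.

    DNA: background subtraction, LOESS within-array, scale between-array.
    RNA: LOESS within-array (no background correction), quantile
    between-array.
    """
    if scan.branch == "dna":
        scan = background_subtract(scan, floor=floor)
        m = loess_within_array(scan, span=span, iterations=iterations)
        return scale_between_arrays(m)
    if scan.branch == "rna":
        m = loess_within_array(scan, span=span, iterations=iterations)
        return quantile_between_arrays(m)
    raise ValueError(f"unknown branch {scan.branch!r}")
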