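import numpy as np
import pandas as pd
import pytest

from wildpopsig import (
    SimConfig,
    call_polymorphic,
    generate_genotype_arrays,
    normalize_branch,
    ratio_to_mean,
)
from wildpopsig.normalize import NormalizedMatrix
from wildpopsig.simulate import ScanSet


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(master_seed=11, n_genes=1500)


@pytest.fixture(scope="session")
def small_dna(small_cfg):
    return generate_genotype_arrays(small_cfg)


@pytest.fixture(scope="session")
def small_norm(small_dna):
    scan, _ = small_dna
    return normalize_branch(scan)


@pytest.fixture(scope="session")
def small_ratio(small_norm):
    return ratio_to_mean(small_norm)


@pytest.fixture(scope="session")
def small_calls(small_ratio):
    return call_polymorphic(small_ratio)


def make_scanset(test, ref, background=None, branch="dna", chrom=None, pos=None):
    """Build a ScanSet from raw matrices; probes get one gene each."""
    test = np.asarray(test, dtype=float)
    ref = np.asarray(ref, dtype=float)
    n_probes, n_arrays = test.shape
    probe_ids = [f"p{i}" for i in range(n_probes)]
    array_ids = [f"a{j}" for j in range(n_arrays)]
    probes = pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(n_probes)],
            "chrom": chrom if chrom is not None else ["I"] * n_probes,
            "pos": pos if pos is not None else np.arange(1, n_probes + 1) * 100,
            "background": background if background is not None else np.zeros(n_probes),
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    arrays = pd.DataFrame(
        {"batch": [0] * n_arrays, "strain": [f"s{j}" for j in range(n_arrays)]},
        index=pd.Index(array_ids, name="array_id"),
    )
    return ScanSet(
        probes=probes,
        arrays=arrays,
        test=pd.DataFrame(test, index=probe_ids, columns=array_ids),
        ref=pd.DataFrame(ref, index=probe_ids, columns=array_ids),
        branch=branch,
    )


def make_norm(values, branch="dna", chrom=None, pos=None, strains=None, batches=None):
    """Build a NormalizedMatrix directly from a probe x array matrix."""
    values = np.asarray(values, dtype=float)
    n_probes, n_arrays = values.shape
    probe_ids = [f"p{i}" for i in range(n_probes)]
    array_ids = [f"a{j}" for j in range(n_arrays)]
    probes = pd.DataFrame(
        {
            "gene_id": [f"g{i}" for i in range(n_probes)],
            "chrom": chrom if chrom is not None else ["I"] * n_probes,
            "pos": pos if pos is not None else np.arange(1, n_probes + 1) * 100,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    arrays = pd.DataFrame(
        {
            "batch": batches if batches is not None else [0] * n_arrays,
            "strain": strains if strains is not None else [f"s{j}" for j in range(n_arrays)],
        },
        index=pd.Index(array_ids, name="array_id"),
    )
    return NormalizedMatrix(
        values=pd.DataFrame(values, index=probe_ids, columns=array_ids),
        arrays=arrays,
        probes=probes,
        branch=branch,
    )
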