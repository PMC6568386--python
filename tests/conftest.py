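import numpy as np
import pandas as pd
import pytest

from tailscan.genotype_io import MISSING, GenotypeDataset
from tailscan.simulate import tiny_dataset


def make_dataset(
    calls: np.ndarray,
    pos: list[int] | None = None,
    chroms: list[str] | None = None,
    groups: list[str] | None = None,
    missing_mask: np.ndarray | None = None,
) -> GenotypeDataset:
    """Small helper to build a dataset from a genotype matrix."""
    calls = np.asarray(calls, dtype=np.int8)
    if missing_mask is not None:
        calls = np.where(missing_mask, MISSING, calls).astype(np.int8)
    n, m = calls.shape
    pos = pos if pos is not None else [(j + 1) * 1000 for j in range(m)]
    chroms = chroms if chroms is not None else ["1"] * m
    snps = pd.DataFrame(
        {
            "chrom": chroms,
            "snp_id": [f"s{j}" for j in range(m)],
            "pos_bp": pos,
            "allele_a": "A",
            "allele_b": "B",
        }
    )
    groups = groups if groups is not None else ["g1"] * n
    return GenotypeDataset([f"i{k}" for k in range(n)], list(groups), snps, calls)


def random_dataset(rng, n=6, m=12, missing_rate=0.1, groups=None) -> GenotypeDataset:
    calls = rng.integers(0, 3, size=(n, m))
    mask = rng.random((n, m)) < missing_rate
    return make_dataset(calls, missing_mask=mask, groups=groups)


@pytest.fixture
def tiny():
    """4 phased diploids x 10 SNPs, hand-checkable."""
    return tiny_dataset()


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
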