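import numpy as np
import pandas as pd
import pytest

from rohscape import GenotypeMatrix, make_markers, make_samples


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def tiny_matrix():
    """4 samples x 6 markers on two chromosomes, with one missing call."""
    markers = make_markers(
        chroms=["1", "1", "1", "2", "2", "2"],
        positions=[1_000, 50_000, 120_000, 10_000, 60_000, 200_000],
        allele1=["A", "C", "A", "G", "A", "C"],
        allele2=["G", "T", "G", "T", "C", "G"],
    )
    calls = np.array(
        [
            [0, 1, 2, 0, 0, 1],
            [2, 2, 2, 1, 0, 0],
            [1, 0, 0, 2, -1, 2],
            [0, 0, 1, 0, 2, 2],
        ],
        dtype=np.int8,
    )
    samples = make_samples(
        ["s1", "s2", "s3", "s4"],
        populations=["A", "A", "B", "B"],
        sexes=["male", "female", "male", "female"],
    )
    return GenotypeMatrix(calls, samples, markers)


def random_matrix(rng, n_samples, n_markers, n_chrom=2, spacing_bp=50_000,
                  p_het=0.3, p_missing=0.02):
    """Random matrix with uniform marker spacing, for oracle-equivalence tests."""
    per = n_markers // n_chrom
    chroms, positions = [], []
    for c in range(1, n_chrom + 1):
        n = per if c < n_chrom else n_markers - per * (n_chrom - 1)
        chroms += [str(c)] * n
        positions += list((np.arange(n) + 1) * spacing_bp)
    markers = make_markers(chroms, positions)
    calls = rng.choice(
        [0, 1, 2, -1],
        size=(n_samples, n_markers),
        p=[(1 - p_het - p_missing) / 2, p_het, (1 - p_het - p_missing) / 2, p_missing],
    ).astype(np.int8)
    samples = make_samples([f"s{i}" for i in range(n_samples)])
    return GenotypeMatrix(calls, samples, markers)
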