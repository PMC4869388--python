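"""Shared fixtures and independent oracles.

The oracle routines below deliberately avoid the package's entropy code:
they count joint categories with ``collections.Counter`` and use
``math.log2`` directly, so measure tests compare two independent paths.
"""

from __future__ import annotations

import math
from collections import Counter
from itertools import combinations

import numpy as np
import pytest

from noedv.data_io import GenotypeDataset


def oracle_entropy(*columns) -> float:
    """Plug-in joint entropy in bits via Counter over row tuples."""
    rows = list(zip(*[list(c) for c in columns]))
    m = len(rows)
    counts = Counter(rows)
    return -sum((c / m) * math.log2(c / m) for c in counts.values())


def oracle_ci(dataset: GenotypeDataset, snps) -> float:
    """Brute-force inclusion-exclusion over all 2^(n+1) subsets of SNPs + phenotype."""
    snps = tuple(snps)
    n = len(snps)
    cols = {s: list(dataset.genotypes[:, s - 1]) for s in snps}
    pheno = list(dataset.phenotype)
    total = 0.0
    for r in range(n + 1):
        for sub in combinations(snps, r):
            for with_pheno in (False, True):
                size = r + with_pheno
                if size == 0:
                    continue
                vecs = [cols[s] for s in sub] + ([pheno] if with_pheno else [])
                sign = (-1) ** (n + 1 - size)
                total -= sign * oracle_entropy(*vecs)
    return total


def random_dataset(rng: np.random.Generator, m: int = 50, n: int = 5) -> GenotypeDataset:
    """Random genotype/phenotype table guaranteed to contain both classes."""
    geno = rng.integers(0, 3, size=(m, n))
    pheno = rng.integers(0, 2, size=m)
    pheno[0], pheno[1] = 0, 1
    return GenotypeDataset(geno, pheno)


@pytest.fixture
def xor_dataset() -> GenotypeDataset:
    """8 rows: S1, S2 uniform on {0,1}^2 (each combination twice), C = S1 xor S2."""
    s1 = np.array([0, 0, 1, 1] * 2)
    s2 = np.array([0, 1, 0, 1] * 2)
    return GenotypeDataset(np.stack([s1, s2], axis=1), s1 ^ s2)


@pytest.fixture
def xor_noise_dataset() -> GenotypeDataset:
    """XOR pair (SNPs 1, 2) plus 8 independent MAF-0.5 noise SNPs, M = 400."""
    rng = np.random.default_rng(20240917)
    m = 400
    s1 = rng.integers(0, 2, size=m)
    s2 = rng.integers(0, 2, size=m)
    noise = rng.choice(3, size=(m, 8), p=[0.25, 0.5, 0.25])
    geno = np.column_stack([s1, s2, noise])
    return GenotypeDataset(geno, s1 ^ s2)
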