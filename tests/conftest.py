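"""Shared fixtures: small genotype/haplotype tables with known properties."""

from __future__ import annotations

import numpy as np
import pytest

from rescuegen.containers import GenotypeTable, HaplotypeSet


@pytest.fixture
def two_pop_table() -> GenotypeTable:
    """Two populations, two loci, fully genotyped, hand-checkable."""
    geno = np.array([
        [[100, 102], [140, 140]],
        [[100, 100], [140, 142]],
        [[102, 102], [142, 142]],
        [[104, 104], [140, 140]],
        [[100, 104], [140, 142]],
        [[104, 104], [142, 142]],
    ])
    return GenotypeTable(
        [f"ind{k}" for k in range(6)],
        ["north"] * 3 + ["south"] * 3,
        ["LocA", "LocB"],
        geno,
    )


@pytest.fixture
def small_alignment() -> HaplotypeSet:
    return HaplotypeSet(
        [f"seq{k}|popA" for k in range(4)],
        ["popA"] * 4,
        ["ACGTACGTAC", "ACGTACGTAC", "ACGTACGTAT", "ACGAACGTAT"],
    )


def random_genotype_table(
    rng: np.random.Generator,
    n_pops: int = 2,
    n_per_pop: int = 8,
    n_loci: int = 4,
    missing_rate: float = 0.1,
) -> GenotypeTable:
    n = n_pops * n_per_pop
    geno = 100 + 2 * rng.integers(0, 6, size=(n, n_loci, 2))
    mask = rng.random((n, n_loci)) < missing_rate
    geno[mask] = 0
    return GenotypeTable(
        [f"i{k:03d}" for k in range(n)],
        [f"p{k // n_per_pop}" for k in range(n)],
        [f"L{j}" for j in range(n_loci)],
        geno.astype(np.int32),
    )
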