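"""Shared fixtures: all test data is generated programmatically."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from divscan.datatypes import MISSING, GenotypeDataset, HaplotypeSet
from divscan.simulate import SimConfig, SweepSpec, simulate


def make_marker_map(n: int, chrom: str = "1", spacing: int = 1000) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "marker_id": [f"m{chrom}_{i}" for i in range(n)],
            "chrom": chrom,
            "pos_bp": np.arange(1, n + 1) * spacing,
            "allele_ref": "A",
            "allele_alt": "G",
        }
    )


def random_dataset(
    rng: np.random.Generator, n: int = 12, m: int = 30, missing_rate: float = 0.1
) -> GenotypeDataset:
    g = rng.integers(0, 3, (n, m)).astype(np.int8)
    g[rng.random((n, m)) < missing_rate] = MISSING
    samples = pd.DataFrame({"sample_id": [f"s{i}" for i in range(n)]})
    return GenotypeDataset(g, make_marker_map(m), samples)


def random_haplotypes(
    rng: np.random.Generator, n_samples: int = 8, m: int = 40,
    chrom: str = "1", spacing: int = 5000,
) -> HaplotypeSet:
    h = rng.integers(0, 2, (2 * n_samples, m)).astype(np.int8)
    ids = [f"s{i}" for i in range(n_samples)]
    pops = {sid: ("SJ" if i < n_samples // 2 else "NS") for i, sid in enumerate(ids)}
    return HaplotypeSet.from_sample_pairs(
        h, ids, make_marker_map(m, chrom, spacing), pops
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20231115)


@pytest.fixture(scope="session")
def small_cohort():
    """A small neutral two-population cohort reused across modules."""
    cfg = SimConfig(
        n_pop=40, n_chrom=2, m_snps=300, chrom_len_bp=6_000_000,
        split_generations=20, burnin_generations=20, missing_rate=0.05, seed=11,
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def sweep_cohort():
    """Default-scale cohort with one verified established sweep in SJ."""
    cfg = SimConfig(
        seed=15, sweeps=[SweepSpec("3", 10_000_000, 0.1, "SJ")]
    )
    return simulate(cfg)
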