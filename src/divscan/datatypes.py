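"""Shared in-memory data model for the divergence-scan pipeline.

Genotypes are stored as alt-allele dosages in {0, 1, 2} with ``MISSING``
(-1) as the dedicated missing sentinel; phased haplotypes are binary
(0 = ref, 1 = alt) with the same sentinel allowed only before filtering.
Marker positions are 1-based inclusive throughout the library; BED export
converts to 0-based half-open at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Dedicated missing-genotype sentinel (never 0).
MISSING: int = -1

MARKER_COLUMNS = ["marker_id", "chrom", "pos_bp", "allele_ref", "allele_alt"]

#: Subpopulation labels: show-jumping and non-show-jumping.
GROUP_SJ = "SJ"
GROUP_NS = "NS"
GROUP_UNASSIGNED = "unassigned"


def validate_marker_map(markers: pd.DataFrame) -> None:
    """Check the marker-map invariants.

    Requires the standard columns, unique marker ids, positions >= 1 and,
    within each chromosome, strictly increasing positions.
    """
    missing_cols = [c for c in MARKER_COLUMNS if c not in markers.columns]
    if missing_cols:
        raise ValueError(f"marker map lacks columns: {missing_cols}")
    if markers["marker_id"].duplicated().any():
        raise ValueError("marker ids are not unique")
    if (markers["pos_bp"] < 1).any():
        raise ValueError("marker positions must be >= 1 (1-based)")
    for chrom, sub in markers.groupby("chrom", sort=False):
        pos = sub["pos_bp"].to_numpy()
        if np.any(np.diff(pos) <= 0):
            raise ValueError(f"positions not strictly increasing on {chrom}")


@dataclass
class GenotypeDataset:
    """Sample-by-marker diploid dosage matrix with marker map and metadata.

    Parameters
    ----------
    genotypes
        ``(n_samples, n_markers)`` int8 array of alt-allele dosages in
        {0, 1, 2} or :data:`MISSING`.
    markers
        Marker map with columns :data:`MARKER_COLUMNS`.
    samples
        Per-sample table; must contain ``sample_id``. Optional columns used
        downstream: ``ebv_jump``, ``ebv_dressage``, ``group``,
        ``tb_fraction``, ``sire_id``, ``dam_id``, ``sex``.
    """

    genotypes: np.ndarray
    markers: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        n, m = self.genotypes.shape
        if len(self.samples) != n:
            raise ValueError(f"{len(self.samples)} sample rows for {n} genotype rows")
        if len(self.markers) != m:
            raise ValueError(f"{len(self.markers)} marker rows for {m} genotype columns")
        validate_marker_map(self.markers)
        bad = ~np.isin(self.genotypes, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("genotype values must be in {0,1,2} or MISSING")
        if "sample_id" not in self.samples.columns:
            raise ValueError("sample table lacks sample_id")
        self.markers = self.markers.reset_index(drop=True)
        self.samples = self.samples.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    def take_markers(self, index: np.ndarray) -> "GenotypeDataset":
        """Subset to the given marker indices (order preserved as given)."""
        index = np.asarray(index)
        return GenotypeDataset(
            genotypes=self.genotypes[:, index],
            markers=self.markers.iloc[index],
            samples=self.samples.copy(),
        )

    def marker_index(self, marker_ids) -> np.ndarray:
        """Positional indices for a sequence of marker ids."""
        lookup = pd.Series(np.arange(self.n_markers), index=self.markers["marker_id"])
        return lookup.loc[list(marker_ids)].to_numpy()


@dataclass
class HaplotypeSet:
    """Phased binary haplotype matrix with a per-row carrier mapping.

    ``haplotypes`` is ``(n_rows, n_markers)`` int8 with alleles in {0, 1};
    :data:`MISSING` may appear only before
    :func:`divscan.xpehh.filter_haplotypes`. ``carrier[i]`` is the sample id
    of row ``i`` (a freshly phased set has two consecutive rows per sample;
    haplotype filtering may leave a sample with a single row). ``pop_of``
    maps each sample id to its subpopulation label.
    """

    haplotypes: np.ndarray
    carrier: list
    markers: pd.DataFrame
    pop_of: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.int8)
        self.carrier = list(self.carrier)
        if self.haplotypes.shape[0] != len(self.carrier):
            raise ValueError("one carrier sample id required per haplotype row")
        if pd.Series(self.carrier).value_counts().max() > 2 if self.carrier else False:
            raise ValueError("a diploid sample cannot carry more than two haplotypes")
        if len(self.markers) != self.haplotypes.shape[1]:
            raise ValueError("marker map does not match haplotype columns")
        validate_marker_map(self.markers)
        bad = ~np.isin(self.haplotypes, (0, 1, MISSING))
        if bad.any():
            raise ValueError("haplotype alleles must be 0, 1 or MISSING")
        self.markers = self.markers.reset_index(drop=True)

    @classmethod
    def from_sample_pairs(
        cls, haplotypes: np.ndarray, sample_ids, markers: pd.DataFrame,
        pop_of: dict | None = None,
    ) -> "HaplotypeSet":
        """Build from a ``(2n, m)`` matrix whose rows 2i, 2i+1 belong to sample i."""
        carrier = [s for s in sample_ids for _ in range(2)]
        return cls(haplotypes, carrier, markers, dict(pop_of or {}))

    @property
    def sample_ids(self) -> list:
        return list(dict.fromkeys(self.carrier))

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return self.haplotypes.shape[1]

    def population_rows(self, pop: str) -> np.ndarray:
        """Haplotype row indices belonging to one subpopulation."""
        return np.asarray(
            [i for i, sid in enumerate(self.carrier) if self.pop_of.get(sid) == pop],
            dtype=np.int64,
        )

    def to_genotypes(self, samples: pd.DataFrame | None = None) -> GenotypeDataset:
        """Collapse the two phased rows per sample into dosages.

        Requires every sample to carry exactly two consecutive rows.
        """
        ids = self.sample_ids
        if self.haplotypes.shape[0] != 2 * len(ids) or any(
            self.carrier[2 * i] != self.carrier[2 * i + 1] for i in range(len(ids))
        ):
            raise ValueError("haplotypes are not paired per sample")
        h = self.haplotypes
        g = h[0::2].astype(np.int16) + h[1::2].astype(np.int16)
        g[(h[0::2] == MISSING) | (h[1::2] == MISSING)] = MISSING
        if samples is None:
            samples = pd.DataFrame({"sample_id": ids})
        return GenotypeDataset(g.astype(np.int8), self.markers.copy(), samples)
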