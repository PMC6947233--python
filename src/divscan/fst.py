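"""Per-SNP Nei fixation index between two subpopulations.

The statistic is Nei's G_ST form for two demes with unweighted mean allele
frequency: with p_bar = (p1 + p2)/2,

    H_T = 2 p_bar (1 - p_bar)
    H_S = (2 p1 (1 - p1) + 2 p2 (1 - p2)) / 2
    F_ST = (H_T - H_S) / H_T

Markers monomorphic in both groups (H_T = 0) score 0, and negative values
are clamped to 0. Significance uses an empirical nearest-rank quantile of
the genome-wide distribution (top 0.1% by default), ties included.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import MISSING, GenotypeDataset


@dataclass
class FstResult:
    """Per-SNP F_ST track aligned to the marker map (NaN = excluded)."""

    table: pd.DataFrame  # marker_id, chrom, pos_bp, fst, significant
    threshold: float
    mean: float
    sd: float

    @property
    def significant_ids(self) -> set:
        return set(self.table.loc[self.table["significant"], "marker_id"])


def group_allele_freqs(
    ds: GenotypeDataset, labels: np.ndarray | pd.Series, groups: tuple = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Alt-allele frequency per marker in each of two groups.

    Returns ``(p1, p2, n1_called, n2_called)``; a marker with no called
    genotype in a group has NaN frequency there and is excluded from the
    scan by the caller.
    """
    labels = np.asarray(labels)
    if groups is None:
        groups = tuple(pd.unique(labels[pd.notna(labels)]))
    if len(groups) != 2:
        raise ValueError(f"exactly two groups required, got {groups}")
    out = []
    for grp in groups:
        g = ds.genotypes[labels == grp]
        if g.shape[0] == 0:
            raise ValueError(f"group {grp} has no samples")
        called = g != MISSING
        n_called = called.sum(axis=0)
        alt = np.where(called, g, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n_called > 0, alt / (2.0 * n_called), np.nan)
        out.append((p, n_called))
    (p1, n1), (p2, n2) = out
    return p1, p2, n1, n2


def nei_fst(p1, p2):
    """Nei's two-population fixation index from allele frequencies.

    Accepts scalars or arrays; clamps negatives to 0 and defines
    monomorphic-in-both markers (H_T = 0) as 0.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if np.any((p1 < -1e-12) | (p1 > 1 + 1e-12) | (p2 < -1e-12) | (p2 > 1 + 1e-12)):
        raise ValueError("allele frequencies must lie in [0, 1]")
    p_bar = (p1 + p2) / 2.0
    h_t = 2.0 * p_bar * (1.0 - p_bar)
    h_s = (2.0 * p1 * (1.0 - p1) + 2.0 * p2 * (1.0 - p2)) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(h_t > 0, (h_t - h_s) / np.where(h_t > 0, h_t, 1.0), 0.0)
    fst = np.clip(fst, 0.0, 1.0)
    return float(fst) if fst.ndim == 0 else fst


def empirical_threshold(fst: np.ndarray, top_fraction: float = 0.001) -> float:
    """Nearest-rank (1 - top_fraction) quantile of the F_ST distribution."""
    if not (0.0 < top_fraction < 1.0):
        raise ValueError("top_fraction must be in (0, 1)")
    values = np.asarray(fst, dtype=float)
    values = values[~np.isnan(values)]
    if values.size == 0:
        raise ValueError("no F_ST values")
    ordered = np.sort(values)
    # 1-based nearest rank chosen so that the significant set {fst >= t}
    # holds the top `top_fraction` of markers (plus ties)
    rank = int(np.floor((1.0 - top_fraction) * ordered.size)) + 1
    rank = min(max(rank, 1), ordered.size)
    threshold = float(ordered[rank - 1])
    if threshold == ordered[0]:
        warnings.warn("degenerate F_ST distribution: all markers tied at threshold")
    return threshold


WRIGHT_BANDS = ("little", "moderate", "large", "very_large")


def classify_wright(fst: float) -> str:
    """Qualitative differentiation band for an F_ST value.

    < 0.05 little; [0.05, 0.15) moderate; [0.15, 0.25] large; > 0.25
    very large.
    """
    if not (0.0 <= fst <= 1.0):
        raise ValueError("fst must be in [0, 1]")
    if fst < 0.05:
        return "little"
    if fst < 0.15:
        return "moderate"
    if fst <= 0.25:
        return "large"
    return "very_large"


def fst_scan(
    ds: GenotypeDataset,
    labels: np.ndarray | pd.Series,
    top_fraction: float = 0.001,
    groups: tuple = None,
) -> FstResult:
    """Genome-wide per-SNP Nei F_ST scan with empirical significance.

    Markers entirely uncalled in either group are excluded (NaN) and do
    not enter the quantile denominator. ``significant`` is
    ``fst >= threshold`` (ties included).
    """
    p1, p2, n1, n2 = group_allele_freqs(ds, labels, groups)
    valid = ~np.isnan(p1) & ~np.isnan(p2)
    fst = np.full(ds.n_markers, np.nan)
    fst[valid] = nei_fst(p1[valid], p2[valid])
    threshold = empirical_threshold(fst[valid], top_fraction)
    significant = np.zeros(ds.n_markers, dtype=bool)
    significant[valid] = fst[valid] >= threshold
    table = pd.DataFrame(
        {
            "marker_id": ds.markers["marker_id"],
            "chrom": ds.markers["chrom"],
            "pos_bp": ds.markers["pos_bp"],
            "fst": fst,
            "significant": significant,
        }
    )
    return FstResult(
        table=table,
        threshold=threshold,
        mean=float(np.nanmean(fst)),
        sd=float(np.nanstd(fst)),
    )
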