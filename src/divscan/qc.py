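"""Marker quality control and LD pruning.

The filters are applied in a fixed order — call rate, MAF, exact HWE — and
each marker removal is attributed to the first filter that rejects it.
LD pruning (sliding window of ``ld_window`` SNPs advanced by ``ld_step``)
is intended only for the structure analyses (PCoA/DAPC); the selection
scans run on the full post-QC panel.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .datatypes import MISSING, GenotypeDataset


@dataclass
class QCConfig:
    min_call_rate: float = 0.90
    min_maf: float = 0.01
    hwe_alpha: float = 1e-4   # 0 disables the HWE filter
    ld_window: int = 50
    ld_step: int = 5
    ld_r2_max: float = 0.5

    def __post_init__(self) -> None:
        if not (0 <= self.min_call_rate <= 1 and 0 <= self.min_maf <= 0.5):
            raise ValueError("call-rate / MAF thresholds out of range")
        if not (0 <= self.hwe_alpha < 1):
            raise ValueError("hwe_alpha out of range")
        if self.ld_step > self.ld_window:
            raise ValueError("ld_step must be <= ld_window")


@dataclass
class QCReport:
    """Per-stage marker attrition, in application order."""

    n_input: int = 0
    removed: dict = field(default_factory=dict)  # stage -> list of marker ids
    n_retained: int = 0
    n_samples: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows, remaining = [], self.n_input
        for stage, ids in self.removed.items():
            rows.append({"stage": stage, "removed": len(ids),
                         "remaining": remaining - len(ids)})
            remaining -= len(ids)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Per-marker statistics
# ---------------------------------------------------------------------------

def call_rates(ds: GenotypeDataset) -> np.ndarray:
    """Fraction of non-missing genotypes per marker."""
    return (ds.genotypes != MISSING).mean(axis=0)


def allele_freqs(ds: GenotypeDataset) -> np.ndarray:
    """Alt-allele frequency per marker among called genotypes (NaN if none)."""
    g = ds.genotypes
    called = g != MISSING
    n_called = called.sum(axis=0)
    alt = np.where(called, g, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n_called > 0, alt / (2.0 * n_called), np.nan)


def call_rate_filter(
    ds: GenotypeDataset, min_call_rate: float = 0.90
) -> tuple[GenotypeDataset, list]:
    """Drop markers whose call rate is strictly below the threshold."""
    keep = call_rates(ds) >= min_call_rate
    removed = ds.markers.loc[~keep, "marker_id"].tolist()
    return ds.take_markers(np.flatnonzero(keep)), removed


def maf_filter(
    ds: GenotypeDataset, min_maf: float = 0.01
) -> tuple[GenotypeDataset, list]:
    """Drop markers with minor-allele frequency strictly below ``min_maf``.

    MAF is ``min(p, 1-p)`` with ``p`` estimated from called dosages only;
    markers with zero called genotypes are removed with a warning.
    """
    p = allele_freqs(ds)
    uncalled = np.isnan(p)
    if uncalled.any():
        warnings.warn(f"{int(uncalled.sum())} markers with no called genotypes removed")
    maf = np.minimum(p, 1.0 - p)
    keep = ~uncalled & (maf >= min_maf)
    removed = ds.markers.loc[~keep, "marker_id"].tolist()
    return ds.take_markers(np.flatnonzero(keep)), removed


# ---------------------------------------------------------------------------
# Exact Hardy-Weinberg test
# ---------------------------------------------------------------------------

@lru_cache(maxsize=200_000)
def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact HWE p-value conditional on the allele counts.

    Sums the probabilities of all heterozygote configurations that are no
    more probable than the observed one (the standard exact conditional
    test used by PLINK). Returns a value in (0, 1].
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n < 1:
        raise ValueError("at least one genotype required")
    n_rare = 2 * min(n_AA, n_aa) + n_Aa
    # P(het = h | n, n_rare) via the stable mid-out recurrence
    h_obs = n_Aa
    h_vals = range(n_rare % 2, n_rare + 1, 2)
    logp = {}
    # start at the most probable-ish midpoint: compute all by recurrence from h0
    h0 = n_rare % 2
    lp = 0.0
    logp[h0] = lp
    for h in h_vals:
        if h == h0:
            continue
        # ratio P(h)/P(h-2) = (hom_r+1)(hom_c+1)*4 / (h*(h-1)) inverted:
        hom_r_prev = (n_rare - (h - 2)) // 2
        hom_c_prev = n - (h - 2) - hom_r_prev
        lp = lp + math.log(4.0 * hom_r_prev * hom_c_prev) - math.log(h * (h - 1))
        logp[h] = lp
    mx = max(logp.values())
    probs = {h: math.exp(v - mx) for h, v in logp.items()}
    total = sum(probs.values())
    p_obs = probs[h_obs]
    p_value = sum(v for v in probs.values() if v <= p_obs * (1 + 1e-12)) / total
    return min(1.0, p_value)


def hwe_filter(
    ds: GenotypeDataset, alpha: float = 1e-4
) -> tuple[GenotypeDataset, list]:
    """Drop markers whose exact HWE p-value is below ``alpha`` (whole cohort)."""
    g = ds.genotypes
    keep = np.ones(ds.n_markers, dtype=bool)
    for j in range(ds.n_markers):
        col = g[:, j]
        col = col[col != MISSING]
        if col.size == 0:
            continue
        n_aa = int((col == 0).sum())
        n_Aa = int((col == 1).sum())
        n_AA = int((col == 2).sum())
        if hwe_exact_test(n_AA, n_Aa, n_aa) < alpha:
            keep[j] = False
    removed = ds.markers.loc[~keep, "marker_id"].tolist()
    return ds.take_markers(np.flatnonzero(keep)), removed


# ---------------------------------------------------------------------------
# LD
# ---------------------------------------------------------------------------

def ld_r2(g1: np.ndarray, g2: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors.

    Computed over pairwise-complete entries; 0 if either vector is constant
    there; NaN if fewer than 2 complete pairs (the caller skips such pairs).
    """
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    ok = (g1 != MISSING) & (g2 != MISSING)
    if ok.sum() < 2:
        return float("nan")
    x, y = g1[ok], g2[ok]
    vx = x.var()
    vy = y.var()
    if vx == 0.0 or vy == 0.0:
        return 0.0
    c = ((x - x.mean()) * (y - y.mean())).mean()
    return float(c * c / (vx * vy))


def _window_r2(g: np.ndarray) -> np.ndarray:
    """Pairwise-complete r^2 matrix for a dosage block (MISSING-aware).

    Matmul formulation of pairwise-complete Pearson correlation; pairs with
    < 2 complete rows or a constant column come out as 0.
    """
    mask = (g != MISSING).astype(float)
    x = np.where(g == MISSING, 0.0, g.astype(float))
    n_ab = mask.T @ mask
    sx = x.T @ mask      # sum of column a over rows complete in (a, b)
    sxx = (x * x).T @ mask
    sxy = x.T @ x
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sx.T / n_ab
        var_a = sxx - sx * sx / n_ab
        denom = var_a * var_a.T
        r2 = np.where(denom > 0, cov * cov / denom, 0.0)
    r2[n_ab < 2] = 0.0
    np.fill_diagonal(r2, 0.0)
    return r2


def ld_prune(ds: GenotypeDataset, cfg: QCConfig | None = None) -> list:
    """Sliding-window LD pruning; returns the retained marker ids.

    Within each window of ``ld_window`` SNPs (advanced by ``ld_step``,
    never crossing a chromosome boundary), while any retained pair has
    r^2 > ``ld_r2_max`` the member with the lower MAF is removed
    (ties: the one later in map order).
    """
    cfg = cfg or QCConfig()
    p = allele_freqs(ds)
    maf = np.minimum(p, 1.0 - p)
    keep = np.ones(ds.n_markers, dtype=bool)
    chroms = ds.markers["chrom"].to_numpy()

    for chrom in pd.unique(chroms):
        idx = np.flatnonzero(chroms == chrom)
        start = 0
        while start < len(idx):
            window = idx[start : start + cfg.ld_window]
            live = [j for j in window if keep[j]]
            if len(live) > 1:
                sub = ds.genotypes[:, live].astype(float)
                r2 = _window_r2(sub)
                local_live = list(range(len(live)))
                while True:
                    worst = None
                    for ai in range(len(local_live)):
                        for bi in range(ai + 1, len(local_live)):
                            a, b = local_live[ai], local_live[bi]
                            if r2[a, b] > cfg.ld_r2_max:
                                ja, jb = live[a], live[b]
                                # victim: lower MAF, tie -> later in map
                                victim = (
                                    jb
                                    if (maf[jb] < maf[ja])
                                    or (maf[jb] == maf[ja])
                                    else ja
                                )
                                worst = victim
                                break
                        if worst is not None:
                            break
                    if worst is None:
                        break
                    keep[worst] = False
                    local_live = [k for k in local_live if live[k] != worst]
            if start + cfg.ld_window >= len(idx):
                break
            start += cfg.ld_step
    return ds.markers.loc[keep, "marker_id"].tolist()


def apply_qc(
    ds: GenotypeDataset, cfg: QCConfig | None = None
) -> tuple[GenotypeDataset, QCReport]:
    """Run call-rate, MAF and HWE filters in order and report attrition."""
    cfg = cfg or QCConfig()
    report = QCReport(n_input=ds.n_markers, n_samples=ds.n_samples)
    ds, removed = call_rate_filter(ds, cfg.min_call_rate)
    report.removed["call_rate"] = removed
    ds, removed = maf_filter(ds, cfg.min_maf)
    report.removed["maf"] = removed
    if cfg.hwe_alpha > 0:
        # NOTE: under strong between-group divergence, whole-cohort HWE
        # testing removes the most differentiated markers (Wahlund
        # heterozygote deficit); set hwe_alpha = 0 for such designs.
        ds, removed = hwe_filter(ds, cfg.hwe_alpha)
        report.removed["hwe"] = removed
    report.n_retained = ds.n_markers
    return ds, report
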