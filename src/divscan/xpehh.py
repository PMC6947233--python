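"""Cross-population extended haplotype homozygosity (XPEHH) scan.

For each core SNP the site-EHH decay EHHS(x) — the probability that two
haplotypes drawn from one population are identical over the interval from
the core out to x, normalized by identity at the core site — is integrated
over physical distance on both flanks to give iES. The raw cross-population
score is ln(iES_A / iES_B); by pipeline convention A = NS and B = SJ, so
positive scores point to selection in NS horses and negative scores to SJ.
Raw scores are standardized genome-wide, transformed to a two-sided
-log10 p via the Gaussian CDF, and thresholded with Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .datatypes import MISSING, GROUP_NS, GROUP_SJ, HaplotypeSet
from ._kernels import scan_site_ies

#: -log10 p cap for |z| so large that the two-sided tail underflows.
DEFAULT_MAX_LOG10_P = 300.0


# ---------------------------------------------------------------------------
# Haplotype filtering
# ---------------------------------------------------------------------------

def filter_haplotypes(hs: HaplotypeSet) -> HaplotypeSet:
    """Drop haplotype rows with any missing call, then incomplete markers.

    Mirrors the standard pre-scan filtering of phased data: (1) discard
    haplotypes containing missing data, (2) keep only markers fully
    genotyped in the surviving rows. The result has no missing entries.
    """
    h = hs.haplotypes
    row_ok = ~(h == MISSING).any(axis=1)
    h2 = h[row_ok]
    col_ok = ~(h2 == MISSING).any(axis=0)
    if not row_ok.any() or not col_ok.any():
        raise ValueError("haplotype filtering removed everything")
    carrier = [c for c, ok in zip(hs.carrier, row_ok) if ok]
    return HaplotypeSet(
        h2[:, col_ok], carrier, hs.markers.loc[col_ok].copy(), dict(hs.pop_of)
    )


# ---------------------------------------------------------------------------
# EHHS decay and integration (reference path; the genome scan uses the
# numba kernel, tested for equality against this one)
# ---------------------------------------------------------------------------

@dataclass
class EhhDecay:
    """Site-EHH decay around one core SNP for one population."""

    core_index: int
    left_pos: np.ndarray    # bp positions, core-outward (decreasing)
    left_ehhs: np.ndarray
    right_pos: np.ndarray   # bp positions, core-outward (increasing)
    right_ehhs: np.ndarray
    core_pos: int = 0
    left_truncated: bool = False   # hit the chromosome end still above cutoff
    right_truncated: bool = False


def _identical_pairs(h: np.ndarray) -> int:
    """Number of pairs of identical rows of a binary matrix."""
    _, counts = np.unique(h, axis=0, return_counts=True)
    return int((counts * (counts - 1) // 2).sum())


def ehhs_decay(
    hs: HaplotypeSet,
    core: int,
    pop: str,
    cutoff: float = 0.05,
    max_gap_bp: int = 200_000,
) -> EhhDecay:
    """Site-EHH decay curve from a core SNP outward in both directions.

    The curve is extended until EHHS drops below ``cutoff`` (the first
    sub-cutoff point is kept, terminating the flank) or an inter-marker
    gap exceeds ``max_gap_bp``; a flank that reaches the chromosome end
    with EHHS still >= cutoff is flagged truncated.
    """
    rows = hs.population_rows(pop)
    if rows.size < 2:
        raise ValueError(f"fewer than 2 haplotypes in population {pop!r}")
    chrom = hs.markers.loc[core, "chrom"]
    in_chrom = np.flatnonzero((hs.markers["chrom"] == chrom).to_numpy())
    h = hs.haplotypes[np.ix_(rows, in_chrom)]
    pos = hs.markers["pos_bp"].to_numpy()[in_chrom]
    c = int(np.flatnonzero(in_chrom == core)[0])

    denom = _identical_pairs(h[:, [c]])
    if denom < 1:
        raise ValueError("no identical haplotype pair at the core site")

    flanks = {}
    for direction in (-1, 1):
        positions, values = [], []
        truncated = False
        prev_pos = pos[c]
        prev_ehhs = 1.0
        j = c + direction
        while 0 <= j < h.shape[1]:
            if abs(int(pos[j]) - int(prev_pos)) > max_gap_bp:
                break
            span = h[:, min(c, j): max(c, j) + 1]
            ehhs = _identical_pairs(span) / denom
            positions.append(int(pos[j]))
            values.append(ehhs)
            if ehhs < cutoff:
                break
            prev_pos = pos[j]
            prev_ehhs = ehhs
            j += direction
        else:
            truncated = prev_ehhs >= cutoff
        flanks[direction] = (
            np.asarray(positions, dtype=np.int64),
            np.asarray(values, dtype=float),
            truncated,
        )

    return EhhDecay(
        core_index=core,
        core_pos=int(pos[c]),
        left_pos=flanks[-1][0],
        left_ehhs=flanks[-1][1],
        right_pos=flanks[1][0],
        right_ehhs=flanks[1][1],
        left_truncated=flanks[-1][2],
        right_truncated=flanks[1][2],
    )


def integrate_ies(decay: EhhDecay) -> float:
    """Trapezoidal integral of EHHS over physical distance, both flanks.

    Each flank starts at the core (EHHS = 1 by definition) and runs to its
    truncation point.
    """
    total = 0.0
    for positions, values in (
        (decay.left_pos, decay.left_ehhs),
        (decay.right_pos, decay.right_ehhs),
    ):
        prev_pos, prev_val = decay.core_pos, 1.0
        for p, v in zip(positions, values):
            total += 0.5 * (prev_val + v) * abs(int(p) - int(prev_pos))
            prev_pos, prev_val = p, v
    return total


# ---------------------------------------------------------------------------
# Genome scan
# ---------------------------------------------------------------------------

@dataclass
class XpehhResult:
    """Per-SNP XPEHH track with p/q values and direction calls."""

    table: pd.DataFrame
    pop_a: str = GROUP_NS   # numerator population (positive scores)
    pop_b: str = GROUP_SJ   # denominator population (negative scores)
    fdr_level: float = 0.05
    n_excluded: int = 0
    notes: dict = field(default_factory=dict)

    @property
    def significant_ids(self) -> set:
        return set(self.table.loc[self.table["significant"], "marker_id"])


def xpehh_raw(
    hs: HaplotypeSet,
    pop_a: str = GROUP_NS,
    pop_b: str = GROUP_SJ,
    cutoff: float = 0.05,
    max_gap_bp: int = 200_000,
) -> pd.DataFrame:
    """Unstandardized ln(iES_a / iES_b) at every core SNP.

    Cores where either population's iES is zero, has no identical core
    pair, or whose decay is truncated by a chromosome end are returned as
    NaN with an ``excluded`` flag (they stay out of standardization).
    """
    markers = hs.markers
    m = len(markers)
    raw = np.full(m, np.nan)
    excluded = np.zeros(m, dtype=bool)
    for pop in (pop_a, pop_b):
        if hs.population_rows(pop).size < 2:
            raise ValueError(f"population {pop!r} has fewer than 2 haplotypes")
    if (hs.haplotypes == MISSING).any():
        raise ValueError("run filter_haplotypes first: missing calls present")

    chrom_codes = markers["chrom"].to_numpy()
    pos_all = markers["pos_bp"].to_numpy(dtype=np.int64)
    rows_a = hs.population_rows(pop_a)
    rows_b = hs.population_rows(pop_b)
    for chrom in pd.unique(chrom_codes):
        idx = np.flatnonzero(chrom_codes == chrom)
        pos = np.ascontiguousarray(pos_all[idx])
        ies = {}
        flags = {}
        for key, rows in (("a", rows_a), ("b", rows_b)):
            h = np.ascontiguousarray(hs.haplotypes[np.ix_(rows, idx)])
            ies[key], flags_end, valid = scan_site_ies(
                h, pos, float(cutoff), int(max_gap_bp)
            )
            flags[key] = flags_end | ~valid | (ies[key] <= 0)
        bad = flags["a"] | flags["b"]
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = np.log(ies["a"] / ies["b"])
        vals[bad] = np.nan
        raw[idx] = vals
        excluded[idx] = bad

    return pd.DataFrame(
        {
            "marker_id": markers["marker_id"],
            "chrom": markers["chrom"],
            "pos_bp": markers["pos_bp"],
            "raw_lnratio": raw,
            "excluded": excluded,
        }
    )


def standardize(raw: np.ndarray) -> np.ndarray:
    """Genome-wide z-standardization over non-missing values."""
    raw = np.asarray(raw, dtype=float)
    ok = ~np.isnan(raw)
    if ok.sum() < 2:
        raise ValueError("need at least 2 scores to standardize")
    mu = raw[ok].mean()
    sd = raw[ok].std()
    if sd == 0:
        raise ValueError("zero variance: cannot standardize")
    z = np.full_like(raw, np.nan)
    z[ok] = (raw[ok] - mu) / sd
    return z


def p_xpehh(z, max_log10_p: float = DEFAULT_MAX_LOG10_P):
    """Two-sided -log10 p for a standardized score via the Gaussian CDF.

    Computes -log10(1 - 2|Phi(z) - 1/2|) = -log10(2 Phi(-|z|)); values
    beyond the floating-point tail are capped at ``max_log10_p``.
    """
    z = np.asarray(z, dtype=float)
    with np.errstate(divide="ignore"):
        p_two = 2.0 * norm.sf(np.abs(z))
        out = np.where(p_two > 0, -np.log10(np.where(p_two > 0, p_two, 1.0)),
                       max_log10_p)
    out = np.minimum(out, max_log10_p)
    out = np.where(np.isnan(z), np.nan, out)
    return float(out) if out.ndim == 0 else out


def bh_fdr(p_log10: np.ndarray, q_level: float = 0.05):
    """Benjamini-Hochberg step-up on -log10-scale p-values.

    Returns ``(q, significant)`` on the probability scale, with the usual
    monotonicity enforcement; NaN inputs stay NaN and are not counted.
    """
    p_log10 = np.asarray(p_log10, dtype=float)
    if p_log10.size == 0:
        raise ValueError("empty p-value vector")
    ok = ~np.isnan(p_log10)
    q = np.full_like(p_log10, np.nan)
    sig = np.zeros(p_log10.shape, dtype=bool)
    if ok.any():
        p = np.power(10.0, -p_log10[ok])
        rej, q_ok, _, _ = multipletests(p, alpha=q_level, method="fdr_bh")
        q[ok] = q_ok
        sig[ok] = q_ok <= q_level
    return q, sig


def xpehh_scan(
    hs: HaplotypeSet,
    pop_a: str = GROUP_NS,
    pop_b: str = GROUP_SJ,
    cutoff: float = 0.05,
    max_gap_bp: int = 200_000,
    fdr_level: float = 0.05,
    z_abs_significance: float = 4.0,
) -> XpehhResult:
    """Full haplotype scan: raw score, z, -log10 p, BH q, direction.

    ``direction`` is ``pop_a`` where z > 0 and ``pop_b`` where z < 0.
    ``significant`` is the primary BH-FDR call; ``significant_z4`` is the
    alternative fixed |z| >= ``z_abs_significance`` rule.
    """
    table = xpehh_raw(hs, pop_a, pop_b, cutoff, max_gap_bp)
    n_excluded = int(table["excluded"].sum())
    if n_excluded:
        warnings.warn(
            f"{n_excluded} cores excluded from standardization "
            "(chromosome-end truncation or undefined iES)"
        )
    z = standardize(table["raw_lnratio"].to_numpy())
    p = p_xpehh(z)
    q, sig = bh_fdr(p, fdr_level)
    table = table.assign(
        z=z,
        p_log10=p,
        q=q,
        significant=sig,
        significant_z4=np.abs(np.nan_to_num(z)) >= z_abs_significance,
        direction=np.where(np.isnan(z), "", np.where(z > 0, pop_a, pop_b)),
    )
    return XpehhResult(
        table=table,
        pop_a=pop_a,
        pop_b=pop_b,
        fdr_level=fdr_level,
        n_excluded=n_excluded,
    )
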