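"""Candidate selection regions: construction from significant SNPs,
F_ST/XPEHH concordance, gene annotation from GFF3, enrichment, QTL overlap.

A candidate region is the union of +/- ``pad_bp`` (default 250 kb) windows
around haplotype-scan-significant SNPs, merged per chromosome, flagged
concordant when it also contains at least one F_ST-significant SNP.
Coordinates are 1-based inclusive internally; BED import/export converts
to and from 0-based half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

#: Controlled gene biotype vocabulary for annotation tallies.
BIOTYPES = (
    "protein_coding", "pseudogene", "lncRNA", "snoRNA", "miRNA",
    "miscRNA", "snRNA",
)

# Ensembl spellings folded into the vocabulary above
_BIOTYPE_ALIASES = {"misc_RNA": "miscRNA", "lincRNA": "lncRNA"}


@dataclass
class CandidateRegion:
    chrom: str
    start_bp: int
    end_bp: int
    source_snps: list = field(default_factory=list)
    direction: str | None = None
    min_q: float | None = None
    max_fst_overlap: float | None = None
    concordant: bool = False
    genes: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.start_bp < 1 or self.start_bp > self.end_bp:
            raise ValueError("invalid region bounds")

    @property
    def length_kb(self) -> int:
        return region_length_kb(self)


def region_length_kb(region) -> int:
    """Region length in kb rounded to the nearest integer.

    Accepts a :class:`CandidateRegion` or a ``(start_bp, end_bp)`` pair.
    """
    if isinstance(region, CandidateRegion):
        start, end = region.start_bp, region.end_bp
    else:
        start, end = region
    return int(round((end - start) / 1000.0))


def build_regions(
    snps: pd.DataFrame,
    pad_bp: int = 250_000,
    direction: str | None = None,
) -> list[CandidateRegion]:
    """Merge +/- ``pad_bp`` windows around significant SNPs into regions.

    ``snps`` needs columns ``chrom`` and ``pos_bp`` (optionally
    ``marker_id`` and ``q``), sorted or not. Windows are clamped at 1,
    and overlapping or touching windows on a chromosome merge; per-region
    provenance (source SNP ids, lowest q) is retained.
    """
    regions: list[CandidateRegion] = []
    if len(snps) == 0:
        return regions
    snps = snps.sort_values(["chrom", "pos_bp"])
    for chrom, sub in snps.groupby("chrom", sort=False):
        current = None
        for _, row in sub.iterrows():
            pos = int(row["pos_bp"])
            lo = max(1, pos - pad_bp)
            hi = pos + pad_bp
            sid = row.get("marker_id", f"{chrom}:{pos}")
            q = row.get("q", np.nan)
            if current is not None and lo <= current.end_bp + 1:
                current.end_bp = max(current.end_bp, hi)
                current.source_snps.append(sid)
                if not np.isnan(q):
                    current.min_q = (
                        q if current.min_q is None else min(current.min_q, q)
                    )
            else:
                current = CandidateRegion(
                    chrom=str(chrom), start_bp=lo, end_bp=hi,
                    source_snps=[sid], direction=direction,
                    min_q=None if np.isnan(q) else float(q),
                )
                regions.append(current)
    return regions


def concordance(
    regions: list[CandidateRegion], fst_result
) -> tuple[list[CandidateRegion], float]:
    """Flag regions containing at least one F_ST-significant SNP.

    Sets ``concordant`` and ``max_fst_overlap`` (the highest significant
    F_ST value inside the region, absent otherwise) and returns the
    concordance rate over the region list.
    """
    sig = fst_result.table[fst_result.table["significant"]]
    for region in regions:
        inside = sig[
            (sig["chrom"].astype(str) == str(region.chrom))
            & (sig["pos_bp"] >= region.start_bp)
            & (sig["pos_bp"] <= region.end_bp)
        ]
        region.concordant = len(inside) > 0
        region.max_fst_overlap = (
            float(inside["fst"].max()) if len(inside) else None
        )
    rate = (
        float(np.mean([r.concordant for r in regions])) if regions else float("nan")
    )
    return regions, rate


# ---------------------------------------------------------------------------
# Gene annotation (GFF3)
# ---------------------------------------------------------------------------

_GENE_FEATURES = {"gene", "ncRNA_gene", "pseudogene"}


def read_gff3_genes(path: str | Path, strict: bool = False) -> pd.DataFrame:
    """Extract gene-level records (with biotype) from a GFF3 file.

    Malformed lines are skipped with a warning in lenient mode and raise
    in strict mode. Attribute parsing goes through gffutils.
    """
    from gffutils.feature import feature_from_line

    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                if strict:
                    raise ValueError(f"malformed GFF3 line {lineno}")
                warnings.warn(f"skipping malformed GFF3 line {lineno}")
                continue
            if fields[2] not in _GENE_FEATURES:
                continue
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # malformed attributes etc.
                if strict:
                    raise ValueError(f"malformed GFF3 line {lineno}: {exc}")
                warnings.warn(f"skipping malformed GFF3 line {lineno}")
                continue
            attr = feat.attributes
            biotype = (attr.get("biotype") or attr.get("gene_biotype") or [""])[0]
            biotype = _BIOTYPE_ALIASES.get(biotype, biotype)
            gene_id = (attr.get("gene_id") or attr.get("ID") or [""])[0]
            gene_id = gene_id.removeprefix("gene:")
            symbol = (attr.get("Name") or [gene_id])[0]
            rows.append(
                {
                    "gene_id": gene_id,
                    "symbol": symbol,
                    "biotype": biotype,
                    "chrom": str(feat.seqid),
                    "start": int(feat.start),
                    "end": int(feat.end),
                    "strand": feat.strand,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "symbol", "biotype", "chrom", "start", "end", "strand"],
    )


def annotate_genes(
    regions: list[CandidateRegion],
    gff3: str | Path | pd.DataFrame,
    strict: bool = False,
) -> tuple[list[CandidateRegion], pd.Series]:
    """Attach genes overlapping each region (any overlap, inclusive coords).

    Returns the regions (with ``genes`` filled with gene_ids) and a tally
    of gene biotypes over all regions.
    """
    genes = (
        gff3 if isinstance(gff3, pd.DataFrame) else read_gff3_genes(gff3, strict)
    )
    hit_ids = []
    for region in regions:
        inside = genes[
            (genes["chrom"].astype(str) == str(region.chrom))
            & (genes["start"] <= region.end_bp)
            & (genes["end"] >= region.start_bp)
        ]
        region.genes = inside["gene_id"].tolist()
        hit_ids.extend(region.genes)
    tally = (
        genes[genes["gene_id"].isin(set(hit_ids))]["biotype"]
        .value_counts()
        .reindex(BIOTYPES, fill_value=0)
    )
    return regions, tally


# ---------------------------------------------------------------------------
# Enrichment and QTL overlap
# ---------------------------------------------------------------------------

def enrichment_test(
    hit_genes: set, background: set, term_map: dict
) -> pd.DataFrame:
    """Database-agnostic fold enrichment with hypergeometric upper tail.

    For a term with K background genes of which k are hits, among n hits
    from N background genes: fold = (k/n)/(K/N) and
    p = P(X >= k), X ~ Hypergeom(N, K, n). Raw p-values by default (the
    optional BH column is adjusted across the supplied terms).
    """
    hit_genes, background = set(hit_genes), set(background)
    if not background:
        raise ValueError("empty background")
    if not hit_genes <= background:
        raise ValueError("hit genes must be a subset of the background")
    n, n_bg = len(hit_genes), len(background)
    rows = []
    for term, genes in term_map.items():
        genes = set(genes) & background
        k_term = len(genes)
        k_hit = len(genes & hit_genes)
        fold = (k_hit / n) / (k_term / n_bg) if k_term and n else 0.0
        p = float(hypergeom.sf(k_hit - 1, n_bg, k_term, n)) if k_term else 1.0
        rows.append(
            {"term": term, "n_term": k_term, "n_hit": k_hit,
             "fold_enrichment": fold, "p_raw": p}
        )
    out = pd.DataFrame(rows)
    if len(out):
        from statsmodels.stats.multitest import multipletests

        out["q_bh"] = multipletests(out["p_raw"], method="fdr_bh")[1]
    return out


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED file into 1-based inclusive intervals."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed BED line {lineno}")
            name = fields[3] if len(fields) > 3 else f"interval_{lineno}"
            rows.append(
                {
                    "chrom": fields[0],
                    "start_bp": int(fields[1]) + 1,  # 0-based half-open -> 1-based
                    "end_bp": int(fields[2]),
                    "label": name,
                }
            )
    return pd.DataFrame(rows, columns=["chrom", "start_bp", "end_bp", "label"])


def qtl_overlap(
    regions: list[CandidateRegion], qtl_bed: str | Path | pd.DataFrame
) -> pd.DataFrame:
    """Report user-supplied (QTL) intervals overlapping each region."""
    qtl = qtl_bed if isinstance(qtl_bed, pd.DataFrame) else read_bed(qtl_bed)
    rows = []
    for i, region in enumerate(regions):
        hits = qtl[
            (qtl["chrom"].astype(str) == str(region.chrom))
            & (qtl["start_bp"] <= region.end_bp)
            & (qtl["end_bp"] >= region.start_bp)
        ]
        for _, q in hits.iterrows():
            rows.append(
                {
                    "region_index": i,
                    "chrom": region.chrom,
                    "region_start": region.start_bp,
                    "region_end": region.end_bp,
                    "qtl_label": q["label"],
                    "qtl_start": q["start_bp"],
                    "qtl_end": q["end_bp"],
                }
            )
    return pd.DataFrame(
        rows,
        columns=["region_index", "chrom", "region_start", "region_end",
                 "qtl_label", "qtl_start", "qtl_end"],
    )


def regions_to_frame(regions: list[CandidateRegion]) -> pd.DataFrame:
    """Region list as a table mirroring the published region-report layout."""
    return pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "start_bp": r.start_bp,
                "end_bp": r.end_bp,
                "length_kb": r.length_kb,
                "direction": r.direction,
                "lowest_adjusted_p": r.min_q,
                "highest_fst": r.max_fst_overlap,
                "concordant": r.concordant,
                "n_source_snps": len(r.source_snps),
                "n_genes": len(r.genes),
            }
            for r in regions
        ]
    )


def write_regions_bed(regions: list[CandidateRegion], path: str | Path) -> None:
    """Export regions as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for r in regions:
            name = r.direction or "region"
            fh.write(f"{r.chrom}\t{r.start_bp - 1}\t{r.end_bp}\t{name}\n")


def load_reference_regions() -> pd.DataFrame:
    """Published candidate regions of the Swedish Warmblood SJ/NS cohort.

    Coordinates and printed lengths of the reported XPEHH regions (both
    directions), used as worked examples for the region-geometry
    operations. ``length_consistent`` is 0 for the one row whose printed
    length does not match its own coordinates.
    """
    with resources.files("divscan.data").joinpath("swb_regions.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
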