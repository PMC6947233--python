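"""Readers and writers for PLINK 1.9 binary triples, phased VCF, and the
sample table, plus EBV-based group assignment and pedigree blood fractions.

Dosage orientation: on load, the .bim allele-1 (A1) column is taken as the
alternate allele, so dosages count A1 copies. This makes downstream allele
frequencies and F_ST invariant to which allele the genotyping platform
labelled first.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    GROUP_NS,
    GROUP_SJ,
    GROUP_UNASSIGNED,
    MISSING,
    GenotypeDataset,
    HaplotypeSet,
    validate_marker_map,
)

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # SNP-major PLINK 1.9 header

# 2-bit PLINK codes -> A1 dosage (alt orientation): 00=hom A1, 01=missing,
# 10=het, 11=hom A2.
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


class PlinkFormatError(ValueError):
    pass


class VcfFormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# PLINK binary triple
# ---------------------------------------------------------------------------

def read_plink(path_prefix: str | Path) -> GenotypeDataset:
    """Read a ``.bed``/``.bim``/``.fam`` triple into a :class:`GenotypeDataset`.

    Marker order is preserved; genotype values are A1 (= alt) dosages.
    """
    prefix = Path(path_prefix)
    bed, bim, fam = (prefix.with_suffix(s) for s in (".bed", ".bim", ".fam"))
    for p in (bed, bim, fam):
        if not p.exists():
            raise FileNotFoundError(f"missing PLINK member: {p}")

    bim_df = pd.read_csv(
        bim, sep=r"\s+", header=None,
        names=["chrom", "marker_id", "cm", "pos_bp", "a1", "a2"],
        dtype={"chrom": str, "marker_id": str, "a1": str, "a2": str},
    )
    fam_df = pd.read_csv(
        fam, sep=r"\s+", header=None,
        names=["fid", "sample_id", "sire_id", "dam_id", "sex", "phenotype"],
        dtype={"fid": str, "sample_id": str, "sire_id": str, "dam_id": str},
    )
    n, m = len(fam_df), len(bim_df)

    raw = bed.read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise PlinkFormatError(f"{bed}: bad magic bytes (not SNP-major PLINK 1.9)")
    bytes_per_snp = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != bytes_per_snp * m:
        raise PlinkFormatError(
            f"{bed}: {body.size} data bytes, expected {bytes_per_snp * m} "
            f"for {n} samples x {m} markers"
        )
    body = body.reshape(m, bytes_per_snp)
    # unpack 2-bit codes, little end first within each byte
    codes = np.stack(
        [(body >> shift) & 0b11 for shift in (0, 2, 4, 6)], axis=-1
    ).reshape(m, -1)[:, :n]
    genotypes = _CODE_TO_DOSAGE[codes].T  # (n, m)

    markers = pd.DataFrame(
        {
            "marker_id": bim_df["marker_id"],
            "chrom": bim_df["chrom"],
            "pos_bp": bim_df["pos_bp"].astype(np.int64),
            "allele_ref": bim_df["a2"],
            "allele_alt": bim_df["a1"],
        }
    )
    samples = fam_df[["sample_id", "sire_id", "dam_id", "sex"]].copy()
    return GenotypeDataset(genotypes, markers, samples)


def write_plink(ds: GenotypeDataset, path_prefix: str | Path) -> None:
    """Write a :class:`GenotypeDataset` as a PLINK 1.9 SNP-major triple."""
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = ds.genotypes.shape

    code = np.empty((m, n), dtype=np.uint8)
    g = ds.genotypes.T
    for dosage, c in _DOSAGE_TO_CODE.items():
        code[g == dosage] = c
    pad = (-n) % 4
    if pad:
        code = np.concatenate(
            [code, np.zeros((m, pad), dtype=np.uint8)], axis=1
        )
    quads = code.reshape(m, -1, 4)
    packed = (
        quads[:, :, 0]
        | (quads[:, :, 1] << 2)
        | (quads[:, :, 2] << 4)
        | (quads[:, :, 3] << 6)
    ).astype(np.uint8)
    prefix.with_suffix(".bed").write_bytes(_BED_MAGIC + packed.tobytes())

    mk = ds.markers
    bim = pd.DataFrame(
        {
            "chrom": mk["chrom"],
            "marker_id": mk["marker_id"],
            "cm": 0,
            "pos_bp": mk["pos_bp"],
            "a1": mk["allele_alt"],
            "a2": mk["allele_ref"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)

    sm = ds.samples
    fam = pd.DataFrame(
        {
            "fid": sm.get("fid", pd.Series(["0"] * n)),
            "sample_id": sm["sample_id"],
            "sire_id": sm.get("sire_id", pd.Series(["0"] * n)).fillna("0"),
            "dam_id": sm.get("dam_id", pd.Series(["0"] * n)).fillna("0"),
            "sex": sm.get("sex", pd.Series([0] * n)).fillna(0),
            "phenotype": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Phased VCF
# ---------------------------------------------------------------------------

def read_phased_vcf(
    path: str | Path,
    pop_of: dict | None = None,
    strict: bool = True,
) -> HaplotypeSet:
    """Read phased biallelic genotypes from a VCF into a :class:`HaplotypeSet`.

    Rows ``2i`` and ``2i+1`` hold the two haplotypes of sample ``i``. In
    strict mode an unphased GT or a non-biallelic record raises
    :class:`VcfFormatError`; otherwise offending records are skipped with a
    warning.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    n = len(sample_ids)

    rows: list[np.ndarray] = []
    records: list[tuple] = []
    for var in vcf:
        if len(var.ALT) != 1:
            if strict:
                raise VcfFormatError(
                    f"non-biallelic record at {var.CHROM}:{var.POS}"
                )
            warnings.warn(f"skipping non-biallelic record {var.CHROM}:{var.POS}")
            continue
        gts = var.genotypes  # [a0, a1, phased] per sample
        col = np.empty(2 * n, dtype=np.int8)
        ok = True
        for i, gt in enumerate(gts):
            a0, a1, phased = gt[0], gt[1], gt[-1]
            if not phased and not (a0 < 0 and a1 < 0):
                if strict:
                    raise VcfFormatError(
                        f"unphased GT for {sample_ids[i]} at {var.CHROM}:{var.POS}"
                    )
                ok = False
                break
            col[2 * i] = a0 if a0 >= 0 else MISSING
            col[2 * i + 1] = a1 if a1 >= 0 else MISSING
        if not ok:
            warnings.warn(f"skipping unphased record {var.CHROM}:{var.POS}")
            continue
        rows.append(col)
        records.append((var.ID or f"{var.CHROM}_{var.POS}", var.CHROM, var.POS,
                        var.REF, var.ALT[0]))
    vcf.close()

    markers = pd.DataFrame(
        records, columns=["marker_id", "chrom", "pos_bp", "allele_ref", "allele_alt"]
    )
    haps = (
        np.array(rows, dtype=np.int8).T
        if rows
        else np.empty((2 * n, 0), dtype=np.int8)
    )
    return HaplotypeSet.from_sample_pairs(haps, sample_ids, markers, pop_of)


def write_phased_vcf(hs: HaplotypeSet, path: str | Path) -> None:
    """Write a :class:`HaplotypeSet` as an uncompressed VCF v4.2 with '|' GTs."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    h = hs.haplotypes
    sample_ids = hs.sample_ids
    if h.shape[0] != 2 * len(sample_ids):
        raise ValueError("VCF export requires two haplotype rows per sample")

    def allele_str(a: int) -> str:
        return "." if a == MISSING else str(int(a))

    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, sub in hs.markers.groupby("chrom", sort=False):
            fh.write(
                f"##contig=<ID={chrom},length={int(sub['pos_bp'].max()) + 1}>\n"
            )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(s) for s in hs.sample_ids)
            + "\n"
        )
        for j, mk in hs.markers.iterrows():
            gts = "\t".join(
                f"{allele_str(h[2 * i, j])}|{allele_str(h[2 * i + 1, j])}"
                for i in range(hs.n_samples)
            )
            fh.write(
                f"{mk['chrom']}\t{int(mk['pos_bp'])}\t{mk['marker_id']}\t"
                f"{mk['allele_ref']}\t{mk['allele_alt']}\t.\t.\t.\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Sample table, groups, pedigree
# ---------------------------------------------------------------------------

SAMPLE_TABLE_COLUMNS = [
    "sample_id", "ebv_jump", "ebv_dressage", "sire_id", "dam_id", "tb_flag",
]


def read_sample_table(path: str | Path) -> pd.DataFrame:
    """Read the headered TSV of sample metadata."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str,
                                            "sire_id": str, "dam_id": str})
    if "sample_id" not in df.columns:
        raise ValueError("sample table must have a sample_id column")
    return df


def write_sample_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def assign_groups(samples: pd.DataFrame, threshold: float = 100.0) -> pd.DataFrame:
    """Split samples into SJ / NS on the show-jumping EBV.

    EBV strictly above ``threshold`` (population mean 100) -> SJ, otherwise
    NS; an EBV exactly at the threshold goes to NS so the partition is
    total. Missing EBVs are left ``unassigned`` with a warning.
    """
    out = samples.copy()
    if "ebv_jump" not in out.columns:
        raise ValueError("samples lack ebv_jump")
    ebv = pd.to_numeric(out["ebv_jump"], errors="coerce")
    group = np.where(ebv > threshold, GROUP_SJ, GROUP_NS)
    n_missing = int(ebv.isna().sum())
    if n_missing:
        warnings.warn(f"{n_missing} samples without EBV left unassigned")
        group = np.where(ebv.isna(), GROUP_UNASSIGNED, group)
    out["group"] = group
    return out


def group_counts(samples: pd.DataFrame) -> dict:
    return samples["group"].value_counts().to_dict()


def pedigree_from_table(samples: pd.DataFrame) -> dict:
    """Build a ``sample -> (sire, dam)`` mapping; unknown parents are None."""
    ped = {}
    for _, row in samples.iterrows():
        sire = row.get("sire_id")
        dam = row.get("dam_id")
        ped[row["sample_id"]] = (
            None if pd.isna(sire) or sire in ("0", "", None) else sire,
            None if pd.isna(dam) or dam in ("0", "", None) else dam,
        )
    return ped


def blood_fraction(
    sample_id: str,
    pedigree: dict,
    flagged: set,
    generations: int = 4,
) -> float:
    """Fraction of the genome expected from flagged founders within ``generations``.

    Walks every ancestral path upward; the first flagged ancestor met on a
    path at depth ``d`` contributes ``(1/2)**d`` and the path stops there
    (a flagged ancestor's whole genome share counts once, so the result is
    bounded by 1 and monotone in the flagged set). Unknown ancestors
    contribute 0. Truncated at the given depth.
    """
    if generations < 1:
        raise ValueError("generations must be >= 1")

    def walk(ind, depth: int, lineage: tuple) -> float:
        if ind is None:
            return 0.0
        if ind in lineage:
            raise ValueError(f"pedigree cycle involving {ind}")
        if depth > 0 and ind in flagged:
            return 0.5 ** depth
        if depth == generations:
            return 0.0
        sire, dam = pedigree.get(ind, (None, None))
        return walk(sire, depth + 1, lineage + (ind,)) + walk(
            dam, depth + 1, lineage + (ind,)
        )

    return walk(sample_id, 0, ())
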