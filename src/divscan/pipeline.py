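"""Config-driven orchestration of the full divergence scan.

Stage order mirrors the analysis workflow: QC -> (LD-pruned) population
structure (PCoA, BIC clustering, DAPC) -> per-SNP F_ST scan -> XPEHH
haplotype scan -> concordant candidate regions -> gene/QTL annotation.
Every output table is regenerable from the config and seed alone; the run
log records marker attrition and all effective parameters.
"""

from __future__ import annotations

import json
import logging
import sys
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dio
from . import qc as dqc
from . import structure as dstruct
from . import fst as dfst
from . import xpehh as dxp
from . import regions as dreg
from .datatypes import GROUP_NS, GROUP_SJ, GenotypeDataset, HaplotypeSet

logger = logging.getLogger("divscan")

ALL_STAGES = ("qc", "structure", "fst", "xpehh", "regions", "annotate")


@dataclass
class PipelineConfig:
    # inputs
    plink_prefix: str | None = None
    vcf: str | None = None
    samples: str | None = None
    gff3: str | None = None
    qtl_bed: str | None = None
    # QC
    qc: dqc.QCConfig = field(default_factory=dqc.QCConfig)
    # structure
    k_max: int = 5
    pcs_grid: tuple = (10, 20, 40, 60, 80, 100)
    cv_replicates: int = 30
    # scans
    top_fraction: float = 0.001
    fdr_level: float = 0.05
    pad_bp: int = 250_000
    ehh_cutoff: float = 0.05
    max_gap_bp: int = 200_000
    ebv_threshold: float = 100.0
    # run
    outdir: str = "results/run"
    seed: int = 0
    stages: tuple = ALL_STAGES

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        raw = tomllib.loads(Path(path).read_text())
        cfg = cls()
        for key, val in raw.get("inputs", {}).items():
            setattr(cfg, key, val)
        if "qc" in raw:
            cfg.qc = dqc.QCConfig(**raw["qc"])
        for section in ("structure", "scan", "output", "run"):
            for key, val in raw.get(section, {}).items():
                setattr(cfg, key, tuple(val) if isinstance(val, list) else val)
        for p in ("plink_prefix", "vcf", "samples", "gff3", "qtl_bed"):
            val = getattr(cfg, p)
            if val is not None and p != "plink_prefix" and not Path(val).exists():
                raise FileNotFoundError(f"configured input {p} = {val} not found")
        return cfg


@dataclass
class ScanReport:
    """Bundle of everything a full run produces."""

    qc_report: dqc.QCReport | None = None
    group_summary: pd.DataFrame | None = None
    pcoa: dstruct.PcoaResult | None = None
    bic_table: pd.DataFrame | None = None
    cv_table: pd.DataFrame | None = None
    dapc: dstruct.DapcModel | None = None
    dapc_posteriors: pd.DataFrame | None = None
    self_assignment: float | None = None
    fst: dfst.FstResult | None = None
    xpehh: dxp.XpehhResult | None = None
    regions: list = field(default_factory=list)
    concordance_rate: float | None = None
    biotype_tally: pd.Series | None = None
    qtl_report: pd.DataFrame | None = None
    log: dict = field(default_factory=dict)


def group_summary(samples: pd.DataFrame) -> pd.DataFrame:
    """Per-group means and SDs of the available EBV columns."""
    cols = [c for c in ("ebv_jump", "ebv_dressage") if c in samples.columns]
    rows = []
    for grp, sub in samples.groupby("group"):
        row = {"group": grp, "n": len(sub)}
        for c in cols:
            vals = pd.to_numeric(sub[c], errors="coerce").dropna()
            row[f"{c}_mean"] = float(vals.mean()) if len(vals) else np.nan
            row[f"{c}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def run_scan_from_data(
    ds: GenotypeDataset,
    hs: HaplotypeSet | None,
    cfg: PipelineConfig,
    outdir: Path | None = None,
) -> ScanReport:
    """Execute the pipeline stages on in-memory data.

    ``hs`` may be None when the haplotype stages are not requested. When
    ``outdir`` is given, each stage writes its plot-ready TSVs there.
    """
    rep = ScanReport()
    log = rep.log
    log["seed"] = cfg.seed
    log["n_samples"] = ds.n_samples
    log["n_markers_input"] = ds.n_markers

    samples = dio.assign_groups(ds.samples, cfg.ebv_threshold)
    ds = GenotypeDataset(ds.genotypes, ds.markers, samples)
    labels = samples["group"].to_numpy()
    log["group_counts"] = dio.group_counts(samples)
    rep.group_summary = group_summary(samples)

    if "qc" in cfg.stages:
        ds, rep.qc_report = dqc.apply_qc(ds, cfg.qc)
        log["n_markers_post_qc"] = ds.n_markers
        log["qc_removed"] = {k: len(v) for k, v in rep.qc_report.removed.items()}

    if "structure" in cfg.stages:
        pruned_ids = dqc.ld_prune(ds, cfg.qc)
        pruned = ds.take_markers(ds.marker_index(pruned_ids))
        log["n_markers_post_pruning"] = pruned.n_markers
        sim = dstruct.ibs_similarity(pruned)
        rep.pcoa = dstruct.pcoa(sim)
        rep.bic_table, _ = dstruct.find_clusters_bic(
            pruned, cfg.k_max, n_pcs_kept=min(50, pruned.n_samples - 1),
            seed=cfg.seed,
        )
        max_rank = min(pruned.n_samples - 1, pruned.n_markers)
        grid = sorted({min(p, max_rank - 1) for p in cfg.pcs_grid})
        rep.cv_table, n_pcs = dstruct.dapc_crossvalidate(
            pruned, labels, grid, n_rep=cfg.cv_replicates, seed=cfg.seed
        )
        rep.dapc = dstruct.dapc_fit(pruned, labels, n_pcs)
        post = rep.dapc.posteriors(pruned.genotypes)
        rep.dapc_posteriors = pd.DataFrame(
            post, columns=[str(c) for c in rep.dapc.classes]
        ).assign(sample_id=samples["sample_id"].to_numpy(), true_group=labels)
        pred = rep.dapc.predict(pruned.genotypes)
        rep.self_assignment = float(np.mean(pred == labels))
        log["dapc_n_pcs"] = n_pcs
        log["dapc_self_assignment"] = rep.self_assignment

    if "fst" in cfg.stages:
        rep.fst = dfst.fst_scan(
            ds, labels, cfg.top_fraction, groups=(GROUP_SJ, GROUP_NS)
        )
        log["fst_mean"] = rep.fst.mean
        log["fst_sd"] = rep.fst.sd
        log["fst_threshold"] = rep.fst.threshold
        log["fst_n_significant"] = int(rep.fst.table["significant"].sum())

    if "xpehh" in cfg.stages and hs is not None:
        kept = set(ds.markers["marker_id"])
        col_keep = hs.markers["marker_id"].isin(kept).to_numpy()
        hs_run = HaplotypeSet(
            hs.haplotypes[:, col_keep], hs.carrier,
            hs.markers.loc[col_keep].copy(),
            {sid: grp for sid, grp in zip(samples["sample_id"], labels)},
        )
        hs_run = dxp.filter_haplotypes(hs_run)
        rep.xpehh = dxp.xpehh_scan(
            hs_run,
            cutoff=cfg.ehh_cutoff,
            max_gap_bp=cfg.max_gap_bp,
            fdr_level=cfg.fdr_level,
        )
        log["xpehh_n_significant"] = int(rep.xpehh.table["significant"].sum())
        log["xpehh_n_excluded"] = rep.xpehh.n_excluded

    if "regions" in cfg.stages and rep.xpehh is not None:
        tab = rep.xpehh.table
        rep.regions = []
        for direction in (GROUP_SJ, GROUP_NS):
            sig = tab[tab["significant"] & (tab["direction"] == direction)]
            rep.regions.extend(
                dreg.build_regions(sig, cfg.pad_bp, direction=direction)
            )
        if rep.fst is not None:
            rep.regions, rep.concordance_rate = dreg.concordance(
                rep.regions, rep.fst
            )
        log["n_regions"] = len(rep.regions)
        log["concordance_rate"] = rep.concordance_rate

    if "annotate" in cfg.stages and rep.regions:
        if cfg.gff3:
            rep.regions, rep.biotype_tally = dreg.annotate_genes(
                rep.regions, cfg.gff3
            )
        if cfg.qtl_bed:
            rep.qtl_report = dreg.qtl_overlap(rep.regions, cfg.qtl_bed)

    if outdir is not None:
        _write_outputs(rep, Path(outdir))
    return rep


def run_scan(cfg: PipelineConfig) -> ScanReport:
    """Read the configured inputs and run the requested stages."""
    if cfg.plink_prefix is None:
        raise ValueError("a PLINK prefix input is required")
    ds = dio.read_plink(cfg.plink_prefix)
    if cfg.samples:
        meta = dio.read_sample_table(cfg.samples)
        ds = GenotypeDataset(
            ds.genotypes,
            ds.markers,
            ds.samples[["sample_id"]].merge(meta, on="sample_id", how="left"),
        )
    hs = dio.read_phased_vcf(cfg.vcf) if cfg.vcf else None
    return run_scan_from_data(ds, hs, cfg, Path(cfg.outdir))


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _write_outputs(rep: ScanReport, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    if rep.qc_report is not None:
        _write_tsv(rep.qc_report.to_frame(), outdir / "qc_report.tsv")
    if rep.group_summary is not None:
        _write_tsv(rep.group_summary, outdir / "group_summary.tsv")
    if rep.pcoa is not None:
        k = rep.pcoa.coordinates.shape[1]
        coords = pd.DataFrame(
            rep.pcoa.coordinates, columns=[f"axis_{i + 1}" for i in range(k)]
        )
        _write_tsv(coords, outdir / "pcoa_coordinates.tsv")
        _write_tsv(
            pd.DataFrame(
                {
                    "eigenvalue": rep.pcoa.eigenvalues[:k],
                    "variance_explained": rep.pcoa.variance_explained,
                }
            ),
            outdir / "pcoa_eigenvalues.tsv",
        )
    if rep.bic_table is not None:
        _write_tsv(rep.bic_table, outdir / "bic_table.tsv")
    if rep.cv_table is not None:
        _write_tsv(rep.cv_table, outdir / "dapc_crossvalidation.tsv")
    if rep.dapc_posteriors is not None:
        _write_tsv(rep.dapc_posteriors, outdir / "dapc_posteriors.tsv")
    if rep.fst is not None:
        _write_tsv(rep.fst.table, outdir / "fst_scan.tsv")
    if rep.xpehh is not None:
        _write_tsv(rep.xpehh.table, outdir / "xpehh_scan.tsv")
    if rep.regions:
        _write_tsv(dreg.regions_to_frame(rep.regions), outdir / "regions.tsv")
        dreg.write_regions_bed(rep.regions, outdir / "regions.bed")
    if rep.biotype_tally is not None:
        rep.biotype_tally.rename("n_genes").to_csv(
            outdir / "biotype_tally.tsv", sep="\t"
        )
    if rep.qtl_report is not None:
        _write_tsv(rep.qtl_report, outdir / "qtl_overlap.tsv")
    (outdir / "run_log.json").write_text(json.dumps(rep.log, indent=2) + "\n")


def setup_logging(verbose: bool = True) -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO if verbose else logging.WARNING)
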