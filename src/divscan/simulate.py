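"""Forward Wright-Fisher generator of two diverging subpopulations.

The generator emulates the structure of a genotyped sport-horse cohort:
two subpopulations of diploids split ``split_generations`` ago, tens of
thousands of biallelic autosomal SNPs over several chromosomes, bimodal
pseudo breeding values (EBVs) separating the groups, and optional planted
selective sweeps private to one group.

Procedure: an ancestral pool is initialized with independent per-site
frequencies drawn from a Beta distribution (a mildly bell-shaped spectrum
mimicking array ascertainment), run through ``burnin_generations`` of
random mating with recombination to build up linkage disequilibrium, then
split; each daughter population drifts independently for
``split_generations``. A sweep is a standing variant planted at low
frequency at the split whose target population samples parents with genic
fitness w = 1, 1+s, 1+2s, amplifying the carrier haplotypes (selection +
binomial drift); lost or unestablished sweeps are retried with fresh
post-split randomness up to a cap. Everything is reproducible from the
single master seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._kernels import evolve_pop
from .datatypes import GROUP_NS, GROUP_SJ, MISSING, GenotypeDataset, HaplotypeSet
from . import io as dio


@dataclass
class SweepSpec:
    """A planted sweep: position, genic selection coefficient, target pop."""

    chrom: str
    pos_bp: int
    s: float
    target_pop: str = GROUP_SJ


@dataclass
class SweepTruth:
    """Ground truth recorded for every configured sweep."""

    chrom: str
    pos_bp: int
    marker_id: str
    s: float
    target_pop: str
    final_freq_target: float
    final_freq_other: float
    established: bool

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic cohort."""

    n_pop: int = 190                 # diploids per subpopulation
    n_chrom: int = 5
    m_snps: int = 2000               # per chromosome
    chrom_len_bp: int = 20_000_000
    # 5e-8 per bp gives ~1 Morgan per 20 Mb toy chromosome, the map length
    # of a typical full-size autosome, keeping haplotype-block scale
    # realistic relative to chromosome ends and SNP spacing
    recomb_rate: float = 5e-8
    split_generations: int = 50
    burnin_generations: int = 50
    ancestral_beta: tuple = (2.0, 2.0)
    sweeps: list = field(default_factory=list)   # list[SweepSpec]
    # The sweep allele arises as a single de novo copy in the ancestral
    # pool and is driven by the same genic selection until it reaches
    # sweep_p0, at which point the populations split: a single-origin
    # (hard) sweep on one haplotype background. p0 is set so the
    # deterministic genic trajectory logit(p_T) ~ logit(p0) + T ln(1+s)
    # reaches ~0.8 at the default s = 0.1, T = 50.
    sweep_p0: float = 0.04
    sweep_min_freq: float = 0.50     # "established" = reached majority
    sweep_establish_max_gen: int = 80
    sweep_max_retries: int = 60
    missing_rate: float = 0.04       # genotype missingness (cohort call rate 0.96)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.missing_rate < 1 and 0 < self.sweep_p0 < 1):
            raise ValueError("rates out of range")
        if self.recomb_rate < 0 or self.split_generations < 0:
            raise ValueError("invalid rate or split time")
        for sw in self.sweeps:
            if not (1 <= sw.pos_bp <= self.chrom_len_bp):
                raise ValueError(f"sweep position {sw.pos_bp} outside chromosome")
            if sw.target_pop not in (GROUP_SJ, GROUP_NS):
                raise ValueError(f"unknown target population {sw.target_pop}")


def _derive_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))


def _establish_sweep(
    h_anc: np.ndarray,
    col: int,
    s: float,
    cfg: "SimConfig",
    pos: np.ndarray,
    offsets: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Drive a de novo single-copy allele at ``col`` up to ``sweep_p0``.

    The allele is injected on one random haplotype of the ancestral pool
    and the pool evolves generation by generation under genic selection;
    attempts that lose the allele (or stall past
    ``sweep_establish_max_gen``) restart from the same pre-injection
    state. Returns the pool at the first generation with frequency
    >= ``sweep_p0``.
    """
    n_hap = h_anc.shape[0]
    idx = np.array([col], dtype=np.int64)
    s_arr = np.array([s], dtype=np.float64)
    for _ in range(cfg.sweep_max_retries):
        h_try = h_anc.copy()
        h_try[:, col] = 0
        h_try[rng.integers(0, n_hap), col] = 1
        for _gen in range(cfg.sweep_establish_max_gen):
            h_try = evolve_pop(
                h_try, pos, offsets, float(cfg.chrom_len_bp),
                cfg.recomb_rate, 1, idx, s_arr, n_hap // 2, _derive_seed(rng),
            )
            freq = h_try[:, col].mean()
            if freq == 0.0:
                break
            if freq >= cfg.sweep_p0:
                return h_try
    warnings.warn(
        f"sweep allele at column {col} failed to establish after "
        f"{cfg.sweep_max_retries} attempts; planting at p0 on random backgrounds"
    )
    k0 = max(1, int(round(n_hap * cfg.sweep_p0)))
    h_anc = h_anc.copy()
    h_anc[:, col] = 0
    h_anc[rng.choice(n_hap, k0, replace=False), col] = 1
    return h_anc


def _marker_map(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Irregular strictly-increasing positions on each chromosome."""
    frames = []
    for c in range(cfg.n_chrom):
        pos = np.unique(rng.integers(1, cfg.chrom_len_bp + 1, cfg.m_snps * 2))
        while pos.size < cfg.m_snps:  # vanishingly unlikely at default sizes
            extra = rng.integers(1, cfg.chrom_len_bp + 1, cfg.m_snps)
            pos = np.unique(np.concatenate([pos, extra]))
        pos = np.sort(rng.choice(pos, cfg.m_snps, replace=False))
        frames.append(
            pd.DataFrame(
                {
                    "marker_id": [f"snp_{c + 1}_{i + 1}" for i in range(cfg.m_snps)],
                    "chrom": str(c + 1),
                    "pos_bp": pos.astype(np.int64),
                    "allele_ref": "A",
                    "allele_alt": "G",
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate(cfg: SimConfig) -> tuple[HaplotypeSet, GenotypeDataset, list[SweepTruth]]:
    """Run the generator; returns phased haplotypes, genotypes and truth.

    The haplotype set is complete (phasing upstream of the scan is assumed
    to have imputed missing calls); missingness at ``missing_rate`` is
    applied to the genotype matrix only.
    """
    rng = np.random.default_rng(cfg.seed)
    markers = _marker_map(cfg, rng)
    m_total = len(markers)
    pos = markers["pos_bp"].to_numpy(dtype=np.int64)
    offsets = np.arange(0, (cfg.n_chrom + 1) * cfg.m_snps, cfg.m_snps, dtype=np.int64)

    # Fission model: the ancestral pool holds as many diploids as the two
    # daughter demes combined and splits into them at generation 0.
    n_anc = 2 * cfg.n_pop
    a, b = cfg.ancestral_beta
    p_anc = rng.beta(a, b, m_total)
    h0 = (rng.random((2 * n_anc, m_total)) < p_anc[None, :]).astype(np.int8)

    no_sweep = np.empty(0, dtype=np.int64)
    no_s = np.empty(0, dtype=np.float64)
    h_anc = evolve_pop(
        h0, pos, offsets, float(cfg.chrom_len_bp), cfg.recomb_rate,
        cfg.burnin_generations, no_sweep, no_s, n_anc, _derive_seed(rng),
    ) if cfg.burnin_generations > 0 else h0

    # Establish each sweep allele from a single de novo copy under the
    # same genic selection until it reaches sweep_p0 (hard sweep on one
    # haplotype background), then split.
    sweep_cols = []
    for sw in cfg.sweeps:
        in_chrom = markers.index[markers["chrom"] == sw.chrom].to_numpy()
        if in_chrom.size == 0:
            raise ValueError(f"no markers on chromosome {sw.chrom}")
        col = int(in_chrom[np.argmin(np.abs(pos[in_chrom] - sw.pos_bp))])
        h_anc = _establish_sweep(h_anc, col, sw.s, cfg, pos, offsets, rng)
        sweep_cols.append(col)

    # fission by partition: the two daughter demes are disjoint halves of
    # the ancestral pool, then drift independently for T generations
    perm = rng.permutation(n_anc)
    halves = {GROUP_SJ: perm[: cfg.n_pop], GROUP_NS: perm[cfg.n_pop :]}
    pops = {}
    established = {c: True for c in sweep_cols}
    for pop in (GROUP_SJ, GROUP_NS):
        rows = np.empty(2 * cfg.n_pop, dtype=np.int64)
        rows[0::2] = 2 * halves[pop]
        rows[1::2] = 2 * halves[pop] + 1
        h_start = np.ascontiguousarray(h_anc[rows])
        idx = np.array(
            [c for c, sw in zip(sweep_cols, cfg.sweeps) if sw.target_pop == pop],
            dtype=np.int64,
        )
        s_vals = np.array(
            [sw.s for c, sw in zip(sweep_cols, cfg.sweeps) if sw.target_pop == pop],
            dtype=np.float64,
        )
        for attempt in range(max(1, cfg.sweep_max_retries)):
            h_pop = evolve_pop(
                h_start, pos, offsets, float(cfg.chrom_len_bp), cfg.recomb_rate,
                cfg.split_generations, idx, s_vals, cfg.n_pop, _derive_seed(rng),
            )
            if idx.size == 0:
                break
            freqs = h_pop[:, idx].mean(axis=0)
            if np.all(freqs >= cfg.sweep_min_freq):
                break
        else:
            warnings.warn(
                f"sweep in {pop} not established after "
                f"{cfg.sweep_max_retries} retries (freqs {freqs})"
            )
            for c in idx:
                established[int(c)] = False
        pops[pop] = h_pop

    sample_ids = [f"{GROUP_SJ}_{i + 1:04d}" for i in range(cfg.n_pop)] + [
        f"{GROUP_NS}_{i + 1:04d}" for i in range(cfg.n_pop)
    ]
    pop_true = [GROUP_SJ] * cfg.n_pop + [GROUP_NS] * cfg.n_pop
    pop_of = dict(zip(sample_ids, pop_true))
    haps = np.vstack([pops[GROUP_SJ], pops[GROUP_NS]])
    hs = HaplotypeSet.from_sample_pairs(haps, sample_ids, markers, pop_of)

    truths = []
    for col, sw in zip(sweep_cols, cfg.sweeps):
        target, other = (
            (GROUP_SJ, GROUP_NS) if sw.target_pop == GROUP_SJ else (GROUP_NS, GROUP_SJ)
        )
        truths.append(
            SweepTruth(
                chrom=sw.chrom,
                pos_bp=int(pos[col]),
                marker_id=markers.loc[col, "marker_id"],
                s=sw.s,
                target_pop=sw.target_pop,
                final_freq_target=float(pops[target][:, col].mean()),
                final_freq_other=float(pops[other][:, col].mean()),
                established=established[col],
            )
        )

    samples = pd.DataFrame({"sample_id": sample_ids, "pop_true": pop_true})
    ebv = make_pseudo_ebvs(np.asarray(pop_true), seed=_derive_seed(rng))
    samples["ebv_jump"] = ebv["ebv_jump"].to_numpy()
    samples["ebv_dressage"] = ebv["ebv_dressage"].to_numpy()
    ds = hs.to_genotypes(samples)
    if cfg.missing_rate > 0:
        mask = rng.random(ds.genotypes.shape) < cfg.missing_rate
        g = ds.genotypes.copy()
        g[mask] = MISSING
        ds = GenotypeDataset(g, ds.markers, ds.samples)
    return hs, ds, truths


def make_pseudo_ebvs(
    labels: np.ndarray,
    mean_sj: float = 125.0,
    sd_sj: float = 13.4,
    mean_ns: float = 77.0,
    sd_ns: float = 11.3,
    mean_dressage_sj: float = 94.0,
    sd_dressage_sj: float = 10.2,
    mean_dressage_ns: float = 119.0,
    sd_dressage_ns: float = 21.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Gaussian pseudo-EBVs per group, bimodal over the cohort.

    Defaults reproduce the cohort summary: show-jumping EBV means 125 (SD
    13.4) for SJ and 77 (SD 11.3) for NS, with the dressage EBV means
    mirrored the opposite way.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    is_sj = labels == GROUP_SJ
    jump = np.where(
        is_sj,
        rng.normal(mean_sj, sd_sj, labels.size),
        rng.normal(mean_ns, sd_ns, labels.size),
    )
    dressage = np.where(
        is_sj,
        rng.normal(mean_dressage_sj, sd_dressage_sj, labels.size),
        rng.normal(mean_dressage_ns, sd_dressage_ns, labels.size),
    )
    return pd.DataFrame({"label": labels, "ebv_jump": jump, "ebv_dressage": dressage})


def write_fixtures(
    hs: HaplotypeSet,
    ds: GenotypeDataset,
    truths: list[SweepTruth],
    outdir: str | Path,
    prefix: str = "cohort",
) -> dict:
    """Write the PLINK triple, phased VCF, sample TSV and truth JSON.

    The file set is sufficient to run the full pipeline with no other
    input; everything parses back into identical matrices.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "plink": outdir / prefix,
        "vcf": outdir / f"{prefix}.vcf",
        "samples": outdir / f"{prefix}.samples.tsv",
        "truth": outdir / f"{prefix}.truth.json",
    }
    dio.write_plink(ds, paths["plink"])
    dio.write_phased_vcf(hs, paths["vcf"])
    dio.write_sample_table(ds.samples, paths["samples"])
    paths["truth"].write_text(
        json.dumps([t.to_dict() for t in truths], indent=2) + "\n"
    )
    return paths
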