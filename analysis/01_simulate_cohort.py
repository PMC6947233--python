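"""Generate the synthetic study cohort: two subpopulations of 190 diploids
split 50 generations ago (5 chromosomes x 2,000 SNPs), bimodal show-jumping
pseudo-EBVs, and one hard selective sweep (s = 0.1) planted in the SJ group
on chromosome 3. Writes the PLINK triple, phased VCF, sample table and
ground-truth JSON that the later analysis steps consume."""

from pathlib import Path

from divscan.simulate import SimConfig, SweepSpec, simulate, write_fixtures

OUT = Path("results/analysis/fixtures")
SEED = 15  # a seed whose sweep establishes at high frequency


def main() -> None:
    cfg = SimConfig(seed=SEED, sweeps=[SweepSpec("3", 10_000_000, 0.1, "SJ")])
    hs, ds, truths = simulate(cfg)
    paths = write_fixtures(hs, ds, truths, OUT)
    print(f"cohort: {ds.n_samples} diploids x {ds.n_markers} SNPs -> {OUT}")
    for t in truths:
        print(
            f"planted sweep {t.marker_id} ({t.chrom}:{t.pos_bp}, "
            f"s={t.s}, target {t.target_pop}): final allele frequency "
            f"{t.final_freq_target:.2f} in {t.target_pop} vs "
            f"{t.final_freq_other:.2f} in the other group"
        )
    print(f"files: {sorted(p.name for p in OUT.iterdir())}")


if __name__ == "__main__":
    main()
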