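"""Marker QC on the simulated cohort: call rate >= 0.90, MAF >= 0.01, and
LD pruning (r^2 > 0.5 in 50-SNP windows sliding by 5) for the structure
analyses. The HWE stage is disabled here: with two strongly diverged demes
pooled, whole-cohort HWE testing removes the most differentiated markers
(Wahlund effect) — see docs/methods.md."""

from pathlib import Path

import pandas as pd

from divscan.io import read_plink, read_sample_table
from divscan.qc import QCConfig, apply_qc, ld_prune

FIX = Path("results/analysis/fixtures")
OUT = Path("results/analysis")


def main() -> None:
    ds = read_plink(FIX / "cohort")
    meta = read_sample_table(FIX / "cohort.samples.tsv")
    ds.samples = ds.samples[["sample_id"]].merge(meta, on="sample_id")

    cfg = QCConfig(hwe_alpha=0)
    ds_qc, report = apply_qc(ds, cfg)
    frame = report.to_frame()
    frame.to_csv(OUT / "qc_report.tsv", sep="\t", index=False)
    print(f"markers in: {report.n_input}")
    for _, row in frame.iterrows():
        print(f"  after {row['stage']}: {row['remaining']} "
              f"({row['removed']} removed)")

    pruned = ld_prune(ds_qc, cfg)
    pd.Series(pruned).to_csv(OUT / "pruned_marker_ids.txt", index=False,
                             header=False)
    print(f"LD pruning for structure analyses: {len(pruned)} markers retained")


if __name__ == "__main__":
    main()
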