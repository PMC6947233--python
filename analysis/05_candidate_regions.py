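"""Candidate selection regions: +-250 kb around BH-significant XPEHH SNPs,
merged per direction, flagged concordant when an F_ST-significant SNP lies
inside, and checked against the simulator's ground truth."""

import json
from pathlib import Path

import pandas as pd

from divscan.fst import FstResult
from divscan.regions import build_regions, concordance, regions_to_frame

FIX = Path("results/analysis/fixtures")
OUT = Path("results/analysis")


def main() -> None:
    xpehh = pd.read_csv(OUT / "xpehh_scan.tsv", sep="\t",
                        dtype={"chrom": str})
    fst_table = pd.read_csv(OUT / "fst_scan.tsv", sep="\t",
                            dtype={"chrom": str})
    fst = FstResult(table=fst_table, threshold=float("nan"),
                    mean=float("nan"), sd=float("nan"))

    regions = []
    for direction in ("SJ", "NS"):
        sig = xpehh[xpehh["significant"] & (xpehh["direction"] == direction)]
        regions.extend(build_regions(sig, pad_bp=250_000, direction=direction))
    regions, rate = concordance(regions, fst)
    frame = regions_to_frame(regions)
    frame.to_csv(OUT / "candidate_regions.tsv", sep="\t", index=False)
    print(f"{len(regions)} candidate regions "
          f"(concordance with F_ST: {100 * rate:.0f}%)"
          if regions else "no candidate regions at FDR 0.05")
    if regions:
        print(frame.to_string(index=False))

    truth = json.loads((FIX / "cohort.truth.json").read_text())
    for t in truth:
        hit = [
            r for r in regions
            if r.chrom == str(t["chrom"])
            and r.start_bp <= t["pos_bp"] <= r.end_bp
            and r.direction == t["target_pop"]
        ]
        verdict = (
            "recovered in a concordant region"
            if hit and hit[0].concordant
            else "recovered (not concordant)" if hit else "NOT recovered"
        )
        print(f"truth sweep {t['chrom']}:{t['pos_bp']} ({t['target_pop']}): "
              f"{verdict}")


if __name__ == "__main__":
    main()
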