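"""Candidate regions, concordance, GFF3 gene annotation, enrichment, QTL."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom, kstest

from divscan.fst import FstResult
from divscan.regions import (
    CandidateRegion,
    annotate_genes,
    build_regions,
    concordance,
    enrichment_test,
    load_reference_regions,
    qtl_overlap,
    read_bed,
    read_gff3_genes,
    region_length_kb,
    regions_to_frame,
    write_regions_bed,
)


def snp_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos_bp", "marker_id", "q"])


class TestBuildRegions:
    def test_single_snp_padding_matches_printed_region(self):
        regions = build_regions(
            snp_frame([("19", 41_709_599, "snp", 0.01)]), pad_bp=250_000
        )
        assert len(regions) == 1
        r = regions[0]
        assert (r.start_bp, r.end_bp) == (41_459_599, 41_959_599)
        assert region_length_kb(r) == 500

    def test_merge_and_left_clamp(self):
        regions = build_regions(
            snp_frame([("1", 100_000, "a", 0.02), ("1", 300_000, "b", 0.01)]),
            pad_bp=250_000,
        )
        assert len(regions) == 1
        assert (regions[0].start_bp, regions[0].end_bp) == (1, 550_000)
        assert regions[0].source_snps == ["a", "b"]
        assert regions[0].min_q == pytest.approx(0.01)

    def test_empty_input(self):
        assert build_regions(snp_frame([])) == []

    def test_chromosomes_not_merged(self):
        regions = build_regions(
            snp_frame([("1", 500_000, "a", 0.1), ("2", 500_000, "b", 0.1)])
        )
        assert len(regions) == 2

    def test_merging_idempotent_and_disjoint(self, rng):
        snps = snp_frame(
            [("3", int(p), f"s{i}", 0.05)
             for i, p in enumerate(np.sort(rng.integers(1, 10**7, 60)))]
        )
        regions = build_regions(snps, pad_bp=100_000)
        again = build_regions(snps, pad_bp=100_000)
        assert [(r.start_bp, r.end_bp) for r in regions] == [
            (r.start_bp, r.end_bp) for r in again
        ]
        for a, b in zip(regions, regions[1:]):
            assert b.start_bp > a.end_bp + 1  # disjoint, non-touching
        # every source SNP lies inside its region
        for r in regions:
            assert all(
                r.start_bp <= snps.set_index("marker_id").loc[s, "pos_bp"]
                <= r.end_bp
                for s in r.source_snps
            )


class TestRegionLength:
    def test_reference_rows_reproduced(self):
        ref = load_reference_regions()
        consistent = ref[ref["length_consistent"] == 1]
        assert len(consistent) == 11
        for _, row in consistent.iterrows():
            assert (
                region_length_kb((row["start_bp"], row["end_bp"]))
                == row["length_kb_printed"]
            )

    def test_degenerate_zero(self):
        assert region_length_kb((100, 100)) == 0

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            CandidateRegion("1", 10, 5)


def fst_result_from(rows):
    table = pd.DataFrame(rows, columns=["marker_id", "chrom", "pos_bp", "fst",
                                        "significant"])
    return FstResult(table=table, threshold=0.12, mean=0.0, sd=0.0)


class TestConcordance:
    def test_overlapping_significant_snp(self):
        regions = [CandidateRegion("7", 1_000, 5_000)]
        fst = fst_result_from([("x", "7", 2_000, 0.16, True)])
        regions, rate = concordance(regions, fst)
        assert regions[0].concordant and regions[0].max_fst_overlap == 0.16
        assert rate == 1.0

    def test_no_overlap_is_na(self):
        regions = [CandidateRegion("7", 1_000, 5_000)]
        fst = fst_result_from(
            [("x", "7", 9_000, 0.5, True), ("y", "7", 3_000, 0.4, False)]
        )
        regions, rate = concordance(regions, fst)
        assert not regions[0].concordant
        assert regions[0].max_fst_overlap is None
        assert rate == 0.0

    def test_rate_over_multiple_regions(self):
        regions = [CandidateRegion("1", 1, 10), CandidateRegion("1", 20, 30)]
        fst = fst_result_from([("a", "1", 5, 0.2, True), ("b", "1", 25, 0.3, True)])
        _, rate = concordance(regions, fst)
        assert rate == 1.0


GFF_HEADER = "##gff-version 3\n"


def gff_line(chrom, start, end, gene_id, biotype, feature="gene"):
    return (
        f"{chrom}\tensembl\t{feature}\t{start}\t{end}\t.\t+\t.\t"
        f"ID=gene:{gene_id};biotype={biotype};Name={gene_id.upper()}\n"
    )


class TestAnnotateGenes:
    def test_overlap_inclusive_boundaries(self, tmp_path):
        gff = tmp_path / "g.gff3"
        gff.write_text(
            GFF_HEADER
            + gff_line("1", 1000, 2000, "inside", "protein_coding")
            + gff_line("1", 3001, 4000, "outside", "protein_coding")
            + gff_line("1", 3000, 4000, "edge", "lncRNA")
        )
        regions = [CandidateRegion("1", 1500, 3000)]
        regions, tally = annotate_genes(regions, gff)
        assert set(regions[0].genes) == {"inside", "edge"}
        assert tally["protein_coding"] == 1 and tally["lncRNA"] == 1

    def test_malformed_line_lenient_vs_strict(self, tmp_path):
        gff = tmp_path / "bad.gff3"
        gff.write_text(
            GFF_HEADER + "1\tonly\tthree\n"
            + gff_line("1", 10, 20, "ok", "miRNA")
        )
        with pytest.warns(UserWarning):
            genes = read_gff3_genes(gff, strict=False)
        assert genes["gene_id"].tolist() == ["ok"]
        with pytest.raises(ValueError):
            read_gff3_genes(gff, strict=True)

    def test_matches_quadratic_overlap_oracle(self, rng, tmp_path):
        genes = []
        for i in range(60):
            start = int(rng.integers(1, 10**6))
            genes.append(("2", start, start + int(rng.integers(100, 50_000)),
                          f"g{i}", "protein_coding"))
        gff = tmp_path / "r.gff3"
        gff.write_text(GFF_HEADER + "".join(gff_line(*g) for g in genes))
        regions = []
        for _ in range(12):
            s = int(rng.integers(1, 10**6))
            regions.append(CandidateRegion("2", s, s + 80_000))
        regions, _ = annotate_genes(regions, gff)
        for r in regions:
            want = {
                gid for c, s, e, gid, _ in genes
                if s <= r.end_bp and e >= r.start_bp
            }
            assert set(r.genes) == want


class TestEnrichment:
    def test_zero_hits(self):
        out = enrichment_test({"a"}, {"a", "b", "c"}, {"t": {"b"}})
        row = out.iloc[0]
        assert row["fold_enrichment"] == 0.0 and row["p_raw"] == 1.0

    def test_worked_example_fold_ten(self):
        background = {f"g{i}" for i in range(20_000)}
        term = {f"g{i}" for i in range(100)}
        hits = {f"g{i}" for i in range(5)} | {f"g{i}" for i in range(10_000, 10_095)}
        out = enrichment_test(hits, background, {"t": term})
        row = out.iloc[0]
        assert row["fold_enrichment"] == pytest.approx(10.0)
        # exact tail-sum oracle
        want = sum(
            hypergeom.pmf(k, 20_000, 100, 100) for k in range(5, 101)
        )
        assert row["p_raw"] == pytest.approx(want, rel=1e-9)

    def test_saturated_term(self):
        background = {f"g{i}" for i in range(50)}
        hits = {f"g{i}" for i in range(10)}
        out = enrichment_test(hits, background, {"t": hits})
        assert out.iloc[0]["fold_enrichment"] == pytest.approx(50 / 10)

    def test_hits_must_be_subset(self):
        with pytest.raises(ValueError):
            enrichment_test({"x"}, {"a"}, {})

    def test_random_terms_yield_uniform_p(self, rng):
        background = [f"g{i}" for i in range(400)]
        hits = set(rng.choice(background, 40, replace=False))
        term_map = {
            f"t{j}": set(rng.choice(background, 25, replace=False))
            for j in range(1000)
        }
        out = enrichment_test(hits, set(background), term_map)
        # mid-p style smoothing for the discrete statistic: draw u in the
        # probability step so uniformity is testable with KS
        k = out["n_hit"].to_numpy()
        p_hi = out["p_raw"].to_numpy()
        p_next = np.array(
            [hypergeom.sf(ki, 400, 25, 40) for ki in k]
        )
        u = p_next + rng.random(len(k)) * (p_hi - p_next)
        assert kstest(u, "uniform").pvalue > 0.01


class TestQtlAndBed:
    def test_region_inside_interval_reported(self, tmp_path):
        bed = tmp_path / "q.bed"
        bed.write_text("5\t999\t5000\tbody_growth\n")
        regions = [CandidateRegion("5", 1_200, 1_400)]
        out = qtl_overlap(regions, bed)
        assert out["qtl_label"].tolist() == ["body_growth"]
        assert out["qtl_start"].iloc[0] == 1000  # 0-based -> 1-based

    def test_disjoint_empty(self, tmp_path):
        bed = tmp_path / "q.bed"
        bed.write_text("5\t10000\t20000\tx\n")
        out = qtl_overlap([CandidateRegion("5", 100, 200)], bed)
        assert out.empty

    def test_matches_bruteforce_intersection(self, rng, tmp_path):
        lines, intervals = [], []
        for i in range(40):
            s = int(rng.integers(0, 10**6))
            e = s + int(rng.integers(1, 100_000))
            lines.append(f"9\t{s}\t{e}\tq{i}\n")
            intervals.append((s + 1, e, f"q{i}"))
        bed = tmp_path / "r.bed"
        bed.write_text("".join(lines))
        regions = [
            CandidateRegion("9", int(p), int(p) + 50_000)
            for p in rng.integers(1, 10**6, 10)
        ]
        out = qtl_overlap(regions, bed)
        got = set(zip(out["region_index"], out["qtl_label"]))
        want = {
            (i, lab)
            for i, r in enumerate(regions)
            for s, e, lab in intervals
            if s <= r.end_bp and e >= r.start_bp
        }
        assert got == want

    def test_bed_round_trip_conversion(self, tmp_path):
        regions = [CandidateRegion("3", 101, 200, direction="SJ")]
        out = tmp_path / "r.bed"
        write_regions_bed(regions, out)
        assert out.read_text() == "3\t100\t200\tSJ\n"
        back = read_bed(out)
        assert (back["start_bp"].iloc[0], back["end_bp"].iloc[0]) == (101, 200)

    def test_malformed_bed_rejected(self, tmp_path):
        bad = tmp_path / "bad.bed"
        bad.write_text("1\t100\n")
        with pytest.raises(ValueError):
            read_bed(bad)


def test_regions_frame_layout():
    regions = [CandidateRegion("8", 10_891_925, 11_400_093, direction="SJ",
                               min_q=0.004, max_fst_overlap=0.13,
                               concordant=True)]
    frame = regions_to_frame(regions)
    row = frame.iloc[0]
    assert row["length_kb"] == 508
    assert row["direction"] == "SJ"
    assert row["highest_fst"] == 0.13 and row["concordant"]
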