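"""Haplotype filtering, EHHS decay, iES, XPEHH, Eq.-style p transform, BH-FDR."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from divscan.datatypes import MISSING, HaplotypeSet
from divscan._kernels import scan_site_ies
from divscan.xpehh import (
    bh_fdr,
    ehhs_decay,
    filter_haplotypes,
    integrate_ies,
    p_xpehh,
    standardize,
    xpehh_raw,
    xpehh_scan,
)

from conftest import make_marker_map, random_haplotypes


# ---------------------------------------------------------------------------
# Brute-force oracles
# ---------------------------------------------------------------------------

def brute_pairs_identical(h):
    """O(n^2 m) count of row pairs identical over all columns."""
    n = h.shape[0]
    return sum(
        1
        for i in range(n)
        for j in range(i + 1, n)
        if np.array_equal(h[i], h[j])
    )


def brute_ehhs_curve(h, pos, core, cutoff, max_gap):
    """Reference EHHS decay + trapezoid iES by direct pair counting."""
    m = h.shape[1]
    denom = brute_pairs_identical(h[:, [core]])
    curves = {}
    total = 0.0
    end_trunc = False
    for direction in (-1, 1):
        xs, ys = [], []
        prev_pos, prev_val = pos[core], 1.0
        j = core + direction
        while 0 <= j < m:
            gap = abs(int(pos[j]) - int(prev_pos))
            if gap > max_gap:
                break
            lo, hi = min(core, j), max(core, j)
            val = brute_pairs_identical(h[:, lo : hi + 1]) / denom
            xs.append(int(pos[j]))
            ys.append(val)
            total += 0.5 * (prev_val + val) * gap
            if val < cutoff:
                break
            prev_pos, prev_val = pos[j], val
            j += direction
        else:
            end_trunc = end_trunc or (prev_val >= cutoff)
        curves[direction] = (xs, ys)
    return curves, total, end_trunc


class TestFilterHaplotypes:
    def base(self):
        h = np.array(
            [[0, 1, 0, 1], [0, 1, 1, 1], [1, MISSING, 0, 0], [1, 0, 0, 0]],
            dtype=np.int8,
        )
        return HaplotypeSet.from_sample_pairs(
            h, ["a", "b"], make_marker_map(4), {"a": "SJ", "b": "NS"}
        )

    def test_row_with_missing_dropped(self):
        out = filter_haplotypes(self.base())
        assert out.haplotypes.shape[0] == 3
        assert out.carrier == ["a", "a", "b"]

    def test_marker_missing_in_survivor_dropped(self):
        hs = self.base()
        hs.haplotypes[0, 2] = MISSING  # row kept? no: row 0 now has missing
        hs.haplotypes[0, 0] = 0
        out = filter_haplotypes(hs)
        assert not (out.haplotypes == MISSING).any()

    def test_random_fixture_fully_complete(self, rng):
        hs = random_haplotypes(rng, n_samples=10, m=30)
        hs.haplotypes[rng.random(hs.haplotypes.shape) < 0.02] = MISSING
        out = filter_haplotypes(hs)
        assert not (out.haplotypes == MISSING).any()
        # rule 1 before rule 2: surviving rows are exactly the complete ones
        complete_rows = ~(hs.haplotypes == MISSING).any(axis=1)
        assert out.haplotypes.shape[0] == int(complete_rows.sum())

    def test_empty_result_raises(self):
        h = np.full((2, 3), MISSING, dtype=np.int8)
        hs = HaplotypeSet.from_sample_pairs(h, ["a"], make_marker_map(3))
        with pytest.raises(ValueError):
            filter_haplotypes(hs)


class TestEhhsDecay:
    def test_identical_haplotypes_stay_at_one(self):
        h = np.tile(np.array([0, 1, 1, 0, 1], dtype=np.int8), (6, 1))
        hs = HaplotypeSet.from_sample_pairs(
            h, ["a", "b", "c"], make_marker_map(5),
            {"a": "SJ", "b": "SJ", "c": "SJ"},
        )
        d = ehhs_decay(hs, 2, "SJ")
        assert np.allclose(d.left_ehhs, 1.0) and np.allclose(d.right_ehhs, 1.0)
        assert d.left_truncated and d.right_truncated

    def test_pair_counting_two_two_split(self):
        # 4 haplotypes monomorphic at core, splitting {2,2} at the next SNP
        h = np.array([[0, 0], [0, 0], [0, 1], [0, 1]], dtype=np.int8)
        hs = HaplotypeSet.from_sample_pairs(
            h, ["a", "b"], make_marker_map(2), {"a": "SJ", "b": "SJ"}
        )
        d = ehhs_decay(hs, 0, "SJ")
        assert d.right_ehhs[0] == pytest.approx(2 / 6)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(10):
            hs = random_haplotypes(rng, n_samples=6, m=25)
            core = int(rng.integers(0, 25))
            d = ehhs_decay(hs, core, "SJ", cutoff=0.05, max_gap_bp=10**9)
            rows = hs.population_rows("SJ")
            curves, total, _ = brute_ehhs_curve(
                hs.haplotypes[rows], hs.markers["pos_bp"].to_numpy(),
                core, 0.05, 10**9,
            )
            assert list(d.left_pos) == curves[-1][0]
            assert np.allclose(d.left_ehhs, curves[-1][1])
            assert np.allclose(d.right_ehhs, curves[1][1])
            assert integrate_ies(d) == pytest.approx(total, abs=1e-9)

    def test_monotone_non_increasing(self, rng):
        for _ in range(5):
            hs = random_haplotypes(rng, n_samples=8, m=30)
            d = ehhs_decay(hs, 15, "NS")
            for vals in (d.left_ehhs, d.right_ehhs):
                assert (np.diff(vals) <= 1e-12).all()
                assert (vals <= 1.0 + 1e-12).all()

    def test_kernel_matches_reference_path(self, rng):
        for _ in range(5):
            hs = random_haplotypes(rng, n_samples=7, m=30)
            rows = hs.population_rows("SJ")
            h = np.ascontiguousarray(hs.haplotypes[rows])
            pos = hs.markers["pos_bp"].to_numpy(dtype=np.int64)
            ies, end_t, valid = scan_site_ies(h, pos, 0.05, 10**9)
            for core in range(30):
                d = ehhs_decay(hs, core, "SJ", 0.05, 10**9)
                want = integrate_ies(d)
                assert ies[core] == pytest.approx(want, abs=1e-9), core
                assert end_t[core] == (d.left_truncated or d.right_truncated)

    def test_too_few_haplotypes(self):
        h = np.array([[0, 1]], dtype=np.int8)
        hs = HaplotypeSet(h, ["a"], make_marker_map(2), {"a": "SJ"})
        with pytest.raises(ValueError):
            ehhs_decay(hs, 0, "SJ")


class TestIntegrateIes:
    def _decay(self, right_pos, right_ehhs, core_pos=0):
        from divscan.xpehh import EhhDecay

        return EhhDecay(
            core_index=0,
            core_pos=core_pos,
            left_pos=np.array([], dtype=np.int64),
            left_ehhs=np.array([]),
            right_pos=np.asarray(right_pos, dtype=np.int64),
            right_ehhs=np.asarray(right_ehhs, dtype=float),
        )

    def test_rectangle(self):
        d = self._decay([10_000], [1.0])
        assert integrate_ies(d) == pytest.approx(10_000)

    def test_triangle(self):
        d = self._decay([1000], [0.0])
        assert integrate_ies(d) == pytest.approx(500)

    def test_zero_support(self):
        d = self._decay([], [])
        assert integrate_ies(d) == 0.0

    def test_matches_trapezoid_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 15))
            pos = np.sort(rng.choice(np.arange(1, 10**6), n, replace=False))
            vals = np.sort(rng.random(n))[::-1]
            d = self._decay(pos, vals, core_pos=0)
            xs = np.concatenate([[0], pos])
            ys = np.concatenate([[1.0], vals])
            assert integrate_ies(d) == pytest.approx(
                np.trapezoid(ys, xs), abs=1e-9
            )


class TestXpehhScore:
    def test_identical_populations_zero(self, rng):
        hs = random_haplotypes(rng, n_samples=8, m=20)
        # make NS haplotypes equal to SJ haplotypes
        hs.haplotypes[8:] = hs.haplotypes[:8]
        tab = xpehh_raw(hs, "NS", "SJ", max_gap_bp=10**9)
        ok = ~tab["excluded"]
        assert np.allclose(tab.loc[ok, "raw_lnratio"], 0.0)

    def test_population_swap_flips_sign(self, rng):
        hs = random_haplotypes(rng, n_samples=8, m=30)
        a = xpehh_raw(hs, "NS", "SJ", max_gap_bp=10**9)
        b = xpehh_raw(hs, "SJ", "NS", max_gap_bp=10**9)
        ok = ~a["excluded"] & ~b["excluded"]
        assert np.allclose(
            a.loc[ok, "raw_lnratio"], -b.loc[ok, "raw_lnratio"], atol=1e-12
        )

    def test_sweep_scores_negative_and_extreme_at_locus(self, sweep_cohort):
        hs, _, truths = sweep_cohort
        tr = truths[0]
        res = xpehh_scan(hs)
        t = res.table
        near = t[(t["chrom"] == tr.chrom)
                 & (abs(t["pos_bp"] - tr.pos_bp) < 1_000_000)]
        assert near["z"].min() < -3  # strong SJ-directed signal
        assert (near.loc[near["z"] < -3, "direction"] == "SJ").all()
        # raw score locally maximal in magnitude around the swept core
        chrom_t = t[t["chrom"] == tr.chrom]
        assert chrom_t["raw_lnratio"].min() == near["raw_lnratio"].min()


class TestStandardize:
    def test_zero_mean_unit_sd(self, rng):
        z = standardize(rng.normal(2, 3, 500))
        assert abs(z.mean()) < 1e-12 and abs(z.std() - 1) < 1e-12

    def test_affine_invariance_and_idempotence(self, rng):
        x = rng.normal(0, 1, 300)
        assert np.allclose(standardize(x), standardize(5 * x - 2))
        assert np.allclose(standardize(standardize(x)), standardize(x))

    def test_two_pass_oracle_with_missing(self, rng):
        x = rng.normal(1, 2, 100)
        x[[3, 50]] = np.nan
        z = standardize(x)
        ok = ~np.isnan(x)
        assert np.allclose(z[ok], (x[ok] - x[ok].mean()) / x[ok].std())
        assert np.isnan(z[3])

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            standardize(np.array([1.0, np.nan]))
        with pytest.raises(ValueError):
            standardize(np.full(10, 3.0))


class TestPTransform:
    def test_zero_maps_to_zero(self):
        assert p_xpehh(0.0) == pytest.approx(0.0, abs=1e-12)

    def test_symmetry(self, rng):
        z = rng.normal(0, 2, 200)
        assert np.allclose(p_xpehh(z), p_xpehh(-z))

    def test_norm_cdf_evaluation(self):
        assert p_xpehh(1.959964) == pytest.approx(1.30103, abs=1e-4)

    def test_matches_direct_formula(self, rng):
        z = rng.normal(0, 1.5, 100)
        want = -np.log10(1.0 - 2.0 * np.abs(norm.cdf(z) - 0.5))
        assert np.allclose(p_xpehh(z), want, atol=1e-10)

    def test_overflow_capped(self):
        assert p_xpehh(60.0) == 300.0


def bh_naive(p, q_level):
    """Definition-based O(m^2) step-up oracle."""
    m = len(p)
    order = np.argsort(p)
    q = np.empty(m)
    for rank0, idx in enumerate(order):
        candidates = [
            p[order[r]] * m / (r + 1) for r in range(rank0, m)
        ]
        q[idx] = min(1.0, min(candidates))
    return q, q <= q_level


class TestBhFdr:
    def test_single_p_unchanged(self):
        q, sig = bh_fdr(np.array([-np.log10(0.03)]), 0.05)
        assert q[0] == pytest.approx(0.03)
        assert sig[0]

    def test_hand_computed_step_up(self):
        p = np.array([0.001, 0.01, 0.02, 0.8])
        q, sig = bh_fdr(-np.log10(p), 0.05)
        assert np.allclose(q, [0.004, 0.02, 0.0266667, 0.8], atol=1e-6)
        assert sig.tolist() == [True, True, True, False]

    def test_matches_naive_oracle(self, rng):
        for _ in range(20):
            p = rng.random(int(rng.integers(2, 40)))
            q, sig = bh_fdr(-np.log10(p), 0.05)
            q_want, sig_want = bh_naive(p, 0.05)
            assert np.allclose(q, q_want, atol=1e-12)
            assert (sig == sig_want).all()

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr(np.array([]))
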