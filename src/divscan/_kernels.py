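"""Numba kernels for the haplotype scan and the forward simulator.

These are performance back-ends only; the public surfaces live in
:mod:`divscan.xpehh` and :mod:`divscan.simulate`, and each kernel has a
plain-Python reference path it is tested against.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _pair_count_step(labels, alleles, counts, code_map, seen, new_labels):
    """Refine haplotype identity classes by one site; return identical pairs.

    ``labels`` holds the current compact class of each haplotype (identity
    over the interval so far, values < n); classes are split by the new
    site's alleles (counting sort over codes label*2+allele) and
    relabelled compactly into ``new_labels``. ``counts``/``code_map`` are
    zeroed scratch arrays of size 2n, ``seen`` of size n; all are left
    zeroed on return.
    """
    n = labels.shape[0]
    n_seen = 0
    for i in range(n):
        code = labels[i] * 2 + alleles[i]
        if counts[code] == 0:
            code_map[code] = n_seen
            seen[n_seen] = code
            n_seen += 1
        counts[code] += 1
        new_labels[i] = code_map[code]
    pairs = 0
    for k in range(n_seen):
        c = counts[seen[k]]
        pairs += c * (c - 1) // 2
        counts[seen[k]] = 0
    return pairs


@njit(cache=True)
def scan_site_ies(h, pos, cutoff, max_gap):
    """Integrated site-EHH (iES) at every core of one chromosome.

    ``h``: (n_hap, m) int8 complete haplotypes of one population;
    ``pos``: (m,) int64 base-pair positions, strictly increasing.

    EHHS(x) = identical pairs over [core..x] / identical pairs at the core,
    extended outward until it falls below ``cutoff`` (that bracketing point
    is kept so the trapezoid reaches it) or an inter-marker gap exceeds
    ``max_gap``. Returns (ies, end_truncated, valid); a core is invalid if
    fewer than one identical pair exists at the core site.
    """
    n_hap, m = h.shape
    ies = np.zeros(m, dtype=np.float64)
    end_trunc = np.zeros(m, dtype=np.bool_)
    valid = np.ones(m, dtype=np.bool_)

    labels = np.empty(n_hap, dtype=np.int64)
    new_labels = np.empty(n_hap, dtype=np.int64)
    counts = np.zeros(2 * n_hap, dtype=np.int64)
    code_map = np.zeros(2 * n_hap, dtype=np.int64)
    seen = np.zeros(n_hap, dtype=np.int64)
    zeros = np.zeros(n_hap, dtype=np.int64)

    for core in range(m):
        # pairs identical at the core site
        denom = _pair_count_step(zeros, h[:, core], counts, code_map, seen,
                                 new_labels)
        if denom < 1:
            valid[core] = False
            continue
        total = 0.0
        for direction in (-1, 1):
            labels[:] = new_labels  # classes at the core
            ehhs_prev = 1.0
            prev_pos = pos[core]
            j = core + direction
            stopped = False
            while 0 <= j < m:
                gap = pos[j] - prev_pos if direction == 1 else prev_pos - pos[j]
                if gap > max_gap:
                    stopped = True
                    break
                pairs = _pair_count_step(labels, h[:, j], counts, code_map,
                                         seen, labels)
                ehhs = pairs / denom
                total += 0.5 * (ehhs_prev + ehhs) * gap
                if ehhs < cutoff:
                    stopped = True
                    break
                ehhs_prev = ehhs
                prev_pos = pos[j]
                j += direction
            if not stopped and ehhs_prev >= cutoff:
                # ran off the chromosome while homozygosity was still high
                end_trunc[core] = True
        ies[core] = total
    return ies, end_trunc, valid


@njit(cache=True)
def evolve_pop(h, pos, chrom_offsets, chrom_len_bp, recomb_rate, n_gen,
               sweep_idx, sweep_s, n_out, seed):
    """Wright-Fisher evolution of one population over ``n_gen`` generations.

    ``h``: (2N, m_total) int8 haplotypes over all chromosomes concatenated;
    ``chrom_offsets``: (n_chrom + 1,) marker-index bounds per chromosome.
    Every generation produces ``n_out`` diploid offspring (pass the parent
    count for constant size; a smaller value models a fission/daughter
    deme). Each offspring draws two parents, fitness-weighted by genic
    selection at the sweep sites (w = prod_k (1 + s_k * dose_k); pass
    empty arrays for neutrality); each gamete picks a random starting
    haplotype per chromosome (independent assortment) and recombines with
    Poisson(recomb_rate * chrom_len_bp) crossovers placed uniformly in
    base pairs. Returns the final haplotype matrix.
    """
    np.random.seed(seed)
    n_hap, m = h.shape
    n_chrom = chrom_offsets.shape[0] - 1
    n_sweeps = sweep_idx.shape[0]
    a = h.copy()
    b = np.empty((2 * n_out, m), dtype=np.int8)

    for _ in range(n_gen):
        n_par = a.shape[0] // 2
        w = np.empty(n_par, dtype=np.float64)
        for i in range(n_par):
            w[i] = 1.0
            for k in range(n_sweeps):
                dose = a[2 * i, sweep_idx[k]] + a[2 * i + 1, sweep_idx[k]]
                w[i] *= 1.0 + sweep_s[k] * dose
        cw = np.cumsum(w)
        tot = cw[n_par - 1]

        for off in range(n_out):
            for gamete in range(2):
                parent = np.searchsorted(cw, np.random.random() * tot)
                if parent >= n_par:
                    parent = n_par - 1
                row = 2 * off + gamete
                for c in range(n_chrom):
                    lo = chrom_offsets[c]
                    hi = chrom_offsets[c + 1]
                    cur = np.random.randint(0, 2)
                    n_x = np.random.poisson(recomb_rate * chrom_len_bp)
                    if n_x == 0:
                        b[row, lo:hi] = a[2 * parent + cur, lo:hi]
                    else:
                        cuts = np.sort(np.random.random(n_x)) * chrom_len_bp
                        seg_lo = lo
                        for x in range(n_x):
                            cut_idx = lo + np.searchsorted(
                                pos[lo:hi], cuts[x]
                            )
                            if cut_idx > seg_lo:
                                b[row, seg_lo:cut_idx] = a[
                                    2 * parent + cur, seg_lo:cut_idx
                                ]
                                seg_lo = cut_idx
                            cur = 1 - cur
                        if seg_lo < hi:
                            b[row, seg_lo:hi] = a[2 * parent + cur, seg_lo:hi]
        tmp = a
        a = b
        b = tmp
        if b.shape[0] != 2 * n_out:  # parent pool shrank to n_out after gen 1
            b = np.empty((2 * n_out, m), dtype=np.int8)
    return a
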