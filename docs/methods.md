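# Methods

`divscan` re-implements, as a tested pipeline, a two-subpopulation genomic
divergence analysis for a genotyped sport-horse cohort: genotype quality
control, population-structure inference (PCoA and DAPC), two complementary
selection scans (per-SNP Nei F_ST and the cross-population extended
haplotype homozygosity score XPEHH), and construction of annotated
candidate selection regions. Because the motivating cohort data are
private, the package ships a forward Wright–Fisher generator that produces
structurally matched synthetic cohorts with known ground truth; every
stage is validated against it.

## Cohort model and group definition

Individuals carry an estimated breeding value (EBV) for show-jumping
performance scaled so that 100 is the tested-population mean. The cohort
is split into a show-jumping (SJ) group, EBV strictly above 100, and a
non-show-jumping (NS) group otherwise. An EBV exactly at the threshold
goes to NS so the partition is total; missing EBVs are left unassigned
with a warning.

The Thoroughbred blood fraction is computed from a pedigree truncated at
four generations: every ancestral path is walked upward and the first
flagged (Thoroughbred) ancestor met at depth d contributes (1/2)^d, after
which the path stops. Stopping at the first flag is what makes the
fraction a genome share — a flagged ancestor's own ancestry is already
counted in their contribution — and guarantees the result is bounded by 1
and monotone in the flagged set. Unknown ancestors contribute 0.

## Quality control

Marker filters are applied in a fixed order, each removal attributed to
the first filter that rejects it:

1. **Call rate** — markers with a fraction of called genotypes strictly
   below 0.90 are removed (a marker exactly at the threshold is kept).
2. **MAF** — minor-allele frequency `min(p, 1-p)` computed from called
   dosages; markers below 0.01 removed.
3. **Exact HWE** — the exact conditional test (probability of heterozygote
   configurations given the allele counts, summing configurations no more
   probable than the observed one), with threshold p < 1e-4. The
   implementation uses the standard stable recurrence in log space and is
   checked against full enumeration for all totals up to 20.

A caveat discovered during calibration: when the two subpopulations are
strongly diverged (two-deme G_ST around 0.06), *whole-cohort* HWE testing
removes about 8% of markers — and precisely the most differentiated ones,
because pooling diverged demes produces a Wahlund heterozygote deficit
proportional to the per-SNP divergence. At the divergence level typical of
a recently specialized breed (F_ST ≈ 0.015) the filter is harmless, which
is the regime the default (1e-4) is intended for. For the synthetic
calibration studies, which run at much higher drift, the HWE stage is
disabled (`hwe_alpha = 0`); otherwise it silently deletes the sweep
signal the scans are meant to find.

**LD pruning** (structure analyses only; the selection scans use the full
post-QC panel): sliding windows of 50 SNPs advanced by 5, never crossing a
chromosome; while any retained pair in a window has r² > 0.5 (squared
Pearson correlation of dosages on pairwise-complete samples; 0 for a
constant column), the member with the lower MAF is removed, ties going to
the marker later in map order — this keeps the more informative marker and
is deterministic.

## Population structure

**PCoA.** Pairwise allele-sharing similarity
`s_ij = 1 - Σ|g_i - g_j| / (2 m_complete)` over markers called in both
samples; squared distances `D² = 2(1 - s)`; Gower double-centering
`B = -1/2 J D² J`; eigendecomposition. Coordinates are eigenvectors scaled
by the square roots of the positive eigenvalues; negative eigenvalues are
reported but dropped (not shifted) and excluded from the
variance-explained denominator. On exactly embeddable inputs the
coordinates reproduce the input distances to 1e-8.

**Cluster number.** K-means (10 restarts, fixed seed) on the top principal
components for K = 1..5, scored by `BIC(K) = n ln(WSS_K/n) + K ln(n)`.
Note that with strong family structure and many retained PCs the BIC curve
can keep creeping downward past the biologically meaningful K, so the full
table is always reported with the argmin flagged rather than a single
answer returned silently.

**DAPC.** PCA on mean-imputed, column-centered dosages; Fisher
discriminant axes (g−1 of them for g groups) maximizing the
between/within variance ratio on the retained PCs (a tiny ridge,
1e-8 of the mean within-scatter diagonal, keeps the solve stable);
posterior membership from Gaussian class-conditional densities with
pooled within-group variance per discriminant axis and uniform priors.
The retained PC count is chosen by stratified 90/10 cross-validation
(default 30 replicates): maximize mean held-out assignment, break ties by
the lower `RMSE = sqrt(mean (1 - proportion_correct)²)`.

## F_ST scan

Per-SNP Nei fixation index with unweighted mean frequency (the groups are
nearly equal in size):

    p̄ = (p1 + p2)/2,  H_T = 2 p̄ (1-p̄),
    H_S = (2 p1(1-p1) + 2 p2(1-p2)) / 2,
    F_ST = (H_T - H_S)/H_T

Monomorphic-in-both markers (H_T = 0) score 0 and negative values are
clamped to 0 (for two demes and this estimator the numerator is
`(p1-p2)²/2 ≥ 0`, so the clamp is a no-op kept for contract clarity).
No small-sample bias correction is applied. Markers uncalled in an entire
group are excluded and do not enter the quantile denominator.

Significance is empirical: the nearest-rank quantile with 1-based rank
`floor((1 - f) m) + 1` for top fraction f (so the significant set
`{F_ST ≥ threshold}` holds the top f of markers, plus ties). Qualitative
interpretation uses the Wright bands: < 0.05 little, 0.05–0.15 moderate,
0.15–0.25 large, above that very large differentiation.

## XPEHH haplotype scan

Haplotypes must be phased ('|' separators; phasing is upstream and
external). Pre-scan filtering first discards haplotype rows containing any
missing call, then markers not fully genotyped in the surviving rows.

**EHHS.** For a core SNP and one population, the site-EHH at flank
position x is the number of haplotype pairs identical over [core..x]
divided by the number of pairs identical at the core site (the
allele-agnostic, core-conditioned normalization). The curve starts at 1,
is non-increasing outward, and is extended until it falls below the
cutoff (default 0.05) or an inter-marker gap exceeds 200 kb; the first
sub-cutoff point is kept so the trapezoid reaches it, making the integral
continuous in the data. Both knobs are configurable.

**iES and the score.** iES is the trapezoidal integral of EHHS against
physical distance over both flanks (no genetic map is assumed). The raw
score is `ln(iES_NS / iES_SJ)`, so positive values indicate longer
haplotypes — more recent selection — in NS and negative values in SJ.
Cores whose decay reaches a chromosome end while still above the cutoff,
or where iES is undefined, are flagged and excluded from standardization.
Scores are z-standardized genome-wide (no frequency binning), transformed
to a two-sided −log10 p via the Gaussian CDF,
`p_XPEHH = -log10(1 - 2|Φ(z) - 1/2|)`, and thresholded by
Benjamini–Hochberg FDR at 0.05. The fixed rule |z| ≥ 4 is provided as an
alternative flag, not the default.

The genome scan runs a numba kernel that refines haplotype identity
classes site by site with a counting sort (O(n) per site per core); the
kernel is tested for exact agreement with a plain-Python reference and an
O(n²m) brute-force pair-counting oracle.

## Candidate regions and annotation

Each scan-significant SNP expands to ±250 kb (clamped at position 1);
overlapping or touching windows on a chromosome merge, per direction,
with provenance (source SNPs, lowest adjusted p) retained. Coordinates are
1-based inclusive internally; BED import/export converts to 0-based
half-open. A region is *concordant* when at least one F_ST-significant
SNP lies inside it; the highest such value is reported, `na` otherwise.
Region length in kb is `round((end - start)/1000)`.

Gene annotation takes gene-level GFF3 features (any overlap, inclusive
coordinates) with biotypes folded into a controlled vocabulary
(protein_coding, pseudogene, lncRNA, snoRNA, miRNA, miscRNA, snRNA).
Enrichment is database-agnostic: for a user-supplied term→gene map,
fold enrichment `(k/n)/(K/N)` and a hypergeometric upper-tail p-value,
reported raw by default (with an optional BH column). QTL overlap reports
user-supplied BED intervals intersecting each region.

## Synthetic cohort generator

The generator is a forward Wright–Fisher simulator chosen over a
coalescent for direct control of the sweep and the split.

* **Sites.** Each chromosome carries `m_snps` biallelic SNPs at irregular
  uniform positions on a 20 Mb chromosome; ancestral frequencies are
  drawn from Beta(2, 2), a mildly bell-shaped spectrum mimicking the
  ascertainment of a genotyping array (few rare variants).
* **Demography.** An ancestral pool of `2 n_pop` diploids (default 380)
  mates randomly for 50 burn-in generations to build up LD, then splits
  by partition: the two demes are disjoint random halves (the partition
  contributes about one generation's worth of between-deme variance).
  Each deme then drifts independently for `split_generations` (default
  T = 50). Offspring are formed by fitness-weighted parent sampling, one
  mating per offspring genome shared across chromosomes, with independent
  assortment and Poisson crossovers placed uniformly in base pairs.
* **Recombination.** Default 5e-8 per bp per generation, i.e. ~1 Morgan
  per 20 Mb chromosome — the map length of a typical full-size autosome,
  so haplotype-block scale is realistic relative to chromosome ends and
  SNP spacing on the shortened chromosome.
* **Sweeps.** A planted sweep arises as a single de novo copy in the
  ancestral pool and is driven by genic selection (fitness 1, 1+s, 1+2s)
  until it reaches a standing frequency of 0.04, at which point the split
  occurs and selection continues only in the target deme — a single-origin
  hard sweep, the signal class XPEHH is designed for. p0 = 0.04 is set so
  the deterministic trajectory `logit p_T ≈ logit p_0 + T ln(1+s)` ends
  near 0.8 at the defaults (s = 0.1, T = 50). Attempts in which the allele
  is lost, stalls, or ends below majority frequency restart with fresh
  randomness up to a cap, after which the failure is reported in the
  ground-truth record.
* **Phenotypes and missingness.** Pseudo-EBVs are Gaussian per group
  (show jumping: 125 ± 13.4 in SJ, 77 ± 11.3 in NS; dressage mirrored
  94 ± 10.2 / 119 ± 21.0), giving the bimodal cohort distribution; about
  3% of SJ and 2% of NS individuals fall on the wrong side of 100, which
  realistically blurs the EBV-defined groups. Genotype missingness is 4%
  (cohort call rate 0.96); the exported phased VCF is complete, as phasing
  imputes missing calls upstream.

Everything is reproducible from one master seed; per-stage streams are
derived from it, and identical seeds give bit-identical output.

**What the generator does not emulate.** The paternal half-sib family
structure of a real breeding cohort (145 sires with up to 11 offspring);
mutation (chip SNPs are treated as standing variation only); ascertainment
LD of a commercial array; variable recombination along chromosomes;
migration or bottlenecks. Passing tests therefore demonstrate correctness
of the statistics and the pipeline's behaviour under a clean two-deme
drift-plus-sweep model, not performance on a real half-sib cohort.

## Calibration results and a detectability limit

Two facts about the default study conditions, both recomputed by the test
suite and the acceptance script:

* **Drift calibration.** The marginal per-site process of the generator is
  exactly a single-locus Wright–Fisher chain (Beta start, burn-in,
  hypergeometric partition, T binomial generations, missingness
  subsampling, MAF filter), so the expected genome-wide mean F_ST is
  computed by an independent 1-D Monte Carlo of that chain and the genome
  simulator is required to match it within 3 standard errors over 20
  seeds (measured ≈ 0.060 at N = 200, T = 50; the oracle gives the same).
  Two closed forms bracket this number and are worth distinguishing:
  `f = 1-(1-1/(2N))^T` is the expectation of a Hudson-type `1 - Hw/Hb`,
  while Nei's two-deme G_ST has expectation ≈ `f/(2-f)` — about half —
  with a further ~6% downward Jensen bias from averaging per-SNP ratios.
  Under the null, BH at FDR 0.05 on the XPEHH scan yields essentially no
  discoveries (measured mean 0.65 per seed over 20 seeds).
* **Sweep detectability.** At T = 50 with N ≈ 200 per deme, post-split
  pair coalescence is T/2N ≈ 0.13, which makes both scans' neutral
  distributions heavy: the per-SNP F_ST top-0.1% threshold lands at
  0.5–0.6 (χ²-like tails), and the genealogical standard deviation of the
  neutral ln-iES ratio is ≈ 0.40. A *completed* hard sweep at s = 0.1
  (final frequency 0.8–0.95) produces a ln-iES ratio of about −1.4 at the
  core — a ≈ 3.5σ effect — while BH significance over ~10⁴ cores needs
  ≈ 4.5σ. Consequently the sweep locus lands in a BH-significant
  concordant region in only ~10% of seeds at these conditions (~40% under
  the |z| ≥ 4 rule; ~70% for the F_ST top-0.1% overlap alone). This is an
  intrinsic property of the statistics at this drift level, not an
  implementation artifact: reliable XPEHH recovery requires lower
  background drift (a shorter split or larger demes), the regime of a
  recently specialized breed with background F_ST ≈ 0.015.

## Numerical choices and degenerate inputs

* Missing genotype sentinel is −1, never 0; positions are 1-based
  inclusive internally.
* PLINK dosages count the .bim allele-1 recoded as the alternate allele,
  making frequencies and F_ST invariant to platform allele labelling.
* `r²` returns 0 for constant columns and is undefined (pair skipped)
  below 2 complete pairs; the windowed matrix form is a matmul
  formulation of pairwise-complete correlation, tested against the scalar.
* The exact HWE p-value caps at 1; the Gaussian p transform caps at
  −log10 p = 300 when the two-sided tail underflows.
* Empirical-threshold ties are always included in the significant set;
  a fully tied distribution saturates with a warning.
* K-means, cross-validation splits and the simulator all take explicit
  seeds; reruns are byte-identical.

## Known limitations

* DAPC posteriors use uniform priors; heavily unbalanced groups would
  warrant proportional priors.
* The BIC table's argmin is reported but, in high-dimensional PC spaces
  with family structure, tends toward the upper end of the K range; read
  the table, not just the flag.
* The enrichment operation assumes the term map and background are given;
  it does not query any annotation service.
* XPEHH cores near chromosome ends are excluded from standardization
  (configurable), which on short synthetic chromosomes removes ~10% of
  cores; real-length chromosomes are much less affected.
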