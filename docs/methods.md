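# Methods

This note documents the statistical model, the estimators, the tunable
parameters, and the numerical and design choices behind `colocnv`, together
with what the synthetic benchmarks do and do not demonstrate.

## Association measure

Mutual information I(A;B) = E[−log(p_A p_B / p_AB)] is estimated with the
B-spline binning estimator: each observation is assigned fractional
membership in `n_bins = 6` bins through B-spline basis functions of
`spline_order = 3` (order 1 recovers hard binning), with knots uniform over
the vector's observed [min, max]. Joint and marginal bin probabilities are
mean membership products, and the plug-in MI is computed in nats. The
association used everywhere downstream is the ratio-normalized, signed
value assoc(a,b) = sign(ρ)·I(a;b)/max(I(a;a), I(b;b)), clipped into
[−1, 1].

Two properties of this estimator family matter for interpretation:

* **Absolute scale.** A binned estimator cannot recover the continuous MI:
  with six bins the discretization itself caps the recoverable information,
  and the soft (order-3) binning smooths further. On a bivariate Gaussian
  with ρ = 0.9 at n = 50,000 the estimator reports ≈ 0.10 nats
  (`scripts/acceptance.py`, `mi_gaussian_rho09_nats`), far below the
  continuous value −½ln(1−ρ²) ≈ 0.83; on independent vectors it reports
  ≈ 0 (bias < 0.02 at n = 10,000). The pipeline never consumes the absolute
  scale: every decision uses the *normalized* ratio, in which the binning
  loss largely cancels (a gene pair with Pearson r ≈ 0.9 at n ≈ 100 scores
  ≈ 0.7). The estimator is kept because it is the standard choice in the
  attractor-metagene literature, it is distribution-free, and it captures
  non-linear dependence that correlation misses.
* **Exactness contracts.** assoc(a,a) = 1 and assoc(a,−a) = −1 exactly:
  MI terms are summed in sorted order (invariant under bin reflection) and
  the ratio is snapped to 1 when within 10⁻¹² (pure floating-point
  residue). The scalar `spline_mi` averages both argument orders so
  symmetry is exact. Affine rescaling of an input changes results only at
  the 10⁻¹⁵ level (bin coordinates are recomputed in floating point).

**Pan-cancer aggregation** uses the *lower* weighted median: the smallest
value whose cumulative cohort weight reaches ½, weights being cohort tumor
counts as a fraction of all tumors. The lower-median convention is
deterministic, interpolation-free, and testable against an exhaustive
oracle; with equal weights over two cohorts it returns the smaller value.
Cohorts with fewer than 8 samples are excluded (with a warning) and the
weights renormalized, since the 6-bin estimate is meaningless below that.

## Windowed attractor signatures

Genes are totally ordered by (chromosome, midpoint, gene id). For a seed
gene at ordered position k on a chromosome with G genes, the window is
positions [max(0, k−S/2), min(G−1, k+S/2)] with `window_size S = 150`
(windows never cross chromosome boundaries). The iteration:

1. weights w start as the seed indicator;
2. per cohort, metagene m_c = Σ_i f(w_i)·x_{i,c} with
   f(w) = max(w, 0)^α / Σ_j max(w_j, 0)^α and `exponent α = 2`;
3. each window gene's new weight is its pan-cancer association with the
   metagene (weighted median over cohorts);
4. stop when max_i |Δw_i| < `convergence_eps = 1e-7`, or flag
   non-convergence after `max_iterations = 100`.

Negative associations get zero mixing weight (CNA-driven signatures are
positively co-expressed); the reported per-gene weight is the signed
association itself. Expression averaging stays within cohort — only the
association is pan-cancer — so cohort-specific scale differences never mix.
The iteration is fully deterministic.

**Strength and filtering.** Strength = fifth-highest weight; signatures
with strength < 0.5 are discarded, so every survivor has at least five
strongly co-expressed genes. The chromosomal range is spanned by member
genes with weight > 0.5. Ranges overlapping on a chromosome are merged
transitively; each merged range is re-seeded from every member gene
(restricted to the range) and represented by the strongest converged
attractor (ties to the leftmost seed). Finally, signatures whose top five
genes include one with raw expression 0 in more than half of all pooled
tumor samples, and signatures on chromosomes X/Y (sex-driven expression
blocks), are removed.

**Basin of attraction.** A seed gene starts with weight 1, so a gene
uncorrelated with its window converges to a weak "self" attractor
(strength ≈ 0.1) rather than drifting to a nearby co-expressed block; this
is why the first pass seeds *every* gene. All member genes of a planted
block converge to the bit-identical fixed point (observed ℓ∞ discrepancy
≈ 3·10⁻⁸ across seeds), which is what makes the per-gene seeding redundant
and the deduplication (same name gene, ℓ∞ < 10⁻⁴) safe.

## Driver designation

**Signature levels** are unweighted means of the top five genes' rows in
the normalized expression and the gene-level CNA matrices.

**Permutation test.** The observed statistic is the pan-cancer association
between expression and CNA levels. For the null, the CNA level is
sample-permuted within each cohort `n_permutations = 10,000` times
(expression fixed; both marginals preserved); each cohort's null is sorted
ascending and the pan-cancer null's r-th element is the weighted median of
the r-th sorted elements across cohorts. P = (count + 1)/(n + 1) where
count is the number of pan-null values strictly above the observed value
(the add-one estimator avoids P = 0), Bonferroni-corrected by the number
of signatures tested.

This rank-paired (comonotone) null is **conservative by construction**:
pairing equal ranks makes the pan-cancer null essentially the common
per-cohort marginal, while the observed statistic — a weighted median of
independent per-cohort draws — concentrates. Measured type-I error at
nominal 0.05 is ≈ 0.015 with three balanced cohorts and ≈ 0 with the
default eight-cohort layout (`permutation_type_i_error_pct`); power
against a real dosage signal remains ≈ 100% because the observed
association lies far outside the null's entire support. Consequence: the
test never overstates significance, and a signature passing it has a
genuinely strong coupling.

**Thresholds.** Each normal sample's gene-level CNA vector is centered by
its own mean (removing per-sample baseline shifts); per cohort, all
centered values are pooled and t_amp|c (t_del|c) is the mean of the values
at or above the 90th (at or below the 10th) percentile
(`percentile = 10`); cohorts aggregate by weighted median. On N(0, 0.25)
noise this converges to ±0.25·E[Z | Z ≥ z₀.₉] ≈ ±0.439, which the
acceptance script reproduces within 1%. Cohorts without normals are
excluded; if none has normals the thresholds must be supplied in the
configuration.

**Frequency rule.** amp_freq(c) = fraction of cohort-c tumors with CNA
level strictly above t_amp (del_freq symmetric below t_del). A signature is
altered in a cohort iff its frequency strictly exceeds `t_freq = 3%`, and
pan-cancer iff altered in strictly more than `min_types = 6` cohorts. All
boundary comparisons are strict, matching the rule's wording; the boundary
cases (exactly 3%, exactly 6 cohorts, CNA difference exactly 0.1, top gene
zero in exactly half the samples) are pinned by tests.

**Co-alteration** of two adjacent same-direction signatures: among tumors
where at least one signature is altered, the fraction whose two CNA levels
differ by strictly less than `co_cna_diff = 0.1`. The denominator
(altered-in-at-least-one) is this package's convention; published
co-amplification frequencies do not state one, so values are comparable
only in contrast, not absolutely.

## Segment-to-gene copy number

Input segments are 1-based inclusive log2 ratios; interval arithmetic is
half-open internally. A gene inside one segment takes its value; a gene
spanning a breakpoint takes the overlap-length-weighted mean (continuous in
the breakpoint position and dosage-proportional — the containment and
gap rules only cover the other cases); a gene in a gap takes the mean of
the two flanking segments; beyond the first/last segment it takes the
nearest one. A sample with no segments on a chromosome yields 0 (diploid)
with a warning rather than aborting the cohort.

Expression preprocessing is log2(1+X) followed by quantile normalization
(per cohort); ties receive the average of the tied ranks' reference values
(the limma dialect — one test cross-checks against
`limma::normalizeQuantiles`). Genes that are zero in every sample of *any*
cohort are removed everywhere before the transform.

## Synthetic cohorts

The generator emulates the statistical structure the method assumes, at
desk scale. Defaults (the "realistic" profile): 3 chromosomes × 200 genes
at 100 kb spacing; eight cohorts of 150…100 tumors (950 total) with 15
normals each; per-sample baseline copy-number profiles from ~5 random
segments of N(0, `cna_noise_sd = 0.1`) log2-ratio noise; two random
germline-like CNVs per sample (5 genes, ±0.8) present in tumors *and*
normals, which is what lifts the derived thresholds (≈ ±0.2) above the
baseline noise and keeps the background alteration frequency ≈ 1–2%, below
t_freq; planted events fire independently per tumor with per-cohort
frequency 0.10 and add ±(1.5 + noise) log2 ratio over their gene range as
a single segment. Expression is baseline Uniform(3, 8) log2 units plus
`dosage_slope = 1.0` times the gene's CNA, plus gene noise
N(0, `expr_noise_sd = 0.4`), emitted on raw scale 2^x − 1.

Planted event blocks additionally share a latent N(0,1) expression factor
with loading `coexpression = 0.95`. This models co-regulation: real
amplicon signatures are strongly co-expressed across *all* samples, not
only the ~10% of altered ones. The modeling point is quantitative — a
10%-frequency binary event carries at most H(0.1) ≈ 0.33 nats, so
dosage-only coupling can never push member-gene weights to the 0.5
strength threshold; without co-regulation the co-expression signature the
method looks for would not exist in the first place. Copy-number-neutral
confounder blocks (loading 0.9, no CNA footprint) probe the dual driver
rule, and the same mechanism with scattered genes probes the window
constraint.

What the generator does **not** emulate: probe-level SNP-array noise,
subclonal mixtures and tumor purity, GC waves, expression heavy tails and
zero inflation beyond the clipping, correlated baseline co-expression
structure, and realistic gene-density variation. Passing tests demonstrate
the pipeline's correctness and its statistical behavior under the stated
model, not performance on real tumor data.

## Problem sizes

The benchmark suites run at sizes chosen to make Monte-Carlo conclusions
stable on a single CPU: estimator checks at n = 50,000 samples; 10,000
random pairs for the bound contracts; 200 null signatures × 1,000
permutations for calibration; 100 noise windows for specificity; ten full
end-to-end replicates (and three in the acceptance script) of the
950-tumor, 600-gene study for recovery. Full-size runs with 10,000
permutations are exercised in every end-to-end replicate.

## Known limitations

* The conservative permutation null (above) trades power near the
  significance boundary for strict type-I control; with a single cohort the
  construction is exact.
* Thresholds derived from fewer than a few hundred normal-sample values are
  noisy; the degenerate all-constant case is flagged and returns 0.
* Attractor discovery seeds every gene and is O(genes × iterations ×
  cohorts); at genome scale (tens of thousands of genes) the per-gene MI
  membership caches dominate memory (≈ genes × samples × bins × 8 bytes
  per cohort) and the first pass is the wall-clock bottleneck.
* Gene-level CNA from segments ignores intra-gene breakpoint detail beyond
  length weighting; cytoband labels are not computed.
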