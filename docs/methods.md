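# Methods

This note documents the statistical machinery implemented in `adgwas`,
the choices made where the design was genuinely open, and what the
synthetic benchmarks do and do not demonstrate.

## The k-sample Anderson–Darling test

`adgwas.adtest` implements the rank-based k-sample Anderson–Darling
procedure in four steps: (1) the tie-adjusted statistic `A²_akN` from the
midrank tie profile of the pooled samples (an unadjusted variant for
tie-free data is provided; the two agree asymptotically but not at small
N); (2) the exact finite-sample null variance `σ²_N = (aN³ + bN² + cN + d)
/ ((N−1)(N−2)(N−3))`, with coefficients that are polynomials in k, in
`H = Σ 1/nᵢ`, and in the harmonic-type sums `h = Σ_{i<N} 1/i` and
`g = Σ_{i=1}^{N−2} Σ_{j=i+1}^{N−1} 1/((N−i)j)`; (3) standardization
`T = (A² − (k−1))/σ_N`; (4) a p-value from the percentile model
`t_m(α) = b0 + b1/√m + b2/m` over the α grid {0.25, 0.10, 0.05, 0.025,
0.01}, shipped as a data file.

Numerical choices:

* **Midrank convention.** `B_aj` and `M_aij` count observations *below*
  z(j) plus half those *equal*; no alternative tie treatment is offered.
* **Tail extrapolation.** Within the table, `ln(α/(1−α))` is interpolated
  linearly against `t_m(α)`; beyond either end the line through the two
  most extreme tabulated points is extrapolated. This is deterministic
  and monotone; the p-value is clamped to (1e-300, 1] so −log₁₀(p) stays
  finite at GWAS-scale tails. The extrapolated tail decays like
  `exp(−0.9·T)` at m = 1, much heavier than a normal tail — permutation
  thresholds are therefore derived in the same p-metric, which makes them
  internally consistent.
* **Degenerate inputs.** A SNP whose pooled phenotype values are all
  identical (zero tie denominator) is *skipped* with a missing p, never
  assigned p = 1, keeping "untestable" distinct from "tested, null".
* **Verification.** Exhaustive enumeration over all two-sample splits of
  N ≤ 10 values confirms `E[A²] = k−1` and `Var[A²] = σ²_N` to 1e-10, and
  the statistic matches scipy's independently coded midrank
  implementation to 1e-10 on random tied and untied configurations.
  Monte-Carlo null calibration (rejection rate at the tabulated 5% point
  over thousands of two-sample replicates) is part of the acceptance
  checks.

## The genome scan

The A-D GWAS workflow tests each SNP within each subpopulation
separately (population structure is controlled by conditioning, not by
covariates), splitting the phenotype by the two homozygote classes.
Heterozygotes are excluded by default (`het_policy="exclude"`): the panel
is inbred and the null hypothesis names exactly two allele classes;
`with_major`/`with_minor` merging is available. Classes below
`min_class_size` (default 10) skip the SNP with a reason code.

Genomic control converts raw p-values to χ²₁ quantiles and estimates λ by
zero-intercept least squares of the sorted observed quantiles on expected
uniform-order-statistic quantiles, trimming the top 5% of observed values
so genuine signals do not lever the fit; λ < 1 is never applied
(no deflation). Thresholds: Bonferroni `α/n` (at the 556,809-SNP scale of
a maize RNA-seq + array panel this gives −log₁₀ cutoffs 5.74 and 7.05 at
α = 1 and 0.05), or the empirical α-quantile of genome-wide minimum p
over within-subpopulation phenotype permutations. Significant SNPs merge
into loci transitively within a 200-kb window (the collapse rule is
distance-based because no linkage-disequilibrium map is assumed).

The scan's hot path (A-D and Kruskal–Wallis statistics over SNPs ×
permutations) is a numba-compiled kernel sharing one gather–sort–walk
pass; the test suite asserts kernel-vs-reference agreement to 1e-10.

## Two-step imputation

Low-density target lines are completed from high-density donors in two
passes. **Frame markers** are the SNPs shared by both platforms, matched
on (chromosome, position); a marker with swapped major/minor orientation
is kept with its codes flipped, one with incompatible alleles is dropped.
**IBD projection** finds maximal runs of identical non-missing frame
genotypes between target and donor (a single informative mismatch breaks
a run; missing calls neither break nor count), keeps runs with ≥ 150
identical markers spanning ≥ 5 Mb (closed interval; both thresholds
configurable), and copies the donor's dense genotypes across the span.
Observed target calls are never overwritten; overlapping segments resolve
by longer bp span, then by higher genome-wide frame identity with the
target. **KNN filling** then handles remaining missing cells: for a cell
(line, SNP) the w = 20 nearest backbone markers by position define a
window; distance to each line observed at the SNP is the mismatch
proportion over mutually non-missing window markers; the k = 6 nearest
vote with weight d^p (p = −7), exact matches (d = 0) short-circuiting to
their own consensus; r = 1 rounds. Lines with > 10% heterozygosity can be
excluded up front.

The mismatch-proportion distance and weighted vote are a reconstruction
of the KNN scheme cited for sequencing-data imputation; the four symbols
(w, k, p, r) map one-to-one onto `KNNParams`. Strict identity (zero
mismatch tolerance) defines IBD runs because observed projection errors
are attributed to recombination/mutation inside true IBD tracts; a
tolerance knob exists but defaults to 0.

**What the benchmark shows.** Planted-mosaic panels (targets pasted
together from donor chromosomes, no mutation, breakpoint-flanking frame
markers forced informative) verify boundary recovery to within one frame
marker, projection accuracy ≥ 99%, and that the KNN step strictly
increases coverage and beats a major-allele-fill baseline under 10%
masking. Real two-platform data adds genotyping error, true mutation
inside IBD tracts and multi-donor ambiguity, so real-data accuracy and
coverage (reported in the 90s and 80s of percent for maize panels) are
necessarily lower than the planted-mosaic figures.

## Comparator methods

* **Kruskal–Wallis**: tie-corrected H on the same allele split, χ²₁ p.
* **Linear model**: OLS F-test of the dosage coefficient (hets count 1),
  vectorized across SNPs; no structure correction, matching its role as
  the uncorrected parametric baseline.
* **Mixed linear model**: EMMAX-style. Kinship is VanRaden's
  centered-dosage cross-product over Σ2p(1−p) (missing calls
  mean-imputed, monomorphic SNPs dropped); structure covariates are
  drop-one subpopulation indicators plus intercept. The variance ratio
  δ = σ²_e/σ²_g is estimated once per phenotype by REML through the
  eigendecomposition of K (grid over log δ ∈ [−8, 8] then bounded
  refinement), and every SNP is tested by GLS with those components held
  fixed (Wald t). A direct-inversion GLS oracle at n = 12 and the
  K = I ⇒ OLS collapse are asserted in tests.

## The simulator

`simulate_structured_genotypes` draws a Balding–Nichols panel: ancestral
frequencies uniform on [0.05, 0.95], subpopulation frequencies
Beta(p(1−F)/F, (1−p)(1−F)/F), inbred lines drawn homozygous with residual
heterozygosity 0.005, codes anchored to the panel-major allele. Default
Fst = 0.1, in the range reported between temperate/tropical maize
breeding groups; default 3 subpopulations.

Phenotypes (scheme 1) are the sum of four components, each centered and
exact-rescaled to its variance budget on a unit-variance scale:
subpopulation offsets (10% PVE), additive QTN effects (h², default 0.5
from the grid {0.3, 0.5, 0.7}), epistasis (10% PVE; 10 random disjoint
non-QTN SNP pairs, product of centered dosages with Gaussian pair
weights — the construction is a documented choice), and Gaussian
residual. Exact rescaling (rather than scaling in expectation) makes the
generator auditable: realized component PVEs sit within Monte-Carlo noise
of their targets because only the covariances between components move the
total variance off 1.

The 20 QTNs split 4 major (30% of genetic variance) / 16 moderate (70%),
each half rare (MAF 0.05–0.1) and half common (0.25–0.45). Within a
class, |effect| ∝ 1/√(MAF(1−MAF)), so rare and common QTNs contribute
equal variance (effect ratio ≈ 1.81 between the window anchors 0.075 and
0.35); each class is then jointly rescaled so its realized variance share
matches the split. Scheme 2 adds ±U(1, 6)·SD contamination to a random
10% of lines (range as specified; the uniform draw and random sign are
choices). Scheme 3 replaces the layout with 1 rare background + 3 major
(1 rare, 2 common) + 16 moderate QTNs at shares 25/20/60 — printed values
that sum to 105% and are renormalized to 1; the 20% major share is
treated as joint across the 3 QTNs.

## The power study

Each method's genome-wide threshold is the empirical 5%-quantile of its
minimum-p distribution over 200 *global* (unstratified) permutations of a
calibration phenotype; each of 100 replicates then re-simulates the
phenotype and scores a causal SNP detected iff its own p falls below the
method's threshold. Global permutation gives every method its pure-null
threshold; the realized type-I error among non-causal SNPs is reported
alongside power and differs across methods — the uncorrected tests (A-D,
K-W, LM) pay for structure confounding in false positives, the MLM stays
calibrated. In the power study the A-D test runs on the whole panel with
the same allele split as K-W, so the two nonparametric methods differ
only in their statistic; the per-subpopulation scan remains the
real-data workflow (`method="ad_subpop"`).

The benchmark runs at a deliberately reduced scale — 200 lines, 5,000
SNPs, 100 replicates, 200 permutations (the study design it emulates used
~500 lines, 500 repeats and 1,000 permutations) — and `min_class_size` is
lowered to 5 there, since rare-allele QTNs have only ~10–20 minor
homozygotes in a 200-line panel.

**Known limitations.** At this scale absolute powers are small (a major
QTN explains 3.75% of phenotypic variance), and the scheme-1 ranking
between the MLM and the uncorrected tests on *common major* QTNs depends
on the drawn QTN layout: the apparent power of uncorrected tests at a
causal SNP grows with how strongly that SNP's frequency drifts across
subpopulations, while the MLM — which absorbs both structure and the
polygenic background — can under-rank on layouts with strongly drifted
common QTNs (the familiar over-correction trade-off of kinship models).
Larger panels separate the methods far more stably. The qualitative
signatures of interest — the A-D test's tail-sensitivity advantage over
K-W on rare alleles, and the robustness of both nonparametric tests to
scheme-2 contamination that cripples LM and MLM — are reproduced by the
acceptance checks at the reduced scale. The Balding–Nichols genotypes
carry no linkage disequilibrium, so single-SNP detection is the only
route to a QTN; with real genotypes, linked markers would add detections.
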