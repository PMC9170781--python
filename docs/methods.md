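# Methods

This note documents the models implemented in `hicova`, the parameter
defaults and why they were chosen, what the synthetic data does and does not
emulate, and the numerical decisions made where the design was genuinely
open. Nothing here reports an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Scope and data model

All analyses are intra-chromosomal; matrices are stored per chromosome as
dense symmetric arrays with a boolean exclusion mask (toy working scale is
hundreds of bins per chromosome, where dense storage is both simpler and
faster than sparse). Interval logic is 0-based half-open throughout;
coordinates become 1-based only in VCF emission. Inputs are assumed
MAPQ- and PCR-duplicate-filtered upstream (the standard valid-pair
contract); `hicova` starts from valid pairs, pileup tables, and count
matrices, never from raw reads or alignments.

Two working resolutions are used, matching common practice for these
analyses: 40 kb for TADs, loops, and CNV coverage; 500 kb for A/B
compartments and compartment-stratified mutation rates.

## Synthetic data

The generator is the package's measurement instrument: every stage is
validated by recovering structure planted here.

**Contact maps.** Expected counts are multiplicative across factors:

    E[M_ij] ∝ d_ij^(-α) · exp(γ·v_i·v_j) · τ^[i,j in same TAD]
              · λ^[(i,j) planted loop] · (c_i/2)(c_j/2)

with Poisson counts scaled so the off-diagonal total matches the requested
depth, and the diagonal excluded (zero). A multiplicative model was chosen
because each factor is then independently recoverable, and because it
matches the standard decomposition of Hi-C signal (decay × compartment ×
domain × focal × copy number). Defaults: α = 1.0 (the canonical fractal-
globule-range decay), γ = 0.4 (clearly visible but not saturating
checkerboard), τ = 3, λ = 10, compartment blocks of 4 × 500 kb with random
phase, TADs of 8–28 bins tiling each chromosome. The toy genome is 2
chromosomes × 20 Mb at 40-kb bins; depth defaults to 2 × 10⁶ intra pairs
per 20-Mb chromosome, scaled from typical clinical in-situ Hi-C yields
(~10⁸–4 × 10⁸ valid pairs per 3-Gb genome).

**Paired samples.** The tumor re-draws compartment labels (default 5 % of
bins B→A and 3 % A→B — the mid-single-digit switching regime typical of
paired tumor/normal tissue), re-tiles TAD boundaries inside ~25 % of
domains, and applies planted integer copy states c ∈ {0..4} to the contact
model. Tumor purity (default 0.35) enters only the variant allele-fraction
model: the generator exposes no quantitative purity effect on the contact
map itself, because there is no established model for it at this scale;
contact-map purity mixing is an extension point, not a feature.

**Pileups.** Site depth is Poisson with mean modulated by
`1 + capture_bias·exp(−dist_to_GATC/200 bp)` (normalized to the requested
mean), emulating the restriction-site capture preference of Hi-C libraries;
GATC sites are a Poisson process at 1/256 bp (the motif's expected density
in random sequence). DV is binomial at the allele fraction (purity-scaled
for somatic sites in tumor) or at the sequencing error rate (default 0.1 %)
at non-variant sites.

**Expression.** Negative-binomial counts (default dispersion 0.05, two
replicates — the minimal replicated design) with tumor means scaled by
2^Δ_g; Δ_g can be coupled to compartment switches (+1 for genes in B→A
bins, −1 for A→B) with a background DEG fraction elsewhere.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: mappability- and fragment-length-dependent
coverage artifacts beyond the planted covariates, inter-chromosomal
contacts and translocations, subclonal or allele-specific copy number,
indels and structural variants, library-specific error profiles,
batch/biological replicate variability in expression beyond a single NB
dispersion, and any purity effect on 3D structure. Recovery rates measured
here are upper bounds relative to clinical data.

## Normalization

**ICE.** Iterative proportional fitting of `M_ij = b_i·b_j·T_ij` until the
unmasked marginals of T agree to a relative spread ≤ 1e-5 (max 200
iterations; non-convergence is reported with the final spread).
Zero-marginal bins are masked first; the bias vector is rescaled to mean 1
over unmasked bins and NaN on masked bins.

**caICB-style adjustment.** After ICE, a per-segment correction of the
copy-number scale that balancing cannot remove (block-level, non-
factorizable residuals): fit a chromosome-wide linear regression of log
count on log distance, compute each segment's mean log-residual over
within-segment pixels, and divide its rows and columns by
`exp(residual/2)`. This is a concrete realization of a "linear-regression,
chromosome/segment-level" adjustment; segments under 10 bins are left
unadjusted with a warning. Order of operations: CNV segmentation runs on
raw coverage first, then the adjustment may use its segments — coverage-
based CNV does not depend on the adjusted matrix, so the order is not
circular.

**SCC.** HiCRep-style: both matrices are 3 × 3 mean-filter smoothed
(half-width 1 bin at 40 kb), per-distance-stratum Pearson correlations up
to 5 Mb are combined with weights `N_k·sqrt(var(rank x)·var(rank y))`.
Self-comparison is exactly 1; the statistic is invariant to positive
scaling.

## Compartments

O/E transform → Pearson correlation matrix over unmasked bins → leading
eigenvector of the correlation matrix (the common convention when only
"PCA" is specified) → sign oriented so the positive group has the higher
mean gene density (A = gene-dense) → A/B by sign. Requires ≥ 20 unmasked
bins; a constant correlation matrix yields all-NA with a warning. Switch
fractions are computed over bins defined in both samples (the denominator
convention is stated because it is not standardized). The generator couples
gene density to the planted compartments (Poisson mean 4 in A vs 1 in B),
which is what makes the orientation rule testable.

## TADs

Insulation score: mean contact in a `w × w` square immediately
down-diagonal of each bin, log2-normalized by the chromosome mean of
defined scores. The window is 500 kb (floored to whole bins — 12 bins at
40 kb, since 500 kb is not a bin multiple); delta span 100 kb; boundary =
negative-to-positive zero crossing of the delta vector with amplitude
≥ 0.1 (the cited insulation tooling's conventional defaults; all exposed as
arguments). TADs assemble from consecutive boundaries; intervals ≤ 200 kb
and intervals touching masked bins are dropped (strictly-larger-than
semantics). Conservation uses reciprocal overlap: conserved iff a partner
covers ≥ 80 % of both intervals; classification is interval-based, not
boundary-based, and is reported in both directions because the rule is not
symmetric in general.

Boundary-recovery experiments isolate the TAD factor (γ = 0): compartment
block edges are genuine insulation minima, so scoring them as "false"
boundaries on a full-structure map would measure the generator, not the
caller.

## Loops

Candidates: unmasked pixels with 2 bins ≤ separation ≤ 2 Mb. Expected
count `e_ij = curve(d)·b_i·b_j` with the decay curve computed from the
bias-corrected matrix (so the product is on the raw scale); p-value =
upper-tail binomial `P(X ≥ M_ij)` with `n` = chromosome total and
`p = e_ij/n`; BH correction over all tested pixels; q < 0.01 kept, then
de-duplicated to 1-bin local maxima. Because the counts are discrete, the
exact tail p-value is conservative; for calibration checks the caller
offers a seeded randomized-tail mode (`p = P(X>x) + U·P(X=x)`), which is
exactly Uniform(0,1) under the null — the standard device for verifying
discrete-test calibration. Calling always uses the exact mode. Null
calibration is assessed on the pure-decay null with known (unit) biases;
ICE-estimated biases carry estimation noise that measurably perturbs
p-value uniformity at tens of thousands of tests, which is a property of
the plug-in expectation, not of the test statistic.

Donut refinement keeps a loop iff its O/E exceeds the local mean ratio in
all four neighborhoods — donut ≥ 1.5, lower-left ≥ 1.75, horizontal ≥ 2,
vertical ≥ 2, with peak half-width 1 and donut half-width 3 (mirroring the
widely used HiCCUPS thresholds). Loops too close to the edge are flagged
`edge` and excluded, never silently kept. The full HiCCUPS machinery
(lambda-chunked Poisson statistics, KR-specific corrections, 80-kb merge
radius) is deliberately not reproduced; the decay-binomial caller is
primary and the donut step is an optional filter.

APA averages O/E windows (half-width 5) centered on loops whose windows fit
inside the matrix and clear the diagonal; the score is the center pixel
over the mean of the lower-left w × w corner (the short-distance corner).

## CNV

Coverage = raw row sums (the raw matrix is required; normalized input is
rejected). Bins with GC < 0.2 or mappability < 0.5 are masked — strict
inequalities, so boundary values are kept. Lowess (frac 0.5) removes GC and
fragment-count trends; under 50 usable bins the step falls back to median
scaling with a warning.

Hi-C marginal coverage differs from WGS depth in one important way: it
scales with the copy number of *both* contact endpoints,
`cov_i ∝ (c_i/2)·Σ_j w_ij (c_j/2)`, so a broad gain inflates its own bins'
coverage roughly quadratically deep inside the segment. A fixed-point
deconvolution (`r_i ← cov_i / Σ_j w_ij r_j` with distance-decay weights
`w ∝ d^-1`, median-1 rescaled, 20 iterations) recovers a per-bin ratio
proportional to c/2 before segmentation; it is on by default and exposed as
an argument.

Segmentation: centered moving median (span 25 bins) then a 5-state HMM with
Gaussian emissions at means c/2 (c = 0…4), emission SD = 1.4826 × MAD of
the smoothed coverage floored at 0.05, and state-switch probability 1e-3,
decoded by Viterbi (verified in the tests against exhaustive path
enumeration on small inputs). The HMM replaces kernel-density machinery of
dedicated Hi-C CNV tools because it is exactly testable. Equal-state runs
merge into segments; the altered fraction is the state ≠ 2 share of
segment length.

## Variants

Calling consumes pileup DP/DV directly — the pileup abstraction captures
exactly the evidence the filters use. Two presets coexist because both
regimes are in real use: the paired-sample default (strict DP > 8 and
DV > 4) and a WGS-comparison mode (DV ≥ 3, no depth floor). Thresholds are
monotone by construction (tightening never adds calls). Known-site removal
takes a user-supplied position list (a dbSNP stand-in). Somatic =
tumor-call keys (chrom, pos, alt) absent from the normal calls; requiring
the alt allele to match is the stricter of the two possible conventions and
is documented rather than assumed. Mutation-rate tracks support 1-Mb and
500-kb bins with hotspot flags above the 99th percentile. Functional labels
follow the priority exonic > UTR > intronic > intergenic. Cut-site
distances are to the nearest GATC on either side; two call sets are
compared with a one-sided Mann-Whitney test. LOH handling and indels are
out of scope.

## Integration

**DEG test.** Median-of-ratios size factors; per-gene NB Wald test on
log2(μ_T/μ_N) (pseudo-count 0.5) with variance `μ + φμ²`. The dispersion is
`max(per-gene moment estimate, pooled regression estimate, 0.01)`: the
pooled estimate fits `var − μ = φ·μ²` by least squares across genes, which
is unbiased for a shared dispersion, whereas the median of per-gene moment
estimates is biased low at two replicates. The reference distribution is
normal, not t: the variance is trend-stabilized rather than estimated from
two samples, so t at n−2 df would double-count uncertainty and void power
entirely at n = 2. This combination controls the null FDR in simulation
(part of the test suite) at the cost of power relative to shrinkage-based
NB frameworks — a deliberate trade for a transparent, calibrated stand-in.

**Switch grouping.** Genes map to compartment bins by transcription start.
Classes are B→A / stable / A→B; the trend statistic is the Spearman
correlation of log2FC with the ordered classes (−1, 0, +1). The
"concordant vs no-switch" DEG decomposition (switch direction matching DEG
sign) is reported with both denominators — all DEGs and mappable DEGs —
because the convention is ambiguous.

**Chromosome summary.** Per chromosome: fraction of segment length with
state ≠ 2, fraction of TADs without a reciprocal-80 % partner, fraction of
tested genes flagged DEG; Pearson and Spearman correlations across
chromosomes, NA with a warning when degenerate. The coupled-gradient
generator (`simulate_coupled_alterations`, 12 × 6-Mb chromosomes) exists
specifically to exercise this analysis with a known monotone coupling.

**Mutation-rate association.** Ratio of mean rates over constitutive-B vs
constitutive-A bins; two-sided permutation test on |log ratio| with labels
permuted over bins (default 1999 permutations; p ∈ [1/(n+1), 1]).

## Numerical and edge-case conventions

- Empty decay strata are linearly interpolated from neighbors and flagged;
  the isotonic fit (scikit-learn) enforces monotone non-increase.
- Degenerate inputs reject loudly (empty profile lists, zero mutations,
  one-class association, all-zero genes, DV > DP) rather than returning
  silent NaNs; recoverable oddities warn (non-convergent ICE, short caICB
  segments, empty TAD boundary sets, all-zero genes excluded from testing).
- All generators and stochastic procedures take explicit seeds; identical
  seeds give identical outputs byte-for-byte.
- Problem sizes in the tests and the acceptance script (single 20-Mb or
  50-Mb chromosomes, 100-seed SCC loops, 30–40 null simulations, 199–999
  permutations) were chosen as the smallest sizes at which the measured
  quantities are stable against their stated tolerances.

## Known limitations

- The caICB-style adjustment corrects segment-level multiplicative scale
  only; it cannot repair distance-dependent distortions within a segment.
- The donut filter approximates HiCCUPS with ICE biases and fixed
  thresholds; no FDR is attached to the refined set beyond the primary
  caller's q-values.
- CNV state and purity are not jointly estimated; a low-purity gain whose
  coverage ratio falls between HMM means resolves to the nearest state.
- Somatic calling is subtraction-based; it cannot distinguish a variant
  missed in the normal sample from a true somatic event (no contamination
  model).
- The DEG test's power at two replicates is intentionally modest; its
  recall on planted 2-fold effects is recorded as a regression value in the
  tests, not claimed as competitive.
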