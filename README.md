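# hicova

**Hi-C omics and variant analysis for paired tumor/normal samples.**

Clinical tumor Hi-C is a single assay that carries several layers of
information at once: the 3D genome (A/B compartments, topologically
associated domains, chromatin loops), the underlying genome (copy-number
changes and point mutations, visible in coverage and in the aligned reads),
and — combined with matched RNA-seq — the downstream expression consequences.
`hicova` implements that whole analysis stack as one tested Python library,
together with a planted-truth simulator so that every stage can be scored
against known ground truth:

- **contacts** — contact-matrix model, valid-pair binning, coverage, text I/O
  (valid-pairs TSV, sparse triplets + bin BED, bedGraph, BEDPE, minimal VCF).
- **normalization** — ICE matrix balancing; a caICB-style segment-level
  decay-intercept adjustment that removes residual copy-number scale;
  distance-decay expected model and O/E transform; HiCRep-style
  stratum-adjusted correlation (SCC) for reproducibility.
- **compartments** — A/B calls at 500 kb from the leading eigenvector of the
  O/E correlation matrix, oriented so A is gene-dense; switch classification
  (A→A / A→B / B→A / B→B) between paired samples; constitutive states.
- **domains** — insulation-score TAD calling at 40 kb (500-kb sliding
  square, delta zero-crossings), >200 kb and telomere/centromere filters,
  and reciprocal-80 % overlap conservation between samples.
- **loops** — upper-tail binomial significance against a decay × bias
  expectation with BH correction (q < 0.01), optional HiCCUPS-style donut /
  lower-left / horizontal / vertical local filters, and aggregate peak
  analysis (APA).
- **cnv** — copy number from Hi-C marginal coverage: GC < 0.2 /
  mappability < 0.5 bin filters, lowess covariate normalization, a
  deconvolution of the neighbor copy-number effect, and a 5-state
  Gaussian-emission HMM (states c = 0…4, means c/2) decoded by Viterbi.
- **variants** — SNV calling from pileup DP/DV with strict thresholds
  (DP > 8 and DV > 4; a DV ≥ 3 preset for WGS comparisons), known-site
  removal, paired somatic subtraction, mutation-rate tracks with hotspot
  flags, exon/UTR/intron labeling, and distance-to-GATC-site analysis.
- **integration** — a simplified negative-binomial Wald test for
  differential expression, expression changes grouped by compartment switch,
  chromosome-level CNV/TAD/DEG correlation, and a permutation test of
  mutation-rate enrichment in constitutive compartment B.
- **synthetic** — the generator behind all of it: power-law contact decay
  (exponent α), checkerboard compartments (strength γ), block TADs (boost
  τ), focal loops (boost λ), multiplicative copy-number effects, Poisson
  counting noise, restriction-site-biased pileups with tumor purity, and
  negative-binomial expression with switch-coupled effects.

The statistical core in symbols: the expected contact between bins *i*, *j*
at distance *d* is `E[M_ij] ∝ d^-α · exp(γ v_i v_j) · τ^[same TAD] ·
λ^[loop] · (c_i/2)(c_j/2)`; ICE solves `M_ij = b_i b_j T_ij` for biases *b*
with equal marginals of *T*; loop significance is
`P(X ≥ M_ij), X ~ Binomial(N, e_ij/N)` with `e_ij = curve(d) b_i b_j`; the
CNV HMM emits `N(c/2, σ²)` per smoothed coverage ratio; the DEG statistic is
a Wald z on `log2(μ_T/μ_N)` with NB variance `μ + φμ²`.

## Worked example

Simulate a paired normal/tumor chromosome (20 Mb at 40 kb, with planted
TADs, compartments, loops, a 2-Mb copy-number gain, and somatic variants at
35 % purity), then run the stack:

```python
import numpy as np
import hicova as hv

layout = hv.make_genome_layout(n_chromosomes=1, lengths=[20_000_000],
                               bin_size=40_000, seed=7)
truth = hv.make_truth(layout, seed=7, cnv_segments={"chr1": [(100, 150, 3)]})
normal = hv.simulate_contact_map(layout, truth, depth=2_000_000, seed=8)["chr1"]
tumor = hv.simulate_contact_map(layout, truth, depth=2_000_000, tumor=True,
                                seed=9)["chr1"]

iced_n, bias_n = hv.ice_normalize(normal)
iced_t, _ = hv.ice_normalize(tumor)
print(f"SCC(normal, tumor) = {hv.scc(normal, tumor):.3f}")

tads_n = hv.assemble_tads(hv.insulation_profile(iced_n), layout)
tads_t = hv.assemble_tads(hv.insulation_profile(iced_t), layout)
cmp_ = hv.classify_conservation(tads_n, tads_t)
print(f"TADs: {len(tads_n)} normal / {len(tads_t)} tumor, "
      f"{cmp_.counts['changed_a']} of {len(tads_n)} changed")

b = np.nan_to_num(bias_n, nan=1.0)
corrected = hv.ContactMatrix("chr1", 40_000, normal.matrix / np.outer(b, b),
                             iced_n.mask, bias=bias_n, provenance="iced")
loops = hv.call_loops_decay(normal, bias_n, hv.expected_by_distance(corrected))
print(f"loops: {len(loops.loops)} significant at q<0.01, "
      f"APA score {hv.apa(iced_n, loops).score:.2f}")

cov = hv.normalize_coverage(
    hv.filter_bins(hv.coverage_from_matrix(tumor), layout), layout)
seg = hv.segment_copy_number(cov)
print(seg.segments[seg.segments["state"] != 2].to_string(index=False))

pile_n = hv.simulate_pileups(layout, truth, mean_depth=30,
                             sample_kind="normal", seed=10)
pile_t = hv.simulate_pileups(layout, truth, mean_depth=30,
                             sample_kind="tumor", seed=11)
som = hv.somatic_subtract(hv.call_snvs(pile_n), hv.call_snvs(pile_t))
print(f"somatic SNVs: {len(som)} called")
```

Output:

```
SCC(normal, tumor) = 0.552
TADs: 26 normal / 28 tumor, 4 of 26 changed
loops: 426 significant at q<0.01, APA score 2.41
  start     end  state  mean_coverage
4160000 6000000      3       1.489787
somatic SNVs: 85 called
```

Reading the numbers: the paired maps are well correlated (SCC 0.55 at this
toy depth) yet 4/26 TADs fail the reciprocal-80 % rule, reflecting the
planted domain changes. The decay-binomial caller flags every enriched pixel
(TAD-interior pixels included); `hv.donut_refine(loops, iced_n)` narrows
this to 55 focal peaks that still include all 12 planted loops, and the APA
score of 2.41 confirms aggregate enrichment. The CNV stage recovers the
planted state-3 gain at bins 104–150 (true: 100–150; on a map with full
compartment/TAD structure the extra coverage modulation can shift the
smoothed edge by a few bins — on decay-only maps both breakpoints land
within one bin) with mean copy ratio 1.49 ≈ 3/2. Of 150 planted somatic
variants, 85 pass DP > 8, DV > 4 at 30× and purity 0.35 — detection is
purity-limited, exactly as the binomial model predicts.

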