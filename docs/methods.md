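# Methods

## Problem setting

Haplotype assembly links alleles at heterozygous sites through sequenced
fragments that cover two or more of them. Representing sites as nodes and
co-covering fragments as edges gives the SNP-graph; two sites are phasable
exactly when they are connected, so the connected components are the
haplotype contigs. `strobehap` simulates the experiment that produces this
graph — strobe reads with designable advance lengths — and scores,
optimizes, and error-checks the resulting designs.

## Heterozygous-site tracks

Real tracks load from VCF (biallelic heterozygous SNVs only, one sample,
multi-allelic records skipped and counted), BED (width-1 intervals), or
one-column TSV. All coordinates are 0-based with half-open intervals;
VCF's 1-based positions are shifted on read. Duplicate positions are
deduplicated with a log message rather than an error, since real VCFs
repeat records.

The synthetic generator emulates two robust features of human heterozygous
sites: a genome-wide mean spacing of roughly 1 kbp, and strong clustering —
the inter-site distance distribution has a far heavier tail than the
exponential a homogeneous Poisson process would give. Gaps are drawn as
`min_gap + floor(s·X)` with `X` a unit continuous Pareto variate of tail
index `a` and `s = (mean_gap − min_gap + 0.5)(a − 1)`, so the expected gap
hits `mean_gap` (the +0.5 compensates the floor). The tail index has no
canonical empirical value, so it is a free parameter defaulting to 2.5 —
heavy enough that long gaps dominate connectivity, while keeping a finite
variance so the mean-spacing target is meaningful at 5–10 Mbp scale. As
the index grows the law degenerates toward constant spacing, which the
tests exercise directly.

What the generator does *not* emulate: long-range correlation of SNP
density (recombination hot/cold spots), reference errors, and regions of
atypical density such as HLA. Conclusions from passing tests are therefore
about designs under heavy-tailed, independent-gap spacing — the feature
that actually drives the design problem — not about any particular genomic
region.

Synthetic truth haplotypes are the fixed complementary pair (all-0 /
all-1). HER and SER are invariant to per-component allele relabeling, so
this loses no generality.

## Strobe-read simulator

A design is (L, c, A, k, (α_i, β_i)). Subreads have length `l = floor(L/k)`
(a warning is logged when k does not divide L). The number of reads is
`N = floor(c·G/L)`, inverting the coverage definition `c = NL/G`.

Advance `a_i` is `round(max_i · B)`, `B ~ Beta(α_i, β_i)`. For `k = 2` the
maximum is `A − L`. For `k ≥ 3` the maxima nest: `max_1 = A − 2l` (the
first advance separates the first and the furthest subread), and
`max_i = max(a_{i−1} − l, 0)` for `i ≥ 2`, placing intermediate subreads
inside the fragment. Relative subread starts are `0` and `l + a_i`; after
sorting, a left-to-right sweep enforces `start_{j+1} ≥ start_j + l`. The
sweep is a no-op whenever the nested maxima already give disjoint
placements (the generic case) and resolves the degenerate corner — an
advance falling below `l` — by letting subreads abut; the realized span
never exceeds `max(2l + a_1, k·l) ≤ A`. The fragment start `d_0` is then
uniform on `[0, G − insert]`, so reads never truncate at region
boundaries (avoiding edge-coverage bias in small regions; clipping versus
resampling at boundaries is otherwise a free choice).

A `fixed_advance` design takes every advance at its maximum
deterministically — the fixed-insert limit of the beta family, used as the
degenerate baseline in design comparisons.

Each read covering `s ≥ 2` sites contributes all `C(s, 2)` site-pair edges
*with multiplicity*; multiplicity is what makes wasted-edge accounting
meaningful. Reads covering fewer than 2 sites are tallied as
non-informative.

Determinism: one `numpy` Generator seeded from `DesignParams.seed` is
consumed in a documented order — all Beta variates for advance 1, then
advance 2, …, then all start positions — so a seed fixes the graph
exactly. `generate_read` is the per-read reference path used for
hand-checked placement examples; `simulate_experiment` is the vectorized
path used everywhere else (the two consume the stream in different orders
and are not draw-for-draw comparable; the experiment-level contract is
seed → identical graph).

## Length metrics

Component statistics: size `v`, span (distance between distal sites), and
adjusted span = span × `v / t`, where `t` counts all track sites inside
the component's positional interval (inclusive); singletons have span 0.
S50/N50/AN50 all weight by SNP count: components are sorted by the metric
descending (ties broken by leftmost position for deterministic output) and
the reported value is the metric of the component at which the cumulative
site count first reaches half of all sites. Singletons participate in the
denominator. AN50 ≤ N50 always, since adjusted span never exceeds span and
the weighting is identical.

## Useful and wasted edges

A component with `v` vertices needs `v − 1` edges to be connected; summed
over the graph, useful = n_sites − n_components, wasted = total edges
(with multiplicity) − useful. The useful fraction's denominator counts
multiplicity — re-covering an already-linked pair is precisely the waste
being measured. Long-advance designs spread linking probability across
distant pairs instead of re-linking dense clusters, and consistently win
this fraction.

## Design optimization

The annealer follows the standard Metropolis scheme for maximization.
State is (α, β) ∈ (0, 4]² (flattened to 2(k−1) coordinates for k > 2; the
initial point is uniform on the box). Per iteration: the objective — the
AN50 of one fresh simulated experiment — is evaluated at the current point
and at a neighbor obtained by stepping one coordinate by ±s (s = 0.5 for
the first half of iterations, 0.1 after; candidates leaving the box are
redrawn). Observations accumulate per visited point across revisits, and
comparisons use the *pooled medians*: AN50 is noisy at fixed (α, β), and
pooling makes an artificially lucky value progressively easier to escape.
Temperature starts at T₀ = 11,000 (the scale of meaningful AN50
differences in bp) and decreases linearly by T₀/I per iteration, floored
at 10⁻⁶ to keep the last acceptance ratio finite; a worse neighbor is
accepted with probability `exp(Δ/T)`, a better-or-equal one always. The
default budget is I = 225 iterations = 450 simulations. The reported
optimum is the visited point with the highest pooled median.

The coarse baseline evaluates α ∈ (0, 3.4] step 0.2 × β ∈ (0, 3] step 0.1
(17 × 30 cells) with a fixed replicate count per cell — 12,750 simulations
at 25 replicates — recording median AN50 per cell.

For k > 2 the annealer perturbs one coordinate of one (α_i, β_i) pair per
move; k = 2 reduces exactly to the single-pair search.

## Error model, site filter, and phaser

Each read originates from one haplotype uniformly; every covered-site
observation is dropped with probability `dropout` (standing in for the
platform's indel-dominated errors — alignment is assumed correct, so an
indel manifests as a missing observation) or miscalled with probability
`epsilon`. Optional homozygous decoy sites emit a single allele through
the same process to exercise the filter.

The filter contrasts H₁ (homozygous: one allele, miscalled at rate ε)
against H₀ (heterozygous: both alleles at 1/2):
`Λ = n₁ ln(1−ε) + n₂ ln ε + n ln 2` (binomial coefficients cancel). True
heterozygous sites drive Λ strongly negative; a site is called
heterozygous when Λ ≤ −1, boundary inclusive. At ε = 1/2 the hypotheses
coincide and Λ ≡ 0. At n = 10, ε = 0.05 the decision boundary falls
between minor counts 2 and 3, giving exact error rates
P(minor ≤ 2 | Bin(10, ½)) = 112/1024 ≈ 10.9% (het sites lost) and
P(errors ≥ 3 | Bin(10, 0.05)) ≈ 1.15% (decoys kept) — the unit tests pin
these closed forms, and no cutoff does materially better at this depth
because the two count distributions overlap. Deeper coverage, not a
cleverer threshold, is what separates them.

The phaser is deliberately simple plumbing so accuracy can be measured
end-to-end. Reads vote on each site pair's relative phase
(`obs_u XOR obs_v`); each component is phased by walking a spanning tree
that always expands the unvisited edge with the most supporting
observations, then polished by local refinement sweeps that flip any site
whose incident-edge votes favor it (the redundant "wasted" edges are
exactly what powers this correction). Ties — and edges whose observations
were all dropped — resolve to phase 0, keeping the lower site index's
orientation; everything is deterministic.

## Accuracy metrics

HER is the fraction of miscalled alleles among phased sites (components of
size ≥ 2; singletons carry no phase information), counted per component
under the better of the two labelings — hence HER ≤ 0.5. SER counts
orientation flips between positionally adjacent sites within components,
per phased site; component boundaries are free crossovers, the standard
convention in the phasing literature.

There is a real tension between the two goals the toolkit measures:
long-advance designs maximize AN50 but string components together through
site pairs covered by a single read, whose relative phase is wrong with
probability 2ε(1−ε) (≈ 9.5% at ε = 0.05) — irreducible by any phaser. The
end-to-end accuracy evaluation therefore uses a redundancy-friendly
short-insert paired design (k = 2, L = 900, A = 1500, Beta(1, 1), c = 10×,
2 Mbp track, medians over 5 replicates), where majority votes have real
support; it achieves HER ≈ 2–3% and SER ≈ 1.4% at ε = dropout = 0.05.
Design for length and design for accuracy are different optimizations.

## Problem sizes and numerical choices

- Design-comparison experiments: 5 Mbp track (~5,000 sites), c = 20×
  (111,111 reads per experiment), 25 paired replicates per design, common
  replicate seeds across designs (paired comparison).
- Annealer calibration uses a deterministic quadratic objective peaked at
  (1.6, 0.5) with curvature 26,600 bp per unit² — chosen so the
  peak-to-valley drop across the box matches the observed AN50 landscape
  (~150 kbp to ~40 kbp), making T₀ = 11,000 meaningful.
- Advances round to integer bp; beta shape keys in search bookkeeping are
  rounded to 6 decimals so float step accumulation cannot split a grid
  point's observation list.
- Degenerate inputs: empty tracks raise a dedicated error; `G < A` raises
  a region-too-small error; c = 0 yields an edgeless graph and zero-valued
  metrics rather than an error.

## Known limitations

- No base-level sequences, qualities, alignment, or indel realism; errors
  act on allele observations directly.
- The greedy phaser is a baseline, not a competitive assembler; it has no
  MEC objective and cannot revise component membership.
- The filter model ignores the second-order effect of miscalls on the
  heterozygous hypothesis (H₀ kept at exactly ½).
- Synthetic tracks have i.i.d. gaps; real genomes correlate SNP density
  over long ranges.
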