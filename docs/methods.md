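# Methods

This note records the models implemented in `rohpaint`, the parameter
defaults and why they were chosen, the numerical conventions, and what the
synthetic-data generator does and does not emulate.

## ROH detection

An ROH is a maximal window of consecutive markers on one chromosome of one
animal satisfying six constraints simultaneously: heterozygous calls
≤ `max_het` (default 2), missing calls ≤ `max_missing` (5), every
adjacent-marker gap ≤ `max_gap` (50 kb), span ≥ `min_length` (1 Mb),
marker count ≥ `min_snps` (70) and density ≥ `min_density` (1 SNP / 50 kb).
These are the standard settings of commercial SNP-array ROH scanners for
bovine HD data. Because such scanners do not document their window
resolution, we define it deterministically: among all valid windows,
greedily keep the longest (ties to the leftmost), then re-search the
flanking remainders. This makes the detector exactly equivalent to
brute-force enumeration of every contiguous window, which the test suite
verifies on randomized toys up to 1000 markers. One subtlety the remainder
re-search handles: a sub-window of a discarded overlapping candidate can
itself satisfy all constraints and must still be considered.

Coordinates are 1-based inclusive and segment length is end − start + 1,
matching PLINK's reporting; BED truth tracks alone use 0-based half-open
intervals.

The advisory minimum-SNP formula
`l = ceil( ln(alpha/(ns*ni)) / ln(1-het) )` (α = 0.01) is provided as a
calculator; the fixed default of 70 SNPs is used by the scanner because
the two are stated independently in practice and the formula's inputs
(total SNPs, animals, mean heterozygosity) vary by dataset.

### Generation classes

The expected length of an IBD haplotype from a common ancestor g
generations back is 100/(2g) cM. Converting at `cm_per_mb` = 1.282 — the
average autosomal linkage-map length of the two standard cattle linkage
maps divided by the physical assembly length, and the unique constant
consistent with both published bounds — gives class bounds 13.0, 7.8 and
3.9 Mb for g = 3, 5, 10. Class intervals are closed on the right: a length
exactly on a bound is assigned to the older class. Class 4 (> 13 Mb) is
inbreeding within the last ~3 generations; class 1 (≤ 3.9 Mb) reflects
ancestry more than 10 generations back.

### F_ROH

F_ROH = Σ L_ROH / L_total. The genome-wide default L_total is the
Btau5.0.1 autosome length, 2,522,199,562 bp; per-chromosome F_ROH uses the
chromosome's length, per-class F_ROH sums only that class's segments (the
class values partition the genome value). On synthetic genomes the pipeline
uses the summed simulated chromosome spans instead of the cattle assembly
constant.

## ROH islands

Per-SNP ROH frequency in a population is the fraction of its animals with
an ROH covering the SNP. The island threshold is the empirical 99th
percentile in the 'higher' order-statistic convention — the smallest
observed value with at most 1% of observations strictly above it — which
is distribution-free; the normality testing that sometimes precedes such
thresholds does not change the percentile and is omitted. Above-threshold
runs separated by ≤ `merge_gap` (default 500 kb; no published merging rule
exists, but reported islands are unified multi-Mb regions) are merged.
A population with no ROH at all gets no islands rather than a degenerate
zero threshold selecting the whole genome.

## Chromosome painting

The Li–Stephens copying model treats a recipient haplotype as an imperfect
mosaic of K phased donor haplotypes. Between adjacent markers at genetic
distance d cM the chain keeps its donor with probability e^(−ρd) and
otherwise re-selects uniformly among all K donors; emission matches the
copied donor with probability 1 − μ. Posteriors come from the scaled
(per-site normalized) forward–backward recursion, so no underflow occurs
at any panel size; the log-likelihood is returned from the scaling
factors. Summing donor posteriors within breeds gives per-SNP breed
probabilities; a region's founder percentage averages SNP-wise over all
recipient haplotypes, then over the region's SNPs. The self-copy option
adds the other composite haplotypes to the donor panel under their own
label.

Parameter defaults: ρ = 1.0 per cM and μ = θ/(2(K + θ)) with Watterson's
θ = 1/Σ_{i<K} 1/i, the conventional choices when donors and recipients
share haplotypes. The full E-M estimation of ρ and θ used by ChromoPainter
is out of scope; instead the sensitivity is documented here and matters:
on panels **without** within-breed haplotype sharing (such as this
package's synthetic founders, whose sites are independent draws from the
breed frequencies), Watterson's μ (~0.004 at K = 80) is far below the real
miscopy rate and makes donor switching cheaper than absorbing mismatches,
collapsing the posterior toward the panel prior. For such data the helper
`recommended_copying_params(SimConfig)` sets
μ = 2(1 − F̄)·E[p0(1 − p0)] — the closed-form within-breed mismatch
probability of the generator, 0.31 at F_st 0.15 with Uniform(0.05, 0.95)
ancestral frequencies — and ρ = (founding switch rate + generations)/100
per cM, the expected density of true ancestry breakpoints (0.13 at the
defaults). With these generator-matched values painting recovers
genome-wide ancestry within ±0.05 and per-SNP hard calls at ≥ 0.85
accuracy across replicate simulations (the acceptance suite runs 20).

Posterior breed probabilities shrink toward the panel prior wherever the
local evidence is thin, so the *mean posterior* founder fraction is a
slightly conservative estimate of an extreme true fraction; hard-call
fractions are less biased. Both are exposed.

### F_st

Weir & Cockerham (1984) two-population θ̂: per-SNP variance components a
(among populations), b (among individuals within populations) and c
(within individuals) from sample sizes, allele frequencies and observed
heterozygosity, combined as the ratio of sums Σa/Σ(a+b+c) over the region.
Monomorphic SNPs and SNPs with fewer than two informative samples in
either population contribute nothing. Negative single-SNP estimates are
expected under no differentiation and are retained.

## Drift null

Founder-allele frequency under neutrality: p_{t+1} ~ Binomial(2·Ne, p_t) /
(2·Ne), defaults p0 = 0.625, Ne = 100 diploids, 10 generations — the
founding proportion and a plausible effective size for a young composite —
with no selection, mutation or migration; these stated parameters fully
specify the binomial Wright–Fisher model. The envelope is the
per-generation replicate mean ± 2.576·SD (two-sided 99% Gaussian), clamped
to [0, 1]; both the final-generation and per-generation bounds are
exposed. The default 50 replicates matches the scale of the original
protocol; moment-sensitive checks in the test suite use 5000–10000
replicates, where the closed-form variance p0(1−p0)(1−(1−1/(2Ne))^t)
(= 0.01146 at the defaults) is matched within 10%. Observed founder-B
probabilities are compared against the mirrored envelope (1 − bounds of
the founder-A simulation); values above/below become enriched/depleted.

## Pedigree metrics

- Equivalent generations: g(x) = Σ_parents ½(1 + g(parent)), i.e.
  Σ(1/2)^n over all known-ancestor paths; memoized over a topological
  order, cycles rejected.
- Completeness: C_parent = (1/d)·Σ_{k≤d} known_k/2^k over d ascending
  generations (default d = 5, a common reporting depth); PCI is the
  harmonic mean 2·C_s·C_d/(C_s + C_d), zero when either parent is unknown.
- Inbreeding: Wright's F by recursive coancestry with founders unrelated
  and non-inbred; verified against the full tabular relationship matrix on
  random pedigrees. Parents named but never listed are treated as founder
  records.
- ΔF and Ne: OLS of per-animal F_ROH on equivalent generations; the slope
  is the realized per-generation inbreeding rate and Ne = 1/(2·ΔF).

## Synthetic data

What it emulates: two founder breeds diverged from a common ancestral pool
by the Balding–Nichols model (per-marker ancestral frequency
p0 ~ U(0.05, 0.95); breed frequency ~ Beta(p0(1−F)/F, (1−p0)(1−F)/F), so
Var = F·p0(1−p0)); a composite founded as two-state Markov ancestry
mosaics along the genetic map with expected founder-A fraction 0.625
(modeling the breed-average proportion rather than any specific grading-up
cross, which is not documented for real composites); then `n_generations`
(10) of random mating among `n_composite` (50) animals with
`n_sires_per_gen` (5) sires, which accumulates autozygosity and long ROH.
Meioses place crossovers as a Poisson process on the map (Haldane, no
interference); true ancestry is propagated through every meiosis and
serialized as BED; the pedigree is recorded. Genotyping error and
missingness are injectable (default 0) so QC is testable. The default
genome is 3 × 50 Mb with 2,500 evenly spaced markers per chromosome
(20 kb spacing — dense enough for the standard scanner settings) at
1.282 cM/Mb.

The optional `sweep_region` fixes one founder-A haplotype across all
composite founders in a window. The swept haplotype is drawn from the
genotyped founder-A panel, as a real sweep fixes a haplotype that
segregates in the founder breed; this is what lets painting attribute the
region unambiguously.

What it does **not** emulate, and therefore what passing tests do not
show about real data: within-breed linkage disequilibrium and haplotype
sharing (founder panel haplotypes are independent site-wise draws —
painting real data, where sharing is strong, is easier than painting
these panels); SNP-chip ascertainment bias; mutation; sex chromosomes;
overlapping generations and non-random mating. The composite founding
stock is drawn independently of the genotyped founder panels so that, at
F_st = 0, the two breeds are statistically exchangeable and painting
accuracy collapses to the panel prior — a calibration check the suite
asserts.

## Numerical conventions and degenerate inputs

- Genotypes are alt-dosage int8 with −1 missing; haplotype pair sums equal
  diploid dosages at non-missing sites.
- QC order is markers (call rate ≥ 0.95, then MAF ≥ 0.01 pooled across
  populations — a per-population option exists) then samples (call rate
  ≥ 0.90); the order is observable and a test pins a case where swapping
  it changes the result. QC is idempotent.
- PED/MAP carries no ref/alt designation: re-reading orients dosages by a
  companion `.bim` when present, else by lexicographic allele order
  (monomorphic markers are then coded 0 by convention).
- The empirical percentile uses `np.quantile(..., method="higher")`.
- μ = 0 in painting is allowed only when some donor matches perfectly;
  otherwise a zero-probability path raises an error naming the marker.
- All simulations consume a single integer seed through
  `numpy.random.default_rng`; identical configs give byte-identical
  pipeline reports.

## Problem sizes

Test and acceptance runs use desk-scale genomes (1–3 chromosomes of
30–50 Mb, 800–2,500 markers each, 24–60 founder animals, 20–50 composite
animals), chosen so the full suite exercises every stage — including
20-replicate painting recovery and the end-to-end sweep control — in
about a minute while leaving all statistical checks well-powered. The
implementation itself is vectorized and handles HD-chip scale
(hundreds of thousands of markers) without structural changes.

## Known limitations

- The ROH scanner's greedy longest-first resolution is one deterministic
  choice among several defensible ones; commercial tools may differ on
  overlapping-window tie-breaks.
- ρ and θ are fixed per run, not estimated; region-level founder
  percentages inherit posterior shrinkage toward the panel prior.
- The drift null is single-locus: it ignores linkage between the painted
  SNPs, so neighbouring enrichment labels are correlated in a way the
  null does not model.
- Pedigree metrics assume founders are unrelated and non-inbred.
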