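# Methods

## The simulated breeding system

The package simulates a three-way terminal crossbreeding pyramid in pigs.
Founders form the first great-grandparent nucleus (GGP1): at full production
scale 690 animals (Duroc 10 boars / 50 sows, Landrace 10/100, Yorkshire
20/500). Each nucleus tier is expanded within breed by one-boar-to-many-sows
matings, 10 progeny per sow in a fixed 5-male/5-female litter, giving 6500 GP
animals per generation (500 Duroc, 1000 Landrace, 5000 Yorkshire). The nucleus
is replaced twice: all males and a random half of the females are replaced by
GP recruits (Duroc 10♂/25♀, Landrace 10♂/50♀, Yorkshire 20♂/250♀) drawn
round-robin across dam families (families ordered by id, one eligible progeny
per family per round) so every lineage is represented as evenly as possible.
The parent tier is produced by 100 Landrace boars × 2000 Yorkshire sows from
GP1 (20,000 LY; the 10,000 LY males are recorded but never mated), and the
commercial tier by 100 Duroc boars from GP2 × all 10,000 LY sows (100,000
DLY). "Random selection" of cross parents is uniform without replacement;
dams are assigned to sires in randomized near-equal blocks. No directional
selection occurs anywhere. The candidate set is 2 boars + 2 gilts per GGP3
sow — 2600 GP3 purebreds (200/400/2000, the 1:2:10 breed ratio). Distinct
animals across the system: 690 + 3·6500 + 20,000 + 100,000 = 140,190; the
composed GGP2/GGP3 tiers reuse existing animals.

Meiosis draws a crossover count uniformly on the integers {4, 5, 6} per
chromosome, places breakpoints uniformly on physical length (physical
distance is the recombination coordinate; no genetic map, no interference,
no mutation), starts from a uniformly chosen parental haplotype and switches
at each breakpoint. Gametes for a whole generation are produced by one
vectorised pass per chromosome.

## Synthetic founders

Real ancestral panels carry breed differentiation and strong within-breed
linkage disequilibrium; the generator emulates both.

* **Differentiation** — Balding–Nichols: per locus an ancestral frequency
  p₀ ~ Uniform(0.05, 0.95); per breed p_b ~ Beta(p₀(1−F)/F, (1−p₀)(1−F)/F)
  with F = 0.15 by default (realistic for commercial pig breeds; pairwise
  Hudson F_ST between two such breeds ≈ 0.25).
* **Linkage** — two modes. The default `mosaic` mode draws a pool of 6 base
  haplotypes per breed (alleles Bernoulli(p_b) per locus) and builds each
  founder haplotype as a recombinant mosaic of pool members with
  exponentially distributed segments (mean 20 Mb), emulating the extensive
  haplotype sharing of breeds with small effective population size. The
  `independent` mode draws every locus independently (exact founder HWE, no
  LD) and is used where that property is the point: founder HWE tests, REML
  parameter recovery, GWAS null calibration. Marker-based prediction needs
  founder LD — without it the marker relationship matrix barely tracks the
  relationships realised at the causal loci — so the pipeline defaults to
  mosaic founders.
* **QC** — every retained locus has pooled MAF ≥ 0.01 (failing loci are
  redrawn, allele content only, up to a configurable budget). File readers
  apply call rate ≥ 0.95 and MAF ≥ 0.01 and reject any missingness that
  survives QC; the internal representation is phased-complete with dosages
  in {0, 1, 2}. Coordinates are 1-based as in VCF.

What the generator does **not** emulate: real LD decay shapes, site
frequency spectra from real demography, chip ascertainment bias, or
genotyping error. Passing tests therefore demonstrate correctness of the
machinery and the design's qualitative orderings, not published chip-data
accuracy values, which depend on the real founder panel.

## Trait model

`n_qtl` causal loci (2000 at full scale; 100 is the sensitivity
architecture; desk preset 200) are drawn uniformly from loci segregating in
GGP1. Effect magnitudes are Gamma(shape 0.4, scale 1) — scale is immaterial
because of the rescaling — with equiprobable sign. One constant rescales all
effects so Var(TBV) = 1 over the scaling population (default: every animal
in the system). TBV_j = Σ a_i · dosage_ji; phenotype = TBV + N(0, V_e) with
V_e = V_g(1−h²)/h². A second residual mode (`sd`) treats that V_e quantity
as a standard deviation — the internally consistent variance mode is the
default, the sd mode reproduces summaries in which low-heritability
phenotype dispersions are an order of magnitude larger (SD ≈ 9 at h² = 0.1).

## Reference designs

Two-tailed extreme selection takes the ⌈n/2⌉ highest and ⌊n/2⌋ lowest
phenotypes (ties broken by index; the top gets the extra individual for odd
n). Random designs draw uniformly without replacement from a replicate seed.
CCPS unions a PB draw and a CB_extreme draw (default 50/50). Candidates are
excluded from every source. Replicate r of an experiment uses master seed
+ r for the draws it owns; by default each replicate also redraws the
phenotype residuals, so the extreme design (deterministic given a
realization) varies across replicates through the trait — the most
conservative replication; a config flag freezes the trait instead.

## Estimators

* **GRM** — VanRaden method 1, frequencies computed from the combined
  reference + candidate genotypes of each scenario. The experiment runner
  performs the large cross-product in single precision (float64 everywhere
  after); the library call is float64.
* **REML** — profile restricted likelihood over log(σ_u²/σ_e²) after one
  eigendecomposition of G_rr, bounded search with tolerance 1e−6, jitter
  1e−8 if G is numerically indefinite; non-convergence is a flag, not an
  exception. For extreme-selected references the components are estimated
  from that same selected data — reproducing the documented overestimation
  of σ_u² under selective genotyping — unless components are supplied.
* **GBLUP** — candidate values G_cr (G_rr + λI)⁻¹ (y − μ̂), λ = σ_e²/σ_u²,
  μ̂ the GLS intercept; Cholesky solve.
* **BSLMM** — Gibbs sampler over per-marker inclusion indicators and
  effects. Parameterised by the two mixture variances (large = σ_a² + σ_b²,
  small = σ_b²) for conditional conjugacy (scaled inverse-χ², ν = 4, with
  method-of-moments scales: residual at half the phenotypic variance, large
  effects at half the variance over ~5% of markers, and a weak ~1% floor
  for the polygenic component so null traits are not forced to absorb
  variance). π has a log-uniform prior on [1/m, 1] updated by a reflecting
  Metropolis walk on log π. Default chain 10,000 sweeps (200,000 at full
  scale; desk 5000), 10% burn-in. Reported effects are Rao-Blackwellised
  (averaged full-conditional means); a variance cap guards divergent draws.
  Fixing π = 1 and σ_b² = 0 collapses the model onto ridge regression,
  which equals GBLUP with matched variances — an acceptance test verifies
  correlation > 0.99 between the two prediction routes.
* **Marker panel** — predictions and GWAS use the QC-passing markers minus
  the QTL set (full scale: 39,755 − 2000 = 37,755), so causal loci are
  never directly observed by the estimators.
* **IBS / IBD** — allele-sharing IBS from dosage differences; IBD by the
  method of moments (expected IBS-state counts given panel frequencies
  inverted to state probabilities; negatives truncated and renormalised;
  PI_HAT = P2 + P1/2), without finite-sample allele-count corrections —
  frequencies should come from an adequate panel, and stratified panels
  bias PI_HAT upward (documented and tested). LD pruning: greedy sliding
  window of 50 SNPs, step 10, r² threshold 0.2, later-position marker
  removed.
* **GWAS** — per-marker Wald tests in y = μ + xa + g + e via one spectral
  decomposition and closed-form 2×2 GLS per marker at the null-model REML
  ratio (no per-marker refit); p-values from t with n − 2 df; monomorphic
  markers flagged untested. Thresholds: Bonferroni α/m (significant) and
  1/m (suggestive); both counts are reported since published counts mix the
  two conventions. Each marker is assigned the QTL with maximal composite
  r² (genotype correlation); r² > 0.6 flags high LD. Peak PVE: within each
  QTL's ±500 kb region the significant marker with smallest p contributes
  PVE = 2a²pq / (2a²pq + 2N·Se²·pq) (allele frequency cancels; the full
  form is implemented); a marker peaking in overlapping regions counts in
  each; sigPVE sums peak PVE and is reported in percent.

## Scales

The full production scale (140,190 animals) is run for structural counts
with a reduced marker panel (hundreds of markers; the counts are
marker-free). The desk preset — used by the replicated experiments and
examples — preserves the design's ratios at roughly one tenth the nucleus:
founders D 6♂/30♀, L 6♂/60♀, Y 12♂/300♀; 5 chromosomes × 100 Mb with 400
markers each (2000); 200 QTL; LY cross 20 × 400; DLY cross 20 boars × 2000
LY sows → 20,000 commercial animals; 1560 candidates; reference sizes
{500, 1000, 2000}; 50 replicates; BSLMM chain 5000. These sizes are the
package's chosen desk-scale study conditions; they were designed so the
low-heritability extreme-vs-random comparison has statistical power while
remaining routinely runnable.

## Design choices and limitations

* Crossover counts "4 to 6" are read as uniform on {4,5,6}; breakpoints
  uniform on physical length.
* The desk-scale paired comparison (CB_extreme vs CB_random accuracy at
  h² = 0.1) has a per-replicate win probability of roughly 0.9, not 1:
  overall candidate accuracy includes the alignment of the three breed
  means, which only a few effective degrees of freedom estimate, so single
  replicates can order adversely even when the means are well separated —
  the same Simpson-style effect that motivates the per-breed metrics.
* Only additive effects are simulated (no dominance, epistasis, G×E); the
  purebred–crossbred genetic correlation is implicitly 1. Litter size is
  fixed; generations do not overlap.
* IBD estimates assume the frequency panel matches the pairs' source
  population; cross-breed pairs against pooled frequencies are biased
  upward by stratification.
* The GWAS variance ratio is estimated once from the null model; exact
  per-marker refits would differ negligibly on the tested fixtures.
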