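# crossgp

Genomic prediction in a simulated **Duroc × (Landrace × Yorkshire)** three-way
pig crossbreeding system.

Commercial pig production is a pyramid: a purebred nucleus (great-grandparent,
GGP) of Duroc, Landrace and Yorkshire is expanded within breed into grandparent
(GP) tiers; Landrace boars × Yorkshire sows produce the LY parent generation,
and Duroc terminal boars × LY sows produce the commercial DLY animals.
Selection happens among purebred GP candidates, but the economic trait is
expressed in the crossbreds. `crossgp` simulates this whole system —
gamete-dropping meiosis from phased founders, two nucleus replacements, a
100,000-animal commercial tier at full scale — and asks the design question:
**who should be genotyped and phenotyped as the reference population** for
predicting purebred candidates' breeding values for crossbred performance?

Compared designs, at sizes from 500 to 6500:

* **PB** — random purebred GP2 animals (the conventional nucleus reference);
* **CB_random** — random commercial DLY crossbreds;
* **CB_extreme** — two-tailed selective genotyping: the highest- and
  lowest-phenotype halves of a DLY sample;
* **CCPS** — 50% PB + 50% CB_extreme.

## Models

Phenotypes follow `y = μ + g + e`. Two evaluation engines are implemented:

* **GBLUP** — `y = μ + Zu + e`, `u ~ N(0, G σ_u²)` with VanRaden's genomic
  relationship matrix `G = ZZ′ / (2Σ p_i q_i)`; variance components by REML
  (single spectral decomposition of `G`, one-dimensional profile likelihood),
  breeding values from the mixed-model equations.
* **BSLMM** — a Bayesian sparse linear mixed model `y = μ + Xβ + e` where each
  marker effect is drawn from `N(0, σ_a² + σ_b²)` with probability `π` (large
  effects) and `N(0, σ_b²)` otherwise (polygenic background), fitted by Gibbs
  sampling; candidate GEBV = `Σ β̂_i · dosage_i`.

The trait has `n_qtl` causal loci (default 2000) with gamma(0.4)-distributed
signed effects, rescaled so the genetic variance over the whole system is 1;
heritabilities 0.1 / 0.3 / 0.5 set the residual variance through
`h² = V_g / (V_g + V_e)`. Evaluation uses the Pearson correlation between GEBV
and true breeding value of the 2600 purebred candidates (overall and per
breed) and **Best10%_TBV**, the mean TBV of the top decile by GEBV. The
relatedness machinery (pairwise IBS, method-of-moments IBD after 50/10/0.2 LD
pruning) and a mixed-model GWAS with SNP–QTL `r²` assignment and peak-SNP
phenotypic-variance-explained (PVE) summaries complete the study.

## Worked example

`examples/04_genomic_prediction.py` runs the desk-scale preset (≈36,000
animals, 2000 markers, 200 QTL, 20,000 DLY) and prints, for a low-heritability
trait (h² = 0.1, reference size 1000, GBLUP, 3 replicates):

```
    scheme  accuracy  best10_tbv  accuracy_Duroc  accuracy_Landrace  accuracy_Yorkshire
CB_extreme     0.377      -0.904           0.561              0.279               0.379
 CB_random     0.221      -1.240           0.473              0.221               0.213
        PB     0.516      -0.631           0.183              0.243               0.543
```

Read this as: extreme-phenotype crossbred genotyping beats random crossbred
genotyping everywhere, and is the best design for the terminal sire breed
(Duroc accuracy 0.56 vs 0.18 for the purebred reference) because each
commercial animal carries half its genome from Duroc; the purebred reference
is best for Yorkshire, which dominates the nucleus. Best10%_TBV (response to
selection) orders the same way. The other examples cover founder generation
and formats, the breeding system, trait and reference construction, and
relatedness/GWAS.

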