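# seedsource

Population-genetic and climatic tracing of introduced forest tree stands to
their native seed sources.

Introduced stands of long-lived trees — the motivating system is North
American Douglas-fir (*Pseudotsuga menziesii*) planted in central Europe —
often have unknown geographic origin, may mix diverged intraspecific
varieties, and regenerate naturally on site. Given diploid genotypes at a
panel of ~13 microsatellite (SSR) loci for reference populations from the
native range and for introduced stands (adults plus regeneration, with
mapped coordinates), together with a per-population climate table, this
package answers the questions a forest geneticist asks of such data:

* **Which variety, and which source?** A supervised maximum-likelihood
  admixture estimator gives each individual a membership coefficient
  *Q* to one of two reference gene pools (EM on the mixture likelihood of
  its allele copies); *Q* > 0.8 / *Q* < 0.2 classify parental varieties,
  intermediate values inter-varietal hybrids, with the cut-offs
  calibratable by simulated F1 genotypes. Assignment to individual
  reference populations uses two likelihood measures — the frequency-based
  genotype likelihood (with a floor for alleles unseen in a reference) and
  the Bayesian posterior-predictive likelihood under a 1/k Dirichlet
  prior on reference allele counts — reported as percentage scores.
* **Who are the parents, and how far do propagules move?** Single-parent
  LOD scores (Mendelian transition probability over population allele
  frequencies, with a genotyping-error blend), confidence from the
  LOD gap Δ between best and runner-up candidate calibrated by simulated
  mating events, and realized parent–offspring distances.
* **Did introduction erode diversity?** Na, Ho, He, unbiased He, Fis,
  rarefied allelic richness; Monte-Carlo exact tests for heterozygote
  deficit; a 1000-fold subsampling t-test battery against random groups of
  native populations; the heterozygote-excess bottleneck test under the
  two-phase mutation model (coalescent-simulated equilibrium He
  conditional on the observed allele count, one-tailed Wilcoxon across
  loci); and the allele-frequency mode-shift indicator.
* **Is there fine-scale spatial genetic structure (SGS)?** Pairwise
  Loiselle kinship F_ij, its regression slope b_log on ln(distance) with a
  10,000-fold permutation test and delete-one-locus jackknife SE, distance
  class correlograms, and the summary statistic
  **Sp = −b_log / (1 − F₁)** where F₁ is the mean kinship of the first
  distance class.
* **Does realized origin track climate?** PCA of ten standardized climate
  variables, eigenvalue-weighted Euclidean distances between populations,
  UPGMA dendrograms, and a G-test comparing the climatic distances of the
  genetically assigned origins against those expected if seed had come
  from any putative origin.

A synthetic-data module generates metapopulations with controlled
hierarchical divergence (Balding–Nichols frequencies: variety → cluster →
population), introduced stands with a known mating/dispersal pedigree, and
climate tables with latent group structure, so every analysis is testable
end-to-end with known truth.

## Worked example

```python
import seedsource as ss

metapop = ss.generate_metapopulation(ss.MetapopSpec(seed=42))
stand = ss.generate_stand(
    ss.StandSpec(name="E1", source_mixture={"R01": 0.7, "R02": 0.3},
                 sigma_seed=5.0, seed=43),
    metapop,
)
res = ss.SGSModel(stand.table, stand.coords, cohort="regeneration").fit(
    n_perm=1000, seed=0
)
print(res.summary())
```

```
Spatial genetic structure: (all)
----------------------------------------
individuals / pairs : 40 / 780
F(first class)      : 0.0993
b_log (+/- SE)      : -0.0175 (0.0024)
permutation p       : 0.0010  (1000 permutations)
Sp                  : 0.0194

           n_pairs  mean_F  env_lo  env_hi
class
(0, 5]          10  0.0993 -0.0442  0.0504
(5, 10]          7  0.1209 -0.0518  0.0599
(10, 20]        28  0.0454 -0.0249  0.0270
(20, 40]        72  0.0020 -0.0145  0.0158
(40, 80]       240 -0.0040 -0.0074  0.0080
(80, 160]      384 -0.0065 -0.0048  0.0059
```

The regeneration cohort was simulated with a 5 m seed kernel, so kinship
decays with distance: the slope is negative and significant (p = 0.001),
mean kinship in the nearest classes sits above the 95% permutation
envelope, and Sp ≈ 0.019 indicates strong fine-scale structure — an order
of magnitude above what randomly planted adults show. Parentage on the
same stand (`ss.ParentageModel(stand.offspring, stand.adults)`, critical Δ
from 1,000 simulated mating events) assigns 16 of 40 offspring a parent at
strict 95% confidence:

```
Single-parent likelihood parentage
------------------------------------
offspring analysed  : 40
critical Delta 95%  : 4.284
critical Delta 80%  : 0.011
  strict95  : 16
  relaxed80 : 24
  none      : 0
```

A command-line interface wraps the same functions:
`seedsource diversity|founder|assign|parentage|sgs|climate|simulate --help`.

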