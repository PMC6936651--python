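# Methods

This note documents the statistical procedures implemented in
`seedsource`, the conventions and defaults chosen where the underlying
protocols leave room, and what the synthetic-data generators do and do not
emulate.

## Data model

Genotypes are unordered diploid pairs of integer allele codes (fragment
sizes) at multiallelic codominant loci; 0 is the missing code. Missingness
is a property of a call, not an individual: individuals are never dropped
at read time, and every analysis excludes missing calls locus-wise
(assignment and parentage additionally require a minimum of 9 genotyped
loci per individual, applied uniformly). Allele codes are used verbatim —
no size binning. Coordinates are planar metres; stands are far smaller
than any scale at which geodesy matters. GENEPOP output uses the 3-digit
dialect (input accepts 2- and 3-digit); population names ride on the `Pop`
separator lines so round-trips are lossless.

## Diversity and Hardy–Weinberg

Per locus: Na = allele count, Ho = fraction heterozygous among non-missing
calls, He = 1 − Σp², uHe = He·n/(n−1) over n gene copies. Fis =
(He_used − Ho)/He_used is computed per locus and combined with He_used
weights (monomorphic loci excluded); He_used defaults to uHe because the
introduced and reference samples differ in size — a flag switches to He,
and both are reported. Allelic richness is rarefied exactly,
E[A(g)] = Σ_a [1 − C(N−N_a, g)/C(N, g)], standardized to g = 20 gene
copies ("10 individuals" interpreted as diploids, matching the
gene-copy convention of rarefaction tools); loci with fewer observed
copies than g are excluded from the mean with a flag.

The heterozygote-deficit exact test is Monte-Carlo: conditional on the
observed allele counts, gene copies are randomly re-paired and the
heterozygote count compared to the observed one. The **mid-p convention**
(ties weighted 1/2) is used: the plain `P(T ≤ t_obs)` convention is so
conservative for this discrete statistic that null p-values are visibly
non-uniform, which would bias every downstream multiple-test summary;
with mid-p the null distribution is uniform to within KS noise (checked in
the test suite). Defaults: 100,000 iterations, seedable.

## Founder-effect procedures

*Subsampling t-test battery.* Introduced populations are compared to
`n_groups = 1000` random draws of six native populations by pooled
two-sample t-tests (df = 10 for 6 vs 6; pooled rather than Welch to match
the published degrees of freedom), sign convention introduced − native.
Each draw is Shapiro–Wilk-checked; non-normal draws are flagged but still
tested. Because all tests share the same six introduced values, the
battery's rejection fraction is highly variable between datasets — its
expectation, not any single battery, equals α under the null (the test
suite averages over replicate batteries). To balance sample sizes,
`european_split_means` first splits each introduced population into two
random disjoint 20-individual halves and averages the index over halves;
smaller populations are used whole with a warning.

*Bottleneck test.* For each polymorphic locus with n gene copies and k
alleles, the equilibrium distribution of unbiased gene diversity (Heq)
conditional on k is simulated: Kingman coalescent genealogies of n copies,
mutations Poisson on branches, allele states by mutation model — IAM (each
mutation a novel allele), SMM (±1 steps), or TPM (±1 with probability
p_smm = 0.7, otherwise a geometric multi-step whose jump variance is 0.30;
both configurable — the published analysis cites external run parameters
that the text does not reproduce, so these defaults are configuration, not
a claim). θ is tuned by noisy bisection so the mean simulated allele count
matches k (the IAM tuning is validated against the Ewens sampling-formula
expectation E[K|θ,n] = Σ θ/(θ+i)), then replicates with exactly k alleles
are retained by rejection. One property worth stating explicitly:
conditional on the same (n, k), **mean Heq is higher under SMM/TPM than
under IAM** — homoplasy requires a larger θ to maintain k alleles — which
is precisely why heterozygote-excess tests are more conservative under
stepwise models. The one-tailed Wilcoxon signed-rank test on
(He_obs − mean Heq) across ≥4 polymorphic loci tests for excess. The
mode-shift indicator pools allele frequencies into ten right-closed
classes (0,0.1], …, (0.9,1]; the distribution is L-shaped iff the first
class strictly dominates every other.

*Scale used in the calibration tests:* 6 loci × 20 diploids, 80 retained
equilibrium replicates per locus, 20 null datasets and 10 crash datasets
(a 95% crash simulated as three generations at 10 gene copies). Measured
type-I 2/20 at α = 0.05; crash power 8/10.

## Admixture and assignment

`supervised_q` maximizes, by EM, the per-copy mixture likelihood
Π (q·pA + (1−q)·pB) over the individual's non-missing allele copies, with
reference frequencies fixed — the supervised, deterministic replacement
for an unsupervised MCMC admixture run, appropriate because the reference
pools are fixed and labelled by design. Zero frequencies are floored at
0.01 and renormalized (the floor convention of frequency-based assignment
software; shared with the frequency-based measure below). EM is started at
q = 0.5, so a perfectly flat likelihood returns 0.5; the likelihood is
asserted non-decreasing at every step, and label swap gives 1 − q to
machine precision. Classification: q > 0.8 coastal, q < 0.2 interior,
boundaries inclusive to the hybrid class (the parental inequalities are
strict). `calibrate_thresholds` reproduces the F1-simulation protocol:
120 + 120 parental genotypes, 120 simulated F1s (one gamete drawn from
each pool's observed frequencies per locus), five replicates, confusion
tables per replicate and pooled.

Assignment measures: the frequency-based log-likelihood (HWE genotype
probability under reference frequencies, floored), and the Bayesian
posterior-predictive probability with a symmetric Dirichlet 1/k prior on
reference counts, k the allele count at the locus across all references
(hom: (n_a+1/k)(n_a+1+1/k)/((n+1)(n+2)); het: 2(n_a+1/k)(n_b+1/k)/((n+1)(n+2))).
The two agree in the large-reference limit (tested). Scores are
likelihoods normalized to percentages per individual; a population's
assignment is the reference maximizing the mean percentage score over its
individuals (the mean-of-individual-% aggregation; scoring the pooled
likelihood instead is a one-line variant), ties broken by reference order
with a warning.

## Parentage

Single-parent LOD per locus: ln(T_e / P(g_o)), with T the Mendelian
single-parent transition probability (untransmitted allele from population
frequencies), P the HWE genotype probability, and the error blend
T_e = (1−e)²T + (1−(1−e)²)P at e = 0.01. Confidence uses Δ (LOD gap
between best and second-best candidate): critical Δ values at 95% and 80%
come from simulated mating events (default 10,000; the synthetic-stand
recovery test uses 1,000) with the true parent present among candidates
with probability `prop_parents_sampled` (default 0.5 — this proportion is
not published; it is configuration), per-locus mistyping at 0.01 and
optional missingness. The critical Δ is the smallest threshold above which
realized accuracy reaches the level. Candidates are all genotyped adults
of the stand. Dispersal = Euclidean distances of strictly assigned pairs,
summarized min/max per stand; parent-pair reconstruction and
seed-vs-pollen dissection are out of scope.

## Spatial genetic structure

Loiselle kinship per locus l:
F_ij = [Σ_a (x_ia − p̄_a)(x_ja − p̄_a) + Σ_a p̄_a(1−p̄_a)/(n_l−1)] / Σ_a p̄_a(1−p̄_a)
with dosages x ∈ {0, ½, 1} and reference frequencies from the analysed
cohort itself (old trees and regeneration are analysed separately; a
pooled reference is a flag). Multilocus values weight loci by
Σ p̄(1−p̄); monomorphic loci get weight zero. b_log is the OLS slope of
F_ij on ln d_ij over all pairs, unweighted (pairs, not individuals, enter
the regression); its SE is the delete-one-locus jackknife; significance is
one-sided from permuting spatial positions among individuals (default
10,000 permutations), p = (1 + #{b_perm ≤ b_obs})/(1 + n_perm). Coincident
coordinates are jittered by 0.01 m with a warning (ln 0 is undefined; the
choice is inconsequential at mapping precision). Distance classes are
left-open right-closed with upper edges 5, 10, 20, 40, 80, 160 m;
correlogram envelopes are the 2.5/97.5 permutation percentiles per class.
Sp = −b_log/(1 − F₁) exactly, F₁ the first-class mean kinship. All pairs
enter the regression by default; `max_dist` caps the range if desired.

## Climate space

PCA is computed on z-scored variables (the ten descriptors mix Julian
dates, mm, °C and degree-days, so correlation-structure PCA is the only
defensible choice); the smallest number of components reaching 97%
cumulative variance is retained. The native-range populations can be the
fitting set with introduced sites projected in (default when a fit subset
is given; joint fitting is the alternative). Pairwise distance
d_ij = √(Σ_k w_k (PC_ik − PC_jk)²) with w_k = λ_k/Σλ over retained
components — "weighted for the eigenvalue" is ambiguous between λ, √λ and
the share; the share is the default and the convention is a parameter,
with only convention-independent properties asserted in tests. UPGMA uses
average linkage with ultrametric heights (tip depth = cophenetic
distance/2), emitted as newick. The G-test compares the realized
stand-to-assigned-origin climatic distances against all stand×origin
distances: equal-width bins over the pooled range (10 by default),
expected counts rescaled to the realized total, zero-expectation bins
merged into neighbours, G = 2ΣO·ln(O/E), df = non-empty bins − 1, p from
the χ² upper tail. With very few stands the statistic is discrete and the
χ² reference coarse; the calibration test therefore uses 20 stands.

## Synthetic data: what it emulates, and what it does not

`generate_metapopulation` mirrors the reference design — 2 varieties × 3
clusters × 6 populations (36 populations of 20 diploids; the real panel
has 38) at 13 loci with 5–15 alleles each — via hierarchical
Balding–Nichols sampling: each level's frequencies are Dirichlet around
its parent with concentration (1−F)/F, so the divergence at each level is
a direct, testable parameter. Defaults F(variety)/F(cluster)/F(population)
= 0.08/0.04/0.015: microsatellite-scale differentiation that keeps
within-population He near 0.78, in the vicinity of the high diversity of
real SSR panels (ancestral frequencies use Dirichlet concentration 3 to
keep them even). `generate_stand` places adults uniformly in a
160 × 160 m plot (so all six distance classes are populated), draws
offspring mothers uniformly, positions offspring by a Gaussian seed kernel
(σ_s = 10 m default), and picks fathers by Gaussian pollen-kernel weights
(σ_p = 30 m) or replaces them by immigrant gametes (30% default), emitting
the full pedigree. `generate_climate` uses a 4-factor latent model whose
group means form a balanced Hadamard simplex and whose loadings are
orthonormalized — with anisotropic between-group geometry, the
eigenvalue-share-weighted distance can crush a single group contrast and
clustering recovery becomes seed-dependent; the balanced design makes
recovery a stable property of the separation parameter.

What the generators do **not** emulate: mutation within the stand
pedigree, null alleles and genotyping artefacts beyond the parentage
module's explicit corruption model, linkage, isolation-by-distance within
the native range, demographic history (refugia, expansion), and
climate–genotype correlation (climate groups are independent of the
genetic hierarchy unless the caller aligns them). Passing tests therefore
demonstrate the correctness and calibration of the estimators under the
stated models, not robustness to these real-data complications.

## Numerical conventions

Frequencies sum to 1 within 1e-12; EM tolerance 1e-6 (clamped to [0,1]);
LOD uses −∞ for Mendelian exclusion at e = 0; Monte-Carlo p-values carry
the +1/2 (mid-p) or +1 (permutation) continuity corrections stated above;
UPGMA ties resolve deterministically in label order; all stochastic
procedures take explicit seeds and are bit-reproducible. Problem sizes in
the test suite (e.g. 200 SGS null replicates at 200 permutations, 80
retained equilibrium replicates per locus, 1,000 simulated mating events)
are the package's chosen desk-scale defaults for calibration work;
production defaults follow the cited protocols (10,000 permutations,
10,000 mating events).
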