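# Methods

`strpop` implements the statistical toolchain used to characterise a
conservation-managed livestock population from a codominant STR
(microsatellite) panel: per-locus diversity summaries, Wright's fixation
indices by the Weir–Cockerham estimator, Nei's DA distances, parentage and
identity power statistics with panel-level combination, Bayesian admixture
clustering with the Evanno ΔK model-choice rule, and a Balding–Nichols
simulator that reproduces the sampling design of a six-sire-line horse study
(196 individuals: 48/12/35/32/36/33 across lines, 17 ISAG loci of which LEX3
is X-linked).

## Data model

A `GenotypeTable` stores two integer allele calls per individual × locus;
0 encodes missing, and a genotype is either fully missing or fully called
(half-missing genotypes are validation errors, following the GenAlEx
convention). Allele codes are abstract integers — the simulator emits
fragment-size-styled codes (90, 92, 94, …) purely for realism. Males at an
X-linked locus carry one physical allele, stored as a doubled code plus a
hemizygous flag. The default throughout is to count the doubled copy twice,
so a naive observed-heterozygosity computation sees hemizygous males as
homozygotes; this matches how mixed-sex samples at LEX3 are tabulated in
practice (near-zero Ho at an otherwise diverse locus) and keeps every
downstream statistic consistent. Frequency estimation can instead count one
copy per hemizygote (`count_hemizygous_once=True`).

## Diversity statistics

With allele frequencies p at one locus in one population of n genotypes:

- Na = number of observed alleles; Na(freq ≥ 5%) counts alleles at
  frequency ≥ 0.05 (the "common allele" convention);
- Ae = 1/Σp², effective allele number; I = −Σ p ln p, Shannon index;
- He = 1 − Σp² and uHe = He·2n/(2n−1), the uncorrected and sample-size
  unbiased expected heterozygosities. Both are reported; published tables
  rarely say which variant they used, so neither is privileged;
- Ho = fraction of non-missing genotypes with two distinct alleles;
- PIC = 1 − Σp² − Σ_{i<j} 2p_i²p_j², which is ≤ He with equality only at
  fixation;
- private alleles: an allele is private to a population when it is observed
  in no other population; the per-population summary is the mean count over
  loci;
- allelic richness by hypergeometric rarefaction,
  AR_g = Σ_a [1 − C(N−N_a, g)/C(N, g)], the expected allele count in a
  standardised draw of g gene copies. The default g is twice the smallest
  per-population genotype count at the locus (the largest size every
  population can supply), and AR_N recovers Na exactly.

## F-statistics

Per locus, the Weir–Cockerham (1984) variance components a (among
populations), b (among individuals within populations) and c (within
individuals) are computed allele by allele — treating each allele as a
biallelic indicator with frequency p_i, heterozygote fraction h_i, sample
sizes n_i across r populations — and summed over alleles before forming
F_ST = a/(a+b+c), F_IT = 1 − c/(a+b+c), F_IS = 1 − c/(b+c). The identity
F_IT = F_IS + F_ST − F_IS·F_ST holds to floating tolerance.

Two multi-locus summaries are reported, because published tables mix them:
the arithmetic mean of per-locus ratios (the convention behind a printed
"Mean" row) and the ratio of summed components (FSTAT's "overall"
estimator). Monomorphic loci have undefined ratios and are excluded from
means. X-linked loci violate the diploid sampling model when males are
scored — stored hemizygotes inflate the apparent homozygote excess, driving
per-locus F_IS toward the male fraction — so `x_linked_exclusion` builds
per-statistic exclusion sets and the pipeline reports means both with and
without X-linked loci. Notably, in the study this package emulates, the
printed multi-locus FIT mean recomputes as the all-17-loci mean while the
FIS mean recomputes as the 16-autosomal-loci mean; the report annotates both
conventions rather than guessing one.

## Nei's DA distance

DA(x, y) = 1 − (1/L) Σ_loci Σ_alleles √(x_a y_a), with L the number of loci
scored in both populations (loci missing in either member of a pair are
dropped pairwise and L adjusted). Identical frequency distributions give 0,
fully disjoint allele sets give 1, and under Balding–Nichols divergence the
mean pairwise DA is monotone in the differentiation parameter. No tree
construction is provided.

## Parentage and identity statistics

Let a_k = Σ p_i^k. Per locus:

- PD = 1 − Σ_g f_g² over genotype frequencies. The default uses
  HWE-expected genotype frequencies from allele frequencies; observed
  genotype tallies can be passed instead.
- PE = h²(1 − 2h(1−h)²) with h the observed heterozygosity. This treats
  exclusion power as a function of Ho alone; it reproduces, row for row, the
  published per-locus PE values of the panel this package emulates from the
  published Ho values (two rows differ in the 4th decimal only because the
  published Ho are themselves rounded to 4 decimals).
- PE1 = 1 − 4a₂ + 4a₃ − 3a₄ + 2a₂²: the probability that a random unrelated
  candidate shares no allele with a random true offspring (only the
  candidate parent typed).
- PE2 = 1 − 2a₂ + a₃ + 2a₄ − 3a₅ − 2a₂² + 3a₂a₃: the probability that an
  unrelated candidate cannot supply the obligate allele given the known
  parent and offspring (both parental genotypes available).
- PID = Σp_i⁴ + Σ_{i<j}(2p_ip_j)²: the probability two unrelated
  individuals share a genotype.

The closed forms are a convenience; the semantics are *defined* by
exhaustive enumeration oracles (`exclusion_duo_enumeration`,
`exclusion_trio_enumeration`, `pid_enumeration`) that enumerate all
genotypes under HWE with explicit Mendelian transmission. The acceptance
suite verifies agreement to 1e−12 on 1000 random frequency vectors with
2–10 alleles, which sidesteps the formula-variant ambiguity endemic to the
exclusion-probability literature.

Across an independent panel, powers combine as 1 − Π(1 − x_l) and the
identity probability as Π PID_l; cumulative powers are monotone
non-decreasing in panel size and CPID non-increasing. Percentages are
displayed at 4 decimals of percent.

## Admixture clustering and ΔK

The clustering model is the standard admixture mixture model for unlinked
codominant loci: cluster allele frequencies P with symmetric Dirichlet(λ)
priors (λ = 1), individual admixture proportions q ~ Dirichlet(α), and a
latent cluster of origin for every allele copy. A Gibbs sweep updates
origins given (P, Q), P and Q from their Dirichlet posteriors, and α by a
Metropolis random walk (s.d. 0.025, uniform prior on (0, 10]) — the
standard defaults of the reference implementation of this model. A
no-admixture variant sits behind a flag. Missing allele copies are skipped;
X-linked copies enter doubled by default, with an exclusion option. The
evidence per K is estimated from the post-burn-in trace of ln P(X | P, Q)
as mean − variance/2, and the Evanno statistic over replicate runs is
ΔK = |L(K+1) − 2L(K) + L(K−1)| / sd(L(K)), defined only at interior K; a
zero replicate s.d. yields an infinite ΔK, flagged rather than dropped.
Replicate chains are aligned by permuting cluster labels to maximise summed
column covariance with the first replicate, solved exactly as an assignment
problem (for small K this coincides with exhaustive search over K!
permutations, which the tests verify).

Chain-length defaults are desk-scale (burn-in 5,000 of 20,000 total
sweeps); `iters` counts total sweeps including burn-in. The simulation-
recovery checks use two populations at F_ST = 0.2 with burn-in 2,000 of
8,000 sweeps and 5 replicate chains over K = 1..5, sizes at which the ΔK
arg-max identifies the true K = 2 reliably while a full ladder runs in
about a minute on one core.

## Synthetic data generator

The generator parameterises differentiation directly by F_ST via the
Balding–Nichols construction: ancestral frequencies per locus are
Dirichlet(λ_anc·1_k) with allele count k uniform on 3–12, subpopulation
frequencies are Dirichlet(p(1−F)/F) — so Var(p̃) = F·p(1−p) — and genotypes
follow the inbreeding law P(ii) = p_i² + F_IS·p_i(1−p_i),
P(ij) = 2p_ip_j(1−F_IS). A coalescent simulator with a mutation model was
not needed: every statistic in the package is a functional of allele
frequencies, and Balding–Nichols exposes precisely the parameter (F_ST)
that the recovery checks target.

Defaults encode the emulated study design: six populations of sizes
48/12/35/32/36/33, 17 loci with the last X-linked, F_ST = 0.03 (the
observed regime), male fraction 0.5 for the X-linked locus (no sex ratio is
reported). F_IS defaults to 0 rather than the study's −0.013: the genotype
law requires F_IS ≥ −p/(1−p) for every allele, which a negative default
would violate whenever the Dirichlet draw produces a rare allele, and the
study's estimate is statistically indistinguishable from zero. Invalid
combinations raise with the offending locus and allele named.

What the generator deliberately does not emulate: genotyping error and
allelic dropout, mutation (no stepwise model), linkage between loci,
pedigree structure within lines, and missing data (tables are fully
scored). Passing recovery tests therefore show the estimators are correct
under the idealised frequency model, not that they are robust to those
real-data artefacts.

## Numerical choices and degenerate inputs

Frequencies must lie on the simplex to 1e−9 for the forensic functions;
monomorphic loci yield zero power and PID = 1 and combine as neutral panel
members. Rarefaction requires 1 ≤ g ≤ N. Sampling in the Gibbs sweep guards
zero-probability rows before normalisation (floors at 1e−300 in log space);
the lnPD variance term uses the unbiased (ddof = 1) estimator. Means over
loci exclude undefined records rather than propagating NaN. All randomness
flows through `numpy.random.default_rng(seed)`; every simulation, chain and
pipeline run is bit-for-bit reproducible given its seed, and ladder
replicate r of K derives its seed as `seed + 1000·K + r`.

## Known limitations

Per-locus published values of the emulated study are not recomputable —
the raw genotypes were never deposited — so correctness at that level rests
on the aggregation identities, the PE-from-Ho functional relationship, the
enumeration oracles and simulation-based parameter recovery. The clustering
module implements the admixture and no-admixture models only (no linkage or
correlated-frequencies models) and ΔK magnitudes depend on replicate counts
that published figures rarely state; only the arg-max is a stable target.
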