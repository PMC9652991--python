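# Methods

This package re-implements, as one tested pipeline, the population-genomic
workflow used to dissect divergence, admixture and secondary contact in a
widely distributed spiny-lobster species complex: SNP quality control,
diversity and differentiation statistics, outlier scanning, admixture and
hybrid-category inference, and two-population demographic model fitting on
the folded joint allele-frequency spectrum (AFS). Every analysis can be
exercised end-to-end on synthetic coalescent data; this note records the
models, the numerical choices, and what the synthetic validations do and do
not establish.

## Data model and formats

Genotypes are diploid biallelic SNPs coded as alternate-allele counts
(0/1/2, missing = −9) with one population label per individual. Which
allele is "alternate" is arbitrary: every statistic in the package is
invariant to per-locus allele re-orientation (folding, minor-allele
frequencies, heterozygosity counts, Weir–Cockerham components are all
orientation-free), which the test suite asserts directly. STRUCTURE text
(both the two-rows-per-individual and one-row dialects, auto-detected from
row-label repetition and logged), the DArT two-row scoring CSV (with call
rate, repeatability, depth, tag id/position and tag sequence metadata), a
minimal GT-only VCF (write), and aligned FASTA for mitochondrial
control-region haplotypes are supported.

## Quality control

Filters run in a fixed, logged order with per-step attrition counts:
monomorphic removal; locus call rate < 0.90; individual call rate < 0.80;
mean depth < 5; technical repeatability < 0.95; one SNP per sequenced tag
(highest call rate kept, ties to the smaller position in tag); a paralog
screen dropping one member of any tag-sequence pair with normalized Hamming
distance ≤ 0.25; an exact Hardy–Weinberg test (conditional on allele
counts, two-sided by summing probabilities ≤ that of the observed table)
applied within each population with loci removed at P < 1e−5 in any
population — pooled testing would confound the Wahlund effect of mixing
diverged populations with genotyping error; Plink-style windowed LD pruning
(r² > 0.80, window 50, step 5, the lower-call-rate member of the worst pair
dropped greedily); missingness > 10%; and minor-allele frequency < 2%. All
inequalities are strict as listed. Statistics are recomputed on the
progressively filtered matrix, so a locus can legitimately cross the
missingness threshold after low-call individuals are removed. The synthetic
QC fixture plants exactly one violation per rule and carries a ground truth
computed by an independent brute force (plain loops, exact rational
arithmetic); the pipeline must reproduce it exactly.

## Diversity and differentiation

Per population: observed heterozygosity; unbiased expected heterozygosity
2p(1−p)·2n/(2n−1); the multilocus ratio estimator F_IS = 1 − ΣHo/ΣHe
(the package's choice among closely agreeing multilocus estimators;
published values from other estimators are matched within ±0.02);
multilocus heterozygosity and standardized MLH (individual heterozygosity
divided by the mean heterozygosity of the loci it was typed at, population
mean ≈ 1); and allelic richness rarefied to g gene copies,
AR = Σ_alleles [1 − C(N−N_i, g)/C(N, g)], with g defaulting to twice the
smallest population size. Pairwise differentiation uses the Weir–Cockerham
(1984) ratio-of-sums multilocus θ with permutation p-values (individuals
shuffled within the pair, 999 permutations by default, seed recorded).

AMOVA is computed at the gene-copy level: each individual contributes two
allele copies, the squared inter-copy distance is the allele mismatch count
summed over loci (pairwise deletion, rescaled to the full locus count), and
permutations shuffle whole individuals. Working on gene copies rather than
0/1/2 genotype codes matters: genotype-code distances inflate the
among-population variance share (under Hardy–Weinberg the index tends to
2F/(1+2F) instead of F), whereas the gene-copy index is commensurate with
Weir–Cockerham θ — the package asserts agreement within ±0.02 on balanced
two-population data. Φ_ST for haplotype alignments runs the same
variance-component machinery on pairwise nucleotide mismatch counts
(alignment columns with gaps or N are dropped pairwise).

## Outlier scan

A neutral null cloud of (He, F_ST) pairs is simulated under a hierarchical
island model (2 groups × 5 demes by default; deme sizes equal; more
migration within than between groups), one gene tree per locus with a
single branch-length-weighted mutation (fixed-S conditioning). The
migration scale is calibrated iteratively until the realized mean null F_ST
is within ±0.005 of the observed multilocus value (batch size grows near
convergence; failure after 50 iterations raises with the trace). Observed
loci are assigned two-sided empirical p-values from the null F_ST
distribution conditional on heterozygosity (bins of 0.05, pooled with
neighbours until ≥ 50 null points). Because empirical p-values are floored
at ~1/bin-size — far too coarse for a genome-wide FDR step — observations
beyond nearly all null draws get a generalized-Pareto upper-tail estimate
fitted to the top decile of their conditional null (the standard
permutation-tail smoothing); FDR calibration on null data is verified by
simulation. Benjamini–Hochberg q-values flag divergent/balancing outliers
at q ≤ 0.05. The production default of 100,000 null simulations is scaled
to 10,000 in the acceptance checks.

## Admixture and hybrid categories

The admixture model treats genotypes as binomial draws from
p_il = Σ_k q_ik f_kl. Plain EM updates of Q and F (multiplicative updates
with the log-likelihood asserted non-decreasing every iteration, multiple
seeded restarts) target the same optimum as block-relaxation
implementations; cluster allele frequencies are clipped to [1e−6, 1−1e−6].
K is selected by masked cross-validation: a fraction (default 5%) of
non-missing genotype entries is hidden, the model fitted, and the binomial
cross-entropy of the hidden entries averaged over folds.

Hybrid classification uses the six canonical two-generation categories with
fixed ancestry-pair proportions (P0 (1,0,0), P1 (0,0,1), F1 (0,1,0),
F2 (¼,½,¼), BC0 (½,½,0), BC1 (0,½,½)). A Gibbs sampler alternates:
category assignment per individual (origin states marginalized), origin
pair per genotype given the category, allele-copy attribution to the two
parental frequency pools (heterozygotes with mixed origin resolved by a
Bernoulli draw), Beta(½,½)-conjugate pool updates (Jeffreys prior), and a
Dirichlet update of the category mixing proportions. Known parentals can
be pinned (the z-option) for individuals sampled far from any contact
zone; default off. Defaults are 3 chains × 20,000 sweeps, 5,000 burn-in,
thinning 10; chains disagreeing by a posterior SD > 0.1 for any individual
raise a mixing flag. Classification is normally run on the loci with the
highest parental-pair Weir–Cockerham θ (default n = 300, descending, ties
by locus order, undefined θ last).

## Demographic inference

The observable is the folded joint AFS at a fixed projection (default
(20, 20) gene copies), built by per-locus hypergeometric projection of the
observed allele counts (loci with fewer available copies than the
projection are dropped and counted), folded by pooling each cell with its
mirror and halving the ambiguous half-count diagonal; the (0,0) and (n1,n2)
corners and the majority-allele half-plane are masked.

The model family covers splits with optional asymmetric migration,
secondary contact, and post-T2 size change (seven named models). Units are
the diffusion conventions: sizes nu relative to the ancestral N_ref, times
in 2·N_ref generations, migration m_ij = 2·N_ref × the fraction of
population i replaced by migrants from j per generation. The msprime
engine encodes them exactly (ancestral size 0.5 makes one msprime
generation equal one 2·N_ref-generation unit; backwards lineage movement
from p1 to p2 at rate m12).

Expected spectra are Monte-Carlo branch-length averages: the expected mass
in cell (i, j) is the mean total length of branches subtending i copies in
population 1 and j in population 2 across independent msprime gene trees
(the infinite-sites low-mutation limit; multiplying by θ/2 gives expected
SNP counts, with θ profiled out of the likelihood analytically). Data are
matched by the genotype simulator, which conditions each locus on
segregating via Poisson thinning at a small per-tree mutation load
(default 0.05–0.1 expected mutations; acceptance ∝ 1−exp(−μℓ) is
length-biased exactly as the branch expectation requires, with a
second-order distortion well below Monte-Carlo error at 2000 loci). The
two engines cross-validate by a chi-square test in the suite.

Fitting maximizes the Poisson composite likelihood with
θ̂ = Σdata/Σmodel. Two numerical points matter:

- **Aggregated fit statistics.** Per-cell Poisson evaluation of a
  Monte-Carlo model spectrum is biased against concentrated spectra: cells
  fed by rare tree topologies are underestimated (often to zero) at
  affordable replicate counts, and E[log m̂] < log E[m̂] penalizes exactly
  the parameter regions with high per-cell variance. The optimizer
  therefore scores a fixed coarse binning of the folded spectrum (bands
  doubling in allele count: {0},{1},{2},{3–6},{7–20}) during global search,
  and a finer ~×1.8 binning during local polish and reporting. Both are
  legitimate composite likelihoods of the same observable; the Jensen
  correction d·Var(m̂)/(2m̂²) (capped) is applied where per-cell variances
  are tracked.
- **Search strategy.** The surface is multimodal (strong secondary contact
  is mimicked by shallow splits) and nearly flat along two directions. The
  fit therefore runs: (A) a global screen — log-uniform random draws plus a
  factorial grid over split-time magnitudes × size pairs × asymmetric
  migration pairs × relative event-time fractions (random draws almost
  never coordinate nu with T1, so the structured grid seeds every
  qualitatively distinct basin) — with Nelder-Mead polish of the best
  points in log-parameter space at ~250 engine replicates, terminals
  re-scored at higher replicates; (B) fine-statistic Nelder-Mead restarts
  at ~1000 replicates; (C) profile refinements at ~4000 replicates with
  common random numbers along the two flat directions: T1 alone (absolute
  T2 held fixed) and the family's near-exact scaling symmetry
  (nu, T → s·nu, s·T; m → m/s), which only the fixed ancestral size breaks.
  T2 is parameterized as a fraction of T1 so T1 > T2 > 0 holds by
  construction; common random numbers hold the engine seed fixed within a
  stage so the simplex sees a smooth surface, and the Nelder-Mead simplex
  is initialized with ~e^0.5-fold coordinate steps (the scipy default 5%
  perturbation is below the Monte-Carlo noise floor in log space and
  stalls). The default production schedule (96 random draws, 4 polished
  basins, 2 extra restarts) is reduced in the acceptance script and tests
  (8 random draws, 3 basins, no restarts, capped simplex iterations) to
  fit a single-CPU budget; problem sizes are stated where used.

AIC = 2k − 2·log-likelihood ranks models fitted to the same data
(fingerprint-checked), with ΔAIC and Akaike weights reported and
Anscombe-style residual spectra available for the visual check. Fitted
parameters convert to biological units via N_ref = θ/(4μL) (default
μ = 8e−8 per site per generation; L and generation time are explicit
inputs, as no single defensible default exists for reduced-representation
data), split time T1·2·N_ref generations, per-generation migrant fraction
m_ij/(2N_ref), and effective migrants m_ij·nu_i/2; an exact algebraic
inverse is provided and tested.

**Identifiability.** Split-time recovery was profiled for the three study
parameter regimes at the study scale (2000 SNPs, folded (20,20) spectrum),
with a sobering outcome: the scaling symmetry is the binding constraint in
every one of them. Varying T1 alone (other parameters held) produces
clear curvature — which makes single-parameter profiles look encouraging —
but along the joint ridge (all sizes and times rescaled, migration
inversely) the log-likelihood is flat to within 0.1–0.5 units across
several-fold rescalings, verified at 25–50k common-random-number
replicates at both binned and per-cell resolution. The only scale
information comes from the fixed ancestral size, and at this SNP count it
is smaller than the data's own sampling noise. The recent-split regime
(C–MI) adds a second pathology: deep-split models with weak ancient
migration near migration-drift equilibrium tie with — and for some data
realizations genuinely beat — the generating recent-split parameters.
Absolute split times from two-population folded-AFS fits of this size are
therefore order-of-magnitude statements, whichever engine maximizes the
likelihood; relative quantities (size ratios, migration asymmetry, the
ordering T1 >> T2 for the secondary-contact fits) are the robust content.
The package's estimator reliably reaches the ridge (fitted log-likelihoods
match or exceed those of the generating parameters) and then reports the
ridge point the data weakly prefer after dedicated high-replicate profile
scans along T1 and along the scale direction, with the median of replicate
fits quoted.

## ABC cross-check

Rejection ABC over the same model family: parameters drawn log-uniformly
from user priors, data simulated with the genotype simulator, summaries
(per-population expected heterozygosity, pairwise θ, private-polymorphism
fractions, quartiles of the folded per-population minor-allele-frequency
distribution) z-scored over the pooled simulation cloud, the nearest
tolerance-fraction accepted, model posterior = acceptance share, and a
posterior-predictive goodness-of-fit quantile for the winning model. The
production default of 1e6 simulations per scenario is scaled to hundreds
in tests, which still verify the calibration property (the generating
model is preferred in most replicates).

## Synthetic data: what it does and does not establish

The generators produce unlinked loci (independent gene trees), matching
the AFS likelihood's independence assumption and the effective linkage
state of LD-pruned reduced-representation data; hybrid swarms are exact
Mendelian draws from parental pools at a target F_ST (Balding–Nichols) or
a fixed-difference fraction; mtDNA-like haplotypes are two clades under a
single-parameter substitution model. Real data differ in ways the
synthetic validations deliberately do not model: linked sites within tags,
allele-specific sequencing error and depth-dependent dropout, ascertainment
from the array design, and departure of real demography from the fitted
family. Passing the synthetic checks therefore establishes the
correctness of the implementations and the internal consistency of the
inference chain, not the adequacy of any model for a particular organism.

## Degenerate inputs and tie-breaks

All-missing loci are treated as monomorphic by QC and undefined by MAF;
populations of size one get NaN diversity statistics; monomorphic data give
AR = 1 exactly and untestable outlier status; all-identical alignments have
undefined Φ_ST; filters completing to an empty matrix return a
zero-remaining report rather than raising. Ties anywhere (equal call
rates, equal θ) resolve to the earlier locus in matrix order except where
a rule states otherwise (one-SNP-per-tag prefers the smaller position in
tag; Hamming and LD ties drop the later locus).
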