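# spinypop

Population-genomic analysis of divergence, admixture and secondary contact
from genome-wide SNPs, built for the study system of a widely distributed
Indo-Pacific spiny-lobster species complex whose peripheral populations
(South Africa, Northwest Indian Ocean, Marquesas) show a mix of old
divergence, recent gene flow and hybrid origins.

The package covers the full pipeline a population genomicist runs on
reduced-representation (DArTseq-style) SNP data:

- **QC** — the standard filter protocol in a fixed order (call rates 0.90
  loci / 0.80 individuals, depth ≥ 5, repeatability ≥ 0.95, one SNP per
  tag, Hamming ≤ 0.25 paralog screen, exact HWE P < 1e−5 per population,
  LD r² > 0.80 pruning, missingness > 10%, MAF < 2%) with a per-step
  attrition ledger.
- **Diversity & structure** — Ho, unbiased He, multilocus F_IS, MLH/sMLH,
  rarefied allelic richness; pairwise Weir–Cockerham
  F_ST = Σa / Σ(a+b+c) with permutation tests; gene-copy-level AMOVA; and
  Φ_ST on mitochondrial control-region alignments.
- **Outlier scan** — FDIST-style: a hierarchical-island coalescent null of
  (He, F_ST) pairs calibrated to the observed multilocus F_ST,
  heterozygosity-conditional p-values with generalized-Pareto tail
  smoothing, Benjamini–Hochberg FDR.
- **Admixture & hybrids** — EM on the binomial admixture likelihood
  P(g_il) = Binom(g | 2, Σ_k q_ik f_kl), masked cross-validation for K,
  and a NewHybrids-style Gibbs sampler over the six two-generation
  categories (P0, P1, F1, F2, BC0, BC1) with Jeffreys Beta(½,½) priors,
  run on the highest-F_ST loci between designated parental populations.
- **Demography** — the core: folded joint allele-frequency spectra by
  hypergeometric projection, a seven-member family of two-population
  split/migration/size-change models (diffusion units: nu relative to
  N_ref, T in 2·N_ref generations, m = 2·N_ref·m_raw), expected spectra by
  Monte-Carlo branch-length coalescent simulation (msprime), Poisson
  composite likelihood with θ profiled out, a multi-stage derivative-free
  optimizer, AIC model ranking, conversion to biological units
  (N_ref = θ/4μL, default μ = 8e−8), and a rejection-ABC cross-check.
- **Synthetic data** — coalescent genotype matrices under any model of the
  family or an island model, Mendelian hybrid swarms, mtDNA-like
  haplotypes, and a pre-QC fixture with planted violations of every filter
  rule plus independently computed ground truth.

## Worked example

```sh
python analysis/01_qc_filtering.py
```

```
pre-QC matrix: 44 individuals x 73 loci
  monomorphic        -  1 loci  -0 individuals (72 x 44 remain)
  locus_call_rate    -  1 loci  -0 individuals (71 x 44 remain)
  indiv_call_rate    -  0 loci  -5 individuals (71 x 39 remain)
  min_depth          -  1 loci  -0 individuals (70 x 39 remain)
  repeatability      -  1 loci  -0 individuals (69 x 39 remain)
  one_snp_per_tag    -  1 loci  -0 individuals (68 x 39 remain)
  hamming            -  1 loci  -0 individuals (67 x 39 remain)
  hwe                -  1 loci  -0 individuals (66 x 39 remain)
  ld_prune           -  1 loci  -0 individuals (65 x 39 remain)
  max_missing        -  1 loci  -0 individuals (64 x 39 remain)
  min_maf            -  1 loci  -0 individuals (63 x 39 remain)
retained 63 loci, 39 individuals; matches independent brute-force ground truth: True
```

Each line is one filter step: the planted violation of that rule (and only
it) is removed, five low-call-rate individuals drop out at the individual
step, one locus crosses the 10% missingness threshold only because those
individuals left, and the final matrix agrees exactly with a brute-force
re-derivation that shares no code with the pipeline.

The demographic driver (`analysis/05_demography.py`) simulates SNPs under
the secondary-contact history fitted for the central/South-African pair
(deep split T1 ≈ 15 in 2·N_ref generations, isolation, then recent
asymmetric gene flow m21 ≈ 22 into the peripheral population), rebuilds
the folded joint AFS, and refits competing models: strict isolation loses
to secondary contact by AIC, and the fitted parameters convert to census
quantities via N_ref = θ/(4μL).

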