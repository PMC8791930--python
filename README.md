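# mitonuclear

Detecting **mito-nuclear epistasis** — joint effects of a nuclear SNP
(nuSNP) and a mitochondrial SNP (mtSNP) beyond their additive
contributions — on nuclear morphology phenotypes extracted from
H&E-stained histology, with a downstream survival read-out. The package
is aimed at statistical geneticists and computational pathologists who
want a tested, reusable implementation of this analysis chain that runs
end-to-end on synthetic data (no controlled-access downloads required).

## What it computes

**Phenotypes.** Each RGB tile passes a brightness QC (excluded if the
85th percentile of pooled pixel values is < 15 or the 15th percentile
is > 240), is colour-deconvolved to the hematoxylin channel
(Ruifrok–Johnston stain vectors, optical density −log10((v+1)/256)),
thresholded at half the channel mean, and segmented by hole filling, an
equivalent-radius ≥ 10 px filter, and watershed on distance-transform
maxima (search radius 10 px). Per tile: number of nuclei, Size Area
(object pixels), Intensity (mean stain over objects), Circularity
(mean 4πA/P², P traced through border-pixel centres). Per subject:
log2(mean Size Area / mean nuclei) and log2(mean Intensity / mean
nuclei).

**Genotypes.** Autosomal nuSNPs are dropped at call rate < 0.95, exact
Hardy–Weinberg p < 10⁻³, or minor-allele frequency < 0.05; residual
missingness is imputed from the per-SNP genotype distribution; coding is
minor-allele dosage N ∈ {0,1,2}. mtSNPs are binary carrier codes
M ∈ {0,1}, kept at carrier frequency ≥ 0.05. Nuclear SNPs can be
restricted to gene intervals (BED, ±10 kb flank). An identity-by-state
kinship K (K_ij = 1 − mean|g_i − g_j|/2) and the top-5 genotype PCs
complete the inputs.

**The interaction test.** For each (nuSNP, mtSNP, phenotype) triple the
mixed model

    Y = β₀ + β₁N + β₂M + β₃(N·M) + S₀ + Σ₅ βPc·Pc + ε,
    S₀ ~ N(0, σ_g² K),  ε ~ N(0, σ_e² I)

is fitted by maximum likelihood twice (with and without the N·M term)
via the EMMA spectral strategy: profile the likelihood over
δ = σ_e²/σ_g² with β and the scale solved in closed form. The statistic
D = −2(ln L_null − ln L_full) is referred to χ²(1); H₀ is β₃ = 0.

**Significance.** p-values become q-values with Storey's estimator,
π₀ estimated by bootstrapping the p-values across λ ∈ {0.05,…,0.95}.
Hits (q < 0.05) must additionally show the minor-minor group (N = 2 and
M = 1) stochastically greater than every other genotype group: one-sided
Mann–Whitney U with within-pair Bonferroni p < 0.05 per comparison, and
a pointwise empirical-CDF dominance check.

**Survival.** Subjects are dichotomized at cohort percentiles
(high-expression & small-nuclei iff expression > P75 and mean Size Area
< P25, else low-expression & large-nuclei); Cox proportional hazards
(Efron ties; likelihood-ratio test with 1 df univariate, 5 df with ER
status and age quartiles) and Kaplan–Meier curves with the log-rank
test.

A synthetic-data module generates every input with the structure the
analysis assumes: admixed Balding–Nichols genotypes with family-block
kinship, Beer–Lambert-rendered H&E-like tiles with planted nuclei,
phenotypes drawn from the mixed model with a plantable β₃, and
exponential survival with a configurable hazard ratio.

## Worked example

`examples/interaction_scan.py` plants β₃ = 1.5 on the log2 nuclei-size
phenotype for one pair in a 200-subject cohort, scans all 100 pairs and
screens the hits:

```
tested 100 (nuSNP, mtSNP) pairs; pi0 = 0.96
significant at q < 0.05: 1
top hit: rs100021 x mt1001 (planted: rs100021 x mt1001)
  D = 54.1, p = 1.90e-13, q = 1.83e-11, beta3_hat = 1.40 (planted 1.5)
  Mann-Whitney post-hoc screen passed: True
```

The scan recovers exactly the planted pair: D is the χ²(1)
likelihood-ratio statistic, β̂₃ = 1.40 estimates the planted 1.5, the
estimated proportion of true nulls (π₀ = 0.96) matches 1 planted signal
among 100 tests, and the post-hoc screen confirms the minor-minor
group's phenotype is stochastically greater than every other genotype
group. The other scripts in `examples/` demonstrate tile morphometry,
VCF-based genotype QC, survival analysis, and the one-command pipeline
(also available as `mitonuc run --config config.yaml`).

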