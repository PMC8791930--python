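# Methods

## The interaction model and its estimation

The phenotype of subject k is modelled as

    Y_k = β₀ + β₁ N_k + β₂ M_k + β₃ (N·M)_k + S₀ₖ + Σ_{c=1..5} β_{Pc} P_{ck} + ε_k

with N the nuclear minor-allele dosage (0/1/2), M the mitochondrial
carrier code (0/1), S₀ ~ N(0, σ_g²K) a polygenic random effect whose
covariance is the kinship matrix, P_c the top-5 genotype principal
components, and ε ~ N(0, σ_e²I). Both genotype codes enter numerically
(additive, 1 df each), which is what makes the interaction test a 1-df
χ² comparison. The null model drops the N·M column only; the statistic
is D = 2(ℓ_full − ℓ_null), clamped at 0 (the models are nested; a
negative value can only arise from optimisation noise and triggers a
warning below −10⁻⁶), with p from the upper χ²(1) tail.

Both fits are **maximum likelihood, not REML**: the LRT compares two
fixed-effect specifications, and REML likelihoods are not comparable
across fixed-effect designs. Estimation uses the spectral
(EMMA-style) reduction: with K = U Λ Uᵀ computed once per cohort,
rotating y and X by Uᵀ turns the covariance into
σ_g²(Λ + δI), δ = σ_e²/σ_g². At fixed δ the GLS coefficients and the
common scale have closed forms, leaving a one-dimensional profile
likelihood in δ. That profile is maximised on a 100-point log-spaced
grid over δ ∈ [10⁻⁵, 10⁵] followed by golden-section refinement of the
bracketing interval — robust to the multimodality a generic optimiser
can trip over, and directly checkable against a dense grid. The
boundary σ_g² → 0 (δ → ∞) is handled explicitly by comparing with the
OLS likelihood; a response lying in the design span is returned as a
non-converged fit with a diagnostic rather than an infinite likelihood.

Known property: with ~200 subjects and 9 fixed effects the ML variance
estimate is biased low by ≈ n/(n−p), so the χ²(1) reference is mildly
anticonservative (measured type-I ≈ 0.052–0.059 at α = 0.05 depending
on how well-populated the genotype cells are). This is inherent to the
ML likelihood-ratio construction, not an implementation artefact; the
calibration simulations in the test suite quantify it.

## Multiple testing and the post-hoc screen

q-values follow Storey's step-up construction,
q_i = min_{p_j ≥ p_i} π₀ m p_j / rank(p_j), with π₀ estimated from the
ladder π₀(λ) = #{p > λ}/(m(1−λ)), λ ∈ {0.05,…,0.95}. The tuning λ is
chosen by a resampling bootstrap (default 100 draws, seeded): resampled
ladders are scored by squared error against a target, and the target is
the **10% quantile** of the observed ladder rather than its raw
minimum — with few tests the largest λ can see zero exceedances, and a
raw-minimum target of 0 would hijack the selection and collapse π₀
(we observed exactly this at m = 100). π₀ is capped at 1 and floored at
1/m; the floor binds only under overwhelming signal (e.g. every p
≈ 10⁻¹⁰). Forcing π₀ = 1 reproduces Benjamini–Hochberg exactly, which
the tests exploit as an oracle.

Significant pairs are screened with one-sided Mann–Whitney U tests: the
reference group U₁ (homozygous nuclear minor AND mitochondrial carrier)
against each other non-empty genotype group (up to 5 comparisons). The
p-value is exact by enumeration when n₁n₂ ≤ 400 and the pooled sample
is tie-free, otherwise the normal approximation with tie and continuity
corrections. A pair passes only if every comparison has Bonferroni
p < 0.05 — the factor is the number of comparisons actually performed
for that pair (within-pair correction; a global variant is a flag) —
and U₁ is stochastically greater by a pointwise empirical-CDF check
(CDF₁ ≤ CDF₂ at all pooled sample points). "Stochastically greater" has
no single operational definition; reporting both the inferential
(one-sided test) and the descriptive (ECDF dominance) criterion makes
the verdict rank-based and monotone-transform invariant. The minimum
group size for a comparison is 1; group sizes are emitted so users can
re-filter.

## Morphology operators

Tile QC pools all three channels before taking percentiles (the rule
speaks of "the pixels" without a channel qualifier). Deconvolution uses
the Ruifrok–Johnston H&E stain matrix (hematoxylin, eosin, and their
cross product, each normalised) against optical densities
−log10((v+1)/256); the +1 guards log 0 and costs at most one grey level.
The foreground threshold is half the channel mean; an all-zero channel
yields an all-foreground mask (permitted, logged). Segmentation fills
holes first, then removes objects whose equivalent radius √(A/π) is
below 10 px, then splits touching nuclei by watershed seeded at
distance-transform local maxima with a minimum mutual distance equal to
the search radius (10 px); the distance transform is capped at the
maximum radius (15 px) so oversized blobs do not spawn spurious seeds.
Labels are renumbered in raster order of centroids, making outputs
byte-reproducible. The per-object perimeter is the closed contour
through border-pixel centres (border = object pixel with a 4-connected
background neighbour), traced by Moore-neighbour tracing with Jacob's
stopping criterion; axis steps count 1 and diagonal steps √2, so a
filled square of side s has perimeter exactly 4(s−1) and circularity
4πs²/(4(s−1))², while a digital disk lands a few percent below 1.
Intensity is measured on the hematoxylin channel (the original-greyscale
alternative is not exposed). Aggregation keeps zero-nuclei tiles in all
means — dropping them would bias the mean nuclei count upward — and a
subject whose tiles contain no nuclei gets a missing phenotype.

## Genotype QC choices

The Hardy–Weinberg filter uses the exact conditional test (recurrence on
the heterozygote count), not χ²: it is the field standard at small
genotype counts and is checkable against exact-integer enumeration.
MAF is computed in-cohort on non-missing calls (the external-reference
alternative would reintroduce a download dependency). Imputation draws
from the per-SNP empirical genotype distribution — "according to the
frequency distribution" is sampling, not mode substitution — with a
per-column child seed so a column's imputation is independent of which
other columns are present. Minor-allele orientation flips a column when
the alt frequency exceeds 0.5; an exact 0.5 resolves to the alt allele
and is logged. The gene-interval restriction converts BED's half-open
0-based intervals to 1-based SNP coordinates internally; the flank
default is 10 kb (configurable — "in or near genes" states no
distance). Kinship is additive identity-by-state, matching the additive
kinship of the efficient mixed-model association formulation; the
diagonal is set to exactly 1 and a numerically negative spectrum is
clipped at 0 with re-symmetrisation (the repair perturbation on
simulated panels is below 10⁻⁶ in Frobenius norm). PCA centres and
scales SNP columns, drops constants, and fixes signs by making each
component's largest-magnitude loading positive. PCs are computed on the
full retained panel (whether the original used the gene-restricted or
genome-wide panel is unstated; genome-wide chosen, configurable).

## The synthetic cohort

The generator's defaults are the study conditions the tests assume:
200 subjects, 50 nuclear SNPs with ancestral MAF ~ U(0.1, 0.5), 8
mitochondrial variants with carrier frequency ~ U(0.1, 0.5), 2%
missingness, two ancestral populations, family blocks of 4, σ_g² = 0.3,
σ_e² = 0.7 (unit total variance, 30% heritability on the log2 phenotype
scale), β₀ = 4.0 (the scale of log2 Size-Area-per-nucleus values seen
in breast histology), small main effects (0.05) and β₃ = 0 unless
planted.

Population structure follows Balding–Nichols at Fst = 0.05: ancestral
frequency p per SNP, population frequencies Beta(p(1−F)/F,
(1−p)(1−F)/F), Dirichlet(α = 1) admixture weights per family. With a
single population the ancestral frequency is used directly, so the
marginal MAF is exact — the structure model is a deliberate no-op at
n_populations = 1. Family blocks share admixture weights and a founder
allele pair; each member copies each founder allele with probability
√½ (allele correlation ½ within a block), and the declared kinship is
block-diagonal with 0.5 off-diagonal within families. Phenotypes are
drawn from the interaction model above with the genotype codes oriented
to the minor allele — the same orientation the QC stage produces — so a
planted β₃ keeps its sign and magnitude through the pipeline; the PCs
used are computed by the same `compute_pcs` the scan uses.

Tiles are rendered by Beer–Lambert mixing of the same Ruifrok–Johnston
stain vectors the extractor unmixes with: hematoxylin OD ≈ 0.6 inside
non-overlapping planted disks (rejection-sampled with bounded retries;
an impossible packing raises), eosin 0.15 in the background, plus a 1%
hematoxylin speckle (OD 0.05–0.12) emulating faint debris so an empty
tile still has a non-degenerate channel (isolated speckle pixels are
removed by the radius filter, so an empty tile segments to 0 objects).
Survival times are exponential with group-1 hazard = HR × group-0
hazard; censoring is Uniform(0, u) with u solved so the expected
censored fraction matches the request.

What the generator does **not** emulate: linkage disequilibrium,
heteroplasmy, tissue texture, stain variation across scanners,
nucleus-shape irregularity, informative censoring. Passing tests
therefore demonstrate correctness of the operators and calibration of
the inference under the stated model, not robustness to the full
messiness of scanner data.

## Problem sizes and numerical choices

Simulation-based checks use: 1000 replicates for null calibration
(n = 200 subjects), 200 replicates for β₃ recovery, 50 pipeline seeds
for end-to-end detection (25 nuSNPs × 4 mtSNPs), 100 seeds × 1000
subjects for Cox recovery — sizes chosen so the whole suite completes
in a few minutes while leaving Monte-Carlo noise well inside the
asserted bands. The planted end-to-end effect is β₃ = 1.5 on a
unit-variance log2 phenotype with the most informative pair (highest
minor-allele frequencies) carrying the signal; at ~20 minor-minor
subjects this puts the interaction z-score near 6, a regime where
q < 0.05 detection is expected in ≳ 95% of seeds. Real effect sizes on
the phenotype scale are not knowable from summary reports, so planted
magnitudes are demonstration parameters, not estimates.

Numerical details worth knowing: the δ grid spans [10⁻⁵, 10⁵] with 100
points and golden-section refinement to 10⁻⁸ in log δ; degenerate fits
(zero residual variance relative to the response scale) return
converged = false; rank-deficient designs raise naming the collinear
columns; untestable pairs (constant genotype or interaction columns,
collinear designs) are flagged and excluded from the multiple-testing
family rather than fitted. Quantiles everywhere are the
linear-interpolation (type-7) definition — group membership at
percentile boundaries depends on it — with strict inequalities for the
survival grouping and ties-to-lower-bin for age quartiles. Cox models
use the Efron tie approximation; ER-indeterminate subjects are excluded
from ER-adjusted fits. The single pipeline seed is fanned out to
per-stage child seeds via `numpy.random.SeedSequence`, so any stage can
be rerun in isolation and reruns are byte-identical.

## Limitations

The χ²(1) reference for D is asymptotic; at n = 200 with sparse
genotype cells the test is mildly anticonservative (see above), and no
small-sample (Bartlett-type) correction is applied. The q-value
bootstrap needs a few hundred tests before π₀ is stable; below that the
10%-quantile target keeps it sane but conservative. The watershed
splitter assumes roughly convex nuclei at the stated radius scale.
Mitochondrial variants are treated as binary carrier states —
heteroplasmy fractions are out of scope. The survival stage models a
single categorical exposure with fixed covariates; no time-varying
effects, competing risks, or proportionality diagnostics beyond what
lifelines reports.
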