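"""Generate a synthetic cohort and inspect its genetic structure.

Draws admixed, family-structured diploid genotypes plus binary
mitochondrial carrier codes, then verifies the marginal allele
frequencies and the relatedness structure the downstream mixed model
relies on.
"""

import numpy as np

from mitonuclear.genotype_qc import compute_kinship, impute_panel
from mitonuclear.simulate import SimConfig, generate_genotypes

cfg = SimConfig(n_subjects=200, n_nusnps=60, n_mtsnps=8, seed=42)
cohort = generate_genotypes(cfg)

G = cohort.nuclear_complete.to_numpy(float)
print(f"nuclear genotypes: {G.shape[0]} subjects x {G.shape[1]} SNPs")
print(f"mean minor-allele frequency: {np.minimum(G.mean(0) / 2, 1 - G.mean(0) / 2).mean():.3f}")
print(f"missing entries: {(cohort.nuclear_genotypes.to_numpy() == -1).mean():.3%}")

K = compute_kinship(impute_panel(cohort.nuclear_genotypes, seed=0).to_numpy(float))
blocks = np.arange(cfg.n_subjects) // cfg.family_block_size
iu = np.triu_indices(cfg.n_subjects, 1)
same = (blocks[:, None] == blocks[None, :])[iu]
print(f"mean realized kinship within families: {K[iu][same].mean():.3f}")
print(f"mean realized kinship across families: {K[iu][~same].mean():.3f}")
# Family members share alleles, so their identity-by-state kinship must
# sit clearly above the unrelated background.
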