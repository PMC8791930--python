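"""Genotype QC: filters, imputation, coding, kinship and PCs via VCF.

Writes a synthetic cohort to VCF, reads it back, applies the call-rate /
Hardy-Weinberg / MAF filters, imputes residual missingness from the
per-SNP genotype distribution, recodes to minor-allele orientation and
builds the kinship matrix and the top-5 population-structure PCs.
"""

import tempfile
from pathlib import Path

from mitonuclear import io as mio
from mitonuclear.genotype_qc import (
    code_genotypes,
    compute_kinship,
    compute_pcs,
    filter_mito_snps,
    filter_nuclear_snps,
    impute_panel,
)
from mitonuclear.simulate import SimConfig, generate_genotypes

cfg = SimConfig(n_subjects=150, n_nusnps=40, n_mtsnps=6, missing_rate=0.03,
                seed=11)
cohort = generate_genotypes(cfg)

with tempfile.TemporaryDirectory() as tmp:
    vcf = Path(tmp) / "cohort.vcf"
    mio.write_vcf(vcf, cohort.subjects, cohort.nuclear_genotypes,
                  cohort.mito_genotypes, nuclear_pos=cohort.nuclear_pos,
                  mito_pos=cohort.mito_pos)
    nuclear, mito, meta = mio.read_vcf(vcf)

nuc_meta = [m for m in meta if not m.is_mito]
nuclear, nuc_meta = filter_nuclear_snps(nuclear, nuc_meta)
mito, _ = filter_mito_snps(mito, [m for m in meta if m.is_mito])
print(f"retained {nuclear.shape[1]}/{cfg.n_nusnps} nuclear SNPs "
      f"(call rate >= 0.95, HWE p >= 1e-3, MAF >= 0.05)")
print(f"retained {mito.shape[1]}/{cfg.n_mtsnps} mitochondrial variants "
      f"(carrier frequency >= 0.05)")

nuclear = impute_panel(nuclear, seed=0)
nuclear, mito = code_genotypes(nuclear, mito)
K = compute_kinship(nuclear.to_numpy(float))
pcs = compute_pcs(nuclear.to_numpy(float))
print(f"kinship: diagonal 1.0, off-diagonal range "
      f"[{K[~(K == 1)].min():.3f}, {K[~(K == 1)].max():.3f}]")
print("PC explained-variance fractions:",
      [round(v, 3) for v in pcs.explained_variance])
# The kinship matrix becomes the covariance of the polygenic random
# effect; the PCs enter the mixed model as fixed covariates.
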