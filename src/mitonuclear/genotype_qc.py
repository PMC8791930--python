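"""Genotype quality control, coding, kinship and population-structure PCs.

Nuclear SNPs are diploid minor-allele dosages in {0,1,2}; mitochondrial
variants are binary carrier codes in {0,1} (one value per subject — a
mitochondrial variant carries no diploid dosage). Missing entries are
encoded as -1 throughout.

Filters applied to nuclear SNPs (each a pure per-SNP predicate, so the
outcome is order-independent): sex-chromosome exclusion, call rate
>= 0.95, Hardy-Weinberg exact-test p >= 1e-3, cohort minor-allele
frequency >= 0.05. Mitochondrial variants require a cohort carrier
frequency (VAF) >= 0.05.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SNPRecord", "GenotypePanel", "hwe_exact_test", "filter_nuclear_snps",
    "filter_mito_snps", "impute_missing", "impute_panel", "code_genotypes",
    "restrict_to_gene_set", "compute_kinship", "compute_pcs", "PCCovariates",
]

logger = logging.getLogger(__name__)

MISSING = -1
SEX_CONTIGS = {"chrX", "chrY", "X", "Y"}
MITO_CONTIGS = {"chrM", "MT", "chrMT", "M"}

CALL_RATE_MIN = 0.95
HWE_P_MIN = 1e-3
MAF_MIN = 0.05
VAF_MIN = 0.05


@dataclass
class SNPRecord:
    snp_id: str
    contig: str
    position: int  # 1-based
    alleles: tuple[str, str] = ("A", "G")
    call_rate: float = np.nan
    maf_or_vaf: float = np.nan
    hwe_p: float = np.nan
    is_mito: bool = False


@dataclass
class GenotypePanel:
    """Coded genotype matrices plus per-SNP metadata (column-aligned)."""

    subjects: list[str]
    nuclear: pd.DataFrame  # subjects x nuSNPs, values {0,1,2}
    mito: pd.DataFrame  # subjects x mtSNPs, values {0,1}
    snp_meta: list[SNPRecord] = field(default_factory=list)

    def meta_for(self, snp_id: str) -> SNPRecord:
        for rec in self.snp_meta:
            if rec.snp_id == snp_id:
                return rec
        raise KeyError(snp_id)


def hwe_exact_test(n_het: int, n_hom_minor: int, n_hom_major: int) -> float:
    """Exact Hardy-Weinberg equilibrium p-value (Wigginton et al. construction).

    Sums, over all heterozygote counts compatible with the observed
    allele counts, the conditional probabilities no larger than that of
    the observed configuration. Uses the standard recurrence on the
    heterozygote count for numerical stability.
    """
    if min(n_het, n_hom_minor, n_hom_major) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_het + n_hom_minor + n_hom_major
    if n == 0:
        return 1.0
    n_minor = 2 * n_hom_minor + n_het
    n_major = 2 * n_hom_major + n_het
    if n_minor > n_major:
        n_minor, n_major = n_major, n_minor
    # heterozygote count has the parity of the minor-allele count
    het_candidates = list(range(n_minor % 2, n_minor + 1, 2))
    probs = np.zeros(len(het_candidates))
    # start from the mid-range heterozygote count, probability 1 unnormalised
    mid = n_minor * n_major // (2 * n)
    if mid % 2 != n_minor % 2:
        mid += 1
    idx_mid = het_candidates.index(mid)
    probs[idx_mid] = 1.0
    # recurrence downward: P(h-2)/P(h) = h(h-1) / ((m/2 - h/2 + 1)(M/2 - h/2 + 1)*4)
    for i in range(idx_mid, 0, -1):
        h = het_candidates[i]
        hom_min = (n_minor - h) // 2
        hom_maj = (n_major - h) // 2
        probs[i - 1] = probs[i] * h * (h - 1) / (4.0 * (hom_min + 1) * (hom_maj + 1))
    # recurrence upward
    for i in range(idx_mid, len(het_candidates) - 1):
        h = het_candidates[i]
        hom_min = (n_minor - h) // 2
        hom_maj = (n_major - h) // 2
        probs[i + 1] = probs[i] * 4.0 * hom_min * hom_maj / ((h + 1) * (h + 2))
    probs /= probs.sum()
    p_obs = probs[het_candidates.index(n_het)]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def _snp_stats(col: np.ndarray) -> tuple[float, float, float]:
    """(call_rate, maf, hwe_p) for one raw nuclear genotype column."""
    obs = col[col != MISSING]
    call_rate = len(obs) / len(col)
    if len(obs) == 0:
        return 0.0, 0.0, 1.0
    n_het = int(np.sum(obs == 1))
    n_hom_alt = int(np.sum(obs == 2))
    n_hom_ref = int(np.sum(obs == 0))
    alt_freq = (2 * n_hom_alt + n_het) / (2 * len(obs))
    maf = min(alt_freq, 1.0 - alt_freq)
    hwe_p = hwe_exact_test(n_het, n_hom_alt, n_hom_ref)
    return call_rate, maf, hwe_p


def filter_nuclear_snps(
    genotypes: pd.DataFrame,
    meta: list[SNPRecord],
    call_rate_min: float = CALL_RATE_MIN,
    hwe_p_min: float = HWE_P_MIN,
    maf_min: float = MAF_MIN,
) -> tuple[pd.DataFrame, list[SNPRecord]]:
    """Drop sex-chromosome SNPs, then SNPs failing call-rate/HWE/MAF.

    MAF and the HWE exact test are computed on non-missing calls only.
    Returns the surviving columns and their (updated) metadata records.
    """
    by_id = {m.snp_id: m for m in meta}
    keep = []
    for snp_id in genotypes.columns:
        rec = by_id[snp_id]
        if rec.contig in SEX_CONTIGS:
            logger.info("drop %s: sex chromosome %s", snp_id, rec.contig)
            continue
        col = genotypes[snp_id].to_numpy()
        call_rate, maf, hwe_p = _snp_stats(col)
        rec.call_rate, rec.maf_or_vaf, rec.hwe_p = call_rate, maf, hwe_p
        if call_rate < call_rate_min:
            logger.info("drop %s: call rate %.3f", snp_id, call_rate)
            continue
        if hwe_p < hwe_p_min:
            logger.info("drop %s: HWE p %.2e", snp_id, hwe_p)
            continue
        if maf < maf_min:
            logger.info("drop %s: MAF %.3f", snp_id, maf)
            continue
        keep.append(snp_id)
    return genotypes[keep], [by_id[s] for s in keep]


def filter_mito_snps(
    mito: pd.DataFrame,
    meta: list[SNPRecord] | None = None,
    vaf_min: float = VAF_MIN,
) -> tuple[pd.DataFrame, list[SNPRecord]]:
    """Retain mitochondrial variants with carrier frequency >= vaf_min."""
    by_id = {m.snp_id: m for m in meta} if meta else {}
    keep = []
    for snp_id in mito.columns:
        col = mito[snp_id].to_numpy()
        obs = col[col != MISSING]
        vaf = float(np.mean(obs == 1)) if len(obs) else 0.0
        carrier_is_minor = vaf <= 0.5
        freq = vaf if carrier_is_minor else 1.0 - vaf
        if snp_id in by_id:
            by_id[snp_id].maf_or_vaf = freq
        if freq < vaf_min:
            continue
        keep.append(snp_id)
    if not keep:
        logger.warning("no mitochondrial variants survive the VAF filter")
    return mito[keep], [by_id[s] for s in keep if s in by_id]


def impute_missing(column: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Fill missing calls by sampling the empirical genotype distribution
    of the non-missing calls; non-missing entries are never changed."""
    col = np.asarray(column).copy()
    miss = col == MISSING
    obs = col[~miss]
    if len(obs) == 0:
        raise ValueError("all calls missing: column should have been filtered")
    if miss.any():
        cats, counts = np.unique(obs, return_counts=True)
        col[miss] = rng.choice(cats, size=int(miss.sum()), p=counts / counts.sum())
    return col


def impute_panel(genotypes: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Column-wise frequency imputation with a per-column child seed, so a
    column's imputation does not depend on which other columns are present."""
    ss = np.random.SeedSequence(seed)
    out = {}
    for i, snp_id in enumerate(genotypes.columns):
        rng = np.random.default_rng(ss.spawn(i + 1)[0])
        out[snp_id] = impute_missing(genotypes[snp_id].to_numpy(), rng)
    return pd.DataFrame(out, index=genotypes.index)


def code_genotypes(
    nuclear: pd.DataFrame, mito: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Recode to minor-allele orientation.

    Nuclear: number of minor alleles (0,1,2) — if the alt allele is the
    major one the column is flipped (2 - g). Mitochondrial: 1 if the
    subject carries the minor allele else 0. Exact 50/50 frequencies
    resolve the minor allele to the alt allele (logged).
    """
    nuc = nuclear.copy()
    for snp_id in nuc.columns:
        col = nuc[snp_id].to_numpy(float)
        alt_freq = col.mean() / 2.0
        if alt_freq > 0.5:
            nuc[snp_id] = 2 - nuc[snp_id]
        elif alt_freq == 0.5:
            logger.info("%s: ambiguous minor allele (freq 0.5), keeping alt", snp_id)
    mt = mito.copy()
    for snp_id in mt.columns:
        freq = mt[snp_id].to_numpy(float).mean()
        if freq > 0.5:
            mt[snp_id] = 1 - mt[snp_id]
        elif freq == 0.5:
            logger.info("%s: ambiguous minor allele (freq 0.5), keeping alt", snp_id)
    return nuc, mt


def restrict_to_gene_set(
    meta: list[SNPRecord], intervals: pd.DataFrame, flank: int = 10_000
) -> list[SNPRecord]:
    """Keep SNPs inside a gene interval extended by ``flank`` bp each side.

    ``intervals`` uses BED conventions: columns chrom/start/end with
    half-open 0-based coordinates; SNP positions are 1-based, so a SNP at
    1-based position p lies in [start, end) iff start < p <= end.
    """
    if flank < 0:
        raise ValueError("flank must be non-negative")
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for _, row in intervals.iterrows():
        by_chrom.setdefault(str(row["chrom"]), []).append(
            (int(row["start"]) - flank, int(row["end"]) + flank)
        )
    kept = []
    for rec in meta:
        for lo, hi in by_chrom.get(rec.contig, []):
            if lo < rec.position <= hi:
                kept.append(rec)
                break
    return kept


def compute_kinship(coded_nuclear: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Additive identity-by-state kinship from the coded 0/1/2 panel:

        K_ij = (1/L) sum_l [1 - |g_il - g_jl| / 2]

    (EMMA's additive kinship). Diagonal is exactly 1; if roundoff makes
    the smallest eigenvalue negative the spectrum is clipped at 0 and
    the matrix re-symmetrised.
    """
    G = np.asarray(coded_nuclear, dtype=float)
    if G.ndim != 2 or G.shape[1] == 0:
        raise ValueError("need a subjects x SNPs matrix with at least one SNP")
    n, L = G.shape
    # sum_l |g_il - g_jl| via dosage-category indicator products (vectorised)
    diff = np.zeros((n, n))
    for a in (0.0, 1.0, 2.0):
        Ia = (G == a).astype(float)
        for b in (0.0, 1.0, 2.0):
            if abs(a - b) == 0:
                continue
            Ib = (G == b).astype(float)
            diff += abs(a - b) * (Ia @ Ib.T)
    K = 1.0 - diff / (2.0 * L)
    np.fill_diagonal(K, 1.0)
    lam_min = np.linalg.eigvalsh(K)[0]
    if lam_min < 0:
        lam, U = np.linalg.eigh(K)
        K = (U * np.clip(lam, 0.0, None)) @ U.T
        K = 0.5 * (K + K.T)
        np.fill_diagonal(K, 1.0)
    return K


@dataclass
class PCCovariates:
    scores: np.ndarray  # subjects x n_pcs
    explained_variance: np.ndarray  # fractions, non-increasing


def compute_pcs(
    coded_nuclear: pd.DataFrame | np.ndarray, n_pcs: int = 5
) -> PCCovariates:
    """Top principal components of the centred, SNP-scaled genotype matrix.

    Constant SNP columns are dropped (logged). Sign convention: the
    largest-magnitude loading of each component is positive, so scores
    are reproducible across runs and platforms.
    """
    G = np.asarray(coded_nuclear, dtype=float)
    if G.shape[0] < n_pcs + 1:
        raise ValueError("need at least n_pcs + 1 subjects")
    sd = G.std(axis=0)
    const = sd == 0
    if const.any():
        logger.info("dropping %d constant SNP columns before PCA", const.sum())
        G = G[:, ~const]
        sd = sd[~const]
    Z = (G - G.mean(axis=0)) / sd
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    for k in range(min(n_pcs, len(s))):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    scores = U[:, :n_pcs] * s[:n_pcs]
    ev = (s**2) / (s**2).sum()
    return PCCovariates(scores=scores, explained_variance=ev[:n_pcs])
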