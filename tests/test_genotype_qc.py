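"""Variant filters, imputation, coding, kinship and PCs."""

import math

import numpy as np
import pandas as pd
import pytest

from mitonuclear.genotype_qc import (
    MISSING,
    PCCovariates,
    SNPRecord,
    code_genotypes,
    compute_kinship,
    compute_pcs,
    filter_mito_snps,
    filter_nuclear_snps,
    hwe_exact_test,
    impute_missing,
    impute_panel,
    restrict_to_gene_set,
)


def _hwe_enumeration(n_het, n_hom_minor, n_hom_major):
    """Exact-integer enumeration oracle for the HWE exact test."""
    n = n_het + n_hom_minor + n_hom_major
    na = 2 * n_hom_minor + n_het  # minor-allele count (orientation-free)
    na = min(na, 2 * n - na)

    def prob(h):
        hmin = (na - h) // 2
        hmaj = n - hmin - h
        return (math.factorial(n) * 2**h
                / (math.factorial(hmin) * math.factorial(hmaj) * math.factorial(h))
                / math.comb(2 * n, na))

    hs = range(na % 2, na + 1, 2)
    probs = {h: prob(h) for h in hs}
    p_obs = probs[n_het]
    return sum(v for v in probs.values() if v <= p_obs * (1 + 1e-12))


@pytest.mark.parametrize(
    "counts",
    [(10, 0, 90), (0, 50, 50), (25, 5, 70), (57, 13, 30), (2, 2, 2),
     (1, 0, 9), (40, 40, 20), (0, 0, 25)],
)
def test_hwe_exact_matches_enumeration(counts):
    assert hwe_exact_test(*counts) == pytest.approx(
        _hwe_enumeration(*counts), rel=1e-10
    )


def test_hwe_extreme_disequilibrium_is_tiny():
    assert hwe_exact_test(0, 50, 50) < 1e-3


def _panel(columns: dict, contig="chr1"):
    df = pd.DataFrame(columns)
    meta = [SNPRecord(snp_id=c, contig=contig, position=100 * (i + 1))
            for i, c in enumerate(df.columns)]
    return df, meta


def test_filter_call_rate():
    col = np.zeros(100, dtype=int)
    col[:10] = MISSING  # call rate 0.90
    good = np.tile([0, 1, 2, 1], 25)
    df, meta = _panel({"bad": col, "good": good})
    kept, kept_meta = filter_nuclear_snps(df, meta)
    assert list(kept.columns) == ["good"]
    assert kept_meta[0].call_rate == 1.0


def test_filter_maf_boundary_retained():
    # 90 AA + 10 Aa: MAF exactly 0.05 — the rule removes strictly below
    col = np.r_[np.zeros(90, int), np.ones(10, int)]
    df, meta = _panel({"boundary": col})
    kept, _ = filter_nuclear_snps(df, meta)
    assert "boundary" in kept.columns


def test_filter_hwe_removes_het_deficit():
    col = np.r_[np.zeros(50, int), np.full(50, 2)]
    df, meta = _panel({"hwe_fail": col})
    kept, _ = filter_nuclear_snps(df, meta)
    assert len(kept.columns) == 0


def test_filter_drops_sex_chromosomes():
    col = np.tile([0, 1, 2, 1], 25)
    df, meta = _panel({"x_snp": col}, contig="chrX")
    kept, _ = filter_nuclear_snps(df, meta)
    assert len(kept.columns) == 0


@pytest.mark.parametrize("carriers, expected", [(4, 0), (5, 1), (0, 0)])
def test_mito_vaf_filter(carriers, expected):
    col = np.r_[np.ones(carriers, int), np.zeros(100 - carriers, int)]
    df = pd.DataFrame({"mt1": col})
    kept, _ = filter_mito_snps(df, [SNPRecord("mt1", "chrM", 100, is_mito=True)])
    assert len(kept.columns) == expected


def test_impute_degenerate_distribution():
    col = np.zeros(50, dtype=np.int8)
    col[:5] = MISSING
    out = impute_missing(col, np.random.default_rng(0))
    assert (out == 0).all()


def test_impute_matches_frequency_distribution():
    rng = np.random.default_rng(1)
    base = np.r_[np.zeros(25, int), np.ones(50, int), np.full(25, 2)]
    col = np.r_[base, np.full(10_000, MISSING)]
    out = impute_missing(col, rng)
    imputed = out[len(base):]
    props = [(imputed == g).mean() for g in (0, 1, 2)]
    assert props[0] == pytest.approx(0.25, abs=0.02)
    assert props[1] == pytest.approx(0.50, abs=0.02)
    assert props[2] == pytest.approx(0.25, abs=0.02)


def test_impute_is_seeded_and_preserves_observed():
    col = np.array([0, 1, 2, MISSING, MISSING, 1, 0], dtype=np.int8)
    a = impute_missing(col, np.random.default_rng(42))
    b = impute_missing(col, np.random.default_rng(42))
    assert (a == b).all()
    keep = col != MISSING
    assert (a[keep] == col[keep]).all()
    df = pd.DataFrame({"s1": col, "s2": col})
    assert impute_panel(df, 3).equals(impute_panel(df, 3))


def test_code_genotypes_minor_allele_orientation():
    # alt frequency 0.8 > 0.5: column must flip so 2 means homozygous minor
    nuc = pd.DataFrame({"flip": [2, 2, 2, 2, 0], "keep": [0, 0, 1, 1, 2]})
    mito = pd.DataFrame({"mtflip": [1, 1, 1, 1, 0], "mtkeep": [0, 0, 0, 1, 1]})
    nuc_c, mito_c = code_genotypes(nuc, mito)
    assert list(nuc_c["flip"]) == [0, 0, 0, 0, 2]
    assert list(nuc_c["keep"]) == [0, 0, 1, 1, 2]
    assert list(mito_c["mtflip"]) == [0, 0, 0, 0, 1]
    assert list(mito_c["mtkeep"]) == [0, 0, 0, 1, 1]


def test_gene_set_restriction_boundaries():
    bed = pd.DataFrame({"chrom": ["chr1"], "start": [100], "end": [200],
                        "name": ["g1"]})
    meta = [SNPRecord("in", "chr1", 101), SNPRecord("edge", "chr1", 100),
            SNPRecord("out", "chr2", 150)]
    kept = restrict_to_gene_set(meta, bed, flank=0)
    assert [m.snp_id for m in kept] == ["in"]
    kept = restrict_to_gene_set(meta, bed, flank=10)
    assert {m.snp_id for m in kept} == {"in", "edge"}


def test_gene_set_restriction_matches_bruteforce():
    rng = np.random.default_rng(2)
    bed = pd.DataFrame({
        "chrom": ["chr1", "chr1", "chr2"],
        "start": [1000, 5000, 2000],
        "end": [1500, 5200, 2600],
        "name": ["a", "b", "c"],
    })
    meta = [SNPRecord(f"s{i}", rng.choice(["chr1", "chr2"]),
                      int(rng.integers(1, 8000))) for i in range(60)]
    flank = 100
    kept = {m.snp_id for m in restrict_to_gene_set(meta, bed, flank)}
    brute = set()
    for m in meta:
        for _, iv in bed.iterrows():
            if iv.chrom == m.contig and iv.start - flank < m.position <= iv.end + flank:
                brute.add(m.snp_id)
    assert kept == brute


def test_kinship_extremes():
    G = np.array([[0, 0, 0], [0, 0, 0], [2, 2, 2]], float)
    K = compute_kinship(G)
    assert K[0, 1] == pytest.approx(1.0)
    assert K[0, 2] == pytest.approx(0.0)
    assert np.allclose(np.diag(K), 1.0)


def test_kinship_unrelated_expectation_closed_form():
    """For i.i.d. Binomial(2, p) genotypes the expected IBS kinship is
    1 - E|g_i - g_j|/2, computable by enumeration over genotype pairs."""
    p = 0.3
    probs = {0: (1 - p) ** 2, 1: 2 * p * (1 - p), 2: p**2}
    expect = sum(
        probs[a] * probs[b] * (1 - abs(a - b) / 2)
        for a in probs for b in probs
    )
    rng = np.random.default_rng(3)
    G = rng.binomial(2, p, size=(40, 5000)).astype(float)
    K = compute_kinship(G)
    off = K[np.triu_indices(40, 1)]
    assert np.abs(off - expect).max() < 0.02


def test_kinship_psd_after_repair(small_cohort):
    _, cohort = small_cohort
    G = impute_panel(cohort.nuclear_genotypes, 1).to_numpy(float)
    K = compute_kinship(G)
    lam = np.linalg.eigvalsh(K)
    assert lam[0] > -1e-8
    assert np.allclose(K, K.T)


def test_pcs_separate_populations():
    rng = np.random.default_rng(4)
    n_per, L = 60, 400
    p = rng.uniform(0.2, 0.5, L)
    f = 0.1
    pa = rng.beta(p * (1 - f) / f, (1 - p) * (1 - f) / f)
    pb = rng.beta(p * (1 - f) / f, (1 - p) * (1 - f) / f)
    G = np.vstack([rng.binomial(2, pa, (n_per, L)),
                   rng.binomial(2, pb, (n_per, L))]).astype(float)
    pcs = compute_pcs(G)
    sign = np.sign(pcs.scores[:, 0])
    acc = max((sign[:n_per] > 0).mean() + (sign[n_per:] < 0).mean(),
              (sign[:n_per] < 0).mean() + (sign[n_per:] > 0).mean()) / 2
    assert acc >= 0.95


def test_pcs_variance_fractions_and_duplicates(small_cohort):
    _, cohort = small_cohort
    G = cohort.nuclear_complete.to_numpy(float)
    pcs = compute_pcs(G)
    assert isinstance(pcs, PCCovariates)
    ev = pcs.explained_variance
    assert np.all(np.diff(ev) <= 1e-12)
    assert ev.sum() <= 1.0 + 1e-12

    dup = np.vstack([G, G])
    scores = compute_pcs(dup).scores
    assert np.allclose(scores[: len(G)], scores[len(G):], atol=1e-8)


def test_filters_are_order_independent():
    rng = np.random.default_rng(5)
    cols = {f"s{i}": rng.choice([0, 1, 2, MISSING], size=80,
                                p=[0.45, 0.3, 0.15, 0.1])
            for i in range(12)}
    df, meta = _panel(cols)
    kept_a, _ = filter_nuclear_snps(df, meta)
    # reversed column order
    df_r = df[list(df.columns)[::-1]]
    kept_b, _ = filter_nuclear_snps(df_r, [m for m in reversed(meta)])
    assert set(kept_a.columns) == set(kept_b.columns)
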