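"""Genome-scale scan for nuclear-SNP x mitochondrial-SNP interaction effects.

For every (nuSNP, mtSNP, phenotype) triple the phenotype is modelled as

    Y = b0 + b1*N + b2*M + b3*(N*M) + S0 + sum_c bPc*Pc + eps

with N the 0/1/2 minor-allele dosage of the nuclear SNP, M the 0/1
mitochondrial carrier code, S0 a polygenic random effect with kinship
covariance, and Pc the top-5 genotype principal components. The
interaction is tested with a likelihood-ratio statistic

    D = 2 * (ll_full - ll_null)      (null drops the N*M column)

referred to chi-square with 1 degree of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .mixed_model import KinshipSpectrum, fit_mixed_model

__all__ = ["InteractionResult", "lrt_interaction", "scan"]

MIN_SUBJECTS = 10


@dataclass
class InteractionResult:
    nusnp_id: str
    mtsnp_id: str
    phenotype_name: str
    D: float
    p_value: float
    n_used: int
    beta3_hat: float = np.nan
    testable: bool = True
    flag: str = ""


def _design(nu: np.ndarray, mt: np.ndarray, pcs: np.ndarray) -> np.ndarray:
    n = len(nu)
    inter = nu * mt
    return np.column_stack([np.ones(n), nu, mt, inter, pcs])


def lrt_interaction(
    y: np.ndarray,
    nu: np.ndarray,
    mt: np.ndarray,
    pcs: np.ndarray,
    K: np.ndarray | None = None,
    spectrum: KinshipSpectrum | None = None,
    nusnp_id: str = "nu",
    mtsnp_id: str = "mt",
    phenotype_name: str = "phenotype",
    _rotated_base: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
) -> InteractionResult:
    """Likelihood-ratio test of the interaction coefficient b3 = 0.

    Pairs whose interaction column is constant (e.g. no subject carries
    both minor alleles) are flagged untestable instead of being fitted,
    which avoids spurious boundary likelihoods.
    """
    y = np.asarray(y, float)
    nu = np.asarray(nu, float)
    mt = np.asarray(mt, float)
    pcs = np.atleast_2d(np.asarray(pcs, float))
    if pcs.shape[0] != len(y):
        pcs = pcs.T
    n = len(y)
    if n < MIN_SUBJECTS:
        raise ValueError(f"need at least {MIN_SUBJECTS} subjects, got {n}")
    if np.ptp(nu) == 0 or np.ptp(mt) == 0:
        return InteractionResult(nusnp_id, mtsnp_id, phenotype_name,
                                 np.nan, np.nan, n, testable=False,
                                 flag="constant genotype column")
    inter = nu * mt
    if np.ptp(inter) == 0:
        return InteractionResult(nusnp_id, mtsnp_id, phenotype_name,
                                 np.nan, np.nan, n, testable=False,
                                 flag="constant interaction column")
    X_full = _design(nu, mt, pcs)
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        return InteractionResult(nusnp_id, mtsnp_id, phenotype_name,
                                 np.nan, np.nan, n, testable=False,
                                 flag="collinear design")
    X_null = np.delete(X_full, 3, axis=1)

    if spectrum is None:
        spectrum = KinshipSpectrum.from_kinship(K)

    if _rotated_base is not None:
        yr, ones_r, pcs_r = _rotated_base
        nu_r = spectrum.rotate(nu)
        mt_r = spectrum.rotate(mt)
        int_r = spectrum.rotate(inter)
        Xr_full = np.column_stack([ones_r, nu_r, mt_r, int_r, pcs_r])
        Xr_null = np.column_stack([ones_r, nu_r, mt_r, pcs_r])
        fit_full = fit_mixed_model(y, X_full, spectrum=spectrum,
                                   rotated=(yr, Xr_full))
        fit_null = fit_mixed_model(y, X_null, spectrum=spectrum,
                                   rotated=(yr, Xr_null))
    else:
        fit_full = fit_mixed_model(y, X_full, spectrum=spectrum)
        fit_null = fit_mixed_model(y, X_null, spectrum=spectrum)

    if not (fit_full.converged and fit_null.converged):
        return InteractionResult(nusnp_id, mtsnp_id, phenotype_name,
                                 np.nan, np.nan, n, testable=False,
                                 flag="degenerate fit")

    D = 2.0 * (fit_full.log_likelihood - fit_null.log_likelihood)
    if D < -1e-6:
        import warnings

        warnings.warn(f"negative LRT statistic {D:.3g} clamped to 0")
    D = max(D, 0.0)
    p = float(stats.chi2.sf(D, df=1))
    p = min(max(p, np.nextafter(0.0, 1.0)), 1.0)
    return InteractionResult(nusnp_id, mtsnp_id, phenotype_name, float(D), p,
                             n, beta3_hat=float(fit_full.beta_hat[3]))


def scan(
    nuclear: pd.DataFrame,
    mito: pd.DataFrame,
    phenotypes: pd.DataFrame,
    pcs: np.ndarray,
    K: np.ndarray,
    nuclear_pos: pd.Series | None = None,
    mito_pos: pd.Series | None = None,
) -> pd.DataFrame:
    """Test every nuSNP x mtSNP pair against every phenotype column.

    The kinship spectral decomposition is computed once and shared by
    all fits. Rows are ordered deterministically by nuclear position,
    mitochondrial position, then phenotype name; untestable pairs are
    retained with a flag and NaN statistics so they can be excluded from
    multiple testing downstream.
    """
    subjects = nuclear.index
    if not (mito.index.equals(subjects) and phenotypes.index.equals(subjects)):
        raise ValueError("subject indices of nuclear, mito and phenotypes must align")
    spectrum = KinshipSpectrum.from_kinship(K)
    n = len(subjects)
    yr_cache = {ph: spectrum.rotate(phenotypes[ph].to_numpy(float))
                for ph in phenotypes.columns}
    ones_r = spectrum.rotate(np.ones(n))
    pcs = np.asarray(pcs, float)
    pcs_r = spectrum.rotate(pcs)

    nu_order = (list(nuclear_pos.sort_values().index) if nuclear_pos is not None
                else list(nuclear.columns))
    mt_order = (list(mito_pos.sort_values().index) if mito_pos is not None
                else list(mito.columns))
    ph_order = sorted(phenotypes.columns)

    rows = []
    for nu_id in nu_order:
        nu = nuclear[nu_id].to_numpy(float)
        for mt_id in mt_order:
            mt = mito[mt_id].to_numpy(float)
            for ph in ph_order:
                res = lrt_interaction(
                    phenotypes[ph].to_numpy(float), nu, mt, pcs,
                    spectrum=spectrum, nusnp_id=nu_id, mtsnp_id=mt_id,
                    phenotype_name=ph,
                    _rotated_base=(yr_cache[ph], ones_r, pcs_r),
                )
                rows.append(res)
    out = pd.DataFrame(
        {
            "nusnp_id": [r.nusnp_id for r in rows],
            "mtsnp_id": [r.mtsnp_id for r in rows],
            "phenotype": [r.phenotype_name for r in rows],
            "D": [r.D for r in rows],
            "p": [r.p_value for r in rows],
            "beta3_hat": [r.beta3_hat for r in rows],
            "n_used": [r.n_used for r in rows],
            "testable": [r.testable for r in rows],
            "flag": [r.flag for r in rows],
        }
    )
    return out
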