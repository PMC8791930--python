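"""Synthetic cohorts with the statistical structure the scan assumes.

Four generators, each a pure function of its configuration and seed:

* diploid nuclear genotypes with admixed population structure
  (Balding-Nichols allele-frequency deviates when more than one
  population is requested), family-block relatedness and missingness;
* binary mitochondrial carrier codes (one value per subject — a
  mitochondrial variant carries no diploid dosage);
* phenotypes drawn from the kinship mixed model with a plantable
  nuclear x mitochondrial interaction coefficient;
* H&E-like RGB tiles with planted non-overlapping elliptical nuclei
  rendered under Beer-Lambert two-stain mixing, using the same
  Ruifrok-Johnston stain vectors the extractor unmixes with;
* right-censored exponential survival times with a configurable group
  hazard ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .genotype_qc import MISSING, compute_pcs
from .morphology import RUIFROK_HE_MATRIX

__all__ = [
    "SimConfig", "SyntheticCohort", "TileImage", "NucleusRecord",
    "generate_genotypes", "generate_phenotype", "generate_tiles",
    "generate_survival",
]

BALDING_NICHOLS_FST = 0.05
#: per-allele copy probability giving within-family allele correlation 0.5
_FAMILY_RHO = np.sqrt(0.5)
_FAMILY_KINSHIP = 0.5


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    ``beta`` is the fixed-effect vector (b0, b1, b2, b3, bP1..bP5) of the
    phenotype model; ``sigma_g2``/``sigma_e2`` are the polygenic and
    residual variances. Defaults describe a 200-subject admixed cohort
    with modest relatedness, typical array-scale allele frequencies and
    phenotypes on the log2 scale of the morphology features.
    """

    n_subjects: int = 200
    n_nusnps: int = 50
    n_mtsnps: int = 8
    maf_range: tuple[float, float] = (0.1, 0.5)
    mt_vaf_range: tuple[float, float] = (0.1, 0.5)
    missing_rate: float = 0.02
    n_populations: int = 2
    admixture_alpha: float = 1.0
    family_block_size: int = 4
    sigma_g2: float = 0.3
    sigma_e2: float = 0.7
    beta: tuple[float, ...] = (4.0, 0.05, 0.05, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_subjects, self.n_nusnps, self.n_mtsnps) <= 0:
            raise ValueError("counts must be positive")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie in (0, 0.5]")
        lo, hi = self.mt_vaf_range
        if not (0 < lo <= hi < 1):
            raise ValueError("mt_vaf_range must lie in (0, 1)")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be a probability")
        if self.sigma_g2 < 0 or self.sigma_e2 < 0:
            raise ValueError("variances must be non-negative")
        if self.n_populations < 1 or self.family_block_size < 1:
            raise ValueError("n_populations and family_block_size must be >= 1")
        if len(self.beta) != 9:
            raise ValueError("beta must have 9 entries (b0..b3, bP1..bP5)")


@dataclass
class SyntheticCohort:
    subjects: list[str]
    nuclear_genotypes: pd.DataFrame  # with missing entries (-1)
    nuclear_complete: pd.DataFrame  # pre-missingness truth
    mito_genotypes: pd.DataFrame
    true_kinship: np.ndarray
    nuclear_pos: pd.Series = None
    mito_pos: pd.Series = None
    nuclear_maf: np.ndarray = None
    mito_vaf: np.ndarray = None
    phenotypes: pd.DataFrame | None = None
    survival: pd.DataFrame | None = None


def generate_genotypes(config: SimConfig) -> SyntheticCohort:
    """Draw the genotype fields of a cohort.

    Per SNP, an ancestral frequency is drawn uniformly from
    ``maf_range``. With ``n_populations > 1``, population-specific
    frequencies follow the Balding-Nichols model at Fst = 0.05 and each
    family block receives Dirichlet(``admixture_alpha``) admixture
    weights; with a single population the ancestral frequency is used
    directly. Subjects within a family block copy each founder allele
    with probability sqrt(1/2), producing within-block allele
    correlation 1/2. Missing entries are inserted at ``missing_rate``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, L, Lm = config.n_subjects, config.n_nusnps, config.n_mtsnps

    p_anc = rng.uniform(*config.maf_range, size=L)
    K_pop = config.n_populations
    if K_pop > 1:
        f = BALDING_NICHOLS_FST
        a = p_anc * (1 - f) / f
        b = (1 - p_anc) * (1 - f) / f
        p_pop = rng.beta(a, b, size=(K_pop, L))  # populations x SNPs
    else:
        p_pop = p_anc[None, :]

    blocks = np.repeat(np.arange(int(np.ceil(n / config.family_block_size))),
                       config.family_block_size)[:n]
    n_blocks = blocks.max() + 1
    w = rng.dirichlet(np.full(K_pop, config.admixture_alpha), size=n_blocks)
    q_block = w @ p_pop  # blocks x SNPs, per-subject allele frequency

    q = q_block[blocks]  # subjects x SNPs
    if config.family_block_size > 1:
        founder = rng.random((n_blocks, L, 2)) < q_block[:, :, None]
        copy = rng.random((n, L, 2)) < _FAMILY_RHO
        fresh = rng.random((n, L, 2)) < q[:, :, None]
        alleles = np.where(copy, founder[blocks], fresh)
        G = alleles.sum(axis=2).astype(np.int8)
    else:
        G = rng.binomial(2, q).astype(np.int8)

    vaf = rng.uniform(*config.mt_vaf_range, size=Lm)
    M = (rng.random((n, Lm)) < vaf).astype(np.int8)

    subjects = [f"S{i:04d}" for i in range(n)]
    nu_ids = [f"rs{100000 + i}" for i in range(L)]
    mt_ids = [f"mt{1000 + i}" for i in range(Lm)]
    nuclear_complete = pd.DataFrame(G, index=subjects, columns=nu_ids)
    nuclear = nuclear_complete.copy()
    if config.missing_rate > 0:
        mask = rng.random((n, L)) < config.missing_rate
        nuclear = nuclear.mask(mask, MISSING).astype(np.int8)

    K = np.eye(n)
    for b_id in range(n_blocks):
        idx = np.nonzero(blocks == b_id)[0]
        for i in idx:
            for j in idx:
                if i != j:
                    K[i, j] = _FAMILY_KINSHIP

    # positions: nuclear on chr1 spaced 10 kb, mito on chrM spaced 100 bp
    nuclear_pos = pd.Series(10_000 * (np.arange(L) + 1), index=nu_ids)
    mito_pos = pd.Series(100 * (np.arange(Lm) + 1), index=mt_ids)
    return SyntheticCohort(
        subjects=subjects,
        nuclear_genotypes=nuclear,
        nuclear_complete=nuclear_complete,
        mito_genotypes=pd.DataFrame(M, index=subjects, columns=mt_ids),
        true_kinship=K,
        nuclear_pos=nuclear_pos,
        mito_pos=mito_pos,
        nuclear_maf=np.minimum(p_anc, 1 - p_anc),
        mito_vaf=vaf,
    )


def generate_phenotype(
    cohort: SyntheticCohort,
    config: SimConfig,
    nusnp_index: int,
    mtsnp_index: int,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Draw one phenotype vector from the mixed model

        Y = b0 + b1*N + b2*M + b3*(N*M) + S0 + sum_c bPc*Pc + eps,

    with S0 ~ N(0, sigma_g2 * K) and eps ~ N(0, sigma_e2 * I). The PC
    covariates are the top-5 PCs of the complete coded genotype matrix
    (the same definition the scan uses), so generator and scan share
    the covariate meaning.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    nu = cohort.nuclear_complete.iloc[:, nusnp_index].to_numpy(float)
    mt = cohort.mito_genotypes.iloc[:, mtsnp_index].to_numpy(float)
    # orient to minor-allele coding so the planted coefficient has the
    # same sign and meaning as in the downstream coded panel
    if nu.mean() / 2.0 > 0.5:
        nu = 2.0 - nu
    if mt.mean() > 0.5:
        mt = 1.0 - mt
    n = len(nu)
    pcs = compute_pcs(cohort.nuclear_complete.to_numpy(float)).scores
    b = np.asarray(config.beta, float)
    mean = b[0] + b[1] * nu + b[2] * mt + b[3] * nu * mt + pcs @ b[4:9]

    K = cohort.true_kinship
    lam = np.linalg.eigvalsh(K)
    if lam[0] < -1e-8:
        raise ValueError("kinship must be positive semidefinite")
    s0 = np.zeros(n)
    if config.sigma_g2 > 0:
        lam, U = np.linalg.eigh(K)
        lam = np.clip(lam, 0.0, None)
        s0 = U @ (np.sqrt(config.sigma_g2 * lam) * rng.standard_normal(n))
    eps = (np.sqrt(config.sigma_e2) * rng.standard_normal(n)
           if config.sigma_e2 > 0 else np.zeros(n))
    return mean + s0 + eps


@dataclass
class NucleusRecord:
    center: tuple[float, float]  # row, col
    radius: float
    concentration: float  # hematoxylin optical-density coefficient


@dataclass
class TileImage:
    pixels: np.ndarray  # h x w x 3 uint8
    tile_id: str = ""
    subject_id: str = ""
    nuclei: list[NucleusRecord] = field(default_factory=list)
    hematoxylin_truth: np.ndarray | None = None


# rendering constants: optical-density coefficients
NUCLEUS_H_MEAN, NUCLEUS_H_SD = 0.60, 0.05
BACKGROUND_EOSIN = 0.15
NUCLEUS_EOSIN = 0.05
SPECKLE_FRACTION, SPECKLE_LO, SPECKLE_HI = 0.01, 0.05, 0.12

MAX_PLACEMENT_TRIES = 2000


def _render(h_conc: np.ndarray, e_conc: np.ndarray) -> np.ndarray:
    """Beer-Lambert two-stain mixing to an 8-bit RGB image."""
    od = (h_conc[..., None] * RUIFROK_HE_MATRIX[0]
          + e_conc[..., None] * RUIFROK_HE_MATRIX[1])
    rgb = 255.0 * 10.0 ** (-od)
    return np.clip(np.round(rgb), 0, 255).astype(np.uint8)


def generate_tiles(
    n_tiles: int,
    nuclei_per_tile: int,
    radius_mean: float = 12.0,
    radius_sd: float = 0.0,
    seed: int = 0,
    tile_shape: tuple[int, int] = (256, 256),
    min_separation: float | None = None,
    subject_id: str = "",
) -> list[TileImage]:
    """Render H&E-like tiles with planted non-overlapping circular nuclei.

    Nuclei are placed by rejection sampling with centre separation at
    least ``min_separation`` (default: 2 * (radius_mean + 3 * radius_sd)
    + 4 px) and kept clear of the tile border, so segmentation ground
    truth is unambiguous; an error is raised when the requested count
    cannot be packed. Background carries eosin plus a sparse hematoxylin
    speckle (1% of pixels) emulating faint debris, so an empty tile
    still has a non-degenerate hematoxylin channel.
    """
    if radius_mean <= 0 or radius_sd < 0:
        raise ValueError("radii must be positive")
    if nuclei_per_tile < 0 or n_tiles < 0:
        raise ValueError("counts must be non-negative")
    rng = np.random.default_rng(seed)
    h, w = tile_shape
    if min_separation is None:
        min_separation = 2.0 * (radius_mean + 3.0 * radius_sd) + 4.0
    rows, cols = np.mgrid[0:h, 0:w]
    tiles = []
    for t in range(n_tiles):
        centers: list[tuple[float, float]] = []
        radii: list[float] = []
        for _ in range(nuclei_per_tile):
            placed = False
            for _try in range(MAX_PLACEMENT_TRIES):
                r = max(2.0, rng.normal(radius_mean, radius_sd)) if radius_sd else radius_mean
                margin = r + 3
                if 2 * margin >= min(h, w):
                    break
                cy = rng.uniform(margin, h - margin)
                cx = rng.uniform(margin, w - margin)
                if all((cy - y) ** 2 + (cx - x) ** 2 >= min_separation**2
                       for y, x in centers):
                    centers.append((cy, cx))
                    radii.append(r)
                    placed = True
                    break
            if not placed:
                raise RuntimeError(
                    f"cannot place {nuclei_per_tile} nuclei of radius ~{radius_mean} "
                    f"in a {h}x{w} tile (separation {min_separation:.0f})"
                )
        h_conc = np.zeros((h, w))
        e_conc = np.full((h, w), BACKGROUND_EOSIN)
        nuclei = []
        for (cy, cx), r in zip(centers, radii):
            c = float(np.clip(rng.normal(NUCLEUS_H_MEAN, NUCLEUS_H_SD), 0.3, 1.0))
            inside = (rows - cy) ** 2 + (cols - cx) ** 2 <= r**2
            h_conc[inside] = c
            e_conc[inside] = NUCLEUS_EOSIN
            nuclei.append(NucleusRecord((cy, cx), r, c))
        speckle = rng.random((h, w)) < SPECKLE_FRACTION
        speckle &= h_conc == 0
        h_conc[speckle] = rng.uniform(SPECKLE_LO, SPECKLE_HI, size=int(speckle.sum()))
        tiles.append(TileImage(
            pixels=_render(h_conc, e_conc),
            tile_id=f"tile{t:04d}",
            subject_id=subject_id,
            nuclei=nuclei,
            hematoxylin_truth=h_conc,
        ))
    return tiles


def generate_survival(
    n: int,
    hazard_ratio: float,
    censor_rate: float = 0.3,
    seed: int = 0,
    baseline_hazard: float = 0.1,
    group_fraction: float = 0.5,
) -> pd.DataFrame:
    """Exponential survival times with a two-level group hazard.

    Group 1 has hazard ``hazard_ratio`` times group 0. Censoring is
    independent Uniform(0, u) with ``u`` solved numerically so the
    expected censored fraction equals ``censor_rate``. ER status and age
    covariates are included for multivariate survival fits.
    """
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be positive")
    if not (0 <= censor_rate < 1):
        raise ValueError("censor_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    group = (rng.random(n) < group_fraction).astype(int)
    lam = baseline_hazard * np.where(group == 1, hazard_ratio, 1.0)
    times = rng.exponential(1.0 / lam)

    event = np.ones(n, dtype=int)
    obs = times.copy()
    if censor_rate > 0:
        p1 = group.mean()

        def censored_frac(u: float) -> float:
            # P(C < T) for C ~ U(0, u), T ~ Exp(l) is (1 - e^{-l u}) / (l u)
            def one(l: float) -> float:
                x = l * u
                return (1.0 - np.exp(-x)) / x
            l0, l1 = baseline_hazard, baseline_hazard * hazard_ratio
            return (1 - p1) * one(l0) + p1 * one(l1)

        u = brentq(lambda u: censored_frac(u) - censor_rate, 1e-6, 1e8)
        cens = rng.uniform(0.0, u, size=n)
        event = (times <= cens).astype(int)
        obs = np.minimum(times, cens)

    er = rng.choice(["positive", "negative"], size=n, p=[0.7, 0.3])
    age = rng.uniform(30, 85, size=n)
    return pd.DataFrame({
        "subject_id": [f"S{i:04d}" for i in range(n)],
        "time": obs,
        "event": event,
        "group": group,
        "er_status": er,
        "age": age,
    }).set_index("subject_id")
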