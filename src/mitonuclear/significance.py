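"""Multiple-testing control and post-hoc evaluation of scan hits.

q-values follow Storey's procedure with the proportion of true nulls
pi0 estimated by bootstrapping the p-values across a ladder of lambda
tuning values (the ``qvalue`` package's ``pi0.method = "bootstrap"``).
Significant pairs (q < alpha) are then screened with one-sided
Mann-Whitney U tests requiring the minor-minor genotype group to be
(a) significantly greater than every other genotype group after a
within-pair Bonferroni correction and (b) stochastically greater by the
pointwise empirical-CDF criterion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "QValueResult", "PosthocVerdict", "qvalues_bootstrap",
    "mannwhitney_one_sided", "posthoc_filter",
]

logger = logging.getLogger(__name__)

LAMBDA_GRID = np.round(np.arange(0.05, 0.951, 0.05), 2)  # 19 values
EXACT_MAX_PRODUCT = 400


@dataclass
class QValueResult:
    p_values: np.ndarray
    pi0_hat: float
    q_values: np.ndarray
    lambda_hat: float = np.nan


def _pi0_ladder(p: np.ndarray, lambdas: np.ndarray) -> np.ndarray:
    m = len(p)
    return np.array([np.sum(p > lam) / (m * (1.0 - lam)) for lam in lambdas])


def qvalues_bootstrap(
    p_values: np.ndarray,
    n_boot: int = 100,
    seed: int = 0,
    lambdas: np.ndarray = LAMBDA_GRID,
    pi0: float | None = None,
) -> QValueResult:
    """Storey q-values with bootstrap selection of the pi0 tuning lambda.

    For each lambda, pi0(lambda) = #{p > lambda} / (m (1 - lambda)). The
    bootstrap (resampling the p-values with replacement ``n_boot``
    times) picks the lambda minimising the estimated mean squared error
    against the minimum of the plug-in ladder, taken as its 10% quantile
    (the qvalue package's guard: with few tests the largest lambda can
    see zero exceedances and a raw minimum of 0 would hijack the
    selection). The estimate is capped at 1 and floored at 1/m (the
    floor can bind only under overwhelming signal).
    q_i = min over p_j >= p_i of pi0 * m * p_j / rank(p_j).

    ``pi0`` may be forced (e.g. to 1, which reproduces Benjamini-
    Hochberg adjusted p-values exactly).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)

    lambda_hat = np.nan
    if pi0 is None:
        pi0_lam = _pi0_ladder(p, lambdas)
        min_pi0 = float(np.quantile(pi0_lam, 0.1))
        rng = np.random.default_rng(seed)
        mse = np.zeros(len(lambdas))
        for _ in range(n_boot):
            pb = rng.choice(p, size=m, replace=True)
            mse += (_pi0_ladder(pb, lambdas) - min_pi0) ** 2
        k = int(np.argmin(mse))
        lambda_hat = float(lambdas[k])
        pi0 = float(pi0_lam[k])
        if pi0 <= 0:
            logger.info("pi0 estimate hit its floor 1/m")
        pi0 = min(max(pi0, 1.0 / m), 1.0)

    order = np.argsort(p, kind="mergesort")
    ranks = np.arange(1, m + 1)
    q_sorted = pi0 * m * p[order] / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return QValueResult(p_values=p, pi0_hat=float(pi0), q_values=q,
                        lambda_hat=lambda_hat)


def mannwhitney_one_sided(
    group1: np.ndarray, group2: np.ndarray
) -> tuple[float, float]:
    """One-sided Mann-Whitney U: H_a is group1 stochastically greater.

    Exact enumeration p-value when n1*n2 <= 400 and the pooled sample has
    no ties; otherwise the normal approximation with tie and continuity
    corrections.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.size == 0 or g2.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([g1, g2])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (g1.size * g2.size <= EXACT_MAX_PRODUCT and no_ties) \
        else "asymptotic"
    res = stats.mannwhitneyu(g1, g2, alternative="greater", method=method)
    return float(res.statistic), float(res.pvalue)


@dataclass
class PosthocVerdict:
    pair_id: str
    comparisons: list[dict] = field(default_factory=list)
    passes: bool = False
    reason: str = ""


def _ecdf_dominates(g1: np.ndarray, g2: np.ndarray, tol: float = 1e-12) -> bool:
    """True iff g1 is stochastically >= g2: ECDF_1(t) <= ECDF_2(t) at all
    pooled sample points."""
    pts = np.unique(np.concatenate([g1, g2]))
    c1 = np.searchsorted(np.sort(g1), pts, side="right") / len(g1)
    c2 = np.searchsorted(np.sort(g2), pts, side="right") / len(g2)
    return bool(np.all(c1 <= c2 + tol))


GROUP_LABELS = {(0, 0): "majmaj_nocarrier", (1, 0): "het_nocarrier",
                (2, 0): "minmin_nocarrier", (0, 1): "majmaj_carrier",
                (1, 1): "het_carrier", (2, 1): "minmin_carrier"}


def posthoc_filter(
    phenotype: np.ndarray,
    nu: np.ndarray,
    mt: np.ndarray,
    pair_id: str = "",
    alpha: float = 0.05,
) -> PosthocVerdict:
    """Mann-Whitney post-hoc screen for one significant pair.

    The reference group U1 holds subjects homozygous for the nuclear
    minor allele AND carrying the mitochondrial minor allele; it is
    compared against each other non-empty genotype group. The pair
    passes only if every comparison has Bonferroni-corrected one-sided
    p < alpha (factor = number of comparisons actually performed) and
    U1 is stochastically greater by the pointwise ECDF criterion.
    """
    y = np.asarray(phenotype, float)
    nu = np.asarray(nu)
    mt = np.asarray(mt)
    u1_mask = (nu == 2) & (mt == 1)
    if not u1_mask.any():
        return PosthocVerdict(pair_id, passes=False,
                              reason="no minor-minor subjects")
    u1 = y[u1_mask]
    comparisons = []
    others = [(g, c) for g in (0, 1, 2) for c in (0, 1) if (g, c) != (2, 1)]
    groups = {
        lbl: y[(nu == g) & (mt == c)]
        for (g, c), lbl in ((gc, GROUP_LABELS[gc]) for gc in others)
    }
    groups = {lbl: v for lbl, v in groups.items() if v.size > 0}
    if not groups:
        return PosthocVerdict(pair_id, passes=False, reason="no comparison groups")
    n_comp = len(groups)
    all_pass = True
    for lbl, u2 in groups.items():
        u_stat, p = mannwhitney_one_sided(u1, u2)
        p_bonf = min(1.0, p * n_comp)
        dominates = _ecdf_dominates(u1, u2)
        ok = (p_bonf < alpha) and dominates
        all_pass &= ok
        comparisons.append({
            "other_group": lbl, "n_other": int(u2.size), "U": u_stat,
            "p_one_sided": p, "p_bonferroni": p_bonf,
            "stochastically_greater": dominates, "passes": ok,
        })
    return PosthocVerdict(pair_id, comparisons=comparisons, passes=bool(all_pass),
                          reason="" if all_pass else "failed a comparison")


def evaluate_hits(
    scan_table: pd.DataFrame,
    phenotypes: pd.DataFrame,
    nuclear: pd.DataFrame,
    mito: pd.DataFrame,
    alpha: float = 0.05,
    n_boot: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """q-values over the testable scan rows + post-hoc screen of hits.

    Untestable rows are excluded from the multiple-testing family.
    Returns the scan table augmented with ``q`` and, for rows with
    q < alpha, the post-hoc verdict columns.
    """
    tab = scan_table.copy()
    testable = tab["testable"].to_numpy(bool) if "testable" in tab else \
        np.isfinite(tab["p"].to_numpy(float))
    p = tab.loc[testable, "p"].to_numpy(float)
    if len(p) == 0:
        tab["q"] = np.nan
        tab["significant"] = False
        tab["posthoc_pass"] = False
        return tab
    qres = qvalues_bootstrap(p, n_boot=n_boot, seed=seed)
    tab["q"] = np.nan
    tab.loc[testable, "q"] = qres.q_values
    tab["significant"] = tab["q"] < alpha
    tab["posthoc_pass"] = False
    tab.attrs["pi0_hat"] = qres.pi0_hat
    for idx in tab.index[tab["significant"].fillna(False)]:
        row = tab.loc[idx]
        verdict = posthoc_filter(
            phenotypes[row["phenotype"]].to_numpy(float),
            nuclear[row["nusnp_id"]].to_numpy(),
            mito[row["mtsnp_id"]].to_numpy(),
            pair_id=f"{row['nusnp_id']}x{row['mtsnp_id']}",
            alpha=alpha,
        )
        tab.loc[idx, "posthoc_pass"] = verdict.passes
    return tab
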