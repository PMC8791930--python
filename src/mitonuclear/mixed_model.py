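"""Single-random-effect linear mixed model with a kinship covariance.

The model is

    y = X beta + u + e,   u ~ N(0, sigma_g^2 K),   e ~ N(0, sigma_e^2 I),

where ``K`` is a subject-by-subject kinship matrix. Maximum likelihood
(not REML) is used throughout, because the interaction test compares two
fixed-effect specifications and REML likelihoods are not comparable
across fixed-effect designs.

Estimation follows the spectral strategy of efficient mixed-model
association (EMMA): decompose ``K = U diag(lam) U^T`` once, rotate ``y``
and ``X`` by ``U^T``, and profile the log-likelihood over the variance
ratio ``delta = sigma_e^2 / sigma_g^2``. At any fixed ``delta`` the
rotated model is a weighted least-squares problem with weights
``1 / (lam_i + delta)``, so ``beta`` and the total variance are solved in
closed form; the one-dimensional profile is maximised by a log-spaced
grid followed by golden-section refinement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["KinshipSpectrum", "MixedModelFit", "fit_mixed_model", "ols_loglik"]

_LOG2PI = np.log(2.0 * np.pi)

#: delta-profile search domain and grid resolution (EMMA's defaults scaled).
DELTA_MIN = 1e-5
DELTA_MAX = 1e5
N_GRID = 100


@dataclass
class KinshipSpectrum:
    """Eigendecomposition of a kinship matrix, reusable across many fits."""

    eigenvalues: np.ndarray  # ascending, clipped at 0
    eigenvectors: np.ndarray  # columns

    @classmethod
    def from_kinship(cls, K: np.ndarray) -> "KinshipSpectrum":
        K = np.asarray(K, dtype=float)
        if K.ndim != 2 or K.shape[0] != K.shape[1]:
            raise ValueError("kinship matrix must be square")
        if not np.allclose(K, K.T, atol=1e-8):
            raise ValueError("kinship matrix must be symmetric")
        lam, U = np.linalg.eigh(K)
        if lam[0] < -1e-6 * max(1.0, lam[-1]):
            raise ValueError(
                f"kinship matrix is not positive semidefinite (min eigenvalue {lam[0]:.3g})"
            )
        return cls(eigenvalues=np.clip(lam, 0.0, None), eigenvectors=U)

    def rotate(self, a: np.ndarray) -> np.ndarray:
        return self.eigenvectors.T @ a


@dataclass
class MixedModelFit:
    """ML fit of the kinship mixed model.

    ``delta_hat`` is the profiled variance ratio sigma_e^2 / sigma_g^2;
    ``np.inf`` denotes the boundary solution sigma_g^2 = 0 (plain OLS).
    """

    beta_hat: np.ndarray
    sigma_g2_hat: float
    sigma_e2_hat: float
    log_likelihood: float
    delta_hat: float
    converged: bool
    n: int = 0
    message: str = ""
    cov_beta: np.ndarray | None = field(default=None, repr=False)


def ols_loglik(y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Gaussian ML log-likelihood of OLS: returns (beta, sigma2=RSS/n, ll)."""
    n = len(y)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / n
    if sigma2 <= 0.0:
        return beta, 0.0, np.inf
    ll = -0.5 * n * (_LOG2PI + np.log(sigma2) + 1.0)
    return beta, sigma2, ll


def _profile_ll_grid(yr: np.ndarray, Xr: np.ndarray, lam: np.ndarray,
                     deltas: np.ndarray) -> np.ndarray:
    """Profile log-likelihood at each delta, vectorised over the grid."""
    n, p = Xr.shape
    w = 1.0 / (lam[:, None] + deltas[None, :])  # (n, d)
    # per-delta normal equations: A[d] = Xr^T diag(w_d) Xr, b[d] = Xr^T (w_d * yr)
    A = np.einsum("ni,nd,nj->dij", Xr, w, Xr, optimize=True)
    b = np.einsum("ni,nd,n->di", Xr, w, yr, optimize=True)
    beta = np.linalg.solve(A, b[..., None])[..., 0]  # (d, p)
    resid = yr[:, None] - Xr @ beta.T  # (n, d)
    rss_w = np.einsum("nd,nd->d", resid * w, resid)
    sigma_g2 = rss_w / n
    with np.errstate(divide="ignore"):
        ll = -0.5 * (n * (_LOG2PI + np.log(sigma_g2) + 1.0) - np.log(w).sum(axis=0))
    return ll


def _profile_ll_scalar(delta: float, yr: np.ndarray, Xr: np.ndarray,
                       lam: np.ndarray) -> float:
    return float(_profile_ll_grid(yr, Xr, lam, np.array([delta]))[0])


def _golden_section(f, lo: float, hi: float, tol: float = 1e-8,
                    max_iter: int = 200) -> float:
    """Maximise f on [lo, hi] (in log-delta space) by golden-section search."""
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = f(c), f(d)
    for _ in range(max_iter):
        if b - a < tol:
            break
        if fc > fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = f(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = f(d)
    return 0.5 * (a + b)


def _check_design(X: np.ndarray) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # name offending columns via QR diagonal
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        bad = np.nonzero(diag < 1e-8 * max(diag.max(), 1.0))[0].tolist()
        raise np.linalg.LinAlgError(
            f"design matrix is rank deficient; collinear column indices {bad}"
        )


def fit_mixed_model(
    y: np.ndarray,
    X: np.ndarray,
    K: np.ndarray | None = None,
    spectrum: KinshipSpectrum | None = None,
    rotated: tuple[np.ndarray, np.ndarray] | None = None,
    delta: float | None = None,
) -> MixedModelFit:
    """Fit the kinship mixed model by ML.

    Parameters
    ----------
    y, X
        Phenotype vector and fixed-effect design (rows aligned).
    K, spectrum
        The kinship matrix, or its precomputed :class:`KinshipSpectrum`
        (pass the spectrum when fitting many models against one kinship).
    rotated
        Optional pre-rotated ``(U^T y, U^T X)`` to skip the rotation.
    delta
        If given, the variance ratio is fixed (profiling disabled) —
        useful for oracle comparisons against an explicit GLS solve.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or len(y) != X.shape[0]:
        raise ValueError("y and X must be row-aligned")
    n, p = X.shape
    if n <= p:
        raise ValueError("need more observations than fixed effects")
    _check_design(X)

    if spectrum is None:
        if K is None:
            raise ValueError("supply K or its spectrum")
        spectrum = KinshipSpectrum.from_kinship(K)
    lam = spectrum.eigenvalues
    if rotated is not None:
        yr, Xr = rotated
    else:
        yr, Xr = spectrum.rotate(y), spectrum.rotate(X)

    beta_ols, sigma2_ols, ll_ols = ols_loglik(y, X)
    var_scale = max(float(np.var(y)), np.finfo(float).tiny)
    if sigma2_ols <= 1e-12 * var_scale:
        ll_ols = np.inf
    if not np.isfinite(ll_ols):
        return MixedModelFit(
            beta_hat=beta_ols, sigma_g2_hat=0.0, sigma_e2_hat=0.0,
            log_likelihood=np.inf, delta_hat=np.inf, converged=False, n=n,
            message="degenerate fit: response lies in the column span of the design",
        )

    if delta is not None:
        log_d = np.log(delta)
    else:
        grid = np.exp(np.linspace(np.log(DELTA_MIN), np.log(DELTA_MAX), N_GRID))
        ll_grid = _profile_ll_grid(yr, Xr, lam, grid)
        k = int(np.nanargmax(ll_grid))
        lo = np.log(grid[max(k - 1, 0)])
        hi = np.log(grid[min(k + 1, N_GRID - 1)])
        f = lambda t: _profile_ll_scalar(np.exp(t), yr, Xr, lam)
        log_d = _golden_section(f, lo, hi)

    d = float(np.exp(log_d))
    w = 1.0 / (lam + d)
    A = (Xr * w[:, None]).T @ Xr
    b = (Xr * w[:, None]).T @ yr
    beta = np.linalg.solve(A, b)
    resid = yr - Xr @ beta
    sigma_g2 = float((resid * w) @ resid) / n
    ll = -0.5 * (n * (_LOG2PI + np.log(sigma_g2) + 1.0) - np.log(w).sum())

    # boundary: sigma_g2 -> 0 is the delta -> inf limit, whose likelihood is OLS
    if delta is None and ll_ols >= ll:
        return MixedModelFit(
            beta_hat=beta_ols, sigma_g2_hat=0.0, sigma_e2_hat=sigma2_ols,
            log_likelihood=ll_ols, delta_hat=np.inf, converged=True, n=n,
            message="boundary solution sigma_g2 = 0 (OLS likelihood)",
            cov_beta=sigma2_ols * np.linalg.inv(X.T @ X),
        )

    if sigma_g2 <= 0.0 or not np.isfinite(ll):
        return MixedModelFit(
            beta_hat=beta, sigma_g2_hat=0.0, sigma_e2_hat=0.0,
            log_likelihood=np.inf, delta_hat=d, converged=False, n=n,
            message="degenerate fit: zero residual variance",
        )

    return MixedModelFit(
        beta_hat=beta, sigma_g2_hat=sigma_g2, sigma_e2_hat=d * sigma_g2,
        log_likelihood=float(ll), delta_hat=d, converged=True, n=n,
        cov_beta=sigma_g2 * np.linalg.inv(A),
    )
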