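"""Dense linear-algebra and log-density primitives.

All covariance work in the sampler goes through one Cholesky factorization
per matrix; these helpers keep that contract and raise
:class:`InvalidParameterError` on non-SPD input instead of propagating
``LinAlgError`` from deep inside an update.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import cho_solve, solve_triangular
from scipy.special import multigammaln

__all__ = [
    "InvalidParameterError",
    "InvalidStateError",
    "spd_cholesky",
    "chol_logdet",
    "mvn_logpdf",
    "invwishart_logpdf",
    "wishart_logpdf",
    "dirichlet_logpdf",
    "logsumexp_rows",
]

_LOG_2PI = np.log(2.0 * np.pi)


class InvalidParameterError(ValueError):
    """A covariance/scale matrix is not symmetric positive definite."""


class InvalidStateError(ValueError):
    """A model state violates a structural invariant (e.g. all Z_j off)."""


def spd_cholesky(sigma: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor of an SPD matrix.

    Raises
    ------
    InvalidParameterError
        If ``sigma`` is not symmetric positive definite.
    """
    sigma = np.asarray(sigma, dtype=float)
    if sigma.ndim != 2 or sigma.shape[0] != sigma.shape[1]:
        raise InvalidParameterError(f"expected square matrix, got shape {sigma.shape}")
    if not np.allclose(sigma, sigma.T, rtol=1e-8, atol=1e-10):
        raise InvalidParameterError("matrix is not symmetric")
    try:
        return np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as exc:
        raise InvalidParameterError("matrix is not positive definite") from exc


def chol_logdet(chol: np.ndarray) -> float:
    """log-determinant of the SPD matrix with lower Cholesky factor ``chol``."""
    return 2.0 * float(np.sum(np.log(np.diag(chol))))


def mvn_logpdf(y: np.ndarray, mu: np.ndarray, sigma: np.ndarray | None = None,
               chol: np.ndarray | None = None) -> np.ndarray | float:
    """Multivariate normal log density.

    ``y`` may be a single d-vector or an (n, d) matrix; in the latter case an
    (n,) vector of log densities is returned.  Either ``sigma`` or its
    pre-computed Cholesky factor ``chol`` must be given.
    """
    if chol is None:
        chol = spd_cholesky(sigma)
    y = np.asarray(y, dtype=float)
    single = y.ndim == 1
    resid = np.atleast_2d(y) - np.asarray(mu, dtype=float)
    d = resid.shape[1]
    # solve L z = resid^T  ->  quadratic form = ||z||^2 per row
    z = solve_triangular(chol, resid.T, lower=True)
    quad = np.sum(z * z, axis=0)
    out = -0.5 * (d * _LOG_2PI + chol_logdet(chol) + quad)
    return float(out[0]) if single else out


def invwishart_logpdf(S: np.ndarray, psi: np.ndarray, nu: float,
                      chol_S: np.ndarray | None = None,
                      chol_psi: np.ndarray | None = None) -> float:
    """log density of InverseWishart(psi, nu) at SPD matrix S.

    Parametrized so that E[S] = psi / (nu - d - 1) for nu > d + 1.
    """
    psi = np.asarray(psi, dtype=float)
    d = psi.shape[0]
    if chol_S is None:
        chol_S = spd_cholesky(S)
    if chol_psi is None:
        chol_psi = spd_cholesky(psi)
    ld_S = chol_logdet(chol_S)
    ld_psi = chol_logdet(chol_psi)
    # tr(psi S^{-1}) = || L_S^{-1} L_psi ||_F^2
    A = solve_triangular(chol_S, chol_psi, lower=True)
    trace = float(np.sum(A * A))
    return (0.5 * nu * ld_psi
            - 0.5 * nu * d * np.log(2.0)
            - multigammaln(0.5 * nu, d)
            - 0.5 * (nu + d + 1.0) * ld_S
            - 0.5 * trace)


def wishart_logpdf(W: np.ndarray, scale: np.ndarray, df: float,
                   chol_W: np.ndarray | None = None,
                   chol_scale: np.ndarray | None = None) -> float:
    """log density of Wishart(scale, df) at SPD matrix W; E[W] = df * scale."""
    scale = np.asarray(scale, dtype=float)
    d = scale.shape[0]
    if chol_W is None:
        chol_W = spd_cholesky(W)
    if chol_scale is None:
        chol_scale = spd_cholesky(scale)
    ld_W = chol_logdet(chol_W)
    ld_sc = chol_logdet(chol_scale)
    # tr(scale^{-1} W) = || L_scale^{-1} L_W ||_F^2
    A = solve_triangular(chol_scale, chol_W, lower=True)
    trace = float(np.sum(A * A))
    return (0.5 * (df - d - 1.0) * ld_W
            - 0.5 * trace
            - 0.5 * df * d * np.log(2.0)
            - 0.5 * df * ld_sc
            - multigammaln(0.5 * df, d))


def dirichlet_logpdf(p: np.ndarray, alpha: np.ndarray) -> float:
    """log density of Dirichlet(alpha) at probability vector p."""
    from scipy.special import gammaln

    p = np.asarray(p, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-8:
        raise InvalidParameterError("p is not a probability vector")
    return float(np.sum((alpha - 1.0) * np.log(np.clip(p, 1e-300, None)))
                 + gammaln(alpha.sum()) - np.sum(gammaln(alpha)))


def logsumexp_rows(logw: np.ndarray) -> np.ndarray:
    """Row-wise log-sum-exp of an (n, K) matrix, underflow safe."""
    m = np.max(logw, axis=1, keepdims=True)
    m = np.where(np.isfinite(m), m, 0.0)
    return (m + np.log(np.sum(np.exp(logw - m), axis=1, keepdims=True)))[:, 0]


def cho_inverse(sigma: np.ndarray, chol: np.ndarray | None = None) -> np.ndarray:
    """Inverse of an SPD matrix via its Cholesky factor."""
    if chol is None:
        chol = spd_cholesky(sigma)
    d = chol.shape[0]
    return cho_solve((chol, True), np.eye(d))
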