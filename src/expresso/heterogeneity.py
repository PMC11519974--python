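"""Cross-cell-type heterogeneity test for TWAS effects.

For a gene with TWAS z-scores ``U = (U_1, ..., U_K)`` across K cell types,
the statistic is the centered quadratic form

    H = sum_k (U_k - Ubar)^2 = U' C U,     C = I - (1/K) 11'.

Because prediction models of the same gene in different cell types share
variants and LD, the U_k are correlated under the null; their covariance is
the quadratic-form kernel ``beta_k1' Sigma beta_k2`` over the union variant
set, normalized to a correlation matrix Phi so that z-scores have unit null
variance.  Under H0 (equal means), ``H ~ sum_k lambda_k chi2_1`` with
``lambda_k`` the eigenvalues of C Phi C'.  Tail probabilities come from
Ruben's chi-square-mixture series (machine precision, rigorous truncation
bound), falling back to numeric inversion of the characteristic function
(Imhof's method) for near-singular spectra and to a Satterthwaite-Welch
moment match as a last resort; a seeded Monte-Carlo oracle is provided for
validation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate
from scipy import stats as sps

__all__ = [
    "HetResult",
    "bonferroni_threshold",
    "twas_effect_cov",
    "het_statistic",
    "het_pvalue",
    "weighted_chisq_sf",
    "mc_null_oracle",
    "het_test",
]

_EIG_CLIP_REL = 1e-10


@dataclass
class HetResult:
    gene_id: str
    H: float
    Phi: np.ndarray
    eigenvalues: np.ndarray
    p: float
    method: str


def bonferroni_threshold(alpha: float, n_tests: int) -> float:
    """Per-test significance threshold alpha / n_tests."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests


def centering_matrix(K: int) -> np.ndarray:
    return np.eye(K) - np.ones((K, K)) / K


def twas_effect_cov(weights: np.ndarray, Sigma: np.ndarray, normalize: bool = True) -> np.ndarray:
    """Null covariance of the per-cell-type TWAS effects.

    ``weights`` is K x P in the union variant coordinate system (zeros where a
    variant is unused by a cell type).  The kernel is
    ``Phi[k1, k2] = beta_k1' Sigma beta_k2``; with ``normalize=True`` (the
    default, matching z-score U) it is scaled to a correlation matrix with
    unit diagonal.
    """
    W = np.atleast_2d(np.asarray(weights, dtype=float))
    raw = W @ Sigma @ W.T
    if not normalize:
        return raw
    d = np.sqrt(np.diag(raw))
    if np.any(d <= 0):
        raise ValueError("zero-norm weight vector: w' Sigma w must be > 0 for every cell type")
    Phi = raw / np.outer(d, d)
    np.fill_diagonal(Phi, 1.0)
    return (Phi + Phi.T) / 2.0


def het_statistic(U: np.ndarray) -> float:
    """H = sum_k (U_k - Ubar)^2."""
    U = np.asarray(U, dtype=float)
    if U.size < 2:
        raise ValueError("need >= 2 cell types")
    return float(np.sum((U - U.mean()) ** 2))


def _imhof_sf(x: float, lam: np.ndarray, epsabs: float = 1e-10) -> float:
    """P(sum lam_k chi2_1 > x) by Imhof's characteristic-function inversion."""

    def theta(u):
        return 0.5 * np.sum(np.arctan(lam * u)) - 0.5 * x * u

    def rho(u):
        return np.prod((1.0 + (lam * u) ** 2) ** 0.25)

    def integrand(u):
        return np.sin(theta(u)) / (u * rho(u))

    val, _ = integrate.quad(
        integrand, 0.0, np.inf, epsabs=epsabs, epsrel=1e-10, limit=2000
    )
    return 0.5 + val / np.pi


def _ruben_sf(x: float, lam: np.ndarray, atol: float = 1e-11, max_terms: int = 20_000) -> float:
    """Tail of sum lam_k chi2_1 by Ruben's central chi-square mixture series.

    With beta <= min(lam) the mixture coefficients a_k are nonnegative and sum
    to one, so the truncation error is bounded by 1 - sum(a_k): the series is
    run until that bound drops below ``atol``.  Geometric convergence with
    ratio max(1 - beta/lam); raises on failure so callers can fall back.
    """
    m = lam.size
    lmin, lmax = float(lam.min()), float(lam.max())
    beta = 2.0 * lmin * lmax / (lmin + lmax)
    ratio = beta / lam
    a0 = float(np.exp(0.5 * np.sum(np.log(ratio))))
    if a0 == 0.0 or not np.isfinite(a0):
        raise FloatingPointError("Ruben series underflow")
    rmax = float(np.max(1.0 - ratio))
    if rmax >= 1.0 or (rmax > 0 and np.log(atol) / np.log(rmax) > max_terms):
        raise FloatingPointError("Ruben series would need too many terms")
    one_minus = 1.0 - ratio
    a = np.zeros(max_terms)
    d = np.zeros(max_terms)
    a[0] = a0
    powers = np.ones_like(lam)
    total = a0
    T = max_terms
    for k in range(1, max_terms):
        powers = powers * one_minus
        d[k - 1] = powers.sum()
        a[k] = float(np.dot(d[:k], a[k - 1 :: -1])) / (2.0 * k)
        total += a[k]
        if 1.0 - total < atol:
            T = k + 1
            break
    else:
        raise FloatingPointError("Ruben series did not converge")
    ks = np.arange(T)
    cdf = float(np.dot(a[:T], sps.chi2.cdf(x / beta, m + 2 * ks)))
    return float(min(max(1.0 - cdf, 0.0), 1.0))


def _satterthwaite_sf(x: float, lam: np.ndarray) -> float:
    """Moment-matched c * chi2_nu tail (Satterthwaite-Welch)."""
    s1, s2 = lam.sum(), np.sum(lam**2)
    if s2 == 0:
        return 1.0 if x <= 0 else 0.0
    c = s2 / s1
    nu = s1**2 / s2
    return float(sps.chi2.sf(x / c, df=nu))


def weighted_chisq_sf(x: float, lam: np.ndarray):
    """Tail probability of a weighted sum of 1-df chi-squares.

    Returns ``(p, method)``; falls back to moment matching when the numeric
    inversion misbehaves.
    """
    lam = np.asarray(lam, dtype=float)
    lam = lam[lam > 0]
    if lam.size == 0:
        return 1.0, "degenerate"
    # eigenvalues carrying negligible mass only stall the series
    lam = lam[lam > 1e-12 * lam.max()]
    if x <= 0:
        return 1.0, "boundary"
    try:
        return _ruben_sf(x, lam), "ruben"
    except FloatingPointError:
        pass
    try:
        with np.errstate(all="ignore"):
            import warnings as _w

            with _w.catch_warnings():
                _w.simplefilter("ignore")
                p = _imhof_sf(x, lam)
        if np.isfinite(p) and -1e-8 <= p <= 1 + 1e-8:
            return float(min(max(p, 0.0), 1.0)), "imhof"
    except Exception:  # pragma: no cover - scipy.quad failure path
        pass
    return _satterthwaite_sf(x, lam), "satterthwaite"


def het_pvalue(H: float, Phi: np.ndarray):
    """P-value of the heterogeneity statistic under the weighted-chi-square null.

    Eigenvalues of C Phi C' below -1e-10 (relative) are an error; tiny
    negatives from floating point are clipped at zero.
    """
    Phi = np.asarray(Phi, dtype=float)
    K = Phi.shape[0]
    C = centering_matrix(K)
    M = C @ Phi @ C.T
    lam = np.linalg.eigvalsh((M + M.T) / 2.0)
    scale = max(lam.max(), 1.0)
    if np.any(lam < -_EIG_CLIP_REL * scale):
        raise ValueError("C Phi C' has a materially negative eigenvalue; Phi is not PSD")
    lam = np.clip(lam, 0.0, None)
    if np.all(lam == 0):
        return 1.0, np.zeros_like(lam), "degenerate"
    p, method = weighted_chisq_sf(float(H), lam)
    return p, lam, method


def het_test(gene_id: str, U: np.ndarray, weights: np.ndarray, Sigma: np.ndarray,
             normalize: bool = True) -> HetResult:
    """Convenience wrapper: covariance, statistic and p-value in one call."""
    Phi = twas_effect_cov(weights, Sigma, normalize=normalize)
    H = het_statistic(U)
    p, lam, method = het_pvalue(H, Phi)
    return HetResult(gene_id=gene_id, H=H, Phi=Phi, eigenvalues=lam, p=p, method=method)


def mc_null_oracle(Phi: np.ndarray, n_draws: int = 100_000, seed=None, mu: float = 0.0):
    """Empirical null distribution of H via seeded draws U ~ MVN(mu 1, Phi).

    H is invariant to a common shift of U, so any mu gives the same law.
    Returns the sorted draws and a tail-probability function.
    """
    if n_draws < 1_000:
        raise ValueError("n_draws must be >= 1000")
    rng = np.random.default_rng(seed)
    Phi = np.asarray(Phi, dtype=float)
    K = Phi.shape[0]
    vals, vecs = np.linalg.eigh((Phi + Phi.T) / 2.0)
    L = vecs * np.sqrt(np.clip(vals, 0.0, None))
    U = mu + rng.standard_normal((n_draws, K)) @ L.T
    Hs = np.sum((U - U.mean(axis=1, keepdims=True)) ** 2, axis=1)
    Hs.sort()

    def tail(x: float) -> float:
        return float(np.mean(Hs > x))

    return Hs, tail
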