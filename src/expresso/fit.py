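"""Summary-statistics elastic net with a partitioned (annotation-aware) penalty.

The gene-expression model is ``y = X beta + eps`` with standardized genotypes
and expression (var = 1).  Dropping the constant ``y'y`` term and dividing by
the sample size N, the penalized loss evaluated from summary statistics is

    f(beta) = beta' G beta - 2 beta' r
              + (lambda/4) sum_j m_j beta_j^2 + (lambda/2) sum_j m_j |beta_j|

where ``G`` is the LD (correlation) matrix from a reference panel standing in
for X'X/N, ``r`` is the vector of marginal genotype-expression correlations
standing in for X'y/N, and ``m_j`` is the per-variant penalty multiplier: the
mitigation factor ``phi`` (< 1 softens shrinkage) for variants overlapping
epigenomic annotation ("essential" variants), 1 otherwise.

The minimizer is found by cyclic coordinate descent; the single-coordinate
update is the soft-threshold rule

    beta_j <- S(rho_j, lambda m_j / 4) / (G_jj + lambda m_j / 4),
    rho_j  =  r_j - sum_{k != j} G_jk beta_k.

All public entry points are pure functions of numpy arrays so that the tuning
and association layers can drive them on arbitrary variant subsets.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


__all__ = [
    "GramMatrix",
    "PenaltySpec",
    "assemble_gram",
    "assemble_xty",
    "objective_value",
    "cd_solve",
    "lambda_max",
]


@dataclass
class GramMatrix:
    """LD Gram matrix on the correlation scale.

    ``matrix`` is symmetric p x p with unit diagonal before ridge
    regularization; after ``G <- (1 - ridge_eps) G + ridge_eps I`` the diagonal
    stays 1 and the matrix is positive definite for ridge_eps > 0.
    """

    matrix: np.ndarray
    variant_ids: list = field(default_factory=list)
    n_ref: int = 0
    ridge_eps: float = 0.0

    @property
    def p(self) -> int:
        return self.matrix.shape[0]

    def subset(self, idx) -> "GramMatrix":
        idx = np.asarray(idx)
        ids = [self.variant_ids[i] for i in idx] if self.variant_ids else []
        return GramMatrix(
            matrix=self.matrix[np.ix_(idx, idx)],
            variant_ids=ids,
            n_ref=self.n_ref,
            ridge_eps=self.ridge_eps,
        )


@dataclass
class PenaltySpec:
    """Shrinkage lambda >= 0 and per-variant multipliers m (phi for essential)."""

    lam: float
    multipliers: np.ndarray

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")
        self.multipliers = np.asarray(self.multipliers, dtype=float)
        if np.any(self.multipliers <= 0):
            raise ValueError("penalty multipliers must be > 0")

    @classmethod
    def from_mask(cls, lam: float, essential: np.ndarray, phi: float) -> "PenaltySpec":
        if phi <= 0:
            raise ValueError("mitigation factor phi must be > 0")
        essential = np.asarray(essential, dtype=bool)
        return cls(lam, np.where(essential, phi, 1.0))


def assemble_gram(genotypes: np.ndarray, variant_ids=None, ridge_eps: float = 0.05) -> GramMatrix:
    """Correlation-scale Gram matrix from a reference genotype matrix (n x p).

    Monomorphic variants (zero variance) are removed with a warning.  The
    ridge step shrinks off-diagonals toward identity to keep out-of-sample LD
    positive definite.
    """
    X = np.asarray(genotypes, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D genotype matrix with >= 2 individuals")
    if not 0 <= ridge_eps < 1:
        raise ValueError("ridge_eps must be in [0, 1)")
    sd = X.std(axis=0, ddof=0)
    keep = sd > 0
    if not np.all(keep):
        dropped = np.flatnonzero(~keep)
        warnings.warn(f"removed {dropped.size} monomorphic variant(s): {dropped.tolist()}")
        X = X[:, keep]
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
    G = Z.T @ Z / X.shape[0]
    G = (G + G.T) / 2.0
    p = G.shape[0]
    G = (1.0 - ridge_eps) * G + ridge_eps * np.eye(p)
    ids = None
    if variant_ids is not None:
        ids = [v for v, k in zip(variant_ids, keep) if k]
    return GramMatrix(matrix=G, variant_ids=ids or [], n_ref=X.shape[0], ridge_eps=ridge_eps)


def assemble_xty(z: np.ndarray, n: np.ndarray):
    """Marginal correlations r_j = z_j / sqrt(z_j^2 + n_j - 2) and median N.

    This is the per-sample X'y proxy: with standardized genotypes and
    expression the marginal correlation is a monotone transform of the
    marginal z-score, independent of effect-size units in the input file.
    Variants with n <= 2 are dropped by the caller (see sumstats module).
    """
    z = np.asarray(z, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(n <= 2):
        raise ValueError("per-variant sample size must be > 2")
    r = z / np.sqrt(z * z + n - 2.0)
    return r, float(np.median(n))


def objective_value(beta: np.ndarray, G: np.ndarray, r: np.ndarray, pen: PenaltySpec) -> float:
    """Per-sample penalized loss (constant y'y/N term omitted)."""
    beta = np.asarray(beta, dtype=float)
    quad = float(beta @ G @ beta - 2.0 * beta @ r)
    m = pen.multipliers
    l2 = pen.lam / 4.0 * float(np.sum(m * beta * beta))
    l1 = pen.lam / 2.0 * float(np.sum(m * np.abs(beta)))
    return quad + l2 + l1


def lambda_max(r: np.ndarray, multipliers: np.ndarray) -> float:
    """Smallest lambda at which beta = 0 is optimal: max_j 4 |r_j| / m_j."""
    r = np.asarray(r, dtype=float)
    m = np.asarray(multipliers, dtype=float)
    if r.size == 0:
        return 0.0
    return float(np.max(4.0 * np.abs(r) / m))


@njit(cache=False)
def _cd_kernel(G, r, thr, beta, tol, max_sweeps):  # pragma: no cover - jitted
    p = r.shape[0]
    for sweep in range(max_sweeps):
        delta = 0.0
        for j in range(p):
            bj = beta[j]
            rho = r[j] - np.dot(G[j], beta) + G[j, j] * bj
            t = thr[j]
            if rho > t:
                bnew = (rho - t) / (G[j, j] + t)
            elif rho < -t:
                bnew = (rho + t) / (G[j, j] + t)
            else:
                bnew = 0.0
            d = abs(bnew - bj)
            if d > delta:
                delta = d
            beta[j] = bnew
        if delta < tol:
            return sweep + 1
    return -max_sweeps


def cd_solve(
    G: np.ndarray,
    r: np.ndarray,
    pen: PenaltySpec,
    tol: float = 1e-9,
    max_sweeps: int = 10_000,
    beta0: np.ndarray | None = None,
):
    """Cyclic coordinate descent on the summary-statistics objective.

    Variants are visited in array order (callers keep genomic-position
    order).  Returns ``(beta, converged)``; non-convergence raises a warning
    but still returns the last iterate.
    """
    G = np.ascontiguousarray(G, dtype=float)
    r = np.ascontiguousarray(r, dtype=float)
    if tol <= 0:
        raise ValueError("tol must be > 0")
    p = r.shape[0]
    if G.shape != (p, p):
        raise ValueError("G and r dimensions disagree")
    # threshold and L2 add-on coincide: both are lambda * m_j / 4
    thr = np.ascontiguousarray(pen.lam * pen.multipliers / 4.0)
    beta = np.zeros(p) if beta0 is None else np.array(beta0, dtype=float)
    status = _cd_kernel(G, r, thr, beta, tol, max_sweeps)
    converged = status > 0
    if not converged:
        warnings.warn(f"coordinate descent did not converge in {max_sweeps} sweeps")
    return beta, converged
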