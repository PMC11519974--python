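"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import minimize

from expresso import simulate as sim
from expresso.fit import assemble_gram


def lbfgs_oracle(G: np.ndarray, r: np.ndarray, lam: float, m: np.ndarray) -> np.ndarray:
    """Generic projected convex solver for the penalized summary objective.

    Independent of the coordinate-descent path: the L1 term is handled by the
    standard split beta = a - b with a, b >= 0 and the smooth objective is
    minimized by L-BFGS-B under bound constraints.
    """
    p = r.size

    def fun(x):
        a, b = x[:p], x[p:]
        beta = a - b
        quad = beta @ G @ beta - 2.0 * beta @ r
        pen = lam / 4.0 * np.sum(m * beta**2) + lam / 2.0 * np.sum(m * (a + b))
        return quad + pen

    def grad(x):
        a, b = x[:p], x[p:]
        beta = a - b
        g = 2.0 * G @ beta - 2.0 * r + lam / 2.0 * m * beta
        l1 = lam / 2.0 * m
        return np.concatenate([g + l1, -g + l1])

    res = minimize(
        fun,
        np.zeros(2 * p),
        jac=grad,
        method="L-BFGS-B",
        bounds=[(0, None)] * (2 * p),
        options=dict(maxiter=50_000, ftol=1e-18, gtol=1e-14),
    )
    return res.x[:p] - res.x[p:]


def in_sample_problem(seed: int, n: int = 500, p: int = 50, n_causal: int = 5):
    """Individual-level data plus its exact Gram/X'y summary representation."""
    rng = np.random.default_rng(seed)
    C = np.linalg.cholesky(0.5 ** np.abs(np.subtract.outer(np.arange(p), np.arange(p))))
    X = rng.standard_normal((n, p)) @ C.T
    X = (X - X.mean(0)) / X.std(0)
    beta_t = np.zeros(p)
    beta_t[rng.choice(p, n_causal, replace=False)] = rng.standard_normal(n_causal) * 0.3
    y = X @ beta_t + rng.standard_normal(n)
    y = (y - y.mean()) / y.std()
    G = X.T @ X / n
    r = X.T @ y / n
    essential = np.zeros(p, dtype=bool)
    essential[rng.choice(p, p // 3, replace=False)] = True
    return X, y, G, r, essential


@pytest.fixture(scope="session")
def signal_gene():
    """One simulated gene with h2 = 0.3 and its ridge-regularized LD."""
    cfg = sim.SimConfig(seed=11, causal_in_essential_prob=1.0)
    gene = sim.simulate_gene(cfg)
    gram = assemble_gram(gene.ref_genotypes, ridge_eps=0.05)
    return cfg, gene, gram


@pytest.fixture(scope="session")
def null_gene():
    cfg = sim.SimConfig(seed=13, h2_cis=0.0, n_causal=0)
    gene = sim.simulate_gene(cfg)
    gram = assemble_gram(gene.ref_genotypes, ridge_eps=0.05)
    return cfg, gene, gram
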