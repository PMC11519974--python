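"""Tuning-parameter selection for the summary-statistics elastic net.

Two nested selection problems are solved per gene:

* **Shrinkage (lambda) via pseudo-variable selection (PVS).**  For each
  (mitigation phi, window w) pair, "pseudo variables" with the same LD
  structure as the measured variants but no true association are simulated on
  the summary-statistic scale, ``r_pi ~ N(0, G / N)`` (per-sample scale,
  var(Y) = 1).  The augmented system with block-diagonal Gram
  ``[[G, 0], [0, G]]`` is solved along an ascending lambda grid, and
  lambda-hat is the smallest grid value at which every pseudo coefficient is
  zero.  Ten replicates are averaged for stability.

* **(phi, w) via summary-statistics cross-validation.**  X'y is decomposed
  into N per-individual contribution vectors ``X_i y_i ~ N(X'y / N, Sigma)``
  whose sum is exactly the observed X'y; contributions are partitioned into
  5 folds, each fold's held-out statistics validate the model trained on the
  remaining folds.  The validated loss is the penalized objective evaluated
  at lambda-hat(phi, w) (strategy ``pvs``) or the unpenalized quadratic loss
  with lambda joining the grid search (strategy ``mse``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fit import GramMatrix, PenaltySpec, cd_solve, lambda_max, objective_value
from .sumstats import MarginalEqtlStats, WeightModel
from .windows import RegionSet, variants_in_regions

logger = logging.getLogger(__name__)

DEFAULT_PHI_GRID = (1.0 / 6.0, 1.0 / 3.0, 1.0 / 2.0, 1.0)


@dataclass
class PseudoStats:
    """One replicate of simulated pseudo-variable summary statistics."""

    replicate: int
    r_pi: np.ndarray


@dataclass
class FoldContributions:
    """Per-fold partial X'y vectors (sum scale) that conserve the total."""

    fold_sums: np.ndarray  # n_folds x p
    fold_sizes: np.ndarray  # individuals per fold
    xty_sum: np.ndarray  # the full (sum-scale) X'y

    def __post_init__(self):
        if self.fold_sums.shape[0] != self.fold_sizes.shape[0]:
            raise ValueError("fold count mismatch")

    @property
    def n_folds(self) -> int:
        return self.fold_sums.shape[0]


@dataclass
class TuningResult:
    chosen_lambda: float
    chosen_phi: float
    chosen_window: str
    table: pd.DataFrame  # one row per evaluated (window, phi [, lambda])
    strategy: str
    chosen_loss: float = float("nan")


@dataclass
class CandidateWindow:
    """A named candidate cis-window resolved to variant indices."""

    name: str
    idx: np.ndarray
    span_bp: int


@dataclass
class TrainConfig:
    phis: tuple = DEFAULT_PHI_GRID
    strategy: str = "pvs"  # or "mse"
    n_pseudo: int = 10
    n_folds: int = 5
    n_lambda: int = 50
    lambda_min_ratio: float = 0.01
    cd_tol: float = 1e-8
    max_sweeps: int = 5000
    cell_type: str = "NA"


def _psd_sqrt(G: np.ndarray) -> np.ndarray:
    """Cholesky factor, falling back to an eigenvalue square root (clip at 0)."""
    try:
        return np.linalg.cholesky(G)
    except np.linalg.LinAlgError:
        vals, vecs = np.linalg.eigh(G)
        vals = np.clip(vals, 0.0, None)
        return vecs * np.sqrt(vals)


def lambda_grid(lmax: float, n_points: int = 50, min_ratio: float = 0.01) -> np.ndarray:
    """Ascending log-spaced grid on [min_ratio * lmax, lmax]."""
    if lmax <= 0:
        return np.zeros(1)
    return np.geomspace(min_ratio * lmax, lmax, n_points)


def simulate_pseudo_xty(G, N: float, n_replicates: int = 10, rng=None) -> list:
    """Draw pseudo-variable summary statistics r_pi ~ N(0, G / N)."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng(rng)
    Gm = G.matrix if isinstance(G, GramMatrix) else np.asarray(G, float)
    L = _psd_sqrt(Gm) / np.sqrt(N)
    return [
        PseudoStats(replicate=i, r_pi=L @ rng.standard_normal(Gm.shape[0]))
        for i in range(n_replicates)
    ]


def _augment(G: np.ndarray, r: np.ndarray, r_pi: np.ndarray, m: np.ndarray):
    p = r.shape[0]
    Gaug = np.zeros((2 * p, 2 * p))
    Gaug[:p, :p] = G
    Gaug[p:, p:] = G
    r_aug = np.concatenate([r, r_pi])
    m_aug = np.concatenate([m, np.ones(p)])  # pseudo variables are never mitigated
    return Gaug, r_aug, m_aug


def pvs_lambda(
    G: np.ndarray,
    r: np.ndarray,
    pseudo: PseudoStats,
    multipliers: np.ndarray,
    grid: np.ndarray,
    cd_tol: float = 1e-8,
    max_sweeps: int = 5000,
) -> float:
    """Smallest grid lambda at which all pseudo coefficients are zero.

    The grid is scanned from small to large with warm starts and stops at the
    first all-zero pseudo block.  If even the grid maximum leaves a pseudo
    coefficient nonzero (only possible for a grid not anchored at the
    augmented lambda_max) the maximum is returned with a warning.
    """
    p = r.shape[0]
    Gaug, r_aug, m_aug = _augment(G, r, pseudo.r_pi, multipliers)
    beta = np.zeros(2 * p)
    for lam in grid:
        beta, _ = cd_solve(
            Gaug, r_aug, PenaltySpec(lam, m_aug), tol=cd_tol, max_sweeps=max_sweeps, beta0=beta
        )
        if np.all(beta[p:] == 0.0):
            return float(lam)
    logger.warning("pseudo coefficients nonzero at grid maximum; returning grid max")
    return float(grid[-1])


def aggregate_pvs(lambda_hats) -> float:
    """Arithmetic mean across pseudo replicates."""
    lams = np.asarray(list(lambda_hats), dtype=float)
    if lams.size == 0:
        raise ValueError("need >= 1 replicate")
    return float(lams.mean())


def simulate_individual_contributions(
    xty_sum: np.ndarray, G, N: int, n_folds: int = 5, rng=None
) -> FoldContributions:
    """Decompose X'y (sum scale) into N simulated per-individual contributions.

    N - 1 contributions are drawn from N(X'y / N, Sigma); the last is the
    residual so that the sum is exact.  A seeded balanced partition assigns
    contributions to folds.
    """
    if not N >= n_folds >= 2:
        raise ValueError("need N >= n_folds >= 2")
    rng = np.random.default_rng(rng)
    Gm = G.matrix if isinstance(G, GramMatrix) else np.asarray(G, float)
    xty_sum = np.asarray(xty_sum, dtype=float)
    p = xty_sum.shape[0]
    L = _psd_sqrt(Gm)
    contrib = xty_sum / N + rng.standard_normal((N - 1, p)) @ L.T
    last = xty_sum - contrib.sum(axis=0)
    contrib = np.vstack([contrib, last])

    assignment = rng.permutation(np.arange(N) % n_folds)
    fold_sums = np.zeros((n_folds, p))
    fold_sizes = np.zeros(n_folds, dtype=int)
    for f in range(n_folds):
        mask = assignment == f
        fold_sizes[f] = mask.sum()
        fold_sums[f] = contrib[mask].sum(axis=0)
    return FoldContributions(fold_sums=fold_sums, fold_sizes=fold_sizes, xty_sum=xty_sum)


def _cv_fold_fits(Gw, folds: FoldContributions, lam, m, N, cfg: TrainConfig):
    """Per-fold solutions at one penalty, with the held-out validation r."""
    fits = []
    for f in range(folds.n_folds):
        n_val = folds.fold_sizes[f]
        n_train = N - n_val
        r_train = (folds.xty_sum - folds.fold_sums[f]) / n_train
        r_val = folds.fold_sums[f] / n_val
        beta, _ = cd_solve(
            Gw, r_train, PenaltySpec(lam, m), tol=cfg.cd_tol, max_sweeps=cfg.max_sweeps
        )
        fits.append((beta, r_val))
    return fits


def _cv_loss(fits, Gw, lam, m, penalized: bool) -> float:
    losses = []
    for beta, r_val in fits:
        quad = float(beta @ Gw @ beta - 2.0 * beta @ r_val)
        if penalized:
            quad += objective_value(beta, np.zeros_like(Gw), np.zeros_like(r_val), PenaltySpec(lam, m))
        losses.append(quad)
    return float(np.mean(losses))


def sumstats_cv_select(
    gram: GramMatrix,
    r: np.ndarray,
    N: float,
    windows: list,
    phis=DEFAULT_PHI_GRID,
    strategy: str = "pvs",
    essential: np.ndarray | None = None,
    cfg: TrainConfig | None = None,
    rng=None,
) -> TuningResult:
    """Grid search over (phi, window [, lambda]) by summary-statistics 5-fold CV.

    ``windows`` is a list of :class:`CandidateWindow`; empty ones are skipped
    with a log entry.  Candidates are visited smaller-window first, then
    larger phi, then larger lambda, and only a strictly smaller CV loss
    displaces the incumbent — which realizes the tie-breaking rules.
    """
    cfg = cfg or TrainConfig(strategy=strategy)
    if strategy not in ("pvs", "mse"):
        raise ValueError("strategy must be 'pvs' or 'mse'")
    rng = np.random.default_rng(rng)
    essential = (
        np.zeros(gram.p, dtype=bool) if essential is None else np.asarray(essential, bool)
    )
    N = float(N)
    usable = [w for w in windows if w.idx.size > 0]
    for w in windows:
        if w.idx.size == 0:
            logger.info("window %s contains no variants; skipped", w.name)
    if not usable:
        raise ValueError("no candidate window contains any variant")

    rows = []
    best = None  # (loss, lambda, phi, window)
    for win in sorted(usable, key=lambda w: (w.span_bp, w.name)):
        Gw = gram.matrix[np.ix_(win.idx, win.idx)]
        rw = r[win.idx]
        ew = essential[win.idx]
        folds = simulate_individual_contributions(
            N * rw, Gw, int(N), n_folds=cfg.n_folds, rng=rng.integers(2**31)
        )
        pseudo = simulate_pseudo_xty(Gw, N, n_replicates=cfg.n_pseudo, rng=rng.integers(2**31))
        for phi in sorted(phis, reverse=True):
            m = np.where(ew, phi, 1.0)
            if strategy == "pvs":
                lmax_aug = max(
                    (lambda_max(rw, m), *(lambda_max(ps.r_pi, np.ones_like(rw)) for ps in pseudo))
                )
                grid = lambda_grid(lmax_aug, cfg.n_lambda, cfg.lambda_min_ratio)
                lam_hat = aggregate_pvs(
                    pvs_lambda(Gw, rw, ps, m, grid, cfg.cd_tol, cfg.max_sweeps) for ps in pseudo
                )
                fits = _cv_fold_fits(Gw, folds, lam_hat, m, int(N), cfg)
                loss = _cv_loss(fits, Gw, lam_hat, m, penalized=True)
                rows.append(
                    {"window": win.name, "phi": phi, "lambda": lam_hat, "cv_loss": loss}
                )
                if np.isfinite(loss) and (best is None or loss < best[0]):
                    best = (loss, lam_hat, phi, win)
            else:  # mse: lambda joins the grid search, quadratic loss only
                grid = lambda_grid(lambda_max(rw, m), cfg.n_lambda, cfg.lambda_min_ratio)
                for lam in grid[::-1]:  # descending so ties keep the larger lambda
                    fits = _cv_fold_fits(Gw, folds, lam, m, int(N), cfg)
                    loss = _cv_loss(fits, Gw, lam, m, penalized=False)
                    rows.append(
                        {"window": win.name, "phi": phi, "lambda": lam, "cv_loss": loss}
                    )
                    if np.isfinite(loss) and (best is None or loss < best[0]):
                        best = (loss, lam, phi, win)

    if best is None:
        raise ValueError("all CV losses are non-finite")
    table = pd.DataFrame(rows)
    return TuningResult(
        chosen_lambda=best[1],
        chosen_phi=best[2],
        chosen_window=best[3].name,
        table=table,
        strategy=strategy,
        chosen_loss=best[0],
    )


def resolve_windows(variants: pd.DataFrame, window_regions: dict) -> list:
    """Map named RegionSets to variant-index CandidateWindows (1-based positions)."""
    out = []
    for name, reg in window_regions.items():
        if isinstance(reg, RegionSet):
            mask = variants_in_regions(variants, reg)
            out.append(CandidateWindow(name=name, idx=np.flatnonzero(mask), span_bp=reg.span_bp()))
        else:
            idx = np.asarray(reg, dtype=int)
            out.append(CandidateWindow(name=name, idx=idx, span_bp=int(idx.size)))
    return out


def train_model(
    stats: MarginalEqtlStats,
    gram: GramMatrix,
    essential: np.ndarray,
    windows,
    cfg: TrainConfig | None = None,
    rng=None,
) -> WeightModel | None:
    """Full training for one gene: tuning search then a final fit.

    ``stats`` and ``gram`` must be variant-aligned (harmonized, position
    sorted).  Returns None ("no model") when the final solution is all-zero
    or when the best cross-validated loss is not below zero — the held-out
    loss of the null (all-zero) predictor — i.e., when no candidate model
    validates better than predicting nothing.
    """
    from .fit import assemble_xty

    cfg = cfg or TrainConfig()
    rng = np.random.default_rng(rng)
    r, N = assemble_xty(stats.table["z"].to_numpy(), stats.table["n"].to_numpy())
    if isinstance(windows, dict):
        windows = resolve_windows(stats.table, windows)

    sel = sumstats_cv_select(
        gram, r, N, windows, phis=cfg.phis, strategy=cfg.strategy,
        essential=essential, cfg=cfg, rng=rng,
    )
    if not sel.chosen_loss < 0:
        logger.info(
            "gene %s: no candidate beats the null predictor in CV (best loss %.4g); no model",
            stats.gene_id, sel.chosen_loss,
        )
        return None
    win = next(w for w in windows if w.name == sel.chosen_window)
    Gw = gram.matrix[np.ix_(win.idx, win.idx)]
    rw = r[win.idx]
    ew = np.asarray(essential, bool)[win.idx]
    m = np.where(ew, sel.chosen_phi, 1.0)
    beta, _ = cd_solve(
        Gw, rw, PenaltySpec(sel.chosen_lambda, m), tol=cfg.cd_tol, max_sweeps=cfg.max_sweeps
    )
    nz = beta != 0.0
    if not nz.any():
        logger.info("gene %s: all-zero final model, reported as no model", stats.gene_id)
        return None
    keep = win.idx[nz]
    return WeightModel(
        gene_id=stats.gene_id,
        cell_type=cfg.cell_type,
        variants=stats.table.iloc[keep][["chrom", "pos", "ref", "alt"]].reset_index(drop=True),
        beta_hat=beta[nz],
        essential_flags=np.asarray(essential, bool)[keep],
        chosen_lambda=sel.chosen_lambda,
        chosen_phi=sel.chosen_phi,
        chosen_window=sel.chosen_window,
        training_n=N,
    )
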