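"""Synthetic-data generator with known ground truth.

Emulates every input the toolkit consumes: a blockwise-LD reference panel, an
eQTL cohort with causal cis-variants enriched in annotated ("essential")
intervals, marginal eQTL summary statistics, GWAS summary statistics under a
mediation model (variants -> expression -> trait), epigenomic BED tracks and
a promoter-to-enhancer loop, and multi-cell-type effect sharing with tunable
heterogeneity.

Genotypes are latent-Gaussian AR(1) haplotypes thresholded at the MAF
quantile; LD blocks restart every ``block_size`` variants.  Expression
follows ``y = X beta + eps`` with effects scaled to a target cis
heritability and standardized expression.  All randomness flows through a
single seeded generator; the same seed reproduces every matrix and file.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .sumstats import GwasSumStats, MarginalEqtlStats
from .windows import RegionSet

TRACK_NAMES = ("H3K27ac", "H3K4me3", "DNase", "CTCF")


@dataclass
class SimConfig:
    """Study conditions for the generator.

    Cohort sizes and genetic architecture default to the conditions used
    throughout the test suite: a 1,000-sample eQTL cohort, 50 cis-variants
    per gene with moderate AR(1) LD, cis heritability 0.3 spread over 5
    causal variants that fall in annotated intervals 90% of the time, and a
    moderate mediated effect on the GWAS trait.
    """

    n_ref: int = 500
    n_eqtl: int = 1_000
    n_gwas: int = 50_000
    p: int = 50
    ld_rho: float = 0.5
    h2_cis: float = 0.3
    n_causal: int = 5
    essential_frac: float = 0.3
    causal_in_essential_prob: float = 0.9
    alpha_med: float = 0.1
    K: int = 3
    share_prob: float = 0.7
    seed: int = 0
    block_size: int = 200
    chrom: str = "1"
    region_start: int = 1_000_000
    spacing_bp: int = 2_000

    def __post_init__(self):
        if not 0 <= self.h2_cis < 1:
            raise ValueError("h2_cis must be in [0, 1)")
        if not 0 <= self.ld_rho < 1:
            raise ValueError("ld_rho must be in [0, 1)")
        for name in ("essential_frac", "causal_in_essential_prob", "share_prob"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class SimulatedGene:
    cfg: SimConfig
    variants: pd.DataFrame
    ref_genotypes: np.ndarray
    cohort_genotypes: np.ndarray
    essential: np.ndarray
    beta_true: np.ndarray
    expression: np.ndarray
    stats: MarginalEqtlStats
    gene: dict
    tracks: dict
    loop: RegionSet
    truth: dict


def _ar1_latent(rng, n_hap: int, p: int, rho: float, block_size: int) -> np.ndarray:
    z = np.empty((n_hap, p))
    innov = rng.standard_normal((n_hap, p))
    scale = np.sqrt(1.0 - rho * rho)
    for j in range(p):
        if j % block_size == 0:
            z[:, j] = innov[:, j]
        else:
            z[:, j] = rho * z[:, j - 1] + scale * innov[:, j]
    return z


def _variant_frame(cfg: SimConfig, maf: np.ndarray) -> pd.DataFrame:
    pos = cfg.region_start + np.arange(cfg.p) * cfg.spacing_bp + 1  # 1-based
    # non-palindromic allele pairs so harmonization keeps every variant
    refs = np.array(["A", "C"])[np.arange(cfg.p) % 2]
    alts = np.array(["G", "T"])[np.arange(cfg.p) % 2]
    return pd.DataFrame(
        {
            "chrom": cfg.chrom,
            "pos": pos,
            "id": [f"rs{p_}" for p_ in pos],
            "ref": refs,
            "alt": alts,
            "maf": maf,
        }
    )


def _genotypes(rng, cfg: SimConfig, n: int, maf: np.ndarray) -> np.ndarray:
    """Dosages 0/1/2 from two thresholded AR(1) haplotypes."""
    cut = sps.norm.isf(maf)  # latent > cut with probability maf
    h1 = _ar1_latent(rng, n, cfg.p, cfg.ld_rho, cfg.block_size) > cut
    h2 = _ar1_latent(rng, n, cfg.p, cfg.ld_rho, cfg.block_size) > cut
    return (h1 + h2).astype(float)


def simulate_reference(cfg: SimConfig, rng=None):
    """Reference-panel genotypes plus variant records (MAF ~ U(0.05, 0.5))."""
    if cfg.n_ref < 2:
        raise ValueError("n_ref must be >= 2")
    rng = np.random.default_rng(cfg.seed if rng is None else rng)
    maf = rng.uniform(0.05, 0.5, size=cfg.p)
    variants = _variant_frame(cfg, maf)
    X = _genotypes(rng, cfg, cfg.n_ref, maf)
    return X, variants


def _standardize(X: np.ndarray) -> np.ndarray:
    sd = X.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    return (X - X.mean(axis=0)) / sd


def _draw_causal(rng, cfg: SimConfig, essential: np.ndarray) -> np.ndarray:
    ess_idx = np.flatnonzero(essential)
    non_idx = np.flatnonzero(~essential)
    chosen: list[int] = []
    for _ in range(cfg.n_causal):
        pool = ess_idx if (ess_idx.size and rng.random() < cfg.causal_in_essential_prob) else non_idx
        pool = np.setdiff1d(pool, chosen)
        if pool.size == 0:
            pool = np.setdiff1d(np.arange(cfg.p), chosen)
        chosen.append(int(rng.choice(pool)))
    return np.array(sorted(chosen), dtype=int)


def _marginal_stats(Z: np.ndarray, y: np.ndarray, variants: pd.DataFrame, n: int,
                    gene_id: str) -> MarginalEqtlStats:
    """Per-variant simple-regression summary statistics (standardized scale)."""
    r = Z.T @ y / n
    r = np.clip(r, -0.999999, 0.999999)
    z = r * np.sqrt((n - 2) / (1.0 - r * r))
    beta = r
    se = np.where(z != 0, beta / z, np.sqrt((1.0 - r * r) / (n - 2)))
    tab = variants[["chrom", "pos", "id", "ref", "alt"]].copy()
    tab["beta"] = beta
    tab["se"] = se
    tab["z"] = z
    tab["n"] = n
    return MarginalEqtlStats(gene_id=gene_id, table=tab)


def _make_tracks(cfg: SimConfig, variants: pd.DataFrame, essential: np.ndarray,
                 rng) -> dict:
    """Four epigenomic BED tracks whose union covers the essential variants.

    Each essential variant's +-250 bp neighborhood is assigned to one track
    cyclically, so the OR over tracks reproduces the essential mask exactly.
    """
    tracks: dict[str, list] = {name: [] for name in TRACK_NAMES}
    for rank, i in enumerate(np.flatnonzero(essential)):
        pos0 = int(variants["pos"].iloc[i]) - 1  # to 0-based
        iv = (cfg.chrom, max(0, pos0 - 250), pos0 + 251)
        tracks[TRACK_NAMES[rank % len(TRACK_NAMES)]].append(iv)
    return {
        name: RegionSet(kind="linear", intervals=ivs) for name, ivs in tracks.items()
    }


def simulate_gene(cfg: SimConfig, rng=None, gene_id: str = "GENE1") -> SimulatedGene:
    """One gene's full generative draw: genotypes, truth, stats, annotation."""
    rng = np.random.default_rng(cfg.seed if rng is None else rng)
    maf = rng.uniform(0.05, 0.5, size=cfg.p)
    variants = _variant_frame(cfg, maf)
    X_ref = _genotypes(rng, cfg, cfg.n_ref, maf)
    X = _genotypes(rng, cfg, cfg.n_eqtl, maf)
    Z = _standardize(X)

    n_ess = int(round(cfg.essential_frac * cfg.p))
    essential = np.zeros(cfg.p, dtype=bool)
    essential[rng.choice(cfg.p, size=n_ess, replace=False)] = True

    beta = np.zeros(cfg.p)
    causal = np.array([], dtype=int)
    if cfg.h2_cis > 0 and cfg.n_causal > 0:
        causal = _draw_causal(rng, cfg, essential)
        raw = rng.standard_normal(causal.size)
        g = Z[:, causal] @ raw
        scale = np.sqrt(cfg.h2_cis / np.var(g))
        beta[causal] = raw * scale
    genetic = Z @ beta
    y = genetic + rng.standard_normal(cfg.n_eqtl) * np.sqrt(max(1.0 - cfg.h2_cis, 1e-12))
    y = (y - y.mean()) / y.std(ddof=0)

    stats = _marginal_stats(Z, y, variants, cfg.n_eqtl, gene_id)

    # gene body occupies the central fifth of the simulated region
    lo = int(variants["pos"].iloc[0]) - 1
    hi = int(variants["pos"].iloc[-1])
    width = hi - lo
    gene = {
        "gene_id": gene_id,
        "chrom": cfg.chrom,
        "start": lo + 2 * width // 5,
        "end": lo + 3 * width // 5,
        "strand": "+",
    }
    tracks = _make_tracks(cfg, variants, essential, rng)

    tss = gene["start"]
    anchor_a = (cfg.chrom, max(0, tss - 1000), tss + 1000)
    if causal.size:
        cpos = variants["pos"].iloc[causal].to_numpy() - 1
        anchor_b = (cfg.chrom, int(cpos.min()) - 500, int(cpos.max()) + 501)
    else:
        anchor_b = (cfg.chrom, lo, lo + 1000)
    loop = RegionSet(kind="loop", intervals=[anchor_a, anchor_b], anchors=[(anchor_a, anchor_b)])

    truth = {
        "gene_id": gene_id,
        "seed": cfg.seed,
        "h2_cis": cfg.h2_cis,
        "causal_idx": causal.tolist(),
        "causal_ids": variants["id"].iloc[causal].tolist(),
        "beta_true": beta.tolist(),
        "essential_idx": np.flatnonzero(essential).tolist(),
        "realized_h2": float(np.var(genetic)),
    }
    return SimulatedGene(
        cfg=cfg,
        variants=variants,
        ref_genotypes=X_ref,
        cohort_genotypes=X,
        essential=essential,
        beta_true=beta,
        expression=y,
        stats=stats,
        gene=gene,
        tracks=tracks,
        loop=loop,
        truth=truth,
    )


def simulate_gwas_sumstats(cfg: SimConfig, G: np.ndarray, beta_true: np.ndarray,
                           variants: pd.DataFrame, rng=None) -> GwasSumStats:
    """GWAS z-scores under the mediation model.

    ``z = sqrt(n_gwas) * alpha_med * G beta_true + MVN(0, G)``: the signal is
    the LD-projected joint effect of expression-mediated variants, the noise
    carries the LD correlation structure.
    """
    if not np.isfinite(cfg.alpha_med):
        raise ValueError("alpha_med must be finite")
    rng = np.random.default_rng(cfg.seed if rng is None else rng)
    G = np.asarray(G, dtype=float)
    vals, vecs = np.linalg.eigh((G + G.T) / 2.0)
    L = vecs * np.sqrt(np.clip(vals, 0.0, None))
    z = np.sqrt(cfg.n_gwas) * cfg.alpha_med * (G @ beta_true)
    z = z + L @ rng.standard_normal(G.shape[0])
    tab = variants[["chrom", "pos", "id", "ref", "alt"]].copy()
    tab["z"] = z
    tab["n"] = cfg.n_gwas
    return GwasSumStats(table=tab)


def simulate_multicelltype(cfg: SimConfig, rng=None, gene_id: str = "GENE1"):
    """Per-cell-type cohorts with tunable effect sharing.

    A base causal set is drawn once; each causal variant is shared across all
    K cell types with probability ``share_prob``, otherwise private to one
    random cell type.  Every cell type gets its own eQTL cohort and summary
    statistics; the truth records each cell type's joint effect vector.
    """
    if cfg.K < 2:
        raise ValueError("need K >= 2 cell types")
    rng = np.random.default_rng(cfg.seed if rng is None else rng)
    maf = rng.uniform(0.05, 0.5, size=cfg.p)
    variants = _variant_frame(cfg, maf)
    X_ref = _genotypes(rng, cfg, cfg.n_ref, maf)

    n_ess = int(round(cfg.essential_frac * cfg.p))
    essential = np.zeros(cfg.p, dtype=bool)
    essential[rng.choice(cfg.p, size=n_ess, replace=False)] = True
    causal = _draw_causal(rng, cfg, essential) if cfg.n_causal else np.array([], int)

    raw = rng.standard_normal(causal.size)
    shared = rng.random(causal.size) < cfg.share_prob
    owner = rng.integers(cfg.K, size=causal.size)  # used when private

    cohorts = {}
    betas = {}
    for k in range(cfg.K):
        ct = f"CT{k + 1}"
        active = shared | (owner == k)
        beta = np.zeros(cfg.p)
        Xk = _genotypes(rng, cfg, cfg.n_eqtl, maf)
        Zk = _standardize(Xk)
        if cfg.h2_cis > 0 and active.any():
            g = Zk[:, causal[active]] @ raw[active]
            v = np.var(g)
            if v > 0:
                beta[causal[active]] = raw[active] * np.sqrt(cfg.h2_cis / v)
        genetic = Zk @ beta
        y = genetic + rng.standard_normal(cfg.n_eqtl) * np.sqrt(max(1.0 - cfg.h2_cis, 1e-12))
        y = (y - y.mean()) / y.std(ddof=0)
        cohorts[ct] = _marginal_stats(Zk, y, variants, cfg.n_eqtl, gene_id)
        betas[ct] = beta

    truth = {
        "gene_id": gene_id,
        "seed": cfg.seed,
        "causal_idx": causal.tolist(),
        "shared_mask": shared.tolist(),
        "beta_true": {ct: b.tolist() for ct, b in betas.items()},
        "essential_idx": np.flatnonzero(essential).tolist(),
    }
    return {
        "variants": variants,
        "ref_genotypes": X_ref,
        "essential": essential,
        "stats": cohorts,
        "beta_true": betas,
        "truth": truth,
    }


# ---------------------------------------------------------------------------
# plain-text emission of every input format the readers consume

def write_dosage_matrix(path, genotypes: np.ndarray, variants: pd.DataFrame) -> None:
    """Reference panel as TSV: variant columns then one column per individual."""
    meta = variants[["chrom", "pos", "id", "ref", "alt"]].reset_index(drop=True)
    dose = pd.DataFrame(
        genotypes.T.astype(int),
        columns=[f"I{i + 1}" for i in range(genotypes.shape[0])],
    )
    pd.concat([meta, dose], axis=1).to_csv(path, sep="\t", index=False)


def read_dosage_matrix(path):
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta_cols = ["chrom", "pos", "id", "ref", "alt"]
    ind_cols = [c for c in df.columns if c not in meta_cols]
    genotypes = df[ind_cols].to_numpy(dtype=float).T
    return genotypes, df[meta_cols]


def write_bed(path, regions: RegionSet) -> None:
    with open(path, "w") as fh:
        for c, s, e in regions.intervals:
            fh.write(f"{c}\t{s}\t{e}\t.\n")


def write_bedpe(path, regions: RegionSet) -> None:
    with open(path, "w") as fh:
        for a, b in regions.anchors:
            fh.write(f"{a[0]}\t{a[1]}\t{a[2]}\t{b[0]}\t{b[1]}\t{b[2]}\n")


def emit_files(sim: SimulatedGene, outdir, gwas: GwasSumStats | None = None) -> dict:
    """Write every consumable input plus a ground-truth manifest; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    eqtl = outdir / "eqtl.tsv"
    tab = sim.stats.table.copy()
    tab.insert(0, "gene", sim.stats.gene_id)
    tab.to_csv(eqtl, sep="\t", index=False)
    paths["eqtl"] = eqtl

    ref = outdir / "reference.dosage.tsv"
    write_dosage_matrix(ref, sim.ref_genotypes, sim.variants)
    paths["reference"] = ref

    genes = outdir / "genes.tsv"
    pd.DataFrame([sim.gene]).to_csv(genes, sep="\t", index=False)
    paths["genes"] = genes

    trackdir = outdir / "tracks"
    trackdir.mkdir(exist_ok=True)
    for name, reg in sim.tracks.items():
        p = trackdir / f"{name}.bed"
        write_bed(p, reg)
        paths[f"track_{name}"] = p
    loops = outdir / "loops.bedpe"
    write_bedpe(loops, sim.loop)
    paths["loops"] = loops

    if gwas is not None:
        gpath = outdir / "gwas.tsv"
        gwas.table.to_csv(gpath, sep="\t", index=False)
        paths["gwas"] = gpath

    manifest = outdir / "truth.json"
    payload = dict(sim.truth)
    payload["config"] = asdict(sim.cfg)
    with open(manifest, "w") as fh:
        json.dump(payload, fh, indent=1)
    paths["truth"] = manifest
    return paths
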