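"""Readers/writers for eQTL and GWAS summary statistics and weight models.

Effect sizes are interpreted on the standardized scale (variance-1 genotypes
and expression).  Files are tab-delimited with a header; column naming is
configurable through a mapping dict (YAML-friendly) so that eQTLGen-style or
GWAS-style headers can both be consumed.

Also provides allele harmonization against a reference panel and exact
leave-cohort-out subtraction under inverse-variance fixed-effect
meta-analysis.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

WEIGHT_FORMAT_VERSION = "1"

#: default header names; override via ``colmap`` arguments
DEFAULT_COLMAP = {
    "chrom": "chrom",
    "pos": "pos",
    "id": "id",
    "ref": "ref",
    "alt": "alt",
    "beta": "beta",
    "se": "se",
    "z": "z",
    "n": "n",
    "gene": "gene",
}

_PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


@dataclass
class VariantRecord:
    chrom: str
    pos: int
    id: str
    ref_allele: str
    alt_allele: str
    maf: float = float("nan")

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError("pos must be >= 1 (1-based)")
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")
        if np.isfinite(self.maf) and not 0 <= self.maf <= 0.5:
            raise ValueError("maf must lie in [0, 0.5]")


@dataclass
class MarginalEqtlStats:
    """Per-variant marginal eQTL statistics for one gene.

    ``table`` columns: chrom, pos, id, ref, alt, beta, se, z, n.  The z column
    is always populated (derived from beta/se when absent) and is the source
    of the X'y proxy downstream.
    """

    gene_id: str
    table: pd.DataFrame

    def __post_init__(self):
        self.table = self.table.reset_index(drop=True)
        both = self.table["z"].notna() & self.table["se"].notna() & self.table["beta"].notna()
        if both.any():
            zchk = self.table.loc[both, "beta"] / self.table.loc[both, "se"]
            if not np.allclose(zchk, self.table.loc[both, "z"], atol=1e-6):
                raise ValueError("z inconsistent with beta/se")
        if (self.table["n"] < 2).any():
            raise ValueError("per-variant sample size must be >= 2")

    def __len__(self):
        return len(self.table)


@dataclass
class GwasSumStats:
    """Per-variant GWAS z-scores; ``table`` columns mirror MarginalEqtlStats."""

    table: pd.DataFrame

    def __post_init__(self):
        self.table = self.table.reset_index(drop=True)
        if not np.isfinite(self.table["z"]).all():
            raise ValueError("GWAS z-scores must be finite")

    def __len__(self):
        return len(self.table)


@dataclass
class WeightModel:
    """Fitted prediction weights for one (gene, cell type) pair."""

    gene_id: str
    cell_type: str
    variants: pd.DataFrame  # chrom, pos, ref, alt (and id if available)
    beta_hat: np.ndarray
    essential_flags: np.ndarray
    chosen_lambda: float
    chosen_phi: float
    chosen_window: str
    training_n: float

    def __post_init__(self):
        self.beta_hat = np.asarray(self.beta_hat, dtype=float)
        self.essential_flags = np.asarray(self.essential_flags, dtype=bool)
        if not (len(self.variants) == len(self.beta_hat) == len(self.essential_flags)):
            raise ValueError("variant list, weights and flags must have equal length")
        if self.chosen_phi <= 0:
            raise ValueError("chosen_phi must be > 0")
        if np.count_nonzero(self.beta_hat) == 0:
            raise ValueError("an emitted model must have >= 1 nonzero weight")


def _resolve_columns(header, colmap, required):
    cm = dict(DEFAULT_COLMAP)
    if colmap:
        cm.update(colmap)
    missing = [k for k in required if cm[k] not in header]
    if missing:
        raise ValueError(
            f"required column(s) {missing} not mappable; header = {list(header)}"
        )
    return cm


def read_eqtl_sumstats(path, gene_id: str | None = None, colmap: dict | None = None):
    """Read marginal eQTL summary statistics.

    Returns a single :class:`MarginalEqtlStats` when ``gene_id`` is given (or
    the file has no gene column), otherwise a dict keyed by gene.  Rows with
    neither effect nor z, or with se = 0, are dropped with a logged count;
    duplicated (variant, gene) rows are an error.
    """
    df = pd.read_csv(path, sep="\t")
    cm = _resolve_columns(df.columns, colmap, ["chrom", "pos", "ref", "alt", "n"])
    has_beta = cm["beta"] in df.columns
    has_z = cm["z"] in df.columns
    if not (has_beta or has_z):
        raise ValueError("need an effect (beta) or z column")

    out = pd.DataFrame(
        {
            "chrom": df[cm["chrom"]].astype(str),
            "pos": df[cm["pos"]].astype(int),
            "id": df[cm["id"]].astype(str)
            if cm["id"] in df.columns
            else df[cm["chrom"]].astype(str) + ":" + df[cm["pos"]].astype(str),
            "ref": df[cm["ref"]].astype(str),
            "alt": df[cm["alt"]].astype(str),
            "beta": df[cm["beta"]] if has_beta else np.nan,
            "se": df[cm["se"]] if cm["se"] in df.columns else np.nan,
            "z": df[cm["z"]] if has_z else np.nan,
            "n": df[cm["n"]],
        }
    )
    if cm["gene"] in df.columns:
        out["gene"] = df[cm["gene"]].astype(str)
    else:
        out["gene"] = gene_id if gene_id is not None else "NA"

    bad_se = out["se"].notna() & (out["se"] == 0) & out["z"].isna()
    if bad_se.any():
        logger.warning("dropped %d row(s) with se = 0 and no z", int(bad_se.sum()))
        out = out[~bad_se]
    fill = out["z"].isna() & out["beta"].notna() & out["se"].notna() & (out["se"] > 0)
    out.loc[fill, "z"] = out.loc[fill, "beta"] / out.loc[fill, "se"]
    missing = out["z"].isna() & out["beta"].isna()
    if missing.any():
        logger.warning("dropped %d row(s) with neither effect nor z", int(missing.sum()))
        out = out[~missing]

    dup = out.duplicated(subset=["gene", "chrom", "pos", "ref", "alt"], keep=False)
    if dup.any():
        first = out[dup].iloc[0]
        raise ValueError(
            f"duplicated (variant, gene) row: {first['chrom']}:{first['pos']} "
            f"gene {first['gene']}"
        )

    by_gene = {
        g: MarginalEqtlStats(gene_id=g, table=t.drop(columns="gene").sort_values("pos"))
        for g, t in out.groupby("gene", sort=True)
    }
    if gene_id is not None:
        if gene_id not in by_gene:
            raise ValueError(f"gene {gene_id} not present in {path}")
        return by_gene[gene_id]
    if len(by_gene) == 1:
        return next(iter(by_gene.values()))
    return by_gene


def read_gwas_sumstats(path, colmap: dict | None = None) -> GwasSumStats:
    df = pd.read_csv(path, sep="\t")
    cm = _resolve_columns(df.columns, colmap, ["chrom", "pos", "ref", "alt", "z", "n"])
    out = pd.DataFrame(
        {
            "chrom": df[cm["chrom"]].astype(str),
            "pos": df[cm["pos"]].astype(int),
            "id": df[cm["id"]].astype(str)
            if cm["id"] in df.columns
            else df[cm["chrom"]].astype(str) + ":" + df[cm["pos"]].astype(str),
            "ref": df[cm["ref"]].astype(str),
            "alt": df[cm["alt"]].astype(str),
            "z": df[cm["z"]].astype(float),
            "n": df[cm["n"]],
        }
    )
    return GwasSumStats(table=out.sort_values("pos"))


def harmonize_alleles(stats, reference_variants: pd.DataFrame, drop_ambiguous: bool = True):
    """Align effect alleles to a reference panel.

    ``reference_variants`` needs columns chrom, pos, ref, alt.  Variants whose
    alleles are swapped relative to the panel get their z (and beta) negated;
    strand-ambiguous (A/T, C/G) variants are dropped by default; unmatched or
    incompatible variants are dropped with logged counts.  Output rows are
    ordered as in the reference.  Idempotent.
    """
    tab = stats.table.copy()
    ref = reference_variants.reset_index(drop=True).copy()
    ref["_order"] = np.arange(len(ref))
    merged = tab.merge(
        ref[["chrom", "pos", "ref", "alt", "_order"]],
        on=["chrom", "pos"],
        how="inner",
        suffixes=("", "_panel"),
    )
    n_unmatched = len(tab) - len(merged)
    if n_unmatched:
        logger.info("harmonize: %d variant(s) not in reference panel, dropped", n_unmatched)

    if drop_ambiguous:
        amb = [
            (a.upper(), b.upper()) in _PALINDROMIC
            for a, b in zip(merged["ref"], merged["alt"])
        ]
        amb = np.array(amb, dtype=bool)
        if amb.any():
            logger.info("harmonize: dropped %d strand-ambiguous variant(s)", int(amb.sum()))
        merged = merged[~amb]

    same = (merged["ref"] == merged["ref_panel"]) & (merged["alt"] == merged["alt_panel"])
    swapped = (merged["ref"] == merged["alt_panel"]) & (merged["alt"] == merged["ref_panel"])
    incompatible = ~(same | swapped)
    if incompatible.any():
        logger.info(
            "harmonize: dropped %d variant(s) with incompatible alleles",
            int(incompatible.sum()),
        )
        merged = merged[~incompatible]
        same, swapped = same[~incompatible], swapped[~incompatible]

    flip = swapped.to_numpy()
    merged.loc[flip, "z"] = -merged.loc[flip, "z"]
    if "beta" in merged.columns:
        merged.loc[flip, "beta"] = -merged.loc[flip, "beta"]
    merged.loc[flip, ["ref", "alt"]] = merged.loc[flip, ["alt", "ref"]].to_numpy()

    merged = merged.sort_values("_order").drop(columns=["ref_panel", "alt_panel", "_order"])
    if isinstance(stats, MarginalEqtlStats):
        return MarginalEqtlStats(gene_id=stats.gene_id, table=merged)
    return GwasSumStats(table=merged)


def meta_subtract(meta: MarginalEqtlStats, cohort: MarginalEqtlStats) -> MarginalEqtlStats:
    """Exact leave-cohort-out statistics under fixed-effect IVW meta-analysis.

    With weights w = se^-2: beta_out = (w_m b_m - w_c b_c) / (w_m - w_c) and
    se_out = (w_m - w_c)^{-1/2}.  Inverse of re-meta-analyzing the cohort back
    in, to floating-point precision.
    """
    key = ["chrom", "pos", "ref", "alt"]
    m = meta.table.set_index(key)
    c = cohort.table.set_index(key)
    common = m.index.intersection(c.index)
    if len(common) == 0:
        raise ValueError("no shared variants between meta and cohort")
    m, c = m.loc[common], c.loc[common]
    for tab, name in ((m, "meta"), (c, "cohort")):
        if tab["beta"].isna().any() or tab["se"].isna().any():
            raise ValueError(f"{name} statistics must provide beta and se per variant")
    w_m = 1.0 / m["se"] ** 2
    w_c = 1.0 / c["se"] ** 2
    if (w_m <= w_c).any():
        bad = m.index[(w_m <= w_c).to_numpy()][0]
        raise ValueError(
            f"cohort precision >= meta precision at {bad}; cohort is not a subset"
        )
    w_out = w_m - w_c
    beta_out = (w_m * m["beta"] - w_c * c["beta"]) / w_out
    se_out = w_out ** -0.5
    out = m.reset_index()
    out["beta"] = beta_out.to_numpy()
    out["se"] = se_out.to_numpy()
    out["z"] = out["beta"] / out["se"]
    out["n"] = (m["n"] - c["n"]).to_numpy()
    return MarginalEqtlStats(gene_id=meta.gene_id, table=out)


# ---------------------------------------------------------------------------
# weight-model persistence: one weights TSV + one JSON metadata sidecar

def write_weight_models(models, prefix: str) -> None:
    rows = []
    meta = {"version": WEIGHT_FORMAT_VERSION, "models": {}}
    for mod in models:
        key = f"{mod.gene_id}::{mod.cell_type}"
        meta["models"][key] = {
            "chosen_lambda": mod.chosen_lambda,
            "chosen_phi": mod.chosen_phi,
            "chosen_window": mod.chosen_window,
            "training_n": mod.training_n,
        }
        for i in range(len(mod.beta_hat)):
            v = mod.variants.iloc[i]
            rows.append(
                {
                    "gene": mod.gene_id,
                    "cell_type": mod.cell_type,
                    "chrom": v["chrom"],
                    "pos": int(v["pos"]),
                    "ref": v["ref"],
                    "alt": v["alt"],
                    "weight": repr(float(mod.beta_hat[i])),
                    "essential": int(mod.essential_flags[i]),
                }
            )
    pd.DataFrame(rows).to_csv(prefix + ".weights.tsv", sep="\t", index=False)
    with open(prefix + ".meta.json", "w") as fh:
        json.dump(meta, fh, indent=1)


def read_weight_models(prefix: str) -> dict:
    """Load all models, keyed by (gene_id, cell_type)."""
    with open(prefix + ".meta.json") as fh:
        meta = json.load(fh)
    if meta.get("version") != WEIGHT_FORMAT_VERSION:
        raise ValueError(
            f"weight model format version {meta.get('version')!r} != {WEIGHT_FORMAT_VERSION!r}"
        )
    # keep_default_na: literal "NA" is a legitimate cell-type label
    df = pd.read_csv(
        prefix + ".weights.tsv",
        sep="\t",
        dtype={"chrom": str, "gene": str, "cell_type": str},
        keep_default_na=False,
        na_values=[],
    )
    out = {}
    for (gene, ct), tab in df.groupby(["gene", "cell_type"], sort=True):
        info = meta["models"][f"{gene}::{ct}"]
        tab = tab.sort_values("pos").reset_index(drop=True)
        out[(gene, ct)] = WeightModel(
            gene_id=gene,
            cell_type=ct,
            variants=tab[["chrom", "pos", "ref", "alt"]],
            beta_hat=tab["weight"].astype(float).to_numpy(),
            essential_flags=tab["essential"].astype(bool).to_numpy(),
            chosen_lambda=info["chosen_lambda"],
            chosen_phi=info["chosen_phi"],
            chosen_window=info["chosen_window"],
            training_n=info["training_n"],
        )
    return out
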