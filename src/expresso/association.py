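"""Summary-based TWAS: gene-trait z-statistics, loci, and known/novel status.

The gene-level statistic is the standard weighted-burden form

    Z = w' z / sqrt(w' G w)

with prediction weights ``w``, GWAS z-scores ``z`` and reference LD ``G``
over the intersected variant set.  Significant genes are grouped into loci by
an iterative procedure: the smallest-p unassigned gene becomes the sentinel
of a 1 Mb window (gene midpoint +- window/2), absorbing every unassigned
significant gene inside, until the list is exhausted.  A locus is "known"
when a same-trait catalog hit lies within the distance threshold of the
sentinel, else "novel".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .fit import GramMatrix
from .sumstats import GwasSumStats, WeightModel, harmonize_alleles

logger = logging.getLogger(__name__)

DEFAULT_LOCUS_WINDOW_BP = 1_000_000


@dataclass
class TwasResult:
    gene_id: str
    cell_type: str
    z: float
    p: float
    n_weights_used: int
    chrom: str
    midpoint: int
    low_coverage: bool = False

    def __post_init__(self):
        expect = 2.0 * sps.norm.sf(abs(self.z))
        if not np.isclose(self.p, expect, atol=1e-12):
            raise ValueError("p must equal the two-sided normal tail of z")

    @property
    def chisq(self) -> float:
        return self.z ** 2


@dataclass
class Locus:
    sentinel_gene: str
    chrom: str
    start: int
    end: int
    member_genes: list
    sentinel_pos: int
    is_known: bool | None = None


@dataclass
class LocusTable:
    loci: list = field(default_factory=list)

    def __len__(self):
        return len(self.loci)


def twas_zscore(
    model: WeightModel,
    gwas: GwasSumStats,
    gram: GramMatrix,
    gene_chrom: str | None = None,
    gene_midpoint: int | None = None,
) -> TwasResult:
    """Weighted-burden TWAS z-score for one gene in one cell type.

    ``gram`` must be aligned to the model's variant list.  GWAS z-scores are
    harmonized to the model's alleles; if the retained fraction of absolute
    weight mass drops below 50% the result is flagged low-coverage.
    """
    if len(model.variants) != gram.p:
        raise ValueError("Gram matrix must be aligned to the model variants")
    harmonized = harmonize_alleles(gwas, model.variants, drop_ambiguous=False)
    key = ["chrom", "pos"]
    idx = (
        model.variants.reset_index(drop=True)
        .reset_index()
        .merge(harmonized.table[key + ["z"]], on=key, how="inner")
    )
    if len(idx) == 0:
        raise ValueError("no model variant present in the GWAS after harmonization")
    used = idx["index"].to_numpy()
    w = model.beta_hat[used]
    z = idx["z"].to_numpy()
    Gsub = gram.matrix[np.ix_(used, used)]
    denom = float(w @ Gsub @ w)
    if denom <= 0:
        raise ValueError("w' G w must be positive")
    Z = float(w @ z / np.sqrt(denom))
    total_mass = float(np.abs(model.beta_hat).sum())
    coverage = float(np.abs(w).sum()) / total_mass if total_mass > 0 else 0.0
    low = coverage < 0.5
    if low:
        logger.warning(
            "gene %s: only %.1f%% of weight mass covered by GWAS", model.gene_id, 100 * coverage
        )
    mid = int(gene_midpoint) if gene_midpoint is not None else int(model.variants["pos"].median())
    chrom = gene_chrom if gene_chrom is not None else str(model.variants["chrom"].iloc[0])
    return TwasResult(
        gene_id=model.gene_id,
        cell_type=model.cell_type,
        z=Z,
        p=2.0 * sps.norm.sf(abs(Z)),
        n_weights_used=len(used),
        chrom=chrom,
        midpoint=mid,
        low_coverage=low,
    )


def define_loci(results: list, window_bp: int = DEFAULT_LOCUS_WINDOW_BP) -> LocusTable:
    """Iterative locus definition over pre-filtered significant genes.

    The total window width is ``window_bp`` (sentinel midpoint +- half).
    Ties in p go to the lower genomic position.  Input order is irrelevant.
    """
    pending = sorted(results, key=lambda t: (t.p, t.chrom, t.midpoint, t.gene_id))
    assigned: set = set()
    half = window_bp / 2.0
    loci = []
    for sentinel in pending:
        if sentinel.gene_id in assigned:
            continue
        lo, hi = sentinel.midpoint - half, sentinel.midpoint + half
        members = [
            t.gene_id
            for t in pending
            if t.gene_id not in assigned and t.chrom == sentinel.chrom and lo <= t.midpoint <= hi
        ]
        assigned.update(members)
        loci.append(
            Locus(
                sentinel_gene=sentinel.gene_id,
                chrom=sentinel.chrom,
                start=int(lo),
                end=int(hi),
                member_genes=members,
                sentinel_pos=sentinel.midpoint,
            )
        )
    return LocusTable(loci=loci)


def classify_known(
    loci: LocusTable,
    catalog: pd.DataFrame,
    trait: str | None = None,
    distance_bp: int = DEFAULT_LOCUS_WINDOW_BP,
) -> LocusTable:
    """Known iff a same-trait catalog hit lies within distance_bp (inclusive)
    of the sentinel position."""
    cat = catalog
    if trait is not None and "trait" in cat.columns:
        cat = cat[cat["trait"] == trait]
    for locus in loci.loci:
        hits = cat[cat["chrom"].astype(str) == str(locus.chrom)]
        locus.is_known = bool(
            (np.abs(hits["pos"].to_numpy() - locus.sentinel_pos) <= distance_bp).any()
        )
    return loci


def mean_chisq_at_known(results: list, loci: LocusTable) -> float:
    """Mean sentinel Z^2 over known loci (estimates the noncentrality)."""
    by_gene = {t.gene_id: t for t in results}
    vals = [
        by_gene[locus.sentinel_gene].chisq
        for locus in loci.loci
        if locus.is_known
    ]
    if not vals:
        raise ValueError("no known loci")
    return float(np.mean(vals))


def genomic_control_lambda(pvalues) -> float:
    """Median chi-square of the p-values over the null median (0.4549)."""
    chi = sps.chi2.isf(np.asarray(pvalues, dtype=float), df=1)
    return float(np.median(chi) / sps.chi2.isf(0.5, df=1))
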