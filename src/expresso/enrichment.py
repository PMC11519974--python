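"""Cell-type specificity scoring, TWAS-hit enrichment, and drug signatures.

Expression processing follows the standard specificity recipe: drop genes
with zero expression in every cell type, rescale each cell-type column to one
million TPM (library-size control), then divide each gene's rescaled
expression in a cell type by its total across cell types so that specificity
rows sum to one.  Cell-type-specific gene sets come from either the
top-decile specificity rule or the 1-standard-deviation-above-the-mean TPM
rule.  Enrichment of significant TWAS hits in a gene set is assessed by
regressing gene-level TWAS chi-square statistics on set membership with
heteroskedasticity-robust standard errors (one-sided test for positive
enrichment), with an optional permutation p-value.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

logger = logging.getLogger(__name__)

TOTAL_TPM = 1_000_000.0
MIN_SIGNATURE_GENES = 10


@dataclass
class CellTypeExpression:
    rescaled: pd.DataFrame  # gene x cell type, columns sum to 1e6
    specificity: pd.DataFrame  # rows sum to 1


@dataclass
class DrugSignature:
    trait: str
    up_genes: list  # positively associated, ranked by |z| descending
    down_genes: list

    @property
    def eligible(self) -> bool:
        return (
            len(self.up_genes) >= MIN_SIGNATURE_GENES
            and len(self.down_genes) >= MIN_SIGNATURE_GENES
        )


def process_expression(tpm: pd.DataFrame) -> CellTypeExpression:
    """Rescale to 1M TPM per cell type and compute specificity scores."""
    if (tpm < 0).any().any():
        raise ValueError("TPM must be >= 0")
    zero_cols = tpm.columns[(tpm.sum(axis=0) == 0)]
    if len(zero_cols):
        raise ValueError(f"cell type(s) with zero total expression: {list(zero_cols)}")
    expressed = tpm.sum(axis=1) > 0
    if (~expressed).any():
        logger.info("removed %d gene(s) not expressed in any cell type", int((~expressed).sum()))
    tpm = tpm.loc[expressed]
    rescaled = tpm / tpm.sum(axis=0) * TOTAL_TPM
    specificity = rescaled.div(rescaled.sum(axis=1), axis=0)
    return CellTypeExpression(rescaled=rescaled, specificity=specificity)


def specific_genes_decile(expr: CellTypeExpression, cell_type: str) -> set:
    """Genes in the top 10th percentile of specificity for one cell type.

    The threshold is the nearest-rank 90th percentile; ties at the threshold
    are all included (with a warning in the fully degenerate case).
    """
    s = expr.specificity[cell_type]
    ranked = np.sort(s.to_numpy())
    k = int(np.ceil(0.1 * len(ranked)))  # nearest-rank: top 10% of genes
    threshold = ranked[len(ranked) - k]
    hits = set(s.index[s >= threshold])
    if len(hits) == len(s):
        warnings.warn("uniform specificity: every gene is tied at the threshold")
    return hits


def specific_genes_sd(tpm: pd.DataFrame, cell_type: str) -> set:
    """Genes whose TPM in ``cell_type`` exceeds mean + 1 sample SD across cell types."""
    if tpm.shape[1] < 2:
        raise ValueError("need >= 2 cell types")
    mean = tpm.mean(axis=1)
    sd = tpm.std(axis=1, ddof=1)
    qualifies = tpm[cell_type] > mean + sd  # strict: constant genes never qualify
    return set(tpm.index[qualifies])


def enrichment_test(twas: pd.DataFrame, gene_set: set, perm: int = 0, seed=None):
    """Are cell-type-specific genes enriched with strong TWAS signals?

    ``twas`` needs columns ``gene`` and either ``chisq`` or ``z``.  Gene-level
    chi-squares are regressed on the membership indicator with HC1-robust
    standard errors; the p-value is one-sided for a positive coefficient.
    With ``perm > 0`` a label-permutation p-value is returned instead of the
    analytic one (same estimate).
    """
    df = twas.copy()
    if "chisq" not in df.columns:
        df["chisq"] = df["z"].astype(float) ** 2
    member = df["gene"].isin(gene_set).to_numpy().astype(float)
    n_in = int(member.sum())
    n_out = len(df) - n_in
    if n_in < 10 or n_out < 10:
        raise ValueError("need >= 10 genes inside and outside the set")
    y = df["chisq"].to_numpy(dtype=float)
    X = sm.add_constant(member)
    fit = sm.OLS(y, X).fit(cov_type="HC1")
    est = float(fit.params[1])
    if np.allclose(y, y[0]):
        return est, 0.5  # no variation in the outcome: uninformative
    t = float(fit.tvalues[1])
    p_one = float(sps.norm.sf(t))
    if perm > 0:
        rng = np.random.default_rng(seed)
        obs = est
        count = 0
        for _ in range(perm):
            shuf = rng.permutation(member)
            diff = y[shuf == 1].mean() - y[shuf == 0].mean()
            if diff >= obs:
                count += 1
        p_one = (count + 1) / (perm + 1)
    return est, p_one


def build_drug_signature(twas: pd.DataFrame, alpha: float = 0.05, trait: str = "NA") -> DrugSignature:
    """Signed, Bonferroni-significant gene lists for perturbation-database queries.

    ``twas`` needs columns gene, z, p.  Genes with z exactly 0 are excluded
    from both lists; lists are ranked by |z| descending; a signature is
    eligible only with >= 10 genes on each side.
    """
    threshold = alpha / len(twas)
    sig = twas[(twas["p"] <= threshold) & (twas["z"] != 0)].copy()
    sig["absz"] = sig["z"].abs()
    sig = sig.sort_values("absz", ascending=False)
    up = sig.loc[sig["z"] > 0, "gene"].tolist()
    down = sig.loc[sig["z"] < 0, "gene"].tolist()
    return DrugSignature(trait=trait, up_genes=up, down_genes=down)
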