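"""Cis-window construction and epigenomic annotation of variants.

Candidate windows come in two families: linear flanks around the gene body
and 3D-genome-informed regions (chromatin loops, TADs, contact domains,
promoter-capture Hi-C), each of which defines one value of the window tuning
parameter.  Variants overlapping at least one of four epigenomic tracks
(H3K27ac, H3K4me3, DNase hypersensitivity, CTCF) are classified "essential"
and receive mitigated penalties during fitting.

Coordinate conventions: BED/BEDPE inputs are 0-based half-open; variant
positions are 1-based (VCF convention).  Conversion happens at the overlap
boundary only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy.stats import spearmanr

logger = logging.getLogger(__name__)

PAIRED_KINDS = {"loop", "pchic"}
VALID_KINDS = {"linear", "loop", "tad", "domain", "pchic"}

#: promoter half-width used to anchor loops/pcHi-C at the TSS (bp)
DEFAULT_PROMOTER_BP = 2_000


@dataclass
class RegionSet:
    """A set of genomic intervals (half-open, 0-based), optionally paired.

    For ``loop``/``pchic`` kinds, ``anchors`` holds (interval_a, interval_b)
    pairs with both anchors on the same chromosome; ``intervals`` then holds
    the flattened union.
    """

    kind: str
    intervals: list = field(default_factory=list)  # (chrom, start, end)
    anchors: list = field(default_factory=list)  # ((c,s,e), (c,s,e))

    def __post_init__(self):
        if self.kind not in VALID_KINDS:
            raise ValueError(f"unknown region kind {self.kind!r}")
        for c, s, e in self.intervals:
            if not s < e:
                raise ValueError(f"degenerate interval {c}:{s}-{e}")
        for a, b in self.anchors:
            if a[0] != b[0]:
                raise ValueError("anchor pairs must share a chromosome")
        self.intervals = sorted(self.intervals)

    def __len__(self):
        return len(self.intervals)

    def is_empty(self):
        return len(self.intervals) == 0

    def span_bp(self) -> int:
        return int(sum(e - s for _, s, e in self.intervals))


@dataclass
class CellTypeProfile:
    """Mean expression per gene (TPM) and annotation availability for one cell type."""

    cell_type: str
    tpm: pd.Series  # indexed by gene id
    has_epigenome: bool = False
    has_3d: bool = False

    def __post_init__(self):
        if (self.tpm < 0).any():
            raise ValueError("TPM must be >= 0")


def read_bed(path, kind: str = "linear") -> RegionSet:
    """BED4+ reader (first three columns used)."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    ivs = [(str(c), int(s), int(e)) for c, s, e in zip(df[0], df[1], df[2])]
    return RegionSet(kind=kind, intervals=ivs)


def read_bedpe(path, kind: str = "loop") -> RegionSet:
    """BEDPE reader (6 required columns) for loops / pcHi-C anchor pairs."""
    if kind not in PAIRED_KINDS:
        raise ValueError("BEDPE input requires a paired kind (loop or pchic)")
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    anchors, flat = [], []
    for row in df.itertuples(index=False):
        a = (str(row[0]), int(row[1]), int(row[2]))
        b = (str(row[3]), int(row[4]), int(row[5]))
        anchors.append((a, b))
        flat.extend([a, b])
    return RegionSet(kind=kind, intervals=flat, anchors=anchors)


def read_gene_table(path) -> pd.DataFrame:
    """Minimal gene annotation: gene_id, chrom, start, end, strand (TSV)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    need = {"gene_id", "chrom", "start", "end", "strand"}
    if not need.issubset(df.columns):
        raise ValueError(f"gene table must have columns {sorted(need)}")
    return df


def gene_tss(gene) -> int:
    """0-based TSS coordinate: start on +, end-1 on - strand."""
    return int(gene["start"]) if gene["strand"] == "+" else int(gene["end"]) - 1


def build_linear_window(gene_start: int, gene_end: int, flank_bp: int, chrom: str = "1") -> RegionSet:
    """Single interval [gene_start - flank, gene_end + flank), clipped at 0."""
    if gene_start > gene_end:
        raise ValueError("gene_start must be <= gene_end")
    if flank_bp <= 0:
        raise ValueError("flank_bp must be > 0")
    return RegionSet(
        kind="linear",
        intervals=[(str(chrom), max(0, int(gene_start) - int(flank_bp)), int(gene_end) + int(flank_bp))],
    )


def build_3d_window(gene, regions: RegionSet, promoter_bp: int = DEFAULT_PROMOTER_BP) -> RegionSet:
    """3D-genome-informed candidate window for one gene.

    TAD/domain: the union of intervals containing the TSS.  Loop/pcHi-C: both
    anchors of every pair with one anchor overlapping the promoter
    (TSS +- promoter_bp).  An empty result means this window value is skipped
    for the gene (logged by the tuning layer).
    """
    chrom = str(gene["chrom"])
    tss = gene_tss(gene)
    if regions.kind in ("tad", "domain"):
        hits = [iv for iv in regions.intervals if iv[0] == chrom and iv[1] <= tss < iv[2]]
        return RegionSet(kind=regions.kind, intervals=hits)
    if regions.kind in PAIRED_KINDS:
        lo, hi = tss - promoter_bp, tss + promoter_bp + 1
        out = []
        for a, b in regions.anchors:
            if a[0] != chrom:
                continue
            if (a[1] < hi and a[2] > lo) or (b[1] < hi and b[2] > lo):
                out.extend([a, b])
        return RegionSet(kind=regions.kind, intervals=sorted(set(out)))
    raise ValueError("build_3d_window requires a 3D region kind")


@dataclass
class AnnotationMask:
    """Per-variant essential flags plus per-track provenance."""

    essential: np.ndarray
    provenance: pd.DataFrame  # boolean, one column per track

    def __post_init__(self):
        self.essential = np.asarray(self.essential, dtype=bool)
        if not np.array_equal(self.essential, self.provenance.to_numpy().any(axis=1)):
            raise ValueError("essential flags must be the OR over tracks")


def _tree_by_chrom(regions: RegionSet) -> dict:
    trees: dict[str, IntervalTree] = {}
    for c, s, e in regions.intervals:
        trees.setdefault(c, IntervalTree()).addi(s, e)
    return trees


def variants_in_regions(variants: pd.DataFrame, regions: RegionSet) -> np.ndarray:
    """Boolean mask: 1-based variant position falls in a half-open interval."""
    trees = _tree_by_chrom(regions)
    out = np.zeros(len(variants), dtype=bool)
    for i, (c, pos) in enumerate(zip(variants["chrom"].astype(str), variants["pos"])):
        tree = trees.get(c)
        if tree is not None and tree.overlaps_point(int(pos) - 1):
            out[i] = True
    return out


def classify_essential(variants: pd.DataFrame, tracks: dict) -> AnnotationMask:
    """Essential iff a variant overlaps >= 1 interval of >= 1 epigenomic track.

    ``tracks`` maps track name (e.g. H3K27ac) to a single-interval RegionSet.
    """
    prov = {}
    for name, reg in tracks.items():
        if reg.kind in PAIRED_KINDS:
            raise ValueError("epigenomic tracks must be single-interval region sets")
        prov[name] = variants_in_regions(variants, reg)
    prov_df = pd.DataFrame(prov, index=variants.index)
    essential = prov_df.to_numpy().any(axis=1) if prov else np.zeros(len(variants), bool)
    return AnnotationMask(essential=essential, provenance=prov_df)


def select_proxy_celltype(target: CellTypeProfile, candidates: list) -> str:
    """Nearest annotated neighbor by Spearman correlation of log1p(TPM).

    Cell types lacking their own 3D/epigenomic data borrow annotation from
    the most transcriptionally similar annotated cell type; ties break
    lexicographically.
    """
    if target.has_epigenome and target.has_3d:
        return target.cell_type
    annotated = [c for c in candidates if c.has_epigenome and c.has_3d and c.cell_type != target.cell_type]
    if not annotated:
        raise ValueError("no annotated candidate cell type available")
    best_name, best_rho = None, -np.inf
    for cand in sorted(annotated, key=lambda c: c.cell_type):
        shared = target.tpm.index.intersection(cand.tpm.index)
        if len(shared) < 3:
            continue
        rho = spearmanr(np.log1p(target.tpm[shared]), np.log1p(cand.tpm[shared])).statistic
        if rho > best_rho:
            best_name, best_rho = cand.cell_type, rho
    if best_name is None:
        raise ValueError("no candidate shares enough genes with the target")
    logger.info("proxy for %s: %s (rho = %.3f)", target.cell_type, best_name, best_rho)
    return best_name
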