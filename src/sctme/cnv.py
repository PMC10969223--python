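"""Expression-based copy-number estimation.

Per-cell, per-window log2 copy-number-ratio (CNR) profiles are estimated by
the standard expression-smoothing approach: depth-normalize and log-
transform counts, center each gene on its mean over normal reference cells
(all major cell types other than epithelial), clip residuals, smooth with a
running mean over genomically consecutive genes within each chromosome, and
remove each cell's median window value.  A scalar per-cell CNV score — the
mean squared window value — summarizes genome-wide aberration magnitude and
is zero exactly for a flat profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import Dataset, NON_CNV_CHROM_RANK, chromosome_rank

logger = logging.getLogger(__name__)

__all__ = ["CNVMatrix", "select_reference", "estimate_cnv", "cnv_score"]

_LN2 = np.log(2.0)
_TARGET_SUM = 1e4


@dataclass
class CNVMatrix:
    """Cell × window log2(CNR) estimates.

    ``window_map`` has one row per window: chromosome plus the half-open
    gene-index range [gene_start, gene_end) into the genomically sorted
    gene order.  Windows never span chromosomes and follow genomic order.
    """

    values: np.ndarray  # cells × windows, float
    window_map: pd.DataFrame  # columns: chromosome, gene_start, gene_end
    cell_ids: pd.Index

    @property
    def n_windows(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"{r.chromosome}:{r.gene_start}-{r.gene_end}"
                for r in self.window_map.itertuples()]
        return pd.DataFrame(self.values, index=self.cell_ids, columns=cols)


def select_reference(cells: pd.DataFrame) -> np.ndarray:
    """Mask of normal-reference cells: every major type except epithelial."""
    mask = (cells["major_type"] != "Epithelial").to_numpy()
    if not mask.any():
        raise ValueError(
            "no reference cells: CNV estimation requires non-epithelial "
            "major types (fibroblast, endothelial, immune)"
        )
    return mask


def estimate_cnv(
    ds: Dataset,
    reference_mask: np.ndarray,
    window_genes: int = 100,
    stride: int | None = None,
    clip: float = 1.5,
) -> CNVMatrix:
    """Estimate per-window log2(CNR) for every cell.

    Genes must already be in genomic order (see
    :func:`sctme.io.sort_genes_genomically`).  Mitochondrial / unplaced
    contigs are excluded from windows (logged).  A chromosome with fewer
    genes than ``window_genes`` becomes a single window (logged).
    """
    if reference_mask.dtype != bool or len(reference_mask) != ds.n_cells:
        raise ValueError("reference_mask must be a boolean per-cell mask")
    if not reference_mask.any():
        raise ValueError("reference mask selects no cells")
    stride = stride or max(1, window_genes // 2)

    totals = np.asarray(ds.counts.sum(axis=1)).ravel()
    totals[totals == 0] = 1.0
    scale = _TARGET_SUM / totals  # per-cell depth factor

    chroms = ds.genes["chromosome"].to_numpy()
    ranks = np.array([chromosome_rank(c) for c in chroms])
    order_ok = np.all(np.diff(ranks) >= 0)
    if not order_ok:
        raise ValueError("genes are not in genomic order; sort first")

    window_rows = []
    window_cols: list[np.ndarray] = []
    n_cells = ds.n_cells
    ref_idx = np.flatnonzero(reference_mask)

    for chrom in pd.unique(chroms):
        if chromosome_rank(chrom) >= NON_CNV_CHROM_RANK:
            logger.info("excluding contig %s from CNV windows", chrom)
            continue
        gidx = np.flatnonzero(chroms == chrom)
        n = len(gidx)
        # dense block for this chromosome only (keeps memory bounded)
        block = np.asarray(ds.counts[:, gidx].todense(), dtype=np.float64)
        block *= scale[:, None]
        np.log1p(block, out=block)
        ref_mean = block[ref_idx].mean(axis=0)
        block -= ref_mean[None, :]
        block /= _LN2  # natural-log residuals → log2 scale
        np.clip(block, -clip, clip, out=block)

        if n < window_genes:
            logger.info("chromosome %s has %d < %d genes: single window",
                        chrom, n, window_genes)
            starts = [0]
            w = n
        else:
            starts = list(range(0, n - window_genes + 1, stride))
            w = window_genes
        for s in starts:
            e = s + w
            window_cols.append(block[:, s:e].mean(axis=1))
            window_rows.append((chrom, int(gidx[s]), int(gidx[e - 1]) + 1))

    if not window_cols:
        raise ValueError("no CNV windows could be formed")
    values = np.column_stack(window_cols)
    values -= np.median(values, axis=1, keepdims=True)
    window_map = pd.DataFrame(window_rows,
                              columns=["chromosome", "gene_start", "gene_end"])
    return CNVMatrix(values=values, window_map=window_map,
                     cell_ids=ds.cells.index)


def cnv_score(cnv: CNVMatrix) -> pd.Series:
    """Per-cell mean squared window value; 0 iff the profile is flat zero."""
    return pd.Series(np.mean(cnv.values ** 2, axis=1), index=cnv.cell_ids,
                     name="cnv_score")
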