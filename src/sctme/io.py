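"""Data model and file I/O.

The universal input object is a :class:`Dataset`: a sparse non-negative
integer cell×gene count matrix plus two metadata tables — one per cell
(sample, condition, major/minor cell type) and one per gene (genomic
coordinates, 1-based inclusive, GTF convention).

On disk a dataset is a Matrix Market (MTX) coordinate file with cells as
rows, and two TSVs (``cells.tsv``, ``genes.tsv``) whose headers match the
metadata fields.  ``read_dataset(write_dataset(d)) == d`` for any valid
dataset.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

logger = logging.getLogger(__name__)

#: Valid experimental conditions (breast-cancer subtypes plus normal tissue).
CONDITIONS = ("HRpos", "HER2pos", "TNBC", "Normal")

#: Major cell-type vocabulary.  Epithelial cells are the tumor candidates;
#: every other major type serves as the normal reference for CNV estimation.
MAJOR_TYPES = ("Epithelial", "Fibroblast", "Endothelial", "T", "B", "Myeloid")

#: Major types counted as immune when summing immune fractions.
IMMUNE_TYPES = ("T", "B", "Myeloid")

CELL_COLUMNS = ["cell_id", "sample_id", "condition", "major_type", "minor_type"]
GENE_COLUMNS = ["gene_id", "chromosome", "start", "end"]


class ValidationError(ValueError):
    """A dataset or config violates one of its structural invariants."""


@dataclass
class Dataset:
    """Sparse cell×gene counts with aligned per-cell and per-gene metadata.

    Attributes
    ----------
    counts
        CSR matrix, cells × genes, non-negative integers.
    cells
        DataFrame indexed by ``cell_id`` with columns ``sample_id``,
        ``condition``, ``major_type``, ``minor_type``.
    genes
        DataFrame indexed by ``gene_id`` with columns ``chromosome``,
        ``start``, ``end`` (1-based inclusive).
    """

    counts: sp.csr_matrix
    cells: pd.DataFrame
    genes: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        validate_dataset(self)

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Dataset):
            return NotImplemented
        return (
            self.counts.shape == other.counts.shape
            and (self.counts != other.counts).nnz == 0
            and self.cells.equals(other.cells)
            and self.genes.equals(other.genes)
        )

    def to_anndata(self):
        """Convenience converter to an AnnData object (lazy import)."""
        import anndata

        return anndata.AnnData(
            X=self.counts.copy(), obs=self.cells.copy(), var=self.genes.copy()
        )


def validate_dataset(ds: Dataset) -> None:
    n_cells, n_genes = ds.counts.shape
    if len(ds.cells) != n_cells:
        raise ValidationError(
            f"cell metadata has {len(ds.cells)} rows but matrix has {n_cells} rows"
        )
    if len(ds.genes) != n_genes:
        raise ValidationError(
            f"gene metadata has {len(ds.genes)} rows but matrix has {n_genes} columns"
        )
    if ds.counts.nnz:
        data = ds.counts.data
        if data.min() < 0:
            raise ValidationError("count matrix contains negative entries")
        if not np.issubdtype(data.dtype, np.integer) and np.any(data != np.round(data)):
            raise ValidationError("count matrix contains non-integer entries")
    if ds.cells.index.has_duplicates:
        raise ValidationError("duplicate cell_ids")
    if ds.genes.index.has_duplicates:
        raise ValidationError("duplicate gene_ids")
    bad = set(ds.cells["condition"]) - set(CONDITIONS)
    if bad:
        raise ValidationError(f"unknown conditions: {sorted(bad)}")


def read_dataset(matrix_path, cells_path, genes_path) -> Dataset:
    """Read a dataset from an MTX count matrix plus cell/gene TSVs.

    Raises
    ------
    ValidationError
        On dimension mismatch (the error names the offending file) or on
        negative / non-integer matrix entries.
    """
    counts = sp.csr_matrix(scipy.io.mmread(matrix_path))
    cells = pd.read_csv(cells_path, sep="\t", dtype=str).set_index("cell_id")
    genes = pd.read_csv(genes_path, sep="\t").set_index("gene_id")
    genes.index = genes.index.astype(str)
    genes["start"] = genes["start"].astype(np.int64)
    genes["end"] = genes["end"].astype(np.int64)
    if counts.shape[0] != len(cells):
        raise ValidationError(
            f"{matrix_path} declares {counts.shape[0]} cells but "
            f"{cells_path} has {len(cells)} rows"
        )
    if counts.shape[1] != len(genes):
        raise ValidationError(
            f"{matrix_path} declares {counts.shape[1]} genes but "
            f"{genes_path} has {len(genes)} rows"
        )
    if counts.nnz and np.any(counts.data != np.round(counts.data)):
        raise ValidationError(f"{matrix_path} contains non-integer entries")
    counts = counts.astype(np.int64)
    return Dataset(counts=counts, cells=cells, genes=genes)


def write_dataset(ds: Dataset, out_dir) -> dict[str, Path]:
    """Write a dataset as matrix.mtx + cells.tsv + genes.tsv under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "matrix": out / "matrix.mtx",
        "cells": out / "cells.tsv",
        "genes": out / "genes.tsv",
    }
    scipy.io.mmwrite(str(paths["matrix"]), sp.coo_matrix(ds.counts), field="integer")
    ds.cells.reset_index().to_csv(paths["cells"], sep="\t", index=False)
    ds.genes.reset_index().to_csv(paths["genes"], sep="\t", index=False)
    return paths


_CHROM_RE = re.compile(r"^(chr)?(\d+|X|Y)$", re.IGNORECASE)

#: Contigs excluded from CNV windows (mitochondrial / unplaced).
NON_CNV_CHROM_RANK = 10_000


def chromosome_rank(chrom: str) -> int:
    """Natural ordering key: 1..22 numerically, then X, then Y.

    Mitochondrial and unplaced contigs sort after Y and are flagged by a
    rank ≥ :data:`NON_CNV_CHROM_RANK` so CNV windowing can skip them.
    """
    m = _CHROM_RE.match(str(chrom))
    if m is None:
        return NON_CNV_CHROM_RANK
    token = m.group(2).upper()
    if token == "X":
        return 1000
    if token == "Y":
        return 1001
    return int(token)


def sort_genes_genomically(ds: Dataset) -> tuple[Dataset, np.ndarray]:
    """Order genes by (chromosome, start) and return the permutation used.

    Chromosomes sort naturally (chr2 before chr10), then X, then Y; other
    contigs go last (they are excluded from CNV windows downstream, which is
    logged there, not here).  Returns ``(sorted_dataset, perm)`` where
    ``perm[i]`` is the original column index of sorted gene ``i``.
    """
    genes = ds.genes
    missing = genes.index[genes["chromosome"].isna() | genes["start"].isna()]
    if len(missing):
        raise ValidationError(f"genes missing coordinates: {list(missing)}")
    ranks = genes["chromosome"].map(chromosome_rank).to_numpy()
    # lexsort: primary key last
    perm = np.lexsort((genes.index.to_numpy(), genes["start"].to_numpy(), ranks))
    sorted_ds = Dataset(
        counts=sp.csr_matrix(ds.counts[:, perm]),
        cells=ds.cells,
        genes=genes.iloc[perm],
    )
    return sorted_ds, perm
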