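"""Sample-balanced marker discovery.

Differential expression per cell type is biased when a few samples dominate
the cell pool, so cells are first re-balanced across samples: samples with
more target cells than a lower cutoff are kept, the upper cutoff is twice
the minimum kept-sample count, and larger samples are subsampled to it.

On the balanced pool, each condition is compared against the rest with a
tie-corrected Wilcoxon rank-sum test on log-normalized expression, and each
gene receives the marker score

    score = pct_nz_group × (1 − pct_nz_reference)

where the two quantities are the fractions of cells with nonzero raw counts
in the target group and in the pooled reference.  Markers must be detected
in at least half the target cells (pct_nz_group ≥ 0.5) and in fewer than
30% of reference cells (pct_nz_reference < 0.3); the top M by score are
reported.  A separate p/log2FC filter produces the ranked gene list that
would feed pre-ranked enrichment (enrichment itself is out of scope).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import norm, rankdata

from .io import Dataset
from .rng import substream

logger = logging.getLogger(__name__)

__all__ = [
    "BalancedSelection",
    "balanced_sample",
    "log_normalize",
    "rank_genes",
    "select_markers",
    "prerank_filter",
]

_TARGET_SUM = 1e4
_PSEUDO = 1e-9


@dataclass
class BalancedSelection:
    """Per-sample cell selections for one target cell type."""

    target_cell_type: str
    lower_cutoff: int
    upper_cutoff: int
    selected: dict[str, list[str]]  # sample_id -> cell_ids

    def cell_ids(self) -> list[str]:
        out: list[str] = []
        for sample in sorted(self.selected):
            out.extend(self.selected[sample])
        return out


def balanced_sample(ds: Dataset, cell_type: str, lower_cutoff: int = 200,
                    seed: int = 0, level: str = "major") -> BalancedSelection:
    """Balance target-type cell counts across samples.

    Samples contributing more than ``lower_cutoff`` cells of ``cell_type``
    are kept; the upper cutoff is 2 × the minimum kept-sample count, and
    samples above it are subsampled uniformly without replacement.
    """
    col = f"{level}_type"
    mask = ds.cells[col] == cell_type
    if not mask.any():
        raise ValueError(f"no cells of {level} type {cell_type!r}")
    per_sample = ds.cells.loc[mask].groupby("sample_id", observed=True).groups
    counts = {s: len(idx) for s, idx in per_sample.items()}
    kept = {s: n for s, n in counts.items() if n > lower_cutoff}
    if not kept:
        raise ValueError(
            f"no sample has more than {lower_cutoff} cells of type "
            f"{cell_type!r} (max observed: {max(counts.values())})"
        )
    upper = 2 * min(kept.values())
    rng = substream(seed, f"balanced:{cell_type}")
    selected: dict[str, list[str]] = {}
    for sample in sorted(kept):
        ids = list(per_sample[sample])
        if len(ids) > upper:
            pick = rng.choice(len(ids), size=upper, replace=False)
            ids = [ids[i] for i in sorted(pick)]
        selected[sample] = ids
    return BalancedSelection(target_cell_type=cell_type,
                             lower_cutoff=lower_cutoff, upper_cutoff=upper,
                             selected=selected)


def log_normalize(counts: sp.spmatrix) -> sp.csr_matrix:
    """Depth-normalize to 10⁴ counts per cell, then log1p (sparse-safe)."""
    counts = sp.csr_matrix(counts, dtype=np.float64)
    totals = np.asarray(counts.sum(axis=1)).ravel()
    totals[totals == 0] = 1.0
    scaled = sp.diags(_TARGET_SUM / totals) @ counts
    scaled.data = np.log1p(scaled.data)
    return sp.csr_matrix(scaled)


def _wilcoxon_group_vs_rest(X: np.ndarray, group_mask: np.ndarray
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized tie-corrected rank-sum z and two-sided p per gene.

    Normal approximation without continuity correction; a constant gene
    (zero rank variance) gets z = 0, p = 1 by convention.
    """
    n = X.shape[0]
    n1 = int(group_mask.sum())
    n2 = n - n1
    ranks = rankdata(X, axis=0)
    rank_sum = ranks[group_mask].sum(axis=0)
    mu = n1 * (n + 1) / 2.0
    # tie correction: sum over tied groups of (t^3 - t)
    tie_term = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        _, t = np.unique(X[:, j], return_counts=True)
        tie_term[j] = np.sum(t.astype(float) ** 3 - t)
    var = (n1 * n2 / 12.0) * ((n + 1) - tie_term / (n * (n - 1.0)))
    sd = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (rank_sum - mu) / sd, 0.0)
    p = np.where(sd > 0, 2.0 * norm.sf(np.abs(z)), 1.0)
    return z, p


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_i in range(m - 1, -1, -1):
        idx = order[rank_i]
        running = min(running, p[idx] * m / (rank_i + 1))
        adj[idx] = running
    return adj


def rank_genes(ds: Dataset, selection: BalancedSelection,
               group_key: str = "condition") -> pd.DataFrame:
    """Group-vs-rest DEG statistics on the balanced cell pool.

    Returns one row per (gene, group) with columns ``gene_id``, ``group``,
    ``statistic`` (rank-sum z), ``log2fc``, ``p_value``, ``adj_p``,
    ``pct_nz_group``, ``pct_nz_reference`` and ``score``.
    """
    cell_ids = selection.cell_ids()
    pos = ds.cells.index.get_indexer(cell_ids)
    groups = ds.cells[group_key].to_numpy()[pos]
    uniq = [g for g in pd.unique(groups)]
    sizes = {g: int((groups == g).sum()) for g in uniq}
    usable = [g for g in uniq if sizes[g] >= 2]
    if len(usable) < 2:
        raise ValueError("need at least two groups with ≥ 2 cells each")

    raw = ds.counts[pos]
    logX = np.asarray(log_normalize(raw).todense())
    nz = np.asarray((raw > 0).todense())
    expr = np.expm1(logX)  # normalized (non-log) expression for fold changes

    records = []
    for g in usable:
        gm = groups == g
        if (~gm).sum() < 2:
            continue
        z, p = _wilcoxon_group_vs_rest(logX, gm)
        adj = _bh_adjust(p)
        mean_g = expr[gm].mean(axis=0)
        mean_r = expr[~gm].mean(axis=0)
        log2fc = np.log2((mean_g + _PSEUDO) / (mean_r + _PSEUDO))
        pct_g = nz[gm].mean(axis=0)
        pct_r = nz[~gm].mean(axis=0)
        rec = pd.DataFrame({
            "gene_id": ds.genes.index,
            "group": g,
            "statistic": z,
            "log2fc": log2fc,
            "p_value": p,
            "adj_p": adj,
            "pct_nz_group": pct_g,
            "pct_nz_reference": pct_r,
        })
        records.append(rec)
    out = pd.concat(records, ignore_index=True)
    out["score"] = out["pct_nz_group"] * (1.0 - out["pct_nz_reference"])
    out["cell_type"] = selection.target_cell_type
    return out


def select_markers(records: pd.DataFrame, m: int = 12,
                   min_target_frac: float = 0.5,
                   max_ref_frac: float = 0.3) -> dict[tuple[str, str], list[str]]:
    """Top-M marker genes per (cell_type, group) by descending score.

    A gene qualifies when pct_nz_group ≥ ``min_target_frac`` and
    pct_nz_reference < ``max_ref_frac`` (strict).  Ties break by gene_id.
    """
    out: dict[tuple[str, str], list[str]] = {}
    for (ct, grp), sub in records.groupby(["cell_type", "group"], sort=True):
        ok = sub[(sub["pct_nz_group"] >= min_target_frac)
                 & (sub["pct_nz_reference"] < max_ref_frac)]
        ok = ok.sort_values(["score", "gene_id"],
                            ascending=[False, True], kind="stable")
        out[(ct, grp)] = ok["gene_id"].head(m).tolist()
    return out


def prerank_filter(records: pd.DataFrame, max_p: float = 0.05,
                   min_lfc: float = 0.25) -> pd.DataFrame:
    """DEGs passing p ≤ max_p and log2FC ≥ min_lfc, ranked by statistic.

    Both boundaries are inclusive.  This ranked list is the terminal output
    that a pre-ranked enrichment tool would consume.
    """
    keep = records[(records["p_value"] <= max_p)
                   & (records["log2fc"] >= min_lfc)]
    if keep.empty:
        warnings.warn("no genes pass the pre-rank filter")
    return keep.sort_values(["statistic", "gene_id"],
                            ascending=[False, True],
                            kind="stable").reset_index(drop=True)
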