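"""Cohort-level statistics.

Per-sample cell-type proportions with pairwise Welch t-tests (Bonferroni-
corrected) on immune fractions across conditions, and a screen correlating
per-sample mean tumor-cell log2(CNR) per genomic window against the
sample's immune-cell fraction.  The correlation screen reports Pearson r
with the sample count and no significance procedure: with a handful of
samples per condition formal inference is not meaningful, so interpretation
is left to the user.
"""

from __future__ import annotations

import logging
import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .cnv import CNVMatrix
from .io import IMMUNE_TYPES, Dataset

logger = logging.getLogger(__name__)

__all__ = [
    "cell_type_proportions",
    "immune_fractions",
    "proportion_tests",
    "cnv_immune_correlation",
]


def cell_type_proportions(ds: Dataset, level: str = "major") -> pd.DataFrame:
    """Per-sample cell-type fractions (sum to 1 within each sample).

    Returns rows (sample_id, condition, cell_type, fraction).  Empty
    samples cannot occur in a valid dataset, but samples whose cells were
    all filtered upstream are skipped with a warning.
    """
    col = f"{level}_type"
    counts = (ds.cells.groupby(["sample_id", col], observed=True).size()
              .rename("n").reset_index())
    totals = counts.groupby("sample_id")["n"].transform("sum")
    counts["fraction"] = counts["n"] / totals
    cond = ds.cells.groupby("sample_id", observed=True)["condition"].first()
    counts["condition"] = counts["sample_id"].map(cond)
    return counts.rename(columns={col: "cell_type"})[
        ["sample_id", "condition", "cell_type", "fraction"]]


def immune_fractions(proportions: pd.DataFrame) -> pd.DataFrame:
    """Per-sample immune fraction: sum over T, B and myeloid cells."""
    imm = proportions[proportions["cell_type"].isin(IMMUNE_TYPES)]
    out = (imm.groupby(["sample_id", "condition"], observed=True)["fraction"]
           .sum().rename("immune_fraction").reset_index())
    # samples with zero immune cells are absent from imm; restore them at 0
    all_samples = proportions[["sample_id", "condition"]].drop_duplicates()
    out = all_samples.merge(out, on=["sample_id", "condition"], how="left")
    out["immune_fraction"] = out["immune_fraction"].fillna(0.0)
    return out


def proportion_tests(proportions: pd.DataFrame,
                     equal_var: bool = False) -> pd.DataFrame:
    """Pairwise Welch t-tests on per-sample immune fractions by condition.

    Bonferroni-adjusted p = min(1, p × n_pairs).  Pairs where a condition
    has fewer than 2 samples are skipped with a warning.
    """
    imm = immune_fractions(proportions)
    by_cond = {c: g["immune_fraction"].to_numpy()
               for c, g in imm.groupby("condition", observed=True)}
    pairs = list(combinations(sorted(by_cond), 2))
    rows = []
    for a, b in pairs:
        if len(by_cond[a]) < 2 or len(by_cond[b]) < 2:
            warnings.warn(f"skipping {a} vs {b}: fewer than 2 samples")
            continue
        t, p = stats.ttest_ind(by_cond[a], by_cond[b], equal_var=equal_var)
        if np.isnan(p):  # zero variance in both groups: no evidence
            t, p = 0.0, 1.0
        rows.append({"group_a": a, "group_b": b, "t": float(t),
                     "p_value": float(p)})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["adj_p"] = np.minimum(1.0, out["p_value"] * len(out))
    return out


def cnv_immune_correlation(cnv: CNVMatrix, calls: pd.DataFrame,
                           proportions: pd.DataFrame, condition: str,
                           cells: pd.DataFrame, min_samples: int = 3,
                           r_threshold: float | None = 0.6) -> pd.DataFrame:
    """Correlate per-window tumor CNV with immune fraction across samples.

    For every sample of ``condition`` with ≥ 1 tumor cell, the mean
    log2(CNR) over its tumor cells is taken per window; each window's
    Pearson r against the samples' immune fractions is computed and spots
    are returned sorted by |r| descending.  Requires ≥ ``min_samples``
    contributing samples; zero-variance windows are skipped with a note.
    ``r_threshold`` (|r| ≥ threshold), if given, filters the report; pass
    None for all spots.
    """
    imm = immune_fractions(proportions).set_index("sample_id")
    tumor_ids = calls.index[calls["is_tumor"]]
    meta = cells.loc[tumor_ids]
    meta = meta[meta["condition"] == condition]
    if meta.empty:
        raise ValueError(f"no tumor cells in condition {condition!r}")
    pos = cnv.cell_ids.get_indexer(meta.index)

    sample_means, fractions = [], []
    for sample, grp in meta.groupby("sample_id", observed=True):
        rows = pos[meta["sample_id"].to_numpy() == sample]
        sample_means.append(cnv.values[rows].mean(axis=0))
        fractions.append(imm.loc[sample, "immune_fraction"])
    if len(sample_means) < min_samples:
        raise ValueError(
            f"only {len(sample_means)} samples of {condition!r} have tumor "
            f"cells; ≥ {min_samples} required")
    M = np.vstack(sample_means)  # samples × windows
    f = np.asarray(fractions)

    rows_out = []
    for w in range(M.shape[1]):
        x = M[:, w]
        if np.std(x) == 0 or np.std(f) == 0:
            logger.info("window %d skipped: zero variance", w)
            continue
        r = float(np.corrcoef(x, f)[0, 1])
        wm = cnv.window_map.iloc[w]
        rows_out.append({
            "condition": condition, "window": w,
            "chromosome": wm["chromosome"],
            "gene_start": int(wm["gene_start"]),
            "gene_end": int(wm["gene_end"]),
            "pcc": r, "n_samples": len(f),
        })
    out = pd.DataFrame(rows_out)
    if out.empty:
        return out
    out = out.iloc[np.argsort(-np.abs(out["pcc"].to_numpy()),
                              kind="stable")].reset_index(drop=True)
    if r_threshold is not None:
        out = out[np.abs(out["pcc"]) >= r_threshold].reset_index(drop=True)
    return out
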