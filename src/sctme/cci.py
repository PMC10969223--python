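"""Ligand–receptor interaction inference with cross-sample consensus.

For each (ligand–receptor pair, sender type, receiver type) and each
eligible sample (both participating cell types present with ≥ 40 cells),
the interaction statistic is the mean of the ligand's log-normalized
expression over sender cells and the receptor's over receiver cells,
averaged.  Its null distribution comes from permuting cell-type labels
within the sample; the permutation p-value uses the +1 correction so it is
never 0.  If the ligand is detected in fewer than 10% of sender cells (or
the receptor in fewer than 10% of receivers) the pair has no expression
support and p is forced to 1.

Per-sample results pass a significance filter (p ≤ 0.05 and mean ≥ 0.1);
an interaction reaches *consensus* in a condition when it is significant in
at least 75% of that condition's eligible samples.  A reporting step then
keeps consensus interactions with median mean ≥ 0.5, sorted by p ascending
then mean descending, truncated to the top 50.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Dataset
from .markers import log_normalize
from .rng import substream

logger = logging.getLogger(__name__)

__all__ = [
    "LRPair",
    "read_pair_table",
    "eligible_samples",
    "interaction_test",
    "significance_filter",
    "consensus",
    "top_interactions",
    "run_cci",
]

_SUPPORT_FRAC = 0.10


@dataclass(frozen=True)
class LRPair:
    ligand: str
    receptor: str
    pair_id: str


def read_pair_table(path, ds: Dataset | None = None) -> list[LRPair]:
    """Read a TSV with columns pair_id, ligand, receptor.

    Pairs referencing genes absent from ``ds`` are dropped with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    pairs = [LRPair(r.ligand, r.receptor, r.pair_id) for r in df.itertuples()]
    if ds is not None:
        pairs = filter_pairs(pairs, ds)
    return pairs


def filter_pairs(pairs: list[LRPair], ds: Dataset) -> list[LRPair]:
    present = set(ds.genes.index)
    kept = []
    for p in pairs:
        if p.ligand in present and p.receptor in present:
            kept.append(p)
        else:
            warnings.warn(f"dropping pair {p.pair_id}: gene not in dataset")
    return kept


def eligible_samples(ds: Dataset, sender_type: str, receiver_type: str,
                     min_cells: int = 40, level: str = "minor") -> list[str]:
    """Samples where both participating cell types have ≥ min_cells cells."""
    col = f"{level}_type"
    tab = ds.cells.groupby(["sample_id", col], observed=True).size().unstack(
        fill_value=0)
    out = []
    for sample in tab.index:
        ns = tab.loc[sample].get(sender_type, 0)
        nr = tab.loc[sample].get(receiver_type, 0)
        if ns >= min_cells and nr >= min_cells:
            out.append(sample)
    if not out:
        warnings.warn(
            f"no sample has ≥ {min_cells} cells of both {sender_type!r} "
            f"and {receiver_type!r}")
    return sorted(out)


def _pair_stat(lig: np.ndarray, rec: np.ndarray,
               send_idx: np.ndarray, recv_idx: np.ndarray) -> float:
    return 0.5 * (lig[send_idx].mean() + rec[recv_idx].mean())


def interaction_test(ds: Dataset, sample_id: str, pair: LRPair,
                     sender_type: str, receiver_type: str,
                     n_perm: int = 1000, seed: int = 0,
                     level: str = "minor") -> dict:
    """Permutation test of one pair in one sample.

    Returns a dict with pair_id, sender/receiver types, sample_id, mean and
    p_value.  p = (1 + #{null ≥ observed}) / (n_perm + 1).
    """
    col = f"{level}_type"
    in_sample = (ds.cells["sample_id"] == sample_id).to_numpy()
    if not in_sample.any():
        raise ValueError(f"unknown sample {sample_id!r}")
    sub_idx = np.flatnonzero(in_sample)
    types = ds.cells[col].to_numpy()[sub_idx]

    li = ds.genes.index.get_loc(pair.ligand)
    ri = ds.genes.index.get_loc(pair.receptor)
    raw = ds.counts[sub_idx][:, [li, ri]]
    logX = np.asarray(log_normalize(ds.counts[sub_idx]).todense())[:, [li, ri]]
    lig, rec = logX[:, 0], logX[:, 1]
    nz = np.asarray((raw > 0).todense())

    send_local = np.flatnonzero(types == sender_type)
    recv_local = np.flatnonzero(types == receiver_type)
    if len(send_local) == 0 or len(recv_local) == 0:
        raise ValueError(
            f"sample {sample_id} lacks {sender_type} or {receiver_type} cells")
    observed = _pair_stat(lig, rec, send_local, recv_local)

    supported = (nz[send_local, 0].mean() >= _SUPPORT_FRAC
                 and nz[recv_local, 1].mean() >= _SUPPORT_FRAC)
    if not supported:
        p = 1.0
    else:
        rng = substream(seed, f"cci:{sample_id}:{pair.pair_id}:"
                              f"{sender_type}>{receiver_type}")
        n = len(sub_idx)
        ns, nr = len(send_local), len(recv_local)
        perms = rng.permuted(
            np.tile(np.arange(n), (n_perm, 1)), axis=1)
        send_sets = perms[:, :ns]
        if sender_type == receiver_type:
            recv_sets = send_sets[:, :nr]
        else:
            recv_sets = perms[:, ns:ns + nr]
        null = 0.5 * (lig[send_sets].mean(axis=1) + rec[recv_sets].mean(axis=1))
        p = (1.0 + np.sum(null >= observed)) / (n_perm + 1.0)
    return {
        "pair_id": pair.pair_id,
        "sender_type": sender_type,
        "receiver_type": receiver_type,
        "sample_id": sample_id,
        "mean": float(observed),
        "p_value": float(p),
    }


def significance_filter(tests: pd.DataFrame, p_cutoff: float = 0.05,
                        mean_cutoff: float = 0.1) -> pd.DataFrame:
    """Keep tests with p ≤ p_cutoff and mean ≥ mean_cutoff (both inclusive)."""
    if tests.empty:
        return tests
    return tests[(tests["p_value"] <= p_cutoff)
                 & (tests["mean"] >= mean_cutoff)].reset_index(drop=True)


def consensus(tests: pd.DataFrame, p_cutoff: float = 0.05,
              mean_cutoff: float = 0.1,
              fraction: float = 0.75) -> pd.DataFrame:
    """Cross-sample consensus per (pair, sender, receiver, condition).

    ``tests`` holds one row per eligible sample per pair (with a
    ``condition`` column); an interaction reaches consensus when the
    fraction of its condition's eligible samples passing the significance
    filter is ≥ ``fraction``.  Median p and mean across eligible samples
    are attached for reporting.
    """
    if tests.empty:
        return pd.DataFrame(columns=[
            "pair_id", "sender_type", "receiver_type", "condition",
            "n_samples_tested", "n_samples_significant", "consensus",
            "median_p", "median_mean"])
    keys = ["pair_id", "sender_type", "receiver_type", "condition"]
    sig = (tests["p_value"] <= p_cutoff) & (tests["mean"] >= mean_cutoff)
    grouped = tests.assign(_sig=sig).groupby(keys, observed=True)
    out = grouped.agg(
        n_samples_tested=("sample_id", "nunique"),
        n_samples_significant=("_sig", "sum"),
        median_p=("p_value", "median"),
        median_mean=("mean", "median"),
    ).reset_index()
    out["n_samples_significant"] = out["n_samples_significant"].astype(int)
    out["consensus"] = (out["n_samples_significant"]
                        >= fraction * out["n_samples_tested"])
    return out


def top_interactions(consensus_df: pd.DataFrame, mean_cutoff: float = 0.5,
                     k: int = 50) -> pd.DataFrame:
    """Reporting filter: consensus calls with median mean ≥ mean_cutoff,
    sorted by p ascending then mean descending, truncated at k."""
    if consensus_df.empty:
        warnings.warn("no consensus interactions to report")
        return consensus_df
    kept = consensus_df[consensus_df["consensus"]
                        & (consensus_df["median_mean"] >= mean_cutoff)]
    if kept.empty:
        warnings.warn("no consensus interaction passes the reporting "
                      f"mean cutoff {mean_cutoff}")
        return kept.reset_index(drop=True)
    kept = kept.sort_values(
        ["median_p", "median_mean", "pair_id"],
        ascending=[True, False, True], kind="stable")
    return kept.head(k).reset_index(drop=True)


def run_cci(ds: Dataset, pairs: list[LRPair],
            type_pairs: list[tuple[str, str]],
            min_cells: int = 40, n_perm: int = 1000, seed: int = 0,
            p_cutoff: float = 0.05, mean_cutoff: float = 0.1,
            consensus_fraction: float = 0.75,
            level: str = "minor") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Test every pair × type-pair across all eligible samples per condition.

    Returns (per_sample_tests, consensus_table).
    """
    pairs = filter_pairs(pairs, ds)
    cond_of_sample = (ds.cells.groupby("sample_id", observed=True)["condition"]
                      .first())
    rows = []
    for sender, receiver in type_pairs:
        samples = eligible_samples(ds, sender, receiver,
                                   min_cells=min_cells, level=level)
        for sample in samples:
            for pair in pairs:
                res = interaction_test(ds, sample, pair, sender, receiver,
                                       n_perm=n_perm, seed=seed, level=level)
                res["condition"] = cond_of_sample[sample]
                rows.append(res)
    tests = pd.DataFrame(rows)
    cons = consensus(tests, p_cutoff=p_cutoff, mean_cutoff=mean_cutoff,
                     fraction=consensus_fraction)
    return tests, cons
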