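"""Workflow orchestration.

``run_all`` executes the stages in dependency order — simulate (or load) →
CNV estimation → tumor calling → marker discovery → cell–cell interaction
consensus → cohort statistics — writing every inter-stage artifact as plain
TSV/MTX so any stage can be re-driven from external data of the right
shape, plus a machine-readable run manifest.  Re-running with the same
config and seed reproduces byte-identical TSV outputs.

Cell-type annotation is consumed, never computed: the input dataset must
carry major/minor type labels in its cell metadata.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .cci import LRPair, run_cci
from .cnv import cnv_score, estimate_cnv, select_reference
from .cohort import cell_type_proportions, cnv_immune_correlation, proportion_tests
from .config import PipelineConfig
from .io import Dataset, read_dataset, sort_genes_genomically, write_dataset
from .markers import balanced_sample, prerank_filter, rank_genes, select_markers
from .simulate import default_cohort, generate_cohort
from .tumor import call_tumors

logger = logging.getLogger(__name__)

__all__ = ["run_all"]

_FLOAT_FMT = "%.6g"


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> Path:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)
    return path


def _config_hash(config: PipelineConfig) -> str:
    from dataclasses import asdict

    blob = json.dumps(asdict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_all(config: PipelineConfig, out_dir, seed: int | None = None,
            dataset: Dataset | None = None, dataset_dir=None,
            scale: str = "tiny", marker_cell_type: str = "Epithelial",
            lr_pairs: list[LRPair] | None = None,
            cci_type_pairs: list[tuple[str, str]] | None = None) -> dict:
    """Run the full workflow and return the manifest (also written as JSON).

    Input is one of: an in-memory ``dataset``, an on-disk ``dataset_dir``
    (matrix.mtx + cells.tsv + genes.tsv), or neither — in which case a
    synthetic cohort at ``scale`` is generated (the simulate stage).
    """
    seed = config.rng_seed if seed is None else seed
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": _config_hash(config),
        "seed": int(seed),
        "version": __version__,
        "stages": {},
    }
    manifest_path = out / "manifest.json"

    def record(stage: str, status: str, outputs: list[Path],
               t0: float) -> None:
        manifest["stages"][stage] = {
            "status": status,
            "outputs": [str(p) for p in outputs],
            "seconds": round(time.monotonic() - t0, 3),
        }
        manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")

    def run_stage(stage, fn):
        t0 = time.monotonic()
        try:
            outputs = fn()
        except Exception:
            record(stage, "failed", [], t0)
            raise
        record(stage, "completed", outputs, t0)

    truth = None

    # --- stage: simulate / load -------------------------------------------
    def stage_input():
        nonlocal dataset, truth
        if dataset is None and dataset_dir is not None:
            d = Path(dataset_dir)
            for f in ("matrix.mtx", "cells.tsv", "genes.tsv"):
                if not (d / f).exists():
                    raise FileNotFoundError(
                        f"dataset file {d / f} missing; provide a dataset "
                        "directory with matrix.mtx, cells.tsv, genes.tsv "
                        "(cell-type labels must be present in cells.tsv — "
                        "annotation is consumed, not computed)")
            dataset = read_dataset(d / "matrix.mtx", d / "cells.tsv",
                                   d / "genes.tsv")
            return []
        if dataset is None:
            cfg = default_cohort(scale)
            dataset, truth = generate_cohort(cfg, seed)
            paths = write_dataset(dataset, out / "dataset")
            tpath = _write_tsv(truth.tumor_labels.to_frame(),
                               out / "dataset" / "ground_truth.tsv")
            lrp = pd.DataFrame(
                [{"pair_id": f"{s.ligand}_{s.receptor}", "ligand": s.ligand,
                  "receptor": s.receptor} for s in truth.lr_specs])
            ppath = out / "dataset" / "lr_pairs.tsv"
            lrp.to_csv(ppath, sep="\t", index=False)
            return list(paths.values()) + [tpath, ppath]
        return []

    run_stage("input", stage_input)

    sorted_ds, _ = sort_genes_genomically(dataset)

    # --- stage: cnv --------------------------------------------------------
    cnv = None

    def stage_cnv():
        nonlocal cnv
        ref = select_reference(sorted_ds.cells)
        cnv = estimate_cnv(sorted_ds, ref, window_genes=config.window_genes,
                           stride=config.stride, clip=config.cnv_clip)
        p1 = _write_tsv(cnv.to_frame(), out / "cnv.tsv")
        p2 = _write_tsv(cnv.window_map, out / "cnv_windows.tsv", index=False)
        p3 = _write_tsv(cnv_score(cnv).to_frame(), out / "cnv_scores.tsv")
        return [p1, p2, p3]

    run_stage("cnv", stage_cnv)

    # --- stage: call-tumor -------------------------------------------------
    calls = None

    def stage_calls():
        nonlocal calls
        calls = call_tumors(sorted_ds, cnv, config=config, seed=seed)
        return [_write_tsv(calls, out / "calls.tsv")]

    run_stage("call_tumor", stage_calls)

    # --- stage: markers ----------------------------------------------------
    records = None

    def stage_markers():
        nonlocal records
        sel = balanced_sample(sorted_ds, marker_cell_type,
                              lower_cutoff=config.deg_lower_cutoff, seed=seed)
        records = rank_genes(sorted_ds, sel)
        markers = select_markers(records, m=config.marker_top_m,
                                 min_target_frac=config.marker_min_target_frac,
                                 max_ref_frac=config.marker_max_ref_frac)
        mrows = [{"cell_type": ct, "condition": cond, "rank": i + 1, "gene_id": g}
                 for (ct, cond), genes in sorted(markers.items())
                 for i, g in enumerate(genes)]
        pre = prerank_filter(records, max_p=config.prerank_max_p,
                             min_lfc=config.prerank_min_lfc)
        return [
            _write_tsv(records, out / "deg.tsv", index=False),
            _write_tsv(pd.DataFrame(mrows), out / "markers.tsv", index=False),
            _write_tsv(pre[["gene_id", "group", "statistic"]],
                       out / "prerank.tsv", index=False),
        ]

    run_stage("markers", stage_markers)

    # --- stage: cci --------------------------------------------------------
    def stage_cci():
        pairs = lr_pairs
        if pairs is None:
            ppath = out / "dataset" / "lr_pairs.tsv"
            if not ppath.exists():
                raise FileNotFoundError(
                    "no ligand–receptor pair table: pass lr_pairs or run "
                    "the simulate stage first")
            df = pd.read_csv(ppath, sep="\t")
            pairs = [LRPair(r.ligand, r.receptor, r.pair_id)
                     for r in df.itertuples()]
        tpairs = cci_type_pairs
        if tpairs is None:
            tpairs = [("Epithelial", "Fibroblast"), ("Epithelial", "Endothelial"),
                      ("Fibroblast", "Epithelial"), ("Epithelial", "Epithelial")]
        tests, cons = run_cci(
            sorted_ds, pairs, tpairs, min_cells=config.cci_min_cells,
            n_perm=config.cci_n_perm, seed=seed, p_cutoff=config.cci_p,
            mean_cutoff=config.cci_mean,
            consensus_fraction=config.consensus_fraction, level="major")
        from .cci import top_interactions

        top = top_interactions(cons, mean_cutoff=config.report_mean,
                               k=config.report_top)
        return [
            _write_tsv(tests, out / "cci_tests.tsv", index=False),
            _write_tsv(cons, out / "cci_consensus.tsv", index=False),
            _write_tsv(top, out / "cci_top.tsv", index=False),
        ]

    run_stage("cci", stage_cci)

    # --- stage: cohort-stats ----------------------------------------------
    def stage_stats():
        props = cell_type_proportions(sorted_ds)
        tests = proportion_tests(props)
        outputs = [
            _write_tsv(props, out / "proportions.tsv", index=False),
            _write_tsv(tests, out / "proportion_tests.tsv", index=False),
        ]
        spots_frames = []
        for condition in sorted(sorted_ds.cells["condition"].unique()):
            if condition == "Normal":
                continue
            try:
                spots = cnv_immune_correlation(
                    cnv, calls, props, condition, sorted_ds.cells,
                    min_samples=config.corr_min_samples,
                    r_threshold=config.corr_r_threshold)
                spots_frames.append(spots)
            except ValueError as e:
                logger.warning("correlation skipped for %s: %s", condition, e)
        spots_all = (pd.concat(spots_frames, ignore_index=True)
                     if spots_frames else pd.DataFrame())
        outputs.append(_write_tsv(spots_all, out / "cnv_immune_spots.tsv",
                                  index=False))
        return outputs

    run_stage("cohort_stats", stage_stats)

    return manifest
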