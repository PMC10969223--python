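"""Synthetic cohort generator.

Emulates the statistical structure of a multi-sample breast-cancer
single-cell cohort: several samples per condition (HR+, HER2+, TNBC,
Normal), a mixture of major cell types whose proportions vary across
samples, tumor cells carrying segmental copy-number gains/losses,
condition-specific epithelial marker genes, and condition-specific
ligand–receptor co-expression.  Every injected signal is recorded in a
:class:`GroundTruth` object so downstream stages can be scored.

Counts are negative binomial with gene-shared dispersion θ and log-normal
per-cell library-size factors; the expected count of gene g in cell c is

    mean(c, g) = libsize(c) · baseline(g) · 2^{log2_cnr}·[CNV active]
                 · fold·[marker or LR spec applies]

CNV thus acts multiplicatively on expected expression, which is what
expression-based CNV inference can recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CONDITIONS, MAJOR_TYPES, Dataset
from .rng import substream

__all__ = [
    "CNVSegmentSpec",
    "MarkerSpec",
    "LRInjectionSpec",
    "GroundTruth",
    "CohortConfig",
    "generate_cohort",
    "default_cohort",
]

TUMOR_CONDITIONS = ("HRpos", "HER2pos", "TNBC")


@dataclass(frozen=True)
class CNVSegmentSpec:
    """A segmental copy-number event carried by tumor cells of ``conditions``.

    ``start_gene_index`` indexes genes within the chromosome in genomic
    order; ``log2_cnr`` > 0 is a gain, < 0 a loss.
    """

    chromosome: str
    start_gene_index: int
    n_genes: int
    log2_cnr: float
    conditions: frozenset[str]

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValueError("n_genes must be ≥ 1")
        if abs(self.log2_cnr) > 2:
            raise ValueError("|log2_cnr| must be ≤ 2")


@dataclass(frozen=True)
class MarkerSpec:
    """A gene up-regulated (× fold_change) in one cell type of one condition."""

    gene_id: str
    target_condition: str
    target_cell_type: str
    fold_change: float

    def __post_init__(self):
        if self.fold_change <= 1:
            raise ValueError("fold_change must be > 1")


@dataclass(frozen=True)
class LRInjectionSpec:
    """A ligand–receptor pair co-elevated in sender/receiver types of ``conditions``."""

    ligand: str
    receptor: str
    sender_type: str
    receiver_type: str
    conditions: frozenset[str]
    fold_change: float

    def __post_init__(self):
        if self.ligand == self.receptor:
            raise ValueError("ligand and receptor must differ")
        if self.fold_change <= 1:
            raise ValueError("fold_change must be > 1")


@dataclass
class GroundTruth:
    """Everything the generator injected, keyed for downstream scoring."""

    tumor_labels: pd.Series  # bool per cell_id
    marker_specs: list[MarkerSpec]
    cnv_specs: list[CNVSegmentSpec]
    lr_specs: list[LRInjectionSpec]


@dataclass
class CohortConfig:
    """Generator parameters.

    Defaults describe a mid-sized cohort; use :func:`default_cohort` for the
    two stock scales.  ``injected_gene_baseline`` pins the baseline mean
    count of marker/ligand/receptor genes to a detectable but sparse level
    so that injected signals are governed by their fold changes rather than
    by the luck of the log-normal baseline draw.
    """

    samples_per_condition: dict[str, int]
    cells_per_sample: int = 300
    cell_type_props: dict[str, float] = field(
        default_factory=lambda: {
            "Epithelial": 0.35, "Fibroblast": 0.15, "Endothelial": 0.10,
            "T": 0.20, "B": 0.08, "Myeloid": 0.12,
        }
    )
    n_genes: int = 3000
    n_chromosomes: int = 6
    baseline_sigma: float = 1.0
    target_total_counts: float = 6000.0
    nb_dispersion: float = 2.0
    libsize_sigma: float = 0.3
    dirichlet_concentration: float = 5.0
    tumor_normal_fraction: float = 0.10
    injected_gene_baseline: float = 0.25
    cnv_segments: list[CNVSegmentSpec] = field(default_factory=list)
    marker_specs: list[MarkerSpec] = field(default_factory=list)
    lr_specs: list[LRInjectionSpec] = field(default_factory=list)

    def gene_panel(self) -> pd.DataFrame:
        """Deterministic gene panel: ids G0001.. spread over chr1..chrN."""
        per_chr = self.n_genes // self.n_chromosomes
        rows = []
        g = 0
        for c in range(self.n_chromosomes):
            n_here = per_chr if c < self.n_chromosomes - 1 else self.n_genes - g
            for i in range(n_here):
                g += 1
                start = (i + 1) * 10_000
                rows.append((f"G{g:04d}", f"chr{c + 1}", start, start + 999))
        df = pd.DataFrame(rows, columns=["gene_id", "chromosome", "start", "end"])
        return df.set_index("gene_id")

    def validate(self) -> None:
        genes = self.gene_panel()
        by_chr = genes.groupby("chromosome").size()
        for seg in self.cnv_segments:
            if seg.chromosome not in by_chr.index:
                raise ValueError(f"CNV segment on unknown chromosome {seg.chromosome}")
            if seg.start_gene_index + seg.n_genes > by_chr[seg.chromosome]:
                raise ValueError(
                    f"CNV segment exceeds {seg.chromosome} "
                    f"({by_chr[seg.chromosome]} genes)"
                )
            if not seg.conditions <= set(TUMOR_CONDITIONS):
                raise ValueError(f"CNV segment conditions {seg.conditions} invalid")
        known_types = set(self.cell_type_props)
        for m in self.marker_specs:
            if m.gene_id not in genes.index:
                raise ValueError(f"marker spec references unknown gene {m.gene_id}")
            if m.target_cell_type not in known_types:
                raise ValueError(f"marker spec references unknown type {m.target_cell_type}")
            if m.target_condition not in CONDITIONS:
                raise ValueError(f"marker spec condition {m.target_condition} invalid")
        for lr in self.lr_specs:
            for gid in (lr.ligand, lr.receptor):
                if gid not in genes.index:
                    raise ValueError(f"LR spec references unknown gene {gid}")
            for t in (lr.sender_type, lr.receiver_type):
                if t not in known_types:
                    raise ValueError(f"LR spec references unknown type {t}")
        for cond in self.samples_per_condition:
            if cond not in CONDITIONS:
                raise ValueError(f"unknown condition {cond}")
        if abs(sum(self.cell_type_props.values()) - 1.0) > 1e-6:
            raise ValueError("cell_type_props must sum to 1")


_MINOR_SPLIT = {"T": ("CD4T", "CD8T"), "Myeloid": ("Macrophage", "DC")}


def _segment_gene_mask(cfg: CohortConfig, genes: pd.DataFrame,
                       condition: str) -> np.ndarray:
    """Per-gene log2 CNV carried by tumor cells of ``condition``."""
    log2 = np.zeros(len(genes))
    chrom = genes["chromosome"].to_numpy()
    for seg in cfg.cnv_segments:
        if condition not in seg.conditions:
            continue
        on_chr = np.flatnonzero(chrom == seg.chromosome)
        idx = on_chr[seg.start_gene_index: seg.start_gene_index + seg.n_genes]
        log2[idx] += seg.log2_cnr
    return log2


def generate_cohort(cfg: CohortConfig, seed: int) -> tuple[Dataset, GroundTruth]:
    """Sample a cohort; identical (cfg, seed) → identical output."""
    cfg.validate()
    genes = cfg.gene_panel()
    gene_index = {g: i for i, g in enumerate(genes.index)}
    n_genes = len(genes)

    # Baseline expression: log-normal, scaled so expected total counts per
    # cell ≈ target_total_counts; injected genes pinned to a fixed baseline.
    rng_base = substream(seed, "baselines")
    baseline = rng_base.lognormal(mean=0.0, sigma=cfg.baseline_sigma, size=n_genes)
    baseline *= cfg.target_total_counts / baseline.sum()
    pinned = {m.gene_id for m in cfg.marker_specs}
    for lr in cfg.lr_specs:
        pinned.update((lr.ligand, lr.receptor))
    for gid in pinned:
        baseline[gene_index[gid]] = cfg.injected_gene_baseline

    types = list(cfg.cell_type_props)
    base_props = np.array([cfg.cell_type_props[t] for t in types])
    theta = cfg.nb_dispersion

    blocks, cell_rows, tumor_flags = [], [], []
    for condition in CONDITIONS:
        n_samples = cfg.samples_per_condition.get(condition, 0)
        cnv_log2 = _segment_gene_mask(cfg, genes, condition)
        cnv_mult = np.power(2.0, cnv_log2)
        for s in range(n_samples):
            sample_id = f"{condition}_{s + 1:02d}"
            rng = substream(seed, f"sample:{sample_id}")
            alpha = cfg.dirichlet_concentration * len(types) * base_props
            props = rng.dirichlet(alpha)
            n_by_type = rng.multinomial(cfg.cells_per_sample, props)

            type_of_cell = np.repeat(np.arange(len(types)), n_by_type)
            n_cells = len(type_of_cell)
            is_epi = np.array([types[t] == "Epithelial" for t in type_of_cell])
            if condition in TUMOR_CONDITIONS:
                tumor = is_epi & (rng.random(n_cells) >= cfg.tumor_normal_fraction)
            else:
                tumor = np.zeros(n_cells, dtype=bool)

            # per-cell expected expression
            mean = np.tile(baseline, (n_cells, 1))
            mean[tumor] *= cnv_mult
            for m in cfg.marker_specs:
                if m.target_condition != condition:
                    continue
                sel = np.array([types[t] == m.target_cell_type for t in type_of_cell])
                mean[sel, gene_index[m.gene_id]] *= m.fold_change
            for lr in cfg.lr_specs:
                if condition not in lr.conditions:
                    continue
                send = np.array([types[t] == lr.sender_type for t in type_of_cell])
                recv = np.array([types[t] == lr.receiver_type for t in type_of_cell])
                mean[send, gene_index[lr.ligand]] *= lr.fold_change
                mean[recv, gene_index[lr.receptor]] *= lr.fold_change

            libsize = rng.lognormal(mean=0.0, sigma=cfg.libsize_sigma, size=n_cells)
            mean *= libsize[:, None]
            # NB via gamma-Poisson: var = μ + μ²/θ
            lam = rng.gamma(shape=theta, scale=mean / theta)
            counts = rng.poisson(lam)
            blocks.append(sp.csr_matrix(counts))

            for i in range(n_cells):
                major = types[type_of_cell[i]]
                minors = _MINOR_SPLIT.get(major)
                minor = minors[i % len(minors)] if minors else major
                cell_rows.append(
                    (f"{sample_id}:C{i + 1:04d}", sample_id, condition, major, minor)
                )
            tumor_flags.append(tumor)

    counts = sp.vstack(blocks, format="csr").astype(np.int32)
    cells = pd.DataFrame(
        cell_rows, columns=["cell_id", "sample_id", "condition",
                            "major_type", "minor_type"]
    ).set_index("cell_id")
    ds = Dataset(counts=counts, cells=cells, genes=genes)
    truth = GroundTruth(
        tumor_labels=pd.Series(np.concatenate(tumor_flags), index=cells.index,
                               name="is_tumor"),
        marker_specs=list(cfg.marker_specs),
        cnv_specs=list(cfg.cnv_segments),
        lr_specs=list(cfg.lr_specs),
    )
    return ds, truth


def default_cohort(scale: str = "tiny") -> CohortConfig:
    """Stock cohort configurations.

    ``tiny``: 6 samples × 300 cells (fast, CI-friendly).
    ``standard``: 12 samples × 1,500 cells, ≥3 samples per condition.

    Both carry ≥2 CNV segments per tumor condition (placed to echo known
    subtype biology: TNBC gains on chr1/chr7-analogues, a strong HER2+ gain,
    HR+ losses), 12 epithelial marker genes per tumor condition, and one
    injected ligand–receptor pair per tumor condition plus a pan-condition
    pair.
    """
    if scale == "tiny":
        samples = {"TNBC": 2, "HRpos": 1, "HER2pos": 1, "Normal": 2}
        cells, n_genes, n_chr = 300, 3000, 6
    elif scale == "standard":
        samples = {"TNBC": 3, "HRpos": 3, "HER2pos": 3, "Normal": 3}
        cells, n_genes, n_chr = 1500, 6000, 10
    else:
        raise ValueError(f"unknown scale {scale!r} (expected 'tiny' or 'standard')")

    per_chr = n_genes // n_chr
    arm = per_chr // 2  # segments are arm-scale, as real tumor CNVs are

    def seg(chrom, arm_index, log2, conds):
        return CNVSegmentSpec(chrom, arm_index * arm, arm, log2,
                              frozenset(conds))

    segments = [
        seg("chr1", 0, +0.6, {"TNBC"}),
        seg("chr2", 1, +0.5, {"TNBC"}),
        seg("chr3", 0, +0.8, {"HER2pos"}),
        seg("chr4", 1, -0.6, {"HER2pos"}),
        seg("chr5", 0, -0.5, {"HRpos"}),
        seg("chr1", 1, +0.5, {"HRpos"}),
    ]

    # Marker genes live on the last chromosome, clear of CNV segments.
    last_chr_first_gene = (n_chr - 1) * per_chr  # 0-based global index
    marker_specs: list[MarkerSpec] = []
    gid = last_chr_first_gene
    for condition in TUMOR_CONDITIONS:
        for _ in range(12):
            gid += 1
            marker_specs.append(
                MarkerSpec(f"G{gid:04d}", condition, "Epithelial", fold_change=8.0)
            )

    lr_genes = [f"G{gid + k + 1:04d}" for k in range(8)]
    gid += 8
    lr_specs = [
        LRInjectionSpec(lr_genes[0], lr_genes[1], "Epithelial", "Fibroblast",
                        frozenset({"TNBC"}), 6.0),
        LRInjectionSpec(lr_genes[2], lr_genes[3], "Epithelial", "Endothelial",
                        frozenset({"HER2pos"}), 6.0),
        LRInjectionSpec(lr_genes[4], lr_genes[5], "Fibroblast", "Epithelial",
                        frozenset({"HRpos"}), 6.0),
        LRInjectionSpec(lr_genes[6], lr_genes[7], "Epithelial", "Epithelial",
                        frozenset(TUMOR_CONDITIONS), 6.0),
    ]

    return CohortConfig(
        samples_per_condition=samples,
        cells_per_sample=cells,
        n_genes=n_genes,
        n_chromosomes=n_chr,
        cnv_segments=segments,
        marker_specs=marker_specs,
        lr_specs=lr_specs,
    )


def null_cohort(scale: str = "tiny") -> CohortConfig:
    """A cohort with no injected signal of any kind (for calibration tests)."""
    cfg = default_cohort(scale)
    return replace(cfg, cnv_segments=[], marker_specs=[], lr_specs=[])
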