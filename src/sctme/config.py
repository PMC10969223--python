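"""Pipeline configuration.

Every tunable threshold of every stage lives in :class:`PipelineConfig`,
with the workflow's published values as defaults.  Configs serialize to and
from YAML so a run is fully described by one file plus one seed.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """All tunable parameters of the workflow.

    CNV estimation
    --------------
    window_genes / window_stride : running-mean window over genomically
        ordered genes (stride defaults to half the window).
    cnv_clip : expression residuals are clipped to ±cnv_clip (log2 scale)
        before smoothing.

    Tumor calling
    -------------
    pca_components, knn, louvain_resolution : CNV-space embedding, neighbor
        graph and clustering granularity.
    seed_ref_fraction : a cluster seeds the normal set when its normal-
        reference fraction strictly exceeds this.
    connectivity_normalized : aggregate cluster connectivity as
        edges/(|a|·|b|) rather than raw edge counts.
    seed_connectivity_mode : "max" (default) or "sum" over individual seed
        clusters when scoring a candidate's connectivity to the seed set.
    gmm_space : "pca" (default) or "windows" — feature space for the normal
        Gaussian mixture.
    bimodal_method : "gmm" (default) or "otsu" for the final threshold.

    Marker discovery
    ----------------
    deg_lower_cutoff : minimum per-sample target-cell count for the
        sample-balanced selection.
    marker_min_target_frac / marker_max_ref_frac : nonzero-fraction
        conditions (≥ / strict <) a marker must satisfy.
    marker_top_m : markers reported per (cell type, condition).
    prerank_max_p / prerank_min_lfc : raw-p and log2FC filters applied to
        DEGs before pre-ranked enrichment (enrichment itself external).

    Cell–cell interaction
    ---------------------
    cci_min_cells : per-sample minimum count of each participating cell type.
    cci_n_perm : label permutations per test.
    cci_p / cci_mean : per-sample significance filters.
    consensus_fraction : fraction of a condition's eligible samples that must
        be significant for a consensus call.
    report_mean / report_top : reporting filter and list length.

    Cohort analysis
    ---------------
    corr_min_samples / corr_r_threshold : minimum samples per correlation
        spot and the |r| report threshold.
    """

    # cnv_estimation
    window_genes: int = 100
    window_stride: int | None = None
    cnv_clip: float = 1.5
    # tumor_caller
    pca_components: int = 15
    knn: int = 15
    louvain_resolution: float = 2.0
    seed_ref_fraction: float = 0.20
    connectivity_normalized: bool = True
    seed_connectivity_mode: str = "max"
    gmm_space: str = "pca"
    gmm_max_components: int = 5
    bimodal_method: str = "gmm"
    # marker_discovery
    deg_lower_cutoff: int = 200
    marker_min_target_frac: float = 0.5
    marker_max_ref_frac: float = 0.3
    marker_top_m: int = 12
    prerank_max_p: float = 0.05
    prerank_min_lfc: float = 0.25
    # cci_consensus
    cci_min_cells: int = 40
    cci_n_perm: int = 1000
    cci_p: float = 0.05
    cci_mean: float = 0.1
    consensus_fraction: float = 0.75
    report_mean: float = 0.5
    report_top: int = 50
    # cohort_analysis
    corr_min_samples: int = 3
    corr_r_threshold: float = 0.6
    # randomness
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = [
            "window_genes", "pca_components", "knn", "deg_lower_cutoff",
            "cci_min_cells", "cci_n_perm", "marker_top_m", "report_top",
            "gmm_max_components", "corr_min_samples",
        ]
        for name in positive:
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be ≥ 1")
        for name in ["seed_ref_fraction", "marker_min_target_frac",
                     "marker_max_ref_frac", "cci_p", "consensus_fraction",
                     "prerank_max_p"]:
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.louvain_resolution <= 0:
            raise ValueError("louvain_resolution must be positive")
        if self.seed_connectivity_mode not in ("max", "sum"):
            raise ValueError("seed_connectivity_mode must be 'max' or 'sum'")
        if self.gmm_space not in ("pca", "windows"):
            raise ValueError("gmm_space must be 'pca' or 'windows'")
        if self.bimodal_method not in ("gmm", "otsu"):
            raise ValueError("bimodal_method must be 'gmm' or 'otsu'")

    @property
    def stride(self) -> int:
        return self.window_stride or max(1, self.window_genes // 2)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
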