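"""Pipeline-wide configuration with study defaults.

All thresholds that recur across stages live here so that a single YAML
file can drive a full run: LD-clumping parameters, the MAF floor, the
second-degree kinship cutoff, the haplotype frequency filter, the number
of principal components used as covariates, and the assumed population
prevalence for the liability-scale transformation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

#: Default p-value grid for the pruning+thresholding model search.
DEFAULT_THRESHOLD_GRID: tuple[float, ...] = (
    5e-8, 1e-6, 1e-4, 1e-3, 0.01, 0.05, 0.1, 0.5, 1.0,
)


@dataclass
class PipelineConfig:
    """Tunable parameters shared by the analysis stages.

    Parameters
    ----------
    clump_r2 : float
        Pairwise r² above which a variant is absorbed into an index
        variant's clump.
    clump_window_kb : float
        Maximum index-to-candidate distance, in kilobases, for clumping.
    maf_min : float
        Minor-allele-frequency floor; variants with MAF below this are
        removed before scoring (inclusive bound: MAF == maf_min is kept).
    kinship_max : float
        Kinship coefficient above which a pair counts as related when
        building the unrelated subset. 0.0884 is the conventional
        second-degree cutoff; 0.0442 the third-degree one.
    kinship_3rd_degree : float
        Numeric third-degree cutoff used by subset re-runs.
    hap_freq_min : float
        Minimum haplotype frequency for association testing.
    n_pcs : int
        Number of genotype principal components used as covariates.
    prevalence_k : float
        Assumed population prevalence for the liability-scale R²
        transformation. This must be set thoughtfully per trait; the
        default is a placeholder and a warning is logged when it is used.
    threshold_grid : tuple of float
        p-value cutoffs searched by pruning+thresholding.
    seed : int
        Seed for every stochastic step of a run.
    """

    clump_r2: float = 0.1
    clump_window_kb: float = 250.0
    maf_min: float = 0.05
    kinship_max: float = 0.0884
    kinship_3rd_degree: float = 0.0442
    hap_freq_min: float = 0.01
    n_pcs: int = 10
    prevalence_k: float = 0.005
    threshold_grid: tuple[float, ...] = field(default_factory=lambda: DEFAULT_THRESHOLD_GRID)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.clump_r2 <= 1.0:
            raise ValueError("clump_r2 must be in [0, 1]")
        if self.clump_window_kb <= 0:
            raise ValueError("clump_window_kb must be positive")
        if not 0.0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min must be in [0, 0.5]")
        if not 0.0 < self.kinship_max <= 0.5:
            raise ValueError("kinship_max must be in (0, 0.5]")
        if not 0.0 <= self.hap_freq_min < 1.0:
            raise ValueError("hap_freq_min must be in [0, 1)")
        if not 0.0 < self.prevalence_k < 1.0:
            raise ValueError("prevalence_k must be in (0, 1)")
        if self.n_pcs < 0:
            raise ValueError("n_pcs must be non-negative")
        grid = tuple(float(t) for t in self.threshold_grid)
        if any(not 0.0 < t <= 1.0 for t in grid):
            raise ValueError("threshold grid entries must be in (0, 1]")
        self.threshold_grid = grid

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)
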