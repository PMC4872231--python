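"""Run configuration for the analysis pipeline.

All thresholds that the analysis stages consume live in :class:`RunConfig`,
so a run is fully described by one config object plus the input matrices.
Configs round-trip through flat YAML key/value files.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, asdict
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Invalid configuration value."""


@dataclass
class RunConfig:
    """Pipeline-wide thresholds and switches.

    Parameters
    ----------
    bin_width : float
        Width of the mean log10(FPKM+1) bins used for CV outlier detection.
    grubbs_alpha : float
        Significance level of the Smirnov–Grubbs outlier test within a bin.
    cea_alpha : float
        Per-gene significance level for the composition/expression ANOVA.
    tss_window_bp : int
        Maximum |CpG position − TSS| distance (bases, inclusive) for a
        gene–CpG pair.
    n_permutations : int
        Number of random permutations for the Spearman permutation test.
    reference_day_index : int
        Index of the timepoint used as the reference for relative values
        (the "Day 1" column).
    rng_seed : int
        Seed for every stochastic step (permutations, simulation).
    cv_scale : str
        ``"log"`` computes CV on log10(FPKM+1); ``"raw"`` on FPKM.
    min_bin_size : int
        Bins smaller than this are skipped by the Grubbs test.
    grubbs_one_sided : bool
        Flag only unusually *high* CVs (default) or both tails.
    grubbs_iterative : bool
        Repeat single-outlier removal until no rejection.
    min_ref_value : float
        Series whose reference-day value is below this are excluded from
        the relative transformation rather than divided by ~0.
    normalize_composition : bool
        Rescale each estimated composition vector to sum to 1.
    mea_r2_partial : bool
        Model-2 R² as partial (squared correlation of the adjusted partial
        residual with the fitted methylation term); if False, plain joint R².
    mea_two_sided : bool
        Permutation p computed on |rho| (two-sided) or on rho (upper).
    mea_stratified : bool
        Exclude CEA genes from the stratified MEA report.
    compare_test : str
        Two-sample distribution test for dynamic vs non-dynamic summaries:
        ``"mannwhitney"`` or ``"ks"``.
    min_mean_fpkm : float
        Optional gene-universe expression filter; 0 disables it.
    """

    bin_width: float = 0.05
    grubbs_alpha: float = 0.05
    cea_alpha: float = 0.05
    tss_window_bp: int = 5000
    n_permutations: int = 1000
    reference_day_index: int = 0
    rng_seed: int = 0
    cv_scale: str = "log"
    min_bin_size: int = 3
    grubbs_one_sided: bool = True
    grubbs_iterative: bool = True
    min_ref_value: float = 1e-6
    normalize_composition: bool = False
    mea_r2_partial: bool = True
    mea_two_sided: bool = True
    mea_stratified: bool = True
    compare_test: str = "mannwhitney"
    min_mean_fpkm: float = 0.0

    def __post_init__(self) -> None:
        if self.bin_width <= 0:
            raise ConfigError("bin_width must be > 0")
        for name in ("grubbs_alpha", "cea_alpha"):
            a = getattr(self, name)
            if not 0 < a < 1:
                raise ConfigError(f"{name} must lie in (0, 1), got {a}")
        if self.n_permutations < 1:
            raise ConfigError("n_permutations must be >= 1")
        if self.tss_window_bp < 0:
            raise ConfigError("tss_window_bp must be >= 0")
        if self.cv_scale not in ("log", "raw"):
            raise ConfigError(f"cv_scale must be 'log' or 'raw', got {self.cv_scale!r}")
        if self.compare_test not in ("mannwhitney", "ks"):
            raise ConfigError(f"unknown compare_test {self.compare_test!r}")
        if self.min_bin_size < 3:
            raise ConfigError("min_bin_size must be >= 3")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        """Load a config from a flat YAML key/value file."""
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: expected a flat key/value mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
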