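"""Pipeline configuration: every threshold in one validated, serializable place.

No stage hides a numeric constant: seeding and significance thresholds,
the region gap, the conditional stopping rule, colocalization priors and
posterior cutoff, factor-model adequacy bounds and the MR alpha all live
here and round-trip through YAML unchanged.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml


class ConfigError(ValueError):
    """Raised when a configuration value is out of range."""


@dataclass
class PipelineConfig:
    seed: int = 1
    outdir: str = "polyfactor_run"

    # trait grouping and factor-model adequacy
    rg_group: float = 0.4
    cfi_min: float = 0.95
    srmr_max: float = 0.10

    # harmonization
    maf_min: float = 0.01

    # LD-score regression
    ld_window_kb: float = 200.0
    n_jackknife_blocks: int = 200

    # region definition
    p_seed: float = 1e-6
    p_sig: float = 5e-8
    gap_kb: float = 250.0
    region_pad_kb: float = 100.0
    filter_before_merge: bool = True
    exclude_hla: bool = True

    # conditional analysis
    p_stop: float = 1e-4
    p_cond: float = 1e-6
    collinearity_r2: float = 0.9

    # colocalization
    pp4_min: float = 0.9
    coloc_p1: float = 1e-4
    coloc_p2: float = 1e-4
    coloc_p12: float = 1e-5
    prior_sd_gwas: float = 0.2
    prior_sd_qtl: float = 0.15
    min_overlap: int = 25

    # Mendelian randomization
    mr_alpha: float = 0.05

    # synthetic study (optional; absent when running on user data)
    simulate: dict = field(default_factory=dict)
    # candidate factor models: name -> {factor -> [traits]}
    models: dict = field(default_factory=dict)
    # interpretability exclusions among candidate models
    model_exclude: list = field(default_factory=list)

    def validate(self) -> "PipelineConfig":
        probs = {"p_seed": self.p_seed, "p_sig": self.p_sig,
                 "p_stop": self.p_stop, "p_cond": self.p_cond,
                 "pp4_min": self.pp4_min, "coloc_p1": self.coloc_p1,
                 "coloc_p2": self.coloc_p2, "coloc_p12": self.coloc_p12,
                 "mr_alpha": self.mr_alpha, "maf_min": self.maf_min,
                 "cfi_min": self.cfi_min, "srmr_max": self.srmr_max,
                 "collinearity_r2": self.collinearity_r2}
        for name, v in probs.items():
            if not (0.0 < v <= 1.0):
                raise ConfigError(f"{name} must lie in (0, 1], got {v}")
        positives = {"gap_kb": self.gap_kb, "region_pad_kb": self.region_pad_kb,
                     "ld_window_kb": self.ld_window_kb,
                     "n_jackknife_blocks": self.n_jackknife_blocks,
                     "min_overlap": self.min_overlap}
        for name, v in positives.items():
            if v <= 0:
                raise ConfigError(f"{name} must be positive, got {v}")
        if self.rg_group <= 0 or self.rg_group > 1:
            raise ConfigError("rg_group must lie in (0, 1]")
        return self

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**d).validate()

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
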