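"""Pipeline configuration: thresholds, null-model settings, input paths."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Thresholds and settings for the full co-occurrence analysis.

    Defaults are the reference values of the analysis: Spearman |rho| >= 0.9
    with p < 0.01 and Storey q < 0.05 for species-species edges; |rho| >= 0.6
    with p < 0.05 for environment-species edges; OTUs kept when present in at
    least 8 samples of a zone; node roles split at Zi = 2.5 / Pi = 0.62;
    modules below 4 members skipped in the eigengene analysis; 1000 G(n, m)
    random networks for the null ensembles.
    """

    # species-species edge thresholds
    r_min: float = 0.9
    p_max: float = 0.01
    q_max: float = 0.05
    # environment-species edge thresholds
    env_r_min: float = 0.6
    env_p_max: float = 0.05
    # prevalence filter
    min_prevalence: int = 8
    # node roles
    zi_thr: float = 2.5
    pi_thr: float = 0.62
    # eigengene analysis
    min_module_size: int = 4
    # null models
    null_model: str = "gnm"
    n_replicates: int = 1000
    n_boot: int = 50
    seed: int = 0
    # I/O (optional; used by the CLI `run` subcommand)
    counts: str | None = None
    taxonomy: str | None = None
    metadata: str | None = None
    groups: str | None = None
    outdir: str = "micronet_out"

    def __post_init__(self) -> None:
        if not 0 < self.r_min <= 1:
            raise ValueError("r_min must lie in (0, 1]")
        if not 0 < self.env_r_min <= 1:
            raise ValueError("env_r_min must lie in (0, 1]")
        for name in ("p_max", "q_max", "env_p_max"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.min_prevalence < 1:
            raise ValueError("min_prevalence must be >= 1")
        if self.null_model not in ("gnm", "degree_preserving_swap"):
            raise ValueError(f"unknown null model {self.null_model!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)
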