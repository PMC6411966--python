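"""Pipeline configuration with the method's printed defaults."""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, asdict
from pathlib import Path


@dataclass
class PipelineConfig:
    """All tunable parameters of the tissue-type mapping pipeline.

    Defaults are the method's canonical values: 50 histogram bins per axis,
    MRSI purity 0.90, necrosis p threshold 4×10⁻³ mm² s⁻¹, normal-tissue
    probability 0.95, SLIC grid size 30 / regularisation 0.2 at ×4
    upsampling, lesion and high-grade probability thresholds 0.5, and the
    PDD-derived ("paper") prior.
    """

    bins: int = 50
    mrsi_purity_threshold: float = 0.90
    necrosis_p_threshold: float = 4e-3
    normal_prob_threshold: float = 0.95
    slic_grid_size: int = 30
    slic_regularisation: float = 0.2
    upsample_factor: int = 4
    lesion_threshold: float = 0.5
    highgrade_threshold: float = 0.5
    prior: str = "paper"
    smoothing_sigma_bins: float = 0.0
    seed: int = 0
    channel_paths: dict[str, str] = field(default_factory=dict)
    reference_histograms: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        if self.prior not in ("paper", "flat"):
            raise ValueError("prior must be 'paper' or 'flat'")
        if self.bins < 2:
            raise ValueError("bins must be >= 2")

    @classmethod
    def from_toml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        data.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)
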