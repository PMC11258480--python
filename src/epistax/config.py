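"""Pipeline configuration: thresholds, paths and seeds, round-tripped via YAML."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """All tunable thresholds and input paths for a pipeline run.

    Defaults mirror the analysis conventions used throughout the package:
    DEGs at fold change > 2 and adjusted p < 0.05; epistasis feature selection
    at adjusted p < 0.1; empirical negative controls at nominal p > 0.1;
    no-replicate BCV 0.1; term reporting at |NES| > 1.5; network links at
    intensity >= 0.8; splicing significance at nominal p < 0.05.
    """

    counts: str | None = None
    metadata: str | None = None
    gmt: str | None = None
    annotation: str | None = None

    fc: float = 2.0
    deg_q: float = 0.05
    episel_q: float = 0.1
    control_p: float = 0.1
    nes: float = 1.5
    link: float = 0.8
    splice_p: float = 0.05
    bcv: float = 0.1
    ruv_k: int = 1
    n_top: int = 500

    n_boot: int = 5000
    n_perm: int = 1000
    seed: int = 0

    # simulation block (used when counts is None)
    simulate: dict = field(default_factory=lambda: {
        "model": "unbranched", "n_features": 500, "effect_sd": 1.0,
        "noise_sd": 0.05, "frac_nonnull": 1.0, "n_reps": 3,
        "depth_mean": 200.0, "batch_sd": 0.0,
    })

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        positive = {"fc": self.fc, "nes": self.nes, "n_top": self.n_top}
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"config field {name!r} must be > 0, got {value}")
        unit = {"deg_q": self.deg_q, "episel_q": self.episel_q,
                "control_p": self.control_p, "link": self.link, "splice_p": self.splice_p}
        for name, value in unit.items():
            if not 0 < value <= 1:
                raise ValueError(f"config field {name!r} must be in (0, 1], got {value}")
        if self.bcv < 0:
            raise ValueError(f"config field 'bcv' must be >= 0, got {self.bcv}")
        if self.n_boot < 100 or self.n_perm < 100:
            raise ValueError("n_boot and n_perm must be >= 100")
        if self.ruv_k < 0:
            raise ValueError("ruv_k must be >= 0")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)
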