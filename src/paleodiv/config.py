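"""Pipeline configuration: one dataclass, YAML round-trippable.

Defaults encode the study settings the package was designed around: 0.5 Myr
slice grid, ariaDNE bandwidth 0.1, eight 5.625-degree OPCR rotations with
8 azimuth bins and 3-face minimum patches, ten ASR replicates, and a
10,000-tree null ensemble.  One global seed fans out to per-stage seeds via
``numpy.random.SeedSequence.spawn`` so each stage is independently
reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # synthetic study
    seed: int = 0
    n_clades: int = 4
    clade_tags: list[str] = field(
        default_factory=lambda: ["anomaluroid", "anthropoid", "hystricognath", "strepsirrhine"]
    )
    root_age: float = 76.16
    birth_rate: float = 0.22
    death_rate: float = 0.175
    fossil_rate: float = 0.32
    min_tips: int = 150
    max_tips: int = 600
    # meshes / DTM
    mesh_face_count: int = 8000
    ariadne_epsilon: float = 0.1
    opcr_rotations: int = 8
    opcr_rotation_step: float = 5.625
    opcr_bins: int = 8
    opcr_min_patch: int = 3
    # slicing / disparity
    slice_step: float = 0.5
    exclusion_edges: list[int] = field(default_factory=list)
    peak_window: tuple[float, float] = (38.0, 33.9)
    trough_window: tuple[float, float] = (33.9, 27.0)
    # ASR
    asr_replicates: int = 10
    asr_restarts: int = 2
    # null model
    null_trees: int = 10_000
    run_null: bool = False

    # -- seeds --------------------------------------------------------------

    STAGES = ("simulate", "dtm", "pca", "asr", "slice", "null")

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed spawned from the global seed."""
        idx = self.STAGES.index(stage)
        child = np.random.SeedSequence(self.seed).spawn(len(self.STAGES))[idx]
        return int(child.generate_state(1)[0] % (2**31))

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["peak_window"] = list(d["peak_window"])
        d["trough_window"] = list(d["trough_window"])
        return d

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "peak_window" in data:
            data["peak_window"] = tuple(data["peak_window"])
        if "trough_window" in data:
            data["trough_window"] = tuple(data["trough_window"])
        return cls(**data)
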