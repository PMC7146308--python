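"""Run configuration: a fully serializable description of one experiment.

A run is reproducible from its configuration plus a single master seed; the
seed fans out to per-stage seeds through ``numpy.random.SeedSequence``.
Every file a command produces embeds the SHA-256 hash of the producing
configuration, so identical hash implies identical output.
"""

from __future__ import annotations

import hashlib
import json

import numpy as np
import yaml
from pydantic import BaseModel, Field


class TrainSection(BaseModel):
    n_trees: int = Field(10, ge=1)
    max_splits: int = Field(5, ge=1)
    min_split_samples: int = Field(10, ge=2)
    min_leaf_samples: dict[str, int] = Field(
        default_factory=lambda: {"stage1": 71, "sedentary": 143,
                                 "moderate": 47, "rigorous": 74})


class ReductionSection(BaseModel):
    cap: int = Field(8, ge=1)
    tolerance: float = Field(0.02, ge=0.0, le=1.0)
    n_splits: int = Field(100, ge=1)


class RunConfig(BaseModel):
    """Everything a command needs: seed, data size, training and reduction."""

    seed: int = 1
    windows_per_class: int = Field(200, ge=1)
    duration_per_activity_s: float = Field(60.0, gt=0.0)
    train: TrainSection = Field(default_factory=TrainSection)
    reduction: ReductionSection = Field(default_factory=ReductionSection)

    def config_hash(self) -> str:
        doc = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(doc.encode()).hexdigest()[:16]

    def stage_seed(self, stage: int) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        return int(np.random.SeedSequence(self.seed).generate_state(stage + 1)[stage]
                   % (2**31))

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        return cls.model_validate(doc)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=True)


__all__ = ["TrainSection", "ReductionSection", "RunConfig"]
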