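"""Run configuration: one nested, strictly validated document.

Unknown keys are rejected so typos fail loudly; the whole configuration
round-trips through YAML, and ``DEEPPATH_``-prefixed environment variables
override scalar leaves (e.g. ``DEEPPATH_SEED=3``).
"""

from __future__ import annotations

import hashlib
import json
import os

import yaml
from pydantic import BaseModel, ConfigDict, Field


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SlideConfig(_Strict):
    height: int = 640
    width: int = 640
    n_blobs: int = 3


class SegmentationConfig(_Strict):
    downsample: int = 8
    sat_threshold: int = 8
    median_kernel: int = 7
    close_kernel: int = 5
    min_area: float = 50.0


class PatchConfig(_Strict):
    patch_size: int = 64
    min_foreground_frac: float = 0.5


class EmbeddingConfig(_Strict):
    backbone: str = "fixture"
    out_dim: int = 64
    batch_size: int = 128


class IMConfig(_Strict):
    n_bags: int = 80
    n_instances: int = 30
    dim: int = 32
    delta: float = 2.0
    signal_frac: float = 0.1
    folds: int = 3
    epochs: int = 60
    lr: float = 1e-3
    embed_dim: int = 32
    att_dim: int = 16


class SubtypeRunConfig(_Strict):
    n_samples: int = 60
    n_iter: int = 100
    resample_frac: float = 0.8


class PGMConfig(_Strict):
    n_samples: int = 120
    beta: float = 1.5
    censoring_rate: float = 0.3
    folds: int = 3
    epochs: int = 60
    lr: float = 5e-3
    tau: float = 1.0


class EvalConfig(_Strict):
    horizons: list[float] = Field(default_factory=lambda: [12.0, 36.0, 60.0])


class RunConfig(_Strict):
    seed: int = 0
    outdir: str = "deeppath-demo"
    log_level: str = "INFO"
    slide: SlideConfig = Field(default_factory=SlideConfig)
    segmentation: SegmentationConfig = Field(default_factory=SegmentationConfig)
    patching: PatchConfig = Field(default_factory=PatchConfig)
    embedding: EmbeddingConfig = Field(default_factory=EmbeddingConfig)
    im: IMConfig = Field(default_factory=IMConfig)
    subtyping: SubtypeRunConfig = Field(default_factory=SubtypeRunConfig)
    pgm: PGMConfig = Field(default_factory=PGMConfig)
    evaluate: EvalConfig = Field(default_factory=EvalConfig)

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.model_dump(), sort_keys=False)


def _apply_env_overrides(data: dict) -> dict:
    for key, val in os.environ.items():
        if not key.startswith("DEEPPATH_"):
            continue
        path = key[len("DEEPPATH_"):].lower().split("__")
        node = data
        for part in path[:-1]:
            node = node.setdefault(part, {})
        node[path[-1]] = yaml.safe_load(val)
    return data


def validate_config(path) -> RunConfig:
    """Load and strictly validate a YAML config file."""
    try:
        with open(path) as f:
            data = yaml.safe_load(f)
    except yaml.YAMLError as exc:
        raise ValueError(f"malformed config file {path}: {exc}") from exc
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValueError(f"config root must be a mapping, got {type(data).__name__}")
    return RunConfig.model_validate(_apply_env_overrides(data))


def version() -> str:
    from . import __version__

    return __version__
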