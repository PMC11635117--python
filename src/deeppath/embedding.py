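"""Patch embedding: pluggable backbone contract and per-slide feature bags.

A backbone is any deterministic map from an RGB patch to a fixed-length
float32 vector. The shipped :class:`FixtureBackbone` block-averages the patch
to a small fixed grid and applies a frozen random linear projection (seeded
from the backbone name, not from user seeds), which satisfies the contract —
determinism, batch invariance, fixed output dimension — without requiring any
pretrained weights. Heavier encoders can be plugged in through the same
interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import h5py
import numpy as np
from skimage.transform import resize

from .slide_prep import PatchSet

__all__ = ["EmbeddingBackbone", "FixtureBackbone", "FeatureBag", "embed_patches",
           "write_bag", "read_bag"]


@dataclass
class EmbeddingBackbone:
    """A named deterministic patch-to-vector transform."""

    name: str
    out_dim: int
    transform: Callable[[np.ndarray], np.ndarray]

    def __post_init__(self):
        if self.out_dim < 1:
            raise ValueError("out_dim must be >= 1")

    def __call__(self, patch: np.ndarray) -> np.ndarray:
        return self.transform(patch)


class FixtureBackbone(EmbeddingBackbone):
    """Frozen random linear projection of a downsampled patch.

    The patch is resized to ``grid x grid`` (anti-aliased block average),
    flattened and scaled to [0, 1], then projected with a Gaussian matrix drawn
    once from a seed derived from the backbone name — so the transform is a
    fixed function, identical across processes and batch layouts.
    """

    def __init__(self, out_dim: int = 1024, grid: int = 16):
        self.grid = grid
        in_dim = grid * grid * 3
        seed = abs(hash_name(f"fixture-{out_dim}-{grid}")) % (2**32)
        rng = np.random.default_rng(seed)
        self._W = rng.standard_normal((in_dim, out_dim)).astype(np.float32) / np.sqrt(in_dim)
        super().__init__(name="fixture", out_dim=out_dim, transform=self._transform)

    def _transform(self, patch: np.ndarray) -> np.ndarray:
        if patch.ndim != 3 or patch.shape[2] != 3:
            raise ValueError(
                f"backbone expects an H x W x 3 RGB patch, got shape {patch.shape}"
            )
        small = resize(patch.astype(np.float64) / 255.0, (self.grid, self.grid, 3),
                       anti_aliasing=False, order=1)
        return (small.reshape(-1).astype(np.float32) @ self._W).astype(np.float32)


def hash_name(s: str) -> int:
    """Stable (process-independent) string hash for seeding frozen weights."""
    h = 2166136261
    for ch in s.encode():
        h = (h ^ ch) * 16777619 % (2**32)
    return h


@dataclass
class FeatureBag:
    """Per-slide multiple-instance bag: one embedding row per patch."""

    slide_id: str
    H: np.ndarray  # N x M float32
    coords: np.ndarray  # N x 2 int64, aligned with rows of H
    label: Optional[object] = None
    backbone: str = ""
    signal_idx: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.H = np.asarray(self.H, dtype=np.float32)
        self.coords = np.asarray(self.coords, dtype=np.int64).reshape(-1, 2)
        if len(self.H) != len(self.coords):
            raise ValueError("H rows and coords must align 1:1")
        if not np.isfinite(self.H).all():
            raise ValueError("feature bag contains non-finite values")

    def __len__(self) -> int:
        return len(self.H)


def embed_patches(ps: PatchSet, backbone: EmbeddingBackbone, batch_size: int = 128) -> FeatureBag:
    """Embed every patch of a PatchSet; row order matches ``ps.coords``.

    The result is independent of ``batch_size`` (each patch is transformed
    individually; batching only controls traversal granularity).
    """
    if ps.patches is None:
        raise ValueError("PatchSet has no pixel data to embed")
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    rows = []
    for start in range(0, len(ps), batch_size):
        for patch in ps.patches[start : start + batch_size]:
            rows.append(backbone(patch))
    H = (np.stack(rows) if rows else
         np.zeros((0, backbone.out_dim), dtype=np.float32))
    return FeatureBag(slide_id=ps.slide_id, H=H.astype(np.float32),
                      coords=ps.coords, backbone=backbone.name)


def write_bag(bag: FeatureBag, path) -> None:
    """Store a FeatureBag as HDF5 (features float32, coords int64, metadata attrs)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("features", data=bag.H.astype(np.float32))
        f.create_dataset("coords", data=bag.coords)
        f.attrs["slide_id"] = bag.slide_id
        f.attrs["backbone"] = bag.backbone
        f.attrs["out_dim"] = bag.H.shape[1] if bag.H.ndim == 2 else 0
        if bag.label is not None:
            f.attrs["label"] = str(bag.label)


def read_bag(path) -> FeatureBag:
    try:
        f = h5py.File(path, "r")
    except (OSError, FileNotFoundError) as exc:
        raise IOError(f"cannot read feature bag at {path!s}: {exc}") from exc
    with f:
        return FeatureBag(
            slide_id=str(f.attrs["slide_id"]),
            H=np.asarray(f["features"], dtype=np.float32),
            coords=np.asarray(f["coords"], dtype=np.int64),
            label=f.attrs.get("label", None),
            backbone=str(f.attrs.get("backbone", "")),
        )
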