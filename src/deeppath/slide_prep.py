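"""Tissue segmentation and patch extraction for whole-slide rasters.

The pipeline mirrors the standard weakly-supervised computational-pathology
preprocessing recipe: the slide is downsampled, converted to HSV, thresholded
on the saturation channel (tissue is stained and saturated, glass background is
not), cleaned up with a median filter and morphological closing, filtered by
contour area, and finally tiled into fixed-size non-overlapping patches whose
coordinates are stored in the level-0 pixel frame.

Plain rasters (PNG/TIFF arrays) are first-class inputs so that no pyramidal WSI
reader is required; a pyramidal file can be flattened to a :class:`SlideRaster`
by any reader that yields an RGB array plus its level downsample factors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
from skimage import measure, morphology
from skimage.color import rgb2hsv
from skimage.filters import median as _median_filter

__all__ = [
    "SlideRaster",
    "SegmentationParams",
    "TissueMask",
    "PatchSet",
    "segment_tissue",
    "extract_patches",
    "write_patchset",
    "read_patchset",
]


@dataclass
class SlideRaster:
    """An RGB slide image with optional pyramid level factors.

    ``pixels`` holds the level-0 raster (H x W x 3, uint8). ``level_downsamples``
    lists the integer downsample factor of each available level relative to
    level 0; a plain raster has ``[1]``.
    """

    pixels: np.ndarray
    slide_id: str = "slide"
    level_downsamples: list[int] = field(default_factory=lambda: [1])

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("slide pixels must be an H x W x 3 RGB array")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("slide raster is empty")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]

    def level_image(self, level: int) -> np.ndarray:
        if level < 0 or level >= len(self.level_downsamples):
            raise ValueError(
                f"level {level} not present; available levels: "
                f"{list(range(len(self.level_downsamples)))} "
                f"(downsamples {self.level_downsamples})"
            )
        d = self.level_downsamples[level]
        return self.pixels[::d, ::d]


@dataclass
class SegmentationParams:
    """Tissue-segmentation parameters.

    Defaults follow the common CLAM-style toolbox behaviour: saturation
    threshold 8 (0-255 scale), 7 px median filter, 5 px 4-connected closing
    element, and a 100 px^2 minimum contour area at 32x downsampling.
    """

    downsample: int = 32
    sat_threshold: int = 8
    median_kernel: int = 7
    close_kernel: int = 5
    min_area: float = 100.0
    use_otsu: bool = False

    def __post_init__(self):
        if self.downsample < 1:
            raise ValueError("downsample must be >= 1")
        for name in ("median_kernel", "close_kernel"):
            k = getattr(self, name)
            if k < 1 or k % 2 == 0:
                raise ValueError(f"{name} must be an odd integer >= 1")
        if self.min_area < 0:
            raise ValueError("min_area must be >= 0")


@dataclass
class TissueMask:
    """Binary foreground mask at ``downsample`` resolution, with level-0 contours."""

    mask: np.ndarray
    downsample: int
    contours: list[np.ndarray] = field(default_factory=list)

    @property
    def n_contours(self) -> int:
        return len(self.contours)


@dataclass
class PatchSet:
    """Non-overlapping tiles kept from the foreground grid.

    ``coords`` are (x, y) top-left corners, 0-based, in the level-0 frame;
    tiles are half-open ``[x, x + s*d) x [y, y + s*d)`` where ``d`` is the
    downsample of the extraction level.
    """

    slide_id: str
    level: int
    patch_size: int
    coords: np.ndarray
    patches: np.ndarray | None = None
    level_downsample: int = 1

    def __len__(self) -> int:
        return len(self.coords)


def segment_tissue(slide: SlideRaster, params: SegmentationParams | None = None) -> TissueMask:
    """Segment stained tissue from a slide raster.

    Steps: stride-downsample -> RGB to HSV -> threshold the saturation channel
    -> median blur -> morphological closing -> connected-component area filter.
    Deterministic: identical inputs and params give a bit-identical mask. An
    all-background slide yields a valid empty mask.
    """
    params = params or SegmentationParams()
    if slide.pixels.size == 0:
        raise ValueError("cannot segment an empty raster")
    d = params.downsample
    small = slide.pixels[::d, ::d]
    sat = rgb2hsv(small)[..., 1] * 255.0
    if params.use_otsu:
        from skimage.filters import threshold_otsu

        thr = threshold_otsu(sat) if sat.max() > sat.min() else params.sat_threshold
    else:
        thr = params.sat_threshold
    binary = (sat >= thr).astype(np.uint8)
    if params.median_kernel > 1:
        binary = _median_filter(binary, footprint=np.ones((params.median_kernel,) * 2))
    if params.close_kernel > 1:
        radius = (params.close_kernel - 1) // 2
        binary = morphology.closing(binary.astype(bool), morphology.diamond(radius))
    binary = binary.astype(bool)

    labels = measure.label(binary, connectivity=2)
    keep = np.zeros_like(binary)
    for region in measure.regionprops(labels):
        if region.area >= params.min_area:
            keep[labels == region.label] = True

    contours = []
    for contour in measure.find_contours(keep.astype(float), 0.5):
        # (row, col) at the downsampled level -> (x, y) level-0 polygon
        contours.append(np.column_stack([contour[:, 1] * d, contour[:, 0] * d]))
    return TissueMask(mask=keep, downsample=d, contours=contours)


def extract_patches(
    slide: SlideRaster,
    mask: TissueMask,
    patch_size: int = 256,
    level: int = 0,
    min_foreground_frac: float = 0.5,
    with_pixels: bool = True,
) -> PatchSet:
    """Tile the slide on a non-overlapping grid and keep foreground tiles.

    A tile is kept iff the fraction of foreground mask pixels under its level-0
    footprint is at least ``min_foreground_frac``. Edge tiles that do not fit
    entirely inside the slide are dropped.
    """
    if not 0.0 <= min_foreground_frac <= 1.0:
        raise ValueError("min_foreground_frac must be in [0, 1]")
    if patch_size < 1:
        raise ValueError("patch_size must be positive")
    img = slide.level_image(level)
    dl = slide.level_downsamples[level]
    md = mask.downsample
    H, W = img.shape[:2]

    coords, patches = [], []
    for row in range(0, H - patch_size + 1, patch_size):
        for col in range(0, W - patch_size + 1, patch_size):
            x0, y0 = col * dl, row * dl  # level-0 frame
            span = patch_size * dl
            r0, r1 = y0 // md, max(y0 // md + 1, -((y0 + span) // -md))
            c0, c1 = x0 // md, max(x0 // md + 1, -((x0 + span) // -md))
            window = mask.mask[r0:r1, c0:c1]
            if window.size == 0:
                continue
            if window.mean() >= min_foreground_frac - 1e-12:
                coords.append((x0, y0))
                if with_pixels:
                    patches.append(img[row : row + patch_size, col : col + patch_size])
    coords_arr = np.asarray(coords, dtype=np.int64).reshape(-1, 2)
    patch_arr = np.asarray(patches, dtype=np.uint8) if with_pixels and patches else None
    if with_pixels and not patches:
        patch_arr = np.zeros((0, patch_size, patch_size, 3), dtype=np.uint8)
    return PatchSet(
        slide_id=slide.slide_id,
        level=level,
        patch_size=patch_size,
        coords=coords_arr,
        patches=patch_arr,
        level_downsample=dl,
    )


def write_patchset(ps: PatchSet, path) -> None:
    """Store a PatchSet as HDF5 (coords int64, optional uint8 patches, metadata attrs)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("coords", data=ps.coords.astype(np.int64))
        if ps.patches is not None:
            f.create_dataset("patches", data=ps.patches.astype(np.uint8))
        f.attrs["slide_id"] = ps.slide_id
        f.attrs["level"] = ps.level
        f.attrs["patch_size"] = ps.patch_size
        f.attrs["level_downsample"] = ps.level_downsample


def read_patchset(path) -> PatchSet:
    """Read a PatchSet written by :func:`write_patchset`; lossless round-trip."""
    try:
        f = h5py.File(path, "r")
    except (OSError, FileNotFoundError) as exc:
        raise IOError(f"cannot read patch store at {path!s}: {exc}") from exc
    with f:
        coords = np.asarray(f["coords"], dtype=np.int64)
        patches = np.asarray(f["patches"], dtype=np.uint8) if "patches" in f else None
        return PatchSet(
            slide_id=str(f.attrs["slide_id"]),
            level=int(f.attrs["level"]),
            patch_size=int(f.attrs["patch_size"]),
            coords=coords,
            patches=patches,
            level_downsample=int(f.attrs.get("level_downsample", 1)),
        )
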