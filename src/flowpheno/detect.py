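"""Cell-event detection and single-cell cropping from brightfield frames.

A frame contains a cell event when its maximum patch-wise intensity
variance is at least ``ratio_threshold`` (default 2) times the variance of
the whole frame; the single-cell crop is a ``crop_size`` x ``crop_size``
(default 128) square around the centre of the maximum-variance patch.
Patches tile the frame without overlap (remainder pixels at the right and
bottom edges are ignored); population variance is used throughout so the
ratio test is exactly scale-free.  Blank (zero-variance) frames are
rejected even though the bare inequality would hold for them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class DetectorConfig:
    patch_size: int = 16
    ratio_threshold: float = 2.0
    crop_size: int = 128
    sliding: bool = False            # sliding-window variance map instead of tiling

    def __post_init__(self):
        if self.patch_size < 2:
            raise ValueError("patch_size must be >= 2")
        if self.crop_size % 2 != 0:
            raise ValueError("crop_size must be even")
        if self.ratio_threshold <= 0:
            raise ValueError("ratio_threshold must be > 0")


@dataclass
class CellCrop:
    pixels: np.ndarray                       # (crop, crop) float32
    source_frame: int = -1
    center: tuple[int, int] = (0, 0)         # (row, col) of the crop centre
    ground_truth: dict | None = None


def _as_array(frame) -> np.ndarray:
    return np.asarray(getattr(frame, "pixels", frame), dtype=np.float64)


def patch_variance_map(frame, patch_size: int, sliding: bool = False) -> np.ndarray:
    """Per-patch population variances over a non-overlapping tiling.

    With ``sliding=True`` returns the dense sliding-window variance map
    instead (every valid window position).
    """
    a = _as_array(frame)
    h, w = a.shape
    if h < patch_size or w < patch_size:
        raise ValueError(f"frame {a.shape} smaller than patch_size {patch_size}")
    if sliding:
        mean = ndimage.uniform_filter(a, patch_size, mode="constant")
        sq = ndimage.uniform_filter(a * a, patch_size, mode="constant")
        var = sq - mean ** 2
        half = patch_size // 2
        lo = half
        return np.maximum(var[lo:lo + h - patch_size + 1,
                              lo:lo + w - patch_size + 1], 0.0)
    nh, nw = h // patch_size, w // patch_size
    tiles = a[:nh * patch_size, :nw * patch_size].reshape(
        nh, patch_size, nw, patch_size).transpose(0, 2, 1, 3)
    return tiles.reshape(nh, nw, -1).var(axis=2)


def _max_patch(frame, cfg: DetectorConfig):
    vmap = patch_variance_map(frame, cfg.patch_size, cfg.sliding)
    idx = np.unravel_index(int(np.argmax(vmap)), vmap.shape)
    return vmap, idx


def detect_cell_frame(frame, cfg: DetectorConfig = DetectorConfig()) -> bool:
    """True iff the max patch variance is >= threshold x whole-frame variance.

    Zero-variance (blank) frames return False: a frame with no intensity
    structure contains no cell, even though 0 >= 2*0 holds arithmetically.
    """
    a = _as_array(frame)
    vmap, _ = _max_patch(a, cfg)
    vmax = float(vmap.max())
    if vmax <= 0.0:
        return False
    return vmax >= cfg.ratio_threshold * float(a.var())


def extract_crop(frame, cfg: DetectorConfig = DetectorConfig(),
                 source_frame: int = -1,
                 ground_truth: dict | None = None) -> CellCrop:
    """Crop a ``crop_size`` square around the maximum-variance patch centre.

    Windows that would extend past the frame are shifted (clamped) to stay
    inside — never padded, so no synthetic pixels enter downstream
    learning.  The emitted crop is always exactly crop_size x crop_size.
    """
    a = _as_array(frame)
    h, w = a.shape
    c = cfg.crop_size
    if h < c or w < c:
        raise ValueError(f"frame {a.shape} smaller than crop_size {c}")
    vmap, (pi, pj) = _max_patch(a, cfg)
    if cfg.sliding:
        cy = pi + cfg.patch_size // 2
        cx = pj + cfg.patch_size // 2
    else:
        cy = pi * cfg.patch_size + cfg.patch_size // 2
        cx = pj * cfg.patch_size + cfg.patch_size // 2
    r0 = int(np.clip(cy - c // 2, 0, h - c))
    c0 = int(np.clip(cx - c // 2, 0, w - c))
    pixels = np.ascontiguousarray(a[r0:r0 + c, c0:c0 + c], dtype=np.float32)
    return CellCrop(pixels, source_frame, (r0 + c // 2, c0 + c // 2), ground_truth)


def normalize_crop(crop, mode: str = "zscore"):
    """Normalize pixel intensities: 'zscore' (mean 0, var 1) or 'minmax' ([0,1]).

    Constant crops normalize to all zeros (with a warning): there is no
    scale to divide by.
    """
    pixels = np.asarray(getattr(crop, "pixels", crop), dtype=np.float64)
    if mode == "zscore":
        std = pixels.std()
        if std < 1e-12:
            warnings.warn("constant crop; returning zeros", stacklevel=2)
            out = np.zeros_like(pixels, dtype=np.float32)
        else:
            out = ((pixels - pixels.mean()) / std).astype(np.float32)
    elif mode == "minmax":
        rng_ = pixels.max() - pixels.min()
        if rng_ < 1e-12:
            warnings.warn("constant crop; returning zeros", stacklevel=2)
            out = np.zeros_like(pixels, dtype=np.float32)
        else:
            out = ((pixels - pixels.min()) / rng_).astype(np.float32)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if isinstance(crop, CellCrop):
        return CellCrop(out, crop.source_frame, crop.center, crop.ground_truth)
    return out


def laplacian_sharpness(img, presmooth: float = 1.0) -> float:
    """Laplacian-of-Gaussian variance — the sharpness score used to pick
    well-focused reference cells and to locate the focal slice of a stack.

    The Gaussian pre-smooth (sigma ``presmooth`` px) suppresses pixel
    noise, whose Laplacian variance is focus-independent and would
    otherwise swamp the edge signal at realistic noise levels.
    """
    a = _as_array(img)
    if presmooth > 0:
        a = ndimage.gaussian_filter(a, presmooth)
    return float(ndimage.laplace(a).var())


def detect_and_crop(frames, cfg: DetectorConfig = DetectorConfig(),
                    truth=None) -> list[CellCrop]:
    """Run detection over a frame sequence and crop every positive frame.

    If a ground-truth table is supplied, its species/z columns are attached
    to each crop's provenance.
    """
    crops: list[CellCrop] = []
    for i, frame in enumerate(frames):
        if not detect_cell_frame(frame, cfg):
            continue
        gt = None
        if truth is not None:
            row = truth.iloc[i]
            if bool(row["has_cell"]):
                gt = {"species": row["species"], "z": float(row["z_um"])}
        crops.append(extract_crop(frame, cfg, source_frame=i, ground_truth=gt))
    return crops
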