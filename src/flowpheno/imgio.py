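"""Image and table I/O: single- and multi-page grayscale TIFF, CSV tables.

Intensities are float32 in [0, 1] in memory; integer bit depths exist only
at file boundaries and conversions are explicit: 8-bit divides by 255,
16-bit by 65535.  Float TIFFs round-trip losslessly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile

from .synth import Frame, ZStack


def _to_float(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        raise ValueError("multi-channel images are not supported; "
                         "provide single-channel grayscale")
    if arr.dtype == np.uint8:
        return (arr.astype(np.float32) / 255.0)
    if arr.dtype == np.uint16:
        return (arr.astype(np.float32) / 65535.0)
    if arr.dtype.kind == "f":
        return arr.astype(np.float32)
    raise ValueError(f"unsupported dtype {arr.dtype}")


def read_image(path, px_size: float = 1.0):
    """Read a TIFF as a Frame (single page) or ZStack (multi-page)."""
    arr = tifffile.imread(str(path))
    arr = _to_float(np.asarray(arr))
    if arr.ndim == 2:
        return Frame(arr, px_size)
    if arr.ndim == 3:
        return ZStack(arr, px_size, spacing=np.nan,
                      z_labels=np.full(len(arr), np.nan))
    raise ValueError(f"unsupported TIFF shape {arr.shape}")


def write_image(path, image, dtype: str = "float32") -> None:
    """Write a Frame/ZStack/array to TIFF; bit-depth conversion is explicit."""
    if isinstance(image, Frame):
        arr = image.pixels
    elif isinstance(image, ZStack):
        arr = image.slices
    else:
        arr = np.asarray(image)
    if dtype == "float32":
        out = arr.astype(np.float32)
    elif dtype == "uint8":
        out = np.clip(arr * 255.0, 0, 255).astype(np.uint8)
    elif dtype == "uint16":
        out = np.clip(arr * 65535.0, 0, 65535).astype(np.uint16)
    else:
        raise ValueError(f"unsupported dtype {dtype!r}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(str(path), out)


def write_zstack(path, stack: ZStack, dtype: str = "float32") -> None:
    write_image(path, stack, dtype=dtype)


def read_zstack(path, px_size: float = 1.0, spacing: float = 0.25,
                focal_index: int | None = None) -> ZStack:
    """Read a multi-page TIFF as a z-stack with reconstructed z labels."""
    arr = _to_float(np.asarray(tifffile.imread(str(path))))
    if arr.ndim == 2:
        arr = arr[None]
    n = len(arr)
    focus = n // 2 if focal_index is None else focal_index
    labels = (np.arange(n) - focus) * spacing
    return ZStack(arr, px_size, spacing, labels)
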