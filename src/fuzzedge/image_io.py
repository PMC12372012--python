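"""Image loading, saving, padding, resizing and grayscale conversion.

All processing modules operate on :class:`GrayImage`, a plain 2-D intensity
grid with an explicit declared value range (1.0 for normalized data, 255 for
8-bit, 65535 for 16-bit).  Loading keeps pixel values untouched; the caller
decides when to convert or normalize.  Coordinates are row-major, 0-based,
``(row, col)`` with pixel (0, 0) at the top-left.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
from skimage.transform import resize as _sk_resize

__all__ = [
    "GrayImage",
    "ColorImage",
    "ImageFormatError",
    "load_image",
    "to_grayscale",
    "pad_to_square",
    "resize_image",
    "save_image",
]

#: ITU-R BT.601 luma weights, the MATLAB rgb2gray convention.
LUMA_WEIGHTS = (0.2989, 0.5870, 0.1140)

_SUPPORTED_EXT = {".png", ".tif", ".tiff", ".jpg", ".jpeg", ".bmp"}


class ImageFormatError(ValueError):
    """Raised for unsupported or corrupt image files."""


@dataclass
class GrayImage:
    """A single-channel image: ``pixels`` (m x n) in [0, value_range]."""

    pixels: np.ndarray
    value_range: float = 255.0
    provenance: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError(f"GrayImage needs a 2-D grid, got ndim={self.pixels.ndim}")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("GrayImage must have at least one row and column")
        if self.pixels.min() < 0 or self.pixels.max() > self.value_range:
            raise ValueError(
                f"intensities outside [0, {self.value_range}]: "
                f"[{self.pixels.min()}, {self.pixels.max()}]"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class ColorImage:
    """A 3-channel image: ``pixels`` (m x n x 3) in [0, value_range]."""

    pixels: np.ndarray
    value_range: float = 255.0
    provenance: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("ColorImage needs an (m, n, 3) grid")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


def _value_range_for(arr: np.ndarray) -> float:
    if arr.dtype == np.uint8:
        return 255.0
    if arr.dtype == np.uint16:
        return 65535.0
    if np.issubdtype(arr.dtype, np.integer):
        return 65535.0 if arr.max() > 255 else 255.0
    # Floating data: treat as normalized when it fits [0, 1].
    return 1.0 if arr.size and arr.max() <= 1.0 else 255.0


def load_image(path: str | os.PathLike) -> GrayImage | ColorImage:
    """Read a TIFF/PNG/JPG/BMP file, preserving pixel values.

    Single-channel files become :class:`GrayImage`; multi-channel files
    become :class:`ColorImage` (an alpha channel, if present, is dropped).
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"image file not found: {path}")
    ext = os.path.splitext(path)[1].lower()
    if ext not in _SUPPORTED_EXT:
        raise ImageFormatError(f"unsupported image format: {ext!r}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # corrupt or unreadable file
        raise ImageFormatError(f"cannot decode image {path}: {exc}") from exc
    vr = _value_range_for(arr)
    if arr.ndim == 2:
        return GrayImage(arr, value_range=vr, provenance=path)
    if arr.ndim == 3:
        if arr.shape[2] >= 3:
            return ColorImage(arr[:, :, :3], value_range=vr, provenance=path)
        if arr.shape[2] == 1:
            return GrayImage(arr[:, :, 0], value_range=vr, provenance=path)
    raise ImageFormatError(f"unsupported image layout with shape {arr.shape}")


def to_grayscale(img: ColorImage | GrayImage) -> GrayImage:
    """Luma-weighted channel combination (0.2989 R + 0.5870 G + 0.1140 B).

    Integer-ranged images are rounded to the nearest integer, matching the
    behaviour of MATLAB's ``rgb2gray``.  Grayscale input passes through.
    """
    if isinstance(img, GrayImage):
        return img
    w = np.asarray(LUMA_WEIGHTS)
    gray = img.pixels @ w
    if img.value_range >= 2:  # integer-valued range
        gray = np.round(gray)
    gray = np.clip(gray, 0, img.value_range)
    return GrayImage(gray, value_range=img.value_range, provenance=img.provenance)


def pad_to_square(img: GrayImage) -> GrayImage:
    """Pad with black (zero) pixels to an s x s grid, s = max(m, n).

    The original content stays anchored at the top-left; padding is appended
    on the right and/or bottom.  Already-square images are returned unchanged.
    """
    m, n = img.pixels.shape
    s = max(m, n)
    if m == n:
        return img
    out = np.zeros((s, s), dtype=float)
    out[:m, :n] = img.pixels
    return GrayImage(out, value_range=img.value_range, provenance=img.provenance)


def resize_image(img: GrayImage, target_side: int) -> GrayImage:
    """Bilinear resize of a square image to target_side x target_side.

    Anti-aliasing is applied when downsampling.  Non-square input raises:
    callers should :func:`pad_to_square` first.
    """
    m, n = img.pixels.shape
    if m != n:
        raise ValueError(
            f"resize_image needs a square input (got {m}x{n}); apply pad_to_square first"
        )
    if target_side < 1:
        raise ValueError("target_side must be positive")
    if target_side == m:
        return GrayImage(img.pixels.copy(), img.value_range, img.provenance)
    out = _sk_resize(
        img.pixels,
        (target_side, target_side),
        order=1,
        anti_aliasing=target_side < m,
        preserve_range=True,
        mode="edge",
    )
    out = np.clip(out, 0, img.value_range)
    return GrayImage(out, value_range=img.value_range, provenance=img.provenance)


def _to_uint8_membership(mu: np.ndarray) -> np.ndarray:
    # round half away from zero: floor(255*mu + 0.5) for non-negative mu
    return np.floor(255.0 * np.clip(mu, 0.0, 1.0) + 0.5).astype(np.uint8)


def save_image(img, path: str | os.PathLike) -> None:
    """Write an image; format inferred from the file extension.

    Membership maps (objects with a ``mu`` grid in [0, 1]) are scaled to
    8-bit with round-half-away-from-zero.  Binary edge maps (objects with
    {0,1} ``pixels``) are written as 0/255.  JPG output is lossy and
    triggers a warning.
    """
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    if ext not in _SUPPORTED_EXT:
        raise ImageFormatError(f"unsupported output format: {ext!r}")
    if ext in {".jpg", ".jpeg"}:
        warnings.warn("JPG output is lossy; prefer PNG or TIFF", stacklevel=2)

    if hasattr(img, "mu"):  # FuzzyEdgeMap
        data = _to_uint8_membership(np.asarray(img.mu))
    elif isinstance(img, (GrayImage, ColorImage)):
        px = img.pixels
        if img.value_range <= 1.0:
            data = _to_uint8_membership(px)
        elif img.value_range <= 255:
            data = np.clip(np.round(px), 0, 255).astype(np.uint8)
        else:
            data = np.clip(np.round(px), 0, 65535).astype(np.uint16)
    elif hasattr(img, "pixels"):  # EdgeMap-like: {0,1} grid
        px = np.asarray(img.pixels)
        data = (px > 0).astype(np.uint8) * np.uint8(255)
    else:
        raise TypeError(f"cannot save object of type {type(img).__name__}")
    parent = os.path.dirname(path)
    if parent:
        os.makedirs(parent, exist_ok=True)
    iio.imwrite(path, data)
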