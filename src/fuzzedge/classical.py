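"""Classical edge operators (Prewitt, Sobel, Roberts, Canny) and enhancement
filters (Laplace, Sobel gradient, smoothed Sobel gradient, sharpen).

Convolutions use replicate-edge padding so image borders do not generate
spurious responses.  The automatic gradient threshold (4x mean magnitude)
follows the familiar MATLAB ``edge`` heuristic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.morphology import thin as _thin

from .image_io import GrayImage

__all__ = [
    "EdgeMap",
    "GradientField",
    "gradient_edges",
    "canny_edges",
    "apply_filter",
    "SOBEL_X",
    "SOBEL_Y",
    "PREWITT_X",
    "PREWITT_Y",
]

SOBEL_X = np.array([[-1, 0, 1], [-2, 0, 2], [-1, 0, 1]], dtype=float)
SOBEL_Y = SOBEL_X.T
PREWITT_X = np.array([[-1, 0, 1], [-1, 0, 1], [-1, 0, 1]], dtype=float)
PREWITT_Y = PREWITT_X.T
ROBERTS_X = np.array([[1, 0], [0, -1]], dtype=float)
ROBERTS_Y = np.array([[0, 1], [-1, 0]], dtype=float)

LAPLACE_4 = np.array([[0, 1, 0], [1, -4, 1], [0, 1, 0]], dtype=float)

#: default Gaussian width for Canny smoothing
CANNY_SIGMA = math.sqrt(2.0)
#: smoothed-Sobel-gradient filter Gaussian width
SMOOTHED_SOBEL_SIGMA = 1.0
#: sharpen strength (image - k * Laplacian)
SHARPEN_K = 1.0


@dataclass
class EdgeMap:
    """Binary edge image: values exactly {0, 1}."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        uniq = np.unique(px)
        if not np.isin(uniq, (0, 1)).all():
            raise ValueError("EdgeMap values must be exactly {0, 1}")
        self.pixels = px.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class GradientField:
    gx: np.ndarray
    gy: np.ndarray
    magnitude: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        if self.magnitude is None:
            self.magnitude = np.hypot(self.gx, self.gy)


def _correlate(arr: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    return ndimage.correlate(arr, kernel, mode="nearest")


def gradient_edges(
    img: GrayImage,
    operator: str = "sobel",
    threshold: float | None = None,
) -> tuple[GradientField, EdgeMap]:
    """First-derivative edge detection with a named kernel pair.

    Returns the gradient field and the thresholded binary map
    (magnitude >= threshold).  ``threshold=None`` selects the automatic
    rule threshold = 4 * mean(magnitude).
    """
    a = np.asarray(img.pixels, dtype=float)
    kernels = {
        "prewitt": (PREWITT_X, PREWITT_Y, 3),
        "sobel": (SOBEL_X, SOBEL_Y, 3),
        "roberts": (ROBERTS_X, ROBERTS_Y, 2),
    }
    if operator not in kernels:
        raise ValueError(f"unknown operator {operator!r}; choose from {sorted(kernels)}")
    kx, ky, min_side = kernels[operator]
    if min(a.shape) < min_side:
        raise ValueError(f"image too small for {operator}: need side >= {min_side}")
    gx = _correlate(a, kx)
    gy = _correlate(a, ky)
    grad = GradientField(gx=gx, gy=gy)
    if threshold is None:
        threshold = 4.0 * grad.magnitude.mean()
    edges = EdgeMap((grad.magnitude >= threshold) & (grad.magnitude > 0))
    return grad, edges


def _nms(mag: np.ndarray, gx: np.ndarray, gy: np.ndarray) -> np.ndarray:
    """Non-maximum suppression along the quantized (4-way) gradient direction."""
    m, n = mag.shape
    ang = np.rad2deg(np.arctan2(gy, gx)) % 180.0
    # quantize: 0 = E/W, 45 = NE/SW, 90 = N/S, 135 = NW/SE
    sector = np.zeros((m, n), dtype=np.int8)
    sector[(ang >= 22.5) & (ang < 67.5)] = 1
    sector[(ang >= 67.5) & (ang < 112.5)] = 2
    sector[(ang >= 112.5) & (ang < 157.5)] = 3
    padded = np.pad(mag, 1, mode="constant")
    offs = {0: ((0, 1), (0, -1)), 1: ((-1, 1), (1, -1)), 2: ((-1, 0), (1, 0)), 3: ((-1, -1), (1, 1))}
    out = np.zeros_like(mag)
    rr, cc = np.mgrid[0:m, 0:n]
    for s, ((dr1, dc1), (dr2, dc2)) in offs.items():
        sel = sector == s
        n1 = padded[rr + 1 + dr1, cc + 1 + dc1]
        n2 = padded[rr + 1 + dr2, cc + 1 + dc2]
        keep = sel & (mag > n1) & (mag >= n2) & (mag > 0)
        out[keep] = mag[keep]
    return out


def canny_edges(
    img: GrayImage,
    sigma: float = CANNY_SIGMA,
    low: float | None = None,
    high: float | None = None,
) -> EdgeMap:
    """Canny edge detection: Gaussian smoothing, Sobel gradient, quantized
    non-maximum suppression, and hysteresis linking.

    Automatic thresholds: ``high`` is the 70th percentile of the nonzero
    suppressed magnitudes and ``low = 0.4 * high`` (the MATLAB default
    ratio).  A final thinning pass guarantees 1-pixel-wide edges.
    """
    a = np.asarray(img.pixels, dtype=float)
    if min(a.shape) < 5:
        raise ValueError("canny needs side >= 5")
    sm = ndimage.gaussian_filter(a, sigma, mode="nearest")
    gx = _correlate(sm, SOBEL_X)
    gy = _correlate(sm, SOBEL_Y)
    mag = np.hypot(gx, gy)
    nms = _nms(mag, gx, gy)
    nz = nms[nms > 0]
    if nz.size == 0:
        return EdgeMap(np.zeros_like(a, dtype=np.uint8))
    if high is None:
        high = float(np.percentile(nz, 70))
    if low is None:
        low = 0.4 * high
    if low > high:
        raise ValueError(f"low threshold {low} exceeds high threshold {high}")
    weak = nms >= low
    strong = nms >= high
    # hysteresis: keep weak components containing at least one strong pixel
    labels, nlab = ndimage.label(weak, structure=np.ones((3, 3)))
    if nlab == 0:
        return EdgeMap(np.zeros_like(a, dtype=np.uint8))
    keep_ids = np.unique(labels[strong])
    keep_ids = keep_ids[keep_ids > 0]
    keep = np.isin(labels, keep_ids)
    return EdgeMap(_thin(keep))


def apply_filter(img: GrayImage, name: str) -> GrayImage:
    """Enhancement filters: laplace, sobel_gradient, smoothed_sobel_gradient,
    sharpen.

    Response-type filters (laplace and the Sobel magnitudes) are rescaled to
    the image's value range; sharpen subtracts the raw Laplacian from the
    image and clips.
    """
    a = np.asarray(img.pixels, dtype=float)
    if min(a.shape) < 3:
        raise ValueError("filters need side >= 3")
    vr = img.value_range

    def rescale(resp: np.ndarray) -> np.ndarray:
        mx = resp.max()
        return resp * (vr / mx) if mx > 0 else resp

    if name == "laplace":
        out = rescale(np.abs(_correlate(a, LAPLACE_4)))
    elif name == "sobel_gradient":
        out = rescale(np.hypot(_correlate(a, SOBEL_X), _correlate(a, SOBEL_Y)))
    elif name == "smoothed_sobel_gradient":
        sm = ndimage.gaussian_filter(a, SMOOTHED_SOBEL_SIGMA, mode="nearest")
        out = rescale(np.hypot(_correlate(sm, SOBEL_X), _correlate(sm, SOBEL_Y)))
    elif name == "sharpen":
        out = np.clip(a - SHARPEN_K * _correlate(a, LAPLACE_4), 0, vr)
    else:
        raise ValueError(f"unknown filter {name!r}")
    return GrayImage(np.clip(out, 0, vr), value_range=vr, provenance=img.provenance)


def laplacian_raw(img: GrayImage) -> np.ndarray:
    """Unscaled 4-neighbor Laplacian response (replicate borders)."""
    return _correlate(np.asarray(img.pixels, dtype=float), LAPLACE_4)
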