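"""Fuzzy edge maps and fuzzy edge linking.

A fuzzy edge map grades each pixel's edge evidence in [0, 1] instead of
forcing a binary decision: the Sobel gradient magnitude of the Gaussian
smoothed image is normalized and passed through an S-shaped membership
function.  Linking then keeps weak evidence only where it is connected to
strong evidence (hysteresis) and bridges small gaps between edge endpoints,
producing a more continuous boundary while preserving the graded values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.draw import line as _draw_line

from .classical import SOBEL_X, SOBEL_Y, _correlate
from .image_io import GrayImage

__all__ = ["FuzzyEdgeMap", "s_function", "fuzzy_edge_map", "link_fuzzy_edges"]

#: Gaussian smoothing width (pixels) before the gradient
DEFAULT_SIGMA = 1.5
#: hysteresis thresholds and maximum bridgeable gap (Chebyshev pixels)
DEFAULT_T_HIGH = 0.7
DEFAULT_T_LOW = 0.3
DEFAULT_MAX_GAP = 3

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass
class FuzzyEdgeMap:
    """Graded edge evidence: ``mu`` in [0, 1], same shape as the source."""

    mu: np.ndarray

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        if self.mu.ndim != 2:
            raise ValueError("FuzzyEdgeMap needs a 2-D grid")
        if self.mu.min() < 0 or self.mu.max() > 1:
            raise ValueError("memberships must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mu.shape


def s_function(x: np.ndarray, a: float, b: float) -> np.ndarray:
    """The standard S-shaped membership function on [a, b].

    0 below ``a``, 1 above ``b``, with two quadratic pieces meeting at the
    crossover (a+b)/2.  Non-decreasing for b > a.
    """
    if b <= a:
        raise ValueError("s_function requires b > a")
    x = np.asarray(x, dtype=float)
    mid = 0.5 * (a + b)
    out = np.zeros_like(x)
    lo = (x > a) & (x <= mid)
    hi = (x > mid) & (x < b)
    out[lo] = 2.0 * ((x[lo] - a) / (b - a)) ** 2
    out[hi] = 1.0 - 2.0 * ((b - x[hi]) / (b - a)) ** 2
    out[x >= b] = 1.0
    return out


def fuzzy_edge_map(
    img: GrayImage,
    sigma: float = DEFAULT_SIGMA,
    a: float = 0.05,
    b: float | None = None,
) -> FuzzyEdgeMap:
    """Graded edge evidence from smoothed-gradient magnitude.

    The normalized gradient g in [0, 1] is mapped through ``s_function``;
    ``b`` defaults to mean + std of the positive normalized gradients,
    capped at 1, so the upper knee adapts to the image's contrast.  The
    endpoints are pinned: g = 0 maps to 0 and g = 1 maps to 1.
    """
    arr = np.asarray(img.pixels, dtype=float)
    if min(arr.shape) < 5:
        raise ValueError("fuzzy_edge_map needs side >= 5")
    sm = ndimage.gaussian_filter(arr, sigma, mode="nearest")
    g = np.hypot(_correlate(sm, SOBEL_X), _correlate(sm, SOBEL_Y))
    gmax = g.max()
    if gmax <= 0:
        return FuzzyEdgeMap(np.zeros_like(arr))
    g = g / gmax
    if b is None:
        pos = g[g > 0]
        b = min(1.0, float(pos.mean() + pos.std()))
    b = max(b, a + 1e-9)
    mu = s_function(g, a, b)
    # endpoint contract: the extreme gradients map exactly to 0 and 1
    mu[g >= 1.0] = 1.0
    mu[g <= 0.0] = 0.0
    return FuzzyEdgeMap(np.clip(mu, 0.0, 1.0))


def _endpoints(keep: np.ndarray) -> np.ndarray:
    """Pixels of the keep-set with at most one 8-neighbor in the set."""
    nbrs = ndimage.convolve(keep.astype(int), _EIGHT, mode="constant") - keep
    return np.argwhere(keep & (nbrs <= 1))


def link_fuzzy_edges(
    fmap: FuzzyEdgeMap,
    t_low: float = DEFAULT_T_LOW,
    t_high: float = DEFAULT_T_HIGH,
    max_gap: int = DEFAULT_MAX_GAP,
) -> FuzzyEdgeMap:
    """Hysteresis keep + deterministic gap bridging.

    (i) keep pixels with mu >= t_low that are 8-connected to a pixel with
    mu >= t_high; (ii) join pairs of keep-set endpoints within Chebyshev
    distance max_gap by the discrete line between them, giving bridged
    pixels the smaller of the two endpoint memberships; (iii) zero out
    everything else.  Kept memberships are never amplified.
    """
    if not 0 <= t_low <= t_high <= 1:
        raise ValueError("need 0 <= t_low <= t_high <= 1")
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    mu = fmap.mu
    weak = mu >= t_low
    strong = mu >= t_high
    labels, nlab = ndimage.label(weak, structure=_EIGHT)
    out = np.zeros_like(mu)
    if nlab == 0:
        return FuzzyEdgeMap(out)
    keep_ids = np.unique(labels[strong])
    keep_ids = keep_ids[keep_ids > 0]
    keep = np.isin(labels, keep_ids)
    out[keep] = mu[keep]
    if max_gap > 0 and keep.any():
        eps = _endpoints(keep)
        for i in range(len(eps)):
            r0, c0 = eps[i]
            for j in range(i + 1, len(eps)):
                r1, c1 = eps[j]
                d = max(abs(int(r1) - int(r0)), abs(int(c1) - int(c0)))
                if 1 < d <= max_gap:
                    rr, cc = _draw_line(int(r0), int(c0), int(r1), int(c1))
                    bridge_mu = min(mu[r0, c0], mu[r1, c1])
                    out[rr, cc] = np.maximum(out[rr, cc], np.where(keep[rr, cc], out[rr, cc], bridge_mu))
    return FuzzyEdgeMap(out)
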