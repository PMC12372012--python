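"""Fuzzy confusion metrics and the distance-weighted fuzzy index (FI).

Edge maps are compared as fuzzy sets over the pixel grid: a reference map
Ni (conventionally a Canny edge image) and a detected map Nd, both with
memberships in [0, 1].  Pixelwise,

    FTP = min(Ni, Nd)        (fuzzy intersection — true-positive mass)
    FFP = max(0, Ni - Nd)    (bounded difference Ni minus Nd)
    FFN = max(0, Nd - Ni)    (bounded difference Nd minus Ni)

and scalar cardinalities |X| are the grid sums.  These definitions give the
exact identities |FTP| + |FFP| = |Ni| and |FTP| + |FFN| = |Nd|.  Note the
FFP/FFN naming follows the bounded-difference formulas above, with Ni the
reference: "FFP" is reference mass unmatched by the detection, which is
opposite to the everyday false-positive reading.  We keep the formula
semantics rather than renaming.

The fuzzy index weights the true-positive mass by proximity to the detected
support (a Pratt figure-of-merit style 1/(1+d) weight):

    FI = ( |FTP| * sum_ij 1/(1 + FD(i,j)) - |FFP| - |FFN| )
         / ( m * n * max(|Ni|, |Nd|) ),

where FD is the Euclidean distance from each pixel to the nearest detected
pixel, normalized by maxD = sqrt((m-1)^2 + (n-1)^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image_io import GrayImage

__all__ = [
    "MembershipImage",
    "FuzzyConfusion",
    "FuzzyDistanceField",
    "to_membership",
    "fuzzy_confusion",
    "fuzzy_distance_field",
    "fuzzy_index",
    "percent_summary",
    "evaluate_pair",
]


@dataclass
class MembershipImage:
    """A fuzzy set over the pixel grid: values in [0, 1]."""

    values: np.ndarray
    role: str = "detected"  # or "reference"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("MembershipImage needs a 2-D grid")
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("memberships must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class FuzzyConfusion:
    ftp_map: np.ndarray
    ffp_map: np.ndarray
    ffn_map: np.ndarray
    card_ftp: float
    card_ffp: float
    card_ffn: float
    card_ni: float
    card_nd: float
    fi: float | None = None
    pct_ftp: float | None = None
    pct_ffp: float | None = None
    pct_ffn: float | None = None


@dataclass
class FuzzyDistanceField:
    fd: np.ndarray
    maxD: float


def _card(x: np.ndarray) -> float:
    # compensated, order-independent summation
    return float(math.fsum(x.ravel().tolist()))


def to_membership(img, role: str = "detected") -> MembershipImage:
    """Normalize an image or edge map to membership values in [0, 1]."""
    if isinstance(img, MembershipImage):
        return MembershipImage(img.values, role)
    if isinstance(img, GrayImage):
        return MembershipImage(img.pixels / img.value_range, role)
    if hasattr(img, "mu"):  # FuzzyEdgeMap
        return MembershipImage(np.asarray(img.mu, dtype=float), role)
    if hasattr(img, "pixels"):  # EdgeMap or raw container
        px = np.asarray(img.pixels, dtype=float)
        vr = px.max() if px.max() > 1 else 1.0
        return MembershipImage(px / vr, role)
    return MembershipImage(np.asarray(img, dtype=float), role)


def fuzzy_confusion(ni: MembershipImage, nd: MembershipImage) -> FuzzyConfusion:
    """Pixelwise FTP/FFP/FFN maps and their scalar cardinalities."""
    if ni.shape != nd.shape:
        raise ValueError(f"shape mismatch: {ni.shape} vs {nd.shape}")
    a, b = ni.values, nd.values
    ftp = np.minimum(a, b)
    ffp = np.maximum(0.0, a - b)
    ffn = np.maximum(0.0, b - a)
    return FuzzyConfusion(
        ftp_map=ftp,
        ffp_map=ffp,
        ffn_map=ffn,
        card_ftp=_card(ftp),
        card_ffp=_card(ffp),
        card_ffn=_card(ffn),
        card_ni=_card(a),
        card_nd=_card(b),
    )


def fuzzy_distance_field(
    nd: MembershipImage, support_threshold: float = 0.0
) -> FuzzyDistanceField:
    """Normalized distance from every pixel to the nearest detected pixel.

    The detected support is {nd > support_threshold}; distances are
    Euclidean and divided by maxD = sqrt((m-1)^2 + (n-1)^2), so fd is 0 on
    the support and at most 1 anywhere on the grid.
    """
    m, n = nd.shape
    support = nd.values > support_threshold
    if not support.any():
        raise ValueError("no detected edges: empty support")
    max_d = math.hypot(m - 1, n - 1)
    dist = ndimage.distance_transform_edt(~support)
    return FuzzyDistanceField(fd=dist / max_d, maxD=max_d)


def fuzzy_index(
    ni: MembershipImage, nd: MembershipImage, fd: FuzzyDistanceField
) -> float:
    """The distance-weighted fuzzy agreement index (see module docstring)."""
    if ni.shape != nd.shape or fd.fd.shape != ni.shape:
        raise ValueError("shape mismatch between images and distance field")
    conf = fuzzy_confusion(ni, nd)
    denom_card = max(conf.card_ni, conf.card_nd)
    if denom_card <= 0:
        raise ValueError("fuzzy index undefined: both images are identically zero")
    m, n = ni.shape
    weight_sum = _card(1.0 / (1.0 + fd.fd))
    return (conf.card_ftp * weight_sum - conf.card_ffp - conf.card_ffn) / (
        m * n * denom_card
    )


def percent_summary(conf: FuzzyConfusion, m: int, n: int) -> tuple[float, float, float]:
    """Cardinalities as percentages of the pixel count: 100 * |X| / (m*n)."""
    area = m * n
    return (
        100.0 * conf.card_ftp / area,
        100.0 * conf.card_ffp / area,
        100.0 * conf.card_ffn / area,
    )


def evaluate_pair(
    ni: MembershipImage, nd: MembershipImage, support_threshold: float = 0.0
) -> FuzzyConfusion:
    """Full evaluation of a detected map against a reference: confusion
    maps, cardinalities, percent summaries and the fuzzy index."""
    conf = fuzzy_confusion(ni, nd)
    fd = fuzzy_distance_field(nd, support_threshold)
    conf.fi = fuzzy_index(ni, nd, fd)
    m, n = ni.shape
    conf.pct_ftp, conf.pct_ffp, conf.pct_ffn = percent_summary(conf, m, n)
    return conf
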