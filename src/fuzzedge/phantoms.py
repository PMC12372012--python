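"""Synthetic square phantoms with analytically known edges and regions.

Every downstream stage (edge operators, ACO, fuzzy linking, clustering,
metrics) is exercised against these images, whose true boundary pixels and
region labels are known by construction.  The noise model is additive
Gaussian clipped to [0, 255], a standard stand-in for MRI test images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .image_io import GrayImage

__all__ = [
    "PhantomTruth",
    "make_step_image",
    "make_disk_phantom",
    "make_tissue_phantom",
]


@dataclass
class PhantomTruth:
    """A phantom image plus its analytic ground truth.

    ``true_edge_set`` holds (row, col) pixels on the ideal boundary;
    ``true_labels`` is a region-id grid used by clustering tests.
    """

    image: GrayImage
    true_edge_set: set[tuple[int, int]]
    true_labels: np.ndarray

    def edge_mask(self) -> np.ndarray:
        """Binary mask of the true edge set, same shape as the image."""
        mask = np.zeros(self.image.shape, dtype=bool)
        for r, c in self.true_edge_set:
            mask[r, c] = True
        return mask


def _add_noise(img: np.ndarray, noise_sd: float, rng: np.random.Generator) -> np.ndarray:
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    return np.clip(img, 0.0, 255.0)


def make_step_image(
    side: int,
    step_col: int,
    low: float,
    high: float,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> PhantomTruth:
    """Vertical intensity step: columns < step_col at ``low``, rest at ``high``.

    The true edge set is the two columns adjacent to the step
    (step_col - 1 and step_col).
    """
    if side < 8:
        raise ValueError("side must be >= 8")
    if not 0 < step_col < side:
        raise ValueError(f"step_col must be in (0, {side}), got {step_col}")
    rng = np.random.default_rng(seed)
    img = np.full((side, side), float(low))
    img[:, step_col:] = high
    labels = (np.arange(side)[None, :] >= step_col).astype(np.int32)
    labels = np.broadcast_to(labels, (side, side)).copy()
    edges = {(r, c) for r in range(side) for c in (step_col - 1, step_col)}
    return PhantomTruth(
        image=GrayImage(_add_noise(img, noise_sd, rng), 255.0, "phantom:step"),
        true_edge_set=edges,
        true_labels=labels,
    )


def make_disk_phantom(
    side: int,
    center: tuple[float, float],
    radius: float,
    inside: float,
    outside: float,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> PhantomTruth:
    """Filled disk of intensity ``inside`` on an ``outside`` background.

    The true edge set is every pixel whose distance to the circle of the
    given radius is < 1.  The disk must lie fully inside the image.
    """
    if side < 8:
        raise ValueError("side must be >= 8")
    cr, cc = center
    if radius >= side / 2:
        raise ValueError("radius must be < side/2")
    if cr - radius < 0 or cc - radius < 0 or cr + radius > side - 1 or cc + radius > side - 1:
        raise ValueError("disk exceeds image bounds")
    rng = np.random.default_rng(seed)
    rr, cc_grid = np.mgrid[0:side, 0:side]
    dist = np.hypot(rr - cr, cc_grid - cc)
    img = np.where(dist <= radius, float(inside), float(outside))
    labels = (dist <= radius).astype(np.int32)
    on_circle = np.abs(dist - radius) < 1.0
    edges = set(zip(*np.nonzero(on_circle)))
    edges = {(int(r), int(c)) for r, c in edges}
    return PhantomTruth(
        image=GrayImage(_add_noise(img, noise_sd, rng), 255.0, "phantom:disk"),
        true_edge_set=edges,
        true_labels=labels,
    )


def make_tissue_phantom(
    side: int,
    region_intensities: list[float],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> PhantomTruth:
    """Nested elliptical regions of distinct mean intensity.

    Region 0 is the background (outermost); successive intensities fill
    shrinking concentric ellipses, mimicking nested tissue compartments
    (e.g. edema around a tumor core).  ``true_labels`` gives the region id
    per pixel; the true edge set is the union of all region boundaries.
    """
    if side < 8:
        raise ValueError("side must be >= 8")
    k = len(region_intensities)
    if not 2 <= k <= 6:
        raise ValueError("need 2-6 region intensities")
    if len(set(region_intensities)) != k:
        raise ValueError("region intensities must be pairwise distinct")
    rng = np.random.default_rng(seed)
    rr, cc = np.mgrid[0:side, 0:side]
    c0 = (side - 1) / 2.0
    # normalized elliptical radius; slight anisotropy so regions are ellipses
    er = np.sqrt(((rr - c0) / (0.49 * side)) ** 2 + ((cc - c0) / (0.46 * side)) ** 2)
    labels = np.zeros((side, side), dtype=np.int32)
    img = np.full((side, side), float(region_intensities[0]))
    # region j (j >= 1) occupies er <= radius_j; radii chosen so the nested
    # annuli split the ellipse into equal areas, keeping region populations
    # comparable for clustering tests
    radii = [math.sqrt((k - j) / (k - 1)) for j in range(1, k)]
    for j, rad in enumerate(radii, start=1):
        inside = er <= rad
        labels[inside] = j
        img[inside] = region_intensities[j]
    # boundary pixels: any pixel with a 4-neighbor in a different region
    edge_mask = np.zeros((side, side), dtype=bool)
    edge_mask[:-1, :] |= labels[:-1, :] != labels[1:, :]
    edge_mask[1:, :] |= labels[1:, :] != labels[:-1, :]
    edge_mask[:, :-1] |= labels[:, :-1] != labels[:, 1:]
    edge_mask[:, 1:] |= labels[:, 1:] != labels[:, :-1]
    edges = {(int(r), int(c)) for r, c in zip(*np.nonzero(edge_mask))}
    return PhantomTruth(
        image=GrayImage(_add_noise(img, noise_sd, rng), 255.0, "phantom:tissue"),
        true_edge_set=edges,
        true_labels=labels,
    )
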