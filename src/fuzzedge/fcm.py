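"""Contrast enhancement and fuzzy C-means (FCM) intensity clustering.

FCM partitions the image into k soft tissue classes by minimizing

    J = sum_p sum_k u_pk^f (x_p - v_k)^2,

where x_p are pixel intensities, v_k the cluster centers and f > 1 the
fuzzifier controlling membership softness.  Clustering runs on the 1-D
intensity feature only; since many pixels share an intensity, the updates
are computed on the unique intensity values weighted by their pixel counts,
which is algebraically identical to per-pixel FCM but much faster.
Clusters are reported in ascending center order so "cluster 1..k" is
reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .image_io import GrayImage

__all__ = ["FCMResult", "enhance_image", "fcm_cluster", "memberships_to_labels"]

DEFAULT_K = 4
DEFAULT_FUZZIFIER = 2.0
DEFAULT_TOL = 1e-5
DEFAULT_MAX_ITER = 200


@dataclass
class FCMResult:
    memberships: np.ndarray  # (k, m*n), columns sum to 1
    centers: np.ndarray      # (k,) ascending
    labels: np.ndarray       # (m, n) argmax cluster ids
    objective_trace: list[float]
    iterations_used: int
    shape: tuple[int, int]


def enhance_image(img: GrayImage, p_low: float = 1.0, p_high: float = 99.0) -> GrayImage:
    """Linear contrast stretch mapping the [p_low, p_high] intensity
    percentiles onto [0, value_range], clipping the tails."""
    if p_low >= p_high:
        raise ValueError("p_low must be < p_high")
    a = np.asarray(img.pixels, dtype=float)
    lo, hi = np.percentile(a, [p_low, p_high])
    if hi <= lo:
        warnings.warn("constant image: enhancement is a no-op", stacklevel=2)
        return GrayImage(a.copy(), img.value_range, img.provenance)
    out = np.clip((a - lo) / (hi - lo) * img.value_range, 0, img.value_range)
    return GrayImage(out, img.value_range, img.provenance)


def _objective(d2: np.ndarray, um: np.ndarray, w: np.ndarray) -> float:
    return float(np.sum(w[None, :] * um * d2))


def fcm_cluster(
    img: GrayImage,
    k: int = DEFAULT_K,
    fuzzifier: float = DEFAULT_FUZZIFIER,
    tol: float = DEFAULT_TOL,
    max_iter: int = DEFAULT_MAX_ITER,
    seed: int = 0,
) -> FCMResult:
    """Fuzzy C-means on pixel intensities with alternating updates.

    Centers are initialized at evenly spaced intensity quantiles, jittered
    by up to +-1% of the range from ``seed`` to break symmetry; iteration
    stops when the largest center shift drops below ``tol`` or after
    ``max_iter`` rounds.  Pixels coinciding exactly with a center receive
    crisp membership there.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if fuzzifier <= 1:
        raise ValueError("fuzzifier must be > 1")
    a = np.asarray(img.pixels, dtype=float)
    m, n = a.shape
    flat = a.ravel()
    xs, inverse, counts = np.unique(flat, return_inverse=True, return_counts=True)
    if k > xs.size:
        raise ValueError(f"k={k} exceeds the {xs.size} distinct intensities")
    w = counts.astype(float)

    rng = np.random.default_rng(seed)
    qs = (np.arange(k) + 0.5) / k
    centers = np.quantile(flat, qs)
    span = float(flat.max() - flat.min())
    centers = centers + rng.uniform(-0.01, 0.01, size=k) * span
    expo = 1.0 / (fuzzifier - 1.0)

    trace: list[float] = []
    iters = 0
    u = np.ones((k, xs.size)) / k
    for iters in range(1, max_iter + 1):
        d2 = (xs[None, :] - centers[:, None]) ** 2
        # membership update with the crisp convention at zero distance
        zero = d2 <= 0
        any_zero = zero.any(axis=0)
        with np.errstate(divide="ignore"):
            inv = d2 ** (-expo)
        u = inv / inv.sum(axis=0, keepdims=True)
        if any_zero.any():
            u[:, any_zero] = 0.0
            first = zero.argmax(axis=0)
            u[first[any_zero], np.nonzero(any_zero)[0]] = 1.0
        um = u**fuzzifier
        new_centers = (um * (w * xs)[None, :]).sum(axis=1) / (um * w[None, :]).sum(axis=1)
        trace.append(_objective((xs[None, :] - new_centers[:, None]) ** 2, um, w))
        shift = np.abs(new_centers - centers).max()
        centers = new_centers
        if shift < tol:
            break

    order = np.argsort(centers)
    centers = centers[order]
    u = u[order]
    memberships = u[:, inverse]
    labels = memberships.argmax(axis=0).reshape(m, n)
    return FCMResult(
        memberships=memberships,
        centers=centers,
        labels=labels,
        objective_trace=trace,
        iterations_used=iters,
        shape=(m, n),
    )


def memberships_to_labels(result: FCMResult) -> tuple[np.ndarray, list[np.ndarray]]:
    """Argmax label image (ties go to the lowest cluster id) and per-cluster
    binary masks that partition the image."""
    k = result.memberships.shape[0]
    labels = result.memberships.argmax(axis=0).reshape(result.shape)
    masks = [labels == j for j in range(k)]
    return labels, masks
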