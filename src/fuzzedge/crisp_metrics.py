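"""Crisp edge-map and image comparison metrics.

Binary confusion metrics (precision, recall, F1, Jaccard, Dice, accuracy),
mean structural similarity (SSIM, MATLAB-compatible constants) and the
maximum zero-normalized cross-correlation over integer shifts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity as _ssim

from .classical import EdgeMap
from .image_io import GrayImage

__all__ = ["BinaryComparison", "binary_confusion_metrics", "ssim_index", "max_ncc"]


@dataclass
class BinaryComparison:
    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    jaccard: float
    dice: float
    edge_pct_a: float
    edge_pct_b: float


def _as_bool(x) -> np.ndarray:
    px = x.pixels if isinstance(x, EdgeMap) else np.asarray(x)
    uniq = np.unique(px)
    if not np.isin(uniq, (0, 1)).all():
        raise ValueError("binary metrics need {0,1} masks")
    return px.astype(bool)


def binary_confusion_metrics(a, b) -> BinaryComparison:
    """Confusion counts and overlap metrics for truth mask ``a`` vs
    prediction ``b``.

    Empty-denominator conventions: all ratio metrics are 1 when both masks
    are empty and 0 when exactly one is empty.
    """
    ta, tb = _as_bool(a), _as_bool(b)
    if ta.shape != tb.shape:
        raise ValueError(f"shape mismatch: {ta.shape} vs {tb.shape}")
    tp = int(np.sum(ta & tb))
    fp = int(np.sum(~ta & tb))
    fn = int(np.sum(ta & ~tb))
    tn = int(np.sum(~ta & ~tb))
    total = ta.size
    if ta.sum() == 0 and tb.sum() == 0:
        p = r = f1 = j = d = 1.0
    else:
        p = tp / (tp + fp) if tp + fp else 0.0
        r = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * p * r / (p + r) if p + r else 0.0
        j = tp / (tp + fp + fn) if tp + fp + fn else 0.0
        d = 2 * tp / (2 * tp + fp + fn) if 2 * tp + fp + fn else 0.0
    return BinaryComparison(
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        accuracy=(tp + tn) / total,
        precision=p,
        recall=r,
        f1=f1,
        jaccard=j,
        dice=d,
        edge_pct_a=100.0 * ta.sum() / total,
        edge_pct_b=100.0 * tb.sum() / total,
    )


def ssim_index(a: GrayImage, b: GrayImage) -> float:
    """Mean local SSIM with an 11x11 Gaussian window (sigma 1.5),
    K1 = 0.01, K2 = 0.03 and the declared value range as dynamic range."""
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    if min(a.shape) < 11:
        raise ValueError("ssim needs side >= 11")
    if a.value_range != b.value_range:
        raise ValueError("value ranges differ")
    return float(
        _ssim(
            a.pixels,
            b.pixels,
            win_size=11,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            K1=0.01,
            K2=0.03,
            data_range=a.value_range,
        )
    )


def max_ncc(a: GrayImage, b: GrayImage, min_overlap: float = 0.25) -> float:
    """Maximum zero-normalized cross-correlation over integer shifts.

    Each shift's overlap region is mean-centered and re-normalized; shifts
    covering less than ``min_overlap`` of the grid are skipped.  Inputs must
    have nonzero variance.
    """
    x = np.asarray(a.pixels, dtype=float)
    y = np.asarray(b.pixels, dtype=float)
    if x.shape != y.shape:
        raise ValueError("shape mismatch")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("undefined correlation: zero-variance input")
    m, n = x.shape
    need = min_overlap * m * n
    best = -1.0
    max_dr = int(m - np.ceil(need / n))
    max_dc = int(n - np.ceil(need / m))
    for dr in range(-max_dr, max_dr + 1):
        r0a, r1a = max(0, dr), min(m, m + dr)
        r0b, r1b = max(0, -dr), min(m, m - dr)
        for dc in range(-max_dc, max_dc + 1):
            c0a, c1a = max(0, dc), min(n, n + dc)
            c0b, c1b = max(0, -dc), min(n, n - dc)
            if (r1a - r0a) * (c1a - c0a) < need:
                continue
            xa = x[r0a:r1a, c0a:c1a]
            yb = y[r0b:r1b, c0b:c1b]
            xa = xa - xa.mean()
            yb = yb - yb.mean()
            denom = np.sqrt((xa * xa).sum() * (yb * yb).sum())
            if denom == 0:
                continue
            best = max(best, float((xa * yb).sum() / denom))
    return best
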