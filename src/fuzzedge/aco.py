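"""Ant colony optimization (ACO) edge extraction.

Artificial ants walk the pixel grid, preferring moves onto pixels with high
pheromone ``tau`` and high local intensity variation ``eta``; pheromone
deposited along their paths accumulates on intensity discontinuities.  The
transition weight for a candidate neighbor is ``tau^alpha * eta^beta``.
Four heuristic kernels (kh, chi, sin, pow) reshape the normalized variation
before it enters the transition rule; they are pluggable so alternative
operator families can be swapped in.

Default parameterization: 4 optimization stages of 1536 iterations each,
initial pheromone 0.0001, (alpha, beta) = (1, 0.01), local evaporation rate
0.1, global decay coefficient 0.001; the stopping criterion is reaching the
maximum number of iterations.  Stages are sequential restarts of the ant
positions sharing one pheromone field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .classical import EdgeMap
from .image_io import GrayImage

__all__ = [
    "ACOConfig",
    "PheromoneField",
    "HeuristicKernel",
    "KERNELS",
    "default_aco_config",
    "heuristic_field",
    "run_aco",
    "pheromone_to_edges",
]

#: kernel shape parameter lambda
KERNEL_LAMBDA = 10.0
#: length of each ant's tabu memory (recently visited pixels)
TABU_LENGTH = 8


@dataclass(frozen=True)
class HeuristicKernel:
    """A non-decreasing shape function f: [0,1] -> [0,inf) with f(0) = 0."""

    name: str
    f: callable

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.f(np.asarray(x, dtype=float))


def _chi(x: np.ndarray, lam: float = KERNEL_LAMBDA) -> np.ndarray:
    # x * exp(-x^2 / 2 lam), rescaled so the peak over [0,1] equals 1
    raw = x * np.exp(-(x**2) / (2.0 * lam))
    peak = 1.0 * math.exp(-1.0 / (2.0 * lam))  # monotone on [0,1] since sqrt(lam) > 1
    return raw / peak


KERNELS: dict[str, HeuristicKernel] = {
    "kh": HeuristicKernel("kh", lambda x: KERNEL_LAMBDA * x),
    "chi": HeuristicKernel("chi", _chi),
    "sin": HeuristicKernel("sin", lambda x: np.sin(np.pi * x / 2.0)),
    "pow": HeuristicKernel("pow", lambda x: (KERNEL_LAMBDA * x) ** 2),
}


@dataclass
class ACOConfig:
    stages: int = 4
    iterations_per_stage: int = 1536
    n_ants: int | None = None  # None -> floor(sqrt(m*n))
    tau0: float = 0.0001
    alpha: float = 1.0
    beta: float = 0.01
    rho_local: float = 0.1
    rho_global: float = 0.001
    kernel: str = "kh"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.rho_local < 1 and 0 < self.rho_global < 1):
            raise ValueError("evaporation/decay rates must be in (0, 1)")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("exponents must be >= 0")
        if self.tau0 <= 0:
            raise ValueError("tau0 must be > 0")
        if self.kernel not in KERNELS:
            raise ValueError(f"unknown kernel {self.kernel!r}; choose from {sorted(KERNELS)}")


@dataclass
class PheromoneField:
    """Per-pixel trail intensity; entries clamped to a floor of tau0 * 1e-3."""

    tau: np.ndarray
    tau0: float = 0.0001

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=float)
        floor = self.tau0 * 1e-3
        np.maximum(self.tau, floor, out=self.tau)


def default_aco_config(image_side: int, **overrides) -> ACOConfig:
    """The standard configuration for a square image of the given side.

    The number of ants defaults to floor(sqrt(m*n)) = image_side for square
    images, the convention of the classical ACO edge-detection literature.
    """
    if image_side < 8:
        raise ValueError("image_side must be >= 8")
    cfg = ACOConfig(n_ants=int(math.isqrt(image_side * image_side)))
    return replace(cfg, **overrides) if overrides else cfg


def heuristic_field(img: GrayImage) -> np.ndarray:
    """Normalized local intensity variation in [0, 1].

    V(i,j) is the maximum absolute intensity difference over the four
    symmetric pixel pairs of the 8-neighborhood (left-right, up-down and the
    two diagonals); the field is V / max V, or all zeros for a flat image.
    Differences make the field invariant to adding a constant intensity.
    """
    a = np.asarray(img.pixels, dtype=float)
    if min(a.shape) < 3:
        raise ValueError("heuristic_field needs side >= 3")
    p = np.pad(a, 1, mode="edge")
    pairs = [
        np.abs(p[1:-1, 2:] - p[1:-1, :-2]),  # E - W
        np.abs(p[2:, 1:-1] - p[:-2, 1:-1]),  # S - N
        np.abs(p[2:, 2:] - p[:-2, :-2]),     # SE - NW
        np.abs(p[2:, :-2] - p[:-2, 2:]),     # SW - NE
    ]
    v = np.maximum.reduce(pairs)
    vmax = v.max()
    return v / vmax if vmax > 0 else np.zeros_like(v)


_NEIGH = np.array(
    [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)],
    dtype=np.int64,
)


def run_aco(img: GrayImage, config: ACOConfig) -> tuple[PheromoneField, dict]:
    """Run the ant colony and return the final pheromone field.

    Per iteration every ant takes one step to an 8-neighbor sampled with
    probability proportional to ``tau^alpha * eta^beta`` (recently visited
    pixels excluded via a per-ant tabu list; an ant with no admissible move
    teleports to a uniformly random pixel).  After each move the visited
    pixel evaporates locally toward tau0; after each iteration the pixels
    visited in it receive the global update toward eta.  All randomness comes
    from one seeded generator, so equal seeds give bit-identical fields.
    """
    a = np.asarray(img.pixels, dtype=float)
    m, n = a.shape
    if m != n:
        raise ValueError("run_aco expects a square image (pad first)")
    rng = np.random.default_rng(config.seed)
    npix = m * n
    n_ants = config.n_ants if config.n_ants is not None else int(math.isqrt(npix))

    x = heuristic_field(img)
    diagnostics: dict = {"kernel": config.kernel, "mean_tau_trace": []}
    if x.max() <= 0:
        diagnostics["flat_image"] = True
        return PheromoneField(np.full((m, n), config.tau0), config.tau0), diagnostics

    eta = KERNELS[config.kernel](x)
    eta = eta / eta.max()
    eta_flat = eta.ravel()

    tau = np.full(npix, config.tau0, dtype=float)
    floor = config.tau0 * 1e-3
    dr, dc = _NEIGH[:, 0], _NEIGH[:, 1]

    for _stage in range(config.stages):
        pos = rng.integers(0, npix, size=n_ants)
        tabu = np.full((n_ants, TABU_LENGTH), -1, dtype=np.int64)
        for it in range(config.iterations_per_stage):
            r, c = pos // n, pos % n
            nr = r[:, None] + dr[None, :]
            nc = c[:, None] + dc[None, :]
            valid = (nr >= 0) & (nr < m) & (nc >= 0) & (nc < n)
            nidx = np.where(valid, nr * n + nc, 0)
            w = tau[nidx] ** config.alpha * eta_flat[nidx] ** config.beta
            w[~valid] = 0.0
            w[(nidx[:, :, None] == tabu[:, None, :]).any(axis=2)] = 0.0
            tot = w.sum(axis=1)
            u = rng.random(n_ants) * tot
            choice = (np.cumsum(w, axis=1) > u[:, None]).argmax(axis=1)
            new = nidx[np.arange(n_ants), choice]
            stuck = tot <= 0
            if stuck.any():
                new[stuck] = rng.integers(0, npix, size=int(stuck.sum()))
            # local evaporation on each visited pixel (once per visiting ant)
            visited, counts = np.unique(new, return_counts=True)
            shrink = (1.0 - config.rho_local) ** counts
            tau[visited] = tau[visited] * shrink + config.tau0 * (1.0 - shrink)
            # global update on this iteration's visited pixels
            tau[visited] = (1.0 - config.rho_global) * tau[visited] + config.rho_global * eta_flat[visited]
            np.maximum(tau, floor, out=tau)
            tabu[:, it % TABU_LENGTH] = new
            pos = new
        diagnostics["mean_tau_trace"].append(float(tau.mean()))
    return PheromoneField(tau.reshape(m, n), config.tau0), diagnostics


def pheromone_to_edges(field: PheromoneField) -> tuple[EdgeMap, dict]:
    """Binarize a pheromone field with the iterative mean-split threshold.

    T starts at mean(tau) and is refined to the midpoint of the class means
    below/above T until convergence (|dT| < 1e-8 or 100 rounds).  A constant
    field yields an empty map.
    """
    tau = field.tau
    diag: dict = {}
    if np.ptp(tau) == 0:
        diag["warning"] = "constant pheromone field; no edges"
        diag["threshold"] = float(tau.flat[0])
        return EdgeMap(np.zeros_like(tau, dtype=np.uint8)), diag
    t = float(tau.mean())
    trace = [t]
    for _ in range(100):
        lo = tau[tau < t]
        hi = tau[tau >= t]
        if lo.size == 0 or hi.size == 0:
            break
        t_new = 0.5 * (lo.mean() + hi.mean())
        trace.append(float(t_new))
        if abs(t_new - t) < 1e-8:
            t = t_new
            break
        t = t_new
    diag["threshold"] = t
    diag["threshold_trace"] = trace
    return EdgeMap(tau >= t), diag
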