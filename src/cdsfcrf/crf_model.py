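"""The cross-domain CRF energy and its analytic gradient.

The model couples two domains. The unary (data-fidelity) potential
lives in k-space: it penalizes the squared-magnitude residual between
the Fourier transform of the current estimate and the observed
coefficients, over sampled frequencies only. The pairwise potential
lives in the spatial domain: over a stochastically sampled set of
long-range pixel cliques, it penalizes ``1 - f`` with the guided
similarity kernel

    f(y_i, y_j, x_i, x_j) = exp(-(y_i - y_j)^2 (x_i - x_j)^2 / (3 sigma^2)),

where ``x`` is the zero-filled spatial observation acting as guide.
Minimizing the total energy therefore keeps the estimate consistent
with the measured k-space data while suppressing intensity differences
between pixel pairs whose guide values disagree — the undersampling
artifacts the zero-filled guide exposes.

Cliques are drawn once per reconstruction from a stochastic law that
favors nearby, similar-intensity pairs: each unordered pair {i, j}
within ``max_radius`` is included independently with probability

    P(i, j) = rho * exp(-d_ij^2 / (2 gamma^2)) * exp(-(g_i - g_j)^2 / (2 sigma^2)),

with the immediate 4-neighborhood always included so local connectivity
never vanishes at small rho.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import yaml

from .kspace_ops import KSpaceData, forward_transform, inverse_transform

__all__ = [
    "CRFConfig",
    "CliqueSet",
    "sample_cliques",
    "pairwise_feature",
    "unary_energy",
    "pairwise_energy",
    "total_energy",
    "energy_gradient",
]


@dataclass(frozen=True)
class CRFConfig:
    """Hyperparameters of the cross-domain CRF.

    Parameters
    ----------
    lambda_u : float
        Weight of the k-space data-fidelity term.
    lambda_p : float
        Weight of the spatial pairwise term.
    sigma : float
        Bandwidth of the pairwise kernel and of the guide-similarity
        factor of the clique law. The kernel argument is the product
        of the state and guide differences, so small values saturate
        the penalty at strong edges (preserving them) while smoothing
        low-amplitude undersampling artifacts.
    clique_gamma : float
        Spatial bandwidth of the clique-inclusion probability, pixels.
    clique_rho : float
        Density scale of the clique law, in (0, 1].
    max_radius : int or None
        Truncation radius for clique candidates, pixels; None means
        unbounded (every pair is a candidate).
    seed : int
        Seed for the clique sampler.
    """

    lambda_u: float = 1.0
    lambda_p: float = 0.01
    sigma: float = 0.004
    clique_gamma: float = 3.0
    clique_rho: float = 0.5
    max_radius: int | None = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lambda_u < 0 or self.lambda_p < 0:
            raise ValueError("lambda_u and lambda_p must be non-negative")
        if self.lambda_u + self.lambda_p <= 0:
            raise ValueError("at least one of lambda_u, lambda_p must be positive")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.clique_gamma <= 0:
            raise ValueError("clique_gamma must be positive")
        if not 0.0 < self.clique_rho <= 1.0:
            raise ValueError("clique_rho must lie in (0, 1]")
        if self.max_radius is not None and self.max_radius < 1:
            raise ValueError("max_radius must be >= 1 or None")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CRFConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


class CliqueSet:
    """Realized pairwise cliques as parallel arrays of flat pixel indices.

    Pairs are stored canonically with ``i < j``, deduplicated, with no
    self-pairs.
    """

    def __init__(self, i: np.ndarray, j: np.ndarray, shape: tuple[int, int]):
        i = np.asarray(i, dtype=np.int64).ravel()
        j = np.asarray(j, dtype=np.int64).ravel()
        if i.shape != j.shape:
            raise ValueError("index arrays must have equal length")
        n = shape[0] * shape[1]
        if i.size and (i.min() < 0 or j.min() < 0 or i.max() >= n or j.max() >= n):
            raise ValueError("clique index out of range for grid")
        if np.any(i == j):
            raise ValueError("self-pairs are not allowed")
        lo, hi = np.minimum(i, j), np.maximum(i, j)
        keys = np.unique(lo * n + hi)
        self.i = (keys // n).astype(np.int64)
        self.j = (keys % n).astype(np.int64)
        self.shape = tuple(shape)

    def __len__(self) -> int:
        return self.i.size

    def as_pair_set(self) -> set[tuple[int, int]]:
        return set(zip(self.i.tolist(), self.j.tolist()))

    def to_csv(self, path: str | Path) -> None:
        """Write the edge list as a two-column CSV (flat indices i, j)."""
        np.savetxt(
            path,
            np.column_stack([self.i, self.j]),
            fmt="%d",
            delimiter=",",
            header="i,j",
            comments="",
        )


def _half_plane_offsets(height: int, width: int, max_radius: int | None):
    """Canonical offsets (dy, dx) enumerating each unordered pair once."""
    if max_radius is None:
        ry, rx = height - 1, width - 1
        r2 = np.inf
    else:
        ry = rx = int(max_radius)
        r2 = float(max_radius) ** 2
    out = []
    for dy in range(0, ry + 1):
        xs = range(1, rx + 1) if dy == 0 else range(-rx, rx + 1)
        for dx in xs:
            if dy * dy + dx * dx <= r2:
                out.append((dy, dx))
    return out


def _offset_pairs(height: int, width: int, dy: int, dx: int):
    """Flat index arrays (i, j) of all in-grid pairs at offset (dy, dx)."""
    y0, y1 = 0, height - dy
    x0, x1 = max(0, -dx), min(width, width - dx)
    if y1 <= y0 or x1 <= x0:
        return None
    yy, xx = np.mgrid[y0:y1, x0:x1]
    i = (yy * width + xx).ravel()
    j = ((yy + dy) * width + (xx + dx)).ravel()
    return i, j


def sample_cliques(
    height: int, width: int, guide: np.ndarray, config: CRFConfig
) -> CliqueSet:
    """Draw the active pairwise cliques from the stochastic inclusion law.

    Deterministic for a fixed ``config.seed``. The immediate
    4-neighborhood is always included.
    """
    g = np.abs(np.asarray(guide))
    if g.shape != (height, width):
        raise ValueError(f"guide shape {g.shape} does not match ({height}, {width})")
    rng = np.random.default_rng(config.seed)
    inv_2g2 = 1.0 / (2.0 * config.clique_gamma**2)
    inv_2s2 = 1.0 / (2.0 * config.sigma**2)

    parts_i, parts_j = [], []
    for dy, dx in _half_plane_offsets(height, width, config.max_radius):
        pairs = _offset_pairs(height, width, dy, dx)
        if pairs is None:
            continue
        i, j = pairs
        gi, gj = g.ravel()[i], g.ravel()[j]
        d2 = dy * dy + dx * dx
        p = (
            config.clique_rho
            * np.exp(-d2 * inv_2g2)
            * np.exp(-((gi - gj) ** 2) * inv_2s2)
        )
        keep = rng.random(p.size) < p
        if (dy, dx) in ((0, 1), (1, 0)):  # guaranteed local connectivity
            keep |= True
        if keep.any():
            parts_i.append(i[keep])
            parts_j.append(j[keep])
    i = np.concatenate(parts_i) if parts_i else np.empty(0, dtype=np.int64)
    j = np.concatenate(parts_j) if parts_j else np.empty(0, dtype=np.int64)
    return CliqueSet(i, j, (height, width))


def pairwise_feature(y_i, y_j, x_i, x_j, sigma: float):
    """Guided similarity kernel exp(-(y_i-y_j)^2 (x_i-x_j)^2 / (3 sigma^2)).

    Equals 1 when either the states or the guide values agree, and
    decays with the product of their squared differences. Broadcasts
    over array inputs.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    dy = np.asarray(y_i, dtype=float) - np.asarray(y_j, dtype=float)
    dx = np.asarray(x_i, dtype=float) - np.asarray(x_j, dtype=float)
    return np.exp(-(dy**2) * (dx**2) / (3.0 * sigma**2))


def unary_energy(Y: np.ndarray, kdata: KSpaceData, config: CRFConfig) -> float:
    """k-space data fidelity: lambda_u * sum over sampled frequencies of
    |F(Y)_w - x_w|^2."""
    arr = np.asarray(Y)
    if arr.shape != kdata.shape:
        raise ValueError(f"estimate shape {arr.shape} does not match k-space {kdata.shape}")
    residual = forward_transform(arr) - kdata.coeffs
    return float(config.lambda_u * np.sum(np.abs(residual[kdata.mask.grid]) ** 2))


def pairwise_energy(
    Y: np.ndarray, guide: np.ndarray, cliques: CliqueSet, config: CRFConfig
) -> float:
    """Spatial smoothness penalty: lambda_p * sum over cliques of (1 - f).

    Magnitudes of complex entries are used for both the estimate and
    the guide.
    """
    m = np.abs(np.asarray(Y)).ravel()
    g = np.abs(np.asarray(guide)).ravel()
    if m.size != cliques.shape[0] * cliques.shape[1]:
        raise ValueError("estimate size does not match the cliques' grid")
    if g.size != m.size:
        raise ValueError("guide size does not match the estimate")
    if len(cliques) == 0:
        return 0.0
    f = pairwise_feature(m[cliques.i], m[cliques.j], g[cliques.i], g[cliques.j], config.sigma)
    return float(config.lambda_p * np.sum(1.0 - f))


def total_energy(
    Y: np.ndarray,
    kdata: KSpaceData,
    guide: np.ndarray,
    cliques: CliqueSet,
    config: CRFConfig,
) -> float:
    """Unary plus pairwise energy."""
    return unary_energy(Y, kdata, config) + pairwise_energy(Y, guide, cliques, config)


def energy_gradient(
    Y: np.ndarray,
    kdata: KSpaceData,
    guide: np.ndarray,
    cliques: CliqueSet,
    config: CRFConfig,
) -> np.ndarray:
    """Analytic gradient of :func:`total_energy` with respect to the estimate.

    For complex estimates this is the steepest-ascent direction
    ``dE/dRe + i dE/dIm``. The unary part is
    ``2 lambda_u * F^{-1}(mask * (F(Y) - X))``; the pairwise part acts
    on the magnitude of each pixel and is routed through the phase
    ``y / |y|`` (zero where the magnitude vanishes).
    """
    arr = np.asarray(Y, dtype=complex)
    if arr.shape != kdata.shape:
        raise ValueError(f"estimate shape {arr.shape} does not match k-space {kdata.shape}")
    residual = np.where(kdata.mask.grid, forward_transform(arr) - kdata.coeffs, 0.0)
    grad = 2.0 * config.lambda_u * inverse_transform(residual)

    if config.lambda_p > 0 and len(cliques) > 0:
        m = np.abs(arr).ravel()
        g = np.abs(np.asarray(guide)).ravel()
        mi, mj = m[cliques.i], m[cliques.j]
        gi, gj = g[cliques.i], g[cliques.j]
        f = pairwise_feature(mi, mj, gi, gj, config.sigma)
        # d/dm_i of (1 - f) = f * 2 (m_i - m_j) (g_i - g_j)^2 / (3 sigma^2)
        per_pair = (
            config.lambda_p * f * 2.0 * (mi - mj) * (gi - gj) ** 2 / (3.0 * config.sigma**2)
        )
        dm = np.bincount(cliques.i, weights=per_pair, minlength=m.size) - np.bincount(
            cliques.j, weights=per_pair, minlength=m.size
        )
        flat = arr.ravel()
        phase = np.where(m > 1e-300, flat / np.maximum(m, 1e-300), 0.0)
        grad = grad + (dm * phase).reshape(arr.shape)
    return grad
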