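"""Fourier operators, radial sampling masks, and masked acquisition.

All spectra use the *centered, unitary* 2-D DFT convention: the DC
coefficient sits at ``(H // 2, W // 2)`` and Parseval's identity holds
exactly, so the data-fidelity gradient carries no stray scale factors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SamplingMask",
    "KSpaceData",
    "forward_transform",
    "inverse_transform",
    "radial_mask",
    "lines_for_rate",
    "acquire",
]


@dataclass(frozen=True)
class SamplingMask:
    """Boolean k-space sampling pattern on an H×W centered-spectrum grid."""

    grid: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=bool)
        if grid.ndim != 2:
            raise ValueError(f"mask grid must be 2-D, got shape {grid.shape}")
        object.__setattr__(self, "grid", grid)

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    @property
    def rate(self) -> float:
        """Exact fraction of sampled cells."""
        return int(self.grid.sum()) / self.grid.size

    @classmethod
    def full(cls, height: int, width: int) -> "SamplingMask":
        return cls(np.ones((height, width), dtype=bool))


@dataclass(frozen=True)
class KSpaceData:
    """Complex k-space coefficients plus the mask under which they were observed.

    Coefficients are identically zero wherever the mask is false:
    unobserved frequencies carry no information.
    """

    coeffs: np.ndarray
    mask: SamplingMask

    def __post_init__(self) -> None:
        coeffs = np.asarray(self.coeffs, dtype=complex)
        if coeffs.shape != self.mask.shape:
            raise ValueError(
                f"coeffs shape {coeffs.shape} does not match mask shape {self.mask.shape}"
            )
        coeffs = np.where(self.mask.grid, coeffs, 0.0 + 0.0j)
        object.__setattr__(self, "coeffs", coeffs)

    @property
    def shape(self) -> tuple[int, int]:
        return self.coeffs.shape


def _check_image(values: np.ndarray) -> np.ndarray:
    arr = np.asarray(values)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D grid, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite values")
    return arr


def forward_transform(image: np.ndarray) -> np.ndarray:
    """Centered unitary 2-D DFT of a spatial-domain grid."""
    arr = _check_image(image)
    return np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(arr), norm="ortho"))


def inverse_transform(coeffs: np.ndarray) -> np.ndarray:
    """Exact unitary inverse of :func:`forward_transform`.

    Returns a complex-valued spatial grid; callers take the magnitude
    for display.
    """
    arr = np.asarray(coeffs, dtype=complex)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D spectrum, got shape {arr.shape}")
    return np.fft.fftshift(np.fft.ifft2(np.fft.ifftshift(arr), norm="ortho"))


def _rasterize_line(grid: np.ndarray, theta: float) -> None:
    """Mark the cells of a full-length line through the DC cell at angle ``theta``.

    Nearest-cell rasterization marching one step per cell along the
    dominant axis, symmetric about the center by construction.
    """
    h, w = grid.shape
    cy, cx = h // 2, w // 2
    dy, dx = np.sin(theta), np.cos(theta)
    scale = max(abs(dy), abs(dx))
    sy, sx = dy / scale, dx / scale  # dominant component has magnitude 1
    t = np.arange(max(h, w), dtype=float)
    oy = np.floor(t * sy + 0.5).astype(int)
    ox = np.floor(t * sx + 0.5).astype(int)
    ys = np.concatenate([cy + oy, cy - oy])
    xs = np.concatenate([cx + ox, cx - ox])
    keep = (ys >= 0) & (ys < h) & (xs >= 0) & (xs < w)
    grid[ys[keep], xs[keep]] = True


def radial_mask(height: int, width: int, n_lines: int) -> SamplingMask:
    """Union of ``n_lines`` straight lines through the spectrum center.

    Line ``k`` lies at angle ``k * pi / n_lines``; each line is
    rasterized nearest-cell across the full grid, symmetrically about
    the DC cell. The DC cell is always sampled.
    """
    if n_lines < 1:
        raise ValueError(f"n_lines must be >= 1, got {n_lines}")
    if height < 4 or width < 4:
        raise ValueError("grid must be at least 4x4")
    grid = np.zeros((height, width), dtype=bool)
    for k in range(n_lines):
        _rasterize_line(grid, np.pi * k / n_lines)
    return SamplingMask(grid)


def lines_for_rate(height: int, width: int, target_rate: float) -> int:
    """Number of radial lines whose mask rate is closest to ``target_rate``.

    Ties break toward fewer lines. The scan stops once the (non-
    decreasing) achieved rate reaches the target, or at the line count
    beyond which the angular spacing drops below the grid's angular
    resolution and additional lines stop contributing cells.
    """
    if not 0.0 < target_rate <= 1.0:
        raise ValueError(f"target_rate must lie in (0, 1], got {target_rate}")
    n_max = int(np.ceil(np.pi * float(np.hypot(height, width))))
    best_n, best_err = 1, np.inf
    for n in range(1, n_max + 1):
        rate = radial_mask(height, width, n).rate
        err = abs(rate - target_rate)
        if err < best_err:
            best_n, best_err = n, err
        if rate >= target_rate:
            break
    return best_n


def acquire(
    image: np.ndarray,
    mask: SamplingMask,
    noise_sigma: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> KSpaceData:
    """Simulate a masked k-space acquisition of ``image``.

    Transforms the image to k-space, optionally adds complex Gaussian
    noise of standard deviation ``noise_sigma`` per component, and zeroes
    every cell outside the mask.
    """
    arr = _check_image(image)
    if arr.shape != mask.shape:
        raise ValueError(f"image shape {arr.shape} does not match mask shape {mask.shape}")
    if noise_sigma < 0:
        raise ValueError(f"noise_sigma must be non-negative, got {noise_sigma}")
    coeffs = forward_transform(arr)
    if noise_sigma > 0:
        gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
        noise = gen.normal(scale=noise_sigma, size=coeffs.shape) + 1j * gen.normal(
            scale=noise_sigma, size=coeffs.shape
        )
        coeffs = coeffs + noise
    return KSpaceData(coeffs=np.where(mask.grid, coeffs, 0.0), mask=mask)
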