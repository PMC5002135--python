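"""Synthetic 2-D prostate phantom with known geometry and labels.

Emulates a slice through a multi-modality prostate training phantom: an
ellipsoidal prostate of 5 × 4.5 cm in-plane, a 0.7 cm urethra on the
midline, and a configurable number of randomly placed hypoechoic
lesions with diameters between 0.5 and 1.0 cm, on a low-backscatter
background. Intensities are synthetic contrast levels in [0, 1]; they
mimic the hypoechoic lesion contrast qualitatively, not any acquired
modality quantitatively.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "PhantomImage",
    "PhantomGenerationError",
    "DEFAULT_INTENSITIES",
    "generate_phantom",
    "add_texture",
]

# Synthetic contrast levels (fraction of full scale).
DEFAULT_INTENSITIES: dict[str, float] = {
    "background": 0.1,
    "prostate": 0.7,
    "urethra": 0.2,
    "lesion": 0.4,
}

PROSTATE_AXES_MM = (50.0, 45.0)  # full in-plane width x height
URETHRA_DIAMETER_MM = 7.0
LESION_DIAMETER_RANGE_MM = (5.0, 10.0)

LABEL_BACKGROUND = 0
LABEL_PROSTATE = 1
LABEL_URETHRA = 2
LABEL_FIRST_LESION = 3


class PhantomGenerationError(RuntimeError):
    """Raised when the requested geometry cannot be realized on the grid."""


@dataclass(frozen=True)
class PhantomImage:
    """A phantom slice: intensity image, integer label map, and pixel size.

    Labels: 0 background, 1 prostate, 2 urethra, 3.. lesions.
    """

    image: np.ndarray
    labels: np.ndarray
    pixel_size_mm: float
    meta: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.image.shape

    @property
    def n_lesions(self) -> int:
        return int(max(0, self.labels.max() - LABEL_FIRST_LESION + 1))


def _ellipse_mask(
    shape: tuple[int, int], cy: float, cx: float, semi_y: float, semi_x: float
) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return ((yy - cy) / semi_y) ** 2 + ((xx - cx) / semi_x) ** 2 <= 1.0


def generate_phantom(
    height: int = 256,
    width: int = 256,
    n_lesions: int = 3,
    pixel_size_mm: float = 0.5,
    seed: int = 0,
    intensities: dict[str, float] | None = None,
    max_attempts: int = 1000,
) -> PhantomImage:
    """Generate a deterministic phantom slice for a given seed.

    Lesion centers and diameters are rejection-sampled so that every
    lesion lies strictly inside the prostate and is disjoint from the
    urethra and from every other lesion.
    """
    if pixel_size_mm <= 0:
        raise ValueError("pixel_size_mm must be positive")
    if n_lesions < 0:
        raise ValueError("n_lesions must be non-negative")
    levels = dict(DEFAULT_INTENSITIES)
    if intensities:
        levels.update(intensities)

    semi_x = PROSTATE_AXES_MM[0] / 2.0 / pixel_size_mm
    semi_y = PROSTATE_AXES_MM[1] / 2.0 / pixel_size_mm
    if 2 * semi_x >= width or 2 * semi_y >= height:
        raise PhantomGenerationError(
            f"prostate ({PROSTATE_AXES_MM[0]}x{PROSTATE_AXES_MM[1]} mm) does not fit "
            f"a {height}x{width} grid at {pixel_size_mm} mm/pixel"
        )

    rng = np.random.default_rng(seed)
    cy, cx = (height - 1) / 2.0, (width - 1) / 2.0

    labels = np.zeros((height, width), dtype=np.int32)
    prostate = _ellipse_mask((height, width), cy, cx, semi_y, semi_x)
    labels[prostate] = LABEL_PROSTATE

    urethra_r = URETHRA_DIAMETER_MM / 2.0 / pixel_size_mm
    urethra = _ellipse_mask((height, width), cy, cx, urethra_r, urethra_r)
    labels[urethra & prostate] = LABEL_URETHRA

    lesion_specs = []
    lo, hi = LESION_DIAMETER_RANGE_MM
    for k in range(n_lesions):
        placed = False
        for _ in range(max_attempts):
            dia_y = rng.uniform(lo, hi) / pixel_size_mm
            dia_x = rng.uniform(lo, hi) / pixel_size_mm
            ly = rng.uniform(cy - semi_y, cy + semi_y)
            lx = rng.uniform(cx - semi_x, cx + semi_x)
            # interior to the prostate: the lesion's bounding ellipse must
            # fit inside the prostate ellipse (conservative per-axis check)
            u = (ly - cy) / (semi_y - dia_y / 2.0)
            v = (lx - cx) / (semi_x - dia_x / 2.0)
            if semi_y <= dia_y / 2.0 or semi_x <= dia_x / 2.0 or u * u + v * v > 1.0:
                continue
            lesion = _ellipse_mask((height, width), ly, lx, dia_y / 2.0, dia_x / 2.0)
            if not lesion.any():
                continue
            if np.any(labels[lesion] != LABEL_PROSTATE):
                continue  # overlaps urethra or a previous lesion
            labels[lesion] = LABEL_FIRST_LESION + k
            lesion_specs.append(
                {
                    "center_px": [float(ly), float(lx)],
                    "diameters_mm": [dia_y * pixel_size_mm, dia_x * pixel_size_mm],
                }
            )
            placed = True
            break
        if not placed:
            raise PhantomGenerationError(
                f"could not place lesion {k + 1} of {n_lesions} in {max_attempts} attempts"
            )

    image = np.full((height, width), levels["background"], dtype=float)
    image[labels == LABEL_PROSTATE] = levels["prostate"]
    image[labels == LABEL_URETHRA] = levels["urethra"]
    image[labels >= LABEL_FIRST_LESION] = levels["lesion"]

    meta = {
        "seed": int(seed),
        "pixel_size_mm": float(pixel_size_mm),
        "intensities": levels,
        "lesions": lesion_specs,
    }
    return PhantomImage(image=image, labels=labels, pixel_size_mm=pixel_size_mm, meta=meta)


def add_texture(phantom: PhantomImage, amplitude: float, seed: int = 0) -> PhantomImage:
    """Add smooth band-limited random texture inside the prostate footprint.

    The texture gives the reconstruction problem fine structure to
    preserve. Peak absolute perturbation equals ``amplitude``; pixels
    outside the prostate (background) are untouched; the result is
    clipped to [0, 1].
    """
    if not 0.0 <= amplitude < 0.5:
        raise ValueError(f"amplitude must lie in [0, 0.5), got {amplitude}")
    if amplitude == 0.0:
        return phantom
    rng = np.random.default_rng(seed)
    noise = gaussian_filter(rng.standard_normal(phantom.shape), sigma=2.0)
    peak = np.abs(noise).max()
    if peak > 0:
        noise = noise * (amplitude / peak)
    support = phantom.labels >= LABEL_PROSTATE
    image = phantom.image.copy()
    image[support] = np.clip(image[support] + noise[support], 0.0, 1.0)
    meta = dict(phantom.meta)
    meta["texture"] = {"amplitude": float(amplitude), "seed": int(seed)}
    return PhantomImage(
        image=image, labels=phantom.labels, pixel_size_mm=phantom.pixel_size_mm, meta=meta
    )
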