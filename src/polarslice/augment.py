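"""Rotation-based augmentation of the minority (normal) class.

Normal maps are the minority class (about 10% of the cohort), so the
training partitions are enlarged by adding rotated copies of each normal
map — three per source by default.  Because the uptake disc is centred,
rotation about the grid centre keeps it inside the frame; right-angle
rotations (90/180/270) are exact index permutations and conserve total
intensity to the last count, while arbitrary angles use interpolation.

Augmentation happens on images, never in feature space: rotating an image
changes its band sums, which is precisely the variation the augmented
samples are meant to contribute.  Leakage control (augmenting only inside a
training partition) is the caller's job; see the cross-validation pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .synth import NORMAL, ConfigurationError, PolarMapImage

__all__ = ["AugmentationConfig", "rotate_map", "augment_normals"]

_INTERP_ORDER = {"nearest": 0, "bilinear": 1}


@dataclass(frozen=True)
class AugmentationConfig:
    """How many rotated copies to make per normal map, and at which angles.

    The default angles 90/180/270 degrees are lossless on a square grid; any
    other angles fall back to interpolation (``interpolation``) with
    ``fill_value`` for pixels rotated in from outside the frame.
    """

    copies_per_image: int = 3
    angles: tuple[float, ...] = (90.0, 180.0, 270.0)
    interpolation: str = "bilinear"
    fill_value: float = 0.0

    def __post_init__(self) -> None:
        if self.copies_per_image < 1:
            raise ConfigurationError("copies_per_image must be >= 1")
        if len(self.angles) != self.copies_per_image:
            raise ConfigurationError(
                f"need exactly {self.copies_per_image} angles, got {len(self.angles)}"
            )
        if self.interpolation not in _INTERP_ORDER:
            raise ConfigurationError(
                f"interpolation must be one of {sorted(_INTERP_ORDER)}"
            )
        if not 0.0 <= self.fill_value <= 255.0:
            raise ConfigurationError("fill_value must lie in [0, 255]")


def rotate_map(
    image: PolarMapImage, angle: float, config: AugmentationConfig | None = None
) -> PolarMapImage:
    """Rotate a polar map counter-clockwise about the grid centre.

    Multiples of 90 degrees are implemented as exact index permutations (no
    interpolation, total intensity conserved exactly).  Other angles use the
    configured interpolation with constant fill.  The result keeps the
    source's label, phase, sex and patient_id but is marked
    ``provenance="augmented"``.
    """
    if not np.isfinite(angle):
        raise ValueError("rotation angle must be finite")
    config = config or AugmentationConfig()
    if angle % 90 == 0:
        pix = np.rot90(image.pixels, k=int(angle // 90) % 4).copy()
    else:
        rotated = ndimage.rotate(
            image.pixels.astype(np.float64),
            angle,
            reshape=False,
            order=_INTERP_ORDER[config.interpolation],
            mode="constant",
            cval=config.fill_value,
        )
        pix = np.clip(np.rint(rotated), 0, 255).astype(np.uint8)
    return image.replace(pixels=pix, provenance="augmented")


def augment_normals(
    images: Sequence[PolarMapImage], config: AugmentationConfig | None = None
) -> list[PolarMapImage]:
    """Generate rotated copies of every normal map in ``images``.

    Abnormal maps pass through untouched and unaugmented; the output
    contains only the newly created maps, ``copies_per_image`` per normal
    input, all with ``provenance="augmented"``.
    """
    config = config or AugmentationConfig()
    out: list[PolarMapImage] = []
    for img in images:
        if img.label == NORMAL:
            for angle in config.angles:
                out.append(rotate_map(img, angle, config))
    return out
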