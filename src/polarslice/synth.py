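"""Synthetic polar-map phantoms.

A myocardial-perfusion polar map (bull's-eye plot) projects tracer uptake in
the left-ventricular wall onto a disc: apex at the centre, base at the rim,
intensity proportional to perfusion.  The phantoms generated here reproduce
the two statistical regimes a normal/abnormal classifier has to separate:

* **normal** — a centred disc of near-homogeneous uptake plus pixel noise on
  a dark background;
* **abnormal** — the same disc with one or more angular-sector perfusion
  defects, i.e. contiguous wedges whose intensity is reduced by a fractional
  *severity*.

Maps carry the clinical metadata the study design implies (stress/rest/prone
phase, patient sex, a patient identifier) so that per-patient and per-phase
summary tables can be reproduced, but none of it influences the pixels.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "SynthConfig",
    "PolarMapImage",
    "sector_mask",
    "generate_map",
    "generate_dataset",
]

NORMAL = 1
ABNORMAL = 0

# Patient-level sex mix of the emulated cohort: 10/49 of normal and 91/404 of
# abnormal patients are male.  Males contribute three maps (stress, rest,
# prone), females two (stress, rest).
_MALE_PATIENT_FRACTION = {NORMAL: 10 / 49, ABNORMAL: 91 / 404}
_PHASES_BY_SEX = {"M": ("stress", "rest", "prone"), "F": ("stress", "rest")}


class ConfigurationError(ValueError):
    """Raised when a configuration object violates its own invariants."""


@dataclass(frozen=True)
class SynthConfig:
    """Parameters of the phantom generator.

    Intensities are on the 8-bit [0, 255] grayscale; angles in degrees;
    ``disc_radius_fraction`` is the disc radius as a fraction of the image
    width and must not exceed 0.5 so that the disc survives rotation about
    the grid centre without clipping.
    """

    image_size: int = 175
    disc_radius_fraction: float = 0.48
    normal_intensity_mean: float = 180.0
    normal_intensity_sd: float = 10.0
    pixel_noise_sd: float = 8.0
    defect_count_range: tuple[int, int] = (1, 3)
    defect_angular_extent_range: tuple[float, float] = (30.0, 120.0)
    defect_severity_range: tuple[float, float] = (0.3, 0.9)
    background_value: float = 0.0

    def __post_init__(self) -> None:
        if self.image_size < 5:
            raise ConfigurationError("image_size must be at least 5")
        if not 0.0 < self.disc_radius_fraction <= 0.5:
            raise ConfigurationError(
                "disc_radius_fraction must lie in (0, 0.5] so the disc fits "
                "the frame under rotation"
            )
        lo, hi = self.defect_count_range
        if not (1 <= lo <= hi):
            raise ConfigurationError("defect_count_range must be an integer interval >= 1")
        lo, hi = self.defect_angular_extent_range
        if not (0.0 < lo <= hi < 360.0):
            raise ConfigurationError("defect_angular_extent_range must lie within (0, 360)")
        lo, hi = self.defect_severity_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ConfigurationError("defect_severity_range must lie within (0, 1]")
        if not 0.0 <= self.background_value <= 255.0:
            raise ConfigurationError("background_value must lie in [0, 255]")
        for name in ("normal_intensity_sd", "pixel_noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")


@dataclass
class PolarMapImage:
    """A single polar map: a square 8-bit intensity grid plus metadata.

    ``label`` follows the convention normal=1, abnormal=0.  ``provenance``
    distinguishes maps that stand for acquired clinical images from rotated
    copies created by augmentation.  ``defects`` records the ground-truth
    (centre angle, angular extent, severity) of each simulated defect of a
    synthetic abnormal map; it is empty for normal maps and not used by any
    classifier.
    """

    pixels: np.ndarray
    label: int
    phase: str = "stress"
    sex: str = "M"
    provenance: str = "acquired"
    patient_id: str = ""
    defects: tuple[tuple[float, float, float], ...] = ()

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError(f"pixel grid must be square 2-D, got shape {self.pixels.shape}")
        if self.pixels.dtype != np.uint8:
            arr = np.asarray(self.pixels, dtype=np.float64)
            if not np.all(np.isfinite(arr)) or arr.min() < 0 or arr.max() > 255:
                raise ValueError("pixel values must be finite and within [0, 255]")
            self.pixels = np.rint(arr).astype(np.uint8)
        if self.label not in (0, 1):
            raise ValueError("label must be 0 (abnormal) or 1 (normal)")
        if self.phase not in ("stress", "rest", "prone"):
            raise ValueError(f"unknown phase {self.phase!r}")
        if self.sex not in ("M", "F"):
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.provenance not in ("acquired", "augmented"):
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @property
    def size(self) -> int:
        return self.pixels.shape[0]

    def total_intensity(self) -> int:
        return int(self.pixels.sum(dtype=np.int64))

    def replace(self, **changes) -> "PolarMapImage":
        return dataclasses.replace(self, **changes)


def disc_mask(size: int, radius: float) -> np.ndarray:
    """Boolean mask of the centred disc on a ``size``x``size`` grid."""
    c = (size - 1) / 2.0
    yy, xx = np.ogrid[:size, :size]
    return (yy - c) ** 2 + (xx - c) ** 2 <= radius**2


def sector_mask(size: int, centre_angle: float, extent: float) -> np.ndarray:
    """Boolean mask of an angular sector (wedge) about the grid centre.

    Angles are measured counter-clockwise from the +x axis in image
    coordinates (row 0 at the top); the wedge spans ``extent`` degrees
    centred on ``centre_angle`` and extends over the full radius.
    """
    c = (size - 1) / 2.0
    yy, xx = np.ogrid[:size, :size]
    theta = np.degrees(np.arctan2(c - yy, xx - c))  # CCW, +x axis = 0 deg
    delta = (theta - centre_angle + 180.0) % 360.0 - 180.0
    return np.abs(delta) <= extent / 2.0


def generate_map(
    config: SynthConfig,
    label: int,
    rng: np.random.Generator,
    *,
    phase: str = "stress",
    sex: str = "M",
    patient_id: str = "",
) -> PolarMapImage:
    """Draw one synthetic polar map of the requested class.

    The per-map base intensity is drawn from
    N(normal_intensity_mean, normal_intensity_sd); independent pixel noise
    with standard deviation ``pixel_noise_sd`` is added inside the disc.
    Abnormal maps then receive ``defect_count_range`` angular-sector defects,
    each multiplying in-sector disc pixels by (1 - severity).  Pixels are
    clipped to [0, 255] and rounded to 8-bit.
    """
    if label not in (0, 1):
        raise ValueError("label must be 0 (abnormal) or 1 (normal)")
    size = config.image_size
    mask = disc_mask(size, config.disc_radius_fraction * size)

    base = rng.normal(config.normal_intensity_mean, config.normal_intensity_sd)
    pix = np.full((size, size), float(config.background_value))
    pix[mask] = base + rng.normal(0.0, config.pixel_noise_sd, size=int(mask.sum()))

    defects: list[tuple[float, float, float]] = []
    if label == ABNORMAL:
        lo, hi = config.defect_count_range
        n_defects = int(rng.integers(lo, hi + 1))
        for _ in range(n_defects):
            angle = float(rng.uniform(0.0, 360.0))
            extent = float(rng.uniform(*config.defect_angular_extent_range))
            severity = float(rng.uniform(*config.defect_severity_range))
            wedge = sector_mask(size, angle, extent) & mask
            pix[wedge] *= 1.0 - severity
            defects.append((angle, extent, severity))

    pix = np.clip(np.rint(pix), 0, 255).astype(np.uint8)
    return PolarMapImage(
        pixels=pix,
        label=label,
        phase=phase,
        sex=sex,
        provenance="acquired",
        patient_id=patient_id,
        defects=tuple(defects),
    )


def _class_maps(
    n_maps: int, label: int, config: SynthConfig, rng: np.random.Generator
) -> list[PolarMapImage]:
    """Generate ``n_maps`` maps of one class, organised into patients.

    Patients are drawn until the map budget is exhausted: each male patient
    contributes stress/rest/prone maps, each female stress/rest, mirroring
    the cohort's acquisition protocol.  The last patient's series is
    truncated so the total is exact.
    """
    maps: list[PolarMapImage] = []
    p_male = _MALE_PATIENT_FRACTION[label]
    tag = "N" if label == NORMAL else "A"
    patient = 0
    while len(maps) < n_maps:
        sex = "M" if rng.random() < p_male else "F"
        pid = f"{tag}{patient:04d}"
        for phase in _PHASES_BY_SEX[sex]:
            if len(maps) >= n_maps:
                break
            maps.append(
                generate_map(config, label, rng, phase=phase, sex=sex, patient_id=pid)
            )
        patient += 1
    return maps


def generate_dataset(
    n_normal: int,
    n_abnormal: int,
    config: SynthConfig | None = None,
    seed: int = 0,
) -> list[PolarMapImage]:
    """Generate a labelled dataset of synthetic polar maps.

    Returns exactly ``n_normal + n_abnormal`` maps (normals first), with
    phase and sex drawn to mimic the per-class patient mix of the emulated
    cohort.  Deterministic for fixed (config, seed).
    """
    if n_normal < 0 or n_abnormal < 0:
        raise ValueError("map counts must be non-negative")
    config = config or SynthConfig()
    rng = np.random.default_rng(seed)
    return _class_maps(n_normal, NORMAL, config, rng) + _class_maps(
        n_abnormal, ABNORMAL, config, rng
    )
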