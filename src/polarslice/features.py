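"""Band-slicing feature extraction.

Each polar map is divided into five horizontal and five vertical bands and
the pixel intensities of each band are summed, giving ten attributes per
image (h1..h5 top-to-bottom, v1..v5 left-to-right).  Because every pixel
falls in exactly one horizontal and exactly one vertical band, the ten sums
obey the conservation identity

    h1 + ... + h5  =  v1 + ... + v5  =  total image intensity,

which holds exactly in integer arithmetic on 8-bit inputs and is asserted by
the test suite.  The feature matrix appends the class label as an eleventh
column.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .synth import PolarMapImage

__all__ = [
    "FEATURE_COLUMNS",
    "MATRIX_COLUMNS",
    "FeatureVector",
    "band_edges",
    "extract_features",
    "build_matrix",
]

N_BANDS = 5
FEATURE_COLUMNS = [f"h{i}" for i in range(1, 6)] + [f"v{i}" for i in range(1, 6)]
MATRIX_COLUMNS = FEATURE_COLUMNS + ["label"]


def band_edges(n: int, n_bands: int = N_BANDS) -> np.ndarray:
    """Cumulative band boundaries partitioning ``n`` pixels into ``n_bands``.

    Bands are contiguous and as equal as possible; when ``n`` is not a
    multiple of ``n_bands`` the remainder pixels go to the last bands.  For
    the default 175-pixel maps every band is exactly 35 pixels wide.
    """
    if n < n_bands:
        raise ValueError(f"cannot partition {n} pixels into {n_bands} bands")
    base, rem = divmod(n, n_bands)
    sizes = [base] * n_bands
    for i in range(rem):
        sizes[n_bands - 1 - i] += 1
    return np.concatenate([[0], np.cumsum(sizes)])


@dataclass(frozen=True)
class FeatureVector:
    """The ten band sums of one image plus its label."""

    h: tuple[int, int, int, int, int]
    v: tuple[int, int, int, int, int]
    label: int

    def as_array(self) -> np.ndarray:
        """The 10 features (no label) in matrix column order h1..h5, v1..v5."""
        return np.array(self.h + self.v, dtype=np.int64)


def band_sums(pixels: np.ndarray) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Horizontal and vertical band sums of a square pixel grid."""
    pixels = np.asarray(pixels)
    if pixels.ndim != 2 or pixels.shape[0] != pixels.shape[1]:
        raise ValueError(f"expected a square 2-D grid, got shape {pixels.shape}")
    edges = band_edges(pixels.shape[0])
    h = tuple(int(pixels[a:b, :].sum(dtype=np.int64)) for a, b in zip(edges, edges[1:]))
    v = tuple(int(pixels[:, a:b].sum(dtype=np.int64)) for a, b in zip(edges, edges[1:]))
    return h, v


def extract_features(image: PolarMapImage) -> FeatureVector:
    """Slice one polar map into 5+5 bands and sum intensities per band."""
    h, v = band_sums(image.pixels)
    return FeatureVector(h=h, v=v, label=image.label)


def build_matrix(images: Sequence[PolarMapImage]) -> pd.DataFrame:
    """Feature matrix with columns h1..h5, v1..v5, label — one row per image.

    Rows follow the input order; the row count always equals the number of
    images supplied.
    """
    images = list(images)
    if not images:
        raise ValueError("cannot build a feature matrix from zero images")
    rows = np.empty((len(images), 11), dtype=np.int64)
    for i, img in enumerate(images):
        fv = extract_features(img)
        rows[i, :10] = fv.as_array()
        rows[i, 10] = fv.label
    return pd.DataFrame(rows, columns=MATRIX_COLUMNS)
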