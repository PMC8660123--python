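"""TIFF, manifest-CSV, feature-CSV and YAML-config I/O.

Polar maps travel as 8-bit grayscale TIFF files, one per map, alongside a
manifest CSV (filename, label, phase, sex, patient_id, provenance) that
carries the metadata — labels are never parsed out of filenames.  Feature
matrices are plain CSV with the fixed header ``h1..h5,v1..v5,label``.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .augment import AugmentationConfig
from .features import MATRIX_COLUMNS
from .models import ModelSpec
from .synth import PolarMapImage, SynthConfig

__all__ = [
    "read_polarmap_tiff",
    "write_polarmap_tiff",
    "write_dataset",
    "read_dataset",
    "write_feature_csv",
    "read_feature_csv",
    "load_run_config",
]

MANIFEST_COLUMNS = ["filename", "label", "phase", "sex", "patient_id", "provenance"]


class FormatError(ValueError):
    """An input file could not be decoded or has the wrong layout."""


def write_polarmap_tiff(image: PolarMapImage, path) -> None:
    tifffile.imwrite(str(path), image.pixels)


def read_polarmap_tiff(
    path,
    *,
    expected_size: int | None = 175,
    strict: bool = False,
    label: int = 0,
    phase: str = "stress",
    sex: str = "M",
    patient_id: str = "",
    provenance: str = "acquired",
) -> PolarMapImage:
    """Read one polar map from a TIFF file.

    Multi-channel images are collapsed to a single channel by the per-pixel
    channel mean (with a warning); size mismatches against ``expected_size``
    warn, or raise when ``strict``.
    """
    try:
        arr = tifffile.imread(str(path))
    except Exception as exc:  # undecodable/truncated file
        raise FormatError(f"cannot decode TIFF {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3:
        warnings.warn(
            f"{path}: multi-channel TIFF collapsed to single channel by channel mean",
            UserWarning,
            stacklevel=2,
        )
        axis = 0 if arr.shape[0] in (3, 4) and arr.shape[0] < arr.shape[-1] else -1
        arr = arr.mean(axis=axis)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise FormatError(f"{path}: expected a square single-channel image, got {arr.shape}")
    if expected_size is not None and arr.shape[0] != expected_size:
        msg = f"{path}: image is {arr.shape[0]}x{arr.shape[1]}, expected {expected_size}"
        if strict:
            raise FormatError(msg)
        warnings.warn(msg, UserWarning, stacklevel=2)
    arr = np.clip(np.rint(arr.astype(np.float64)), 0, 255).astype(np.uint8)
    return PolarMapImage(
        pixels=arr,
        label=label,
        phase=phase,
        sex=sex,
        patient_id=patient_id,
        provenance=provenance,
    )


def write_dataset(images: Sequence[PolarMapImage], out_dir) -> Path:
    """Write one grayscale TIFF per map plus a manifest CSV; returns its path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, img in enumerate(images):
        fname = f"map_{i:05d}.tiff"
        write_polarmap_tiff(img, out_dir / fname)
        rows.append(
            {
                "filename": fname,
                "label": img.label,
                "phase": img.phase,
                "sex": img.sex,
                "patient_id": img.patient_id,
                "provenance": img.provenance,
            }
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(manifest, index=False)
    return manifest


def read_dataset(images_dir, manifest_path=None, *, strict: bool = False) -> list[PolarMapImage]:
    """Load all maps listed in a manifest CSV (default: manifest.csv in dir)."""
    images_dir = Path(images_dir)
    manifest_path = Path(manifest_path) if manifest_path else images_dir / "manifest.csv"
    df = pd.read_csv(manifest_path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"manifest {manifest_path} is missing columns {missing}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            read_polarmap_tiff(
                images_dir / row.filename,
                expected_size=None,
                strict=strict,
                label=int(row.label),
                phase=str(row.phase),
                sex=str(row.sex),
                patient_id=str(row.patient_id),
                provenance=str(row.provenance),
            )
        )
    return out


def write_feature_csv(matrix: pd.DataFrame, path) -> None:
    """Write a feature matrix as CSV with the canonical 11-column header."""
    if list(matrix.columns) != MATRIX_COLUMNS:
        raise FormatError(
            f"feature matrix must have columns {MATRIX_COLUMNS}, got {list(matrix.columns)}"
        )
    matrix.to_csv(path, index=False)


def read_feature_csv(path) -> pd.DataFrame:
    """Read a feature CSV, enforcing the 11-column schema and integer labels."""
    df = pd.read_csv(path)
    if list(df.columns) != MATRIX_COLUMNS:
        raise FormatError(
            f"{path}: expected header {','.join(MATRIX_COLUMNS)}, "
            f"got {','.join(map(str, df.columns))}"
        )
    if not set(df["label"].unique()) <= {0, 1}:
        raise FormatError(f"{path}: label column must be binary 0/1")
    return df.astype({c: np.int64 for c in MATRIX_COLUMNS})


_CONFIG_SECTIONS = {"synth", "augmentation", "pipeline", "models", "seed"}


def load_run_config(path) -> dict:
    """Parse a YAML run configuration into typed config objects.

    Recognised top-level sections: ``synth``, ``augmentation``, ``pipeline``,
    ``models``, ``seed``.  Unknown keys anywhere are errors — silent typos in
    scientific configs are how irreproducible results happen.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise FormatError(f"{path}: top level must be a mapping")
    unknown = set(raw) - _CONFIG_SECTIONS
    if unknown:
        raise FormatError(f"{path}: unknown config sections {sorted(unknown)}")

    def _build(cls, section: dict, name: str):
        try:
            return cls(**section)
        except TypeError as exc:
            raise FormatError(f"{path}: bad keys in section '{name}': {exc}") from exc

    out: dict = {"seed": int(raw.get("seed", 0))}
    out["synth"] = _build(SynthConfig, raw.get("synth", {}), "synth")
    aug = raw.get("augmentation", {})
    if "angles" in aug:
        aug = {**aug, "angles": tuple(float(a) for a in aug["angles"])}
    out["augmentation"] = _build(AugmentationConfig, aug, "augmentation")
    out["pipeline"] = dict(raw.get("pipeline", {}))
    out["models"] = [
        ModelSpec(
            family=m["family"],
            seed=int(m.get("seed", out["seed"])),
            params=dict(m.get("params", {})),
        )
        for m in raw.get("models", [])
    ]
    return out
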