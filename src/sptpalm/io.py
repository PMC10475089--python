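"""File formats: TIFF movies, CSV tables, YAML configs, run manifests.

All tables are CSV (small volumes, diffable, language-neutral); numeric
fields are serialized at full precision (repr round-trip).  Coordinates in
every table follow the half-pixel-centre convention documented in
:mod:`sptpalm.localize`.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "SchemaError",
    "read_movie",
    "write_movie",
    "read_table",
    "write_table",
    "LOCALIZATION_SCHEMA",
    "TRACK_SCHEMA",
    "MOTION_SCHEMA",
    "SUMMARY_SCHEMA",
    "write_manifest",
]

LOCALIZATION_SCHEMA = [
    "frame",
    "x_nm",
    "y_nm",
    "amplitude",
    "sigma_nm",
    "offset",
    "residual_rms",
]
TRACK_SCHEMA = ["track_id", "frame", "x_nm", "y_nm"]
MOTION_SCHEMA = [
    "track_id",
    "n_frames",
    "mobility",
    "alpha",
    "D_um2_s",
    "alpha_in_range",
    "negative_D",
    "exclusion_cause",
]
SUMMARY_SCHEMA = [
    "condition_label",
    "n_tracks",
    "n_immobile",
    "n_mobile",
    "immobile_fraction",
    "boot_sd_fraction",
    "mean_D_mobile",
    "boot_sd_D",
    "n_boot",
    "seed",
]


class SchemaError(ValueError):
    """A table is missing required columns."""


def read_movie(path: str | Path) -> np.ndarray:
    """Read a multi-page grayscale TIFF into a (frames, h, w) array."""
    stack = tifffile.imread(str(path))
    if stack.ndim == 2:
        stack = stack[None]
    return stack


def write_movie(path: str | Path, stack: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(stack), photometric="minisblack")


def _check_schema(df: pd.DataFrame, schema: list[str], what: str) -> None:
    missing = [c for c in schema if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table is missing columns: {missing}")


def write_table(path: str | Path, df: pd.DataFrame, schema: list[str] | None = None) -> None:
    """Write a CSV with full float precision (round-trip exact)."""
    if schema is not None:
        _check_schema(df, schema, Path(path).stem)
        df = df[schema]
    df.to_csv(path, index=False, float_format="%.17g")


def read_table(path: str | Path, schema: list[str] | None = None) -> pd.DataFrame:
    df = pd.read_csv(path)
    if schema is not None:
        _check_schema(df, schema, Path(path).stem)
    return df


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_manifest(path: str | Path, config: dict, counts: dict, seed: int | None) -> dict:
    """Machine-readable run manifest: config (and its hash), seed, library
    versions, and the record counts surviving each stage."""
    import scipy
    import skimage

    from . import __version__

    manifest = {
        "config": config,
        "config_hash": config_hash(config),
        "seed": seed,
        "counts": counts,
        "versions": {
            "sptpalm": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "scikit-image": skimage.__version__,
        },
    }
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return manifest


def load_config_file(path: str | Path) -> dict:
    """YAML (or JSON) key-value config mirroring RunConfig field names."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must contain a mapping")
    return data
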