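"""Image and manifest I/O.

Single-channel grayscale images only: 16-bit TIFF is the default container
(written via tifffile); 8-bit PNG is supported through Pillow.  A simulation
or experiment is described by a manifest CSV with one row per image:
image_id, channel, condition, concentration, replicate, seed, path.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .errors import ImageSizeError, ValidationError

__all__ = ["read_image", "write_image", "read_manifest", "write_manifest", "MANIFEST_COLUMNS"]

MANIFEST_COLUMNS = ["image_id", "channel", "condition", "concentration", "replicate", "seed", "path"]


def read_image(path) -> np.ndarray:
    """Read a single-channel grayscale image (TIFF or PNG)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        img = tifffile.imread(path)
    else:
        img = np.asarray(Image.open(path))
    if img.ndim != 2:
        raise ImageSizeError(f"{path}: expected single-channel image, got shape {img.shape}")
    return img


def write_image(path, image: np.ndarray) -> None:
    """Write a grayscale image; 16-bit TIFF or 8-bit PNG by file suffix."""
    path = Path(path)
    image = np.asarray(image)
    if image.ndim != 2:
        raise ImageSizeError(f"expected single-channel image, got shape {image.shape}")
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image.astype(np.uint16))
    else:
        if image.dtype != np.uint8:
            # scale 16-bit content into the 8-bit range
            image = (image.astype(float) / 257.0).round().clip(0, 255).astype(np.uint8)
        Image.fromarray(image).save(path)


def write_manifest(rows: list[dict], path) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=MANIFEST_COLUMNS + [c for c in (rows[0] if rows else {}) if c not in MANIFEST_COLUMNS])
    df.to_csv(path, index=False)
    return df


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"manifest {path} missing columns {missing}")
    return df
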