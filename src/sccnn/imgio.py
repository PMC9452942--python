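"""Image and map file I/O: 8-bit RGB tiles and float32 density maps."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from .errors import InvalidParameterError

__all__ = ["read_rgb", "write_rgb", "write_density_map", "read_density_map", "write_preview"]


def read_rgb(path) -> np.ndarray:
    """Read a PNG/TIFF image as an (H, W, 3) uint8 array."""
    with Image.open(path) as img:
        arr = np.asarray(img.convert("RGB"))
    return arr


def write_rgb(image: np.ndarray, path) -> None:
    image = np.asarray(image)
    if image.dtype != np.uint8:
        image = np.clip(np.rint(image), 0, 255).astype(np.uint8)
    Image.fromarray(image, mode="RGB").save(path)


def write_density_map(values: np.ndarray, path) -> None:
    """Write a single-channel float32 TIFF (stain density / probability map)."""
    values = np.asarray(values, dtype=np.float32)
    if values.ndim != 2:
        raise InvalidParameterError(f"density map must be 2-D, got shape {values.shape}")
    tifffile.imwrite(path, values)


def read_density_map(path) -> np.ndarray:
    return np.asarray(tifffile.imread(path), dtype=np.float64)


def write_preview(values: np.ndarray, path, tint=(0.55, 0.35, 0.75)) -> None:
    """Pseudo-coloured PNG preview of a non-negative density map."""
    values = np.asarray(values, dtype=np.float64)
    top = values.max() if values.max() > 0 else 1.0
    norm = np.clip(values / top, 0.0, 1.0)
    rgb = (255 * (1.0 - norm[..., None] * (1.0 - np.asarray(tint)))).astype(np.uint8)
    Image.fromarray(rgb, mode="RGB").save(path)
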