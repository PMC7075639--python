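"""Reading micrographs and writing masks, labels and reports."""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .types import BinarySkeleton, Channel, GrayImage, LineSet


def read_image(path: str | Path, resolution: float = 6.0,
               channel: Channel = "alpha_actinin") -> GrayImage:
    """Read an 8/16-bit grayscale TIFF or PNG as a `GrayImage`.

    Multi-channel files are averaged to grayscale; integer data keep their
    native scale as floats.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        pixels = tifffile.imread(path)
    else:
        pixels = iio.imread(path)
    pixels = np.asarray(pixels, dtype=float)
    if pixels.ndim == 3:
        pixels = pixels.mean(axis=-1)
    return GrayImage(pixels=pixels, resolution=resolution, channel=channel)


def write_image(path: str | Path, image: GrayImage) -> None:
    """Write a grayscale image as 32-bit float TIFF (or 8-bit PNG)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image.pixels.astype(np.float32))
    else:
        pix = image.pixels
        top = pix.max() if pix.max() > 0 else 1.0
        iio.imwrite(path, np.clip(pix / top * 255.0, 0, 255).astype(np.uint8))


def write_mask(path: str | Path, mask: np.ndarray | BinarySkeleton) -> None:
    """Write a boolean mask as an 8-bit PNG (255 = true)."""
    if isinstance(mask, BinarySkeleton):
        mask = mask.mask
    iio.imwrite(Path(path), (np.asarray(mask, dtype=bool) * np.uint8(255)))


def read_mask(path: str | Path, resolution: float = 6.0) -> BinarySkeleton:
    """Read an 8-bit PNG mask (nonzero = true) as a skeleton."""
    pixels = iio.imread(Path(path))
    if pixels.ndim == 3:
        pixels = pixels.max(axis=-1)
    return BinarySkeleton(mask=pixels > 0, resolution=resolution)


def write_line_labels(path: str | Path, lines: LineSet,
                      shape: tuple[int, int]) -> None:
    """Write continuous lines as a 16-bit label PNG, one integer id per line."""
    labels = np.zeros(shape, dtype=np.uint16)
    for k, ln in enumerate(lines.lines, start=1):
        labels[ln.path[:, 0], ln.path[:, 1]] = k
    iio.imwrite(Path(path), labels)


def write_gamma_map(path: str | Path, gamma_map: np.ndarray) -> None:
    """Write the per-pixel γ map as a 32-bit float TIFF (NaN = unassigned)."""
    tifffile.imwrite(Path(path), gamma_map.astype(np.float32))


def lines_table(lines: LineSet) -> pd.DataFrame:
    """Per-line CSV table: id, pixel count, length and centroid."""
    rows = []
    for k, ln in enumerate(lines.lines, start=1):
        rows.append({
            "line_id": k,
            "pixel_count": ln.pixel_count,
            "length_um": ln.length_um,
            "centroid_row": float(ln.path[:, 0].mean()),
            "centroid_col": float(ln.path[:, 1].mean()),
        })
    return pd.DataFrame(rows, columns=["line_id", "pixel_count", "length_um",
                                       "centroid_row", "centroid_col"])
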