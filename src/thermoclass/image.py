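"""Thermogram container and image I/O.

A thermogram is a single-channel infrared image whose pixel intensity is a
proxy for surface temperature.  All pixel data is held as float64 normalized
to [0, 1] regardless of the bit depth of the file it came from; the original
bit depth is recorded so round-trips can re-quantize faithfully.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import imageio.v3 as iio
import tifffile

CLASS_LABELS = ("DCIS", "ILC", "Angiosarcoma", "PhyllodesTumor")

#: BT.601 luma weights — green dominates, matching human luminance sensitivity.
GRAYSCALE_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass
class Thermogram:
    """Single-channel intensity grid with provenance metadata.

    Parameters
    ----------
    pixels : ndarray, shape (H, W)
        Intensities in [0, 1], finite.
    source_bit_depth : int
        Bit depth of the originating file (8 or 16); 8 for synthetic images.
    label : str or None
        Optional class label from :data:`CLASS_LABELS`.
    """

    pixels: np.ndarray
    source_bit_depth: int = 8
    label: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("thermogram pixels must be a non-empty 2-D grid")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("thermogram contains non-finite intensities")
        if self.pixels.min() < 0.0 or self.pixels.max() > 1.0:
            raise ValueError("thermogram intensities must lie in [0, 1]")
        if self.label is not None and self.label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.label!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray) -> "Thermogram":
        """Copy of this thermogram with replaced pixel data."""
        return Thermogram(pixels, self.source_bit_depth, self.label, dict(self.meta))


def to_grayscale(rgb: np.ndarray, weights: tuple[float, float, float] = GRAYSCALE_WEIGHTS) -> Thermogram:
    """Collapse a 3-channel image to luminance.

    The weights sum to one with the green channel weighted highest, so a
    gray input (R=G=B) is passed through unchanged.
    """
    rgb = np.asarray(rgb, dtype=np.float64)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) array, got shape {rgb.shape}")
    w = np.asarray(weights, dtype=np.float64)
    if abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("grayscale weights must sum to 1")
    gray = rgb @ w
    return Thermogram(np.clip(gray, 0.0, 1.0))


def load_image(path: str | Path) -> Thermogram:
    """Read a PNG/TIFF thermogram, normalizing intensities to [0, 1].

    8-bit files divide by 255, 16-bit by 65535.  RGB inputs are routed
    through :func:`to_grayscale`.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"image file not found: {path}")
    try:
        if path.suffix.lower() in {".tif", ".tiff"}:
            arr = tifffile.imread(path)
        else:
            arr = iio.imread(path)
    except Exception as exc:  # pragma: no cover - backend-specific messages
        raise IOError(f"cannot read image {path}: {exc}") from exc

    if arr.dtype == np.uint8:
        depth, scale = 8, 255.0
    elif arr.dtype == np.uint16:
        depth, scale = 16, 65535.0
    elif np.issubdtype(arr.dtype, np.floating):
        depth, scale = 8, 1.0
    else:
        raise IOError(f"unsupported pixel dtype {arr.dtype} in {path}")

    arr = np.asarray(arr, dtype=np.float64) / scale
    if arr.ndim == 3:
        if arr.shape[2] == 4:  # drop alpha
            arr = arr[:, :, :3]
        tg = to_grayscale(arr)
        tg.source_bit_depth = depth
        return tg
    tg = Thermogram(np.clip(arr, 0.0, 1.0), source_bit_depth=depth)
    return tg


def save_image(tg: Thermogram, path: str | Path, bit_depth: int | None = None) -> None:
    """Write a thermogram as 8-bit PNG or 16-bit TIFF depending on extension."""
    path = Path(path)
    depth = bit_depth or (16 if path.suffix.lower() in {".tif", ".tiff"} else 8)
    if depth == 8:
        data = np.round(tg.pixels * 255.0).astype(np.uint8)
    elif depth == 16:
        data = np.round(tg.pixels * 65535.0).astype(np.uint16)
    else:
        raise ValueError("bit_depth must be 8 or 16")
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, data)
    else:
        iio.imwrite(path, data)
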