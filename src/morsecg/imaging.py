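"""Render scalogram magnitudes into fixed-size RGB images.

The magnitude matrix is min-max rescaled to [0, 1] per image (linear, not
log), quantized to a fixed number of levels, mapped through a jet colormap
lookup table, and resized with bilinear interpolation.  Rows arrive in
descending frequency order, so frequency increases upward in the rendered
image.  A zero-dynamic-range input maps uniformly to the lowest colormap
entry rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from matplotlib import colormaps
from PIL import Image
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = ["RGBImage", "scalogram_to_image", "write_image", "read_image", "ScalogramImager"]


@dataclass
class RGBImage:
    """An H x W x 3 image of uint8 intensities with provenance."""

    pixels: np.ndarray
    source_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"pixels must be H x W x 3, got shape {self.pixels.shape}")
        if self.pixels.dtype != np.uint8:
            if self.pixels.min() < 0 or self.pixels.max() > 255:
                raise ValueError("channel values must lie in [0, 255]")
            self.pixels = self.pixels.astype(np.uint8)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def _jet_lut(levels: int) -> np.ndarray:
    """Jet colormap lookup table as (levels, 3) uint8."""
    rgba = colormaps["jet"](np.linspace(0.0, 1.0, levels))
    return np.round(rgba[:, :3] * 255).astype(np.uint8)


def colormap_indices(mag: np.ndarray, levels: int = 128) -> np.ndarray:
    """Quantized colormap index per matrix entry, before any resize.

    Min-max rescales to [0, 1], then maps monotonically onto
    ``{0, ..., levels-1}``.  Constant input maps everywhere to index 0.
    """
    mag = np.asarray(mag, dtype=float)
    lo, hi = mag.min(), mag.max()
    if hi > lo:
        norm = (mag - lo) / (hi - lo)
    else:
        norm = np.zeros_like(mag)
    return np.minimum((norm * levels).astype(int), levels - 1)


def scalogram_to_image(
    scalogram,
    size: tuple[int, int] = (227, 227),
    levels: int = 128,
    source_id: str = "",
) -> RGBImage:
    """Render a scalogram (or a raw magnitude matrix) as a jet-colored image.

    Parameters
    ----------
    scalogram : Scalogram or array_like
        A :class:`morsecg.Scalogram` (its magnitude is taken) or a
        nonnegative magnitude matrix with rows in descending frequency order.
    size : (H, W)
        Target image size in pixels; 227 matches the AlexNet input
        convention, 224 the ResNet one.  Default (227, 227).
    levels : int
        Number of quantization levels for the jet lookup table (default 128).

    Returns
    -------
    RGBImage
        Exactly H x W x 3 uint8 pixels, frequency increasing upward.
    """
    mag = np.abs(getattr(scalogram, "coefficients", scalogram))
    mag = np.asarray(mag, dtype=float)
    if mag.size == 0:
        raise ValueError("magnitude matrix is empty")
    if not np.all(np.isfinite(mag)):
        raise ValueError("magnitude matrix contains non-finite values")
    if levels < 2:
        raise ValueError(f"levels must be >= 2, got {levels}")
    h, w = size
    if h < 1 or w < 1:
        raise ValueError(f"target size must be positive, got {size}")

    lut = _jet_lut(levels)
    rgb = lut[colormap_indices(mag, levels)]
    img = Image.fromarray(rgb, mode="RGB").resize((w, h), Image.BILINEAR)
    return RGBImage(pixels=np.asarray(img), source_id=source_id)


def write_image(image: RGBImage, path) -> None:
    """Write an image to disk as lossless PNG."""
    Image.fromarray(image.pixels, mode="RGB").save(Path(path), format="PNG")


def read_image(path) -> RGBImage:
    """Read a PNG image back as an :class:`RGBImage` (lossless round-trip)."""
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"image file not found: {p}")
    with Image.open(p) as img:
        pixels = np.asarray(img.convert("RGB"))
    return RGBImage(pixels=pixels, source_id=str(p))


class ScalogramImager(TransformerMixin, BaseEstimator):
    """Scikit-learn transformer: scalogram magnitude stacks -> RGB image stacks.

    Maps an (n, n_filters, n_samples) magnitude array to an (n, H, W, 3)
    uint8 array via per-image jet rendering.  Stateless; ``fit`` is a no-op.
    """

    def __init__(self, size: tuple[int, int] = (227, 227), levels: int = 128):
        self.size = size
        self.levels = levels

    def fit(self, X, y=None):
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 3:
            raise ValueError(f"X must be (n, n_filters, n_samples), got shape {X.shape}")
        h, w = self.size
        out = np.empty((X.shape[0], h, w, 3), dtype=np.uint8)
        for i, mag in enumerate(X):
            out[i] = scalogram_to_image(mag, size=self.size, levels=self.levels).pixels
        return out
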