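"""Raster image containers and file I/O.

Pixel convention used everywhere in this package: origin at the top-left,
``x`` increases rightward (columns), ``y`` increases downward (rows).
Bounding boxes are half-open ``(x0, y0, x1, y1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image


@dataclass
class RasterImage:
    """An RGB scan with channels normalised to [0, 1].

    ``pixels`` has shape (H, W, 3), dtype float32.  Single-channel input is
    accepted and broadcast to three identical channels, which makes the
    red-saturation step of grid removal degrade gracefully on greyscale
    scans.
    """

    pixels: np.ndarray
    dpi: float | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim == 2:
            px = np.repeat(px[:, :, None], 3, axis=2)
        if px.ndim != 3 or px.shape[2] not in (3, 4):
            raise ValueError(f"expected HxWx3 pixels, got shape {px.shape}")
        if px.shape[2] == 4:  # drop alpha
            px = px[:, :, :3]
        px = px.astype(np.float32, copy=False)
        if px.size and (px.min() < 0 or px.max() > 1):
            raise ValueError("channel values must lie in [0, 1]")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must be at least 1x1")
        self.pixels = px

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]


@dataclass
class BinaryInkImage:
    """Boolean raster where True marks candidate signal/text ink."""

    ink: np.ndarray
    dpi: float | None = None

    def __post_init__(self) -> None:
        ink = np.asarray(self.ink)
        if ink.ndim != 2:
            raise ValueError(f"expected HxW boolean ink, got shape {ink.shape}")
        self.ink = ink.astype(bool, copy=False)

    @property
    def height_px(self) -> int:
        return self.ink.shape[0]

    @property
    def width_px(self) -> int:
        return self.ink.shape[1]

    @property
    def ink_count(self) -> int:
        return int(self.ink.sum())


def load_image(path: str | Path, dpi: float | None = None) -> RasterImage:
    """Read a PNG/TIFF/JPEG scan into a normalised :class:`RasterImage`.

    ``dpi`` overrides the resolution recorded in the file (if any).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input image not found: {path}")
    with Image.open(path) as im:
        file_dpi = None
        info_dpi = im.info.get("dpi")
        if info_dpi:
            file_dpi = float(info_dpi[0]) or None
        arr = np.asarray(im.convert("RGB"), dtype=np.float32) / 255.0
    return RasterImage(arr, dpi=dpi or file_dpi)


def save_image(img: RasterImage | BinaryInkImage, path: str | Path) -> None:
    """Write an image (or a binary ink image, ink = black) as PNG/TIFF/JPEG."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(img, BinaryInkImage):
        arr = np.where(img.ink, 0, 255).astype(np.uint8)
        pil = Image.fromarray(arr, mode="L")
    else:
        pil = Image.fromarray(
            np.clip(np.rint(img.pixels * 255), 0, 255).astype(np.uint8), mode="RGB"
        )
    kwargs = {}
    if getattr(img, "dpi", None):
        kwargs["dpi"] = (img.dpi, img.dpi)
    pil.save(path, **kwargs)
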