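"""Pre-processing: redaction-band stripping and grid removal.

Scanned hospital ECGs carry a black header band of redacted patient
information and a printed millimetre grid.  Both must go before line
detection: the header because it dominates any row-intensity statistic, the
grid because it is ink-coloured noise to a Hough transform.

Grid removal exploits the grid's colour: the red channel is saturated to 1,
the image converted to grey, and everything brighter than a fixed threshold
(default 0.94) is discarded as background.  Red/pink gridlines become
near-white under red saturation while black signal ink and printed lead
names stay dark, so the surviving dark pixels are signal and text only.
"""

from __future__ import annotations

import numpy as np

from .errors import EntirelyRedactedError
from .image_io import BinaryInkImage, RasterImage
from .params import DEFAULT_PARAMS, PipelineParams

#: Luminance weights applied after red saturation (ITU-R BT.601).
_GREY_WEIGHTS = np.array([0.299, 0.587, 0.114], dtype=np.float32)


def strip_redaction(img: RasterImage, params: PipelineParams = DEFAULT_PARAMS) -> RasterImage:
    """Remove the top-anchored band of all-black rows, if present.

    A row belongs to the redaction band when its mean intensity is below a
    near-zero tolerance (anti-aliased scans never produce exact zeros).  Only
    the maximal run of such rows touching the top edge is stripped — the
    header is at the top of the page; black rows elsewhere are content.

    Raises
    ------
    EntirelyRedactedError
        If every row of the image is black.
    """
    row_mean = img.pixels.mean(axis=(1, 2))
    black = row_mean < params.redaction_tol
    if bool(black.all()):
        raise EntirelyRedactedError("entirely redacted image: every row is black")
    n_top = 0
    while n_top < black.size and black[n_top]:
        n_top += 1
    if n_top == 0:
        return img
    return RasterImage(img.pixels[n_top:], dpi=img.dpi)


def remove_grid(img: RasterImage, params: PipelineParams = DEFAULT_PARAMS) -> BinaryInkImage:
    """Suppress the millimetre grid and binarise to an ink image.

    The red channel is set to 1 everywhere, the image converted to grey
    with standard luminance weighting, and pixels with grey value at or
    below ``params.gray_threshold`` are kept as ink (signal or lead-name
    text); brighter pixels are background/grid.  An empty ink image is a
    legal output.
    """
    px = img.pixels
    grey = (
        _GREY_WEIGHTS[0]  # red saturated to 1
        + _GREY_WEIGHTS[1] * px[:, :, 1]
        + _GREY_WEIGHTS[2] * px[:, :, 2]
    )
    return BinaryInkImage(grey <= params.gray_threshold, dpi=img.dpi)


def binary_to_raster(bin_img: BinaryInkImage) -> RasterImage:
    """Render an ink image back to RGB (ink = black) for round-trips/debug."""
    grey = np.where(bin_img.ink, 0.0, 1.0).astype(np.float32)
    return RasterImage(np.repeat(grey[:, :, None], 3, axis=2), dpi=bin_img.dpi)
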