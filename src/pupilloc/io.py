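"""Image reading/writing helpers.

All pipeline code works on 8-bit single-channel ``numpy`` rasters with the
convention x = column index, y = row index, 0-based, pixel centers at integer
coordinates.  RGB inputs are converted with the Rec. 601 luma weights and
16-bit inputs are rescaled to 8-bit; both conversions are logged.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw

logger = logging.getLogger(__name__)

# Rec. 601 luma weights for RGB -> gray
_LUMA = np.array([0.299, 0.587, 0.114])


def load_gray_image(path: str | Path) -> np.ndarray:
    """Read a PNG/JPEG/PGM/BMP file as an 8-bit grayscale array (H, W)."""
    with Image.open(path) as im:
        if im.mode in ("I", "I;16", "I;16B", "I;16L"):
            arr = np.asarray(im, dtype=np.float64)
            logger.warning("%s: 16-bit input rescaled to 8-bit", path)
            peak = max(arr.max(), 1.0)
            scale = 255.0 / peak if peak > 255 else 1.0
            return np.clip(arr * scale, 0, 255).astype(np.uint8)
        if im.mode not in ("L",):
            logger.info("%s: converting mode %s to gray (Rec. 601)", path, im.mode)
            rgb = np.asarray(im.convert("RGB"), dtype=np.float64)
            return np.clip(rgb @ _LUMA, 0, 255).round().astype(np.uint8)
        return np.asarray(im, dtype=np.uint8)


def save_gray_image(img: np.ndarray, path: str | Path) -> None:
    Image.fromarray(np.asarray(img, dtype=np.uint8), mode="L").save(path)


def save_annotated(
    img: np.ndarray,
    path: str | Path,
    xc: float,
    yc: float,
    radius: float,
    cross_half: int = 8,
) -> None:
    """Write an RGB copy of *img* with a cross at the located center and a
    circle of the reported equivalent radius (cosmetic overlay)."""
    im = Image.fromarray(np.asarray(img, dtype=np.uint8), mode="L").convert("RGB")
    draw = ImageDraw.Draw(im)
    green, red = (0, 255, 0), (255, 0, 0)
    draw.line([(xc - cross_half, yc), (xc + cross_half, yc)], fill=green, width=1)
    draw.line([(xc, yc - cross_half), (xc, yc + cross_half)], fill=green, width=1)
    draw.ellipse(
        [xc - radius, yc - radius, xc + radius, yc + radius], outline=red, width=1
    )
    im.save(path)
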