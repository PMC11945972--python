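"""Rough pupil ROI extraction from grayscale statistics.

In near-infrared periocular images the pupil is the darkest structure, so its
pixels populate the lowest-gray mode of the histogram regardless of defocus
level.  The stage therefore:

1. thresholds at the valley to the right of the lowest significant histogram
   peak (adaptive; no fixed gray value),
2. binarizes (foreground = gray <= T),
3. takes per-row and per-column integral projections of the foreground and
   keeps the main interval of each profile (counts >= 15 % of the profile
   maximum),
4. expands the resulting rectangle by 1/20 of the image long side on every
   side, to tolerate glints that eat into the thresholded pupil support.

The output rectangle is a mask for the geometric refinement stage; it is
deliberately generous rather than tight.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .config import AppConfig
from .errors import EmptyImage, EmptyProfile, NoPupilCandidate, NoValleyFound

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Rect:
    """Axis-aligned pixel rectangle; x0/y0 inclusive, x1/y1 exclusive."""

    x0: int
    y0: int
    x1: int
    y1: int

    @property
    def width(self) -> int:
        return self.x1 - self.x0

    @property
    def height(self) -> int:
        return self.y1 - self.y0

    def contains_point(self, x: float, y: float) -> bool:
        return self.x0 <= x < self.x1 and self.y0 <= y < self.y1

    def contains_rect(self, other: "Rect") -> bool:
        return (
            self.x0 <= other.x0
            and self.y0 <= other.y0
            and self.x1 >= other.x1
            and self.y1 >= other.y1
        )


@dataclass
class RoiResult:
    """Rough ROI: expanded rectangle, thresholded mask cropped to it, and the
    gray threshold that produced the mask."""

    rect: Rect
    mask: np.ndarray  # bool, shape (rect.height, rect.width)
    threshold: int
    used_fallback: bool


def compute_histogram(img: np.ndarray) -> np.ndarray:
    """256-bin gray histogram; counts[g] = number of pixels of intensity g."""
    if img.size == 0:
        raise EmptyImage("histogram of an empty image")
    return np.bincount(np.asarray(img, dtype=np.uint8).ravel(), minlength=256)


def _smooth_counts(counts: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with zero padding outside [0, 255]."""
    kernel = np.full(window, 1.0 / window)
    return np.convolve(counts.astype(np.float64), kernel, mode="same")


def _local_maxima(smooth: np.ndarray) -> list[int]:
    """Left-most gray levels of strictly positive local maxima; plateaus are
    collapsed to their left edge (array boundaries count as lower)."""
    peaks: list[int] = []
    n = len(smooth)
    i = 0
    prev = -np.inf
    while i < n:
        j = i
        while j + 1 < n and smooth[j + 1] == smooth[i]:
            j += 1
        nxt = smooth[j + 1] if j + 1 < n else -np.inf
        if smooth[i] > prev and smooth[i] > nxt and smooth[i] > 0:
            peaks.append(i)
        prev = smooth[i]
        i = j + 1
    return peaks


# A valley deeper than this fraction of the lower neighboring peak separates
# two genuine modes; shallower dips are sampling noise within one mode.
_MERGE_VALLEY_FRAC = 0.5


def _histogram_modes(
    smooth: np.ndarray, counts: np.ndarray
) -> list[tuple[int, int, int, float]]:
    """Decompose the smoothed histogram into modes.

    Adjacent local maxima separated by a shallow valley (valley count above
    ``_MERGE_VALLEY_FRAC`` of the lower peak) are merged into one mode, so
    sampling noise within a gray mode never splits it.  Returns a list of
    (peak_gray, support_lo, support_hi, mass) with mass = raw pixel count
    over the mode's support [lo, hi].
    """
    maxima = _local_maxima(smooth)
    # mode entries: [peak, lo, hi]; valleys recomputed lazily from smooth
    modes: list[list[int]] = []
    for p in maxima:
        modes.append([p, p, p])
    # merge shallow-valley neighbors, left to right, until stable
    merged = True
    while merged and len(modes) > 1:
        merged = False
        out: list[list[int]] = [modes[0]]
        for nxt in modes[1:]:
            cur = out[-1]
            seg = smooth[cur[0] + 1 : nxt[0]]
            valley = seg.min() if seg.size else min(smooth[cur[0]], smooth[nxt[0]])
            lower_peak = min(smooth[cur[0]], smooth[nxt[0]])
            if valley > _MERGE_VALLEY_FRAC * lower_peak:
                # same mode: keep the taller maximum as the peak
                peak = cur[0] if smooth[cur[0]] >= smooth[nxt[0]] else nxt[0]
                out[-1] = [peak, cur[1], nxt[2]]
                merged = True
            else:
                out.append(nxt)
        modes = out
    # supports: split gray axis at the deepest valley between peaks
    result: list[tuple[int, int, int, float]] = []
    bounds = [0]
    for left, right in zip(modes[:-1], modes[1:]):
        seg = smooth[left[0] + 1 : right[0]]
        cut = left[0] + 1 + int(np.argmin(seg)) if seg.size else right[0]
        bounds.append(cut)
    bounds.append(len(smooth))
    for mode, lo, hi in zip(modes, bounds[:-1], bounds[1:]):
        mass = float(counts[lo:hi].sum())
        result.append((mode[0], lo, hi - 1, mass))
    return result


def histogram_valley_threshold(
    counts: np.ndarray, smooth_window: int = 5, min_peak_frac: float = 0.001
) -> int:
    """Gray level of the valley after the lowest significant histogram peak.

    The histogram is smoothed with a centered moving average and decomposed
    into modes; a mode is significant when it holds at least
    ``min_peak_frac`` of all pixels.  The threshold is the smallest gray
    level attaining the minimum smoothed count strictly between the peaks of
    the first (darkest) and second significant modes.

    Raises
    ------
    NoValleyFound
        If fewer than two significant modes exist (no brighter mode to
        separate the dark one from).
    """
    if smooth_window < 1:
        raise ValueError("smooth_window must be >= 1")
    total = int(counts.sum())
    if total == 0:
        raise NoValleyFound("empty histogram")
    smooth = _smooth_counts(counts, smooth_window)
    modes = _histogram_modes(smooth, np.asarray(counts))
    significant = [m for m in modes if m[3] >= min_peak_frac * total]
    if len(significant) < 2:
        raise NoValleyFound(
            f"{len(significant)} significant mode(s); "
            "need a dark mode and a brighter mode"
        )
    p0, p1 = significant[0][0], significant[1][0]
    segment = smooth[p0 + 1 : p1]
    if segment.size == 0:
        raise NoValleyFound("adjacent peaks leave no valley gray level")
    return p0 + 1 + int(np.argmin(segment))


def fallback_threshold(counts: np.ndarray, quantile: float = 0.05) -> int | None:
    """Dark-tail fallback: largest gray level T whose cumulative histogram
    fraction stays <= *quantile* (the pupil occupies a small dark fraction).

    Returns None when even gray level 0 already exceeds the quantile, i.e.
    no usable dark tail exists.
    """
    total = int(counts.sum())
    cum = np.cumsum(counts)
    ok = np.flatnonzero(cum <= quantile * total)
    if ok.size == 0:
        return None
    return int(ok[-1])


def binarize(img: np.ndarray, threshold: int) -> np.ndarray:
    """Foreground (True) = gray <= threshold, inclusive."""
    if not 0 <= threshold <= 255:
        raise ValueError("threshold must lie in [0, 255]")
    return np.asarray(img) <= threshold


def integral_projection(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-row and per-column foreground counts of a binary mask."""
    if mask.size == 0:
        raise EmptyImage("projection of an empty mask")
    m = np.asarray(mask, dtype=bool)
    return m.sum(axis=1), m.sum(axis=0)


def profile_main_interval(profile: np.ndarray, frac: float = 0.15) -> tuple[int, int]:
    """First and last index (inclusive) where the profile reaches
    ``frac * max(profile)``."""
    if not 0.0 < frac < 1.0:
        raise ValueError("frac must lie in (0, 1)")
    profile = np.asarray(profile)
    peak = profile.max(initial=0)
    if peak == 0:
        raise EmptyProfile("all-zero projection profile")
    idx = np.flatnonzero(profile >= frac * peak)
    return int(idx[0]), int(idx[-1])


def expand_rect(rect: Rect, height: int, width: int, divisor: int = 20) -> Rect:
    """Move each side outward by ``long_side // divisor`` px, clamped."""
    margin = max(height, width) // divisor
    return Rect(
        x0=max(0, rect.x0 - margin),
        y0=max(0, rect.y0 - margin),
        x1=min(width, rect.x1 + margin),
        y1=min(height, rect.y1 + margin),
    )


def extract_rough_roi(img: np.ndarray, cfg: AppConfig | None = None) -> RoiResult:
    """Grayscale-constraint stage: adaptive threshold, integral projection,
    main-interval rectangle, 1/20-long-side expansion.

    Raises
    ------
    NoPupilCandidate
        When neither the valley rule nor the dark-tail fallback yields any
        foreground (e.g. a uniform image).
    """
    cfg = cfg or AppConfig()
    if img.size == 0:
        raise EmptyImage("cannot extract ROI from an empty image")
    h, w = img.shape
    counts = compute_histogram(img)
    used_fallback = False
    try:
        threshold = histogram_valley_threshold(
            counts, cfg.smooth_window, cfg.min_peak_frac
        )
    except NoValleyFound as exc:
        used_fallback = True
        t = fallback_threshold(counts, cfg.fallback_quantile)
        if t is None:
            raise NoPupilCandidate("no histogram valley and no dark tail") from exc
        logger.warning("valley not found (%s); dark-tail fallback T=%d", exc, t)
        threshold = t
    mask = binarize(img, threshold)
    try:
        rows, cols = integral_projection(mask)
        r0, r1 = profile_main_interval(rows, cfg.projection_frac)
        c0, c1 = profile_main_interval(cols, cfg.projection_frac)
    except EmptyProfile as exc:
        raise NoPupilCandidate("thresholding produced no foreground") from exc
    rect = expand_rect(
        Rect(x0=c0, y0=r0, x1=c1 + 1, y1=r1 + 1), h, w, cfg.expand_divisor
    )
    return RoiResult(
        rect=rect,
        mask=mask[rect.y0 : rect.y1, rect.x0 : rect.x1].copy(),
        threshold=threshold,
        used_fallback=used_fallback,
    )
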