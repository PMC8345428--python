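"""Fast background filtering: discard background-only tiles before inference.

Papanicolaou-stained material is colored on a bright, unsaturated
background, so a tissue/background split falls out of the HSV saturation
channel of a low-resolution thumbnail. The whole filter touches only the
thumbnail (at most ``(W/d)·(H/d)`` pixels for downsample ``d``); level-0
tiles are never read here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, NamedTuple, Tuple, Union

import numpy as np
from skimage.color import rgb2gray, rgb2hsv
from skimage.filters import threshold_otsu

from .slide_io import SlideHandle, TileGrid, TileRef

__all__ = ["FilterConfig", "TissueMask", "FilterCounts",
           "compute_tissue_mask", "select_tiles"]


@dataclass
class FilterConfig:
    """Tissue-detection knobs.

    downsample
        Thumbnail downsample factor relative to level 0 (default 32).
    saturation_floor
        Either an 8-bit saturation threshold, or ``"otsu"`` to derive the
        threshold from the thumbnail's saturation histogram. The Otsu
        estimate is clamped from below by ``otsu_floor`` so that a slide
        with no stained material at all does not get its sensor noise
        split into a spurious "tissue" class.
    tissue_fraction_min
        Minimum fraction of tissue pixels in a tile's thumbnail footprint
        for the tile to be kept (default 0.05).
    brightness_max
        8-bit luminance ceiling: pixels at least this bright are always
        background (glass), whatever their saturation.
    """

    downsample: float = 32.0
    saturation_floor: Union[int, str] = "otsu"
    tissue_fraction_min: float = 0.05
    otsu_floor: int = 20
    brightness_max: int = 250

    def __post_init__(self):
        if not 0.0 <= self.tissue_fraction_min <= 1.0:
            raise ValueError("tissue_fraction_min must be in [0, 1]")
        if self.downsample < 1:
            raise ValueError("downsample must be >= 1")


@dataclass
class TissueMask:
    """Boolean tissue map at a stated downsample of the level-0 frame."""

    mask: np.ndarray  # (h, w) bool
    downsample: float

    @property
    def tissue_fraction(self) -> float:
        return float(self.mask.mean()) if self.mask.size else 0.0


class FilterCounts(NamedTuple):
    kept: int
    discarded: int
    total: int


def compute_tissue_mask(slide: SlideHandle, cfg: FilterConfig = FilterConfig()) -> TissueMask:
    """Threshold the thumbnail's HSV saturation into a tissue mask.

    A pixel is tissue iff its saturation exceeds the threshold and its
    luminance is below ``brightness_max``; deterministic for fixed input.
    """
    thumb = slide.thumbnail(cfg.downsample).astype(np.float32) / 255.0
    sat = rgb2hsv(thumb)[:, :, 1]
    luma = rgb2gray(thumb)

    if cfg.saturation_floor == "otsu":
        floor = cfg.otsu_floor / 255.0
        if float(np.ptp(sat)) < 1.0 / 255.0:
            warnings.warn(
                "degenerate thumbnail (constant saturation); "
                "falling back to fixed saturation floor",
                stacklevel=2,
            )
            thr = floor
        else:
            thr = float(threshold_otsu(sat))
            if thr < floor:
                warnings.warn(
                    "Otsu saturation threshold below fixed floor; clamping "
                    "(thumbnail is background-dominated)",
                    stacklevel=2,
                )
                thr = floor
    else:
        thr = float(cfg.saturation_floor) / 255.0

    tissue = (sat > thr) & (luma < cfg.brightness_max / 255.0)
    return TissueMask(mask=tissue, downsample=cfg.downsample)


def select_tiles(
    grid: TileGrid, tissue: TissueMask, cfg: FilterConfig = FilterConfig()
) -> Tuple[List[TileRef], FilterCounts]:
    """Keep every tile whose thumbnail footprint is sufficiently tissue.

    A tile is kept iff the fraction of tissue pixels inside its
    (downsampled) footprint is at least ``tissue_fraction_min``; with a
    zero threshold every tile is kept. ``kept + discarded`` always equals
    the grid's tile count.
    """
    d = tissue.downsample
    m = tissue.mask
    h, w = m.shape
    # integral image for O(1) footprint sums
    integral = np.zeros((h + 1, w + 1), dtype=np.int64)
    integral[1:, 1:] = np.cumsum(np.cumsum(m.astype(np.int64), axis=0), axis=1)

    kept: List[TileRef] = []
    for tile in grid.tiles():
        c0 = min(int(tile.x0 / d), w)
        r0 = min(int(tile.y0 / d), h)
        c1 = min(int(np.ceil(tile.x1 / d)), w)
        r1 = min(int(np.ceil(tile.y1 / d)), h)
        area = max(0, (r1 - r0)) * max(0, (c1 - c0))
        if area == 0:
            frac = 0.0
        else:
            s = (integral[r1, c1] - integral[r0, c1]
                 - integral[r1, c0] + integral[r0, c0])
            frac = s / area
        if frac >= cfg.tissue_fraction_min:
            kept.append(tile)
    total = len(grid)
    return kept, FilterCounts(kept=len(kept), discarded=total - len(kept), total=total)
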