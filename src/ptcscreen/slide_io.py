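"""Whole-slide image access and the tile decomposition.

Slides are pyramidal (or plain) tiled TIFFs read through :mod:`tifffile`'s
zarr interface, so only the requested region's tiles are ever decoded —
the same code path serves a 4k-pixel fixture and a gigapixel scan.
Coordinates are 0-based, half-open, in the level-0 pixel frame with
``x`` = column and ``y`` = row.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, List, Optional, Sequence, Tuple, Union

import numpy as np
import tifffile
import zarr

__all__ = [
    "SlideFormatError",
    "SlideHandle",
    "TileGrid",
    "TileRef",
    "SlideMask",
    "open_slide",
    "build_tile_grid",
    "read_tile",
    "write_slide_mask",
    "read_slide_mask",
]


class SlideFormatError(ValueError):
    """Raised when a file exists but is not a readable TIFF image."""


@dataclass(frozen=True)
class TileRef:
    """One tile's level-0 pixel bounds, half-open ``[x0,x1) × [y0,y1)``."""

    row: int
    col: int
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


class SlideHandle:
    """An open whole-slide image with tiled, level-aware pixel access.

    Parameters
    ----------
    path:
        A tiled/pyramidal TIFF (BigTIFF allowed) or plain large TIFF.
        Non-pyramidal files get a single level with downsample 1.0.
    """

    def __init__(self, path: Union[str, os.PathLike]):
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"slide file not found: {path}")
        try:
            self._tif = tifffile.TiffFile(str(path))
        except Exception as exc:  # tifffile raises several error types
            raise SlideFormatError(f"not a readable TIFF image: {path}") from exc
        self.source_path = path
        series = self._tif.series[0]
        shape = series.levels[0].shape
        if len(shape) < 2:
            self._tif.close()
            raise SlideFormatError(f"not a 2-D image: {path}")
        self.height_px = int(shape[0])
        self.width_px = int(shape[1])
        self.levels: List[float] = []
        for lvl in series.levels:
            self.levels.append(self.width_px / int(lvl.shape[1]))
        self.mpp: Optional[float] = self._read_mpp()
        self._series = series
        self._zarr = zarr.open(series.aszarr(), mode="r")

    def _read_mpp(self) -> Optional[float]:
        page = self._tif.pages[0]
        res = page.tags.get("XResolution")
        unit = page.tags.get("ResolutionUnit")
        if res is None or unit is None:
            return None
        num, den = res.value
        if num == 0:
            return None
        px_per_unit = num / den
        unit_um = {2: 25400.0, 3: 10000.0}.get(int(unit.value))
        if unit_um is None:
            return None
        return unit_um / px_per_unit

    def _level_array(self, level: int):
        if isinstance(self._zarr, zarr.Group):
            return self._zarr[str(level)]
        return self._zarr

    def read_region(
        self, x0: int, y0: int, x1: int, y1: int, level: int = 0
    ) -> np.ndarray:
        """Read ``[y0:y1, x0:x1]`` from the given pyramid level as uint8 RGB."""
        arr = self._level_array(level)
        h, w = arr.shape[:2]
        if not (0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h):
            raise ValueError(
                f"region [{x0},{x1})x[{y0},{y1}) outside level-{level} "
                f"extent {w}x{h}"
            )
        region = np.asarray(arr[y0:y1, x0:x1])
        if region.ndim == 2:
            region = np.repeat(region[:, :, None], 3, axis=2)
        return region[:, :, :3]

    def best_level_for_downsample(self, downsample: float) -> int:
        """Largest-indexed level whose downsample does not exceed the target."""
        best = 0
        for i, d in enumerate(self.levels):
            if d <= downsample + 1e-9:
                best = i
        return best

    def thumbnail(self, downsample: float) -> np.ndarray:
        """A whole-slide RGB thumbnail at the requested downsample factor.

        Reads the coarsest pyramid level not finer than needed, then
        area-resizes to ``ceil(W/d) × ceil(H/d)``; level 0 is touched only
        for single-level files.
        """
        from skimage.transform import resize

        level = self.best_level_for_downsample(downsample)
        arr = np.asarray(self._level_array(level))
        if arr.ndim == 2:
            arr = np.repeat(arr[:, :, None], 3, axis=2)
        arr = arr[:, :, :3]
        out_h = math.ceil(self.height_px / downsample)
        out_w = math.ceil(self.width_px / downsample)
        if arr.shape[:2] == (out_h, out_w):
            return arr
        thumb = resize(arr, (out_h, out_w), anti_aliasing=True, preserve_range=True)
        return thumb.astype(np.uint8)

    def close(self) -> None:
        self._tif.close()

    def __enter__(self) -> "SlideHandle":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    def __repr__(self) -> str:
        return (
            f"SlideHandle({self.source_path.name!r}, {self.width_px}x"
            f"{self.height_px}, levels={[round(d, 2) for d in self.levels]})"
        )


@dataclass
class TileGrid:
    """Non-overlapping partition of a slide into ``tile_px`` squares."""

    tile_px: int
    n_cols: int
    n_rows: int
    width_px: int
    height_px: int
    slide_ref: Optional[SlideHandle] = field(default=None, repr=False)

    @classmethod
    def from_dimensions(cls, width_px: int, height_px: int, tile_px: int) -> "TileGrid":
        if tile_px <= 0:
            raise ValueError(f"tile_px must be positive, got {tile_px}")
        if width_px < 1 or height_px < 1:
            raise ValueError("slide dimensions must be >= 1")
        return cls(
            tile_px=tile_px,
            n_cols=math.ceil(width_px / tile_px),
            n_rows=math.ceil(height_px / tile_px),
            width_px=width_px,
            height_px=height_px,
        )

    def __len__(self) -> int:
        return self.n_cols * self.n_rows

    def tile(self, row: int, col: int) -> TileRef:
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise ValueError(f"tile ({row},{col}) outside grid "
                             f"{self.n_rows}x{self.n_cols}")
        x0 = col * self.tile_px
        y0 = row * self.tile_px
        return TileRef(
            row=row,
            col=col,
            x0=x0,
            y0=y0,
            x1=min(x0 + self.tile_px, self.width_px),
            y1=min(y0 + self.tile_px, self.height_px),
        )

    def tiles(self) -> Iterator[TileRef]:
        for row in range(self.n_rows):
            for col in range(self.n_cols):
                yield self.tile(row, col)


@dataclass
class SlideMask:
    """Per-pixel label image sharing the level-0 frame of its parent slide."""

    labels: np.ndarray  # (H, W) small non-negative integers

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("mask labels must be a 2-D array")

    @property
    def width_px(self) -> int:
        return int(self.labels.shape[1])

    @property
    def height_px(self) -> int:
        return int(self.labels.shape[0])


def open_slide(path: Union[str, os.PathLike]) -> SlideHandle:
    """Open a tiled/pyramidal TIFF whole-slide image."""
    return SlideHandle(path)


def build_tile_grid(slide, tile_px: int = 512) -> TileGrid:
    """Decompose a slide (or a ``(width, height)`` pair) into the tile grid."""
    if isinstance(slide, SlideHandle):
        grid = TileGrid.from_dimensions(slide.width_px, slide.height_px, tile_px)
        grid.slide_ref = slide
        return grid
    width_px, height_px = slide
    return TileGrid.from_dimensions(width_px, height_px, tile_px)


def read_tile(slide: SlideHandle, tile: TileRef) -> np.ndarray:
    """Pixel-exact level-0 RGB region of one tile.

    Edge tiles come back at their true (smaller) size; padding to the
    network input size is the inference caller's concern.
    """
    if not (
        0 <= tile.x0 < tile.x1 <= slide.width_px
        and 0 <= tile.y0 < tile.y1 <= slide.height_px
    ):
        raise ValueError(
            f"tile bounds [{tile.x0},{tile.x1})x[{tile.y0},{tile.y1}) outside "
            f"slide {slide.width_px}x{slide.height_px}"
        )
    return slide.read_region(tile.x0, tile.y0, tile.x1, tile.y1, level=0)


def write_slide_mask(
    mask: Union[SlideMask, np.ndarray],
    path: Union[str, os.PathLike],
    expected_shape: Optional[Tuple[int, int]] = None,
) -> None:
    """Write a label mask as a single-channel tiled TIFF (lossless).

    BigTIFF is used automatically when the pixel count exceeds what a
    classic TIFF can address.
    """
    labels = mask.labels if isinstance(mask, SlideMask) else np.asarray(mask)
    if labels.ndim != 2:
        raise ValueError("mask must be 2-D")
    if expected_shape is not None and tuple(labels.shape) != tuple(expected_shape):
        raise ValueError(
            f"mask shape {labels.shape} does not match declared {expected_shape}"
        )
    labels = labels.astype(np.uint8)
    bigtiff = labels.size >= 2**31
    tile = (min(256, labels.shape[0]), min(256, labels.shape[1]))
    # tifffile requires tile sides that are multiples of 16
    tile = tuple(max(16, (t // 16) * 16) for t in tile)
    tifffile.imwrite(
        str(path), labels, tile=tile, photometric="minisblack", bigtiff=bigtiff
    )


def read_slide_mask(path: Union[str, os.PathLike]) -> SlideMask:
    """Read back a label mask written by :func:`write_slide_mask`."""
    return SlideMask(labels=tifffile.imread(str(path)))
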