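"""Whole-slide screening: tile, filter, segment, stitch, report.

Discarded background tiles are never scored by the network — that skip is
the entire speed advantage of the approach — and contribute label 0 to
the stitched mask. Tiles partition the slide, so stitching is plain
placement with no blending.
"""

from __future__ import annotations

import csv
import time
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from .background import FilterConfig, compute_tissue_mask, select_tiles
from .nn.model import FCNModel
from .slide_io import (SlideHandle, SlideMask, TileGrid, TileRef,
                       build_tile_grid, read_tile, write_slide_mask)

__all__ = ["ScreeningReport", "screen_slide", "stitch", "append_report_csv"]

PTC_LABEL = 2


@dataclass
class ScreeningReport:
    """Per-slide bookkeeping row (feeds the cohort tile-count histogram)."""

    slide_id: str
    total_tiles: int
    kept_tiles: int
    inferred_tiles: int
    ptc_pixel_count: int
    ptc_area_fraction: float  # of predicted non-background (tissue) pixels
    wall_seconds: float  # informational only


def stitch(
    tiles: Sequence[Tuple[TileRef, np.ndarray]],
    width_px: int,
    height_px: int,
) -> SlideMask:
    """Place per-tile label maps into a whole-slide mask.

    Tiles must be pairwise non-overlapping and inside the slide; pixels
    not covered by any tile get label 0.
    """
    mask = np.zeros((height_px, width_px), dtype=np.uint8)
    covered = np.zeros((height_px, width_px), dtype=bool)
    for ref, labels in tiles:
        labels = np.asarray(labels)
        if not (0 <= ref.x0 < ref.x1 <= width_px
                and 0 <= ref.y0 < ref.y1 <= height_px):
            raise ValueError(f"tile {ref} outside slide {width_px}x{height_px}")
        if labels.shape != (ref.height, ref.width):
            raise ValueError(
                f"tile {ref.row},{ref.col}: label map {labels.shape} does not "
                f"match bounds {(ref.height, ref.width)}")
        region = covered[ref.y0:ref.y1, ref.x0:ref.x1]
        if region.any():
            raise ValueError(f"tile {ref.row},{ref.col} overlaps a prior tile")
        region[:] = True
        mask[ref.y0:ref.y1, ref.x0:ref.x1] = labels
    return SlideMask(labels=mask)


def _pad_to_square(img: np.ndarray, n: int) -> np.ndarray:
    """Reflect-pad an edge tile up to n×n (symmetric mode handles 1-px sides)."""
    ph, pw = n - img.shape[0], n - img.shape[1]
    if ph == 0 and pw == 0:
        return img
    return np.pad(img, ((0, ph), (0, pw), (0, 0)), mode="symmetric")


def screen_slide(
    slide: SlideHandle,
    model: FCNModel,
    filter_cfg: Optional[FilterConfig] = None,
    out_path: Optional[Union[str, Path]] = None,
    report_path: Optional[Union[str, Path]] = None,
    no_filter: bool = False,
    slide_id: Optional[str] = None,
) -> Tuple[SlideMask, ScreeningReport]:
    """Run the full screening pipeline on one slide.

    Tiles the slide at the model's input size, discards background tiles
    via the fast filter (unless ``no_filter``), segments the kept tiles
    (edge tiles reflect-padded to the input size and predictions cropped
    back), and stitches a whole-slide label mask.
    """
    t0 = time.perf_counter()
    if filter_cfg is None:
        filter_cfg = FilterConfig()
    tile_px = model.cfg.input_px
    grid = build_tile_grid(slide, tile_px)

    if no_filter:
        kept: List[TileRef] = list(grid.tiles())
        total = len(grid)
    else:
        tissue = compute_tissue_mask(slide, filter_cfg)
        kept, counts = select_tiles(grid, tissue, filter_cfg)
        total = counts.total

    pieces: List[Tuple[TileRef, np.ndarray]] = []
    for ref in kept:
        img = read_tile(slide, ref)
        padded = _pad_to_square(img, tile_px)
        class_map, _ = model.predict_tile(padded)
        pieces.append((ref, class_map[: ref.height, : ref.width]))
    mask = stitch(pieces, slide.width_px, slide.height_px)

    labels = mask.labels
    ptc_px = int((labels == PTC_LABEL).sum())
    tissue_px = int((labels != 0).sum())
    report = ScreeningReport(
        slide_id=slide_id or slide.source_path.stem,
        total_tiles=total,
        kept_tiles=len(kept),
        inferred_tiles=len(kept),
        ptc_pixel_count=ptc_px,
        ptc_area_fraction=ptc_px / tissue_px if tissue_px else 0.0,
        wall_seconds=time.perf_counter() - t0,
    )
    if out_path is not None:
        write_slide_mask(mask, out_path)
    if report_path is not None:
        append_report_csv(report, report_path)
    return mask, report


def append_report_csv(report: ScreeningReport, path: Union[str, Path]) -> None:
    """Append one report row (header written on first use)."""
    path = Path(path)
    new = not path.exists()
    with open(path, "a", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(asdict(report)))
        if new:
            writer.writeheader()
        writer.writerow(asdict(report))
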