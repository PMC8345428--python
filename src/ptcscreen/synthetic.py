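"""Deterministic papanicolaou-like synthetic slides with exact ground truth.

Real cytology slides show colored cell clusters scattered on bright glass;
the generator emulates that contract — and nothing more — with ellipsoidal
clusters of two stained classes (pale-blue benign material, dark-violet
PTC) on a near-white noisy background. Truth labels are recorded at paint
time, so every downstream stage can be scored against exact references.
Same seed, same bytes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Tuple, Union

import numpy as np
import tifffile

from .training import TrainingSample

__all__ = ["FixtureSpec", "generate_slide", "generate_training_tiles",
           "write_slide_tiff"]

BENIGN_LABEL = 1
PTC_LABEL = 2


@dataclass
class FixtureSpec:
    """Parameters of one synthetic slide.

    ``ptc_fraction`` is the share of clusters labeled PTC (assigned
    exactly, then shuffled); ``cluster_radius_px`` bounds the ellipse
    semi-axes. Colors are chosen so HSV saturation separates both tissue
    classes from background by construction.
    """

    width_px: int = 2048
    height_px: int = 2048
    n_clusters: int = 12
    ptc_fraction: float = 0.5
    cluster_radius_px: Tuple[int, int] = (40, 120)
    background_rgb: Tuple[int, int, int] = (245, 245, 245)
    ptc_rgb: Tuple[int, int, int] = (110, 50, 140)      # dark violet
    benign_rgb: Tuple[int, int, int] = (170, 200, 230)  # pale blue
    noise_sd: float = 3.0
    texture_sd: float = 8.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.ptc_fraction <= 1.0:
            raise ValueError("ptc_fraction must be in [0, 1]")
        lo, hi = self.cluster_radius_px
        if lo < 2 or hi < lo:
            raise ValueError("invalid cluster_radius_px range")


def _place_clusters(spec: FixtureSpec, rng: np.random.Generator) -> List[dict]:
    """Sample non-overlapping ellipses fully inside the canvas."""
    n_ptc = round(spec.n_clusters * spec.ptc_fraction)
    labels = [PTC_LABEL] * n_ptc + [BENIGN_LABEL] * (spec.n_clusters - n_ptc)
    rng.shuffle(labels)
    lo, hi = spec.cluster_radius_px
    placed: List[dict] = []
    for label in labels:
        for _ in range(200):
            a = float(rng.uniform(lo, hi))
            b = float(rng.uniform(lo, hi))
            r = max(a, b)
            if (spec.width_px - 2 * math.ceil(r) <= 1
                    or spec.height_px - 2 * math.ceil(r) <= 1):
                continue
            cx = float(rng.uniform(r + 1, spec.width_px - r - 1))
            cy = float(rng.uniform(r + 1, spec.height_px - r - 1))
            theta = float(rng.uniform(0, math.pi))
            if all((cx - p["cx"]) ** 2 + (cy - p["cy"]) ** 2
                   > (r + p["r_max"] + 2) ** 2 for p in placed):
                placed.append(dict(cx=cx, cy=cy, a=a, b=b, theta=theta,
                                   r_max=r, label=int(label)))
                break
        else:
            raise RuntimeError(
                f"could not place cluster after 200 retries for spec {spec}")
    return placed


def _paint(canvas: np.ndarray, truth: np.ndarray, cluster: dict,
           spec: FixtureSpec, rng: np.random.Generator) -> int:
    """Rasterize one ellipse; returns the painted pixel count."""
    cx, cy, a, b, th = (cluster[k] for k in ("cx", "cy", "a", "b", "theta"))
    r = cluster["r_max"]
    x0, x1 = int(cx - r) - 1, int(cx + r) + 2
    y0, y1 = int(cy - r) - 1, int(cy + r) + 2
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx, dy = xx - cx, yy - cy
    u = dx * math.cos(th) + dy * math.sin(th)
    v = -dx * math.sin(th) + dy * math.cos(th)
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    color = spec.ptc_rgb if cluster["label"] == PTC_LABEL else spec.benign_rgb
    patch = canvas[y0:y1, x0:x1]
    texture = rng.normal(0.0, spec.texture_sd, size=(*inside.shape, 3))
    stained = np.clip(np.asarray(color, dtype=np.float64) + texture, 0, 255)
    patch[inside] = stained[inside]
    truth[y0:y1, x0:x1][inside] = cluster["label"]
    return int(inside.sum())


def generate_slide(
    spec: FixtureSpec,
    out_dir: Optional[Union[str, Path]] = None,
    slide_id: str = "synthetic_slide",
) -> Tuple[np.ndarray, np.ndarray, dict]:
    """Render a synthetic slide, its truth mask, and a manifest.

    Returns ``(image, truth, manifest)``; when ``out_dir`` is given, also
    writes ``<slide_id>.tiff`` (pyramidal tiled RGB, levels ×1/×4/×16),
    ``<slide_id>_truth.tiff`` and ``<slide_id>_manifest.json``.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height_px, spec.width_px
    canvas = np.asarray(spec.background_rgb, dtype=np.float64) + \
        rng.normal(0.0, spec.noise_sd, size=(h, w, 3))
    canvas = np.clip(canvas, 0, 255)
    truth = np.zeros((h, w), dtype=np.uint8)

    clusters = _place_clusters(spec, rng)
    manifest_clusters = []
    for cl in clusters:
        painted = _paint(canvas, truth, cl, spec, rng)
        manifest_clusters.append({
            "center": [cl["cx"], cl["cy"]],
            "radii": [cl["a"], cl["b"]],
            "angle": cl["theta"],
            "label": cl["label"],
            "painted_px": painted,
        })
    image = canvas.astype(np.uint8)

    manifest = {
        "slide_id": slide_id,
        "spec": asdict(spec),
        "clusters": manifest_clusters,
        "label_pixel_counts": {
            str(lbl): int((truth == lbl).sum()) for lbl in (0, 1, 2)
        },
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_slide_tiff(image, out_dir / f"{slide_id}.tiff")
        from .slide_io import write_slide_mask
        write_slide_mask(truth, out_dir / f"{slide_id}_truth.tiff")
        (out_dir / f"{slide_id}_manifest.json").write_text(
            json.dumps(manifest, indent=2))
    return image, truth, manifest


def write_slide_tiff(image: np.ndarray, path: Union[str, Path],
                     mpp: float = 0.5) -> None:
    """Write an RGB image as a 3-level pyramidal tiled TIFF (20×-style mpp)."""
    px_per_cm = 10000.0 / mpp
    opts = dict(tile=(256, 256), photometric="rgb",
                resolution=(px_per_cm, px_per_cm), resolutionunit="CENTIMETER")
    bigtiff = image.size >= 2**31
    with tifffile.TiffWriter(str(path), bigtiff=bigtiff) as tw:
        tw.write(image, subifds=2, **opts)
        tw.write(image[::4, ::4], subfiletype=1, **opts)
        tw.write(image[::16, ::16], subfiletype=1, **opts)


def generate_training_tiles(
    spec: FixtureSpec,
    n_tiles: int,
    tile_px: int = 512,
    seed: Optional[int] = None,
) -> List[TrainingSample]:
    """Cut ``n_tiles`` labeled crops, each guaranteed to contain a cluster.

    Crops are anchored on clusters taken round-robin from a shuffled
    list, so the PTC share of tiles tracks ``spec.ptc_fraction`` closely.
    Reproducible per seed (defaults to the spec's own seed).
    """
    if n_tiles < 1:
        raise ValueError("n_tiles must be >= 1")
    if spec.width_px < tile_px or spec.height_px < tile_px:
        raise ValueError("fixture smaller than the requested tile size")
    image, truth, manifest = generate_slide(spec)
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    clusters = list(manifest["clusters"])
    if not clusters:
        raise ValueError("cannot cut cluster-anchored tiles: n_clusters = 0")
    order = rng.permutation(len(clusters))
    samples: List[TrainingSample] = []
    for i in range(n_tiles):
        cl = clusters[order[i % len(clusters)]]
        cx, cy = cl["center"]
        jx = int(rng.integers(tile_px // 4, 3 * tile_px // 4))
        jy = int(rng.integers(tile_px // 4, 3 * tile_px // 4))
        x0 = int(np.clip(round(cx) - jx, 0, spec.width_px - tile_px))
        y0 = int(np.clip(round(cy) - jy, 0, spec.height_px - tile_px))
        img = image[y0:y0 + tile_px, x0:x0 + tile_px].copy()
        lab = truth[y0:y0 + tile_px, x0:x0 + tile_px].astype(np.int64).copy()
        samples.append(TrainingSample(image=img, label_map=lab))
    return samples
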