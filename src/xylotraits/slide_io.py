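"""Reading section images and processing them as overlapping tiles.

Whole-slide scans are far larger than memory-friendly working arrays, so the
analysis runs fragment-wise: a :class:`TileGrid` covers the image with
half-open, row-major tiles; detections from overlapping tiles are merged by
centroid proximity, keeping the larger-area (less clipped) instance.

Conventions: 0-based pixel indices, origin top-left, half-open ranges.
Object geometry is in µm everywhere outside this module.

Pixel scale: TIFF files carry a resolution tag — with unit CENTIMETER the
scale is 1e4/resolution µm/px; with unit NONE the value is interpreted as
pixels per µm (the convention this package writes).  PNG has no standard
scale metadata, so a ``pixel_scale`` must be supplied explicitly; a missing
scale is always an error, never a silent default.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Sequence

import imageio.v3 as iio
import numpy as np
import tifffile

__all__ = ["TileGrid", "read_image", "write_image", "iter_tiles", "merge_tile_detections"]


@dataclass(frozen=True)
class TileGrid:
    """Half-open tile decomposition of an image.

    tile_size, overlap : pixels; image_shape : (rows, cols);
    pixel_scale : µm per pixel.  Tiles are row-major; the last tile of each
    axis is anchored to the image end so the union of tiles covers the image
    exactly.  A tile larger than the image degenerates to one whole-image
    tile.
    """

    tile_size: int = 2048
    overlap: int = 128
    image_shape: tuple[int, int] = (0, 0)
    pixel_scale: float = 1.0

    def __post_init__(self) -> None:
        if not 0 <= self.overlap < self.tile_size:
            raise ValueError("need 0 <= overlap < tile_size")
        if self.pixel_scale <= 0:
            raise ValueError("pixel_scale must be positive")

    @staticmethod
    def _starts(extent: int, tile: int, step: int) -> list[int]:
        if extent <= tile:
            return [0]
        starts = list(range(0, extent - tile, step))
        starts.append(extent - tile)  # anchor final tile at the image border
        return sorted(set(starts))

    def tile_origins(self) -> list[tuple[int, int]]:
        rows, cols = self.image_shape
        step = self.tile_size - self.overlap
        r_starts = self._starts(rows, self.tile_size, step)
        c_starts = self._starts(cols, self.tile_size, step)
        return [(r, c) for r in r_starts for c in c_starts]

    def tile_bounds(self, origin: tuple[int, int]) -> tuple[int, int, int, int]:
        """(r0, r1, c0, c1) half-open pixel bounds of the tile at ``origin``."""
        r, c = origin
        rows, cols = self.image_shape
        return r, min(r + self.tile_size, rows), c, min(c + self.tile_size, cols)


def read_image(path, pixel_scale: float | None = None) -> tuple[np.ndarray, float]:
    """Read an RGB raster and its pixel scale (µm/px).

    TIFF: the scale comes from the resolution tag (see module docstring);
    an explicit ``pixel_scale`` argument overrides metadata.  PNG and other
    formats require ``pixel_scale``.  Grayscale input and missing scale are
    errors.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    scale = pixel_scale
    if suffix in (".tif", ".tiff"):
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            img = page.asarray()
            if scale is None:
                tags = page.tags
                xres = tags.get("XResolution")
                unit = tags.get("ResolutionUnit")
                if xres is not None:
                    num, den = xres.value
                    if num and den:
                        res = num / den  # pixels per unit
                        unit_val = getattr(unit.value, "value", unit.value) if unit is not None else 1
                        if unit_val == 3:  # CENTIMETER
                            scale = 1e4 / res
                        elif unit_val in (1, 2):  # NONE -> px/µm convention; INCH unsupported
                            if unit_val == 2:
                                raise ValueError(f"{path}: inch-based resolution not supported; pass pixel_scale")
                            scale = 1.0 / res
    else:
        img = iio.imread(path)
    if scale is None:
        raise ValueError(
            f"{path}: no pixel scale available — supply pixel_scale explicitly "
            "(µm per pixel); scales are never defaulted silently"
        )
    if scale <= 0:
        raise ValueError("pixel_scale must be positive")
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] < 3:
        raise ValueError(f"{path}: expected a 3-channel RGB image, got shape {img.shape}")
    return img[:, :, :3], float(scale)


def write_image(path, img: np.ndarray, pixel_scale: float) -> None:
    """Write an RGB raster; TIFF gets a px/µm resolution tag (unit NONE)."""
    path = Path(path)
    img = np.asarray(img)
    if pixel_scale <= 0:
        raise ValueError("pixel_scale must be positive")
    if path.suffix.lower() in (".tif", ".tiff"):
        res = 1.0 / pixel_scale  # pixels per µm
        tifffile.imwrite(path, img, resolution=(res, res), resolutionunit="NONE")
    else:
        iio.imwrite(path, img)


def iter_tiles(raster: np.ndarray, grid: TileGrid) -> Iterator[tuple[np.ndarray, tuple[int, int]]]:
    """Yield (tile view, (row_offset, col_offset)) in row-major order."""
    if raster.shape[:2] != tuple(grid.image_shape):
        raise ValueError(f"grid image_shape {grid.image_shape} != raster shape {raster.shape[:2]}")
    for origin in grid.tile_origins():
        r0, r1, c0, c1 = grid.tile_bounds(origin)
        yield raster[r0:r1, c0:c1], (r0, c0)


def merge_tile_detections(objects: Sequence, dedup_radius_um: float) -> list:
    """Merge duplicate detections from overlapping tiles.

    ``objects`` carry global centroids (``centroid_um`` attribute, (x, y) in
    µm) and an ``area_um2``.  Objects whose centroids fall within
    ``dedup_radius_um`` of each other are considered the same physical
    object; the larger-area instance (the less clipped one) is kept.
    """
    objs = list(objects)
    if len(objs) <= 1 or dedup_radius_um <= 0:
        return objs
    from scipy.spatial import cKDTree

    pts = np.array([o.centroid_um for o in objs], dtype=float)
    tree = cKDTree(pts)
    pairs = tree.query_pairs(r=dedup_radius_um)
    parent = list(range(len(objs)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i, j in pairs:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri
    best: dict[int, int] = {}
    for idx in range(len(objs)):
        root = find(idx)
        cur = best.get(root)
        if cur is None or objs[idx].area_um2 > objs[cur].area_um2:
            best[root] = idx
    return [objs[i] for i in sorted(best.values())]
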