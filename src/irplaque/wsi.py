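"""Whole-slide inference: sliding-window tiling and max-merge stitching.

Tiles are 64 x 64 with a 16-pixel overlap (stride 48); the last tile per
axis is clamped to the image edge so every pixel is covered without ever
feeding padded, synthetic spectra to the model.  Overlaps are resolved by
taking the maximum activation, which is associative and commutative, so the
stitched map is independent of tile order.
"""

from __future__ import annotations

import numpy as np

from .phantom import SpectralCube

__all__ = ["tile_plan", "merge_max", "segment_wsi"]

TILE = 64
OVERLAP = 16


def tile_plan(height: int, width: int, tile: int = TILE,
              overlap: int = OVERLAP) -> list[tuple[int, int]]:
    """Origins (row, col) of all tiles covering an image, stride tile-overlap."""
    if height < tile or width < tile:
        raise ValueError(f"image {height}x{width} smaller than tile {tile}")
    if not 0 <= overlap < tile:
        raise ValueError("overlap must satisfy 0 <= overlap < tile")
    stride = tile - overlap

    def axis_origins(dim: int) -> list[int]:
        origins = list(range(0, dim - tile + 1, stride))
        if origins[-1] != dim - tile:
            origins.append(dim - tile)  # clamp the last tile to the edge
        return origins

    return [(r, c) for r in axis_origins(height) for c in axis_origins(width)]


def merge_max(tile_maps: list[tuple[tuple[int, int], np.ndarray]],
              height: int, width: int) -> np.ndarray:
    """Stitch tile activation maps, taking the max in overlapping regions."""
    out = np.full((height, width), -np.inf, dtype=np.float32)
    covered = np.zeros((height, width), dtype=bool)
    for (r, c), amap in tile_maps:
        th, tw = amap.shape
        region = out[r:r + th, c:c + tw]
        np.maximum(region, amap, out=region)
        covered[r:r + th, c:c + tw] = True
    if not covered.all():
        raise ValueError("tile plan does not cover every pixel")
    return out


def segment_wsi(model, cube: SpectralCube, tile: int = TILE,
                overlap: int = OVERLAP, batch_size: int = 16) -> np.ndarray:
    """Tile, forward and stitch a whole-slide cube into one activation map."""
    h, w, c = cube.shape
    if c != model.spec.in_channels:
        raise ValueError(f"cube has {c} channels, model expects "
                         f"{model.spec.in_channels}")
    plan = tile_plan(h, w, tile, overlap)
    maps: list[tuple[tuple[int, int], np.ndarray]] = []
    for i in range(0, len(plan), batch_size):
        chunk = plan[i:i + batch_size]
        batch = np.stack([cube.data[r:r + tile, c0:c0 + tile, :]
                          for r, c0 in chunk])
        preds = model.predict(batch)
        maps.extend(zip(chunk, preds))
    return merge_max(maps, h, w)
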