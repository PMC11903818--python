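"""Laser-microdissection export: activation map -> plaque-shaped polygons in
stage coordinates.

The morphological chain turns a thresholded activation map into cuttable
shapes: threshold at 0.9, drop specks under 100 um^2, dilate by 15 um, fill
holes, erode by 10 um (net +5 um margin compensating tissue loss during
cutting), then drop components that are still under 300 um^2 or fail the
shape filters that reject elongated fold-like and stringy objects.  Outer
boundaries are traced along pixel edges, so polygon area is exactly
pixel count * pixel_size^2, and a four-parameter Helmert (similarity)
transform fitted on reference points maps image micrometers into microscope
stage coordinates.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from shapely.geometry import box
from shapely.ops import unary_union
from skimage.measure import regionprops
from skimage.morphology import disk

from .ihc_mask import BinaryMask, area_filter

__all__ = [
    "ShapePolygon", "HelmertTransform", "LmdConfig",
    "activation_to_plaque_mask", "mask_to_polygons", "fit_helmert",
    "export_shapes", "read_shapes",
]

CONN8 = np.ones((3, 3), dtype=bool)


@dataclass
class ShapePolygon:
    """Closed outline of one dissectable component, in micrometers."""

    vertices: np.ndarray          # (N, 2) closed ring, first == last
    source_component: int
    area: float                   # um^2
    eccentricity: float
    solidity: float

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if len(v) < 4 or not np.allclose(v[0], v[-1]):
            raise ValueError("vertices must form a closed ring")
        if self.area <= 0:
            raise ValueError("area must be positive")
        self.vertices = v


@dataclass(frozen=True)
class HelmertTransform:
    """Four-parameter 2-D similarity: x' = s R(theta) x + t."""

    scale: float
    rotation: float               # radians
    tx: float
    ty: float

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    def apply(self, pts: np.ndarray) -> np.ndarray:
        pts = np.asarray(pts, dtype=float)
        c, s = math.cos(self.rotation), math.sin(self.rotation)
        rot = np.array([[c, -s], [s, c]])
        return pts @ (self.scale * rot).T + np.array([self.tx, self.ty])

    def inverse(self) -> "HelmertTransform":
        c, s = math.cos(-self.rotation), math.sin(-self.rotation)
        inv_t = -np.array([[c, -s], [s, c]]) @ np.array([self.tx, self.ty]) / self.scale
        return HelmertTransform(1.0 / self.scale, -self.rotation,
                                float(inv_t[0]), float(inv_t[1]))

    @classmethod
    def identity(cls) -> "HelmertTransform":
        return cls(1.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class LmdConfig:
    threshold: float = 0.9
    min_area1_um2: float = 100.0
    dilate_um: float = 15.0
    erode_um: float = 10.0
    min_area2_um2: float = 300.0
    eccentricity_cut: float = 0.97
    solidity_cut: float = 0.7
    #: apply the exclusion rule exactly as printed ("eccentricity < 0.97 or
    #: solidity > 0.7"), which keeps elongated objects; the default polarity
    #: keeps compact, solid (plaque-like) objects instead
    literal_printed_rule: bool = False

    def __post_init__(self):
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")
        if self.dilate_um <= self.erode_um:
            raise ValueError("dilate_um must exceed erode_um (positive net margin)")


def activation_to_plaque_mask(a: np.ndarray, cfg: LmdConfig | None = None,
                              pixel_size: float = 4.25,
                              exclusion_mask: np.ndarray | None = None) -> BinaryMask:
    """Morphological chain from activation map to dissectable plaque mask.

    ``exclusion_mask`` marks manually excluded (damaged) regions; pixels
    under it are zeroed before any morphology.
    """
    cfg = cfg or LmdConfig()
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    px_area = pixel_size ** 2
    m = np.asarray(a, dtype=float) >= cfg.threshold
    if exclusion_mask is not None:
        m &= ~np.asarray(exclusion_mask, dtype=bool)
    m = area_filter(m, cfg.min_area1_um2 / px_area)
    r_dil = int(round(cfg.dilate_um / pixel_size))
    if r_dil > 0 and m.any():
        m = ndimage.binary_dilation(m, structure=disk(r_dil))
    m = ndimage.binary_fill_holes(m)
    r_ero = int(round(cfg.erode_um / pixel_size))
    if r_ero > 0 and m.any():
        m = ndimage.binary_erosion(m, structure=disk(r_ero))
    # final area + shape filters
    lab, n = ndimage.label(m, structure=CONN8)
    out = np.zeros_like(m)
    for prop in regionprops(lab):
        if prop.area * px_area < cfg.min_area2_um2:
            continue
        if cfg.literal_printed_rule:
            # verbatim exclusion: drop ecc < cut or solidity > cut
            if prop.eccentricity < cfg.eccentricity_cut or prop.solidity > cfg.solidity_cut:
                continue
        else:
            # keep compact, solid objects; drop elongated / stringy ones
            if prop.eccentricity > cfg.eccentricity_cut or prop.solidity < cfg.solidity_cut:
                continue
        out[lab == prop.label] = True
    return BinaryMask(out, pixel_size)


def mask_to_polygons(mask: BinaryMask, pixel_size: float | None = None) -> list[ShapePolygon]:
    """Trace the outer ring of every component along pixel boundaries.

    Coordinates are (x, y) = (col, row) * pixel_size in micrometers; the
    ring area equals pixel count * pixel_size^2 exactly.
    """
    ps = mask.pixel_size if pixel_size is None else pixel_size
    lab, n = ndimage.label(mask.values, structure=CONN8)
    shapes: list[ShapePolygon] = []
    for prop in regionprops(lab):
        rows, cols = np.nonzero(lab == prop.label)
        cells = unary_union([box(c * ps, r * ps, (c + 1) * ps, (r + 1) * ps)
                             for r, c in zip(rows, cols)])
        if cells.geom_type == "MultiPolygon":  # 8-connected diagonal touch
            cells = max(cells.geoms, key=lambda g: g.area).buffer(0)
            ring = np.asarray(cells.exterior.coords)
            area = cells.area
        else:
            ring = np.asarray(cells.exterior.coords)
            area = cells.area
        shapes.append(ShapePolygon(
            vertices=ring,
            source_component=int(prop.label),
            area=float(area),
            eccentricity=float(prop.eccentricity),
            solidity=float(prop.solidity),
        ))
    return shapes


def fit_helmert(src: np.ndarray, dst: np.ndarray) -> HelmertTransform:
    """Least-squares four-parameter similarity from matched point pairs.

    Closed form on centered coordinates; exact whenever the pairs are
    related by a true similarity.  Coincident source points leave the
    normal equations degenerate and are rejected.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2 or len(src) < 2:
        raise ValueError("need matching (N, 2) arrays with N >= 2")
    sc = src - src.mean(axis=0)
    dc = dst - dst.mean(axis=0)
    denom = float((sc ** 2).sum())
    if denom == 0:
        raise ValueError("source points are coincident; transform degenerate")
    a = float((sc[:, 0] * dc[:, 0] + sc[:, 1] * dc[:, 1]).sum()) / denom
    b = float((sc[:, 0] * dc[:, 1] - sc[:, 1] * dc[:, 0]).sum()) / denom
    scale = math.hypot(a, b)
    theta = math.atan2(b, a)
    c, s = math.cos(theta), math.sin(theta)
    rot = scale * np.array([[c, -s], [s, c]])
    t = dst.mean(axis=0) - rot @ src.mean(axis=0)
    return HelmertTransform(scale, theta, float(t[0]), float(t[1]))


def export_shapes(shapes: list[ShapePolygon], transform: HelmertTransform,
                  path: str | Path) -> Path:
    """Write stage-coordinate vertices plus a per-shape summary table.

    Produces ``<path>`` with columns (shape_id, vertex_index, x_um, y_um)
    and ``<path stem>_summary.csv`` with (shape_id, n_vertices, area_um2,
    eccentricity, solidity).
    """
    path = Path(path)
    try:
        with path.open("w", newline="") as fh:
            wr = csv.writer(fh)
            wr.writerow(["shape_id", "vertex_index", "x_um", "y_um"])
            for i, shp in enumerate(shapes):
                pts = transform.apply(shp.vertices)
                for j, (x, y) in enumerate(pts):
                    wr.writerow([i, j, f"{x:.6f}", f"{y:.6f}"])
        summary = path.with_name(path.stem + "_summary.csv")
        with summary.open("w", newline="") as fh:
            wr = csv.writer(fh)
            wr.writerow(["shape_id", "n_vertices", "area_um2", "eccentricity", "solidity"])
            for i, shp in enumerate(shapes):
                wr.writerow([i, len(shp.vertices),
                             f"{shp.area:.6f}", f"{shp.eccentricity:.6f}",
                             f"{shp.solidity:.6f}"])
    except OSError as exc:
        raise OSError(f"failed writing shape export to {path}: {exc}") from exc
    return path


def read_shapes(path: str | Path) -> list[np.ndarray]:
    """Read back exported vertex rings as a list of (N, 2) arrays."""
    rings: dict[int, list[tuple[float, float]]] = {}
    with Path(path).open() as fh:
        for row in csv.DictReader(fh):
            rings.setdefault(int(row["shape_id"]), []).append(
                (float(row["x_um"]), float(row["y_um"])))
    return [np.asarray(rings[k]) for k in sorted(rings)]
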