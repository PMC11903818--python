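"""Synthetic QCL-IR scene generator with ground truth.

Emulates hyperspectral infrared absorbance images of brain tissue carrying
amyloid-beta plaques, together with the paired pseudo-IHC rendering a DAB
stain would produce.  Every downstream stage (mask preprocessing, weakly
supervised training, whole-slide inference, purification-factor evaluation,
microdissection export) can therefore be exercised and scored against an
exact ground truth.

The spectral model is deliberately simple: each tissue endmember is a sum of
Gaussian bands in wavenumber.  Background tissue carries the protein
backbone Amide I (~1655 cm^-1) and Amide II (~1545 cm^-1) bands plus weaker
lipid-ester (~1740), C-H deformation (~1455) and fingerprint (~1240) bands.
The plaque endmember differs subtly: a beta-sheet shoulder near 1630 cm^-1
and perturbed amplitudes at the ester, C-H and 1320-1200 cm^-1 bands — the
regions where plaque and background pixel spectra actually diverge.  The
mixing equation per pixel is

    cube = background + density * contrast_scale * jitter * (plaque - background)
           + baseline + noise

so ``contrast_scale`` directly controls how subtle the class difference is,
and ``contrast_scale = 0`` makes both pixel populations identically
distributed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "WavenumberAxis",
    "SpectralCube",
    "SceneTruth",
    "StainParams",
    "SpectralModel",
    "make_wavenumber_axis",
    "generate_scene",
    "render_pseudo_ihc",
]

#: 8-connectivity structure used for all component labelling in this package.
CONN8 = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class WavenumberAxis:
    """Inclusive, strictly descending wavenumber grid in cm^-1."""

    start: float
    stop: float
    step: float
    values: np.ndarray

    @property
    def count(self) -> int:
        return len(self.values)


def make_wavenumber_axis(start: float, stop: float, step: float) -> WavenumberAxis:
    """Build the inclusive descending grid from ``start`` down to ``stop``.

    The span must be an integer multiple of ``step`` — a non-divisible range
    signals a mis-configured instrument emulation and is rejected.
    """
    if not start > stop and start != stop:
        raise ValueError("start must be >= stop")
    if step <= 0:
        raise ValueError("step must be positive")
    n_float = (start - stop) / step
    n = int(round(n_float))
    if abs(n_float - n) > 1e-9 * max(1.0, n_float):
        raise ValueError(f"range {start}..{stop} is not divisible by step {step}")
    values = start - step * np.arange(n + 1)
    return WavenumberAxis(start, stop, step, values)


@dataclass
class SpectralCube:
    """Absorbance cube (H, W, C) with explicit wavenumber axis and pixel size."""

    data: np.ndarray
    axis: WavenumberAxis
    pixel_size: float = 4.25  # um per pixel

    def __post_init__(self):
        if self.data.ndim != 3:
            raise ValueError("cube data must be (H, W, C)")
        if self.data.shape[2] != self.axis.count:
            raise ValueError("channel count does not match wavenumber axis")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("absorbance must be finite")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self):
        return self.data.shape


@dataclass
class SceneTruth:
    """Exact ground truth of a generated scene."""

    plaque_mask: np.ndarray       # bool (H, W)
    plaque_density: np.ndarray    # float in [0, 1]
    plaque_labels: np.ndarray     # int component map, 0 = background
    artifact_mask: np.ndarray     # bool; folds and holes
    plaque_types: list[str] = field(default_factory=list)  # per component, 1-based


@dataclass(frozen=True)
class StainParams:
    """Pseudo-IHC rendering parameters (DAB brown on cresyl-violet counterstain)."""

    dab_blue_min: float = 0.10
    background_blue: float = 0.95
    counterstain_density: float = 400.0  # violet dots per mm^2
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.dab_blue_min < self.background_blue <= 1.0:
            raise ValueError("require 0 <= dab_blue_min < background_blue <= 1")


# band tables: (center cm^-1, sigma cm^-1, amplitude in absorbance units)
_BACKGROUND_BANDS = (
    (1655.0, 28.0, 1.00),   # Amide I
    (1545.0, 25.0, 0.55),   # Amide II
    (1740.0, 18.0, 0.10),   # lipid ester
    (1455.0, 20.0, 0.15),   # C-H deformation
    (1240.0, 30.0, 0.12),   # overlapping fingerprint bands
)
# deviations of the plaque endmember, scaled by contrast_scale at mix time
_PLAQUE_DELTA_BANDS = (
    (1630.0, 15.0, 0.30),   # beta-sheet shoulder on Amide I
    (1740.0, 18.0, -0.40),  # reduced lipid ester
    (1455.0, 20.0, 0.60),   # stronger C-H deformation
    (1240.0, 30.0, 0.65),   # elevated 1320-1200 region
)


@dataclass
class SpectralModel:
    """Gaussian-band endmember model and noise configuration."""

    background_bands: tuple = _BACKGROUND_BANDS
    plaque_delta_bands: tuple = _PLAQUE_DELTA_BANDS
    contrast_scale: float = 0.15
    noise_sd: float = 0.01              # absorbance, i.i.d. per voxel
    baseline_offset: float = 0.05       # absorbance
    baseline_slope_sd: float = 1e-5     # absorbance per cm^-1, truncated at 3 sd
    amplitude_jitter: float = 0.5       # per-plaque +-50 % of the contrast
    #: wavenumber windows (hi, lo) where plaque and background are allowed to differ
    difference_bands: tuple = ((1770.0, 1710.0), (1480.0, 1430.0),
                               (1320.0, 1200.0), (1660.0, 1600.0))

    def endmembers(self, axis: WavenumberAxis) -> tuple[np.ndarray, np.ndarray]:
        """Evaluate (background, plaque) endmember spectra on ``axis``."""
        nu = axis.values
        bg = _bands_to_spectrum(self.background_bands, nu)
        plaque = bg + _bands_to_spectrum(self.plaque_delta_bands, nu)
        return bg, plaque


def _bands_to_spectrum(bands, nu: np.ndarray) -> np.ndarray:
    s = np.zeros_like(nu, dtype=float)
    for center, sigma, amp in bands:
        s += amp * np.exp(-0.5 * ((nu - center) / sigma) ** 2)
    return s


# ---------------------------------------------------------------------------
# plaque morphologies

def _disk(radius: int) -> np.ndarray:
    r = int(radius)
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    return (yy ** 2 + xx ** 2) <= r ** 2


def _cored_density(rng: np.random.Generator) -> np.ndarray:
    """Classic cored plaque: dense core disk plus lower-density corona."""
    core_r = int(rng.integers(3, 7))
    outer_r = 2 * core_r
    yy, xx = np.mgrid[-outer_r:outer_r + 1, -outer_r:outer_r + 1]
    rr = np.sqrt(yy ** 2 + xx ** 2)
    d = np.zeros_like(rr)
    d[rr <= outer_r] = 0.5
    d[rr <= core_r] = 1.0
    return d


def _compact_density(rng: np.random.Generator) -> np.ndarray:
    """Compact plaque: homogeneous disk with a soft rim."""
    r = int(rng.integers(4, 9))
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    rr = np.sqrt(yy ** 2 + xx ** 2)
    d = 0.85 * np.clip(1.2 - rr / r, 0.0, 1.0) ** 0.5
    d[rr > r] = 0.0
    return d


def _diffuse_density(rng: np.random.Generator) -> np.ndarray:
    """Diffuse plaque: ragged low-density blob, kept singly connected."""
    r = int(rng.integers(6, 13))
    size = 2 * r + 1
    noise = ndimage.gaussian_filter(rng.normal(size=(size, size)), sigma=2.0)
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    rr = np.sqrt(yy ** 2 + xx ** 2) / r
    fld = (1.0 - rr) + 0.6 * noise
    blob = fld > 0.25
    # keep only the component containing the centre so the plaque is one object
    lab, _ = ndimage.label(blob, structure=CONN8)
    centre_lab = lab[r, r]
    if centre_lab == 0:
        blob = _disk(max(3, r // 2))
        d = np.zeros((size, size))
        off = (size - blob.shape[0]) // 2
        d[off:off + blob.shape[0], off:off + blob.shape[1]] = blob * 0.45
        return d
    blob = lab == centre_lab
    return blob * 0.45


_MORPHOLOGIES = {
    "cored": _cored_density,
    "compact": _compact_density,
    "diffuse": _diffuse_density,
}


def generate_scene(height: int, width: int, n_plaques: int,
                   spectral: SpectralModel | None = None, seed: int = 0,
                   n_folds: int = 0, n_holes: int = 0,
                   axis: WavenumberAxis | None = None,
                   pixel_size: float = 4.25,
                   max_retries: int = 200) -> tuple[SpectralCube, SceneTruth]:
    """Generate a seeded synthetic scene with exact ground truth.

    Plaques are placed without overlap (1-px separation margin, so each is a
    single 8-connected component of the mask); morphology cycles through
    cored, compact and diffuse types.  Optional fold / hole artifacts distort
    the cube and are recorded in ``SceneTruth.artifact_mask``.
    """
    if height < 64 or width < 64:
        raise ValueError("scene must be at least 64 x 64 pixels")
    if n_plaques < 0:
        raise ValueError("n_plaques must be >= 0")
    spectral = spectral or SpectralModel()
    axis = axis or make_wavenumber_axis(1800.0, 948.0, 2.0)
    rng = np.random.default_rng(seed)

    density = np.zeros((height, width))
    labels = np.zeros((height, width), dtype=np.int32)
    occupied = np.zeros((height, width), dtype=bool)
    jitters: list[float] = []
    types: list[str] = []
    names = list(_MORPHOLOGIES)
    placed = 0
    for k in range(n_plaques):
        name = names[k % len(names)]
        stamp = _MORPHOLOGIES[name](rng)
        sh, sw = stamp.shape
        footprint = ndimage.binary_dilation(stamp > 0, structure=CONN8)
        ok = False
        for _ in range(max_retries):
            r0 = int(rng.integers(0, height - sh + 1))
            c0 = int(rng.integers(0, width - sw + 1))
            if not (occupied[r0:r0 + sh, c0:c0 + sw] & footprint).any():
                ok = True
                break
        if not ok:
            raise RuntimeError(
                f"could not place plaque {k + 1} of {n_plaques} without overlap "
                f"after {max_retries} retries; placed {placed}")
        sl = (slice(r0, r0 + sh), slice(c0, c0 + sw))
        density[sl] = np.where(stamp > 0, stamp, density[sl])
        labels[sl][stamp > 0] = placed + 1
        occupied[sl] |= footprint
        jitters.append(1.0 + spectral.amplitude_jitter * float(rng.uniform(-1, 1)))
        types.append(name)
        placed += 1

    artifact = np.zeros((height, width), dtype=bool)
    fold_mask = np.zeros((height, width), dtype=bool)
    hole_mask = np.zeros((height, width), dtype=bool)
    for _ in range(n_folds):
        fold_mask |= _random_curve(rng, height, width, thickness=2)
    for _ in range(n_holes):
        r = int(rng.integers(5, 12))
        cy = int(rng.integers(r, height - r))
        cx = int(rng.integers(r, width - r))
        d = _disk(r)
        hole_mask[cy - r:cy + r + 1, cx - r:cx + r + 1] |= d
    # artifacts never punch through plaques: ground truth stays recoverable
    fold_mask &= ~(density > 0)
    hole_mask &= ~(density > 0)
    artifact = fold_mask | hole_mask

    bg, plaque = spectral.endmembers(axis)
    jitter_map = np.ones((height, width))
    for i, j in enumerate(jitters):
        jitter_map[labels == i + 1] = j
    mix = density * spectral.contrast_scale * jitter_map
    cube = bg[None, None, :] + mix[:, :, None] * (plaque - bg)[None, None, :]

    # per-pixel linear baseline; slope truncated at 3 sd so absorbance stays >= 0
    nu = axis.values
    nu_mid = 0.5 * (nu[0] + nu[-1])
    slope = np.clip(rng.normal(0.0, spectral.baseline_slope_sd, size=(height, width)),
                    -3 * spectral.baseline_slope_sd, 3 * spectral.baseline_slope_sd)
    cube = cube + spectral.baseline_offset + slope[:, :, None] * (nu - nu_mid)[None, None, :]

    # artifacts: folds are doubled-up tissue (scaled absorbance), holes are bare slide
    if fold_mask.any():
        cube[fold_mask] *= 1.8
    if hole_mask.any():
        cube[hole_mask] = spectral.baseline_offset * 0.2

    if spectral.noise_sd > 0:
        cube = cube + rng.normal(0.0, spectral.noise_sd, size=cube.shape)

    truth = SceneTruth(
        plaque_mask=density > 0,
        plaque_density=density,
        plaque_labels=labels,
        artifact_mask=artifact,
        plaque_types=types,
    )
    return SpectralCube(cube.astype(np.float32), axis, pixel_size), truth


def _random_curve(rng: np.random.Generator, height: int, width: int,
                  thickness: int = 2) -> np.ndarray:
    """Rasterize a random gently-curved line across the scene (a tissue fold)."""
    mask = np.zeros((height, width), dtype=bool)
    t = np.linspace(0, 1, 4 * max(height, width))
    if rng.uniform() < 0.5:
        x0, x1 = 0, width - 1
        y0, y1 = rng.integers(0, height, size=2)
        amp = rng.uniform(-0.15, 0.15) * height
        xs = x0 + t * (x1 - x0)
        ys = y0 + t * (y1 - y0) + amp * np.sin(np.pi * t * rng.uniform(1, 3))
    else:
        y0, y1 = 0, height - 1
        x0, x1 = rng.integers(0, width, size=2)
        amp = rng.uniform(-0.15, 0.15) * width
        ys = y0 + t * (y1 - y0)
        xs = x0 + t * (x1 - x0) + amp * np.sin(np.pi * t * rng.uniform(1, 3))
    rr = np.clip(np.round(ys).astype(int), 0, height - 1)
    cc = np.clip(np.round(xs).astype(int), 0, width - 1)
    mask[rr, cc] = True
    if thickness > 1:
        mask = ndimage.binary_dilation(mask, iterations=thickness - 1)
    return mask


def render_pseudo_ihc(truth: SceneTruth, stain: StainParams | None = None,
                      pixel_size: float = 4.25) -> np.ndarray:
    """Render the DAB-stained brightfield image a registered IHC scan would show.

    The blue channel is the quantitative one consumed by the mask pipeline:

        blue = background_blue - density * (background_blue - dab_blue_min)

    Plaques render brown (red > green > blue), the background is near-white,
    and a seeded sprinkle of small violet counterstain dots emulates cresyl
    violet.  Fold artifacts render as faint gray lines, holes as pure white.
    """
    stain = stain or StainParams()
    rng = np.random.default_rng(stain.seed)
    d = np.clip(truth.plaque_density, 0.0, 1.0)
    h, w = d.shape

    blue = stain.background_blue - d * (stain.background_blue - stain.dab_blue_min)
    # DAB brown: red decays slower than green, which decays slower than blue
    red = 0.97 - d * 0.45
    green = 0.96 - d * 0.65
    img = np.stack([red, green, blue], axis=-1)

    # pale violet counterstain speckle of bounded size (1-2 px radius),
    # off-plaque; cresyl violet is light in brightfield, so the dots stay
    # well above the DAB intensity range in the blue channel
    area_mm2 = (h * pixel_size * 1e-3) * (w * pixel_size * 1e-3)
    n_dots = rng.poisson(stain.counterstain_density * area_mm2)
    violet = np.array([0.62, 0.45, 0.80])
    for _ in range(n_dots):
        cy = int(rng.integers(0, h))
        cx = int(rng.integers(0, w))
        if d[cy, cx] > 0:
            continue
        r = int(rng.integers(1, 3))
        sl = (slice(max(0, cy - r), min(h, cy + r + 1)),
              slice(max(0, cx - r), min(w, cx + r + 1)))
        strength = rng.uniform(0.3, 0.7)
        img[sl] = (1 - strength) * img[sl] + strength * violet

    if truth.artifact_mask.any():
        fold = truth.artifact_mask & ~truth.plaque_mask
        # folds/holes are unstained: near-white, clearly above the DAB window
        img[fold] = np.array([0.94, 0.93, 0.94])
    return np.clip(img, 0.0, 1.0)
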