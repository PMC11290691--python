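"""Synthetic cytology-tile generator with exact ground truth.

Every downstream stage (tiling filter, segmentation, ROI extraction,
classification) is exercised on tiles produced here, so no slide data is
required.  A tile contains a configurable number of textured, radially
perturbed elliptical "cell clumps" on a speckled background:

* benign clumps have a smooth, low-amplitude boundary ("neat edges");
* malignant clumps carry high-amplitude radial perturbations with extra
  high-frequency harmonics (irregular, protruding edges);
* the background holds small (<=6 px) discs that emulate scattered single
  cells and leukocytes — noise a segmenter must reject;
* clump texture is multiplicative smooth (Perlin-style) noise, so the
  interior is chromatin-like rather than flat;
* rendering maps the grayscale geometry through one of two staining
  palettes: a pink/purple H&E-like one or a blue/green Papanicolaou-like
  one.  The ground-truth mask is independent of the palette.

All randomness flows from one seeded generator; the same (spec, seed)
pair yields byte-identical output.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import disk as draw_disk
from skimage.draw import polygon as draw_polygon
from skimage.measure import perimeter as sk_perimeter

from .tileprep import ImageTile

STYLES = ("he", "pap")

# palette endpoints: (background colour, foreground colour), uint8 RGB.
# Intensity 0 maps to background, 1 to foreground; interpolation is linear
# so luminance ordering is preserved across styles.
_PALETTES = {
    "he": (np.array([247.0, 236.0, 241.0]), np.array([112.0, 48.0, 130.0])),
    "pap": (np.array([240.0, 248.0, 244.0]), np.array([36.0, 102.0, 96.0])),
}

BENIGN, MALIGNANT = "benign", "malignant"


@dataclass(frozen=True)
class SynthSpec:
    """Study conditions for one synthetic tile."""

    tile_size: int = 1024
    n_clumps: tuple[int, int] = (0, 10)
    clump_radius: tuple[float, float] = (40.0, 90.0)
    malignant_fraction: float = 0.5
    benign_amplitude: float = 0.04    # radial perturbation, fraction of radius
    malignant_amplitude: float = 0.25
    stain_style: str = "he"           # "he" | "pap" | "mixed"
    background_noise_density: float = 150.0  # speckles per megapixel
    seed: int = 0

    def validate(self):
        if self.tile_size <= 0:
            raise ValueError("tile_size must be positive")
        if not 0.0 <= self.malignant_fraction <= 1.0:
            raise ValueError("malignant_fraction must be in [0, 1]")
        if self.n_clumps[0] < 0 or self.n_clumps[1] < self.n_clumps[0]:
            raise ValueError("invalid n_clumps range")
        if self.clump_radius[0] <= 0 or self.clump_radius[1] < self.clump_radius[0]:
            raise ValueError("invalid clump_radius range")
        if self.clump_radius[1] >= self.tile_size / 2:
            raise ValueError("clump radius must be < tile_size / 2")
        if self.stain_style not in STYLES + ("mixed",):
            raise ValueError(f"unknown stain style {self.stain_style!r}")
        if self.background_noise_density < 0:
            raise ValueError("background_noise_density must be >= 0")


@dataclass(frozen=True)
class ClumpInfo:
    bbox: tuple[int, int, int, int]  # x0, y0, x1, y1; 0-based half-open
    label: str                       # "benign" | "malignant"
    centroid: tuple[float, float]    # (row, col)


@dataclass
class SynthRecord:
    image: ImageTile
    mask: np.ndarray                 # bool, H x W
    clumps: list[ClumpInfo] = field(default_factory=list)


def _boundary_profile(rng: np.random.Generator, malignant: bool, n_theta: int) -> np.ndarray:
    """Zero-mean radial modulation f(theta) with |f| <= 1.

    Benign boundaries use a few low harmonics; malignant ones add
    high-frequency components so the outline grows protrusions.
    """
    theta = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    harmonics = range(2, 10) if malignant else range(2, 6)
    f = np.zeros(n_theta)
    total = 0.0
    for k in harmonics:
        c = rng.uniform(0.3, 1.0)
        phi = rng.uniform(0.0, 2.0 * np.pi)
        f += c * np.cos(k * theta + phi)
        total += c
    return f / total


def _smooth_noise(rng: np.random.Generator, size: int, scale: int = 16) -> np.ndarray:
    """Smooth multiplicative texture field in [0, 1] (Perlin-style)."""
    n = size // scale + 2
    grid = rng.random((n, n))
    field_ = ndimage.zoom(grid, scale, order=3)[:size, :size]
    lo, hi = field_.min(), field_.max()
    return (field_ - lo) / (hi - lo + 1e-12)


def render_stain(style: str, grayscale_base: np.ndarray) -> ImageTile:
    """Map an intensity raster in [0, 1] through a 2-colour staining palette."""
    if style not in _PALETTES:
        raise ValueError(f"unknown stain style {style!r}")
    base = np.asarray(grayscale_base, dtype=np.float64)
    if base.min() < 0 or base.max() > 1:
        raise ValueError("grayscale base must lie in [0, 1]")
    bg, fg = _PALETTES[style]
    rgb = bg[None, None, :] * (1.0 - base[..., None]) + fg[None, None, :] * base[..., None]
    return ImageTile(np.round(rgb).astype(np.uint8), stain_style=style)


def generate_tile(spec: SynthSpec, seed: int | None = None) -> SynthRecord:
    """Render one synthetic tile with its exact mask and clump list."""
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    size = spec.tile_size
    n = int(rng.integers(spec.n_clumps[0], spec.n_clumps[1] + 1))
    style = spec.stain_style
    if style == "mixed":
        style = STYLES[int(rng.integers(0, 2))]

    mask = np.zeros((size, size), dtype=bool)
    base = np.zeros((size, size), dtype=np.float64)
    texture = _smooth_noise(rng, size)
    placed: list[tuple[float, float, float]] = []  # (row, col, effective radius)
    clumps: list[ClumpInfo] = []

    for _ in range(n):
        ok = False
        for _attempt in range(500):
            r = float(rng.uniform(*spec.clump_radius))
            malignant = bool(rng.random() < spec.malignant_fraction)
            amp = spec.malignant_amplitude if malignant else spec.benign_amplitude
            reff = r * (1.0 + amp) + 2.0
            if reff >= size / 2 - 1:
                continue
            cy = float(rng.uniform(reff, size - reff))
            cx = float(rng.uniform(reff, size - reff))
            if all(
                np.hypot(cy - py, cx - px) > reff + pr + 4.0 for py, px, pr in placed
            ):
                ok = True
                break
        if not ok:
            raise ValueError(
                "could not place requested clumps; spec too crowded for tile size"
            )
        n_theta = 256
        theta = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
        f = _boundary_profile(rng, malignant, n_theta)
        rho = r * (1.0 + amp * f)
        aspect = float(rng.uniform(0.6, 1.0))
        rot = float(rng.uniform(0.0, np.pi))
        ex = rho * np.cos(theta)
        ey = rho * np.sin(theta) * aspect
        rows = cy + ex * np.sin(rot) + ey * np.cos(rot)
        cols = cx + ex * np.cos(rot) - ey * np.sin(rot)
        rr, cc = draw_polygon(rows, cols, shape=mask.shape)
        if rr.size == 0:
            raise ValueError("degenerate clump rasterization; increase clump_radius")
        comp = np.zeros_like(mask)
        comp[rr, cc] = True
        mask |= comp
        level = float(rng.uniform(0.45, 0.6))
        base[comp] = np.clip(level + 0.35 * (texture[comp] - 0.5), 0.05, 1.0)
        ys, xs = np.nonzero(comp)
        bbox = (int(xs.min()), int(ys.min()), int(xs.max()) + 1, int(ys.max()) + 1)
        centroid = (float(ys.mean()), float(xs.mean()))
        placed.append((cy, cx, reff))
        clumps.append(ClumpInfo(bbox=bbox, label=MALIGNANT if malignant else BENIGN,
                                centroid=centroid))

    # background speckles: small discs standing in for single cells/leukocytes
    n_speckles = int(rng.poisson(spec.background_noise_density * size * size / 1e6))
    for _ in range(n_speckles):
        sy = float(rng.uniform(3, size - 3))
        sx = float(rng.uniform(3, size - 3))
        sr = float(rng.uniform(1.0, 3.0))
        val = float(rng.uniform(0.25, 0.55))
        rr, cc = draw_disk((sy, sx), sr, shape=mask.shape)
        keep = ~mask[rr, cc]
        base[rr[keep], cc[keep]] = val

    tile = render_stain(style, base)
    tile.origin = (f"synth-{spec.seed if seed is None else seed}", 0, 0)
    return SynthRecord(image=tile, mask=mask, clumps=clumps)


def clump_roughness(mask: np.ndarray) -> float:
    """Boundary roughness perimeter^2 / area of a single-clump mask."""
    mask = np.asarray(mask, dtype=bool)
    area = mask.sum()
    if area == 0:
        raise ValueError("empty mask")
    return float(sk_perimeter(mask) ** 2 / area)


MANIFEST_COLUMNS = [
    "tile_id", "image_path", "mask_path", "stain_style",
    "clump_id", "x0", "y0", "x1", "y1", "label",
]


def generate_dataset(spec: SynthSpec, n_tiles: int, out_dir: str) -> pd.DataFrame:
    """Write `n_tiles` tiles + masks as PNG and a per-clump CSV manifest.

    With stain_style="mixed" the palette alternates deterministically
    (he, pap, he, ...).  Per-tile seeds derive from spec.seed.
    """
    spec.validate()
    os.makedirs(os.path.join(out_dir, "images"), exist_ok=True)
    os.makedirs(os.path.join(out_dir, "masks"), exist_ok=True)
    tile_seeds = np.random.SeedSequence(spec.seed).generate_state(max(n_tiles, 1))
    rows = []
    for i in range(n_tiles):
        style = spec.stain_style
        if style == "mixed":
            style = STYLES[i % 2]
        rec = generate_tile(replace(spec, stain_style=style), seed=int(tile_seeds[i] % (2**31)))
        img_path = os.path.join(out_dir, "images", f"tile_{i:04d}.png")
        mask_path = os.path.join(out_dir, "masks", f"tile_{i:04d}.png")
        iio.imwrite(img_path, rec.image.pixels)
        iio.imwrite(mask_path, (rec.mask.astype(np.uint8) * 255))
        for j, clump in enumerate(rec.clumps):
            rows.append(
                {
                    "tile_id": i,
                    "image_path": img_path,
                    "mask_path": mask_path,
                    "stain_style": style,
                    "clump_id": j,
                    "x0": clump.bbox[0],
                    "y0": clump.bbox[1],
                    "x1": clump.bbox[2],
                    "y1": clump.bbox[3],
                    "label": clump.label,
                }
            )
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(os.path.join(out_dir, "manifest.csv"), index=False)
    return manifest
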