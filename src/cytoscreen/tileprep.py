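"""Tiling of large cytology images, background-tile rejection and augmentation.

Whole-slide scans are far too large for a network, so they are cut into
fixed-size square tiles.  Tiles that are mostly empty background are
rejected with a simple intensity rule: a tile is kept when its pixel mean
(pooled over all pixels and channels) lies in [mean_lo, mean_hi] and its
standard deviation is above std_min — blank glass is bright and flat,
tissue is mid-toned and textured.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.transform import rescale


@dataclass
class ImageTile:
    """An RGB raster plus staining-style tag and source/offset provenance."""

    pixels: np.ndarray  # H x W x 3 uint8
    stain_style: str = "unknown"
    origin: tuple = ("", 0, 0)  # (source id, x offset, y offset)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("ImageTile expects an H x W x 3 array")


@dataclass(frozen=True)
class FilterRule:
    """Background-rejection thresholds on pooled RGB mean and std."""

    mean_lo: float = 50.0
    mean_hi: float = 230.0
    std_min: float = 20.0

    def __post_init__(self):
        if not self.mean_lo < self.mean_hi:
            raise ValueError("mean_lo must be < mean_hi")
        if self.std_min < 0:
            raise ValueError("std_min must be >= 0")


def tile_image(image: np.ndarray, tile_size: int, stride: int | None = None,
               source_id: str = "image", stain_style: str = "unknown") -> list[ImageTile]:
    """Cut `image` into tile_size x tile_size tiles on a regular grid.

    Edge remainders that do not fill a whole tile are dropped.  With
    stride == tile_size (the default) the grid is non-overlapping.
    """
    if tile_size <= 0:
        raise ValueError("tile_size must be positive")
    image = np.asarray(image)
    if image.ndim == 2:
        image = np.stack([image] * 3, axis=-1)
    if image.shape[0] < tile_size or image.shape[1] < tile_size:
        raise ValueError("image smaller than tile_size")
    stride = tile_size if stride is None else stride
    if stride <= 0:
        raise ValueError("stride must be positive")
    tiles = []
    for y in range(0, image.shape[0] - tile_size + 1, stride):
        for x in range(0, image.shape[1] - tile_size + 1, stride):
            tiles.append(
                ImageTile(
                    pixels=np.ascontiguousarray(image[y : y + tile_size, x : x + tile_size]),
                    stain_style=stain_style,
                    origin=(source_id, x, y),
                )
            )
    return tiles


def is_informative(tile: ImageTile | np.ndarray, rule: FilterRule = FilterRule()) -> bool:
    """True iff pooled pixel mean is within [mean_lo, mean_hi] and std > std_min."""
    arr = tile.pixels if isinstance(tile, ImageTile) else np.asarray(tile)
    arr = arr.astype(np.float64)
    mean = arr.mean()
    std = arr.std()
    return (rule.mean_lo <= mean <= rule.mean_hi) and (std > rule.std_min)


def filter_manifest(tiles: list[ImageTile], rule: FilterRule = FilterRule()) -> pd.DataFrame:
    """Per-tile statistics and keep/reject decision as a DataFrame."""
    rows = []
    for i, t in enumerate(tiles):
        arr = t.pixels.astype(np.float64)
        rows.append(
            {
                "tile_id": i,
                "x": t.origin[1],
                "y": t.origin[2],
                "kept": int(is_informative(t, rule)),
                "mean": arr.mean(),
                "std": arr.std(),
            }
        )
    return pd.DataFrame(rows, columns=["tile_id", "x", "y", "kept", "mean", "std"])


AUGMENT_OPS = ("vflip", "hflip", "rot90", "rot180", "rot270", "scale", "gray")


def _geometric(arr: np.ndarray, op: str) -> np.ndarray:
    if op == "vflip":
        return arr[::-1].copy()
    if op == "hflip":
        return arr[:, ::-1].copy()
    if op == "rot90":
        return np.rot90(arr, 1).copy()
    if op == "rot180":
        return np.rot90(arr, 2).copy()
    if op == "rot270":
        return np.rot90(arr, 3).copy()
    raise ValueError(op)


def _rescale_back(arr: np.ndarray, factor: float, order: int) -> np.ndarray:
    """Zoom by `factor`, then center-crop or zero-pad back to the input shape."""
    h, w = arr.shape[:2]
    chan = arr.ndim == 3
    out = rescale(
        arr,
        factor,
        order=order,
        preserve_range=True,
        anti_aliasing=(factor < 1 and order > 0),
        channel_axis=-1 if chan else None,
    )
    out = out.astype(arr.dtype)
    oh, ow = out.shape[:2]
    canvas = np.zeros_like(arr)
    if oh >= h:  # center crop
        y0, x0 = (oh - h) // 2, (ow - w) // 2
        canvas[...] = out[y0 : y0 + h, x0 : x0 + w]
    else:  # center pad
        y0, x0 = (h - oh) // 2, (w - ow) // 2
        canvas[y0 : y0 + oh, x0 : x0 + ow] = out
    return canvas


def augment(tile: ImageTile, op: str, params: dict | None = None,
            mask: np.ndarray | None = None):
    """Apply one augmentation; geometric ops are mirrored onto `mask` if given.

    `scale` takes params={"factor": f} (default drawn from [0.8, 1.2] when
    params={"rng": Generator}); the result is cropped/padded back to the
    original tile size.  `gray` replicates luminance into all channels.
    """
    if op not in AUGMENT_OPS:
        raise ValueError(f"unsupported augmentation: {op!r}")
    params = params or {}
    px = tile.pixels
    if op == "gray":
        lum = (0.299 * px[..., 0] + 0.587 * px[..., 1] + 0.114 * px[..., 2])
        out = np.repeat(np.round(lum)[..., None], 3, axis=2).astype(px.dtype)
        new = ImageTile(out, tile.stain_style, tile.origin)
        return (new, mask) if mask is not None else new
    if op == "scale":
        factor = params.get("factor")
        if factor is None:
            rng = params.get("rng")
            if rng is None:
                raise ValueError("scale needs params['factor'] or params['rng']")
            factor = float(rng.uniform(0.8, 1.2))
        out = _rescale_back(px, factor, order=1)
        new = ImageTile(out, tile.stain_style, tile.origin)
        if mask is not None:
            return new, _rescale_back(mask.astype(np.uint8), factor, order=0).astype(mask.dtype)
        return new
    out = _geometric(px, op)
    new = ImageTile(out, tile.stain_style, tile.origin)
    if mask is not None:
        return new, _geometric(mask, op)
    return new
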