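"""Mask post-processing and ROI extraction.

Predicted masks carry holes and speckle noise; they are cleaned by hole
filling followed by a morphological opening.  Each remaining 8-connected
component of sufficient area becomes one region of interest: the tile
pixels under the component are kept (background zeroed), cropped to the
bounding box and centred on a fixed square zero canvas for the
classifier.  Components larger than the canvas are downscaled preserving
aspect ratio, never cropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.measure import label as sk_label
from skimage.measure import regionprops
from skimage.morphology import disk, opening
from skimage.transform import resize

from .tileprep import ImageTile


@dataclass
class CellClumpROI:
    """One extracted cell clump on a zero-padded square canvas."""

    canvas: np.ndarray               # S x S x 3 uint8, zeros off-clump
    source_tile: str
    bbox: tuple[int, int, int, int]  # x0, y0, x1, y1 in tile coords, half-open
    area: int                        # foreground pixels in the tile mask
    label: str | None = None


def postprocess_mask(mask: np.ndarray, radius: int = 3) -> np.ndarray:
    """Fill holes, then open with a disk of `radius` pixels."""
    mask = np.asarray(mask, dtype=bool)
    filled = ndimage.binary_fill_holes(mask)
    return opening(filled, disk(radius)).astype(bool)


def _to_canvas(crop: np.ndarray, canvas: int) -> np.ndarray:
    h, w = crop.shape[:2]
    if h > canvas or w > canvas:
        s = canvas / max(h, w)
        nh, nw = max(1, round(h * s)), max(1, round(w * s))
        crop = resize(crop, (nh, nw), order=1, preserve_range=True,
                      anti_aliasing=True).astype(np.uint8)
        h, w = nh, nw
    out = np.zeros((canvas, canvas, 3), dtype=np.uint8)
    y0 = (canvas - h) // 2
    x0 = (canvas - w) // 2
    out[y0 : y0 + h, x0 : x0 + w] = crop
    return out


def extract_rois(tile: ImageTile, mask: np.ndarray, min_area: int = 64,
                 canvas: int = 512, masked_crop: bool = True) -> list[CellClumpROI]:
    """Turn each 8-connected mask component with area >= min_area into a ROI."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != tile.pixels.shape[:2]:
        raise ValueError("mask not aligned to tile")
    lab = sk_label(mask, connectivity=2)
    rois = []
    for region in regionprops(lab):
        if region.area < min_area:
            continue
        y0, x0, y1, x1 = region.bbox
        comp = lab[y0:y1, x0:x1] == region.label
        crop = tile.pixels[y0:y1, x0:x1].copy()
        if masked_crop:
            crop[~comp] = 0
        rois.append(
            CellClumpROI(
                canvas=_to_canvas(crop, canvas),
                source_tile=tile.origin[0],
                bbox=(x0, y0, x1, y1),
                area=int(region.area),
            )
        )
    return rois


def rois_from_record(record, min_area: int = 64, canvas: int = 512) -> list[CellClumpROI]:
    """Ground-truth ROIs for a synthetic record, labelled from the generator."""
    lab = sk_label(record.mask, connectivity=2)
    rois = []
    for clump in record.clumps:
        r, c = int(round(clump.centroid[0])), int(round(clump.centroid[1]))
        comp_id = lab[r, c]
        if comp_id == 0:  # centroid off-component (concave clump): pick nearest
            ys, xs = np.nonzero(lab)
            k = np.argmin((ys - r) ** 2 + (xs - c) ** 2)
            comp_id = lab[ys[k], xs[k]]
        comp = lab == comp_id
        area = int(comp.sum())
        if area < min_area:
            continue
        ys, xs = np.nonzero(comp)
        y0, y1 = ys.min(), ys.max() + 1
        x0, x1 = xs.min(), xs.max() + 1
        crop = record.image.pixels[y0:y1, x0:x1].copy()
        crop[~comp[y0:y1, x0:x1]] = 0
        rois.append(
            CellClumpROI(
                canvas=_to_canvas(crop, canvas),
                source_tile=record.image.origin[0],
                bbox=(int(x0), int(y0), int(x1), int(y1)),
                area=area,
                label=clump.label,
            )
        )
    return rois
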