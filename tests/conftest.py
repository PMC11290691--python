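"""Shared fixtures: synthetic datasets and trained models at desk scale.

The trained-model fixtures are session-scoped because training, while
CPU-sized, is the most expensive step; several tests (end-to-end
screening, held-out performance) share the same fit.
"""

from __future__ import annotations

import numpy as np
import pytest

import cytoscreen as cs
from cytoscreen.roiex import rois_from_record

# study conditions for the segmentation experiment: 200 mixed-stain
# 128 px tiles, 0-4 clumps each, speckled background
SEG_SPEC = cs.SynthSpec(
    tile_size=128,
    n_clumps=(1, 4),
    clump_radius=(10.0, 24.0),
    stain_style="mixed",
    background_noise_density=150.0,
    seed=0,
)

# study conditions for the classification experiment: clumps from larger
# mixed-stain tiles, cropped to a 128 px canvas
ROI_SPEC = cs.SynthSpec(
    tile_size=192,
    n_clumps=(2, 4),
    clump_radius=(18.0, 34.0),
    stain_style="mixed",
    malignant_fraction=0.5,
    seed=1,
)

ROI_CANVAS = 128

CLS_CONFIG = dict(
    input_size=64,
    base_channels=8,
    embed_dim=64,
    n_stages=4,
    batch_size=16,
    bank_capacity=512,
    lr=5e-3,
)


@pytest.fixture(scope="session")
def seg_dataset():
    recs = [cs.generate_tile(SEG_SPEC, s) for s in range(200)]
    images = np.stack([r.image.pixels for r in recs])
    masks = np.stack([r.mask for r in recs])
    return {
        "train": (images[:160], masks[:160]),
        "val": (images[160:], masks[160:]),
        "records": recs,
    }


@pytest.fixture(scope="session")
def trained_segmenter(seg_dataset) -> cs.SegmentationResults:
    model = cs.CellClumpSegmenter(depth=2, base_channels=8, batch_size=8, seed=0)
    tr_i, tr_m = seg_dataset["train"]
    va_i, va_m = seg_dataset["val"]
    return model.fit(tr_i, tr_m, epochs=8, val_images=va_i, val_masks=va_m)


@pytest.fixture(scope="session")
def roi_dataset():
    recs = [cs.generate_tile(ROI_SPEC, 1000 + s) for s in range(80)]
    per_record = [rois_from_record(r, min_area=32, canvas=ROI_CANVAS) for r in recs]
    train = [r for rs in per_record[:56] for r in rs]   # split by source tile
    test = [r for rs in per_record[56:] for r in rs]
    return {"train": train, "test": test, "records": recs}


@pytest.fixture(scope="session")
def trained_classifier(roi_dataset) -> cs.ClassificationResults:
    model = cs.ClumpClassifier(beta_loss=0.5, seed=0, **CLS_CONFIG)
    return model.fit(roi_dataset["train"], epochs=30, seed=0)
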