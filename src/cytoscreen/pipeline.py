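"""End-to-end screening orchestration, configuration and cross-validation.

The screening pipeline chains the stages: tile -> segment -> post-process
-> extract ROIs -> classify -> report.  A tile is flagged positive when
any of its ROIs is called malignant (screening favours sensitivity).
Cross-validation folds are split by source-tile group so no tile's ROIs
straddle a fold boundary.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from .ecrnet import BENIGN, LABEL_TO_INT, MALIGNANT, ClumpClassifier
from .evalmetrics import EvalReport
from .roiex import extract_rois, postprocess_mask, rois_from_record
from .tileprep import ImageTile

log = logging.getLogger("cytoscreen")


@dataclass
class RunConfig:
    """Serializable configuration for a full run (YAML round-trip safe)."""

    seed: int = 0
    folds: int = 10
    out_dir: str = "runs"
    tileprep: dict = field(default_factory=lambda: {
        "tile_size": 1024, "mean_lo": 50.0, "mean_hi": 230.0, "std_min": 20.0,
    })
    cmunet: dict = field(default_factory=lambda: {
        "depth": 2, "base_channels": 8, "ca": True, "mss": True,
        "lr": 5e-3, "batch_size": 32, "epochs": 10, "literal_eq6": False,
    })
    roiex: dict = field(default_factory=lambda: {
        "min_area": 64, "canvas": 512, "open_radius": 3,
    })
    ecrnet: dict = field(default_factory=lambda: {
        "input_size": 64, "embed_dim": 128, "tau": 0.07, "momentum": 0.9,
        "beta_loss": 0.5, "bank_capacity": 4096, "lr": 5e-3,
        "batch_size": 32, "epochs": 10,
    })

    def to_yaml(self, path: str | None = None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source: str) -> "RunConfig":
        if "\n" not in source and source.endswith((".yaml", ".yml")):
            with open(source) as fh:
                data = yaml.safe_load(fh)
        else:
            data = yaml.safe_load(source)
        return cls(**data)


def group_kfold(groups, k: int, seed: int = 0) -> list[np.ndarray]:
    """Partition item indices into k folds by shuffled group.

    Returns one index array per fold; every group's items land in a
    single fold.  Raises if k exceeds the number of distinct groups.
    """
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if k > len(uniq):
        raise ValueError(f"k={k} exceeds {len(uniq)} groups")
    rng = np.random.default_rng(seed)
    order = rng.permutation(uniq)
    folds = []
    for chunk in np.array_split(order, k):
        folds.append(np.flatnonzero(np.isin(groups, chunk)))
    return folds


def crossval(manifest: pd.DataFrame, fit_predict, k: int = 10, seed: int = 0,
             group_col: str = "tile_id", label_col: str = "label"):
    """Group-aware k-fold cross-validation of a classifier.

    `fit_predict(train_df, test_df)` must return positive-class scores
    for the test rows.  Returns (per-fold EvalReports, mean-metric dict).
    """
    folds = group_kfold(manifest[group_col].to_numpy(), k, seed)
    reports = []
    for f, test_idx in enumerate(folds):
        test_mask = np.zeros(len(manifest), dtype=bool)
        test_mask[test_idx] = True
        train_df = manifest.loc[~test_mask]
        test_df = manifest.loc[test_mask]
        scores = np.asarray(fit_predict(train_df, test_df), dtype=float)
        y_true = test_df[label_col].map(lambda l: LABEL_TO_INT.get(l, l)).to_numpy()
        y_pred = (scores >= 0.5).astype(int)
        try:
            report = EvalReport.from_predictions(y_true, y_pred, scores=scores)
        except ValueError:  # single-class fold: counts only
            report = EvalReport.from_predictions(y_true, y_pred)
        reports.append(report)
        log.info("fold %d/%d: n_test=%d accuracy=%s", f + 1, k, len(test_df),
                 report.accuracy)
    means = {}
    for name in ("accuracy", "sensitivity", "precision", "f1", "auc"):
        vals = [getattr(r, name) for r in reports if getattr(r, name) is not None]
        means[name] = float(np.mean(vals)) if vals else None
    return reports, means


def _draw_box(img: np.ndarray, bbox, color, width: int = 3):
    x0, y0, x1, y1 = bbox
    x0, y0 = max(x0, 0), max(y0, 0)
    x1, y1 = min(x1, img.shape[1]), min(y1, img.shape[0])
    img[y0 : y0 + width, x0:x1] = color
    img[max(y1 - width, 0) : y1, x0:x1] = color
    img[y0:y1, x0 : x0 + width] = color
    img[y0:y1, max(x1 - width, 0) : x1] = color


def run_screening(segmenter, classifier: ClumpClassifier, tile: ImageTile,
                  threshold: float = 0.5, min_area: int = 64, canvas: int = 512,
                  open_radius: int = 3) -> dict:
    """Segment one tile, classify its ROIs and assemble the annotated result.

    Returns a dict with the binary mask, the ROI list with per-ROI class
    probabilities, a colour-coded overlay (green benign, red malignant)
    and a JSON-ready summary; any malignant ROI flags the tile positive.
    """
    seg_model = getattr(segmenter, "model", segmenter)
    cls_model = getattr(classifier, "model", classifier)
    mask = postprocess_mask(seg_model.segment(tile, threshold), radius=open_radius)
    rois = extract_rois(tile, mask, min_area=min_area, canvas=canvas)
    log.info("screening %s: %d ROI(s) from %d fg px", tile.origin[0], len(rois),
             int(mask.sum()))
    overlay = tile.pixels.copy()
    results = []
    for roi in rois:
        out = cls_model.classify(roi)
        color = (200, 30, 30) if out.label == MALIGNANT else (30, 160, 60)
        _draw_box(overlay, roi.bbox, color)
        results.append(
            {
                "bbox": list(roi.bbox),
                "area": roi.area,
                "label": out.label,
                "p_benign": float(out.probabilities[0]),
                "p_malignant": float(out.probabilities[1]),
            }
        )
    summary = {
        "source": tile.origin[0],
        "n_rois": len(results),
        "positive": any(r["label"] == MALIGNANT for r in results),
        "rois": results,
    }
    return {"mask": mask, "rois": rois, "overlay": overlay, "summary": summary}


def two_stage_vs_one_stage(records, classifier_config: dict | None = None,
                           epochs: int = 8, seed: int = 0,
                           test_fraction: float = 0.3) -> dict:
    """Paired comparison of ROI-level vs whole-tile classification.

    Two-stage: classify ground-truth ROIs (background removed).
    One-stage: classify whole tiles (resized, background kept), with a
    tile labelled malignant when any clump is malignant.  Both arms use
    identical tile-level train/test splits and the same seeds.
    """
    cfg = dict(classifier_config or {})
    canvas = cfg.pop("canvas", 128)
    min_area = cfg.pop("min_area", 32)

    tiles, tile_labels, roi_groups = [], [], []
    all_rois = []
    for i, rec in enumerate(records):
        if not rec.clumps:
            continue
        rois = rois_from_record(rec, min_area=min_area, canvas=canvas)
        if not rois:
            continue
        tiles.append(rec.image.pixels)
        tile_labels.append(
            MALIGNANT if any(c.label == MALIGNANT for c in rec.clumps) else BENIGN
        )
        all_rois.append(rois)
        roi_groups.append(i)

    rng = np.random.default_rng(seed)
    n = len(tiles)
    order = rng.permutation(n)
    n_test = max(1, int(round(test_fraction * n)))
    test_set = set(order[:n_test].tolist())

    def split(items):
        train = [x for i, x in enumerate(items) if i not in test_set]
        test = [x for i, x in enumerate(items) if i in test_set]
        return train, test

    out = {}
    # --- two-stage arm: ROIs
    roi_train, roi_test = split(all_rois)
    tr = [r for rs in roi_train for r in rs]
    te = [r for rs in roi_test for r in rs]
    model2 = ClumpClassifier(seed=seed, **cfg)
    model2.fit(tr, epochs=epochs, seed=seed)
    scores2 = model2.predict_proba(te)[:, 1]
    y2 = np.array([LABEL_TO_INT[r.label] for r in te])
    out["two_stage"] = _report(y2, scores2)
    # --- one-stage arm: whole tiles
    from .roiex import _to_canvas

    tile_canvases = [_to_canvas(t, canvas) for t in tiles]
    t_train, t_test = split(list(zip(tile_canvases, tile_labels)))
    model1 = ClumpClassifier(seed=seed, **cfg)
    model1.fit([c for c, _ in t_train], [l for _, l in t_train],
               epochs=epochs, seed=seed)
    scores1 = model1.predict_proba([c for c, _ in t_test])[:, 1]
    y1 = np.array([LABEL_TO_INT[l] for _, l in t_test])
    out["one_stage"] = _report(y1, scores1)
    return out


def _report(y_true, scores) -> EvalReport:
    y_pred = (np.asarray(scores) >= 0.5).astype(int)
    try:
        return EvalReport.from_predictions(y_true, y_pred, scores=scores)
    except ValueError:
        return EvalReport.from_predictions(y_true, y_pred)
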