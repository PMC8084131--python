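"""Building labeled per-grain training sets from annotated images.

Segmented regions are matched to ground-truth grain annotations by nearest
center: a region takes the label of the closest annotated grain whose center
falls inside the region's footprint radius.  Unmatched regions (debris that
survived filtering, spurious detections) are dropped from training.
"""

from __future__ import annotations

import numpy as np

from .classify import LabeledFeatureSet
from .features import compute_features
from .segment import SegmentationConfig, segment_image
from .synth import SceneParams, SyntheticScene, generate_scene

__all__ = [
    "label_regions",
    "collect_labeled_features",
    "synthetic_training_set",
]


def label_regions(image: np.ndarray, grains, config=None):
    """Segment an image and pair each region with its ground-truth label.

    ``grains`` is an iterable with ``center_xy`` / ``radius_px`` / ``label``
    attributes or ``{"x", "y", "r", "label"}`` mappings.  Returns a list of
    (region, label) pairs for the regions that matched a grain.
    """
    config = config or SegmentationConfig()
    anns = []
    for g in grains:
        if isinstance(g, dict):
            anns.append((float(g["x"]), float(g["y"]), float(g["r"]),
                         g["label"]))
        else:
            anns.append((g.center_xy[0], g.center_xy[1], g.radius_px, g.label))
    pairs = []
    for region in segment_image(image, config):
        cx, cy = region.centroid_xy
        best, best_d = None, np.inf
        for (gx, gy, gr, lab) in anns:
            d = np.hypot(cx - gx, cy - gy)
            if d < best_d:
                best, best_d = (gr, lab), d
        if best is not None and best_d <= best[0]:
            pairs.append((region, best[1]))
    return pairs


def collect_labeled_features(images_with_grains, config=None
                             ) -> LabeledFeatureSet:
    """Extract labeled feature rows from (image, grains) pairs."""
    config = config or SegmentationConfig()
    feats, labels = [], []
    for image, grains in images_with_grains:
        for region, label in label_regions(image, grains, config):
            feats.append(compute_features(image, region))
            labels.append(label)
    if not feats:
        raise ValueError("no labeled grains found in the training images")
    return LabeledFeatureSet(feats, labels)


def synthetic_training_set(n_per_class: int = 400, seed: int = 42,
                           config: SegmentationConfig | None = None,
                           scene_params: SceneParams | None = None
                           ) -> LabeledFeatureSet:
    """Generate synthetic slides until ~n_per_class labeled grains per class.

    Scenes are balanced (equal viable/non-viable requests) and non-touching
    so ground-truth matching is unambiguous.
    """
    base = scene_params or SceneParams(n_viable=15, n_nonviable=15,
                                       touching_fraction=0.0, noise_sd=3.0)
    config = config or SegmentationConfig()
    feats, labels = [], []
    counts = {"viable": 0, "nonviable": 0}
    scene_seed = seed * 1000 % (2 ** 31)
    while min(counts.values()) < n_per_class:
        params = SceneParams(**{**base.__dict__, "seed": scene_seed})
        scene_seed += 1
        scene = generate_scene(params)
        for region, label in label_regions(scene.image, scene.grains, config):
            if counts[label] >= n_per_class:
                continue
            feats.append(compute_features(scene.image, region))
            labels.append(label)
            counts[label] += 1
    return LabeledFeatureSet(feats, labels)
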