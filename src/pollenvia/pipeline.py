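"""End-to-end viability scoring and batch validation.

``process_image`` runs segmentation, feature extraction and classification on
one micrograph and returns a :class:`ViabilityReport` with per-grain labels
and the pollen-viability percentage

    PolVia = 100 * n_viable / (n_viable + n_nonviable).

``evaluate_batch`` reproduces the count-validation design: per-image
automated counts are correlated (Pearson r, per class) against ground-truth
counts.  ``render_overlay`` draws the standard annotation — yellow bounding
boxes for viable grains, blue for non-viable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import NONVIABLE, VIABLE, ViabilityClassifier
from .features import compute_features
from .segment import GrainRegion, SegmentationConfig, segment_image

__all__ = [
    "ViabilityReport",
    "EvaluationResult",
    "process_image",
    "count_viability",
    "evaluate_batch",
    "render_overlay",
]

YELLOW = (255, 255, 0)
BLUE = (0, 0, 255)


@dataclass
class ViabilityReport:
    """Per-image result: counts, PolVia %, and per-region classifications.

    When no grains are detected, ``no_grains`` is set and ``pol_via_pct`` is
    None (undefined), never silently 0.
    """

    image_id: str
    n_viable: int
    n_nonviable: int
    pol_via_pct: float | None
    regions: list[tuple[GrainRegion, str, float]] = field(default_factory=list)

    @property
    def no_grains(self) -> bool:
        return self.n_viable + self.n_nonviable == 0


@dataclass
class EvaluationResult:
    """Batch count validation: Pearson r per class across images."""

    r_viable: float | None
    r_nonviable: float | None
    n_images: int
    table: pd.DataFrame  # image, predicted/true counts per class


def count_viability(labels: list[str]) -> tuple[int, int, float | None]:
    """Counts and PolVia % from a list of grain labels; empty -> undefined."""
    n_viable = sum(lb == VIABLE for lb in labels)
    n_nonviable = sum(lb == NONVIABLE for lb in labels)
    total = n_viable + n_nonviable
    pct = 100.0 * n_viable / total if total else None
    return n_viable, n_nonviable, pct


def process_image(image: np.ndarray, model: ViabilityClassifier,
                  config: SegmentationConfig | None = None,
                  image_id: str = "") -> ViabilityReport:
    """Segment, featurize and classify every grain on one image."""
    config = config or SegmentationConfig()
    regions = segment_image(image, config)
    results: list[tuple[GrainRegion, str, float]] = []
    for region in regions:
        feats = compute_features(image, region)
        margin = float(model.decision_function(feats.values))
        label = VIABLE if margin > 0 else NONVIABLE
        results.append((region, label, margin))
    n_viable, n_nonviable, pct = count_viability([lb for _, lb, _ in results])
    return ViabilityReport(image_id=image_id, n_viable=n_viable,
                           n_nonviable=n_nonviable, pol_via_pct=pct,
                           regions=results)


def _pearson(x: np.ndarray, y: np.ndarray) -> float | None:
    """Closed-form single-pass Pearson r; None when a vector is constant."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = x.size
    sx, sy = x.sum(), y.sum()
    num = n * (x * y).sum() - sx * sy
    den2 = (n * (x * x).sum() - sx * sx) * (n * (y * y).sum() - sy * sy)
    if den2 <= 0:
        return None
    return float(num / np.sqrt(den2))


def evaluate_batch(reports: list[ViabilityReport],
                   truth: dict[str, tuple[int, int]]) -> EvaluationResult:
    """Correlate automated against true per-image counts, per class.

    ``truth`` maps image_id -> (n_viable_true, n_nonviable_true).  Images
    with zero detected grains are kept in the table (their counts are 0) but
    reports flagged ``no_grains`` with zero *true* grains are skipped.
    Requires >= 3 matched images; a constant count vector yields r = None
    (flagged undefined) rather than NaN.
    """
    missing = [r.image_id for r in reports if r.image_id not in truth]
    if missing:
        raise ValueError(f"no ground truth for image ids: {missing}")
    rows = []
    for r in reports:
        tv, tn = truth[r.image_id]
        if r.no_grains and tv + tn == 0:
            continue
        rows.append((r.image_id, r.n_viable, tv, r.n_nonviable, tn))
    if len(rows) < 3:
        raise ValueError("need at least 3 matched images to correlate")
    table = pd.DataFrame(rows, columns=[
        "image", "n_viable_pred", "n_viable_true",
        "n_nonviable_pred", "n_nonviable_true"])
    r_v = _pearson(table["n_viable_pred"], table["n_viable_true"])
    r_n = _pearson(table["n_nonviable_pred"], table["n_nonviable_true"])
    return EvaluationResult(r_viable=r_v, r_nonviable=r_n,
                            n_images=len(table), table=table)


def _draw_box(img: np.ndarray, bbox, color, stroke: int = 2) -> None:
    x0, y0, x1, y1 = bbox
    h, w = img.shape[:2]
    x0, y0 = max(x0, 0), max(y0, 0)
    x1, y1 = min(x1, w), min(y1, h)
    img[y0:min(y0 + stroke, y1), x0:x1] = color
    img[max(y1 - stroke, y0):y1, x0:x1] = color
    img[y0:y1, x0:min(x0 + stroke, x1)] = color
    img[y0:y1, max(x1 - stroke, x0):x1] = color


def render_overlay(image: np.ndarray, report: ViabilityReport) -> np.ndarray:
    """Annotated copy of the image: yellow boxes around viable grains, blue
    around non-viable, 2 px stroke; all other pixels unchanged."""
    out = np.asarray(image).copy()
    for region, label, _ in report.regions:
        _draw_box(out, region.bbox, YELLOW if label == VIABLE else BLUE)
    return out
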