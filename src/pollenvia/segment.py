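"""Pollen grain segmentation.

The workflow mirrors the classical recipe for counting stained grains on a
bright-field slide: (a) grayscale conversion, (b) Sobel gradient highlighting,
(c) Canny edge detection followed by morphological closing and hole filling to
obtain solid candidate regions, (d) marker-based watershed on the interior
distance transform to split touching grains, and (e) contour extraction with
a circularity/area filter (keep only regions with circularity > 0.5 and
area > 100 px, strict inequalities).

Coordinates are 0-based with x = column and y = row; bounding boxes are
half-open ``(x_min, y_min, x_max, y_max)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from skimage import feature as skfeature
from skimage import measure as skmeasure
from skimage import morphology as skmorph
from skimage.segmentation import watershed

__all__ = [
    "SegmentationConfig",
    "GrainRegion",
    "to_grayscale",
    "gradient_highlight",
    "detect_regions",
    "split_touching",
    "extract_grain_regions",
    "segment_image",
]


@dataclass(frozen=True)
class SegmentationConfig:
    """Tunable knobs of the segmentation stages.

    ``circularity_min`` and ``area_min_px`` are the published acceptance
    thresholds (0.5 and 100 px); regions at or below either are discarded.
    The remaining fields have no published values and default to common
    operating points.
    """

    circularity_min: float = 0.5
    area_min_px: float = 100.0
    canny_low: float = 50.0
    canny_high: float = 150.0
    canny_sigma: float = 1.4
    close_kernel_px: int = 5
    close_iterations: int = 1
    watershed_min_peak_distance_px: int = 15
    border_policy: str = "drop"  # {"keep", "drop"} for border-touching regions
    use_gradient_highlight: bool = False  # run Canny on the Sobel magnitude

    def validate(self) -> None:
        if self.circularity_min < 0 or self.area_min_px < 0:
            raise ValueError("thresholds must be non-negative")
        if not self.canny_low < self.canny_high:
            raise ValueError("canny_low must be < canny_high")
        if self.close_kernel_px < 3 or self.close_kernel_px % 2 == 0:
            raise ValueError("close_kernel_px must be an odd integer >= 3")
        if self.close_iterations < 1:
            raise ValueError("close_iterations must be positive")
        if self.watershed_min_peak_distance_px < 1:
            raise ValueError("watershed_min_peak_distance_px must be positive")
        if self.border_policy not in ("keep", "drop"):
            raise ValueError("border_policy must be 'keep' or 'drop'")


@dataclass(frozen=True, eq=False)
class GrainRegion:
    """One segmented candidate grain.

    ``contour`` is a closed polygon of (x, y) vertices; ``area_px`` is the
    enclosed pixel count (holes filled); ``perimeter_px`` the polygonal arc
    length; ``circularity`` = 4*pi*area / perimeter**2 (may slightly exceed 1
    for small digitized shapes and is deliberately not clamped).
    """

    region_id: int
    contour: np.ndarray  # (N, 2) float, columns (x, y)
    area_px: float
    perimeter_px: float
    circularity: float
    bbox: tuple[int, int, int, int]  # (x_min, y_min, x_max, y_max) half-open
    centroid_xy: tuple[float, float]
    pixel_mask: np.ndarray = None  # filled boolean mask over bbox (internal)

    def __post_init__(self):
        if self.area_px <= 0 or self.perimeter_px <= 0:
            raise ValueError("degenerate region")


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """ITU-R 601 luminance (0.299 R + 0.587 G + 0.114 B), rounded half away
    from zero, returned as uint8 of the same height/width."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB image, got {image.shape}")
    rgb = image.astype(np.float64)
    lum = 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]
    return np.floor(lum + 0.5).astype(np.uint8)  # values are non-negative


def gradient_highlight(gray: np.ndarray) -> np.ndarray:
    """Unnormalized 3x3 Sobel gradient magnitude sqrt(Gx^2 + Gy^2).

    Border handling is reflective.  On an 8-bit input the output lies in
    [0, 1020*sqrt(2)] and is returned as float64.
    """
    gray = np.asarray(gray)
    if gray.ndim != 2 or gray.size == 0:
        raise ValueError("expected a non-empty single-channel image")
    g = gray.astype(np.float64)
    gx = ndi.sobel(g, axis=1, mode="reflect")
    gy = ndi.sobel(g, axis=0, mode="reflect")
    return np.hypot(gx, gy)


def detect_regions(gray: np.ndarray, config: SegmentationConfig | None = None
                   ) -> np.ndarray:
    """Binary mask of candidate grain areas.

    Canny edges (hysteresis thresholds on the 8-bit scale) -> morphological
    closing with an elliptical structuring element -> filling of closed edge
    loops.  Optionally runs Canny on the Sobel magnitude instead of the
    grayscale image (``config.use_gradient_highlight``).
    """
    config = config or SegmentationConfig()
    config.validate()
    gray = np.asarray(gray)
    if gray.ndim != 2 or gray.size == 0:
        raise ValueError("expected a non-empty single-channel image")

    if config.use_gradient_highlight:
        src = gradient_highlight(gray)
        # rescale hysteresis thresholds to the gradient range
        scale = src.max() / 255.0 if src.max() > 0 else 1.0
        low, high = config.canny_low * scale, config.canny_high * scale
    else:
        src = gray.astype(np.float64)
        low, high = config.canny_low, config.canny_high
    edges = skfeature.canny(src, sigma=config.canny_sigma,
                            low_threshold=low, high_threshold=high,
                            use_quantiles=False)
    footprint = skmorph.disk(config.close_kernel_px // 2)
    closed = edges
    for _ in range(config.close_iterations):
        closed = skmorph.closing(closed, footprint)
    return ndi.binary_fill_holes(closed)


def split_touching(mask: np.ndarray, config: SegmentationConfig | None = None
                   ) -> np.ndarray:
    """Split touching grains by watershed on the interior distance transform.

    Markers are local maxima of the Euclidean distance transform separated by
    at least ``watershed_min_peak_distance_px``; each connected component
    keeps at least one marker, so disjoint components never merge and never
    vanish.  Returns an int32 label image with labels 1..K, background 0.
    """
    config = config or SegmentationConfig()
    config.validate()
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        return np.zeros(mask.shape, dtype=np.int32)

    components, n_comp = ndi.label(mask)
    dist = ndi.distance_transform_edt(mask)
    peaks = skfeature.peak_local_max(
        dist, min_distance=config.watershed_min_peak_distance_px,
        labels=components, exclude_border=False)
    marker_img = np.zeros(mask.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        marker_img[r, c] = i
    # a component whose distance peaks were all suppressed still needs a marker
    next_label = len(peaks) + 1
    has_marker = set(np.unique(components[marker_img > 0]))
    for comp in range(1, n_comp + 1):
        if comp not in has_marker:
            rs, cs = np.nonzero(components == comp)
            k = int(np.argmax(dist[rs, cs]))
            marker_img[rs[k], cs[k]] = next_label
            next_label += 1
    labels = watershed(-dist, markers=marker_img, mask=mask)
    # relabel to a dense 1..K in raster-scan order of first occurrence
    out = np.zeros_like(labels, dtype=np.int32)
    mapping: dict[int, int] = {}
    flat = labels.ravel()
    order = np.nonzero(flat)[0]
    for idx in order:
        lab = flat[idx]
        if lab not in mapping:
            mapping[lab] = len(mapping) + 1
    for lab, new in mapping.items():
        out[labels == lab] = new
    return out


def _region_from_mask(filled: np.ndarray, offset_xy: tuple[int, int],
                      region_id: int) -> GrainRegion | None:
    """Build a GrainRegion from a filled boolean mask placed at offset."""
    area = float(filled.sum())
    if area <= 0:
        return None
    padded = np.pad(filled, 1).astype(float)
    contours = skmeasure.find_contours(padded, 0.5)
    if not contours:
        return None
    contour_rc = max(contours, key=len)  # outer boundary is the longest
    perimeter = float(np.sum(np.hypot(*np.diff(contour_rc, axis=0).T)))
    if perimeter <= 0:
        return None
    ox, oy = offset_xy
    contour_xy = np.column_stack([contour_rc[:, 1] - 1 + ox,
                                  contour_rc[:, 0] - 1 + oy])
    rs, cs = np.nonzero(filled)
    centroid = (float(cs.mean()) + ox, float(rs.mean()) + oy)
    bbox = (int(cs.min()) + ox, int(rs.min()) + oy,
            int(cs.max()) + 1 + ox, int(rs.max()) + 1 + oy)
    circ = 4.0 * np.pi * area / perimeter ** 2
    # pixel_mask is aligned with (and exactly spans) the bounding box
    cropped = filled[rs.min():rs.max() + 1, cs.min():cs.max() + 1]
    return GrainRegion(region_id=region_id, contour=contour_xy, area_px=area,
                       perimeter_px=perimeter, circularity=circ, bbox=bbox,
                       centroid_xy=centroid, pixel_mask=cropped)


def extract_grain_regions(labeled: np.ndarray,
                          config: SegmentationConfig | None = None
                          ) -> list[GrainRegion]:
    """Contours + shape filter: keep regions with circularity > circularity_min
    and area > area_min_px (strict), optionally dropping border-touching ones.

    Region ids are assigned in raster-scan order of the centroids, so the
    output is deterministic regardless of input label numbering.
    """
    config = config or SegmentationConfig()
    config.validate()
    labeled = np.asarray(labeled)
    h, w = labeled.shape
    candidates: list[GrainRegion] = []
    for sl, lab in zip(ndi.find_objects(labeled),
                       range(1, int(labeled.max()) + 1)):
        if sl is None:
            continue
        filled = ndi.binary_fill_holes(labeled[sl] == lab)
        region = _region_from_mask(filled, (sl[1].start, sl[0].start), 0)
        if region is None:
            continue
        if config.border_policy == "drop":
            x0, y0, x1, y1 = region.bbox
            if x0 == 0 or y0 == 0 or x1 == w or y1 == h:
                continue
        if region.circularity <= config.circularity_min:
            continue
        if region.area_px <= config.area_min_px:
            continue
        candidates.append(region)
    candidates.sort(key=lambda r: (r.centroid_xy[1], r.centroid_xy[0]))
    return [GrainRegion(region_id=i, contour=r.contour, area_px=r.area_px,
                        perimeter_px=r.perimeter_px, circularity=r.circularity,
                        bbox=r.bbox, centroid_xy=r.centroid_xy,
                        pixel_mask=r.pixel_mask)
            for i, r in enumerate(candidates, start=1)]


def segment_image(image: np.ndarray,
                  config: SegmentationConfig | None = None
                  ) -> list[GrainRegion]:
    """Full segmentation: grayscale -> edges/closing -> watershed -> filtered
    grain regions."""
    config = config or SegmentationConfig()
    gray = to_grayscale(image)
    mask = detect_regions(gray, config)
    labeled = split_touching(mask, config)
    return extract_grain_regions(labeled, config)
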