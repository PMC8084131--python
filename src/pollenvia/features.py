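"""Per-grain 19-value descriptor: 10 geometric, 2 texture, 7 color features.

Geometric features describe size and shape of the filled region; texture
features summarize the within-region grayscale intensity distribution
(population standard deviation and Shannon entropy of an 8-bin histogram, in
bits); color features are channel means in RGB and HSV plus the fraction of
region pixels whose red channel dominates — the quantity that separates
stained (viable) from unstained (non-viable) grains.

All statistics are computed over the region's enclosed (filled) pixel set.
Hue is averaged circularly and reported in degrees [0, 360); S and V lie in
[0, 1]; RGB means are on the 8-bit scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure as skmeasure
from skimage.color import rgb2hsv

from .segment import GrainRegion, to_grayscale

__all__ = [
    "FEATURE_NAMES",
    "GrainFeatures",
    "FeatureScaler",
    "compute_features",
    "fit_scaler",
    "apply_scaler",
]

#: canonical feature order; every vector in the package follows it
FEATURE_NAMES: tuple[str, ...] = (
    # 10 geometric
    "area_px", "perimeter_px", "circularity", "equivalent_diameter",
    "major_axis_len", "minor_axis_len", "aspect_ratio", "eccentricity",
    "solidity", "extent",
    # 2 texture
    "intensity_sd", "intensity_entropy",
    # 7 color
    "mean_R", "mean_G", "mean_B", "mean_H", "mean_S", "mean_V",
    "red_fraction",
)

N_FEATURES = len(FEATURE_NAMES)  # == 19


@dataclass(frozen=True, eq=False)
class GrainFeatures:
    """The 19-value descriptor, stored as a float vector in FEATURE_NAMES
    order."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.shape != (N_FEATURES,):
            raise ValueError(f"expected {N_FEATURES} features, got {v.shape}")
        object.__setattr__(self, "values", v)

    def __getitem__(self, name: str) -> float:
        return float(self.values[FEATURE_NAMES.index(name)])

    def as_dict(self) -> dict[str, float]:
        return {n: float(v) for n, v in zip(FEATURE_NAMES, self.values)}


def _entropy_bits(gray_values: np.ndarray, n_bins: int = 8) -> float:
    """Shannon entropy (bits) of an 8-bin histogram over [0, 256)."""
    hist, _ = np.histogram(gray_values, bins=n_bins, range=(0, 256))
    p = hist[hist > 0] / gray_values.size
    return float(-(p * np.log2(p)).sum())


def compute_features(image: np.ndarray, region: GrainRegion) -> GrainFeatures:
    """Extract the 19-feature descriptor of one segmented grain.

    Raises a bounds error if the region does not lie within the image and a
    degenerate-region error if its pixel set is empty.
    """
    image = np.asarray(image)
    h, w = image.shape[:2]
    x0, y0, x1, y1 = region.bbox
    if x0 < 0 or y0 < 0 or x1 > w or y1 > h:
        raise ValueError(f"region bbox {region.bbox} outside image {w}x{h}")
    mask = region.pixel_mask
    if mask is None or not mask.any():
        raise ValueError("degenerate region: empty pixel set")

    # geometric moments from the filled mask
    props = skmeasure.regionprops(mask.astype(np.uint8))[0]
    area = float(region.area_px)
    perimeter = float(region.perimeter_px)
    circularity = float(region.circularity)
    equivalent_diameter = float(np.sqrt(4.0 * area / np.pi))
    major = float(props.axis_major_length)
    minor = float(props.axis_minor_length)
    aspect_ratio = major / minor if minor > 0 else max(major, 1.0)
    eccentricity = float(props.eccentricity)
    solidity = float(props.solidity)
    extent = float(props.extent)

    patch = image[y0:y1, x0:x1]
    pix = patch[mask]  # (N, 3) region pixels
    gray = to_grayscale(patch)[mask].astype(np.float64)
    intensity_sd = float(gray.std())  # population SD
    intensity_entropy = _entropy_bits(gray)

    rgb = pix.astype(np.float64)
    mean_rgb = rgb.mean(axis=0)
    hsv = rgb2hsv(rgb[None, :, :] / 255.0)[0]
    hue_rad = hsv[:, 0] * 2.0 * np.pi
    # circular mean so red hues near 0 deg and 360 deg do not cancel
    mean_h = float(np.degrees(np.arctan2(np.sin(hue_rad).mean(),
                                         np.cos(hue_rad).mean())) % 360.0)
    mean_s = float(hsv[:, 1].mean())
    mean_v = float(hsv[:, 2].mean())
    red_fraction = float(np.mean((rgb[:, 0] > rgb[:, 1])
                                 & (rgb[:, 0] > rgb[:, 2])))

    return GrainFeatures(np.array([
        area, perimeter, circularity, equivalent_diameter, major, minor,
        aspect_ratio, eccentricity, solidity, extent,
        intensity_sd, intensity_entropy,
        mean_rgb[0], mean_rgb[1], mean_rgb[2], mean_h, mean_s, mean_v,
        red_fraction,
    ]))


@dataclass
class FeatureScaler:
    """Per-feature standardizer: (x - mean) / sd, fitted on a training batch.

    Features that are constant in the batch get sd = 1 so scaling is a no-op
    for them rather than a division by zero.
    """

    mean: np.ndarray | None = None
    sd: np.ndarray | None = None

    @property
    def fitted(self) -> bool:
        return self.mean is not None

    def fit(self, batch: list[GrainFeatures] | np.ndarray) -> "FeatureScaler":
        X = _as_matrix(batch)
        if X.shape[0] == 0:
            raise ValueError("cannot fit a scaler on an empty batch")
        self.mean = X.mean(axis=0)
        sd = X.std(axis=0)  # population SD
        sd[sd == 0.0] = 1.0
        self.sd = sd
        return self

    def transform(self, x: GrainFeatures | np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("scaler is not fitted")
        arr = x.values if isinstance(x, GrainFeatures) else np.asarray(x, float)
        if arr.shape[-1] != N_FEATURES:
            raise ValueError(f"expected {N_FEATURES} features")
        return (arr - self.mean) / self.sd

    def inverse_transform(self, z: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("scaler is not fitted")
        return np.asarray(z, float) * self.sd + self.mean


def _as_matrix(batch) -> np.ndarray:
    if isinstance(batch, np.ndarray):
        X = np.asarray(batch, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != N_FEATURES:
            raise ValueError(f"expected (n, {N_FEATURES}) matrix")
        return X
    return np.array([f.values for f in batch], dtype=np.float64).reshape(
        -1, N_FEATURES)


def fit_scaler(batch: list[GrainFeatures]) -> FeatureScaler:
    """Fit a :class:`FeatureScaler` on a non-empty feature batch."""
    return FeatureScaler().fit(batch)


def apply_scaler(scaler: FeatureScaler,
                 features: GrainFeatures | np.ndarray) -> np.ndarray:
    """Standardize one feature vector with a fitted scaler."""
    return scaler.transform(features)
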