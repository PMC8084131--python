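"""Seeded synthetic stained-pollen slide generator with exact ground truth.

Emulates the appearance of acetocarmine-stained pollen on a bright slide
background: viable grains take up the stain and render as filled red,
near-circular blobs; non-viable grains stay "transparent" — interior close to
the background with a visible darker rim.  Scenes optionally include touching
grain pairs, small debris specks, additive Gaussian noise and a left-to-right
illumination ramp, so the downstream segmentation and classifier can be
validated without any external image data.

All randomness is drawn from a single ``numpy.random.default_rng(seed)``
stream in a fixed order (grain sizes/shapes, placements, colors, debris,
noise), so a given :class:`SceneParams` always yields a byte-identical image
and an identical ground-truth list.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.draw import ellipse as draw_ellipse

__all__ = [
    "SceneParams",
    "GroundTruthGrain",
    "SyntheticScene",
    "SceneTooCrowdedError",
    "generate_scene",
    "generate_dataset",
]

#: labels used throughout the package
VIABLE = "viable"
NONVIABLE = "nonviable"

#: how many failed placement draws are tolerated before giving up
PLACEMENT_ATTEMPTS = 2000


@dataclass(frozen=True)
class SceneParams:
    """Parameters of one synthetic slide.

    Defaults describe a 4X-objective-like field of view: a bright slide
    background (~225/255), grains of radius ~15 px, mild sensor noise and a
    gentle illumination gradient.
    """

    image_height_px: int = 512
    image_width_px: int = 512
    n_viable: int = 20
    n_nonviable: int = 10
    radius_mean_px: float = 15.0
    radius_sd_px: float = 2.0
    touching_fraction: float = 0.0
    noise_sd: float = 3.0
    illumination_slope: float = 10.0
    viable_color_mean: tuple[int, int, int] = (178, 44, 74)
    nonviable_color_mean: tuple[int, int, int] = (232, 222, 224)
    n_debris: int = 6
    seed: int = 0

    def validate(self) -> None:
        if self.image_height_px <= 0 or self.image_width_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.n_viable < 0 or self.n_nonviable < 0 or self.n_debris < 0:
            raise ValueError("object counts must be non-negative")
        if self.radius_mean_px < 5:
            raise ValueError("radius_mean_px must be >= 5")
        if not 0.0 <= self.touching_fraction <= 1.0:
            raise ValueError("touching_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for c in (*self.viable_color_mean, *self.nonviable_color_mean):
            if not 0 <= c <= 255:
                raise ValueError("colors must be 8-bit RGB triples")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")


@dataclass(frozen=True)
class GroundTruthGrain:
    """One rendered grain: center (x=column, y=row, 0-based), area-equivalent
    radius in pixels, and the true viability label."""

    center_xy: tuple[float, float]
    radius_px: float
    label: str


@dataclass(frozen=True, eq=False)
class SyntheticScene:
    image: np.ndarray  # (H, W, 3) uint8
    grains: tuple[GroundTruthGrain, ...]
    params: SceneParams
    #: boolean ground-truth stain mask (grain footprints; no debris, no noise)
    mask: np.ndarray = field(default=None, repr=False, compare=False)

    @property
    def n_viable_true(self) -> int:
        return sum(g.label == VIABLE for g in self.grains)

    @property
    def n_nonviable_true(self) -> int:
        return sum(g.label == NONVIABLE for g in self.grains)


class SceneTooCrowdedError(RuntimeError):
    """Raised when grain placement fails after the attempt budget."""


# rim of a non-viable ("transparent") grain, dark enough for Canny
_RIM_COLOR = np.array([128, 108, 118], dtype=float)
_RIM_WIDTH_PX = 2.5
_BACKGROUND_LEVEL = 225.0
_COLOR_JITTER_SD = 6.0
_SEPARATION_MARGIN_PX = 3.0  # > spec's 2 px non-touching guarantee


def _sample_grain_geometry(rng: np.random.Generator, p: SceneParams):
    """Radius, ellipse axis ratio and orientation for one grain."""
    radius = float(np.clip(rng.normal(p.radius_mean_px, p.radius_sd_px),
                           5.0, 0.45 * min(p.image_height_px, p.image_width_px)))
    ratio = float(rng.uniform(0.85, 1.0))  # near-circular by construction
    angle = float(rng.uniform(0.0, np.pi))
    # a*b == radius**2 so the recorded radius is area-equivalent
    a = radius / np.sqrt(ratio)
    b = radius * np.sqrt(ratio)
    return radius, a, b, angle


def _place(rng: np.random.Generator, p: SceneParams, placed, radius, a,
           touching: bool):
    """Rejection-sample a center; ``placed`` is a list of (x, y, r) tuples."""
    h, w = p.image_height_px, p.image_width_px
    border = a + 4.0  # keep whole grain off the image border
    if 2 * border >= min(h, w):
        raise SceneTooCrowdedError("grains too large for the image")
    for _ in range(PLACEMENT_ATTEMPTS):
        if touching and placed:
            k = int(rng.integers(len(placed)))
            ox, oy, orad = placed[k]
            theta = rng.uniform(0.0, 2.0 * np.pi)
            d = rng.uniform(0.80, 0.95) * (orad + radius)
            x, y = ox + d * np.cos(theta), oy + d * np.sin(theta)
            if not (border <= x <= w - border and border <= y <= h - border):
                continue
            # the pair may touch its partner, but nothing else
            ok = all(
                np.hypot(x - px, y - py) > radius + pr + _SEPARATION_MARGIN_PX
                for j, (px, py, pr) in enumerate(placed) if j != k
            )
        else:
            x = rng.uniform(border, w - border)
            y = rng.uniform(border, h - border)
            ok = all(
                np.hypot(x - px, y - py) > radius + pr + _SEPARATION_MARGIN_PX
                for px, py, pr in placed
            )
        if ok:
            return float(x), float(y)
    raise SceneTooCrowdedError(
        f"scene too crowded: could not place a grain after "
        f"{PLACEMENT_ATTEMPTS} attempts (requested "
        f"{p.n_viable + p.n_nonviable} grains on {w}x{h} px)"
    )


def _paint_grain(img, mask, x, y, a, b, angle, label, color):
    h, w = img.shape[:2]
    rr, cc = draw_ellipse(y, x, a, b, shape=(h, w), rotation=angle)
    mask[rr, cc] = True
    if label == VIABLE:
        img[rr, cc] = color
    else:
        img[rr, cc] = _RIM_COLOR
        ai = max(a - _RIM_WIDTH_PX, 1.0)
        bi = max(b - _RIM_WIDTH_PX, 1.0)
        rr_i, cc_i = draw_ellipse(y, x, ai, bi, shape=(h, w), rotation=angle)
        img[rr_i, cc_i] = color


def generate_scene(params: SceneParams) -> SyntheticScene:
    """Render one synthetic slide and its exact ground truth.

    Deterministic: identical ``params`` (including seed) produce a
    byte-identical pixel buffer and the same ordered ground-truth list.

    Raises
    ------
    ValueError
        If the parameters violate their invariants.
    SceneTooCrowdedError
        If the requested grains cannot be placed within the attempt budget.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    h, w = params.image_height_px, params.image_width_px

    # background: flat level plus a left-to-right illumination ramp
    ramp = np.linspace(-params.illumination_slope / 2.0,
                       params.illumination_slope / 2.0, w)
    img = np.empty((h, w, 3), dtype=float)
    img[:] = (_BACKGROUND_LEVEL + ramp)[None, :, None]

    labels = [VIABLE] * params.n_viable + [NONVIABLE] * params.n_nonviable
    n = len(labels)
    order = rng.permutation(n) if n else np.array([], dtype=int)
    labels = [labels[i] for i in order]
    n_touch = int(round(params.touching_fraction * n))

    placed: list[tuple[float, float, float]] = []
    grains: list[GroundTruthGrain] = []
    stain_mask = np.zeros((h, w), dtype=bool)
    for i, label in enumerate(labels):
        radius, a, b, angle = _sample_grain_geometry(rng, params)
        touching = i >= 1 and (n - i) <= n_touch  # last n_touch grains attach
        x, y = _place(rng, params, placed, radius, a, touching)
        mean = params.viable_color_mean if label == VIABLE \
            else params.nonviable_color_mean
        color = np.clip(rng.normal(mean, _COLOR_JITTER_SD), 0, 255)
        _paint_grain(img, stain_mask, x, y, a, b, angle, label, color)
        placed.append((x, y, radius))
        grains.append(GroundTruthGrain((x, y), radius, label))

    # small dark debris specks, well below the 100 px area filter
    for _ in range(params.n_debris):
        r = float(rng.uniform(1.0, 3.0))
        for _ in range(PLACEMENT_ATTEMPTS):
            x = rng.uniform(r + 2, w - r - 2)
            y = rng.uniform(r + 2, h - r - 2)
            if all(np.hypot(x - px, y - py) > r + pr + _SEPARATION_MARGIN_PX
                   for px, py, pr in placed):
                break
        else:
            break  # no room left for debris; skip silently
        rr, cc = draw_ellipse(y, x, r, r, shape=(h, w))
        img[rr, cc] = rng.uniform(60, 120)

    if params.noise_sd > 0:
        img += rng.normal(0.0, params.noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return SyntheticScene(image=img, grains=tuple(grains), params=params,
                          mask=stain_mask)


def generate_dataset(params_list: list[SceneParams], out_dir: str | Path) -> dict:
    """Render many scenes to ``out_dir`` as PNGs plus annotations.

    Writes ``scene_<i>.png`` per scene, one ``annotations.json`` (per-grain
    x/y/r/label records) and ``counts.csv`` (per-image true counts), and
    returns a manifest dict listing files, seeds and true counts.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    manifest = {"images": []}
    for i, p in enumerate(params_list):
        scene = generate_scene(p)
        name = f"scene_{i:04d}.png"
        iio.imwrite(out_dir / name, scene.image)
        records.append({
            "image": name,
            "grains": [
                {"x": g.center_xy[0], "y": g.center_xy[1],
                 "r": g.radius_px, "label": g.label}
                for g in scene.grains
            ],
        })
        manifest["images"].append({
            "image": name,
            "seed": p.seed,
            "n_viable_true": scene.n_viable_true,
            "n_nonviable_true": scene.n_nonviable_true,
        })
    with open(out_dir / "annotations.json", "w") as fh:
        json.dump(records, fh, indent=1, sort_keys=True)
    with open(out_dir / "counts.csv", "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["image", "n_viable_true", "n_nonviable_true"])
        for row in manifest["images"]:
            wr.writerow([row["image"], row["n_viable_true"],
                         row["n_nonviable_true"]])
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
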