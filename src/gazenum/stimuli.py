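"""Dot-array stimulus battery for small-number enumeration experiments.

The battery contains 36 items: numerosities 1-9, each shown once in a
canonical (dice-like, symmetric) arrangement and three times in random
arrangements.  Geometry follows a 24-inch full-HD screen viewed at 60 cm:
dots are 2 cm wide and the whole pattern spans at most 15 cm per axis,
centered on the screen center (where a fixation star is shown between
trials).

Coordinates are 0-based screen pixels, origin top-left, x rightward,
y downward.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "ScreenGeometry",
    "Arrangement",
    "Condition",
    "DotStimulus",
    "StimulusError",
    "make_canonical",
    "make_random",
    "make_item_battery",
    "condition_of",
    "battery_to_json",
    "battery_from_json",
    "render_stimulus_png",
]

# 24" 16:9 panel: width = 24 * 2.54 * 16 / sqrt(16^2 + 9^2) cm ~= 53.13 cm
_SCREEN_WIDTH_CM = 24.0 * 2.54 * 16.0 / math.sqrt(16.0**2 + 9.0**2)
_DEFAULT_PX_PER_CM = 1920.0 / _SCREEN_WIDTH_CM  # ~36.14 px/cm


class StimulusError(ValueError):
    """Invalid stimulus parameters or failed stimulus generation."""


@dataclass(frozen=True)
class ScreenGeometry:
    """Physical/pixel geometry of the presentation screen.

    ``heatmap_h_px`` is the height of the gaze-heatmap band exported per
    trial; it is the vertically centered strip of the screen.
    """

    screen_w_px: int = 1920
    screen_h_px: int = 1080
    heatmap_h_px: int = 760
    px_per_cm: float = _DEFAULT_PX_PER_CM
    dot_diameter_px: float = 2.0 * _DEFAULT_PX_PER_CM
    max_span_px: float = 15.0 * _DEFAULT_PX_PER_CM
    viewing_distance_cm: float = 60.0

    def __post_init__(self) -> None:
        for name in ("screen_w_px", "screen_h_px", "heatmap_h_px", "px_per_cm",
                     "dot_diameter_px", "max_span_px", "viewing_distance_cm"):
            if getattr(self, name) <= 0:
                raise StimulusError(f"{name} must be positive")
        if self.dot_diameter_px >= self.max_span_px:
            raise StimulusError("dot diameter must be smaller than max span")
        if self.heatmap_h_px > self.screen_h_px:
            raise StimulusError("heatmap band cannot exceed screen height")

    @property
    def fixation_star(self) -> tuple[float, float]:
        """Screen center, where the inter-trial fixation star is shown."""
        return (self.screen_w_px / 2.0, self.screen_h_px / 2.0)

    @property
    def band_top_px(self) -> int:
        """First screen row included in the heatmap band."""
        return (self.screen_h_px - self.heatmap_h_px) // 2


class Arrangement(str, Enum):
    CANONICAL = "canonical"
    RANDOM_1 = "random_1"
    RANDOM_2 = "random_2"
    RANDOM_3 = "random_3"

    @property
    def is_random(self) -> bool:
        return self is not Arrangement.CANONICAL


class Condition(str, Enum):
    """Analysis condition of an item (numerosity range x arrangement kind)."""

    SUBITIZING_RANDOM = "subitizing_random"      # 2-4 random
    COUNTING_RANDOM = "counting_random"          # 5-9 random
    DICE_CANONICAL = "dice_canonical"            # 2-6 canonical
    BEYOND_DICE_CANONICAL = "beyond_dice_canonical"  # 7-9 canonical
    EXCLUDED_ONE = "excluded_one"                # numerosity 1 (not analyzed)


@dataclass(frozen=True)
class DotStimulus:
    """One enumeration item: a set of dot centers on the screen."""

    item_id: str
    numerosity: int
    arrangement: Arrangement
    dot_centers: np.ndarray  # (n, 2) float, screen px
    geometry: ScreenGeometry = field(default_factory=ScreenGeometry)

    def __post_init__(self) -> None:
        centers = np.asarray(self.dot_centers, dtype=float)
        object.__setattr__(self, "dot_centers", centers)
        if centers.shape != (self.numerosity, 2):
            raise StimulusError(
                f"{self.item_id}: expected {self.numerosity} dot centers, "
                f"got shape {centers.shape}")

    @property
    def centroid(self) -> np.ndarray:
        """Mean of the dot centers (the 'middle of the pattern')."""
        return self.dot_centers.mean(axis=0)

    def validate(self) -> None:
        """Check the geometric invariants (no overlap, span, centering)."""
        g = self.geometry
        c = self.dot_centers
        n = self.numerosity
        if n > 1:
            d = np.linalg.norm(c[:, None, :] - c[None, :, :], axis=-1)
            iu = np.triu_indices(n, k=1)
            if d[iu].min() < g.dot_diameter_px - 1e-9:
                raise StimulusError(f"{self.item_id}: overlapping dots")
        lo, hi = c.min(axis=0), c.max(axis=0)
        if (hi - lo).max() > g.max_span_px + 1e-9:
            raise StimulusError(f"{self.item_id}: span exceeds maximum")
        box_center = (lo + hi) / 2.0
        if np.abs(box_center - np.array(g.fixation_star)).max() > 1e-6:
            raise StimulusError(f"{self.item_id}: pattern not centered")


# Canonical layouts in half-span units on [-1, 1]^2, (x, y).  2-6 are the
# standard dice faces; 7-9 are symmetric extensions (dice-six plus a center
# dot, two columns of four, and a 3x3 grid).
_CANONICAL_UNIT: dict[int, list[tuple[float, float]]] = {
    1: [(0, 0)],
    2: [(-1, -1), (1, 1)],
    3: [(-1, -1), (0, 0), (1, 1)],
    4: [(-1, -1), (1, -1), (-1, 1), (1, 1)],
    5: [(-1, -1), (1, -1), (0, 0), (-1, 1), (1, 1)],
    6: [(-1, -1), (1, -1), (-1, 0), (1, 0), (-1, 1), (1, 1)],
    7: [(-1, -1), (1, -1), (-1, 0), (0, 0), (1, 0), (-1, 1), (1, 1)],
    8: [(-1, -1), (1, -1), (-1, -1 / 3), (1, -1 / 3),
        (-1, 1 / 3), (1, 1 / 3), (-1, 1), (1, 1)],
    9: [(-1, -1), (0, -1), (1, -1), (-1, 0), (0, 0), (1, 0),
        (-1, 1), (0, 1), (1, 1)],
}

# Random-arrangement constraints beyond the hard invariants: dots keep an
# extra half-diameter clearance, the pattern fills a good part of the
# allowed span, and the display center is not crowded by dots (the region
# around the fixation-star position stays distinguishable from the dots).
_MIN_SEP_FACTOR = 1.5          # pairwise distance >= 1.5 * dot diameter
_MIN_SPAN_FRACTION = 0.55      # bounding box >= 55% of max span per axis
_CENTER_CLEAR_FACTOR = 1.6     # "near centroid" radius in dot diameters
_MAX_ATTEMPTS = 10_000


def make_canonical(numerosity: int, geometry: ScreenGeometry | None = None,
                   item_id: str | None = None) -> DotStimulus:
    """Return the deterministic canonical (dice-style) layout for 2-9 dots."""
    if not 2 <= int(numerosity) <= 9:
        raise StimulusError(f"canonical layouts exist for 2-9 dots, got {numerosity}")
    return _canonical(int(numerosity), geometry or ScreenGeometry(), item_id)


def _canonical(numerosity: int, geometry: ScreenGeometry,
               item_id: str | None = None) -> DotStimulus:
    unit = np.array(_CANONICAL_UNIT[numerosity], dtype=float)
    centers = np.array(geometry.fixation_star) + unit * (geometry.max_span_px / 2.0)
    stim = DotStimulus(
        item_id=item_id or f"n{numerosity}_canonical",
        numerosity=numerosity,
        arrangement=Arrangement.CANONICAL,
        dot_centers=centers,
        geometry=geometry,
    )
    stim.validate()
    return stim


def make_random(numerosity: int, seed: int,
                geometry: ScreenGeometry | None = None,
                item_id: str | None = None,
                arrangement: Arrangement = Arrangement.RANDOM_1) -> DotStimulus:
    """Rejection-sample a random arrangement of ``numerosity`` dots.

    Identical (numerosity, seed) pairs always yield identical centers.
    """
    if not 1 <= int(numerosity) <= 9:
        raise StimulusError(f"numerosity must be 1-9, got {numerosity}")
    n = int(numerosity)
    g = geometry or ScreenGeometry()
    rng = np.random.default_rng(seed)
    center = np.array(g.fixation_star)
    half = g.max_span_px / 2.0
    min_sep = _MIN_SEP_FACTOR * g.dot_diameter_px
    clear_r = _CENTER_CLEAR_FACTOR * g.dot_diameter_px

    for _ in range(_MAX_ATTEMPTS):
        pts = center + rng.uniform(-half, half, size=(n, 2))
        lo, hi = pts.min(axis=0), pts.max(axis=0)
        # recenter the bounding box on the screen center
        pts = pts + (center - (lo + hi) / 2.0)
        if n >= 2:
            span = pts.max(axis=0) - pts.min(axis=0)
            if span.min() < _MIN_SPAN_FRACTION * g.max_span_px:
                continue
            d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
            iu = np.triu_indices(n, k=1)
            if d[iu].min() < min_sep:
                continue
            # keep the pattern middle clear: fewer than half the dots may
            # sit next to the dot centroid
            near = np.linalg.norm(pts - pts.mean(axis=0), axis=1) < clear_r
            if near.sum() >= math.ceil(n / 2):
                continue
        stim = DotStimulus(
            item_id=item_id or f"n{n}_{arrangement.value}",
            numerosity=n,
            arrangement=arrangement,
            dot_centers=pts,
            geometry=g,
        )
        stim.validate()
        return stim
    raise StimulusError(
        f"could not place {n} dots after {_MAX_ATTEMPTS} attempts")


def make_item_battery(seed: int,
                      geometry: ScreenGeometry | None = None) -> list[DotStimulus]:
    """Build the full 36-item battery in a seed-determined presentation order.

    For every numerosity 1-9 there is one canonical item (a single centered
    dot for n=1) and three random items.  The presentation order is shuffled
    once; every participant sees the same order.
    """
    g = geometry or ScreenGeometry()
    ss = np.random.SeedSequence(seed)
    order_rng = np.random.default_rng(ss.spawn(1)[0])
    items: list[DotStimulus] = []
    for n in range(1, 10):
        if n == 1:
            items.append(DotStimulus(
                item_id="n1_canonical", numerosity=1,
                arrangement=Arrangement.CANONICAL,
                dot_centers=np.array([g.fixation_star]), geometry=g))
        else:
            items.append(_canonical(n, g))
        for k, arr in enumerate(
                (Arrangement.RANDOM_1, Arrangement.RANDOM_2, Arrangement.RANDOM_3)):
            item_seed = np.random.SeedSequence(
                entropy=seed, spawn_key=(n, k + 1)).generate_state(1)[0]
            items.append(make_random(n, int(item_seed), g,
                                     item_id=f"n{n}_{arr.value}",
                                     arrangement=arr))
    perm = order_rng.permutation(len(items))
    return [items[i] for i in perm]


def condition_of(stimulus: DotStimulus) -> Condition:
    """Map an item to its analysis condition."""
    n = stimulus.numerosity
    if n == 1:
        return Condition.EXCLUDED_ONE
    if stimulus.arrangement.is_random:
        return (Condition.SUBITIZING_RANDOM if n <= 4
                else Condition.COUNTING_RANDOM)
    return (Condition.DICE_CANONICAL if n <= 6
            else Condition.BEYOND_DICE_CANONICAL)


def battery_to_json(battery: Sequence[DotStimulus], path: str | Path) -> None:
    g = battery[0].geometry
    payload = {
        "geometry": {
            "screen_w_px": g.screen_w_px, "screen_h_px": g.screen_h_px,
            "heatmap_h_px": g.heatmap_h_px, "px_per_cm": g.px_per_cm,
            "dot_diameter_px": g.dot_diameter_px, "max_span_px": g.max_span_px,
            "viewing_distance_cm": g.viewing_distance_cm,
        },
        "items": [
            {"item_id": s.item_id, "numerosity": s.numerosity,
             "arrangement": s.arrangement.value,
             "dot_centers": s.dot_centers.tolist()}
            for s in battery
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


def battery_from_json(path: str | Path) -> list[DotStimulus]:
    payload = json.loads(Path(path).read_text())
    g = ScreenGeometry(**payload["geometry"])
    return [
        DotStimulus(item_id=it["item_id"], numerosity=it["numerosity"],
                    arrangement=Arrangement(it["arrangement"]),
                    dot_centers=np.array(it["dot_centers"]), geometry=g)
        for it in payload["items"]
    ]


def render_stimulus_png(stimulus: DotStimulus, path: str | Path) -> None:
    """Draw the item as black dots on white, for documentation only."""
    from PIL import Image, ImageDraw

    g = stimulus.geometry
    img = Image.new("RGB", (g.screen_w_px, g.screen_h_px), "white")
    draw = ImageDraw.Draw(img)
    r = g.dot_diameter_px / 2.0
    for x, y in stimulus.dot_centers:
        draw.ellipse((x - r, y - r, x + r, y + r), fill="black")
    img.save(Path(path))
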