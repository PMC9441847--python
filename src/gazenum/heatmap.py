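"""Gaze heatmap rendering, correctness filtering, and size reduction.

One trial yields one full-size color heatmap: a 1,920x760 band (the
vertically centered strip of the 1,080-row screen) where a
duration-weighted Gaussian kernel is accumulated per fixation and the
result is normalized relative to the complete trial, then mapped onto a
red-green color table (low intensity green, high intensity red).

For clustering, heatmaps are converted to grayscale and block-average
subsampled to 160x90 - a reduction of the scalar count by a factor of 304.
The color table is affine in intensity per channel, so grayscale
luminance is an affine function of intensity and Euclidean distances on
reduced heatmaps are proportional to distances on the underlying
intensity fields.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .gaze import TrialRecord
from .stimuli import ScreenGeometry

__all__ = [
    "HeatmapImage",
    "ReducedHeatmap",
    "HeatmapError",
    "DEFAULT_KERNEL_SD_PX",
    "render_heatmap",
    "filter_correct",
    "reduce_heatmap",
    "reduction_factor",
    "intensity_of",
    "save_png",
    "load_png",
]

logger = logging.getLogger(__name__)

DEFAULT_KERNEL_SD_PX = 50.0
_KERNEL_TRUNCATE_SD = 3.0

REDUCED_W, REDUCED_H = 160, 90

# Rec. 601 luma weights for grayscale conversion
_LUMA = np.array([0.299, 0.587, 0.114])


class HeatmapError(ValueError):
    """Invalid heatmap input (dimensions, empty fixation sequence, ...)."""


@dataclass
class HeatmapImage:
    """Full-size color gaze heatmap (heatmap_h x 1920 x 3, uint8)."""

    pixels: np.ndarray
    participant_id: str = ""
    item_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise HeatmapError(f"expected (h, w, 3) pixels, got {px.shape}")
        self.pixels = px.astype(np.uint8)


@dataclass
class ReducedHeatmap:
    """160x90 grayscale reduction of a :class:`HeatmapImage`."""

    pixels: np.ndarray
    participant_id: str = ""
    item_id: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.shape != (REDUCED_H, REDUCED_W):
            raise HeatmapError(
                f"expected ({REDUCED_H}, {REDUCED_W}) pixels, got {px.shape}")
        self.pixels = px.astype(np.uint8)


def render_intensity(fixations: np.ndarray, geometry: ScreenGeometry,
                     kernel_sd_px: float = DEFAULT_KERNEL_SD_PX) -> np.ndarray:
    """Accumulate duration-weighted Gaussians on the heatmap band.

    Returns the raw float intensity field (heatmap_h x screen_w), in
    milliseconds of duration mass per kernel; normalization happens in
    :func:`render_heatmap`.
    """
    fixations = np.asarray(fixations, dtype=float).reshape(-1, 3)
    if len(fixations) == 0:
        raise HeatmapError("cannot render an empty fixation sequence")
    if kernel_sd_px <= 0:
        raise HeatmapError("kernel_sd_px must be positive")
    h, w = geometry.heatmap_h_px, geometry.screen_w_px
    band_top = geometry.band_top_px
    field = np.zeros((h, w), dtype=np.float64)
    r = int(np.ceil(_KERNEL_TRUNCATE_SD * kernel_sd_px))
    offsets = np.arange(-r, r + 1, dtype=float)
    for x, y, dur in fixations:
        cx, cy = x, y - band_top  # band coordinates
        ix, iy = int(round(cx)), int(round(cy))
        x0, x1 = max(ix - r, 0), min(ix + r + 1, w)
        y0, y1 = max(iy - r, 0), min(iy + r + 1, h)
        if x0 >= x1 or y0 >= y1:
            continue  # fixation (plus kernel) entirely outside the band
        gx = np.exp(-((x0 + np.arange(x1 - x0) - cx) ** 2)
                    / (2.0 * kernel_sd_px ** 2))
        gy = np.exp(-((y0 + np.arange(y1 - y0) - cy) ** 2)
                    / (2.0 * kernel_sd_px ** 2))
        field[y0:y1, x0:x1] += dur * gy[:, None] * gx[None, :]
    return field


def colorize(intensity: np.ndarray) -> np.ndarray:
    """Map normalized intensity in [0, 1] onto the red-green color table.

    R = 255 t, G = 255 (1 - t), B = 0: low intensity is green, high is
    red, and each channel is affine in t.
    """
    t = np.clip(intensity, 0.0, 1.0)
    rgb = np.zeros(t.shape + (3,), dtype=np.uint8)
    rgb[..., 0] = np.rint(255.0 * t)
    rgb[..., 1] = np.rint(255.0 * (1.0 - t))
    return rgb


def intensity_of(pixels: np.ndarray) -> np.ndarray:
    """Recover the normalized intensity field from heatmap pixels.

    The red channel equals 255 t by construction (and is untouched by
    prototype recoloring), so it serves as the intensity readout.
    """
    return np.asarray(pixels)[..., 0].astype(np.float64) / 255.0


def render_heatmap(fixations: np.ndarray, geometry: ScreenGeometry,
                   kernel_sd_px: float = DEFAULT_KERNEL_SD_PX,
                   participant_id: str = "", item_id: str = "") -> HeatmapImage:
    """Render one trial's fixations into a full-size color heatmap.

    Intensity is normalized relative to the complete trial so that the
    hottest cell maps to full scale; scaling all durations by a common
    factor leaves the image unchanged.
    """
    field = render_intensity(fixations, geometry, kernel_sd_px)
    peak = field.max()
    if peak > 0:
        field = field / peak
    return HeatmapImage(pixels=colorize(field),
                        participant_id=participant_id, item_id=item_id)


def filter_correct(trials: Sequence[TrialRecord]) -> list[TrialRecord]:
    """Keep only correctly solved trials (guessing produces random gaze)."""
    kept = [t for t in trials if t.response_correct]
    logger.info("correctness filter: kept %d of %d trials (%d removed)",
                len(kept), len(trials), len(trials) - len(kept))
    return kept


def _bin_weights(n_in: int, n_out: int) -> np.ndarray:
    """(n_out, n_in) area-weighted averaging matrix for 1-D subsampling.

    Output bin j covers the input interval [j*n_in/n_out, (j+1)*n_in/n_out);
    each input cell contributes in proportion to its overlap.  Rows sum
    to 1, so constants are preserved exactly.
    """
    step = n_in / n_out
    w = np.zeros((n_out, n_in))
    for j in range(n_out):
        lo, hi = j * step, (j + 1) * step
        i0, i1 = int(np.floor(lo)), int(np.ceil(hi))
        for i in range(i0, min(i1, n_in)):
            overlap = min(hi, i + 1) - max(lo, i)
            if overlap > 0:
                w[j, i] = overlap / step
    return w


_WY = _bin_weights(760, REDUCED_H)
_WX = _bin_weights(1920, REDUCED_W).T


def reduce_heatmap(h: HeatmapImage) -> ReducedHeatmap:
    """Grayscale + block-average subsample a full-size heatmap to 160x90.

    1920/160 = 12 columns per cell exactly; 760/90 rows per cell is
    fractional and handled by area-weighted bins.  The scalar count drops
    from 1,920 x 760 x 3 to 160 x 90 (factor 304).
    """
    px = h.pixels
    if px.shape != (760, 1920, 3):
        raise HeatmapError(f"expected (760, 1920, 3) pixels, got {px.shape}")
    gray = px.astype(np.float64) @ _LUMA
    small = _WY @ gray @ _WX
    return ReducedHeatmap(pixels=np.rint(np.clip(small, 0, 255)),
                          participant_id=h.participant_id, item_id=h.item_id)


def reduction_factor(geometry: ScreenGeometry | None = None) -> float:
    """Ratio of scalar values before and after preprocessing."""
    g = geometry or ScreenGeometry()
    return (g.screen_w_px * g.heatmap_h_px * 3) / (REDUCED_W * REDUCED_H)


def save_png(image: HeatmapImage | ReducedHeatmap, path: str | Path,
             sidecar: bool = True) -> None:
    """Write a heatmap as PNG plus a small provenance JSON next to it."""
    from PIL import Image

    path = Path(path)
    mode = "RGB" if image.pixels.ndim == 3 else "L"
    Image.fromarray(image.pixels, mode=mode).save(path)
    if sidecar:
        path.with_suffix(".json").write_text(json.dumps(
            {"participant_id": image.participant_id,
             "item_id": image.item_id}, sort_keys=True))


def load_png(path: str | Path) -> HeatmapImage | ReducedHeatmap:
    from PIL import Image

    path = Path(path)
    arr = np.asarray(Image.open(path))
    meta = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    cls = HeatmapImage if arr.ndim == 3 else ReducedHeatmap
    return cls(pixels=arr, participant_id=meta.get("participant_id", ""),
               item_id=meta.get("item_id", ""))
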