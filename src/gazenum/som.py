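"""Self-organizing-map clustering of reduced gaze heatmaps.

One SOM is trained per item, pooling both participant groups.  The map
is a 3x2 grid of six prototype images; dissimilarity between heatmaps is
the Euclidean distance

    d(H1, H2) = sqrt( sum_ij [H1(i,j) - H2(i,j)]^2 )

on the 160x90 grayscale grids.  Training is the classic online Kohonen
rule: a randomly chosen heatmap pulls its best-matching prototype toward
it, and grid neighbors follow to a lesser (Gaussian-weighted) degree,
with learning rate and neighborhood radius decaying over a fixed
schedule.  Six clusters give each of the three expected enumeration
processes room to occupy a node plus spare nodes for outliers or process
subgroups.

Results depend on the random initialization and presentation order, so
both are derived from an explicit seed and runs are fully reproducible.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .heatmap import HeatmapImage, ReducedHeatmap, HeatmapError

__all__ = [
    "SomSchedule",
    "SomModel",
    "ClusterAssignment",
    "ClusterPrototype",
    "SomError",
    "heatmap_distance",
    "train_som",
    "assign",
    "quantization_error",
    "compute_prototypes",
    "recolor",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

GRID_ROWS, GRID_COLS = 3, 2
N_CLUSTERS = GRID_ROWS * GRID_COLS


class SomError(ValueError):
    pass


def _as_matrix(h: ReducedHeatmap | np.ndarray) -> np.ndarray:
    px = h.pixels if isinstance(h, ReducedHeatmap) else np.asarray(h)
    return px.astype(np.float64)


def heatmap_distance(h1: ReducedHeatmap | np.ndarray,
                     h2: ReducedHeatmap | np.ndarray) -> float:
    """Euclidean distance between two equally sized grayscale grids."""
    a, b = _as_matrix(h1), _as_matrix(h2)
    if a.shape != b.shape:
        raise SomError(f"dimension mismatch: {a.shape} vs {b.shape}")
    return float(np.sqrt(((a - b) ** 2).sum()))


@dataclass(frozen=True)
class SomPhase:
    """One training phase with linearly decaying rate and radius."""

    epochs: int
    lr_start: float
    lr_end: float
    radius_start: float
    radius_end: float

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise SomError("phase must run at least one epoch")
        if self.radius_end > self.radius_start:
            raise SomError("neighborhood radius must not grow")


@dataclass(frozen=True)
class SomSchedule:
    """Two-phase schedule: a coarse ordering phase followed by fine tuning.

    Defaults mirror conventional Kohonen-toolbox settings: ordering with
    radius 2 -> 1 at rate 0.5 -> 0.05 for 100 epochs, then tuning with
    radius 1 -> 0 at rate 0.05 -> 0.01 for 200 epochs.
    """

    phases: tuple[SomPhase, ...] = (
        SomPhase(epochs=100, lr_start=0.5, lr_end=0.05,
                 radius_start=2.0, radius_end=1.0),
        SomPhase(epochs=200, lr_start=0.05, lr_end=0.01,
                 radius_start=1.0, radius_end=0.0),
    )

    @property
    def total_epochs(self) -> int:
        return sum(p.epochs for p in self.phases)


def _grid_coords() -> np.ndarray:
    """Integer (row, col) coordinates of the 6 nodes, row-major."""
    rows, cols = np.meshgrid(np.arange(GRID_ROWS), np.arange(GRID_COLS),
                             indexing="ij")
    return np.stack([rows.ravel(), cols.ravel()], axis=1).astype(float)


@dataclass
class SomModel:
    """Trained 3x2 map: six prototype vectors over the reduced-image grid."""

    prototypes: np.ndarray          # (6, h*w) float
    input_shape: tuple[int, int]    # (h, w) of the reduced heatmaps
    schedule: SomSchedule
    seed: int

    grid: np.ndarray = field(default_factory=_grid_coords)

    def prototype_image(self, k: int) -> np.ndarray:
        return self.prototypes[k].reshape(self.input_shape)


@dataclass
class ClusterAssignment:
    """Per-item mapping of trials to clusters, with group tallies."""

    cluster_of: np.ndarray            # (n,) int in 0..5
    group_labels: list[str]           # per trial
    trial_index: list[int]            # caller-side identifiers, len n

    @property
    def counts(self) -> np.ndarray:
        return np.bincount(self.cluster_of, minlength=N_CLUSTERS)

    def members(self, k: int) -> np.ndarray:
        return np.flatnonzero(self.cluster_of == k)

    def group_counts(self) -> dict[str, np.ndarray]:
        """Cluster-membership counts per group label."""
        out: dict[str, np.ndarray] = {}
        labels = np.asarray(self.group_labels)
        for g in dict.fromkeys(self.group_labels):
            out[g] = np.bincount(self.cluster_of[labels == g],
                                 minlength=N_CLUSTERS)
        return out


@dataclass
class ClusterPrototype:
    """Full-size average heatmap of a (non-empty) cluster."""

    cluster_index: int
    pixels: np.ndarray   # (760, 1920, 3) float, mean of member heatmaps
    member_count: int


def _stack(inputs: Sequence[ReducedHeatmap | np.ndarray]) -> tuple[np.ndarray,
                                                                   tuple[int, int]]:
    if len(inputs) == 0:
        raise SomError("at least one input heatmap is required")
    mats = [_as_matrix(h) for h in inputs]
    shape = mats[0].shape
    for m in mats[1:]:
        if m.shape != shape:
            raise SomError("all inputs must share one shape")
    return np.stack([m.ravel() for m in mats]), shape


def train_som(inputs: Sequence[ReducedHeatmap | np.ndarray],
              schedule: SomSchedule | None = None,
              seed: int = 0) -> SomModel:
    """Online Kohonen training of the 3x2 map on one item's heatmaps.

    Prototypes start as small seeded perturbations around the input mean.
    Each presentation moves the best-matching prototype and, scaled by a
    Gaussian of grid distance, its neighbors toward the input.  The
    schedule is the stopping rule (a fixed proxy for prototype movement
    having ceased).
    """
    schedule = schedule or SomSchedule()
    X, shape = _stack(inputs)
    n, dim = X.shape
    rng = np.random.default_rng(seed)
    spread = X.std() if X.std() > 0 else 1.0
    W = X.mean(axis=0)[None, :] + rng.normal(
        0.0, 0.05 * spread, size=(N_CLUSTERS, dim))
    grid = _grid_coords()
    grid_d2 = ((grid[:, None, :] - grid[None, :, :]) ** 2).sum(axis=-1)

    total_epochs = schedule.total_epochs
    epoch_base = 0
    for phase in schedule.phases:
        for e in range(phase.epochs):
            frac = e / max(phase.epochs - 1, 1)
            lr = phase.lr_start + frac * (phase.lr_end - phase.lr_start)
            rad = (phase.radius_start
                   + frac * (phase.radius_end - phase.radius_start))
            for i in rng.permutation(n):
                x = X[i]
                d2 = ((W - x) ** 2).sum(axis=1)
                bmu = int(np.argmin(d2))
                if rad < 1e-9:
                    W[bmu] += lr * (x - W[bmu])
                else:
                    hfun = np.exp(-grid_d2[bmu] / (2.0 * rad * rad))
                    active = hfun > 1e-3
                    W[active] += (lr * hfun[active, None]) * (x - W[active])
        epoch_base += phase.epochs
    assert epoch_base == total_epochs
    return SomModel(prototypes=W, input_shape=shape, schedule=schedule,
                    seed=seed)


def assign(model: SomModel,
           inputs: Sequence[ReducedHeatmap | np.ndarray],
           group_labels: Sequence[str] | None = None,
           trial_index: Sequence[int] | None = None) -> ClusterAssignment:
    """Map each heatmap to its nearest prototype (ties: lowest index)."""
    X, shape = _stack(inputs)
    if shape != model.input_shape:
        raise SomError("input shape does not match the trained model")
    d2 = ((X[:, None, :] - model.prototypes[None, :, :]) ** 2).sum(axis=-1)
    cluster = d2.argmin(axis=1)
    n = len(inputs)
    return ClusterAssignment(
        cluster_of=cluster.astype(int),
        group_labels=(list(group_labels) if group_labels is not None
                      else [""] * n),
        trial_index=(list(trial_index) if trial_index is not None
                     else list(range(n))))


def quantization_error(model_or_prototypes: SomModel | np.ndarray,
                       inputs: Sequence[ReducedHeatmap | np.ndarray]) -> float:
    """Mean distance of inputs to their best-matching prototype."""
    W = (model_or_prototypes.prototypes
         if isinstance(model_or_prototypes, SomModel)
         else np.asarray(model_or_prototypes, dtype=float))
    X, _ = _stack(inputs)
    d2 = ((X[:, None, :] - W[None, :, :]) ** 2).sum(axis=-1)
    return float(np.sqrt(d2.min(axis=1)).mean())


def compute_prototypes(assignment: ClusterAssignment,
                       fullsize: Sequence[HeatmapImage]) -> list[ClusterPrototype]:
    """Pixel-wise mean of the full-size member heatmaps per non-empty cluster.

    The clustering runs on reduced images for speed only; prototypes for
    interpretation are averaged from the originals.
    """
    if len(fullsize) != len(assignment.cluster_of):
        raise SomError("need one full-size heatmap per assigned trial")
    protos: list[ClusterPrototype] = []
    for k in range(N_CLUSTERS):
        members = assignment.members(k)
        if len(members) == 0:
            continue
        acc = np.zeros(fullsize[members[0]].pixels.shape, dtype=np.float64)
        for i in members:
            acc += fullsize[i].pixels.astype(np.float64)
        protos.append(ClusterPrototype(cluster_index=k,
                                       pixels=acc / len(members),
                                       member_count=len(members)))
    return protos


def recolor(p: ClusterPrototype) -> ClusterPrototype:
    """Shift a prototype from the red-green to a red-blue color table.

    Copies the green channel into the blue channel and zeroes the green
    channel; red is untouched.  Makes averaged prototypes visually
    distinct from single-trial heatmaps.
    """
    px = p.pixels.copy()
    px[..., 2] = px[..., 1]
    px[..., 1] = 0
    return ClusterPrototype(cluster_index=p.cluster_index, pixels=px,
                            member_count=p.member_count)


def save_model(model: SomModel, directory: str | Path) -> None:
    """Persist prototypes as grayscale PNGs plus schedule/seed JSON."""
    from PIL import Image

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for k in range(N_CLUSTERS):
        img = np.rint(np.clip(model.prototype_image(k), 0, 255)).astype(np.uint8)
        Image.fromarray(img, mode="L").save(directory / f"prototype_{k}.png")
    np.save(directory / "prototypes.npy", model.prototypes)
    meta = {
        "input_shape": list(model.input_shape),
        "seed": model.seed,
        "schedule": [asdict(p) for p in model.schedule.phases],
    }
    (directory / "model.json").write_text(json.dumps(meta, indent=2,
                                                     sort_keys=True))


def load_model(directory: str | Path) -> SomModel:
    directory = Path(directory)
    meta = json.loads((directory / "model.json").read_text())
    schedule = SomSchedule(phases=tuple(SomPhase(**p)
                                        for p in meta["schedule"]))
    return SomModel(prototypes=np.load(directory / "prototypes.npy"),
                    input_shape=tuple(meta["input_shape"]),
                    schedule=schedule, seed=meta["seed"])
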