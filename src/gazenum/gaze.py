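"""Synthetic fixation sequences with known latent enumeration processes.

The generator emulates the latent structure the downstream analysis
assumes: each trial is produced by one of three enumeration processes,

1. SIMULTANEOUS - the whole set is taken in at a glance; gaze rests in the
   middle of the pattern (quasi-simultaneous for 5-9 dots in random
   arrangements),
2. GROUPS - the set is enumerated via subgroups; gaze rests on the
   subgroup centroids, between dots rather than on them,
3. COUNTING - dots are fixated serially, at least half of them.

Group membership shifts the mixture over these processes per condition,
and an incorrect-response process removes a fraction of trials downstream.
Fixation positions carry isotropic Gaussian noise whose default scale
(38 px, about 0.9 degrees of visual angle at 60 cm) mirrors the accuracy
of a screen-mounted eye tracker.  Gaze originates at the inter-trial
fixation star in the screen center; the star period itself is not part
of the trial recording, so sequences contain task fixations only.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .stimuli import Condition, DotStimulus, condition_of

__all__ = [
    "ProcessKind",
    "GroupProfile",
    "TrialRecord",
    "GazeError",
    "ParseError",
    "default_profiles",
    "process_label",
    "simulate_trial",
    "simulate_cohort",
    "simulate_type_counts",
    "write_trials",
    "read_trials",
]

logger = logging.getLogger(__name__)

SAMPLING_RATE_HZ = 120  # tracker constant; informational only

# Fixation-duration ranges (ms); uniform draws.  Durations are irrelevant
# to clustering after per-trial normalization but keep heatmaps realistic.
_DUR_SIMULTANEOUS_TOTAL = (300.0, 600.0)
_DUR_GROUPS_PER_SUBGROUP = (200.0, 350.0)
_DUR_COUNTING_PER_DOT = (180.0, 300.0)

DEFAULT_NOISE_SD_PX = 38.0

# GROUPS partition acceptance: fewer than half of the dots may lie within
# this many pixels of a subgroup centroid, so that group-wise gaze stays
# off individual dots.
_GROUP_DOT_CLEARANCE_PX = 115.0
_GROUP_PARTITION_ATTEMPTS = 60


from enum import IntEnum


class ProcessKind(IntEnum):
    """The three enumeration processes (integer codes 1-3)."""

    SIMULTANEOUS = 1
    GROUPS = 2
    COUNTING = 3


def process_label(kind: ProcessKind, condition: Condition) -> str:
    """Human-readable process name; 5-9 dots in random arrangements cannot
    be subitized proper, so type 1 is reported as quasi-simultaneous there."""
    if kind is ProcessKind.SIMULTANEOUS:
        return ("quasi-simultaneous"
                if condition is Condition.COUNTING_RANDOM else "simultaneous")
    if kind is ProcessKind.GROUPS:
        return "groups/structures"
    return "counting"


class GazeError(ValueError):
    """Invalid simulation parameters."""


class ParseError(ValueError):
    """Malformed trial/fixation CSV."""


@dataclass(frozen=True)
class GroupProfile:
    """Per-group latent mixture over processes and error rate per condition."""

    group_label: str
    mixture: Mapping[Condition, tuple[float, float, float]]
    error_rate: Mapping[Condition, float]

    def validate(self) -> None:
        for cond, probs in self.mixture.items():
            p = np.asarray(probs, dtype=float)
            if p.shape != (3,) or (p < 0).any() or (p > 1).any():
                raise GazeError(f"{self.group_label}/{cond.value}: "
                                "mixture must be three probabilities in [0,1]")
            if abs(p.sum() - 1.0) > 1e-9:
                raise GazeError(f"{self.group_label}/{cond.value}: "
                                f"mixture sums to {p.sum()!r}, not 1")
        for cond, e in self.error_rate.items():
            if not 0.0 <= e <= 1.0:
                raise GazeError(f"{self.group_label}/{cond.value}: "
                                f"error rate {e} outside [0,1]")


def default_profiles() -> tuple[GroupProfile, GroupProfile]:
    """Default two-group cohort profiles.

    Group "dhh" leans toward (quasi-)simultaneous enumeration in the
    subitizing, counting and dice conditions; group "hearing" uses
    groups/counting somewhat more.  Beyond the dice range the two groups
    behave identically.  The flat 9% error rate reproduces the scale of
    trial loss to incorrect responses in the study design this generator
    emulates.  Proportions are package choices, not measured values.
    """
    mix_dhh = {
        Condition.SUBITIZING_RANDOM: (0.60, 0.25, 0.15),
        Condition.COUNTING_RANDOM: (0.35, 0.30, 0.35),
        Condition.DICE_CANONICAL: (0.65, 0.20, 0.15),
        Condition.BEYOND_DICE_CANONICAL: (0.30, 0.40, 0.30),
        Condition.EXCLUDED_ONE: (1.0, 0.0, 0.0),
    }
    mix_hearing = {
        Condition.SUBITIZING_RANDOM: (0.50, 0.30, 0.20),
        Condition.COUNTING_RANDOM: (0.25, 0.40, 0.35),
        Condition.DICE_CANONICAL: (0.55, 0.20, 0.25),
        Condition.BEYOND_DICE_CANONICAL: (0.30, 0.40, 0.30),
        Condition.EXCLUDED_ONE: (1.0, 0.0, 0.0),
    }
    err = {c: 0.09 for c in Condition}
    return (GroupProfile("dhh", mix_dhh, err),
            GroupProfile("hearing", mix_hearing, err))


@dataclass
class TrialRecord:
    """One enumeration attempt by one participant on one item.

    ``fixations`` is an (k, 3) float array with columns x_px, y_px,
    duration_ms.  ``latent_process`` is known for synthetic data only.
    """

    participant_id: str
    group_label: str
    item_id: str
    fixations: np.ndarray
    response_correct: bool
    latent_process: ProcessKind | None = None

    def __post_init__(self) -> None:
        self.fixations = np.asarray(self.fixations, dtype=float).reshape(-1, 3)


def _clip_to_screen(xy: np.ndarray, stimulus: DotStimulus) -> np.ndarray:
    g = stimulus.geometry
    return np.clip(xy, [0.0, 0.0],
                   [g.screen_w_px - 1.0, g.screen_h_px - 1.0])


def _scan_order(centers: np.ndarray, band_px: float) -> np.ndarray:
    """Left-to-right within top-to-bottom rows of height ``band_px``."""
    rows = np.floor(centers[:, 1] / band_px)
    return np.lexsort((centers[:, 0], rows))


def _partition_groups(stimulus: DotStimulus,
                      rng: np.random.Generator) -> list[np.ndarray] | None:
    """Split dots into 2-3 spatially contiguous parts whose centroids keep
    clear of individual dots.

    Candidate partitions cut the set along a random direction.  A candidate
    is accepted when fewer than half of the dots lie within
    ``_GROUP_DOT_CLEARANCE_PX`` of any part centroid; after a bounded number
    of attempts the candidate with the fewest such dots is returned.
    """
    pts = stimulus.dot_centers
    n = stimulus.numerosity
    best: list[np.ndarray] | None = None
    best_near = n + 1
    for _ in range(_GROUP_PARTITION_ATTEMPTS):
        k = int(rng.integers(2, 4)) if n >= 6 else 2
        theta = rng.uniform(0.0, math.pi)
        proj = pts @ np.array([math.cos(theta), math.sin(theta)])
        order = np.argsort(proj)
        # contiguous chunks, sizes as balanced as possible
        sizes = [n // k + (1 if i < n % k else 0) for i in range(k)]
        parts, start = [], 0
        for s in sizes:
            parts.append(order[start:start + s])
            start += s
        cents = np.array([pts[p].mean(axis=0) for p in parts])
        dist = np.linalg.norm(pts[:, None, :] - cents[None, :, :], axis=-1)
        near = int((dist.min(axis=1) < _GROUP_DOT_CLEARANCE_PX).sum())
        if near < best_near:
            best, best_near = parts, near
        if near < math.ceil(n / 2):
            return parts
    logger.info("GROUPS partition for %s accepted with %d/%d dots near a "
                "subgroup centroid", stimulus.item_id, best_near, n)
    return best


def simulate_trial(stimulus: DotStimulus, process: ProcessKind,
                   noise_sd_px: float = DEFAULT_NOISE_SD_PX,
                   rng_seed: int | np.random.Generator = 0,
                   participant_id: str = "p0", group_label: str = "g0",
                   response_correct: bool = True) -> TrialRecord:
    """Simulate one trial's fixation sequence under a given process.

    GROUPS requested for fewer than 3 dots falls back to SIMULTANEOUS (no
    meaningful subgroup exists); the returned record carries the process
    that was actually executed.
    """
    if noise_sd_px < 0:
        raise GazeError("noise_sd_px must be non-negative")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    g = stimulus.geometry
    n = stimulus.numerosity

    if process is ProcessKind.GROUPS and n < 3:
        logger.info("GROUPS requested for %d dots; falling back to "
                    "SIMULTANEOUS", n)
        process = ProcessKind.SIMULTANEOUS

    def noisy(points: np.ndarray) -> np.ndarray:
        return points + rng.normal(0.0, noise_sd_px, size=points.shape)

    fixs: list[tuple[float, float, float]] = []
    if process is ProcessKind.SIMULTANEOUS:
        k = int(rng.integers(1, 3))
        total = rng.uniform(*_DUR_SIMULTANEOUS_TOTAL)
        for xy in noisy(np.tile(stimulus.centroid, (k, 1))):
            fixs.append((xy[0], xy[1], total / k))
    elif process is ProcessKind.GROUPS:
        parts = _partition_groups(stimulus, rng)
        assert parts is not None
        cents = np.array([stimulus.dot_centers[p].mean(axis=0) for p in parts])
        order = _scan_order(cents, band_px=g.dot_diameter_px * 2.0)
        for xy in noisy(cents[order]):
            fixs.append((xy[0], xy[1], rng.uniform(*_DUR_GROUPS_PER_SUBGROUP)))
    else:  # COUNTING
        m = int(rng.integers(math.ceil(n / 2), n + 1))
        order = _scan_order(stimulus.dot_centers,
                            band_px=g.dot_diameter_px * 2.0)
        targets = stimulus.dot_centers[order][:m]
        for xy in noisy(targets):
            fixs.append((xy[0], xy[1], rng.uniform(*_DUR_COUNTING_PER_DOT)))

    arr = np.array(fixs, dtype=float)
    arr[:, :2] = _clip_to_screen(arr[:, :2], stimulus)
    return TrialRecord(participant_id=participant_id, group_label=group_label,
                       item_id=stimulus.item_id, fixations=arr,
                       response_correct=response_correct,
                       latent_process=process)


def simulate_cohort(profiles: Sequence[GroupProfile],
                    n_per_group: Sequence[int],
                    battery: Sequence[DotStimulus],
                    rng_seed: int,
                    noise_sd_px: float = DEFAULT_NOISE_SD_PX) -> list[TrialRecord]:
    """Simulate a full two-group cohort; every participant attempts all items.

    Per trial, the latent process is drawn from the participant-group's
    condition mixture and response correctness from the condition error
    rate.  Deterministic under a fixed seed.
    """
    if len(profiles) != 2 or len(n_per_group) != 2:
        raise GazeError("exactly two group profiles and two group sizes required")
    for p in profiles:
        p.validate()
    rng = np.random.default_rng(rng_seed)
    conditions = {s.item_id: condition_of(s) for s in battery}
    trials: list[TrialRecord] = []
    pid = 0
    for profile, n_group in zip(profiles, n_per_group):
        for _ in range(int(n_group)):
            participant = f"{profile.group_label}_{pid:04d}"
            pid += 1
            for stim in battery:
                cond = conditions[stim.item_id]
                probs = np.asarray(profile.mixture[cond], dtype=float)
                kind = ProcessKind(int(rng.choice([1, 2, 3], p=probs)))
                correct = bool(rng.random() >= profile.error_rate[cond])
                trials.append(simulate_trial(
                    stim, kind, noise_sd_px=noise_sd_px, rng_seed=rng,
                    participant_id=participant,
                    group_label=profile.group_label,
                    response_correct=correct))
    return trials


# per-participant item counts by condition in the 36-item battery
ITEMS_PER_CONDITION: dict[Condition, int] = {
    Condition.SUBITIZING_RANDOM: 9,
    Condition.COUNTING_RANDOM: 15,
    Condition.DICE_CANONICAL: 5,
    Condition.BEYOND_DICE_CANONICAL: 3,
    Condition.EXCLUDED_ONE: 4,
}


def simulate_type_counts(profiles: Sequence[GroupProfile],
                         n_per_group: Sequence[int],
                         rng_seed: int) -> dict[Condition, np.ndarray]:
    """Counts-level cohort simulation (no fixations, no rendering).

    Draws, for each analysis condition, the 3 (process) x 2 (group) table
    of correct trials directly: trial loss is binomial with the condition
    error rate and latent processes are multinomial with the group's
    mixture.  Statistically identical to tallying a full simulated cohort
    with oracle process labels; used for test-calibration experiments.
    """
    if len(profiles) != 2 or len(n_per_group) != 2:
        raise GazeError("exactly two group profiles and two group sizes required")
    for p in profiles:
        p.validate()
    rng = np.random.default_rng(rng_seed)
    out: dict[Condition, np.ndarray] = {}
    for cond, n_items in ITEMS_PER_CONDITION.items():
        if cond is Condition.EXCLUDED_ONE:
            continue
        table = np.zeros((3, 2), dtype=int)
        for col, (profile, n_group) in enumerate(zip(profiles, n_per_group)):
            n_trials = int(n_group) * n_items
            n_correct = int(rng.binomial(n_trials,
                                         1.0 - profile.error_rate[cond]))
            table[:, col] = rng.multinomial(
                n_correct, np.asarray(profile.mixture[cond], dtype=float))
        out[cond] = table
    return out


# ---------------------------------------------------------------------------
# CSV round trip: trials.csv + fixations.csv inside a directory

_TRIAL_COLS = ["participant_id", "group", "item_id", "response_correct",
               "latent_process"]
_FIX_COLS = ["participant_id", "item_id", "fix_index", "x_px", "y_px",
             "duration_ms"]


def write_trials(trials: Sequence[TrialRecord], path: str | Path) -> None:
    """Write a cohort as trials.csv + fixations.csv under ``path``."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    trows, frows = [], []
    for t in trials:
        trows.append({
            "participant_id": t.participant_id, "group": t.group_label,
            "item_id": t.item_id,
            "response_correct": int(t.response_correct),
            "latent_process": ("" if t.latent_process is None
                               else int(t.latent_process)),
        })
        for i, (x, y, d) in enumerate(t.fixations):
            frows.append({"participant_id": t.participant_id,
                          "item_id": t.item_id, "fix_index": i,
                          "x_px": x, "y_px": y, "duration_ms": d})
    pd.DataFrame(trows, columns=_TRIAL_COLS).to_csv(
        path / "trials.csv", index=False)
    pd.DataFrame(frows, columns=_FIX_COLS).to_csv(
        path / "fixations.csv", index=False, float_format="%.17g")


def _require_columns(df: pd.DataFrame, cols: Sequence[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ParseError(f"{name}: missing column(s) {', '.join(missing)}")


def read_trials(path: str | Path) -> list[TrialRecord]:
    """Read a cohort written by :func:`write_trials` (or user-supplied CSVs)."""
    path = Path(path)
    tdf = pd.read_csv(path / "trials.csv")
    fdf = pd.read_csv(path / "fixations.csv", float_precision="round_trip")
    _require_columns(tdf, [c for c in _TRIAL_COLS if c != "latent_process"],
                     "trials.csv")
    _require_columns(fdf, _FIX_COLS, "fixations.csv")
    if len(fdf):
        fdf = fdf.sort_values(["participant_id", "item_id", "fix_index"])
        grouped = {k: v for k, v in fdf.groupby(["participant_id", "item_id"],
                                                sort=False)}
    else:
        grouped = {}
    trials = []
    for idx, row in tdf.iterrows():
        key = (row["participant_id"], row["item_id"])
        if key not in grouped:
            raise ParseError(f"trials.csv row {idx}: no fixations for "
                             f"participant {key[0]} item {key[1]}")
        fx = grouped[key][["x_px", "y_px", "duration_ms"]].to_numpy(float)
        latent = row.get("latent_process")
        has_latent = ("latent_process" in tdf.columns
                      and pd.notna(latent) and str(latent) != "")
        trials.append(TrialRecord(
            participant_id=str(row["participant_id"]),
            group_label=str(row["group"]),
            item_id=str(row["item_id"]),
            fixations=fx,
            response_correct=bool(int(row["response_correct"])),
            latent_process=(ProcessKind(int(latent)) if has_latent else None)))
    return trials
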