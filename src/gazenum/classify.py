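"""Rule-based typing of heatmaps/cluster prototypes into enumeration processes.

The verbal criteria behind the three process types are made operational
through three features of the gaze-intensity field relative to the
stimulus:

* ``covered_dot_fraction`` - share of dots whose neighborhood holds
  near-peak intensity ("gazes on at least half of the points" marks
  counting),
* ``central_mass_fraction`` - share of total intensity near the pattern
  centroid ("gazes predominantly in the middle" marks simultaneous
  enumeration),
* ``side_asymmetry`` - normalized left/right (and top/bottom) imbalance
  ("gazes on parts of the dots, for example, to one side" marks the use
  of groups/structures).

The decision rule is: counting if at least half the dots are covered;
otherwise simultaneous if the central mass is high; otherwise groups.
In the study workflow the rule is applied to cluster prototypes and every
member trial inherits its cluster's type; a per-trial mode exists for
validation, and a manual-override table replaces the human-rater step.

Thresholds are explicit and configurable; the defaults are calibrated
against the synthetic generator so that latent processes are recovered
from noisy synthetic data.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .gaze import ProcessKind, TrialRecord
from .heatmap import HeatmapImage, intensity_of
from .som import ClusterAssignment, ClusterPrototype, N_CLUSTERS
from .stimuli import Condition, DotStimulus

__all__ = [
    "GazeFeatures",
    "TypingRule",
    "TypingError",
    "extract_features",
    "classify_type",
    "type_counts",
    "apply_overrides",
    "write_typing_csv",
]

logger = logging.getLogger(__name__)


class TypingError(ValueError):
    pass


@dataclass(frozen=True)
class GazeFeatures:
    """Scalar features of one intensity field w.r.t. one stimulus; all in [0,1]."""

    central_mass_fraction: float
    covered_dot_fraction: float
    side_asymmetry: float
    top_bottom_asymmetry: float


@dataclass(frozen=True)
class TypingRule:
    """Thresholds of the process-typing rule.

    ``r_c_factor``/``r_d_factor`` scale the dot diameter into the central
    radius and the per-dot coverage radius.  ``tau`` is the intensity
    threshold for dot coverage, relative to the field maximum.
    ``theta_asym`` is not used by the default precedence but is exposed
    for custom rules and manual review.
    """

    theta_count: float = 0.5     # covered fraction at/above which -> counting
    theta_central: float = 0.5   # central mass at/above which -> simultaneous
    theta_asym: float = 0.5
    tau: float = 0.45            # relative intensity for "dot covered"
    r_c_factor: float = 1.5      # central radius, in dot diameters
    r_d_factor: float = 0.5      # coverage radius, in dot diameters

    def __post_init__(self) -> None:
        for name in ("theta_count", "theta_central", "theta_asym", "tau"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise TypingError(f"{name} must be in [0,1], got {v}")


def _intensity_field(h: HeatmapImage | ClusterPrototype | np.ndarray) -> np.ndarray:
    if isinstance(h, (HeatmapImage, ClusterPrototype)):
        return intensity_of(h.pixels)
    return np.asarray(h, dtype=float)


def extract_features(h: HeatmapImage | ClusterPrototype | np.ndarray,
                     stimulus: DotStimulus,
                     rule: TypingRule | None = None) -> GazeFeatures:
    """Compute typing features of a heatmap w.r.t. its stimulus.

    ``h`` may be a full-size heatmap, a cluster prototype (recolored or
    not: the red channel is the intensity readout either way), or a raw
    intensity field of band shape.  Item identities must match when both
    sides carry one.
    """
    if isinstance(h, HeatmapImage) and h.item_id and \
            h.item_id != stimulus.item_id:
        raise TypingError(f"heatmap item {h.item_id!r} does not match "
                          f"stimulus {stimulus.item_id!r}")
    rule = rule or TypingRule()
    field_ = _intensity_field(h)
    g = stimulus.geometry
    band_top = g.band_top_px
    total = field_.sum()
    if total <= 0:
        return GazeFeatures(0.0, 0.0, 0.0, 0.0)

    hgt, wid = field_.shape
    ys = np.arange(hgt, dtype=float)[:, None] + band_top  # screen rows
    xs = np.arange(wid, dtype=float)[None, :]
    cx, cy = stimulus.centroid

    r_c = rule.r_c_factor * g.dot_diameter_px
    central_mask = (xs - cx) ** 2 + (ys - cy) ** 2 <= r_c ** 2
    central = float(field_[central_mask].sum() / total)

    r_d = rule.r_d_factor * g.dot_diameter_px
    peak = field_.max()
    covered = 0
    for dx, dy in stimulus.dot_centers:
        mask = (xs - dx) ** 2 + (ys - dy) ** 2 <= r_d ** 2
        if mask.any() and field_[mask].max() >= rule.tau * peak:
            covered += 1
    covered_frac = covered / stimulus.numerosity

    left = float(field_[:, xs[0] < cx].sum())
    right = float(total - left)
    top = float(field_[(ys[:, 0] < cy), :].sum())
    bottom = float(total - top)
    return GazeFeatures(
        central_mass_fraction=central,
        covered_dot_fraction=covered_frac,
        side_asymmetry=abs(left - right) / total,
        top_bottom_asymmetry=abs(top - bottom) / total,
    )


def classify_type(f: GazeFeatures, condition: Condition,
                  rule: TypingRule | None = None) -> ProcessKind:
    """Apply the typing rule; total and deterministic over valid features."""
    if condition is Condition.EXCLUDED_ONE:
        raise TypingError("1-dot items are excluded from process typing")
    rule = rule or TypingRule()
    if f.covered_dot_fraction >= rule.theta_count:
        return ProcessKind.COUNTING
    if f.central_mass_fraction >= rule.theta_central:
        return ProcessKind.SIMULTANEOUS
    return ProcessKind.GROUPS


def apply_overrides(cluster_types: dict[str, dict[int, ProcessKind]],
                    overrides: pd.DataFrame | str | Path
                    ) -> dict[str, dict[int, ProcessKind]]:
    """Replace automatic cluster types with manual ones.

    ``overrides`` is a table (or CSV path) with columns item_id, cluster,
    manual_type; it takes precedence over the automatic classification,
    standing in for the expert-rater review step.
    """
    if not isinstance(overrides, pd.DataFrame):
        overrides = pd.read_csv(overrides)
    out = {item: dict(types) for item, types in cluster_types.items()}
    for _, row in overrides.iterrows():
        item, k = str(row["item_id"]), int(row["cluster"])
        out.setdefault(item, {})[k] = ProcessKind(int(row["manual_type"]))
    return out


def type_counts(assignments: Mapping[str, ClusterAssignment],
                cluster_types: Mapping[str, Mapping[int, ProcessKind]],
                conditions: Mapping[str, Condition],
                group_order: Sequence[str]) -> dict[Condition, np.ndarray]:
    """Aggregate trials into per-condition 3 (process) x 2 (group) tables.

    Every trial inherits the type of its cluster; clusters of the same
    type pool additively, and items pool within their condition.  A
    non-empty cluster without a type (automatic or manual) is an error.
    """
    tables: dict[Condition, np.ndarray] = {
        c: np.zeros((3, 2), dtype=int) for c in Condition
        if c is not Condition.EXCLUDED_ONE}
    gidx = {g: j for j, g in enumerate(group_order)}
    for item, asg in assignments.items():
        cond = conditions[item]
        if cond is Condition.EXCLUDED_ONE:
            continue
        types = cluster_types.get(item, {})
        for k in range(N_CLUSTERS):
            members = asg.members(k)
            if len(members) == 0:
                continue
            if k not in types:
                raise TypingError(
                    f"item {item}: non-empty cluster {k} has no process type")
            row = int(types[k]) - 1
            for i in members:
                tables[cond][row, gidx[asg.group_labels[i]]] += 1
    return tables


def write_typing_csv(path: str | Path,
                     cluster_types: Mapping[str, Mapping[int, ProcessKind]],
                     features: Mapping[str, Mapping[int, GazeFeatures]],
                     overrides: Mapping[str, Mapping[int, ProcessKind]] | None = None
                     ) -> None:
    """Export per-cluster typing decisions and features as CSV."""
    rows = []
    for item in sorted(cluster_types):
        for k in sorted(cluster_types[item]):
            f = features.get(item, {}).get(k)
            manual = (overrides or {}).get(item, {}).get(k)
            rows.append({
                "item_id": item, "cluster": k,
                "auto_type": int(cluster_types[item][k]),
                "manual_type": "" if manual is None else int(manual),
                "central_mass_fraction": None if f is None else f.central_mass_fraction,
                "covered_dot_fraction": None if f is None else f.covered_dot_fraction,
                "side_asymmetry": None if f is None else f.side_asymmetry,
                "top_bottom_asymmetry": None if f is None else f.top_bottom_asymmetry,
            })
    pd.DataFrame(rows).to_csv(Path(path), index=False)
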