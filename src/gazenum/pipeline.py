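"""End-to-end analysis pipeline and run manifest.

Stage order: simulate (or load) trials -> render heatmaps -> correctness
filter -> reduce -> per-item SOM clustering -> cluster assignment ->
full-size prototypes -> prototype typing (automatic, with manual
override) -> per-condition group statistics.  All randomness is derived
from explicit seeds and a run is bit-for-bit reproducible given the same
configuration.
"""
from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from . import classify, gaze, heatmap, som, stats
from .gaze import GroupProfile, ProcessKind, TrialRecord, default_profiles
from .stimuli import Condition, DotStimulus, ScreenGeometry, condition_of, \
    make_item_battery, battery_to_json

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "PipelineError",
    "ItemAnalysis",
    "run_all",
    "analyze_trials",
    "evaluate_recovery",
    "cohen_kappa",
]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Everything a run needs; mirrors the YAML configuration file."""

    battery_seed: int = 1
    cohort_seed: int = 2
    som_seed: int = 3
    n_per_group: tuple[int, int] = (10, 10)
    noise_sd_px: float = gaze.DEFAULT_NOISE_SD_PX
    kernel_sd_px: float = heatmap.DEFAULT_KERNEL_SD_PX
    som_phases: tuple[tuple[int, float, float, float, float], ...] | None = None
    typing_rule: classify.TypingRule = field(default_factory=classify.TypingRule)
    alpha: float = stats.DEFAULT_ALPHA
    bonferroni_m: int = stats.DEFAULT_BONFERRONI_M
    trials_dir: str | None = None       # read trials instead of simulating
    manual_typing_csv: str | None = None
    save_prototypes: bool = True

    def validate(self) -> None:
        if len(self.n_per_group) != 2:
            raise PipelineError("n_per_group must have two entries")
        for s in (self.battery_seed, self.cohort_seed, self.som_seed):
            if not isinstance(s, (int, np.integer)):
                raise PipelineError("seeds must be integers")
        if not 0 < self.alpha < 1:
            raise PipelineError("alpha must be in (0, 1)")
        for p in (self.trials_dir, self.manual_typing_csv):
            if p is not None and not Path(p).exists():
                raise PipelineError(f"path not found: {p}")

    def som_schedule(self) -> som.SomSchedule:
        if self.som_phases is None:
            return som.SomSchedule()
        return som.SomSchedule(phases=tuple(
            som.SomPhase(epochs=int(e), lr_start=a, lr_end=b,
                         radius_start=r0, radius_end=r1)
            for e, a, b, r0, r1 in self.som_phases))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config key(s): {sorted(unknown)}")
        if "typing_rule" in raw:
            raw["typing_rule"] = classify.TypingRule(**raw["typing_rule"])
        if "n_per_group" in raw:
            raw["n_per_group"] = tuple(raw["n_per_group"])
        if "som_phases" in raw:
            raw["som_phases"] = tuple(tuple(p) for p in raw["som_phases"])
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["typing_rule"] = dataclasses.asdict(self.typing_rule)
        return d


@dataclass
class ItemAnalysis:
    """Clustering products of one item (all groups pooled)."""

    stimulus: DotStimulus
    trial_refs: list[int]                    # indices into the filtered list
    assignment: som.ClusterAssignment
    cluster_types: dict[int, ProcessKind]
    features: dict[int, classify.GazeFeatures]
    quantization_error: float


@dataclass
class RunManifest:
    config: dict
    stage_counts: dict
    warnings: list[str]
    started_at: str
    finished_at: str

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self),
                                         indent=2, sort_keys=True))


def analyze_trials(trials: Sequence[TrialRecord],
                   battery: Sequence[DotStimulus],
                   config: PipelineConfig,
                   keep_prototypes: bool = False
                   ) -> tuple[dict[str, ItemAnalysis],
                              dict[Condition, np.ndarray],
                              list[str],
                              dict[str, list[som.ClusterPrototype]]]:
    """Core analysis on already-filtered trials: render, reduce, cluster,
    prototype, and type every analyzable item; return per-item products
    and the per-condition process-by-group tables.

    Full-size heatmaps are rendered per item and released afterwards to
    bound memory; prototypes are kept only when requested.
    """
    stimuli_by_id = {s.item_id: s for s in battery}
    conditions = {s.item_id: condition_of(s) for s in battery}
    group_order = list(dict.fromkeys(t.group_label for t in trials))
    if len(group_order) > 2:
        raise PipelineError(f"expected at most 2 groups, got {group_order}")

    by_item: dict[str, list[int]] = {}
    for i, t in enumerate(trials):
        if conditions[t.item_id] is Condition.EXCLUDED_ONE:
            continue
        by_item.setdefault(t.item_id, []).append(i)

    schedule = config.som_schedule()
    warnings: list[str] = []
    analyses: dict[str, ItemAnalysis] = {}
    prototypes_out: dict[str, list[som.ClusterPrototype]] = {}
    # per-item SOM seeds derived deterministically from the master SOM seed
    item_ids = sorted(by_item)
    item_seeds = {
        item: int(np.random.SeedSequence(
            entropy=config.som_seed, spawn_key=(j,)).generate_state(1)[0])
        for j, item in enumerate(item_ids)}

    for item in item_ids:
        refs = by_item[item]
        stim = stimuli_by_id[item]
        full = [heatmap.render_heatmap(trials[i].fixations, stim.geometry,
                                       config.kernel_sd_px,
                                       participant_id=trials[i].participant_id,
                                       item_id=item)
                for i in refs]
        reduced = [heatmap.reduce_heatmap(h) for h in full]
        model = som.train_som(reduced, schedule, seed=item_seeds[item])
        asg = som.assign(model, reduced,
                         group_labels=[trials[i].group_label for i in refs],
                         trial_index=refs)
        qe = som.quantization_error(model, reduced)
        protos = som.compute_prototypes(asg, full)
        if len(protos) < som.N_CLUSTERS:
            warnings.append(f"{item}: {som.N_CLUSTERS - len(protos)} empty "
                            "cluster(s)")
        ctypes: dict[int, ProcessKind] = {}
        feats: dict[int, classify.GazeFeatures] = {}
        for p in protos:
            f = classify.extract_features(p, stim, config.typing_rule)
            feats[p.cluster_index] = f
            ctypes[p.cluster_index] = classify.classify_type(
                f, conditions[item], config.typing_rule)
        analyses[item] = ItemAnalysis(
            stimulus=stim, trial_refs=refs, assignment=asg,
            cluster_types=ctypes, features=feats, quantization_error=qe)
        if keep_prototypes:
            # recolored, quantized to uint8 to bound memory across items
            prototypes_out[item] = [
                som.ClusterPrototype(
                    cluster_index=q.cluster_index,
                    pixels=np.rint(np.clip(q.pixels, 0, 255)).astype(np.uint8),
                    member_count=q.member_count)
                for q in (som.recolor(p) for p in protos)]
        logger.info("clustered %s: %d trials, qe=%.1f", item, len(refs), qe)

    if config.manual_typing_csv:
        merged = classify.apply_overrides(
            {i: a.cluster_types for i, a in analyses.items()},
            config.manual_typing_csv)
        for item, types in merged.items():
            if item in analyses:
                analyses[item].cluster_types = types

    tables = classify.type_counts(
        {i: a.assignment for i, a in analyses.items()},
        {i: a.cluster_types for i, a in analyses.items()},
        conditions, group_order)
    return analyses, tables, warnings, prototypes_out


def run_all(config: PipelineConfig, out_dir: str | Path) -> RunManifest:
    """Execute the full pipeline and persist all artifacts under ``out_dir``."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    stage = "simulate"
    try:
        battery = make_item_battery(config.battery_seed)
        battery_to_json(battery, out / "battery.json")
        if config.trials_dir:
            trials = gaze.read_trials(config.trials_dir)
        else:
            profiles = default_profiles()
            trials = gaze.simulate_cohort(profiles, config.n_per_group,
                                          battery, config.cohort_seed,
                                          noise_sd_px=config.noise_sd_px)
            gaze.write_trials(trials, out / "trials")
        conditions = {s.item_id: condition_of(s) for s in battery}
        n_analyzable = sum(1 for t in trials
                           if conditions[t.item_id] is not Condition.EXCLUDED_ONE)

        stage = "filter"
        filtered = heatmap.filter_correct(trials)
        analyzable = [t for t in filtered
                      if conditions[t.item_id] is not Condition.EXCLUDED_ONE]

        stage = "cluster"
        analyses, tables, warnings, protos = analyze_trials(
            analyzable, battery, config,
            keep_prototypes=config.save_prototypes)

        stage = "persist"
        rows = []
        for item, a in analyses.items():
            for j, ref in enumerate(a.trial_refs):
                rows.append(f"{analyzable[ref].participant_id},{item},"
                            f"{int(a.assignment.cluster_of[j]) + 1}")
        (out / "assignments.csv").write_text(
            "participant_id,item_id,cluster\n" + "\n".join(rows) + "\n")
        classify.write_typing_csv(
            out / "typing.csv",
            {i: a.cluster_types for i, a in analyses.items()},
            {i: a.features for i, a in analyses.items()})
        if config.save_prototypes:
            pdir = out / "prototypes"
            pdir.mkdir(exist_ok=True)
            for item, plist in protos.items():
                for p in plist:
                    heatmap.save_png(
                        heatmap.HeatmapImage(
                            pixels=np.rint(np.clip(p.pixels, 0, 255)),
                            item_id=item),
                        pdir / f"{item}_c{p.cluster_index + 1}.png")

        stage = "stats"
        group_order = list(dict.fromkeys(t.group_label for t in analyzable))
        reports = stats.condition_reports(tables, group_order,
                                          alpha=config.alpha,
                                          bonferroni_m=config.bonferroni_m)
        stats.reports_to_json(reports, out / "results.json")
        stats.reports_to_csv(reports, out / "results.csv")
        (out / "report.txt").write_text(stats.format_report(reports))
    except Exception as err:  # noqa: BLE001 - re-raise with stage context
        raise PipelineError(f"stage '{stage}' failed: {err}") from err

    manifest = RunManifest(
        config=config.to_dict(),
        stage_counts={
            "trials": len(trials),
            "analyzable": n_analyzable,
            "after_correctness_filter": len(filtered),
            "clustered": {i: len(a.trial_refs) for i, a in analyses.items()},
            "condition_totals": {c.value: int(t.sum())
                                 for c, t in tables.items()},
        },
        warnings=warnings,
        started_at=started,
        finished_at=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    manifest.to_json(out / "manifest.json")
    return manifest


def cohen_kappa(a: Sequence[int], b: Sequence[int]) -> float:
    """Chance-corrected agreement between two label sequences."""
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape or a.size == 0:
        raise PipelineError("label sequences must be equal-length, non-empty")
    labels = np.union1d(a, b)
    po = float((a == b).mean())
    pe = float(sum((a == l).mean() * (b == l).mean() for l in labels))
    if pe >= 1.0:
        return 1.0
    return (po - pe) / (1.0 - pe)


def evaluate_recovery(trials: Sequence[TrialRecord],
                      analyses: Mapping[str, ItemAnalysis]) -> dict:
    """Compare inherited cluster types against the latent generating process.

    Only meaningful on synthetic cohorts, where the latent process is
    known.  Returns the trial-level recovery rate and Cohen's kappa.
    """
    truth, pred = [], []
    for a in analyses.values():
        for j, ref in enumerate(a.trial_refs):
            latent = trials[ref].latent_process
            if latent is None:
                continue
            truth.append(int(latent))
            pred.append(int(a.cluster_types[int(a.assignment.cluster_of[j])]))
    if not truth:
        raise PipelineError("no trials with known latent process")
    truth_a, pred_a = np.asarray(truth), np.asarray(pred)
    return {
        "n_trials": len(truth),
        "recovery_rate": float((truth_a == pred_a).mean()),
        "kappa": cohen_kappa(truth_a, pred_a),
    }
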