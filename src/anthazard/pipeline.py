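"""End-to-end orchestration: trajectories -> reports.

A single :class:`PipelineConfig` (YAML-serialisable, lossless round-trip)
carries every stage's parameters plus one master seed from which per-stage
seeds are derived deterministically.  All spatial quantities are kept in BL
internally; pixel/mm conversions happen only at I/O boundaries via
:class:`~anthazard.segmentation.ArenaSpec`.

Stage order: simulate (or load) -> segment -> features (optionally with a
reconstructed pheromone field) -> incidence-density sampling -> model
comparison -> negative controls -> cross-colony transfer.  Every output
directory gets a ``run.json`` recording the config hash, seed and per-stage
row counts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import controls as ctl
from .covariates import FeatureConfig, assemble_design, pivot_dense
from .hazard import (
    DEFAULT_VARIANTS,
    ModelSpec,
    compare_models,
    cross_colony,
    incidence_density_sample,
)
from .pheromone import FieldParams, run_field
from .segmentation import ArenaSpec, segment
from .simulate import HazardGenerator, MotionModel, SimConfig

logger = logging.getLogger("anthazard")

__all__ = ["ControlConfig", "PipelineConfig", "run_pipeline"]


@dataclass(frozen=True)
class ControlConfig:
    """Negative-control settings (B = 0 disables a control)."""

    identity_B: int = 300
    jitter_B: int = 300
    dwell_B: int = 300
    jitter_multiplier: float = 1.0


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one run needs; defaults reproduce the reference settings
    (lag 3 frames, radius 1.5 BL, 10:1 sampling, 5 folds, 300 permutations,
    1.0 x sigma jitter)."""

    seed: int = 0
    simulate: tuple[SimConfig, ...] = ()
    trajectories: tuple[str, ...] = ()  # CSV paths, one per colony
    arena: ArenaSpec = field(default_factory=ArenaSpec)
    speed_threshold: float = 3.0  # pixels/frame
    min_rest: int = 10  # frames
    min_move: int = 5  # frames
    features: FeatureConfig = field(default_factory=FeatureConfig)
    pheromone: FieldParams | None = None
    model: ModelSpec = field(default_factory=ModelSpec)
    controls: ControlConfig = field(default_factory=ControlConfig)
    variants: tuple[str, ...] = tuple(DEFAULT_VARIANTS)

    # -- YAML (lossless) ----------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(_plain(self.to_dict()), sort_keys=False))

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "simulate" in d:
            d["simulate"] = tuple(
                _sim_from_dict(s) if isinstance(s, dict) else s for s in d["simulate"]
            )
        if "trajectories" in d:
            d["trajectories"] = tuple(d["trajectories"])
        if d.get("arena"):
            d["arena"] = ArenaSpec(**d["arena"])
        if d.get("features"):
            d["features"] = FeatureConfig(**d["features"])
        if d.get("pheromone"):
            d["pheromone"] = FieldParams(**d["pheromone"])
        if d.get("model"):
            m = dict(d["model"])
            for key in ("features", "l1_ratios", "strengths"):
                if key in m:
                    m[key] = tuple(m[key])
            d["model"] = ModelSpec(**m)
        if d.get("controls"):
            d["controls"] = ControlConfig(**d["controls"])
        if d.get("variants"):
            d["variants"] = tuple(d["variants"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(_plain(self.to_dict()), sort_keys=True).encode()
        ).hexdigest()[:12]


def _plain(obj):
    """Recursively convert to YAML/JSON-safe builtins."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _sim_from_dict(d: dict) -> SimConfig:
    d = dict(d)
    if "motion" in d and isinstance(d["motion"], dict):
        d["motion"] = MotionModel(**d["motion"])
    for key in ("stop_hazard", "start_hazard"):
        if key in d and isinstance(d[key], dict):
            d[key] = HazardGenerator(**d[key])
    if d.get("pheromone") and isinstance(d["pheromone"], dict):
        d["pheromone"] = FieldParams(**d["pheromone"])
    return SimConfig(**d)


def _stage(log: dict, name: str, **counts) -> None:
    logger.info("stage %s: %s", name, counts)
    log["stages"].append({"stage": name, **counts})


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run every configured stage and write the report bundle.

    Returns a dict of output paths.  Raises with the failing stage's name
    if any stage errors out.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    log = {"config_hash": config.config_hash(), "seed": config.seed, "stages": []}
    paths: dict[str, Path] = {}
    stage = "load"
    try:
        # ---- trajectories ------------------------------------------------
        stage = "simulate" if config.simulate else "load"
        colonies: dict[str, pd.DataFrame] = {}
        if config.simulate:
            from .simulate import simulate_colony

            for i, sim in enumerate(config.simulate):
                sim = dataclasses.replace(
                    sim,
                    seed=config.seed + sim.seed,
                    colony=sim.colony if sim.colony != "SIM" else f"SIM{i}",
                )
                traj, truth = simulate_colony(sim)
                colonies[sim.colony] = traj
                truth_path = out / f"truth_{sim.colony}.csv"
                truth.to_csv(truth_path, index=False)
        else:
            if not config.trajectories:
                raise ValueError("config provides neither trajectories nor a simulate block")
            for p in config.trajectories:
                df = pd.read_csv(p)
                name = str(df["colony"].iloc[0]) if "colony" in df else Path(p).stem
                colonies[name] = df
        for name, traj in colonies.items():
            path = out / f"trajectory_{name}.csv"
            traj.to_csv(path, index=False)
            paths[f"trajectory_{name}"] = path
            _stage(log, f"trajectories[{name}]", rows=len(traj))

        # ---- segmentation ------------------------------------------------
        stage = "segment"
        seg: dict[str, tuple] = {}
        for name, traj in colonies.items():
            states, bouts, events = segment(
                traj, config.speed_threshold, config.min_rest, config.min_move
            )
            seg[name] = (states, bouts, events)
            for tag, df in (("states", states), ("bouts", bouts), ("events", events)):
                path = out / f"{tag}_{name}.csv"
                df.to_csv(path, index=False)
                paths[f"{tag}_{name}"] = path
            _stage(log, f"segment[{name}]", states=len(states), bouts=len(bouts), events=len(events))

        # ---- features / designs -----------------------------------------
        stage = "features"
        designs: dict[str, dict[str, pd.DataFrame]] = {"stop": {}, "start": {}}
        for name, traj in colonies.items():
            states = seg[name][0]
            phi = None
            if config.pheromone is not None:
                dense = pivot_dense(states, traj, config.arena)
                phi = run_field(dense.x, dense.y, config.pheromone, config.arena.frame_rate)
            for tt in ("stop", "start"):
                design = assemble_design(
                    states, traj, tt, cfg=config.features, arena=config.arena,
                    phi=phi, colony=name,
                )
                sampled = incidence_density_sample(
                    design, config.model.ratio, config.seed + (0 if tt == "stop" else 1)
                )
                designs[tt][name] = sampled
                path = out / f"design_{tt}_{name}.csv"
                sampled.to_csv(path, index=False)
                paths[f"design_{tt}_{name}"] = path
                _stage(
                    log, f"features[{name},{tt}]",
                    at_risk=len(design), sampled=len(sampled), cases=int(sampled["y"].sum()),
                )

        # ---- model comparison -------------------------------------------
        stage = "fit"
        variants = {k: DEFAULT_VARIANTS[k] for k in config.variants}
        if config.pheromone is None:
            variants = {k: v for k, v in variants.items() if "phi" not in v}
        tables = []
        for tt in ("stop", "start"):
            for name, sampled in designs[tt].items():
                spec = dataclasses.replace(config.model, transition_type=tt)
                table, _ = compare_models(sampled, spec, variants)
                table.insert(0, "colony", name)
                tables.append(table)
        comparison = pd.concat(tables, ignore_index=True)
        paths["comparison"] = out / "comparison.csv"
        comparison.to_csv(paths["comparison"], index=False)
        _stage(log, "fit", rows=len(comparison))

        # ---- negative controls ------------------------------------------
        stage = "controls"
        first = next(iter(colonies))
        null_rows, summaries = [], []
        cc = config.controls
        for tt in ("stop", "start"):
            spec = dataclasses.replace(config.model, transition_type=tt)
            runs = []
            if cc.dwell_B > 0:
                runs.append(ctl.dwell_shuffle(designs[tt][first], spec, cc.dwell_B, config.seed))
            if cc.jitter_B > 0:
                runs.append(
                    ctl.feature_jitter(
                        designs[tt][first], spec, cc.jitter_multiplier, cc.jitter_B, config.seed
                    )
                )
            if cc.identity_B > 0:
                runs.append(
                    ctl.identity_shuffle(
                        seg[first][0], colonies[first], spec,
                        config.features, config.arena, cc.identity_B, config.seed,
                    )
                )
            for nd in runs:
                null_rows.extend(
                    {"control_type": nd.control_type, "transition_type": tt,
                     "iteration": i, "auc": a}
                    for i, a in enumerate(nd.null_aucs)
                )
                summaries.append(
                    {"control_type": nd.control_type, "transition_type": tt,
                     "observed": nd.observed_auc, "median_null": nd.null_median,
                     "p": nd.p_value, "B": nd.B, "seed": nd.seed}
                )
        if null_rows:
            paths["controls"] = out / "controls.csv"
            pd.DataFrame(null_rows).to_csv(paths["controls"], index=False)
            (out / "controls_summary.json").write_text(json.dumps(summaries, indent=2))
            paths["controls_summary"] = out / "controls_summary.json"
        _stage(log, "controls", rows=len(null_rows))

        # ---- cross-colony transfer --------------------------------------
        stage = "crosscolony"
        if len(colonies) >= 2:
            rows = []
            for tt in ("stop", "start"):
                spec = dataclasses.replace(config.model, transition_type=tt)
                res = cross_colony(designs[tt], spec)
                for train in res.matrix.index:
                    for test in res.matrix.columns:
                        rows.append(
                            {"transition_type": tt, "train_colony": train,
                             "test_colony": test, "auc": res.matrix.loc[train, test]}
                        )
                rows.append(
                    {"transition_type": tt, "train_colony": "(within)",
                     "test_colony": "(cross)", "auc": res.gap}
                )
            paths["crosscolony"] = out / "crosscolony.csv"
            pd.DataFrame(rows).to_csv(paths["crosscolony"], index=False)
            _stage(log, "crosscolony", rows=len(rows))
    except Exception as err:  # noqa: BLE001 - annotate the failing stage
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    (out / "run.json").write_text(json.dumps(_plain(log), indent=2))
    paths["run_log"] = out / "run.json"
    return {k: str(v) for k, v in paths.items()}
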