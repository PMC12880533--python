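"""Structured-text (YAML) run configuration.

A run config has up to four blocks::

    scenario:
      geometry:  {block_mm: [30, 20, 10], channel_diameter: 2.5, vessel_depth: 1.0}
      actuator:  {diameter: 3.5, power_mw: 56.7}
      layout:    {lateral_offset: 3.5, interlayer_spacing: 1.5}
      ambient:   {ambient_temperature: 25, convective_coefficient: 15,
                  bottom_surface_temperature: 25, inlet_fluid_temperature: 25}
      flow:      {mean_speed: 1.0, profile: plug}
      spacing: 0.5
    dataset:
      depths: [1, 1.5, 2]
      flows:  [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
      replicates: 50
      noise_sd: 0.002
      mode: temperature
    model:
      hidden: [64, 64, 32]
      dropout: 0.1
      epochs: 600
      batch_size: 128
      learning_rate: 3.0e-3
      n_ensemble: 5
    evaluation:
      folds: 5
    seed: 0

All lengths are mm, speeds mm/s, power mW, temperatures degC, conductivities
W/(m K).  A single master seed deterministically expands into per-stage
seeds (stage index appended via ``stage_seed``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .datasets import ConditionGrid, NoiseModel
from .inversion import RegressorSpec, TrainingConfig
from .scenario import (
    ActuatorSpec,
    AmbientConditions,
    FlowCondition,
    PhantomGeometry,
    Scenario,
    SensorLayout,
)

__all__ = ["RunConfig", "load_run_config", "scenario_from_dict", "stage_seed"]

#: Stage indices of the deterministic seed-expansion scheme.
STAGES = ("dataset", "model", "folds", "ambient_test", "bp")


def stage_seed(master: int, stage: str) -> int:
    """Expand one master seed into decorrelated per-stage seeds.

    Uses numpy's SeedSequence spawn-key mechanism with a fixed stage index,
    keeping every derived seed below 2**31.
    """
    import numpy as np

    idx = STAGES.index(stage)
    return int(np.random.SeedSequence([master, idx]).generate_state(1)[0] % (2**31))


def scenario_from_dict(d: dict) -> Scenario:
    def pick(cls, key):
        sub = dict(d.get(key) or {})
        if key == "geometry" and "block_mm" in sub:
            sub["block_mm"] = tuple(float(v) for v in sub["block_mm"])
        return cls(**sub)

    return Scenario(
        geometry=pick(PhantomGeometry, "geometry"),
        actuator=pick(ActuatorSpec, "actuator"),
        layout=pick(SensorLayout, "layout"),
        ambient=pick(AmbientConditions, "ambient"),
        flow=pick(FlowCondition, "flow"),
        spacing=float(d.get("spacing", 0.5)),
    )


@dataclass
class RunConfig:
    scenario: Scenario
    grid: ConditionGrid
    noise: NoiseModel
    spec: RegressorSpec
    training: TrainingConfig
    n_folds: int = 5
    feature_mode: str = "temperature"
    seed: int = 0
    raw: dict = field(default_factory=dict)


def load_run_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    seed = int(raw.get("seed", 0))
    ds = raw.get("dataset") or {}
    grid = ConditionGrid(
        depths=tuple(float(v) for v in ds.get("depths", (1.0, 1.5, 2.0))),
        flows=tuple(float(v) for v in ds.get("flows", range(1, 11))),
        replicates=int(ds.get("replicates", 50)),
    )
    noise = NoiseModel(
        temperature_noise_sd=float(ds.get("noise_sd", 0.002)),
        seed=stage_seed(seed, "dataset"),
    )
    m = raw.get("model") or {}
    spec = RegressorSpec(
        hidden=tuple(int(v) for v in m.get("hidden", (64, 64, 32))),
        dropout=float(m.get("dropout", 0.10)),
    )
    training = TrainingConfig(
        epochs=int(m.get("epochs", 600)),
        batch_size=int(m.get("batch_size", 128)),
        learning_rate=float(m.get("learning_rate", 3e-3)),
        input_jitter_sd=float(m.get("input_jitter_sd", 0.0)),
        n_ensemble=int(m.get("n_ensemble", 5)),
        seed=stage_seed(seed, "model"),
    )
    return RunConfig(
        scenario=scenario_from_dict(raw.get("scenario") or {}),
        grid=grid,
        noise=noise,
        spec=spec,
        training=training,
        n_folds=int((raw.get("evaluation") or {}).get("folds", 5)),
        feature_mode=str(ds.get("mode", "temperature")),
        seed=seed,
        raw=raw,
    )
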