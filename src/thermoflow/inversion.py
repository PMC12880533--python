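"""Neural inversion of the six-channel readings for flow rate and depth.

A small fully connected network — linear layers with ReLU, batch
normalization and 10% dropout — maps the six features to the two targets
(flow in mm/s, vessel depth in mm).  Evaluation follows the benchtop
protocol: condition-grouped five-fold cross-validation with pooled RMSE and
95th-percentile absolute errors, plus ambient-robustness, dynamic-tracking
and single- vs dual-layer ablation studies.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import nn
from .datasets import (
    ConditionGrid,
    FoldAssignment,
    LabeledDataset,
    NoiseModel,
    SteadySolveCache,
    generate_dataset,
)
from .frontend import assemble_features
from .grid import build_scenario_grid
from .scenario import Scenario
from .solver import sensor_positions, solve_transient, probe_temperature

__all__ = [
    "RegressorSpec",
    "TrainingConfig",
    "EvaluationReport",
    "FlowDepthRegressor",
    "rmse",
    "crossval_evaluate",
    "ambient_robustness_eval",
    "dynamic_tracking_eval",
    "layer_ablation",
    "LeakageError",
]


class LeakageError(RuntimeError):
    """A condition appeared in both train and test of one fold."""


@dataclass(frozen=True)
class RegressorSpec:
    """Architecture of the inversion network."""

    n_inputs: int = 6
    hidden: tuple[int, ...] = (64, 64, 32)
    batchnorm: bool = True
    dropout: float = 0.10
    dropout_placement: str = "last"  # "all" hidden layers or "last" only
    n_outputs: int = 2

    def __post_init__(self) -> None:
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")


@dataclass(frozen=True)
class TrainingConfig:
    """Optimization settings; standardization is fitted on training rows only.

    The learning rate follows a cosine decay from ``learning_rate`` to
    ``learning_rate * lr_final_fraction`` over the epochs, which matters for
    squeezing the last order of magnitude out of this smooth regression.
    """

    epochs: int = 600
    batch_size: int = 128
    learning_rate: float = 3e-3
    lr_final_fraction: float = 0.01
    input_jitter_sd: float = 0.0  # train-time Gaussian jitter, standardized units
    weight_decay: float = 0.0  # decoupled L2 shrinkage per step
    n_ensemble: int = 5  # independently seeded replicates, predictions averaged
    seed: int = 0


class FlowDepthRegressor:
    """Six features in, (flow mm/s, depth mm) out.

    Inputs and targets are z-scored with statistics from the training set;
    the loss is unweighted MSE over both standardized outputs.
    """

    def __init__(self, spec: RegressorSpec = RegressorSpec(),
                 cfg: TrainingConfig = TrainingConfig()):
        self.spec = spec
        self.cfg = cfg
        self.net: nn.Sequential | None = None
        self.nets: list[nn.Sequential] = []
        self.first_epoch_loss: float | None = None
        self.last_epoch_loss: float | None = None

    def _build(self, rng: np.random.Generator) -> nn.Sequential:
        layers: list[nn.Layer] = []
        n_prev = self.spec.n_inputs
        for li, width in enumerate(self.spec.hidden):
            layers.append(nn.Linear(n_prev, width, rng))
            if self.spec.batchnorm:
                layers.append(nn.BatchNorm1d(width))
            layers.append(nn.ReLU())
            last = li == len(self.spec.hidden) - 1
            if self.spec.dropout > 0 and (
                self.spec.dropout_placement == "all" or last
            ):
                layers.append(nn.Dropout(self.spec.dropout, rng))
            n_prev = width
        layers.append(nn.Linear(n_prev, self.spec.n_outputs, rng))
        return nn.Sequential(*layers)

    def fit(self, X: np.ndarray, y: np.ndarray) -> "FlowDepthRegressor":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.spec.n_inputs:
            raise ValueError(f"expected (n, {self.spec.n_inputs}) features")
        if len(X) == 0:
            raise ValueError("empty training set")
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite features")
        self.x_mean = X.mean(axis=0)
        self.x_std = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
        self.y_mean = y.mean(axis=0)
        self.y_std = np.where(y.std(axis=0) > 0, y.std(axis=0), 1.0)
        self.y_min = y.min(axis=0)
        self.y_max = y.max(axis=0)
        Xs = (X - self.x_mean) / self.x_std
        ys = (y - self.y_mean) / self.y_std

        self.nets = []
        for member in range(self.cfg.n_ensemble):
            rng = np.random.default_rng(self.cfg.seed + member)
            net = self._build(rng)
            opt = nn.Adam(net.params(), lr=self.cfg.learning_rate,
                          weight_decay=self.cfg.weight_decay)
            n = len(Xs)
            bs = min(self.cfg.batch_size, n)
            lr0 = self.cfg.learning_rate
            lr1 = lr0 * self.cfg.lr_final_fraction
            for epoch in range(self.cfg.epochs):
                frac = epoch / max(self.cfg.epochs - 1, 1)
                opt.lr = lr1 + 0.5 * (lr0 - lr1) * (1 + np.cos(np.pi * frac))
                order = rng.permutation(n)
                total = 0.0
                for start in range(0, n, bs):
                    sel = order[start:start + bs]
                    if len(sel) < 2 and self.spec.batchnorm:
                        continue  # batchnorm needs at least two rows
                    xb = Xs[sel]
                    if self.cfg.input_jitter_sd > 0:
                        xb = xb + rng.normal(0, self.cfg.input_jitter_sd, xb.shape)
                    pred = net.forward(xb, train=True)
                    loss, grad = nn.mse_loss(pred, ys[sel])
                    if not np.isfinite(loss):
                        raise FloatingPointError("training loss diverged to NaN/inf")
                    net.backward(grad)
                    opt.step()
                    total += loss * len(sel)
                epoch_loss = total / n
                if member == 0 and epoch == 0:
                    self.first_epoch_loss = epoch_loss
                if member == 0:
                    self.last_epoch_loss = epoch_loss
            self.nets.append(net)
        self.net = self.nets[0]
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if not self.nets:
            raise RuntimeError("model is not fitted")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.spec.n_inputs:
            raise ValueError(
                f"feature width {X.shape[1]} != contract {self.spec.n_inputs}"
            )
        Xs = (X - self.x_mean) / self.x_std
        out = np.mean([net.forward(Xs, train=False) for net in self.nets], axis=0)
        out = out * self.y_std + self.y_mean
        # the sensor reports within its calibrated range: project onto the
        # training label box (the truth always lies inside it)
        return np.clip(out, self.y_min, self.y_max)

    def save(self, path) -> None:
        """Archive weights, batchnorm statistics, standardization and spec."""
        import json

        if not self.nets:
            raise RuntimeError("model is not fitted")
        arrays = {}
        for k, net in enumerate(self.nets):
            for i, layer in enumerate(net.layers):
                for j, (p, _) in enumerate(layer.params()):
                    arrays[f"net{k}_layer{i}_p{j}"] = p
                if isinstance(layer, nn.BatchNorm1d):
                    arrays[f"net{k}_layer{i}_rmean"] = layer.running_mean
                    arrays[f"net{k}_layer{i}_rvar"] = layer.running_var
        meta = json.dumps({
            "spec": self.spec.__dict__ | {"hidden": list(self.spec.hidden)},
            "cfg": self.cfg.__dict__,
        })
        np.savez(
            path, meta=np.array(meta), x_mean=self.x_mean, x_std=self.x_std,
            y_mean=self.y_mean, y_std=self.y_std,
            y_min=self.y_min, y_max=self.y_max, **arrays,
        )

    @classmethod
    def load(cls, path) -> "FlowDepthRegressor":
        import json

        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            spec_d = meta["spec"]
            spec_d["hidden"] = tuple(spec_d["hidden"])
            cfg = TrainingConfig(**meta["cfg"])
            model = cls(RegressorSpec(**spec_d), cfg)
            model.nets = []
            for k in range(cfg.n_ensemble):
                net = model._build(np.random.default_rng(0))
                for i, layer in enumerate(net.layers):
                    for j, (p, _) in enumerate(layer.params()):
                        p[...] = z[f"net{k}_layer{i}_p{j}"]
                    if isinstance(layer, nn.BatchNorm1d):
                        layer.running_mean[...] = z[f"net{k}_layer{i}_rmean"]
                        layer.running_var[...] = z[f"net{k}_layer{i}_rvar"]
                model.nets.append(net)
            model.net = model.nets[0]
            model.x_mean = z["x_mean"]
            model.x_std = z["x_std"]
            model.y_mean = z["y_mean"]
            model.y_std = z["y_std"]
            model.y_min = z["y_min"]
            model.y_max = z["y_max"]
        return model


def rmse(true: np.ndarray, pred: np.ndarray) -> float:
    """Root of the mean squared deviation, in the inputs' units."""
    true = np.asarray(true, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if true.shape != pred.shape:
        raise ValueError("length mismatch between truth and predictions")
    if true.size == 0:
        raise ValueError("need at least one element")
    return float(np.sqrt(np.mean((true - pred) ** 2)))


@dataclass
class EvaluationReport:
    """Pooled cross-validation metrics for the (flow, depth) inversion."""

    rmse_f: float
    rmse_d: float
    q95_abs_err_f: float
    q95_abs_err_d: float
    fold_rmse_f: list[float]
    fold_rmse_d: list[float]
    per_condition: pd.DataFrame
    per_flow_rmse_d: pd.Series
    predictions: pd.DataFrame

    @property
    def fold_rmse_f_ci(self) -> tuple[float, float]:
        """Mean fold RMSE_f and the half-width of its 95% CI."""
        v = np.asarray(self.fold_rmse_f)
        return float(v.mean()), float(1.96 * v.std(ddof=1) / np.sqrt(len(v)))

    @property
    def error_correlation(self) -> float:
        """Correlation between pooled flow and depth residuals."""
        e = self.predictions
        return float(np.corrcoef(e["err_f"], e["err_d"])[0, 1])

    def summary(self) -> str:
        m, hw = self.fold_rmse_f_ci
        return (
            f"RMSE_f {self.rmse_f:.4f} mm/s (folds {m:.4f} +/- {hw:.4f}), "
            f"RMSE_d {self.rmse_d:.4f} mm, "
            f"q95 |err_f| {self.q95_abs_err_f:.4f} mm/s, "
            f"q95 |err_d| {self.q95_abs_err_d:.4f} mm"
        )


def _report_from_predictions(pred_frame: pd.DataFrame,
                             fold_rmse_f: list[float],
                             fold_rmse_d: list[float]) -> EvaluationReport:
    pf = pred_frame
    per_cond = pf.groupby("condition_id").apply(
        lambda g: pd.Series({
            "rmse_f": rmse(g["f_true"], g["f_pred"]),
            "rmse_d": rmse(g["d_true"], g["d_pred"]),
        }),
        include_groups=False,
    )
    per_flow = pf.groupby("f_true").apply(
        lambda g: rmse(g["d_true"], g["d_pred"]), include_groups=False
    )
    return EvaluationReport(
        rmse_f=rmse(pf["f_true"], pf["f_pred"]),
        rmse_d=rmse(pf["d_true"], pf["d_pred"]),
        q95_abs_err_f=float(np.quantile(np.abs(pf["err_f"]), 0.95)),
        q95_abs_err_d=float(np.quantile(np.abs(pf["err_d"]), 0.95)),
        fold_rmse_f=fold_rmse_f,
        fold_rmse_d=fold_rmse_d,
        per_condition=per_cond,
        per_flow_rmse_d=per_flow,
        predictions=pf,
    )


def crossval_evaluate(
    dataset: LabeledDataset,
    folds: FoldAssignment,
    spec: RegressorSpec = RegressorSpec(),
    cfg: TrainingConfig = TrainingConfig(),
) -> EvaluationReport:
    """Condition-grouped K-fold cross-validation.

    Each fold trains on K-1 condition groups and predicts the held-out
    group, so every row is tested exactly once; metrics are pooled over all
    rows and also reported per fold.
    """
    ids = dataset.condition_ids
    known = set(folds.folds)
    missing = set(ids) - known
    if missing:
        raise ValueError(f"fold assignment missing conditions: {sorted(missing)}")

    frames = []
    fold_rmse_f, fold_rmse_d = [], []
    for k in range(folds.n_folds):
        test_conds = set(folds.test_conditions(k))
        train_conds = set(folds.train_conditions(k))
        if test_conds & train_conds:
            raise LeakageError(
                f"fold {k}: conditions {sorted(test_conds & train_conds)} "
                "appear in both train and test"
            )
        tr = np.isin(ids, list(train_conds))
        te = np.isin(ids, list(test_conds))
        model = FlowDepthRegressor(spec, cfg).fit(dataset.X[tr], dataset.y[tr])
        pred = model.predict(dataset.X[te])
        yte = dataset.y[te]
        frames.append(pd.DataFrame({
            "condition_id": ids[te],
            "fold": k,
            "f_true": yte[:, 0], "d_true": yte[:, 1],
            "f_pred": pred[:, 0], "d_pred": pred[:, 1],
            "err_f": pred[:, 0] - yte[:, 0],
            "err_d": pred[:, 1] - yte[:, 1],
        }))
        fold_rmse_f.append(rmse(yte[:, 0], pred[:, 0]))
        fold_rmse_d.append(rmse(yte[:, 1], pred[:, 1]))
    return _report_from_predictions(pd.concat(frames, ignore_index=True),
                                    fold_rmse_f, fold_rmse_d)


def ambient_robustness_eval(
    scenario: Scenario,
    grid: ConditionGrid,
    noise: NoiseModel,
    spec: RegressorSpec = RegressorSpec(),
    cfg: TrainingConfig = TrainingConfig(),
    test_ambients: tuple[float, ...] = (30.0, 32.5, 35.0),
    test_flows: tuple[float, ...] = (1.0, 3.0, 5.0, 7.0, 9.0),
    test_replicates: int = 10,
    test_seed: int = 1,
    test_depth: float = 1.5,
    cache: SteadySolveCache | None = None,
) -> dict:
    """Train at 25 degC ambient, test at elevated chamber temperatures.

    Features use the reference-compensated differential mode (the linearized
    equivalent of the Wheatstone-bridge differentials).  The elevated-
    temperature condition raises the chamber: ambient air, water bath and
    stage move together, as in the benchtop protocol where the supply water
    is kept at the chamber temperature.  Returns the worst-case
    |f_pred - f_true| over all ambient x flow combinations, plus the
    per-combination table and the uncompensated (raw-temperature) ablation.
    """
    from .frontend import diff_features

    cache = cache if cache is not None else SteadySolveCache()
    results = {}
    for mode in ("diff", "temperature"):
        train = generate_dataset(grid, scenario, noise, mode=mode, cache=cache)
        model = FlowDepthRegressor(spec, cfg).fit(train.X, train.y)
        rng = np.random.default_rng(test_seed)
        rows = []
        for T_a in test_ambients:
            amb = replace(
                scenario.ambient,
                ambient_temperature=T_a,
                inlet_fluid_temperature=T_a,
                bottom_surface_temperature=T_a,
            )
            for f in test_flows:
                sc = scenario.with_(
                    ambient=amb,
                    geometry=replace(scenario.geometry, vessel_depth=test_depth),
                    flow=replace(scenario.flow, mean_speed=f),
                )
                temps = cache.readings(sc)
                draws = temps[None, :] + rng.normal(
                    0.0, noise.temperature_noise_sd, size=(test_replicates, 6)
                )
                feats = diff_features(draws) if mode == "diff" else draws
                pred = model.predict(feats)
                rows.append({
                    "ambient": T_a, "f_true": f,
                    "max_abs_err_f": float(np.max(np.abs(pred[:, 0] - f))),
                })
        tbl = pd.DataFrame(rows)
        results[mode] = {
            "worst_abs_err_f": float(tbl["max_abs_err_f"].max()),
            "table": tbl,
        }
    return {
        "worst_abs_err_f": results["diff"]["worst_abs_err_f"],
        "table": results["diff"]["table"],
        "uncompensated_worst_abs_err_f": results["temperature"]["worst_abs_err_f"],
    }


def dynamic_tracking_eval(
    scenario: Scenario,
    model: FlowDepthRegressor,
    flow_profile: list,
    dt: float = 0.5,
    settle_fraction: float = 0.3,
    warmup: float = 400.0,
) -> pd.DataFrame:
    """Track step changes in flow with 1 Hz predictions.

    The system first runs for ``warmup`` seconds at the profile's initial
    level (step tests are performed on an operating sensor, not from a
    cold start), then the transient solver steps through the
    piecewise-constant profile; the six probes are sampled at 20 Hz by
    temporal interpolation, pushed through the filter/decimation chain and
    predicted at 1 Hz.  Reported per step: settling time (10-90% of the
    prediction transition) and the mean prediction over the trailing
    ``settle_fraction`` of each dwell.  Times in the output are relative
    to the end of the warm-up.
    """
    grid = build_scenario_grid(scenario)
    dwell = flow_profile[1][0] - flow_profile[0][0] if len(flow_profile) > 1 else None
    shifted = [(0.0, flow_profile[0][1])] + [
        (t + warmup, fl) for t, fl in flow_profile[1:]
    ]
    duration = warmup + (flow_profile[-1][0]
                         + (dwell or flow_profile[-1][0] or 60.0))
    fields = solve_transient(
        grid, scenario.material_map, scenario.ambient, shifted,
        scenario.actuator.power_mw, duration, dt,
        initial_temperature=scenario.ambient.ambient_temperature,
    )
    times = np.array([f.time for f in fields])
    pos = sensor_positions(scenario.layout)
    from .solver import CHANNEL_NAMES

    temps = np.array([
        [probe_temperature(f, pos[name]) for name in CHANNEL_NAMES]
        for f in fields
    ])
    t20 = np.arange(0, duration, 1 / 20.0)
    temps20 = np.column_stack([
        np.interp(t20, times, temps[:, c]) for c in range(6)
    ])
    stream = assemble_features(temps20, mode="temperature")
    pred = model.predict(stream.values)
    t1 = stream.timestamps - warmup  # measurement clock starts after warm-up

    rows = []
    for i, (t0, flow) in enumerate(flow_profile):
        t_end = flow_profile[i + 1][0] if i + 1 < len(flow_profile) else duration
        seg = (t1 >= t0) & (t1 < t_end)
        pf = pred[seg, 0]
        ts = t1[seg]
        tail = pf[int(len(pf) * (1 - settle_fraction)):]
        # settling: 10-90% traversal of the prediction between segment ends;
        # the first segment has no flow step (warm-up is actuator settling,
        # not flow tracking), so its settling time is zero by definition
        target = float(np.mean(tail))
        if i == 0:
            start_level, span = pf[0], 0.0
        else:
            start_level = pred[t1 < t0, 0][-1]
            span = target - start_level
        if abs(span) < 1e-9:
            settle = 0.0
        else:
            frac = (pf - start_level) / span
            above = np.nonzero(frac >= 0.9)[0]
            settle = float(ts[above[0]] - t0) if len(above) else float(t_end - t0)
        rows.append({
            "level": flow.mean_speed,
            "t_start": t0,
            "settling_time_s": settle,
            "post_settle_mean": target,
            "post_settle_abs_err": abs(target - flow.mean_speed),
        })
    return pd.DataFrame(rows)


def layer_ablation(
    dataset: LabeledDataset,
    folds: FoldAssignment,
    spec: RegressorSpec = RegressorSpec(),
    cfg: TrainingConfig = TrainingConfig(),
) -> dict[str, EvaluationReport]:
    """Bottom-layer-only (3 features) vs full six-feature inversion.

    Both arms use identical folds; the single-layer arm sees only the
    bottom-layer columns, emulating a conventional one-layer calorimetric
    sensor that cannot separate depth from flow.
    """
    full = crossval_evaluate(dataset, folds, spec, cfg)
    bottom_cols = [n for n in dataset.feature_names
                   if n.startswith(("t_bot", "v_bot"))]
    sub = LabeledDataset(
        dataset.frame[["condition_id", "d_set_mm", "f_set_mm_s", *bottom_cols]],
        tuple(bottom_cols),
        dataset.mode,
    )
    spec3 = replace(spec, n_inputs=len(bottom_cols))
    bottom = crossval_evaluate(sub, folds, spec3, cfg)
    return {"full": full, "bottom_only": bottom}
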