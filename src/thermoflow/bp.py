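"""Blood-pressure estimation by fusing flow-rate and PPG signals.

Two parallel branches process the modalities independently: a recurrent
branch summarizes the 1 Hz flow-rate window and a 1-D convolutional branch
encodes the 128 Hz PPG window.  Their embeddings are concatenated and a
fully connected head emits systolic and diastolic pressure at 1 Hz.  The
``ppg_only`` mode drops the recurrent branch entirely, forming the baseline
that quantifies what the thermal flow channel adds.

Agreement against the reference monitor is summarized with Bland-Altman
statistics (bias and 95% limits of agreement).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .cardio import PPG_RATE, MultimodalRecord

__all__ = [
    "FusionSpec",
    "BPTrainingConfig",
    "AgreementStats",
    "BloodPressureModel",
    "fit_bp_model",
    "evaluate_bp_model",
    "bland_altman",
    "error_reduction",
]


@dataclass(frozen=True)
class FusionSpec:
    window_s: int = 10  # input window length, stride 1 s
    rnn_hidden: int = 16
    conv_channels: tuple[int, int] = (8, 8)
    conv_kernels: tuple[int, int] = (32, 8)
    conv_strides: tuple[int, int] = (8, 4)
    head_hidden: int = 32


@dataclass(frozen=True)
class BPTrainingConfig:
    epochs: int = 30
    batch_size: int = 64
    learning_rate: float = 3e-3
    seed: int = 0


@dataclass(frozen=True)
class AgreementStats:
    """Bland-Altman agreement: bias and 95% limits of agreement (mmHg)."""

    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float


def bland_altman(reference: np.ndarray, measured: np.ndarray) -> AgreementStats:
    """Differences are measured - reference; LoA = bias +/- 1.96 sample SD."""
    reference = np.asarray(reference, dtype=float)
    measured = np.asarray(measured, dtype=float)
    if reference.shape != measured.shape:
        raise ValueError("series length mismatch")
    if reference.size < 2:
        raise ValueError("need at least two paired samples")
    diff = measured - reference
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return AgreementStats(bias, sd, bias - 1.96 * sd, bias + 1.96 * sd)


def error_reduction(err_ppg: float, err_fused: float) -> float | None:
    """Percent error reduction of fusion vs the PPG-only baseline.

    Returns None (undefined) when the baseline error is zero.
    """
    if err_ppg == 0:
        return None
    return 100.0 * (err_ppg - err_fused) / err_ppg


def _windows(records: list[MultimodalRecord], window_s: int):
    """Stack (flow window, ppg window, SP/DP target) per record second."""
    Xf, Xp, Y, rec_idx = [], [], [], []
    for ri, rec in enumerate(records):
        for t in range(window_s, rec.duration):
            Xf.append(rec.flow[t - window_s:t])
            Xp.append(rec.ppg[(t - window_s) * PPG_RATE: t * PPG_RATE])
            Y.append((rec.sp[t], rec.dp[t]))
            rec_idx.append(ri)
    return (np.asarray(Xf), np.asarray(Xp), np.asarray(Y), np.asarray(rec_idx))


class BloodPressureModel:
    """Two-branch (recurrent + convolutional) pressure regressor."""

    def __init__(self, spec: FusionSpec, mode: str, cfg: BPTrainingConfig):
        if mode not in ("fused", "ppg_only"):
            raise ValueError("mode must be 'fused' or 'ppg_only'")
        self.spec = spec
        self.mode = mode
        self.cfg = cfg

    def _build(self, rng: np.random.Generator) -> None:
        s = self.spec
        c1, c2 = s.conv_channels
        k1, k2 = s.conv_kernels
        st1, st2 = s.conv_strides
        self.conv = nn.Sequential(
            nn.Conv1d(1, c1, k1, st1, rng),
            nn.ReLU(),
            nn.Conv1d(c1, c2, k2, st2, rng),
            nn.ReLU(),
            nn.GlobalAvgPool1d(),
        )
        emb = c2
        if self.mode == "fused":
            self.rnn = nn.SimpleRNN(1, s.rnn_hidden, rng)
            emb += s.rnn_hidden
        else:
            self.rnn = None
        self.head = nn.Sequential(
            nn.Linear(emb, s.head_hidden, rng),
            nn.ReLU(),
            nn.Linear(s.head_hidden, 2, rng),
        )

    def _params(self):
        p = self.conv.params() + self.head.params()
        if self.rnn is not None:
            p = self.rnn.params() + p
        return p

    def _forward(self, xf, xp, train: bool):
        hp = self.conv.forward(xp[:, None, :], train)
        if self.rnn is not None:
            hf = self.rnn.forward(xf[:, :, None], train)
            z = np.concatenate([hf, hp], axis=1)
        else:
            z = hp
        self._split = hp.shape[1]
        return self.head.forward(z, train)

    def fit(self, records: list[MultimodalRecord]) -> "BloodPressureModel":
        Xf, Xp, Y, _ = _windows(records, self.spec.window_s)
        self.f_mean, self.f_std = Xf.mean(), max(Xf.std(), 1e-9)
        self.p_mean, self.p_std = Xp.mean(), max(Xp.std(), 1e-9)
        self.y_mean, self.y_std = Y.mean(axis=0), Y.std(axis=0)
        self.y_std = np.where(self.y_std > 0, self.y_std, 1.0)
        Xf = (Xf - self.f_mean) / self.f_std
        Xp = (Xp - self.p_mean) / self.p_std
        Ys = (Y - self.y_mean) / self.y_std

        rng = np.random.default_rng(self.cfg.seed)
        self._build(rng)
        opt = nn.Adam(self._params(), lr=self.cfg.learning_rate)
        n = len(Xf)
        bs = min(self.cfg.batch_size, n)
        for _ in range(self.cfg.epochs):
            order = rng.permutation(n)
            for start in range(0, n, bs):
                sel = order[start:start + bs]
                pred = self._forward(Xf[sel], Xp[sel], train=True)
                loss, grad = nn.mse_loss(pred, Ys[sel])
                if not np.isfinite(loss):
                    raise FloatingPointError("BP training loss diverged")
                dz = self.head.backward(grad)
                if self.rnn is not None:
                    nh = self.spec.rnn_hidden
                    self.rnn.backward(dz[:, :nh])
                    self.conv.backward(dz[:, nh:])
                else:
                    self.conv.backward(dz)
                opt.step()
        return self

    def predict(self, records: list[MultimodalRecord]):
        """1 Hz SP/DP estimates per record (first ``window_s`` seconds skipped)."""
        out = []
        for rec in records:
            Xf, Xp, _, _ = _windows([rec], self.spec.window_s)
            Xf = (Xf - self.f_mean) / self.f_std
            Xp = (Xp - self.p_mean) / self.p_std
            pred = self._forward(Xf, Xp, train=False)
            out.append(pred * self.y_std + self.y_mean)
        return out


def fit_bp_model(
    records: list[MultimodalRecord],
    mode: str = "fused",
    spec: FusionSpec = FusionSpec(),
    cfg: BPTrainingConfig = BPTrainingConfig(),
) -> BloodPressureModel:
    """Train a fused or PPG-only pressure model on whole records.

    Splitting is by record: callers pass disjoint record lists for train and
    evaluation, never windows of the same record.
    """
    return BloodPressureModel(spec, mode, cfg).fit(records)


def evaluate_bp_model(model: BloodPressureModel,
                      records: list[MultimodalRecord]) -> dict:
    """Held-out RMSE and Bland-Altman agreement per output."""
    from .inversion import rmse

    preds = model.predict(records)
    w = model.spec.window_s
    sp_true = np.concatenate([r.sp[w:] for r in records])
    dp_true = np.concatenate([r.dp[w:] for r in records])
    sp_pred = np.concatenate([p[:, 0] for p in preds])
    dp_pred = np.concatenate([p[:, 1] for p in preds])
    return {
        "rmse_sp": rmse(sp_true, sp_pred),
        "rmse_dp": rmse(dp_true, dp_pred),
        "agreement_sp": bland_altman(sp_true, sp_pred),
        "agreement_dp": bland_altman(dp_true, dp_pred),
        "sp_violations": int(np.sum(sp_pred <= dp_pred)),
    }
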