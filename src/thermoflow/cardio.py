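"""Synthetic multimodal cardiovascular records for the BP-fusion demo.

Each record pairs a 1 Hz blood-flow-rate sequence, a 128 Hz PPG waveform and
1 Hz reference systolic/diastolic pressures over a session containing one
Valsalva maneuver.  The maneuver imprints the characteristic four-phase
pressure excursion: (i) an initial elevation at strain onset, (ii) a
compensatory decline while venous return is reduced, (iii) a transient drop
at release and (iv) an overshoot before recovery.

The two modalities carry complementary information by construction: PPG
pulse amplitude follows pulse pressure (SP - DP), while the flow sequence
follows mean arterial pressure through a configurable coupling gain.  With
the gain at zero the flow channel is pure noise, which is the control case
for verifying that fusion gains are not spurious.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CardioSyntheticConfig", "MultimodalRecord", "generate_cardio_dataset"]

PPG_RATE = 128  # Hz


@dataclass(frozen=True)
class CardioSyntheticConfig:
    baseline_sp: float = 120.0  # mmHg
    baseline_dp: float = 80.0
    heart_rate: float = 1.2  # Hz
    valsalva_onset: float = 120.0  # s
    valsalva_duration: float = 140.0
    # phase offsets i-iv applied to SP (mmHg); DP follows at dp_fraction
    phase_amplitudes: tuple[float, float, float, float] = (15.0, -20.0, -15.0, 10.0)
    dp_fraction: float = 0.6
    flow_baseline: float = 5.0  # mm/s
    coupling_gain: float = 0.08  # mm/s per mmHg of mean-pressure deviation
    ppg_amplitude: float = 1.0
    pressure_noise_sd: float = 1.0  # mmHg, slow wander on SP/DP
    flow_noise_sd: float = 0.15  # mm/s
    ppg_noise_sd: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_sp <= self.baseline_dp:
            raise ValueError("baseline SP must exceed baseline DP")
        if self.valsalva_duration <= 0:
            raise ValueError("maneuver duration must be positive")


@dataclass
class MultimodalRecord:
    """Aligned flow (1 Hz), PPG (128 Hz) and reference SP/DP (1 Hz)."""

    flow: np.ndarray
    ppg: np.ndarray
    sp: np.ndarray
    dp: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.flow)
        if len(self.ppg) != PPG_RATE * n:
            raise ValueError("PPG length must be 128 x flow length")
        if not (len(self.sp) == len(self.dp) == n):
            raise ValueError("SP/DP length must match flow length")
        if np.any(self.sp <= self.dp):
            raise ValueError("generated records must satisfy SP > DP everywhere")

    @property
    def duration(self) -> int:
        return len(self.flow)


def _raised_cosine(t: np.ndarray, t0: float, t1: float) -> np.ndarray:
    """Smooth bump: 0 outside [t0, t1], peaking at the interval center."""
    w = np.zeros_like(t)
    inside = (t >= t0) & (t <= t1)
    w[inside] = 0.5 * (1 - np.cos(2 * np.pi * (t[inside] - t0) / (t1 - t0)))
    return w


def _phase_offset(t: np.ndarray, cfg: CardioSyntheticConfig) -> np.ndarray:
    """Four-phase Valsalva pressure deviation (mmHg on SP)."""
    on, dur = cfg.valsalva_onset, cfg.valsalva_duration
    a1, a2, a3, a4 = cfg.phase_amplitudes
    rel = on + dur
    return (
        a1 * _raised_cosine(t, on, on + 0.15 * dur)
        + a2 * _raised_cosine(t, on + 0.10 * dur, rel)
        + a3 * _raised_cosine(t, rel, rel + 10.0)
        + a4 * _raised_cosine(t, rel + 8.0, rel + 30.0)
    )


def _smooth_noise(rng: np.random.Generator, n: int, sd: float,
                  tau: float = 20.0) -> np.ndarray:
    """First-order autoregressive wander at 1 Hz with stationary SD ``sd``."""
    if sd == 0:
        return np.zeros(n)
    rho = np.exp(-1.0 / tau)
    x = np.empty(n)
    x[0] = rng.normal(0, sd)
    innov = rng.normal(0, sd * np.sqrt(1 - rho**2), size=n)
    for i in range(1, n):
        x[i] = rho * x[i - 1] + innov[i]
    return x


def generate_record(cfg: CardioSyntheticConfig, duration: int,
                    rng: np.random.Generator) -> MultimodalRecord:
    if cfg.valsalva_onset + cfg.valsalva_duration > duration:
        raise ValueError("maneuver does not fit in the record length")
    t1 = np.arange(duration, dtype=float)
    off = _phase_offset(t1, cfg)
    sp = cfg.baseline_sp + off + _smooth_noise(rng, duration, cfg.pressure_noise_sd)
    dp = (cfg.baseline_dp + cfg.dp_fraction * off
          + _smooth_noise(rng, duration, cfg.pressure_noise_sd))
    mean_p = (sp + 2.0 * dp) / 3.0
    mean_p0 = (cfg.baseline_sp + 2.0 * cfg.baseline_dp) / 3.0

    flow = (
        cfg.flow_baseline
        + cfg.coupling_gain * (mean_p - mean_p0)
        + rng.normal(0, cfg.flow_noise_sd, size=duration)
    )

    # PPG: two Gaussian lobes per beat (systolic peak + dicrotic hump),
    # amplitude modulated by pulse pressure
    t128 = np.arange(duration * PPG_RATE) / PPG_RATE
    pp = np.interp(t128, t1, sp - dp)
    amp = cfg.ppg_amplitude * pp / (cfg.baseline_sp - cfg.baseline_dp)
    phase = (t128 * cfg.heart_rate) % 1.0
    beat = (
        np.exp(-0.5 * ((phase - 0.25) / 0.08) ** 2)
        + 0.35 * np.exp(-0.5 * ((phase - 0.55) / 0.10) ** 2)
    )
    ppg = amp * beat + rng.normal(0, cfg.ppg_noise_sd, size=len(t128))

    return MultimodalRecord(flow=flow, ppg=ppg, sp=sp, dp=dp)


def generate_cardio_dataset(
    cfg: CardioSyntheticConfig, n_records: int, duration: int = 600
) -> list[MultimodalRecord]:
    """Generate ``n_records`` independent sessions, deterministic under seed.

    Baseline pressures vary mildly between records (inter-subject spread)
    while the maneuver structure is shared.
    """
    records = []
    for i in range(n_records):
        rng = np.random.default_rng(cfg.seed * 100_003 + i)
        cfg_i = CardioSyntheticConfig(
            **{
                **cfg.__dict__,
                "baseline_sp": cfg.baseline_sp + rng.normal(0, 4.0),
                "baseline_dp": cfg.baseline_dp + rng.normal(0, 3.0),
            }
        )
        records.append(generate_record(cfg_i, duration, rng))
    return records
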