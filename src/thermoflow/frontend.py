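"""Thermistor / Wheatstone-bridge signal chain and 20 Hz stream processing.

Models the electrical front end between the probe temperatures and the six
features consumed by the inversion network: NTC thermistor resistances
(beta model), half-bridge differentials against a reference thermistor with
amplification, an exponential moving-average filter (the "smoothing
coefficient" filter), and decimation of the 20 Hz stream to the 1 Hz
inference cadence by 1-s block means.

Two feature modes are provided:

* ``"temperature"`` (default) — the six filtered probe temperatures in deg C,
  in :data:`~thermoflow.solver.CHANNEL_NAMES` order.
* ``"bridge"`` — six amplified bridge differentials that reject the
  common-mode ambient level at each sensing layer:
  ``(V_up, V_dn, V_dnup)`` per layer, where the up/dn channels are bridged
  against the same-layer reference thermistor and ``V_dnup`` bridges the
  downstream against the upstream thermistor (the calorimetric differential
  itself).  All six are invariant to a uniform temperature shift of a layer,
  which is what makes the chain robust to ambient changes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .solver import CHANNEL_NAMES

__all__ = [
    "ThermistorModel",
    "BridgeAmpConfig",
    "SensorStream",
    "thermistor_resistance",
    "bridge_differential",
    "ema_filter",
    "decimate_to_1hz",
    "bridge_features",
    "assemble_features",
]

T0_KELVIN = 273.15


@dataclass(frozen=True)
class ThermistorModel:
    """NTC beta model: R(T) = R0 exp(B (1/T - 1/T_ref)), T in kelvin.

    Defaults describe a 10-kOhm part (R0 at 25 degC) with B = 3380 K,
    typical for small surface-mount NTC thermistors of this class.
    """

    nominal_resistance: float = 10_000.0  # Ohm at reference_temperature
    reference_temperature: float = 298.15  # K
    beta: float = 3380.0  # K

    def __post_init__(self) -> None:
        if self.nominal_resistance <= 0 or self.beta <= 0:
            raise ValueError("R0 and beta must be positive")


@dataclass(frozen=True)
class BridgeAmpConfig:
    """Wheatstone half-bridge pair with a differential amplifier and ADC."""

    supply_voltage: float = 3.3  # V
    fixed_resistance: float = 10_000.0  # Ohm
    gain: float = 100.0
    adc_full_scale: float = 3.3  # V
    adc_bits: int = 12

    def __post_init__(self) -> None:
        if min(self.supply_voltage, self.fixed_resistance, self.gain,
               self.adc_full_scale) <= 0 or self.adc_bits <= 0:
            raise ValueError("all bridge/ADC parameters must be positive")


@dataclass
class SensorStream:
    """Timestamped multichannel sensor record.

    ``values`` has shape (n_samples, n_channels); channel order follows
    CHANNEL_NAMES for raw-temperature streams.  ``units`` records whether
    the samples are temperatures ("degC") or amplified bridge volts ("V").
    """

    sample_rate: float
    timestamps: np.ndarray
    values: np.ndarray
    units: str = "degC"
    channel_names: tuple[str, ...] = field(default_factory=lambda: CHANNEL_NAMES)

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] != self.timestamps.shape[0]:
            raise ValueError("values and timestamps length mismatch")
        if len(self.timestamps) > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]


def thermistor_resistance(T: float | np.ndarray,
                          model: ThermistorModel = ThermistorModel()):
    """NTC resistance (Ohm) at temperature T (deg C)."""
    T = np.asarray(T, dtype=float)
    if np.any(T <= -T0_KELVIN):
        raise ValueError("temperature below absolute zero")
    Tk = T + T0_KELVIN
    R = model.nominal_resistance * np.exp(
        model.beta * (1.0 / Tk - 1.0 / model.reference_temperature)
    )
    return R if R.ndim else float(R)


def bridge_differential(
    T_sense: float | np.ndarray,
    T_ref: float | np.ndarray,
    model: ThermistorModel = ThermistorModel(),
    cfg: BridgeAmpConfig = BridgeAmpConfig(),
):
    """Amplified Wheatstone-bridge differential (V) of sense vs reference.

    Each arm is a divider of the thermistor over (thermistor + fixed R);
    the amplifier outputs gain * Vs * (node_sense - node_ref).  Zero when
    the two temperatures are equal; antisymmetric under swapping.
    """
    Rs = thermistor_resistance(T_sense, model)
    Rr = thermistor_resistance(T_ref, model)
    R = cfg.fixed_resistance
    v = cfg.gain * cfg.supply_voltage * (Rs / (Rs + R) - Rr / (Rr + R))
    return v


def ema_filter(stream: SensorStream, alpha: float = 0.05) -> SensorStream:
    """Exponential moving average, y_t = a x_t + (1-a) y_{t-1}, y_0 = x_0.

    Unity DC gain; ``alpha`` is the smoothing coefficient of the stated
    first-order filter.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    x = stream.values
    if x.shape[0] == 0:
        return SensorStream(stream.sample_rate, stream.timestamps, x,
                            stream.units, stream.channel_names)
    y = np.empty_like(x)
    y[0] = x[0]
    om = 1.0 - alpha
    for t in range(1, x.shape[0]):
        y[t] = alpha * x[t] + om * y[t - 1]
    return SensorStream(stream.sample_rate, stream.timestamps.copy(), y,
                        stream.units, stream.channel_names)


def decimate_to_1hz(stream: SensorStream) -> SensorStream:
    """Average non-overlapping 1-s blocks (20 samples) down to 1 Hz.

    A trailing partial block is dropped.  Emits a warning and an empty
    stream when fewer than 20 samples are available.
    """
    if stream.sample_rate != 20:
        raise ValueError("decimate_to_1hz expects a 20 Hz stream")
    n = stream.n_samples
    nblk = n // 20
    if nblk == 0:
        warnings.warn("fewer than 20 samples: empty 1 Hz stream", stacklevel=2)
        return SensorStream(1.0, np.empty(0), np.empty((0, stream.values.shape[1])),
                            stream.units, stream.channel_names)
    v = stream.values[: nblk * 20].reshape(nblk, 20, -1).mean(axis=1)
    t = stream.timestamps[: nblk * 20].reshape(nblk, 20).mean(axis=1)
    return SensorStream(1.0, t, v, stream.units, stream.channel_names)


def bridge_features(
    temps: np.ndarray,
    model: ThermistorModel = ThermistorModel(),
    cfg: BridgeAmpConfig = BridgeAmpConfig(),
) -> np.ndarray:
    """Map six-channel temperatures to the six bridge-mode features (V).

    Input columns follow CHANNEL_NAMES; output columns are
    (top: up-ref, dn-ref, dn-up, bottom: up-ref, dn-ref, dn-up).
    """
    temps = np.atleast_2d(np.asarray(temps, dtype=float))
    if temps.shape[1] != 6:
        raise ValueError("expected six temperature channels")
    tu, td, tr, bu, bd, br = temps.T
    cols = [
        bridge_differential(tu, tr, model, cfg),
        bridge_differential(td, tr, model, cfg),
        bridge_differential(td, tu, model, cfg),
        bridge_differential(bu, br, model, cfg),
        bridge_differential(bd, br, model, cfg),
        bridge_differential(bd, bu, model, cfg),
    ]
    return np.column_stack(cols)


BRIDGE_CHANNEL_NAMES = (
    "v_top_up", "v_top_dn", "v_top_dnup", "v_bot_up", "v_bot_dn", "v_bot_dnup",
)

DIFF_CHANNEL_NAMES = (
    "dt_top_up", "dt_top_dn", "dt_top_dnup",
    "dt_bot_up", "dt_bot_dn", "dt_bot_dnup",
)


def diff_features(temps: np.ndarray) -> np.ndarray:
    """Reference-compensated temperature differentials (deg C).

    Per layer: (up - ref, dn - ref, dn - up).  These are the digital
    equivalent of the Wheatstone-bridge differentials after thermistor
    linearization; under a uniform shift of every boundary temperature the
    steady heat equation shifts its whole solution by the same constant, so
    these features are exactly ambient-invariant.
    """
    temps = np.atleast_2d(np.asarray(temps, dtype=float))
    if temps.shape[1] != 6:
        raise ValueError("expected six temperature channels")
    tu, td, tr, bu, bd, br = temps.T
    return np.column_stack([tu - tr, td - tr, td - tu,
                            bu - br, bd - br, bd - bu])


def assemble_features(
    probe_temps: np.ndarray,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    mode: str = "temperature",
    alpha: float = 0.05,
    model: ThermistorModel = ThermistorModel(),
    cfg: BridgeAmpConfig = BridgeAmpConfig(),
) -> SensorStream:
    """Full chain: noise -> (bridge) -> EMA -> 1 Hz decimation.

    ``probe_temps`` is an (n_ticks, 6) array of 20 Hz probe temperatures in
    CHANNEL_NAMES order.  Returns the 1 Hz feature stream whose ``units``
    metadata records the feature semantics.
    """
    probe_temps = np.atleast_2d(np.asarray(probe_temps, dtype=float))
    if probe_temps.shape[1] != 6:
        raise ValueError("channel-order contract: expected 6 channels")
    x = probe_temps
    if noise_sd > 0:
        if rng is None:
            raise ValueError("noise requested but no rng supplied")
        x = x + rng.normal(0.0, noise_sd, size=x.shape)
    if mode == "bridge":
        x = bridge_features(x, model, cfg)
        units, names = "V", BRIDGE_CHANNEL_NAMES
    elif mode == "temperature":
        units, names = "degC", CHANNEL_NAMES
    else:
        raise ValueError("mode must be 'temperature' or 'bridge'")
    t = np.arange(x.shape[0]) / 20.0
    stream = SensorStream(20.0, t, x, units, names)
    return decimate_to_1hz(ema_filter(stream, alpha))
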