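"""Seeded gait-like pressure simulation with known redundancy groups.

Stands in for clinical strip data: each redundancy group shares one latent
periodic waveform (a raised, asymmetric stance/swing pulse train with small
per-cycle period jitter); a sensor reads its group waveform through a
per-sensor gain plus Gaussian noise, clamped to the device ceiling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .io_framing import SensorRecording

__all__ = ["GaitSimConfig", "simulate_recording", "paper_like_fixture"]

# Pulse shape constants: stance occupies this fraction of the cycle, raised
# to a power for a peaky stance / flat swing profile.
_STANCE_FRACTION = 0.62
_STANCE_POWER = 2.0


@dataclass(frozen=True)
class GaitSimConfig:
    """Parameters of the synthetic multi-sensor gait recording.

    ``group_assignment[i]`` is the redundancy-group id of sensor ``i``;
    per-group amplitude/baseline/phase control the latent waveforms and
    per-sensor gains scale them.  The default parameterization mimics a
    10-sensor strip sampled at 100 Hz for 30 s at ~0.9 cycles/s (4-5 gait
    cycles per 5 s frame) with a 64 kPa ceiling.
    """

    n_sensors: int = 10
    group_assignment: tuple[int, ...] = (0, 0, 1, 1, 1, 0, 1, 1, 1, 1)
    sampling_rate: float = 100.0
    duration: float = 30.0
    cadence: float = 0.9
    group_amplitude: Mapping[int, float] = field(
        default_factory=lambda: {0: 40.0, 1: 70.0}
    )
    group_baseline: Mapping[int, float] = field(
        default_factory=lambda: {0: 3.0, 1: 5.0}
    )
    group_phase: Mapping[int, float] = field(
        default_factory=lambda: {0: 0.0, 1: 0.35}
    )
    sensor_gain: tuple[float, ...] | None = None
    noise_sd: float = 1.0
    ceiling: float = 64.0
    period_jitter: float = 0.05
    sensor_labels: tuple[str, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sensors < 1:
            raise ValueError("n_sensors must be >= 1")
        if len(self.group_assignment) != self.n_sensors:
            raise ValueError(
                f"group_assignment covers {len(self.group_assignment)} sensors,"
                f" expected {self.n_sensors}"
            )
        for g in self.group_assignment:
            for mapping, name in (
                (self.group_amplitude, "group_amplitude"),
                (self.group_baseline, "group_baseline"),
                (self.group_phase, "group_phase"),
            ):
                if g not in mapping:
                    raise ValueError(f"group {g} missing from {name}")
        if not self.cadence > 0:
            raise ValueError("cadence must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0 <= self.period_jitter < 1:
            raise ValueError("period_jitter must lie in [0, 1)")
        if not self.ceiling > 0:
            raise ValueError("ceiling must be > 0")
        if self.sensor_gain is not None and len(self.sensor_gain) != self.n_sensors:
            raise ValueError("one gain per sensor required")
        if self.sensor_labels is not None:
            if len(self.sensor_labels) != self.n_sensors:
                raise ValueError("one label per sensor required")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.sampling_rate))

    @property
    def labels(self) -> tuple[str, ...]:
        if self.sensor_labels is not None:
            return tuple(self.sensor_labels)
        return tuple(str(i + 1) for i in range(self.n_sensors))


def _gait_phase(cfg: GaitSimConfig, rng: np.random.Generator) -> np.ndarray:
    """Cumulative gait phase (in cycles) at every sample time.

    Cycle periods are jittered independently by up to ``period_jitter`` of
    the nominal period, so the cycle count per window varies slightly.
    """
    n = cfg.n_samples
    dt = 1.0 / cfg.sampling_rate
    nominal = 1.0 / cfg.cadence
    # Enough jittered cycles to cover the recording even at the longest draw.
    n_cycles = int(np.ceil(cfg.duration / (nominal * (1 - cfg.period_jitter)))) + 2
    periods = nominal * (
        1.0 + cfg.period_jitter * rng.uniform(-1.0, 1.0, size=n_cycles)
    )
    boundaries = np.concatenate([[0.0], np.cumsum(periods)])
    t = np.arange(n) * dt
    cycle_idx = np.searchsorted(boundaries, t, side="right") - 1
    frac = (t - boundaries[cycle_idx]) / periods[cycle_idx]
    return cycle_idx + frac


def _pulse(phase: np.ndarray) -> np.ndarray:
    """Unit pulse train: peaky stance lobe, flat swing, per cycle phase."""
    frac = np.mod(phase, 1.0)
    stance = frac < _STANCE_FRACTION
    out = np.zeros_like(frac)
    out[stance] = np.sin(np.pi * frac[stance] / _STANCE_FRACTION) ** _STANCE_POWER
    return out


def simulate_recording(cfg: GaitSimConfig) -> SensorRecording:
    """Generate one seeded recording; identical config => identical output.

    Sensor ``s`` in group ``g`` reads
    ``clamp(gain_s * w_g(t) + noise, 0, ceiling)`` where
    ``w_g(t) = baseline_g + amplitude_g * pulse(phase(t) + phase_g)``.
    """
    rng = np.random.default_rng(cfg.seed)
    phase = _gait_phase(cfg, rng)
    group_ids = sorted(set(cfg.group_assignment))
    waveforms = {
        g: cfg.group_baseline[g]
        + cfg.group_amplitude[g] * _pulse(phase + cfg.group_phase[g])
        for g in group_ids
    }
    gains = (
        np.asarray(cfg.sensor_gain, dtype=float)
        if cfg.sensor_gain is not None
        else np.ones(cfg.n_sensors)
    )
    readings = np.empty((cfg.n_samples, cfg.n_sensors))
    for s, g in enumerate(cfg.group_assignment):
        noise = (
            rng.normal(0.0, cfg.noise_sd, size=cfg.n_samples)
            if cfg.noise_sd > 0
            else 0.0
        )
        readings[:, s] = gains[s] * waveforms[g] + noise
    np.clip(readings, 0.0, cfg.ceiling, out=readings)
    return SensorRecording(
        sensor_labels=cfg.labels,
        readings=readings,
        sampling_rate=cfg.sampling_rate,
        reading_range=(0.0, cfg.ceiling),
    )


def paper_like_fixture(
    seed: int, noise_sd: float = 1.0, period_jitter: float = 0.05
) -> SensorRecording:
    """A 10-sensor, 3000-sample strip with groups {1,2,6} and {3,4,5,7,8,9,10}.

    Sensors are labeled "1".."10"; the larger group is driven into 64 kPa
    saturation at its pulse peaks; per-sensor gains vary moderately, drawn
    from the same seed so the fixture is fully deterministic.
    """
    gain_rng = np.random.default_rng(np.random.default_rng(seed).integers(2**32))
    gains = tuple(gain_rng.uniform(0.98, 1.02, size=10))
    cfg = GaitSimConfig(
        sensor_gain=gains,
        noise_sd=noise_sd,
        period_jitter=period_jitter,
        seed=seed,
    )
    return simulate_recording(cfg)
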