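"""Input-current trains for the network and luminance flicker trains.

Three drive shapes are used throughout: constant currents, broadband
(uniform-noise) currents, and sinusoidal currents.  The broadband drive
mimics fluctuating thalamic input and is the regressor for TRF
estimation, so the exact delivered noise trace is stored on the train.
Flicker trains emulate a projector modulating stimulus luminance with
i.i.d. uniform noise at a high refresh rate (1440 Hz by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "StimulusTrain",
    "FlickerTrain",
    "constant_drive",
    "broadband_drive",
    "sinusoidal_drive",
    "flicker_signal",
]

BROADBAND_DIALECTS = ("centered", "positive", "wide")


@dataclass
class StimulusTrain:
    """Time-resolved currents delivered to the E and I populations.

    ``i_e`` is delivered identically to every E cell and ``i_i`` to
    every I cell.  For broadband drives, ``shared_noise_trace`` holds
    the single zero-mean noise realization added to the E drive so that
    TRF estimation can regress against exactly the delivered input.
    """

    time: np.ndarray
    i_e: np.ndarray
    i_i: np.ndarray
    kind: str
    params: dict = field(default_factory=dict)
    shared_noise_trace: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not (len(self.time) == len(self.i_e) == len(self.i_i)):
            raise ValueError("time, i_e and i_i must share one time axis")

    @property
    def dt(self) -> float:
        return float(self.time[1] - self.time[0]) if len(self.time) > 1 else 1.0

    @property
    def duration_ms(self) -> float:
        return len(self.time) * self.dt

    def to_csv(self, path: str | Path) -> None:
        """Two-column export (time_ms, value) per channel, reloadable bit-exactly."""
        df = pd.DataFrame({"time_ms": self.time, "i_e": self.i_e, "i_i": self.i_i})
        if self.shared_noise_trace is not None:
            df["noise"] = self.shared_noise_trace
        df.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path: str | Path, kind: str = "loaded") -> "StimulusTrain":
        df = pd.read_csv(path, float_precision="round_trip")
        return cls(
            time=df["time_ms"].to_numpy(),
            i_e=df["i_e"].to_numpy(),
            i_i=df["i_i"].to_numpy(),
            kind=kind,
            shared_noise_trace=df["noise"].to_numpy() if "noise" in df else None,
        )


def _time_axis(duration_ms: float, dt: float) -> np.ndarray:
    if duration_ms <= 0:
        raise ValueError("duration must be positive")
    n = int(round(duration_ms / dt))
    return np.arange(n) * dt


def constant_drive(
    i_e: float = 12.25,
    i_i: float = 5.25,
    duration_ms: float = 8000.0,
    dt: float = 1.0,
) -> StimulusTrain:
    """Time-invariant currents to both populations."""
    t = _time_axis(duration_ms, dt)
    return StimulusTrain(
        time=t,
        i_e=np.full(len(t), float(i_e)),
        i_i=np.full(len(t), float(i_i)),
        kind="constant",
        params={"i_e": i_e, "i_i": i_i},
    )


def broadband_drive(
    i0_e: float = 12.25,
    amplitude: float = 4.0,
    i_i: float = 5.25,
    duration_ms: float = 8000.0,
    dt: float = 1.0,
    seed: int | np.random.Generator | None = None,
    dialect: str = "centered",
) -> StimulusTrain:
    """Constant E drive plus uniform noise, constant I drive.

    One fresh noise sample is drawn per integration step and delivered
    identically to all E cells.  ``amplitude`` is interpreted through
    ``dialect``:

    - ``"centered"`` (default): zero-mean Uniform[-A/2, +A/2], so the
      mean operating point stays at ``i0_e``;
    - ``"positive"``: Uniform[0, A];
    - ``"wide"``: Uniform[-A, +A].
    """
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    if dialect not in BROADBAND_DIALECTS:
        raise ValueError(f"unknown broadband dialect {dialect!r}; use one of {BROADBAND_DIALECTS}")
    rng = np.random.default_rng(seed)
    t = _time_axis(duration_ms, dt)
    if dialect == "centered":
        noise = rng.uniform(-amplitude / 2.0, amplitude / 2.0, len(t))
    elif dialect == "positive":
        noise = rng.uniform(0.0, amplitude, len(t))
    else:
        noise = rng.uniform(-amplitude, amplitude, len(t))
    if amplitude == 0:
        noise = np.zeros(len(t))
    return StimulusTrain(
        time=t,
        i_e=i0_e + noise,
        i_i=np.full(len(t), float(i_i)),
        kind="broadband",
        params={"i0_e": i0_e, "amplitude": amplitude, "i_i": i_i, "dialect": dialect},
        shared_noise_trace=noise,
    )


def sinusoidal_drive(
    i0_e: float = 12.25,
    amplitude: float = 9.0,
    frequency: float = 48.0,
    i_i: float = 5.25,
    duration_ms: float = 8000.0,
    dt: float = 1.0,
) -> StimulusTrain:
    """Constant E drive plus a sine wave, constant I drive."""
    nyquist = 1000.0 / (2.0 * dt)
    if not 0 < frequency < nyquist:
        raise ValueError(f"frequency must lie in (0, {nyquist:g}) Hz for dt={dt:g} ms")
    t = _time_axis(duration_ms, dt)
    wave = amplitude * np.sin(2.0 * np.pi * frequency * t / 1000.0)
    return StimulusTrain(
        time=t,
        i_e=i0_e + wave,
        i_i=np.full(len(t), float(i_i)),
        kind="sinusoidal",
        params={"i0_e": i0_e, "amplitude": amplitude, "frequency": frequency, "i_i": i_i},
    )


@dataclass
class FlickerTrain:
    """I.i.d. Uniform[0, 1] luminance samples at a fixed refresh rate."""

    time: np.ndarray  # seconds
    luminance: np.ndarray
    rate: float
    seed: int | None = None

    def resample_hold(self, fs_out: float) -> np.ndarray:
        """Zero-order-hold resampling to an analysis rate (projector-style).

        Each output sample takes the value of the flicker frame being
        displayed at that instant.
        """
        duration = len(self.luminance) / self.rate
        n_out = int(round(duration * fs_out))
        idx = np.minimum(
            (np.arange(n_out) / fs_out * self.rate).astype(int),
            len(self.luminance) - 1,
        )
        return self.luminance[idx]


def flicker_signal(
    duration_s: float,
    rate: float = 1440.0,
    seed: int | np.random.Generator | None = None,
) -> FlickerTrain:
    """Broadband luminance flicker: i.i.d. Uniform[0, 1] at ``rate`` Hz."""
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate))
    return FlickerTrain(
        time=np.arange(n) / rate,
        luminance=rng.uniform(0.0, 1.0, n),
        rate=float(rate),
        seed=seed if isinstance(seed, int) else None,
    )
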