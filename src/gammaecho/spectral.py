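"""Spectral estimation: Welch PSD, Hann-taper time-frequency maps,
peak-frequency extraction and relative power change."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "PSDResult",
    "TFRResult",
    "welch_psd",
    "average_psds",
    "peak_frequency",
    "tfr_hanning",
    "relative_power",
]


@dataclass
class PSDResult:
    """Welch power spectral density."""

    freqs: np.ndarray
    power: np.ndarray
    n_segments: int
    n_trials_averaged: int = 1

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"freq_hz": self.freqs, "power": self.power}).to_csv(
            path, index=False
        )


@dataclass
class TFRResult:
    """Time-frequency power map with frequency-dependent window length.

    The window at frequency ``f`` spans ``cycles_per_window / f``
    seconds; positions where the window does not fit inside the signal
    are masked (NaN).
    """

    times: np.ndarray
    freqs: np.ndarray
    power: np.ndarray  # time x frequency
    cycles_per_window: float

    def to_frame(self) -> pd.DataFrame:
        t, f = np.meshgrid(self.times, self.freqs, indexing="ij")
        return pd.DataFrame(
            {"time_s": t.ravel(), "freq_hz": f.ravel(), "power": self.power.ravel()}
        )


def welch_psd(
    x: np.ndarray,
    fs: float,
    segment_s: float = 1.0,
    overlap: float = 0.5,
    detrend: str = "constant",
) -> PSDResult:
    """Welch PSD: Hann-tapered overlapping segment periodograms, averaged.

    Defaults follow the standard 1 s segment / 50 % overlap convention,
    giving 1 Hz frequency resolution at any sampling rate.
    """
    x = np.asarray(x, dtype=float)
    nperseg = int(round(segment_s * fs))
    if len(x) < nperseg:
        raise ValueError(
            f"signal ({len(x)} samples) shorter than one {nperseg}-sample segment"
        )
    noverlap = int(round(overlap * nperseg))
    freqs, power = sps.welch(
        x, fs=fs, window="hann", nperseg=nperseg, noverlap=noverlap, detrend=detrend
    )
    step = nperseg - noverlap
    n_segments = 1 + (len(x) - nperseg) // step
    return PSDResult(freqs=freqs, power=power, n_segments=n_segments)


def average_psds(psds: list[PSDResult]) -> PSDResult:
    """Average PSDs over trials (all on one frequency grid)."""
    if not psds:
        raise ValueError("no PSDs to average")
    f0 = psds[0].freqs
    for p in psds[1:]:
        if not np.array_equal(p.freqs, f0):
            raise ValueError("PSDs are on different frequency grids")
    return PSDResult(
        freqs=f0,
        power=np.mean([p.power for p in psds], axis=0),
        n_segments=psds[0].n_segments,
        n_trials_averaged=len(psds),
    )


def peak_frequency(psd: PSDResult, band: tuple[float, float]) -> tuple[float, float]:
    """Frequency and power of the maximum within ``band``.

    Ties are broken toward the lower frequency.
    """
    mask = (psd.freqs >= band[0]) & (psd.freqs <= band[1])
    if not mask.any():
        raise ValueError(f"band {band} does not intersect the frequency grid")
    sub_f = psd.freqs[mask]
    sub_p = psd.power[mask]
    i = int(np.argmax(sub_p))  # argmax returns the first (lowest-frequency) maximum
    return float(sub_f[i]), float(sub_p[i])


def tfr_hanning(
    x: np.ndarray,
    fs: float,
    freqs: np.ndarray | None = None,
    cycles: float = 5.0,
    times: np.ndarray | None = None,
    t0: float = 0.0,
) -> TFRResult:
    """Hann-taper time-frequency power with a fixed number of cycles.

    At each (time, frequency) point the signal segment of length
    ``cycles / f`` seconds centred there is Hann-tapered and projected
    on a complex exponential; power is the squared amplitude estimate
    (the projection normalized by the taper sum, so a unit tone gives
    unit power at its own frequency regardless of window length).
    ``t0`` is the time of the first sample of ``x``; the default
    ``times`` grid spans -0.1 to 0.2 s in 5 ms steps.

    Points whose window extends outside the signal are NaN-masked.
    """
    x = np.asarray(x, dtype=float)
    if freqs is None:
        freqs = np.arange(5.0, 101.0, 1.0)
    freqs = np.asarray(freqs, dtype=float)
    if times is None:
        times = np.arange(-0.1, 0.2001, 0.005)
    times = np.asarray(times, dtype=float)
    power = np.full((len(times), len(freqs)), np.nan)
    n = len(x)
    for j, f in enumerate(freqs):
        w = int(round(cycles / f * fs))
        if w < 2 or w > n:
            continue
        taper = np.hanning(w)
        phase = np.exp(-2j * np.pi * f * np.arange(w) / fs)
        probe = taper * phase
        norm = 2.0 / taper.sum()
        half = w // 2
        for i, t in enumerate(times):
            center = int(round((t - t0) * fs))
            start = center - half
            if start < 0 or start + w > n:
                continue
            power[i, j] = np.abs(norm * np.dot(x[start : start + w], probe)) ** 2
    return TFRResult(times=times, freqs=freqs, power=power, cycles_per_window=cycles)


def relative_power(p_stim, p_base):
    """Relative power change ``(P_st - P_bl) / (P_st + P_bl)`` in [-1, 1].

    Positions where both powers are zero are undefined and masked (NaN).
    """
    p_stim = np.asarray(p_stim, dtype=float)
    p_base = np.asarray(p_base, dtype=float)
    if np.any(p_stim < 0) or np.any(p_base < 0):
        raise ValueError("powers must be non-negative")
    total = p_stim + p_base
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, (p_stim - p_base) / total, np.nan)
    return float(out) if out.ndim == 0 else out
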