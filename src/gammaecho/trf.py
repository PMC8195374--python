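"""Temporal response functions by ridge regression.

The TRF is the linear kernel relating a stimulus train to a response
signal, estimated as

    TRF = (S'S + lambda I)^-1 S'x

where S is the time-lagged stimulus matrix.  For a temporally white
stimulus this reduces to a scaled cross-correlation.  The smoothing
constant defaults to lambda = 1 in raw units; stimulus and response are
mean-centered per trial (no variance scaling) before the fit.

Normal equations are accumulated over trials and over chunks of long
recordings, so memory stays bounded, and the system is solved with a
symmetric positive-definite solve rather than an explicit inverse.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.linalg import LinAlgError, solve

__all__ = [
    "LagDesign",
    "TRFResult",
    "build_lagged_matrix",
    "estimate_trf",
    "bandpass_kernel",
    "echo_peak_frequency",
    "decay_time",
]


@dataclass(frozen=True)
class LagDesign:
    """Lag window for the lagged stimulus matrix.

    ``tmin_ms`` may be negative (acausal lags).  The number of lags is
    ``round((tmax - tmin) fs / 1000) + 1``.
    """

    tmin_ms: float = -100.0
    tmax_ms: float = 300.0
    fs: float = 1000.0

    def __post_init__(self) -> None:
        if not self.tmin_ms < self.tmax_ms:
            raise ValueError("tmin must be smaller than tmax")
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_lags(self) -> int:
        return int(round((self.tmax_ms - self.tmin_ms) * self.fs / 1000.0)) + 1

    @property
    def lags_ms(self) -> np.ndarray:
        return self.tmin_ms + np.arange(self.n_lags) * 1000.0 / self.fs

    @property
    def lag_samples(self) -> np.ndarray:
        return np.round(self.lags_ms * self.fs / 1000.0).astype(int)


@dataclass
class TRFResult:
    """Estimated kernel over the lag axis, plus band-filtered views."""

    lags_ms: np.ndarray
    kernel: np.ndarray
    lam: float
    fs: float
    band_views: dict[str, np.ndarray] = field(default_factory=dict)

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame({"lag_ms": self.lags_ms, "raw": self.kernel})
        for name, view in self.band_views.items():
            df[name] = view
        df.to_csv(path, index=False)

    def to_json(self, path: str | Path) -> None:
        """Metadata sidecar: ridge constant, sampling rate, band names."""
        import json

        meta = {"lam": self.lam, "fs": self.fs, "bands": list(self.band_views)}
        Path(path).write_text(json.dumps(meta, indent=2))


def build_lagged_matrix(stimulus: np.ndarray, design: LagDesign) -> np.ndarray:
    """Time x lags matrix; column ``l`` is the stimulus delayed by lag ``l``.

    Out-of-range samples are zero-padded, so row ``t`` of column ``l``
    holds ``stimulus[t - lag_l]`` and the rows align with the response
    time axis.
    """
    stimulus = np.asarray(stimulus, dtype=float)
    n = len(stimulus)
    if n <= design.n_lags:
        raise ValueError(
            f"stimulus ({n} samples) must be longer than the lag window "
            f"({design.n_lags} lags)"
        )
    out = np.zeros((n, design.n_lags))
    for k, lag in enumerate(design.lag_samples):
        if lag >= 0:
            out[lag:, k] = stimulus[: n - lag] if lag else stimulus
        else:
            out[:lag, k] = stimulus[-lag:]
    return out


def _as_trials(x) -> list[np.ndarray]:
    x = x if isinstance(x, (list, tuple)) else [x]
    return [np.asarray(tr, dtype=float) for tr in x]


def estimate_trf(
    stimulus,
    response,
    design: LagDesign | None = None,
    lam: float = 1.0,
    center: bool = True,
    chunk: int = 20000,
) -> TRFResult:
    """Ridge-regression TRF between stimulus and response.

    ``stimulus`` and ``response`` may each be a single array or a
    sequence of equal-length trial arrays; normal equations are
    accumulated across trials before a single solve.  The first and
    last lag-window of each trial is excluded from the solve to avoid
    zero-padding bias at trial edges.

    Raises a ``LinAlgError`` advising ``lam > 0`` if the system is
    singular at ``lam = 0``.
    """
    if design is None:
        design = LagDesign()
    if lam < 0:
        raise ValueError("lam must be non-negative")
    stim_trials = _as_trials(stimulus)
    resp_trials = _as_trials(response)
    if len(stim_trials) != len(resp_trials):
        raise ValueError("stimulus and response trial counts differ")
    p = design.n_lags
    sts = np.zeros((p, p))
    stx = np.zeros(p)
    for s, x in zip(stim_trials, resp_trials):
        if len(s) != len(x):
            raise ValueError("stimulus and response must have equal length")
        if center:
            s = s - s.mean()
            x = x - x.mean()
        n = len(s)
        lo, hi = p, n - p
        if hi <= lo:
            raise ValueError("trial too short for the lag window")
        for start in range(lo, hi, chunk):
            stop = min(start + chunk, hi)
            rows = _lagged_rows(s, design, start, stop)
            sts += rows.T @ rows
            stx += rows.T @ x[start:stop]
    try:
        kernel = solve(sts + lam * np.eye(p), stx, assume_a="pos")
    except LinAlgError as err:
        raise LinAlgError(
            "singular lagged-stimulus system; use a ridge constant lam > 0"
        ) from err
    return TRFResult(lags_ms=design.lags_ms, kernel=kernel, lam=lam, fs=design.fs)


def _lagged_rows(s: np.ndarray, design: LagDesign, start: int, stop: int) -> np.ndarray:
    """Rows [start, stop) of the lagged matrix without materializing it all."""
    n = len(s)
    rows = np.empty((stop - start, design.n_lags))
    t = np.arange(start, stop)
    for k, lag in enumerate(design.lag_samples):
        idx = t - lag
        valid = (idx >= 0) & (idx < n)
        col = np.zeros(stop - start)
        col[valid] = s[idx[valid]]
        rows[:, k] = col
    return rows


def bandpass_kernel(
    trf: TRFResult, band: tuple[float, float], order: int = 6, name: str | None = None
) -> np.ndarray:
    """Zero-phase band-pass of the kernel; stored under ``band_views``.

    Forward-backward Butterworth filtering, so the filtered kernel has
    no phase shift relative to the raw one.
    """
    lo, hi = band
    if not 0 < lo < hi < trf.fs / 2:
        raise ValueError(f"band {band} outside (0, {trf.fs / 2:g}) Hz")
    sos = sps.butter(order, [lo, hi], btype="band", fs=trf.fs, output="sos")
    filtered = sps.sosfiltfilt(sos, trf.kernel)
    trf.band_views[name or f"{lo:g}-{hi:g}Hz"] = filtered
    return filtered


def echo_peak_frequency(
    trf: TRFResult,
    band: tuple[float, float] = (40.0, 100.0),
    window_ms: tuple[float, float] = (0.0, 160.0),
    n_fft: int = 8192,
    smooth_hz: float = 2.0,
    centroid_halfwidth_hz: float = 6.0,
    guard_hz: float = 15.0,
) -> float:
    """Dominant frequency of the band-limited echo in a lag window.

    The kernel is zero-phase filtered with a guard band extending
    ``guard_hz`` beyond ``band`` on each side (so the filter skirt does
    not bias echoes near the band edge), windowed to ``window_ms``, and
    its zero-padded power spectrum searched within ``band``.  Three
    refinements make the estimate robust for noisy kernels:

    - a linear noise floor, fitted away from the peak, is subtracted;
    - the peak location is the power centroid over
      ``±centroid_halfwidth_hz`` around the maximum;
    - the spectral peak of a damped oscillation sits below its true
      frequency by the damping shift, so the envelope decay rate
      ``gamma = 1/(2 pi tau)`` is estimated from the high-amplitude
      part of the Hilbert envelope and ``f = sqrt(f_peak^2 + gamma^2)``
      returned.

    Raises if the window lies outside the lag range or if the kernel
    has no appreciable power in ``band``.
    """
    if window_ms[0] < trf.lags_ms[0] or window_ms[1] > trf.lags_ms[-1]:
        raise ValueError("analysis window outside the lag range")
    lo, hi = band
    if not 0 < lo < hi < trf.fs / 2:
        raise ValueError(f"band {band} outside (0, {trf.fs / 2:g}) Hz")
    fs = trf.fs
    filt = (max(lo - guard_hz, 1.0), min(hi + guard_hz, fs / 2 - 1.0))
    sos = sps.butter(6, filt, btype="band", fs=fs, output="sos")
    kg = sps.sosfiltfilt(sos, trf.kernel)
    mask = (trf.lags_ms >= window_ms[0]) & (trf.lags_ms <= window_ms[1])
    seg = kg[mask]
    raw = trf.kernel[mask]
    if not np.any(seg) or not np.any(raw):
        raise ValueError("kernel is zero everywhere in the analysis window")
    in_band_view = bandpass_kernel(trf, band)[mask]
    if np.sum(in_band_view**2) < 1e-2 * np.sum(raw**2):
        raise ValueError(
            f"no appreciable kernel power in the {lo:g}-{hi:g} Hz band"
        )
    spec = np.abs(np.fft.rfft(seg, n_fft)) ** 2
    freqs = np.fft.rfftfreq(n_fft, 1.0 / fs)
    if smooth_hz:
        w = max(1, int(round(smooth_hz / (fs / n_fft))))
        spec = np.convolve(spec, np.ones(w) / w, mode="same")
    ext = (freqs >= lo - 10.0) & (freqs <= hi + 10.0)
    fe, se = freqs[ext], spec[ext]
    in_band = (fe >= lo) & (fe <= hi)
    f_provisional = fe[in_band][np.argmax(se[in_band])]
    away = np.abs(fe - f_provisional) > 12.0
    if away.sum() >= 10:
        floor = np.polyfit(fe[away], se[away], 1)
        se = np.clip(se - np.polyval(floor, fe), 0.0, None)
    f_peak = fe[in_band][np.argmax(se[in_band])]
    near = np.abs(fe - f_peak) <= centroid_halfwidth_hz
    f_centroid = float(np.sum(fe[near] * se[near]) / np.sum(se[near]))
    # damping shift correction from the envelope of the filtered kernel
    env = np.abs(sps.hilbert(kg))[mask]
    ip = int(np.argmax(env))
    tail = env[ip:]
    lags_tail = trf.lags_ms[mask][ip:]
    if len(tail) >= 10:
        # amplitude-weighted fit: the high-envelope part dominates, so
        # the estimate tracks the echo rather than the noise floor
        slope = np.polyfit(
            lags_tail[4:], np.log(np.maximum(tail[4:], 1e-15)), 1, w=tail[4:]
        )[0]
        if slope < 0:
            gamma = 1000.0 / (2.0 * np.pi * (-1.0 / slope))
            f_centroid = float(np.sqrt(f_centroid**2 + gamma**2))
    return f_centroid


def decay_time(
    trf: TRFResult,
    band: tuple[float, float] = (40.0, 100.0),
    window_ms: tuple[float, float] = (0.0, 200.0),
    method: str = "fit",
) -> float:
    """Decay time constant (ms) of the band-limited echo envelope.

    ``method="fit"`` (default) fits a line to the log Hilbert envelope
    from just past the envelope peak to the end of the window and
    returns the negative inverse slope; robust against the noise floor.
    ``method="crossing"`` returns the lag past the peak at which the
    envelope first falls below ``peak / e``.
    """
    filtered = bandpass_kernel(trf, band)
    env = np.abs(sps.hilbert(filtered))
    mask = (trf.lags_ms >= window_ms[0]) & (trf.lags_ms <= window_ms[1])
    e = env[mask]
    lags = trf.lags_ms[mask]
    ip = int(np.argmax(e))
    if method == "crossing":
        below = np.flatnonzero(e[ip:] < e[ip] / np.e)
        if below.size == 0:
            return float("nan")
        return float(lags[ip + below[0]] - lags[ip])
    if method != "fit":
        raise ValueError("method must be 'fit' or 'crossing'")
    start = min(ip + 5, len(e) - 2)
    y = np.log(np.maximum(e[start:], 1e-15))
    slope = np.polyfit(lags[start:], y, 1)[0]
    if slope >= 0:
        return float("inf")
    return float(-1.0 / slope)
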