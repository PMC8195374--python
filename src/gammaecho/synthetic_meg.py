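"""Synthetic MEG-like flicker-response signals with known echoes.

A visual-cortex channel responding to broadband luminance flicker is
emulated by convolving the flicker train with a ground-truth kernel —
the sum of a short damped gamma oscillation (the "gamma echo", onset
around 40 ms, 2-3 visible cycles) and a longer damped alpha oscillation
(the classic perceptual echo, onset around 200 ms) — and adding 1/f
background noise plus an optional 50 Hz line component.  Because the
embedded kernel is known exactly, the TRF and spectral stages can be
validated by parameter recovery without any recorded data.

The flicker is generated at the projector refresh rate (1440 Hz) and
zero-order-held down to the 1000 Hz analysis rate, reproducing the rate
mismatch present in a real recording.  Signal-to-noise is parameterized
as the ratio of kernel-response variance to noise variance within
1-100 Hz; the default 0.1 emulates a weak cortical response.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
import json

import numpy as np
import pandas as pd
from scipy import signal as sps

from .stimuli import FlickerTrain, flicker_signal

__all__ = [
    "EchoKernelSpec",
    "NoiseSpec",
    "SyntheticTrial",
    "make_echo_kernel",
    "generate_response",
]


@dataclass(frozen=True)
class EchoKernelSpec:
    """Parameters of the embedded damped-sinusoid echoes.

    Each echo is ``A exp(-(t - t0)/tau) sin(2 pi f (t - t0))`` for
    ``t >= t0`` and zero before its onset latency ``t0``.
    """

    gamma_freq: float = 48.0
    gamma_latency_ms: float = 40.0
    gamma_decay_ms: float = 20.0
    gamma_amp: float = 1.0
    alpha_freq: float = 10.0
    alpha_latency_ms: float = 200.0
    alpha_decay_ms: float = 300.0
    alpha_amp: float = 0.5

    def __post_init__(self) -> None:
        if self.gamma_freq <= 0 or self.alpha_freq <= 0:
            raise ValueError("echo frequencies must be positive")
        if self.gamma_latency_ms < 0 or self.alpha_latency_ms < 0:
            raise ValueError("latencies must be non-negative")
        if self.gamma_decay_ms <= 0 or self.alpha_decay_ms <= 0:
            raise ValueError("decay constants must be positive")


@dataclass(frozen=True)
class NoiseSpec:
    """Background noise: power-law (1/f) plus sinusoidal line component.

    ``pink_amp`` and ``line_amp`` set the relative weight of the two
    components; the mixture as a whole is rescaled to the requested
    signal-to-noise ratio by :func:`generate_response`.
    """

    pink_exponent: float = 1.0
    pink_amp: float = 1.0
    line_freq: float = 50.0
    line_amp: float = 0.2
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.pink_amp < 0 or self.line_amp < 0:
            raise ValueError("noise amplitudes must be non-negative")


@dataclass
class SyntheticTrial:
    """One stimulus/response pair with its ground truth attached."""

    stimulus: np.ndarray
    response: np.ndarray
    fs: float
    kernel: np.ndarray
    kernel_lags_ms: np.ndarray
    spec: EchoKernelSpec
    noise: NoiseSpec
    snr: float

    def to_csv(self, prefix: str | Path) -> None:
        prefix = Path(prefix)
        t = np.arange(len(self.stimulus)) / self.fs
        pd.DataFrame({"time_s": t, "stimulus": self.stimulus}).to_csv(
            prefix.with_suffix(".stimulus.csv"), index=False
        )
        pd.DataFrame({"time_s": t, "response": self.response}).to_csv(
            prefix.with_suffix(".response.csv"), index=False
        )
        truth = {
            "fs": self.fs,
            "snr": self.snr,
            "kernel_spec": self.spec.__dict__,
            "noise_spec": {k: v for k, v in self.noise.__dict__.items()},
        }
        prefix.with_suffix(".truth.json").write_text(json.dumps(truth, indent=2))


def make_echo_kernel(
    spec: EchoKernelSpec, lags_ms: np.ndarray, fs: float
) -> np.ndarray:
    """Ground-truth kernel over ``lags_ms``: two causal damped sinusoids."""
    lags_ms = np.asarray(lags_ms, dtype=float)
    if spec.gamma_latency_ms > lags_ms[-1] or spec.alpha_latency_ms > lags_ms[-1]:
        raise ValueError("echo latency lies outside the lag range")
    kernel = np.zeros_like(lags_ms)
    for f, t0, tau, amp in (
        (spec.gamma_freq, spec.gamma_latency_ms, spec.gamma_decay_ms, spec.gamma_amp),
        (spec.alpha_freq, spec.alpha_latency_ms, spec.alpha_decay_ms, spec.alpha_amp),
    ):
        if amp == 0:
            continue
        rel = lags_ms - t0
        active = rel >= 0
        kernel[active] += (
            amp * np.exp(-rel[active] / tau) * np.sin(2 * np.pi * f * rel[active] / 1000.0)
        )
    return kernel


def _pink_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise with a 1/f^exponent power spectrum, unit variance."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-exponent / 2.0)
    scale[0] = 0.0
    out = np.fft.irfft(spec * scale, n)
    return out / out.std()


def _band_variance(x: np.ndarray, fs: float, band=(1.0, 100.0)) -> float:
    sos = sps.butter(4, band, btype="band", fs=fs, output="sos")
    return float(sps.sosfiltfilt(sos, x).var())


def generate_response(
    flicker: FlickerTrain,
    kernel: np.ndarray,
    noise: NoiseSpec | None = None,
    fs_out: float = 1000.0,
    snr: float = 0.1,
    kernel_lags_ms: np.ndarray | None = None,
    spec: EchoKernelSpec | None = None,
) -> SyntheticTrial:
    """Convolve the flicker with the kernel and add calibrated noise.

    The flicker is zero-order-held to ``fs_out``; the clean response is
    the causal convolution with ``kernel``; the pink + line noise
    mixture is scaled so that (clean band variance) / (noise band
    variance) within 1-100 Hz equals ``snr``.  ``snr=inf`` or zero
    noise amplitudes give the noiseless response.
    """
    noise = noise or NoiseSpec()
    stim = flicker.resample_hold(fs_out)
    n = len(stim)
    kernel = np.asarray(kernel, dtype=float)
    if kernel_lags_ms is None:
        kernel_lags_ms = np.arange(len(kernel)) * 1000.0 / fs_out
    # causal part only; acausal lags of a physical kernel are zero anyway
    causal = kernel_lags_ms >= 0
    k = kernel[causal]
    dt_scale = 1.0  # kernel defined per-sample at fs_out
    clean = np.convolve(stim - stim.mean(), k)[:n] * dt_scale
    rng = np.random.default_rng(noise.seed)
    mix = np.zeros(n)
    if noise.pink_amp > 0:
        mix += noise.pink_amp * _pink_noise(n, noise.pink_exponent, rng)
    if noise.line_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        t = np.arange(n) / fs_out
        mix += noise.line_amp * np.sin(2 * np.pi * noise.line_freq * t + phase)
    if np.any(mix) and np.isfinite(snr) and snr > 0:
        target_noise_var = _band_variance(clean, fs_out) / snr
        mix *= np.sqrt(target_noise_var / _band_variance(mix, fs_out))
    elif not np.isfinite(snr):
        mix = np.zeros(n)
    return SyntheticTrial(
        stimulus=stim,
        response=clean + mix,
        fs=fs_out,
        kernel=kernel,
        kernel_lags_ms=np.asarray(kernel_lags_ms, dtype=float),
        spec=spec or EchoKernelSpec(),
        noise=noise,
        snr=snr,
    )
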