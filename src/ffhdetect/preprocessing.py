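"""Causal low-pass filtering of the inertial channels.

The detector has to run before floor impact, so only causal single-pass
filtering is allowed here: zero-phase two-pass filtering would use future
samples. The default is a 2nd-order Butterworth at 5 Hz applied to both
the accelerometer and gyroscope channels. The filter state is initialized
for a step equal to the first sample, which gives unit DC gain without a
startup transient while keeping the filter exactly causal and linear.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .imu_core import ImuTrace


class ConfigurationError(ValueError):
    """Raised for invalid filter settings (e.g. cutoff at/above Nyquist)."""


@dataclass
class FilterConfig:
    """Low-pass filter settings: cutoff (Hz), order, family."""

    cutoff: float = 5.0
    order: int = 2
    kind: str = "butterworth"

    def design(self, fs: float) -> tuple[np.ndarray, np.ndarray]:
        if not 0 < self.cutoff < fs / 2:
            raise ConfigurationError(
                f"cutoff {self.cutoff} Hz must lie in (0, {fs / 2}) Hz"
            )
        if self.kind != "butterworth":
            raise ConfigurationError(f"unknown filter family {self.kind!r}")
        return signal.butter(self.order, self.cutoff, btype="low", fs=fs)


def lowpass_array(x: np.ndarray, fs: float, cfg: FilterConfig | None = None) -> np.ndarray:
    """Causally low-pass filter each column of ``x`` (shape (n,) or (n, k))."""
    cfg = cfg or FilterConfig()
    b, a = cfg.design(fs)
    x = np.asarray(x, dtype=float)
    zi = signal.lfilter_zi(b, a)
    if x.ndim == 1:
        y, _ = signal.lfilter(b, a, x, zi=zi * x[0])
        return y
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        out[:, j], _ = signal.lfilter(b, a, x[:, j], zi=zi * x[0, j])
    return out


def lowpass(trace: ImuTrace, cfg: FilterConfig | None = None) -> ImuTrace:
    """Return a trace with all six inertial channels causally filtered."""
    cfg = cfg or FilterConfig()
    return ImuTrace(
        t=trace.t.copy(),
        acc=lowpass_array(trace.acc, trace.fs, cfg),
        gyro=lowpass_array(trace.gyro, trace.fs, cfg),
        fs=trace.fs,
    )


def magnitude_response(cfg: FilterConfig, fs: float, freq: float) -> float:
    """Analytic gain of the configured filter at ``freq`` Hz."""
    b, a = cfg.design(fs)
    _, h = signal.freqz(b, a, worN=[freq], fs=fs)
    return float(np.abs(h[0]))
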