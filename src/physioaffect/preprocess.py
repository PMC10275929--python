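"""Filtering, tonic/phasic decomposition, synchronization and normalization.

The skin-conductance stream is denoised with a 5 Hz low-pass Butterworth
filter, then split into its tonic component (skin conductance level, SCL;
low-pass at 0.1 Hz) and phasic component (skin conductance responses, SCR;
high-pass at 0.1 Hz).  All filters are 4th-order and applied zero-phase
(forward-backward), so windowed features see no group delay.  Derived level
streams are linearly interpolated onto a shared 36.5 Hz grid, and baseline
normalization subtracts each level stream's mean over the rest period to
remove inter-subject offsets.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

from .io import ChannelSignal, Recording

SYNC_RATE_HZ = 36.5
#: streams carrying a subject-specific level offset; only these are
#: baseline-subtracted (phasic SCR is zero-mean by construction, raw ECG is not
#: a level signal)
LEVEL_CHANNELS = ("gsr", "scl", "hr", "resp_rate")


@dataclass
class DecomposedGsr:
    """Tonic (SCL) and phasic (SCR) components of a denoised GSR stream."""

    scl: np.ndarray
    scr: np.ndarray
    rate_hz: float

    def __post_init__(self) -> None:
        if len(self.scl) != len(self.scr):
            raise ValueError("scl and scr must have equal length")


def butterworth_filter(
    x: np.ndarray,
    rate_hz: float,
    cutoff_hz: float,
    mode: str = "lowpass",
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth filter (two passes, ``scipy.signal.filtfilt``).

    Because the filter is applied forward and backward, the effective
    attenuation at the cutoff is two passes of -3 dB, i.e. amplitude 0.5.
    """
    x = np.asarray(x, dtype=float)
    if mode not in ("lowpass", "highpass"):
        raise ValueError(f"mode must be 'lowpass' or 'highpass', got {mode!r}")
    nyq = rate_hz / 2.0
    if not 0 < cutoff_hz < nyq:
        raise ValueError(f"cutoff {cutoff_hz} Hz outside (0, Nyquist={nyq} Hz)")
    if len(x) < 3 * order:
        raise ValueError(f"signal too short ({len(x)} samples) for order-{order} filter")
    sos = sps.butter(order, cutoff_hz, btype="low" if mode == "lowpass" else "high",
                     fs=rate_hz, output="sos")
    return sps.sosfiltfilt(sos, x)


def decompose_gsr(gsr: ChannelSignal, *, order: int = 4) -> DecomposedGsr:
    """Split a GSR channel into tonic SCL and phasic SCR components.

    Denoise at 5 Hz low-pass, then SCL = 0.1 Hz low-pass of the denoised
    signal and SCR = 0.1 Hz high-pass of the same.  The two components are
    complementary up to the (small) filter leakage, so ``scl + scr``
    reconstructs the denoised stream.
    """
    denoised = butterworth_filter(gsr.samples, gsr.rate_hz, 5.0, "lowpass", order)
    scl = butterworth_filter(denoised, gsr.rate_hz, 0.1, "lowpass", order)
    scr = butterworth_filter(denoised, gsr.rate_hz, 0.1, "highpass", order)
    return DecomposedGsr(scl=scl, scr=scr, rate_hz=gsr.rate_hz)


def resample_to_grid(ch: ChannelSignal, rate_hz: float, t_start: float, t_end: float) -> ChannelSignal:
    """Linear interpolation of one channel onto ``[t_start, t_end)`` at ``rate_hz``."""
    n = int(np.floor((t_end - t_start) * rate_hz + 1e-9))
    grid = t_start + np.arange(n) / rate_hz
    y = np.interp(grid, ch.times(), ch.samples)
    return ChannelSignal(ch.name, ch.unit, rate_hz, y, t0_s=t_start)


def synchronize(recording: Recording, rate_hz: float = SYNC_RATE_HZ) -> Recording:
    """Interpolate every channel onto a shared grid over the common span.

    Beat detection must run on the native-rate ECG *before* this step; the
    grid is meant for level streams (SCL/SCR, instantaneous HR, respiration
    rate).
    """
    t0 = max(c.t0_s for c in recording.channels.values())
    t1 = min(c.end_s for c in recording.channels.values())
    if t1 <= t0:
        raise ValueError("channels have no common time span")
    channels = {
        n: resample_to_grid(c, rate_hz, t0, t1) for n, c in recording.channels.items()
    }
    return replace(recording, channels=channels)


def baseline_mean(ch: ChannelSignal, interval: tuple[float, float]) -> float:
    t = ch.times()
    mask = (t >= interval[0]) & (t < interval[1])
    if not mask.any():
        raise ValueError(f"channel {ch.name!r} has no samples in the baseline interval")
    return float(ch.samples[mask].mean())


def baseline_normalize(recording: Recording, min_baseline_s: float = 30.0) -> Recording:
    """Subtract the rest-period mean from every level-type stream.

    Applies to channels named in :data:`LEVEL_CHANNELS` only; event and
    self-report metadata are untouched.  Raise if the baseline interval is
    shorter than ``min_baseline_s`` — callers wanting to proceed anyway must
    skip normalization explicitly.
    """
    b0, b1 = recording.baseline_interval
    if b1 - b0 < min_baseline_s:
        raise ValueError(
            f"baseline interval ({b0}, {b1}) shorter than {min_baseline_s} s; "
            "skip normalization explicitly if this is intended"
        )
    channels = {}
    for name, ch in recording.channels.items():
        if name in LEVEL_CHANNELS:
            mu = baseline_mean(ch, (b0, b1))
            ch = ChannelSignal(ch.name, ch.unit, ch.rate_hz, ch.samples - mu, ch.t0_s)
        channels[name] = ch
    return replace(recording, channels=channels)
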