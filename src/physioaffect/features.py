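"""Windowed extraction of the 23 physiological features.

Per 0.5-s window the extractor emits 15 electrodermal features (statistics of
the tonic SCL and phasic SCR streams, SCL derivatives, SCR peak count and
amplitudes), 7 cardiac features (statistics of instantaneous heart rate plus
running sDNN and rMSSD of the inter-beat intervals) and 1 respiratory feature
(mean respiration rate).

Frequency-domain heart-rate-variability metrics are deliberately absent: they
need minutes of data and are incompatible with 0.5-s real-time windows.  A
0.5-s window also cannot contain two heartbeats, so sDNN/rMSSD are running
values over a rolling 15-s inter-beat-interval buffer (one image presentation)
ending at the window's end — hence the ``_mean`` suffix in their names.

Standard deviations are population (divide by n) throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .io import ChannelSignal, Recording

WINDOW_S = 0.5
IBI_BUFFER_S = 15.0
IBI_VALID_MS = (200.0, 3000.0)
SCR_PEAK_THRESHOLD_US = 0.03  # midpoint of the 0.01-0.05 uS range used in EDA work

GSR_FEATURES = (
    "SCL_mean", "SCL_std", "SCL_min", "SCL_max", "SCL_max_minus_min",
    "SCL_dot", "SCL_ddot",
    "SCR_mean", "SCR_std", "SCR_min", "SCR_max", "SCR_max_minus_min",
    "N_peaks", "PA_mean", "PA_std",
)
ECG_FEATURES = (
    "HR_mean", "HR_std", "HR_min", "HR_max", "HR_max_minus_min",
    "sDNN_mean", "rMSSD_mean",
)
RESP_FEATURES = ("RR_mean",)
FEATURE_NAMES: tuple[str, ...] = GSR_FEATURES + ECG_FEATURES + RESP_FEATURES
assert len(FEATURE_NAMES) == 23


@dataclass
class IbiSeries:
    """Beat instants and the inter-beat intervals between them."""

    beat_times_s: np.ndarray
    intervals_ms: np.ndarray

    @classmethod
    def from_beats(cls, beat_times_s: np.ndarray) -> "IbiSeries":
        beat_times_s = np.asarray(beat_times_s, dtype=float)
        if np.any(np.diff(beat_times_s) <= 0):
            raise ValueError("beat times must be strictly increasing")
        return cls(beat_times_s, np.diff(beat_times_s) * 1000.0)


def detect_r_peaks(ecg: ChannelSignal, refractory_s: float = 0.25) -> np.ndarray:
    """R-peak instants from an ECG channel (seconds from session start).

    Band-pass (5-15 Hz) energy envelope with an adaptive threshold and a
    250 ms refractory period, then each candidate refined to the local ECG
    maximum within +-50 ms so detected times sit on the R wave itself.
    """
    fs = ecg.rate_hz
    if fs < 100:
        raise ValueError(f"ECG rate {fs} Hz too low for beat detection (need >= 100 Hz)")
    x = ecg.samples
    if len(x) < 2 * fs:
        raise ValueError("ECG shorter than 2 s")
    sos = sps.butter(2, (5.0, 15.0), btype="bandpass", fs=fs, output="sos")
    band = sps.sosfiltfilt(sos, x)
    energy = band ** 2
    # 150 ms moving-average integration window
    w = max(1, int(round(0.15 * fs)))
    env = np.convolve(energy, np.ones(w) / w, mode="same")
    dist = max(1, int(round(refractory_s * fs)))
    cand, props = sps.find_peaks(env, distance=dist, height=1e-12)
    if len(cand) == 0:
        return np.array([])
    heights = props["peak_heights"]
    # adaptive threshold: candidates arrive at the refractory rate, so most
    # are noise; seed the level from a high quantile (QRS envelopes dominate
    # the top of the height distribution) and refine once on the kept set
    thr = 0.2 * np.percentile(heights, 90)
    keep = heights > thr
    if keep.any():
        thr = 0.3 * np.median(heights[keep])
        keep = heights > thr
    cand = cand[keep]
    # refine each detection to the nearest local ECG maximum
    half = int(round(0.05 * fs))
    refined = np.unique([
        max(0, c - half) + int(np.argmax(x[max(0, c - half):min(len(x), c + half + 1)]))
        for c in cand
    ])
    # enforce refractory after refinement
    peaks: list[int] = []
    for p in refined:
        if not peaks or p - peaks[-1] >= dist:
            peaks.append(int(p))
    return ecg.t0_s + np.asarray(peaks) / fs


def instantaneous_hr(ibi: IbiSeries) -> tuple[np.ndarray, np.ndarray]:
    """Instant heart rate, 60000/IBI in bpm, stamped at the second beat.

    Returns ``(times_s, hr_bpm)``; empty arrays for fewer than two beats.
    The series is meant to be held piecewise-constant between beats.
    """
    if len(ibi.beat_times_s) < 2:
        return np.array([]), np.array([])
    return ibi.beat_times_s[1:], 60000.0 / ibi.intervals_ms


def hr_channel(ibi: IbiSeries, rate_hz: float, t_start: float, t_end: float) -> ChannelSignal:
    """Piecewise-constant instantaneous HR resampled onto a uniform grid."""
    t_hr, hr = instantaneous_hr(ibi)
    n = int(np.floor((t_end - t_start) * rate_hz + 1e-9))
    grid = t_start + np.arange(n) / rate_hz
    if len(hr) == 0:
        return ChannelSignal("hr", "bpm", rate_hz, np.zeros(n), t0_s=t_start)
    idx = np.clip(np.searchsorted(t_hr, grid, side="right"), 1, len(hr)) - 1
    return ChannelSignal("hr", "bpm", rate_hz, hr[idx], t0_s=t_start)


def sdnn(intervals_ms: np.ndarray) -> float:
    """Population standard deviation of the inter-beat intervals, in ms."""
    intervals_ms = np.asarray(intervals_ms, dtype=float)
    if len(intervals_ms) < 2:
        return float("nan")
    return float(np.sqrt(np.mean((intervals_ms - intervals_ms.mean()) ** 2)))


def rmssd(intervals_ms: np.ndarray) -> float:
    """Root mean square of successive inter-beat-interval differences, in ms."""
    intervals_ms = np.asarray(intervals_ms, dtype=float)
    if len(intervals_ms) < 3:
        return float("nan")
    d = np.diff(intervals_ms)
    return float(np.sqrt(np.mean(d ** 2)))


def detect_scr_peaks(
    scr: np.ndarray,
    rate_hz: float,
    t0_s: float = 0.0,
    threshold_uS: float = SCR_PEAK_THRESHOLD_US,
) -> tuple[np.ndarray, np.ndarray]:
    """Phasic SCR peaks: local maxima rising more than the threshold.

    A peak is a local maximum whose rise from the preceding local minimum is
    strictly greater than ``threshold_uS``; the amplitude is that rise.
    Returns ``(times_s, amplitudes_uS)``.
    """
    scr = np.asarray(scr, dtype=float)
    if len(scr) < 3:
        return np.array([]), np.array([])
    maxima, _ = sps.find_peaks(scr)
    minima, _ = sps.find_peaks(-scr)
    times, amps = [], []
    for m in maxima:
        prior = minima[minima < m]
        base = scr[prior[-1]] if len(prior) else scr[0]
        rise = scr[m] - base
        if rise > threshold_uS:
            times.append(t0_s + m / rate_hz)
            amps.append(rise)
    return np.asarray(times), np.asarray(amps)


def _pop_std(x: np.ndarray) -> float:
    return float(np.sqrt(np.mean((x - x.mean()) ** 2)))


def _window_stats(prefix: str, x: np.ndarray) -> dict[str, float]:
    lo, hi = float(x.min()), float(x.max())
    return {
        f"{prefix}_mean": float(x.mean()),
        f"{prefix}_std": _pop_std(x),
        f"{prefix}_min": lo,
        f"{prefix}_max": hi,
        f"{prefix}_max_minus_min": hi - lo,
    }


class WindowFeatureExtractor:
    """Extracts the 23-feature vector for 0.5-s windows of one recording.

    Parameters
    ----------
    scl, scr, hr, rr : ChannelSignal
        Preprocessed streams on a shared grid (SCL/SCR from
        :func:`physioaffect.preprocess.decompose_gsr`, HR from
        :func:`hr_channel`).
    ibi : IbiSeries
        Validated inter-beat intervals (implausible intervals outside
        200-3000 ms are discarded) feeding the rolling sDNN/rMSSD buffer.
    scr_peak_times, scr_peak_amps : ndarray
        Output of :func:`detect_scr_peaks` on the full SCR stream.
    """

    def __init__(
        self,
        scl: ChannelSignal,
        scr: ChannelSignal,
        hr: ChannelSignal,
        rr: ChannelSignal,
        ibi: IbiSeries,
        scr_peak_times: np.ndarray,
        scr_peak_amps: np.ndarray,
    ) -> None:
        self.scl, self.scr, self.hr, self.rr = scl, scr, hr, rr
        valid = (ibi.intervals_ms > IBI_VALID_MS[0]) & (ibi.intervals_ms < IBI_VALID_MS[1])
        self._ibi_ends = ibi.beat_times_s[1:][valid]
        self._ibi_ms = ibi.intervals_ms[valid]
        self._peak_t = np.asarray(scr_peak_times)
        self._peak_a = np.asarray(scr_peak_amps)

    def _slice(self, ch: ChannelSignal, start_s: float, end_s: float) -> np.ndarray:
        i0 = int(np.ceil((start_s - ch.t0_s) * ch.rate_hz - 1e-9))
        i1 = int(np.ceil((end_s - ch.t0_s) * ch.rate_hz - 1e-9))
        return ch.samples[max(i0, 0):max(i1, 0)]

    def covers(self, start_s: float, end_s: float) -> bool:
        return all(
            ch.t0_s <= start_s + 1e-9 and ch.end_s >= end_s - 1e-9
            for ch in (self.scl, self.scr, self.hr, self.rr)
        )

    def extract(self, start_s: float, end_s: float) -> dict[str, float]:
        """The 23 named feature values for one ``[start_s, end_s)`` window."""
        if abs((end_s - start_s) - WINDOW_S) > 1e-6:
            raise ValueError(f"window must be {WINDOW_S} s long")
        if not self.covers(start_s, end_s):
            raise ValueError(f"window [{start_s}, {end_s}) not covered by all streams")
        out: dict[str, float] = {}

        scl = self._slice(self.scl, start_s, end_s)
        rate = self.scl.rate_hz
        out.update(_window_stats("SCL", scl))
        d1 = np.diff(scl)
        out["SCL_dot"] = float(d1.mean() * rate) if len(d1) else 0.0
        d2 = np.diff(d1)
        out["SCL_ddot"] = float(d2.mean() * rate ** 2) if len(d2) else 0.0

        scr = self._slice(self.scr, start_s, end_s)
        out.update(_window_stats("SCR", scr))
        in_win = (self._peak_t >= start_s) & (self._peak_t < end_s)
        amps = self._peak_a[in_win]
        out["N_peaks"] = float(len(amps))
        out["PA_mean"] = float(amps.mean()) if len(amps) else 0.0
        out["PA_std"] = _pop_std(amps) if len(amps) else 0.0

        hr = self._slice(self.hr, start_s, end_s)
        out.update(_window_stats("HR", hr))
        lo = np.searchsorted(self._ibi_ends, end_s - IBI_BUFFER_S, side="left")
        hi = np.searchsorted(self._ibi_ends, end_s, side="right")
        buf = self._ibi_ms[lo:hi]
        out["sDNN_mean"] = sdnn(buf)
        out["rMSSD_mean"] = rmssd(buf)

        out["RR_mean"] = float(self._slice(self.rr, start_s, end_s).mean())
        return out


def extract_window_features(
    extractor: WindowFeatureExtractor,
    window: tuple[float, float],
    participant_id: str = "",
    image_id: str = "",
    quadrant: str = "",
) -> dict:
    """One table row: provenance columns plus the 23 named feature values."""
    row = {
        "participant_id": participant_id,
        "image_id": image_id,
        "window_start_s": window[0],
        "quadrant": quadrant,
    }
    row.update(extractor.extract(*window))
    return row


def tile_windows(onset_s: float, duration_s: float, window_s: float = WINDOW_S) -> list[tuple[float, float]]:
    """Non-overlapping windows tiled from an image onset across its display."""
    n = int(np.floor(duration_s / window_s + 1e-9))
    return [(onset_s + i * window_s, onset_s + (i + 1) * window_s) for i in range(n)]


def feature_table(recording: Recording, extractor: WindowFeatureExtractor) -> pd.DataFrame:
    """Window-feature table over all image presentations of a recording.

    Windows during blank slides and self-assessment are excluded; windows not
    fully covered by every stream are skipped.  One row per window with the 23
    feature columns plus ``participant_id, image_id, window_start_s, quadrant``.
    """
    rows = []
    for ev in recording.events:
        for w in tile_windows(ev.onset_s, ev.duration_s):
            if not extractor.covers(*w):
                continue
            row = extract_window_features(
                extractor, w, recording.participant_id, ev.image_id, ev.cluster_quadrant
            )
            rows.append(row)
    df = pd.DataFrame(rows)
    if len(df):
        df = df.dropna(subset=list(FEATURE_NAMES)).reset_index(drop=True)
    return df
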