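"""Data model and on-disk dialect for physiological recordings.

A :class:`Recording` bundles the three monitored channels (skin conductance in
microsiemens, ECG in millivolts, respiration rate in breaths/min), the stimulus
schedule with per-image valence/arousal ratings on the 1-9 scale, and the
participant's SAM self-reports.  On disk a recording is a directory holding one
``time_s,value`` CSV per channel plus a ``session.json`` sidecar with all
metadata — diffable, language-neutral, UTF-8 text throughout.

Times are seconds from session start, 0-based; windows are half-open
``[start, end)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

CHANNEL_UNITS = {"gsr": "uS", "ecg": "mV", "resp_rate": "breaths/min"}
QUADRANTS = ("HAHV", "HALV", "LALV", "LAHV", "N")


class ValidationError(ValueError):
    """A recording, event or report violates a structural invariant."""


@dataclass
class ChannelSignal:
    """A uniformly sampled physiological channel.

    Parameters
    ----------
    name : str
        Channel identifier, e.g. ``"gsr"``, ``"ecg"``, ``"resp_rate"`` or a
        derived stream such as ``"scl"`` or ``"hr"``.
    unit : str
        Physical unit of the samples.
    rate_hz : float
        Sampling frequency, strictly positive.
    samples : ndarray
        Ordered real-valued samples; all finite.
    t0_s : float
        Time of the first sample, seconds from session start.
    """

    name: str
    unit: str
    rate_hz: float
    samples: np.ndarray
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate_hz <= 0:
            raise ValidationError(f"channel {self.name!r}: rate_hz must be > 0")
        if self.samples.ndim != 1:
            raise ValidationError(f"channel {self.name!r}: samples must be 1-D")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError(f"channel {self.name!r}: non-finite samples")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.rate_hz

    @property
    def end_s(self) -> float:
        return self.t0_s + self.duration_s

    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(len(self.samples)) / self.rate_hz

    def crop(self, start_s: float, end_s: float, rebase: bool = True) -> "ChannelSignal":
        """Samples with times in ``[start_s, end_s)``; ``t0_s`` rebased to 0."""
        if start_s >= end_s:
            raise ValueError("start_s must be < end_s")
        t = self.times()
        i0 = int(np.searchsorted(t, start_s - 1e-12, side="left"))
        i1 = int(np.searchsorted(t, end_s - 1e-12, side="left"))
        t0 = t[i0] - start_s if i1 > i0 else 0.0
        return ChannelSignal(
            self.name, self.unit, self.rate_hz, self.samples[i0:i1].copy(),
            t0_s=t0 if rebase else (t[i0] if i1 > i0 else start_s),
        )


@dataclass
class StimulusEvent:
    """One IAPS image presentation with its normative ratings."""

    image_id: str
    iaps_valence_raw: float
    iaps_arousal_raw: float
    onset_s: float
    duration_s: float = 15.0
    cluster_quadrant: str = "N"

    def __post_init__(self) -> None:
        for label, v in (("valence", self.iaps_valence_raw), ("arousal", self.iaps_arousal_raw)):
            if not 1.0 <= v <= 9.0:
                raise ValidationError(
                    f"event {self.image_id!r}: iaps_{label}_raw {v} outside [1, 9]"
                )
        if self.duration_s <= 0:
            raise ValidationError(f"event {self.image_id!r}: duration_s must be > 0")
        if self.cluster_quadrant not in QUADRANTS:
            raise ValidationError(
                f"event {self.image_id!r}: unknown quadrant {self.cluster_quadrant!r}"
            )

    @property
    def offset_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass
class SelfReport:
    """A SAM self-assessment: integer 1-9 valence/arousal for one image."""

    image_id: str
    sam_valence: int
    sam_arousal: int
    response_time_s: float = 0.0

    def __post_init__(self) -> None:
        for label, v in (("valence", self.sam_valence), ("arousal", self.sam_arousal)):
            if int(v) != v or not 1 <= int(v) <= 9:
                raise ValidationError(f"report {self.image_id!r}: sam_{label} {v} not an integer in 1-9")
        if self.response_time_s < 0:
            raise ValidationError(f"report {self.image_id!r}: negative response time")


@dataclass
class Recording:
    """A participant's synchronized multichannel session."""

    participant_id: str
    channels: dict[str, ChannelSignal]
    baseline_interval: tuple[float, float]
    events: list[StimulusEvent] = field(default_factory=list)
    self_reports: list[SelfReport] = field(default_factory=list)

    def __post_init__(self) -> None:
        b0, b1 = self.baseline_interval
        if b0 >= b1:
            raise ValidationError("baseline_interval must be a non-empty (start, end)")
        if self.events:
            onsets = sorted(e.onset_s for e in self.events)
            if b1 > min(onsets) + 1e-9:
                raise ValidationError("baseline_interval must precede the first event onset")
            ordered = sorted(self.events, key=lambda e: e.onset_s)
            for a, b in zip(ordered, ordered[1:]):
                if a.offset_s > b.onset_s + 1e-9:
                    raise ValidationError(f"events {a.image_id!r} and {b.image_id!r} overlap")
        known = {e.image_id for e in self.events}
        for r in self.self_reports:
            if r.image_id not in known:
                raise ValidationError(f"self report for unknown image {r.image_id!r}")

    @property
    def span(self) -> tuple[float, float]:
        t0 = min(c.t0_s for c in self.channels.values())
        t1 = max(c.end_s for c in self.channels.values())
        return t0, t1

    def event_for(self, image_id: str) -> StimulusEvent:
        for e in self.events:
            if e.image_id == image_id:
                return e
        raise KeyError(image_id)


# ---------------------------------------------------------------------------
# on-disk dialect


def write_recording(recording: Recording, path: str | Path) -> None:
    """Write a recording as per-channel CSVs plus a ``session.json`` sidecar."""
    path = Path(path)
    try:
        path.mkdir(parents=True, exist_ok=True)
    except OSError as exc:  # pragma: no cover - depends on fs permissions
        raise OSError(f"cannot create recording directory {path}: {exc}") from exc
    for name, ch in recording.channels.items():
        df = pd.DataFrame({"time_s": ch.times(), "value": ch.samples})
        df.to_csv(path / f"{name}.csv", index=False, float_format="%.9f")
    meta = {
        "participant_id": recording.participant_id,
        "channels": {
            name: {"unit": ch.unit, "rate_hz": ch.rate_hz, "t0_s": ch.t0_s}
            for name, ch in recording.channels.items()
        },
        "baseline_interval": list(recording.baseline_interval),
        "events": [
            {
                "image_id": e.image_id,
                "iaps_valence_raw": e.iaps_valence_raw,
                "iaps_arousal_raw": e.iaps_arousal_raw,
                "onset_s": e.onset_s,
                "duration_s": e.duration_s,
                "cluster_quadrant": e.cluster_quadrant,
            }
            for e in recording.events
        ],
        "self_reports": [
            {
                "image_id": r.image_id,
                "sam_valence": r.sam_valence,
                "sam_arousal": r.sam_arousal,
                "response_time_s": r.response_time_s,
            }
            for r in recording.self_reports
        ],
    }
    (path / "session.json").write_text(json.dumps(meta, indent=1), encoding="utf-8")


def read_recording(path: str | Path) -> Recording:
    """Load a recording directory written by :func:`write_recording`.

    Channel sampling rates are taken from ``session.json``, never inferred from
    the time column; a non-monotone time column is a validation error.
    """
    path = Path(path)
    meta_path = path / "session.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"no session.json under {path}")
    meta = json.loads(meta_path.read_text(encoding="utf-8"))
    channels: dict[str, ChannelSignal] = {}
    for name, info in meta["channels"].items():
        csv_path = path / f"{name}.csv"
        if not csv_path.exists():
            raise FileNotFoundError(f"missing channel file for {name!r}: {csv_path}")
        df = pd.read_csv(csv_path)
        t = df["time_s"].to_numpy()
        if len(t) > 1 and np.any(np.diff(t) <= 0):
            raise ValidationError(f"channel {name!r}: time column not strictly increasing")
        channels[name] = ChannelSignal(
            name=name, unit=info["unit"], rate_hz=float(info["rate_hz"]),
            samples=df["value"].to_numpy(), t0_s=float(info.get("t0_s", 0.0)),
        )
    events = [StimulusEvent(**e) for e in meta["events"]]
    reports = [SelfReport(**r) for r in meta["self_reports"]]
    return Recording(
        participant_id=meta["participant_id"],
        channels=channels,
        baseline_interval=tuple(meta["baseline_interval"]),
        events=events,
        self_reports=reports,
    )


def slice_segment(recording: Recording, start_s: float, end_s: float) -> Recording:
    """Crop all channels to ``[start_s, end_s)`` with times rebased to 0.

    Events not fully inside the span are dropped (and their self-reports with
    them); the baseline interval is intersected with the span.
    """
    if start_s >= end_s:
        raise ValueError(f"inverted interval ({start_s}, {end_s})")
    channels = {n: c.crop(start_s, end_s) for n, c in recording.channels.items()}
    kept = [
        replace(e, onset_s=e.onset_s - start_s)
        for e in recording.events
        if e.onset_s >= start_s - 1e-9 and e.offset_s <= end_s + 1e-9
    ]
    kept_ids = {e.image_id for e in kept}
    reports = [r for r in recording.self_reports if r.image_id in kept_ids]
    b0 = max(recording.baseline_interval[0], start_s) - start_s
    b1 = min(recording.baseline_interval[1], end_s) - start_s
    if b1 <= b0:  # slice misses the baseline entirely; keep a degenerate stub
        first = min((e.onset_s for e in kept), default=end_s - start_s)
        b0, b1 = min(0.0, first) - 1e-6, min(0.0, first)
    return Recording(
        participant_id=recording.participant_id,
        channels=channels,
        baseline_interval=(b0, b1),
        events=kept,
        self_reports=reports,
    )
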