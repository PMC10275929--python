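"""Seeded generator of affect-modulated physiological recordings.

Emulates the IAPS picture-viewing protocol: a 4-minute rest baseline, then two
passes over the cluster order LAHV, HALV, HAHV, LALV, N with 5 images per
cluster — 50 image presentations of 15 s, each preceded by a 5-s blank slide
and followed by a self-assessment gap of about 8.7 s.

Signal synthesis:

* GSR (51.2 Hz, uS) — subject baseline level plus slow drift, a per-image
  tonic response (exponential onset of a quadrant-specific level step plus a
  quadrant-specific linear ramp), a Poisson train of phasic SCRs with
  bi-exponential kinetics (0.75 s rise, 2.0 s decay) and exponentially
  distributed amplitudes, and white measurement noise.
* ECG (250 Hz, mV) — a Gaussian R-bump train driven by an AR(1) inter-beat
  interval process whose mean tracks the quadrant-modulated heart rate and
  whose spread tracks the quadrant-modulated SDNN; a small timestamp jitter
  models beat-detection measurement noise.
* Respiration rate (25 Hz, breaths/min) — subject baseline plus the quadrant
  offset and slow noise.

The default effect structure plants class signal in tonic level/slope, heart
rate, inter-beat variability and respiration rate only: phasic SCR rate and
amplitude are the same in every quadrant, and the SDNN offsets follow the
physiological inverse-square coupling between HRV and heart rate, so that
within-window heart-rate jumps stay class-neutral while the buffer-level
sDNN/rMSSD values remain class-informative.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .io import ChannelSignal, Recording, SelfReport, StimulusEvent

CLUSTER_ORDER = ("LAHV", "HALV", "HAHV", "LALV", "N")
IMAGES_PER_CLUSTER = 5
N_PASSES = 2
BASELINE_S = 240.0
BLANK_S = 5.0
IMAGE_S = 15.0
SAM_MEAN_S, SAM_SD_S, SAM_MIN_S, SAM_MAX_S = 8.7, 1.5, 4.5, 11.3

GSR_RATE = 51.2
ECG_RATE = 250.0
RESP_RATE = 25.0

SCR_RISE_S = 0.75
SCR_DECAY_S = 2.0
GSR_NOISE_US = 0.01
TONIC_ONSET_S = 15.0   # raised-cosine rise of the per-image tonic response
TONIC_DECAY_S = 20.0   # raised-cosine return to baseline after image offset
# The tonic skin-conductance level shift is modeled as a sustained state
# tracking the same-quadrant image cluster (rising/decaying over ~30 s), not
# as a per-image blip: sustained tonic shifts keep the level modulation far
# below the 0.1 Hz tonic/phasic split, so none of it aliases into the phasic
# stream.  Per-image structure enters only through the slope ramps.
CLUSTER_RAMP_S = 30.0
#: guard before each image onset inside which no spontaneous SCR is drawn, so
#: event tails (rise 0.75 s, decay 2.0 s) have died away by the image start
SCR_GUARD_S = 6.0
R_BUMP_SIGMA_S = 0.010
BEAT_JITTER_MS = 2.0
IBI_AR_RHO = 0.5  # successive-interval correlation; rmssd ~= sdnn at 0.5


@dataclass(frozen=True)
class QuadrantEffect:
    """Offsets relative to the neutral/rest condition for one quadrant."""

    scl_level: float = 0.0       # uS
    scl_slope: float = 0.0       # uS/s
    scr_rate: float = 0.0        # events/min
    scr_amp_mean: float = 0.0    # uS
    hr_mean: float = 0.0         # bpm
    ibi_sdnn: float = 0.0        # ms
    ibi_rmssd_factor: float = 1.0
    rr: float = 0.0              # breaths/min


@dataclass(frozen=True)
class EffectSpec:
    """Per-quadrant physiological modulation plus rest-condition levels."""

    quadrants: dict[str, QuadrantEffect] = field(default_factory=lambda: dict(DEFAULT_QUADRANT_EFFECTS))
    rest_scr_rate_per_min: float = 1.0   # spontaneous SCRs in inter-stimulus intervals
    stim_scr_rate_per_min: float = 0.0   # evoked SCRs while an image is shown
    rest_scr_amp_mean_us: float = 0.05
    rest_sdnn_ms: float = 45.0
    #: scale of the slow class-independent components (tonic drift, slow
    #: respiration wander).  The null cohort sets this to 0 so that windows
    #: are exchangeable and chance-level decoding is actually chance: under a
    #: temporally blocked stimulus design, any slow autocorrelated component
    #: leaks class information into a leave-one-image-out split even when it
    #: carries no affect modulation at all.
    slow_noise_scale: float = 1.0

    def offsets(self, quadrant: str) -> QuadrantEffect:
        return self.quadrants[quadrant]


# High-arousal quadrants raise tonic level/slope, heart rate and respiration
# and lower interval variability; valence shapes the asymmetry between the
# two HA (and the two LA) quadrants.  SDNN offsets follow
# sdnn_base * ((hr_base/(hr_base+dhr))^2 - 1) at nominal 70 bpm / 45 ms.
DEFAULT_QUADRANT_EFFECTS: dict[str, QuadrantEffect] = {
    "HAHV": QuadrantEffect(scl_level=0.8, scl_slope=0.004, hr_mean=9.0, ibi_sdnn=-10.0, rr=3.0),
    "HALV": QuadrantEffect(scl_level=0.5, scl_slope=0.0025, hr_mean=6.0, ibi_sdnn=-7.0, rr=2.0),
    "LAHV": QuadrantEffect(scl_level=0.25, scl_slope=0.001, hr_mean=-4.0, ibi_sdnn=5.0, rr=-1.0),
    "LALV": QuadrantEffect(scl_level=0.05, scl_slope=0.0005, hr_mean=-7.0, ibi_sdnn=10.0, rr=-2.0),
    "N": QuadrantEffect(),
}

NULL_EFFECTS = EffectSpec(quadrants={q: QuadrantEffect() for q in CLUSTER_ORDER},
                          slow_noise_scale=0.0)


@dataclass(frozen=True)
class SubjectParams:
    """Per-subject physiological baselines; reproducible from the seed."""

    participant_id: str
    baseline_scl: float   # uS, drawn 2-10
    baseline_hr: float    # bpm, drawn 60-80
    baseline_rr: float    # breaths/min, drawn 12-18
    gain_scl: float = 1.0
    gain_hr: float = 1.0
    gain_rr: float = 1.0
    seed: int = 0

    @classmethod
    def draw(cls, participant_id: str, seed: int) -> "SubjectParams":
        rng = np.random.default_rng(seed)
        return cls(
            participant_id=participant_id,
            baseline_scl=float(rng.uniform(2.0, 10.0)),
            baseline_hr=float(rng.uniform(60.0, 80.0)),
            baseline_rr=float(rng.uniform(12.0, 18.0)),
            gain_scl=float(rng.uniform(0.8, 1.2)),
            gain_hr=float(rng.uniform(0.8, 1.2)),
            gain_rr=float(rng.uniform(0.8, 1.2)),
            seed=seed,
        )


def _draw_rating(rng: np.random.Generator, quadrant: str) -> tuple[float, float]:
    """Synthetic rescaled (valence, arousal) drawn inside the quadrant region."""
    if quadrant == "N":
        return float(rng.uniform(-1, 1)), float(rng.uniform(-1, 1))
    sv = 1 if quadrant in ("HAHV", "LAHV") else -1
    sa = 1 if quadrant in ("HAHV", "HALV") else -1
    while True:
        v = sv * rng.uniform(0.0, 4.0)
        a = sa * rng.uniform(0.0, 4.0)
        if not (abs(v) <= 1 and abs(a) <= 1):
            return float(v), float(a)


def default_protocol(seed: int = 0) -> list[StimulusEvent]:
    """The 50-image stimulus schedule after a 240-s rest baseline.

    Cluster order LAHV, HALV, HAHV, LALV, N presented twice, 5 images per
    cluster; each image preceded by a 5-s blank and followed by a drawn
    self-assessment gap.  Synthetic ratings are drawn uniformly inside each
    image's quadrant region (outside the neutral box for non-N quadrants).
    """
    rng = np.random.default_rng(seed)
    events: list[StimulusEvent] = []
    t = BASELINE_S
    idx = 0
    for p in range(N_PASSES):
        for quadrant in CLUSTER_ORDER:
            for i in range(IMAGES_PER_CLUSTER):
                t += BLANK_S
                v, a = _draw_rating(rng, quadrant)
                events.append(StimulusEvent(
                    image_id=f"img_{quadrant}_{p}_{i}",
                    iaps_valence_raw=v + 5.0,
                    iaps_arousal_raw=a + 5.0,
                    onset_s=t,
                    duration_s=IMAGE_S,
                    cluster_quadrant=quadrant,
                ))
                idx += 1
                t += IMAGE_S
                t += float(np.clip(rng.normal(SAM_MEAN_S, SAM_SD_S), SAM_MIN_S, SAM_MAX_S))
    return events


def _event_envelopes(t: np.ndarray, events: list[StimulusEvent]):
    """Yield (event, step_envelope, ramp_envelope) arrays over ``t``.

    The step envelope is a raised-cosine rise during the image and a
    raised-cosine return to baseline afterwards (C1-smooth, so the tonic
    response stays essentially below the 0.1 Hz tonic/phasic split); the
    ramp envelope grows linearly during the image and decays the same way.
    """
    for ev in events:
        g = np.zeros_like(t)
        r = np.zeros_like(t)
        on = (t >= ev.onset_s) & (t < ev.offset_s)
        dt = t[on] - ev.onset_s
        g[on] = np.where(dt < TONIC_ONSET_S,
                         0.5 * (1 - np.cos(np.pi * dt / TONIC_ONSET_S)), 1.0)
        r[on] = dt
        after = t >= ev.offset_s
        if after.any():
            de = ev.duration_s
            g_end = 0.5 * (1 - np.cos(np.pi * min(de, TONIC_ONSET_S) / TONIC_ONSET_S))
            da = t[after] - ev.offset_s
            decay = np.where(da < TONIC_DECAY_S,
                             0.5 * (1 + np.cos(np.pi * da / TONIC_DECAY_S)), 0.0)
            g[after] = g_end * decay
            r[after] = de * decay
        yield ev, g, r


def _offset_track(
    t: np.ndarray, events: list[StimulusEvent], effects: EffectSpec, attr: str
) -> np.ndarray:
    """Sum over events of the quadrant offset shaped by the step envelope."""
    out = np.zeros_like(t)
    for ev, g, _ in _event_envelopes(t, events):
        val = getattr(effects.offsets(ev.cluster_quadrant), attr)
        if val:
            out += val * g
    return out


def _cluster_spans(events: list[StimulusEvent]) -> list[tuple[str, float, float]]:
    """(quadrant, first onset, last offset) for runs of same-quadrant images."""
    spans: list[tuple[str, float, float]] = []
    for ev in events:
        if spans and spans[-1][0] == ev.cluster_quadrant:
            spans[-1] = (spans[-1][0], spans[-1][1], ev.offset_s)
        else:
            spans.append((ev.cluster_quadrant, ev.onset_s, ev.offset_s))
    return spans


def _cluster_level_track(
    t: np.ndarray, events: list[StimulusEvent], effects: EffectSpec
) -> np.ndarray:
    """Sustained tonic-level offset rising/decaying over each image cluster."""
    out = np.zeros_like(t)
    for quadrant, start, end in _cluster_spans(events):
        level = effects.offsets(quadrant).scl_level
        if not level:
            continue
        g = np.zeros_like(t)
        on = (t >= start) & (t < end)
        dt = t[on] - start
        g[on] = np.where(dt < CLUSTER_RAMP_S,
                         0.5 * (1 - np.cos(np.pi * dt / CLUSTER_RAMP_S)), 1.0)
        after = t >= end
        da = t[after] - end
        g[after] = np.where(da < CLUSTER_RAMP_S,
                            0.5 * (1 + np.cos(np.pi * da / CLUSTER_RAMP_S)), 0.0)
        out += level * g
    return out


def _scr_gap_spans(events: list[StimulusEvent], duration_s: float) -> list[tuple[float, float]]:
    """Inter-stimulus spans where spontaneous SCRs may occur."""
    spans = []
    prev_end = 0.0
    for ev in events:
        lo, hi = prev_end + 0.5, ev.onset_s - SCR_GUARD_S
        if hi > lo:
            spans.append((lo, hi))
        prev_end = ev.offset_s
    if duration_s - SCR_GUARD_S > prev_end + 0.5:
        spans.append((prev_end + 0.5, duration_s - SCR_GUARD_S))
    return spans


def _scr_kernel(rate_hz: float) -> np.ndarray:
    tk = np.arange(0, 8 * SCR_DECAY_S, 1.0 / rate_hz)
    k = np.exp(-tk / SCR_DECAY_S) - np.exp(-tk / SCR_RISE_S)
    return k / k.max()


def _simulate_gsr(
    rng: np.random.Generator, duration_s: float, params: SubjectParams,
    events: list[StimulusEvent], effects: EffectSpec,
) -> ChannelSignal:
    n = int(duration_s * GSR_RATE)
    t = np.arange(n) / GSR_RATE
    x = np.full(n, params.baseline_scl)
    # slow drift: a few very-low-frequency sinusoids, ~0.1 uS scale
    for _ in range(3):
        period = rng.uniform(300, 900)
        x += (effects.slow_noise_scale * rng.uniform(0.02, 0.07)
              * np.sin(2 * np.pi * t / period + rng.uniform(0, 2 * np.pi)))
    x += params.gain_scl * _cluster_level_track(t, events, effects)
    for ev, _, r in _event_envelopes(t, events):
        off = effects.offsets(ev.cluster_quadrant)
        if off.scl_slope:
            x += params.gain_scl * off.scl_slope * r
    # phasic train: spontaneous SCRs in inter-stimulus intervals (with a
    # guard before each onset so tails die out before the image) plus
    # optional evoked SCRs during images (zero under the default policy,
    # which plants no class information in the phasic stream)
    impulses = np.zeros(n)
    gaps = _scr_gap_spans(events, duration_s)
    gap_total = sum(e - s for s, e in gaps)
    n_spont = rng.poisson(effects.rest_scr_rate_per_min / 60.0 * gap_total)
    for _ in range(n_spont):
        u = rng.uniform(0, gap_total)
        for s, e in gaps:
            if u < e - s:
                impulses[int((s + u) * GSR_RATE)] += rng.exponential(effects.rest_scr_amp_mean_us)
                break
            u -= e - s
    for ev in events:
        rate = (effects.stim_scr_rate_per_min
                + effects.offsets(ev.cluster_quadrant).scr_rate) / 60.0
        if rate <= 0:
            continue
        n_ev = rng.poisson(rate * ev.duration_s)
        amp_mean = effects.rest_scr_amp_mean_us + effects.offsets(ev.cluster_quadrant).scr_amp_mean
        for _ in range(n_ev):
            tt = rng.uniform(ev.onset_s, ev.offset_s)
            impulses[int(tt * GSR_RATE)] += rng.exponential(amp_mean)
    x += sps.fftconvolve(impulses, _scr_kernel(GSR_RATE))[:n]
    x += rng.normal(0, GSR_NOISE_US, n)
    return ChannelSignal("gsr", "uS", GSR_RATE, x)


def _simulate_ecg(
    rng: np.random.Generator, duration_s: float, params: SubjectParams,
    events: list[StimulusEvent], effects: EffectSpec,
) -> ChannelSignal:
    # coarse (4 Hz) tracks of the HR and SDNN offsets for the beat loop
    coarse = np.arange(0, duration_s, 0.25)
    hr_track = params.baseline_hr + params.gain_hr * _offset_track(coarse, events, effects, "hr_mean")
    sdnn_track = np.maximum(effects.rest_sdnn_ms + _offset_track(coarse, events, effects, "ibi_sdnn"), 5.0)
    beats = [0.0]
    x_ar = 0.0
    rho = IBI_AR_RHO
    while beats[-1] < duration_s:
        i = min(int(beats[-1] / 0.25), len(coarse) - 1)
        mean_ibi_ms = 60000.0 / hr_track[i]
        x_ar = rho * x_ar + rng.normal(0, sdnn_track[i] * np.sqrt(1 - rho ** 2))
        ibi_ms = np.clip(mean_ibi_ms + x_ar, 300.0, 2000.0)
        beats.append(beats[-1] + ibi_ms / 1000.0)
    beats = np.array(beats[:-1])
    n = int(duration_s * ECG_RATE)
    x = np.zeros(n)
    half = int(4 * R_BUMP_SIGMA_S * ECG_RATE)
    rel = np.arange(-half, half + 1) / ECG_RATE
    rendered = beats + rng.normal(0, BEAT_JITTER_MS / 1000.0, len(beats))
    for b in rendered:
        c = int(round(b * ECG_RATE))
        lo, hi = max(0, c - half), min(n, c + half + 1)
        if hi <= lo:
            continue
        tseg = (np.arange(lo, hi) / ECG_RATE) - b
        x[lo:hi] += np.exp(-0.5 * (tseg / R_BUMP_SIGMA_S) ** 2)
    x += rng.normal(0, 0.02, n)
    return ChannelSignal("ecg", "mV", ECG_RATE, x)


def _simulate_resp(
    rng: np.random.Generator, duration_s: float, params: SubjectParams,
    events: list[StimulusEvent], effects: EffectSpec,
) -> ChannelSignal:
    n = int(duration_s * RESP_RATE)
    t = np.arange(n) / RESP_RATE
    x = params.baseline_rr + params.gain_rr * _offset_track(t, events, effects, "rr")
    slow = sps.sosfiltfilt(
        sps.butter(2, 0.05, btype="low", fs=RESP_RATE, output="sos"),
        rng.normal(0, 1.0, n),
    )
    sd = slow.std()
    if sd > 0:
        x += effects.slow_noise_scale * 0.3 * slow / sd
    x += rng.normal(0, 0.05, n)  # device read-out noise, window-local
    return ChannelSignal("resp_rate", "breaths/min", RESP_RATE, x)


def _self_reports(
    rng: np.random.Generator, events: list[StimulusEvent]
) -> list[SelfReport]:
    """SAM reports: true ratings plus +-1 integer noise and 10% diagonal flips."""
    reports = []
    for ev in events:
        v = ev.iaps_valence_raw - 5.0
        a = ev.iaps_arousal_raw - 5.0
        if rng.random() < 0.10:
            v, a = -v, -a
        v += rng.integers(-1, 2)
        a += rng.integers(-1, 2)
        reports.append(SelfReport(
            image_id=ev.image_id,
            sam_valence=int(np.clip(round(v), -4, 4)) + 5,
            sam_arousal=int(np.clip(round(a), -4, 4)) + 5,
            response_time_s=float(np.clip(rng.normal(SAM_MEAN_S, SAM_SD_S), SAM_MIN_S, SAM_MAX_S)),
        ))
    return reports


def simulate_subject(
    params: SubjectParams,
    events: list[StimulusEvent] | None = None,
    effects: EffectSpec | None = None,
    seed: int | None = None,
) -> Recording:
    """One subject's full session under the stimulation protocol."""
    seed = params.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    if events is None:
        events = default_protocol(int(rng.integers(2 ** 31)))
    effects = effects or EffectSpec()
    duration = events[-1].offset_s + 20.0 if events else BASELINE_S + 20.0
    gsr = _simulate_gsr(rng, duration, params, events, effects)
    ecg = _simulate_ecg(rng, duration, params, events, effects)
    resp = _simulate_resp(rng, duration, params, events, effects)
    reports = _self_reports(rng, events)
    return Recording(
        participant_id=params.participant_id,
        channels={"gsr": gsr, "ecg": ecg, "resp_rate": resp},
        baseline_interval=(0.0, BASELINE_S),
        events=list(events),
        self_reports=reports,
    )


def simulate_cohort(
    n_subjects: int = 20,
    seed: int = 0,
    effects: EffectSpec | None = None,
    out_dir=None,
) -> list[Recording]:
    """Independent subjects from one master seed; optionally write to disk."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_subjects)
    recordings = []
    for i, child in enumerate(children):
        sub_seed = int(child.generate_state(1)[0] % (2 ** 31))
        params = SubjectParams.draw(f"P{i:02d}", sub_seed)
        recordings.append(simulate_subject(params, effects=effects))
    if out_dir is not None:
        from .io import write_recording
        from pathlib import Path

        for rec in recordings:
            write_recording(rec, Path(out_dir) / rec.participant_id)
    return recordings
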