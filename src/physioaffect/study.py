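"""End-to-end study orchestration on a cohort of recordings.

The per-subject chain is: tonic/phasic GSR decomposition and R-peak detection
at native rates, synchronization of the derived level streams onto the
36.5 Hz grid, baseline normalization against the rest period, 0.5-s window
feature extraction, self-assessment consistency filtering,
leave-one-image-per-class-out splitting, per-participant ReliefF, and
classifier training/evaluation.  Cohort-level aggregation yields the optimal
feature set (median-positive rule), accuracy/F-score tables, estimation
times and the pairwise ANOVA comparison of algorithms.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import affect, preprocess, select
from .affect import ALGORITHMS, PROBLEMS, WindowClassifier
from .cohort import EffectSpec, simulate_cohort
from .features import (
    ECG_FEATURES, FEATURE_NAMES, GSR_FEATURES, RESP_FEATURES,
    IbiSeries, WindowFeatureExtractor, detect_r_peaks, detect_scr_peaks,
    feature_table, hr_channel,
)
from .io import ChannelSignal, Recording
from .preprocess import SYNC_RATE_HZ


def build_extractor(recording: Recording, sync_rate_hz: float = SYNC_RATE_HZ) -> WindowFeatureExtractor:
    """Preprocess one recording into a ready window-feature extractor.

    ECG beat detection runs on the native 250 Hz stream before
    synchronization; SCL/SCR, the piecewise-constant instantaneous HR and the
    respiration rate are then interpolated onto the shared grid and the level
    streams are baseline-normalized.
    """
    gsr = recording.channels["gsr"]
    ecg = recording.channels["ecg"]
    resp = recording.channels["resp_rate"]

    dec = preprocess.decompose_gsr(gsr)
    scl = ChannelSignal("scl", "uS", gsr.rate_hz, dec.scl, gsr.t0_s)
    scr = ChannelSignal("scr", "uS", gsr.rate_hz, dec.scr, gsr.t0_s)

    beats = detect_r_peaks(ecg)
    ibi = IbiSeries.from_beats(beats)

    t0 = max(c.t0_s for c in (scl, scr, resp))
    t1 = min(c.end_s for c in (scl, scr, resp))
    scl_g = preprocess.resample_to_grid(scl, sync_rate_hz, t0, t1)
    scr_g = preprocess.resample_to_grid(scr, sync_rate_hz, t0, t1)
    resp_g = preprocess.resample_to_grid(resp, sync_rate_hz, t0, t1)
    hr_g = hr_channel(ibi, sync_rate_hz, t0, t1)

    b = recording.baseline_interval
    for ch in (scl_g, hr_g, resp_g):
        ch.samples = ch.samples - preprocess.baseline_mean(ch, b)

    pk_t, pk_a = detect_scr_peaks(scr_g.samples, sync_rate_hz, t0_s=scr_g.t0_s)
    return WindowFeatureExtractor(scl_g, scr_g, hr_g, resp_g, ibi, pk_t, pk_a)


def subject_feature_table(recording: Recording, apply_consistency: bool = True) -> pd.DataFrame:
    """The labeled window-feature table of one subject.

    Images whose self-assessment is diagonally opposite the normative rating
    are dropped when ``apply_consistency`` is set.
    """
    table = feature_table(recording, build_extractor(recording))
    if apply_consistency and len(table):
        kept, _ = affect.consistency_filter(recording.events, recording.self_reports)
        table = table[table["image_id"].isin(kept)].reset_index(drop=True)
    return table


# ---------------------------------------------------------------------------
# per-window latency measurement


def make_window_processor(recording: Recording, ibi: IbiSeries, window: tuple[float, float]):
    """A closure that filters one raw 0.5-s window and returns its feature row.

    Models the on-line path: the raw channel slices are filtered from
    scratch, features extracted, and the resulting single-row table is handed
    to the classifier.  The inter-beat buffer plays the role of the running
    beat history a live system would maintain.
    """
    w0, w1 = window
    # pad the crops so the 0.5-s analysis window is covered on every stream
    # despite the unaligned sample grids
    gsr_slice = recording.channels["gsr"].crop(w0, w1 + 0.2, rebase=False)
    resp_slice = recording.channels["resp_rate"].crop(w0, w1 + 0.2, rebase=False)

    def process() -> pd.DataFrame:
        dec = preprocess.decompose_gsr(gsr_slice)
        rate = gsr_slice.rate_hz
        scl = ChannelSignal("scl", "uS", rate, dec.scl, gsr_slice.t0_s)
        scr = ChannelSignal("scr", "uS", rate, dec.scr, gsr_slice.t0_s)
        start = max(gsr_slice.t0_s, resp_slice.t0_s)
        hr = hr_channel(ibi, rate, start, start + 0.6)
        pk_t, pk_a = detect_scr_peaks(scr.samples, rate, t0_s=scr.t0_s)
        ext = WindowFeatureExtractor(scl, scr, hr, resp_slice, ibi, pk_t, pk_a)
        row = ext.extract(start, start + 0.5)
        return pd.DataFrame([row])

    return process


def measure_estimation_times(
    model: WindowClassifier,
    recording: Recording,
    ibi: IbiSeries,
    windows: list[tuple[float, float]],
) -> list[float]:
    """Per-window wall-clock latency (ms) of the full raw-to-label chain."""
    out = []
    for w in windows:
        proc = make_window_processor(recording, ibi, w)
        out.append(affect.measure_estimation_time(model, proc))
    return out


def paired_estimation_times(
    models: dict[str, WindowClassifier],
    recording: Recording,
    ibi: IbiSeries,
    windows: list[tuple[float, float]],
) -> dict[str, list[float]]:
    """Per-window latencies for several models on identical windows.

    The shared filtering/extraction stage is timed once per window and
    charged to every model, so model comparisons are paired and the shared
    stage's timing noise cancels exactly; each model's own cost is its
    subset selection plus prediction on the freshly extracted row.
    """
    out: dict[str, list[float]] = {name: [] for name in models}
    for w in windows:
        proc = make_window_processor(recording, ibi, w)
        t0 = time.perf_counter()
        row = proc()
        t_shared = time.perf_counter() - t0
        for name, model in models.items():
            t0 = time.perf_counter()
            model.predict(row)
            out[name].append((t_shared + time.perf_counter() - t0) * 1000.0)
    return out


# ---------------------------------------------------------------------------
# study configuration and runner


ABLATION_SETS = {
    "all": list(FEATURE_NAMES),
    "cardiorespiratory": list(ECG_FEATURES + RESP_FEATURES),
    "gsr": list(GSR_FEATURES),
}


@dataclass
class StudyConfig:
    """Everything a full study run needs; all fields have study defaults."""

    seed: int = 0
    n_subjects: int = 20
    relieff_k: int = 5
    relieff_problem: str = "FIVE_CLASS"
    problems: tuple[str, ...] = ("HL_VALENCE", "HL_AROUSAL", "FOUR_CLASS", "FIVE_CLASS")
    algorithms: tuple[str, ...] = ALGORITHMS
    feature_set_policy: str = "both"  # all | optimal | both
    window_s: float = 0.5
    sync_rate_hz: float = SYNC_RATE_HZ
    knn_k: int = 5
    svm_c: float = 1.0
    n_timing_windows: int = 0  # per cell; 0 disables latency measurement
    run_ablation: bool = True
    effects: EffectSpec | None = None

    def __post_init__(self) -> None:
        for p in self.problems:
            if p not in PROBLEMS:
                raise ValueError(f"unknown problem {p!r}")
        if self.window_s <= 0:
            raise ValueError("window_s must be > 0")

    def feature_sets(self) -> list[str]:
        if self.feature_set_policy == "both":
            return ["all", "optimal"]
        return [self.feature_set_policy]


@dataclass
class StudyReport:
    """Results of one full study run."""

    config: StudyConfig
    optimal_set: select.OptimalFeatureSet
    weights: pd.DataFrame            # participant, k, feature, weight
    accuracy: pd.DataFrame           # problem, algorithm, feature_set, participant, accuracy, f_score
    anova: pd.DataFrame
    ablation: pd.DataFrame | None = None
    timing: pd.DataFrame | None = None
    stage_seconds: dict[str, float] = field(default_factory=dict)


def cohort_optimal_set(
    tables: list[pd.DataFrame],
    k: int = 5,
    problem_id: str = "FIVE_CLASS",
    seed: int = 0,
) -> tuple[select.OptimalFeatureSet, list[select.ReliefFWeights]]:
    """Per-participant ReliefF on training windows, then the median rule.

    Selection is fit on each participant's LOIO training split only, so the
    held-out images never influence ranges, weights, or the selected set.
    """
    problem = PROBLEMS[problem_id]
    per_participant = []
    for i, table in enumerate(tables):
        train, _ = affect.loio_split(table, problem, seed=seed + i)
        w = select.relieff(
            train[list(FEATURE_NAMES)], train["label"].to_numpy(), k=k,
            participant_id=str(table["participant_id"].iloc[0]) if len(table) else f"P{i}",
        )
        per_participant.append(w)
    return select.optimal_feature_set(per_participant), per_participant


def run_study(config: StudyConfig, recordings: list[Recording] | None = None) -> StudyReport:
    """Execute the full study design and return all result tables."""
    stage_t: dict[str, float] = {}
    t0 = time.perf_counter()
    if recordings is None:
        recordings = simulate_cohort(config.n_subjects, seed=config.seed,
                                     effects=config.effects)
    stage_t["simulate"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    tables = [subject_feature_table(rec) for rec in recordings]
    stage_t["features"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    optimal, per_participant = cohort_optimal_set(
        tables, k=config.relieff_k, problem_id=config.relieff_problem, seed=config.seed
    )
    weights_rows = [
        {"participant_id": w.participant_id, "k": w.k, "feature": f, "weight": v}
        for w in per_participant for f, v in w.weights.items()
    ]
    stage_t["select"] = time.perf_counter() - t0

    subsets: dict[str, list[str]] = {"all": list(FEATURE_NAMES)}
    if optimal.features:
        subsets["optimal"] = optimal.features

    t0 = time.perf_counter()
    acc_rows = []
    for table in tables:
        pid = str(table["participant_id"].iloc[0])
        for pname in config.problems:
            problem = PROBLEMS[pname]
            train, test = affect.loio_split(table, problem, seed=config.seed)
            for algo in config.algorithms:
                for fs in config.feature_sets():
                    if fs not in subsets:
                        continue
                    model = affect.fit(algo, train, feature_subset=subsets[fs],
                                       n_neighbors=config.knn_k, C=config.svm_c)
                    rep = affect.evaluate(model, test, problem_id=pname, feature_set=fs)
                    acc_rows.append({
                        "problem": pname, "algorithm": algo, "feature_set": fs,
                        "participant": pid, "accuracy": rep.accuracy,
                        "f_score": rep.f_score,
                    })
    accuracy = pd.DataFrame(acc_rows)
    stage_t["evaluate"] = time.perf_counter() - t0

    anova_rows = []
    for pname in config.problems:
        for fs in config.feature_sets():
            sub = accuracy[(accuracy["problem"] == pname) & (accuracy["feature_set"] == fs)]
            groups = {a: g["accuracy"].tolist() for a, g in sub.groupby("algorithm")}
            if len(groups) >= 2 and all(len(v) >= 2 for v in groups.values()):
                tbl = affect.compare_models(groups)
                tbl.insert(0, "problem", pname)
                tbl.insert(1, "feature_set", fs)
                anova_rows.append(tbl)
    anova = pd.concat(anova_rows, ignore_index=True) if anova_rows else pd.DataFrame()

    ablation = None
    if config.run_ablation:
        t0 = time.perf_counter()
        abl_sets = dict(ABLATION_SETS)
        if optimal.features:
            abl_sets["optimal"] = optimal.features
        abl_rows = []
        for table in tables:
            pid = str(table["participant_id"].iloc[0])
            for pname in config.problems:
                problem = PROBLEMS[pname]
                train, test = affect.loio_split(table, problem, seed=config.seed)
                for fs_name, fs in abl_sets.items():
                    model = affect.fit("KNN", train, feature_subset=fs,
                                       n_neighbors=config.knn_k)
                    rep = affect.evaluate(model, test, problem_id=pname, feature_set=fs_name)
                    abl_rows.append({"problem": pname, "feature_set": fs_name,
                                     "participant": pid, "accuracy": rep.accuracy})
        ablation = pd.DataFrame(abl_rows)
        stage_t["ablation"] = time.perf_counter() - t0

    timing = None
    if config.n_timing_windows > 0:
        t0 = time.perf_counter()
        timing = _measure_timing(config, recordings[0], tables[0], subsets)
        stage_t["timing"] = time.perf_counter() - t0

    return StudyReport(
        config=config, optimal_set=optimal,
        weights=pd.DataFrame(weights_rows), accuracy=accuracy, anova=anova,
        ablation=ablation, timing=timing, stage_seconds=stage_t,
    )


def _measure_timing(config: StudyConfig, recording: Recording, table: pd.DataFrame,
                    subsets: dict[str, list[str]]) -> pd.DataFrame:
    """Latency per algorithm x feature set on the first subject's windows."""
    ibi = IbiSeries.from_beats(detect_r_peaks(recording.channels["ecg"]))
    problem = PROBLEMS["FIVE_CLASS"]
    train, test = affect.loio_split(table, problem, seed=config.seed)
    wins = [(s, s + 0.5) for s in test["window_start_s"].head(config.n_timing_windows)]
    rows = []
    for algo in config.algorithms:
        for fs_name, fs in subsets.items():
            model = affect.fit(algo, train, feature_subset=fs, n_neighbors=config.knn_k,
                               C=config.svm_c)
            times = measure_estimation_times(model, recording, ibi, wins)
            rows.append({"algorithm": algo, "feature_set": fs_name,
                         "mean_ms": float(np.mean(times)), "std_ms": float(np.std(times)),
                         "n_windows": len(times)})
    return pd.DataFrame(rows)


def write_report(report: StudyReport, out_dir: str | Path) -> None:
    """Serialize a study report as CSV tables plus a markdown summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = f"# seed={report.config.seed} n_subjects={report.config.n_subjects}\n"
    for name, df in (("accuracy", report.accuracy), ("weights", report.weights),
                     ("anova", report.anova), ("ablation", report.ablation),
                     ("timing", report.timing)):
        if df is not None and len(df):
            with open(out / f"{name}.csv", "w", encoding="utf-8") as fh:
                fh.write(header)
                df.to_csv(fh, index=False)
    lines = ["# Study summary", "",
             f"Seed: {report.config.seed}; subjects: {report.config.n_subjects}", "",
             f"Optimal feature set ({len(report.optimal_set.features)} features): "
             + ", ".join(report.optimal_set.features), ""]
    if len(report.accuracy):
        mean_acc = (report.accuracy.groupby(["problem", "algorithm", "feature_set"])["accuracy"]
                    .mean().reset_index())
        lines += ["## Mean accuracy", "", mean_acc.to_string(index=False), ""]
    else:
        lines += ["No evaluations were run.", ""]
    for stage, secs in report.stage_seconds.items():
        lines.append(f"- stage {stage}: {secs:.1f} s")
    (out / "summary.md").write_text("\n".join(lines) + "\n", encoding="utf-8")
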