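"""End-to-end orchestration: simulate -> quality-filter -> calibrate ->
convert -> average -> compare.

`run_cohort` mirrors a full validation study on synthetic patients: each
patient's paired recording is SNF-screened, the earliest stable 30-min
overlap is found, the cuff device is calibrated once against the arterial
line at the overlap start, beats are converted to pressure (with offset
recalibration when heart rate or arterial stiffness drift by more than
30%), both devices are averaged over 10-s intervals, and the agreement
battery is computed per patient and pooled.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import quality, pda, series as series_mod
from .agreement import MethodComparison, AgreementResults
from .quality import InclusionThresholds
from .pda import ConversionSlopes, DecompositionConfig
from .simulate import (ChannelConfig, DynamicsConfig, generate_bp_trajectory,
                       synthesize_recording)

__all__ = ["RunConfig", "PatientResult", "CohortReport", "run_cohort",
           "analyze_recording", "render_report"]


@dataclass(frozen=True)
class RunConfig:
    """All knobs of a cohort run; defaults are the validated constants
    (500 Hz, 8-s/1-s SNF windows, thresholds 80/140, 15-s/5-beat
    calibration, 30% recalibration rule, 10-s averaging, 30-min window,
    20/12 mmHg zero-zone exclusions, 5/8 mmHg AAMI limits)."""

    cohort_size: int = 15
    duration_s: float = 1980.0       # 33 min: margin around the 30-min window
    rate_hz: float = 500.0
    analysis_window_s: float = 1800.0
    calibration_window_s: float = 15.0
    calibration_beats: int = 5
    recal_check_every_s: float = 60.0
    recal_threshold: float = 0.30
    interval_s: float = 10.0
    zone_mmhg: float = 10.0
    zone_mode: str = "radius"
    snf_exclude: float = quality.SNF_EXCLUDE_THRESHOLD
    snf_stable: float = quality.SNF_STABLE_THRESHOLD
    dynamics: DynamicsConfig = field(default_factory=DynamicsConfig)
    channels: ChannelConfig = field(default_factory=ChannelConfig)
    slopes: ConversionSlopes = field(default_factory=ConversionSlopes)
    seed: int = 0

    def content_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PatientResult:
    patient_id: int
    overlap: tuple
    paired: "series_mod.PairedSeries"
    results: AgreementResults
    ranges_mmhg: dict
    excluded_fraction: float
    n_beats: int
    recalibrations: list


@dataclass
class CohortReport:
    config: RunConfig
    patients: list
    skipped: list
    pooled: AgreementResults
    pooled_data: pd.DataFrame

    def manifest(self) -> dict:
        return {"config_hash": self.config.content_hash(),
                "seed": self.config.seed,
                "n_patients": len(self.patients),
                "n_skipped": len(self.skipped),
                "n_pooled_pairs": int(len(self.pooled_data))}

    def to_dict(self) -> dict:
        return {
            "manifest": self.manifest(),
            "pooled": self.pooled.to_dict(),
            "patients": [{
                "patient_id": p.patient_id,
                "overlap_s": list(p.overlap),
                "n_pairs": len(p.paired),
                "n_beats": p.n_beats,
                "excluded_fraction": p.excluded_fraction,
                "ranges_mmhg": p.ranges_mmhg,
                "recalibrations": p.recalibrations,
                "results": p.results.to_dict(),
            } for p in self.patients],
            "skipped": self.skipped,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _patient_seeds(master_seed: int, n: int) -> list[tuple[int, int]]:
    """Deterministic (trajectory, recording) sub-seed pair per patient."""
    ss = np.random.SeedSequence(master_seed)
    out = []
    for child in ss.spawn(n):
        a, b = child.generate_state(2)
        out.append((int(a) & 0x7FFFFFFF, int(b) & 0x7FFFFFFF))
    return out


def analyze_recording(recording, config: RunConfig) -> PatientResult | str:
    """Run the full quality/calibration/conversion/averaging chain on one
    paired recording.  Returns a PatientResult, or a reason string if the
    recording has no stable overlap."""
    rate = recording.rate_hz
    snf = quality.compute_snf(recording.cuff, rate)

    try:
        beats = pda.detect_beats(recording.cuff, rate)
    except ValueError as e:
        return f"beat detection failed: {e}"
    beat_times = np.array([b.onset_s for b in beats])
    mask = quality.apply_inclusion_rules(
        recording, snf, InclusionThresholds(snf_min=config.snf_exclude),
        cuff_beat_times_s=beat_times)

    overlap = quality.find_stable_overlap(
        mask, snf, required_s=config.analysis_window_s,
        snf_stable=config.snf_stable)
    if overlap is None:
        return "no stable overlap"
    t0, t1 = overlap

    features = pda.extract_features(recording.cuff, rate, beats=beats)
    features = features[(features["onset_s"] >= t0)
                        & (features["onset_s"] < t1)].reset_index(drop=True)
    if features["valid"].sum() < config.calibration_beats:
        return "too few valid beats in overlap"

    # reference beat-level values from the arterial-line waveform
    rt, rs, rd = quality._reference_beats(recording.reference_mmhg, rate)
    in_overlap = (rt >= t0) & (rt < t1)
    rt, rs, rd = rt[in_overlap], rs[in_overlap], rd[in_overlap]
    if len(rt) == 0:
        return "no reference beats in overlap"

    def reference_reading(t_start: float):
        sel = (rt >= t_start) & (rt < t_start + config.calibration_window_s)
        if sel.sum() < config.calibration_beats:
            return None
        return float(rs[sel].mean()), float(rd[sel].mean())

    reading = reference_reading(t0)
    if reading is None:
        return "no reference reading at overlap start"
    try:
        cal = pda.calibrate(features, *reading, slopes=config.slopes,
                            window_s=config.calibration_window_s,
                            n_beats=config.calibration_beats, time_s=t0)
    except ValueError as e:
        return f"calibration failed: {e}"

    # convert beats piecewise, refreshing offsets on trigger
    recals = []
    converted = []
    seg_start = t0
    checkpoints = np.arange(t0 + config.recal_check_every_s, t1,
                            config.recal_check_every_s)
    for tc in list(checkpoints) + [t1]:
        seg = features[(features["onset_s"] >= seg_start)
                       & (features["onset_s"] < tc)]
        if len(seg):
            converted.append(pda.convert_to_bp(seg, cal))
        seg_start = tc
        if tc >= t1:
            break
        window = features[(features["onset_s"] >= tc - config.recal_check_every_s)
                          & (features["onset_s"] < tc)]
        fire, reason = pda.recalibration_trigger(
            window, cal, window_s=config.recal_check_every_s,
            threshold=config.recal_threshold)
        if fire:
            reading = reference_reading(tc)
            if reading is not None:
                try:
                    cal = pda.calibrate(features, *reading,
                                        slopes=config.slopes,
                                        window_s=config.calibration_window_s,
                                        n_beats=config.calibration_beats,
                                        time_s=tc)
                    recals.append({"time_s": float(tc), "reason": reason})
                except ValueError:
                    pass
    conv = pd.concat(converted, ignore_index=True)

    window = (t0, t0 + config.analysis_window_s)
    test_series = series_mod.beats_to_series(
        conv["onset_s"], conv["sbp"], conv["dbp"], window,
        device="cuff", interval_s=config.interval_s)
    ref_series = series_mod.beats_to_series(
        rt, rs, rd, window, device="a-line", interval_s=config.interval_s)
    paired = series_mod.pair_series(ref_series, test_series, mask)
    if len(paired) < 2:
        return "too few paired intervals"

    results = MethodComparison.from_paired_series(
        paired, zone_mmhg=config.zone_mmhg, zone_mode=config.zone_mode).fit()
    return PatientResult(
        patient_id=-1, overlap=(t0, t1), paired=paired, results=results,
        ranges_mmhg=series_mod.intra_patient_range(ref_series),
        excluded_fraction=paired.excluded_fraction,
        n_beats=int(features["valid"].sum()), recalibrations=recals)


def run_cohort(config: RunConfig | None = None,
               progress: bool = False) -> CohortReport:
    """Simulate and analyze a whole cohort; pool the paired intervals.

    Patients without a stable overlap are reported in ``skipped`` and the
    run continues.  Reruns with an identical config (including seed) are
    bit-identical.
    """
    cfg = config or RunConfig()
    patients, skipped, pooled_frames = [], [], []
    for pid, (s_traj, s_rec) in enumerate(_patient_seeds(cfg.seed,
                                                         cfg.cohort_size)):
        traj = generate_bp_trajectory(cfg.duration_s, cfg.dynamics, s_traj)
        rec = synthesize_recording(traj, channel_config=cfg.channels,
                                   seed=s_rec, rate_hz=cfg.rate_hz)
        out = analyze_recording(rec, cfg)
        if isinstance(out, str):
            skipped.append({"patient_id": pid, "reason": out})
            continue
        out.patient_id = pid
        patients.append(out)
        # offset each patient far beyond interval adjacency so pooled
        # trending statistics never bridge across patients
        block = out.paired.data.copy()
        block["interval_start_s"] += pid * (cfg.duration_s + 1000.0)
        pooled_frames.append(block)
        if progress:
            print(f"patient {pid}: {len(out.paired)} pairs, "
                  f"{len(out.recalibrations)} recalibrations")
    if not pooled_frames:
        raise RuntimeError("no patient produced a stable overlap")
    pooled_data = pd.concat(pooled_frames, ignore_index=True)
    pooled = MethodComparison(pooled_data, interval_s=cfg.interval_s,
                              zone_mmhg=cfg.zone_mmhg,
                              zone_mode=cfg.zone_mode).fit()
    return CohortReport(config=cfg, patients=patients, skipped=skipped,
                        pooled=pooled, pooled_data=pooled_data)


def render_report(report: CohortReport, outdir) -> list:
    """Write the report JSON, the per-quantity CSV table, and the five
    figures (Bland-Altman, correlation, 4-quadrant, polar, SD-over-time).
    Returns the list of created files."""
    import pathlib
    import matplotlib.pyplot as plt
    from . import plots

    if not report.patients:
        raise ValueError("empty cohort report")
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    created = []

    p = outdir / "report.json"
    report.to_json(p)
    created.append(p)
    p = outdir / "agreement.csv"
    report.pooled.to_frame().to_csv(p, index=False)
    created.append(p)

    figures = {
        "bland_altman.png": lambda ax: plots.bland_altman_plot(report.pooled, "map", ax=ax),
        "correlation.png": lambda ax: plots.correlation_plot(report.pooled, "map", ax=ax),
        "four_quadrant.png": lambda ax: plots.four_quadrant_plot(report.pooled, "map", ax=ax),
        "sd_over_time.png": lambda ax: plots.sd_over_time_plot(report.patients[0].results, ax=ax),
    }
    for name, fn in figures.items():
        fig, ax = plt.subplots(figsize=(6, 4.5))
        fn(ax)
        fig.tight_layout()
        fig.savefig(outdir / name, dpi=100)
        plt.close(fig)
        created.append(outdir / name)
    fig = plt.figure(figsize=(6, 5))
    ax = fig.add_subplot(projection="polar")
    plots.polar_plot(report.pooled, "map", ax=ax)
    fig.tight_layout()
    fig.savefig(outdir / "polar.png", dpi=100)
    plt.close(fig)
    created.append(outdir / "polar.png")
    return created
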