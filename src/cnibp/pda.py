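"""Pulse Decomposition Analysis: beat detection, component features,
calibration and blood-pressure conversion.

The peripheral arterial pulse is modelled as a superposition of the
primary left-ventricular ejection pulse (P1) and two reflected pulses
arriving from central reflection sites: the renal juncture (P2) and the
iliac bifurcation (P3).  Two features track pressure: the P1-to-P3 delay
T13 (shortens as systolic pressure rises) and the amplitude ratio
P2/P1 (grows with pulse pressure).  Conversion to absolute pressure is
linear with population slopes and per-patient offsets fixed by a one-time
calibration against a reference reading; only the offsets ever change
(at recalibration events triggered by persistent heart-rate or arterial-
stiffness changes exceeding 30%).

The cuff sensor is derivative-coupled, so all feature extraction operates
on the numerically integrated channel; features are amplitude-ratio and
timing based, hence invariant to the unknown sensor gain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as _sig

__all__ = [
    "Beat", "BeatFeatures", "CalibrationState", "ConversionSlopes",
    "DecompositionConfig", "detect_beats", "decompose_beat",
    "extract_features", "calibrate", "convert_to_bp",
    "recalibration_trigger", "integrate_cuff",
]

MIN_PERIOD_S = 0.24
MAX_PERIOD_S = 3.0


@dataclass(frozen=True)
class Beat:
    """One detected cardiac cycle on the integrated cuff signal."""

    onset_s: float        # pulse foot
    period_s: float
    start_idx: int        # segment bounds into the integrated channel
    end_idx: int


@dataclass
class BeatFeatures:
    """Per-beat PDA quantities.  Amplitudes are in sensor units and only
    meaningful as ratios; timing in seconds."""

    onset_s: float
    p1: float
    p2: float
    p3: float
    t12_s: float
    t13_s: float
    p2p1: float
    hr_bpm: float
    stiffness: float
    valid: bool
    note: str = ""


@dataclass(frozen=True)
class ConversionSlopes:
    """Population conversion slopes (fixed during a run).

    Defaults are the inverse of the simulator's parameter linkage:
    SBP tracks T13 at -1/0.0012 mmHg/s and PP tracks P2P1 at 1/0.006 mmHg
    per unit ratio.
    """

    sbp_per_t13_mmhg_per_s: float = -1.0 / 0.0012
    pp_per_p2p1_mmhg: float = 1.0 / 0.006


@dataclass
class CalibrationState:
    """Baseline features plus the reference pressures that anchor them.

    The linear conversions are written in anchored form, so converting the
    baseline features reproduces the reference SBP/DBP exactly; the
    implied offsets are ``sbp_ref - slope * t13_baseline`` etc.
    """

    sbp_ref_mmhg: float
    dbp_ref_mmhg: float
    t13_baseline_s: float
    p2p1_baseline: float
    hr_baseline_bpm: float
    stiffness_baseline: float
    slopes: ConversionSlopes
    time_s: float = 0.0

    @property
    def pp_ref_mmhg(self) -> float:
        return self.sbp_ref_mmhg - self.dbp_ref_mmhg

    @property
    def sbp_offset_mmhg(self) -> float:
        return self.sbp_ref_mmhg - self.slopes.sbp_per_t13_mmhg_per_s * self.t13_baseline_s

    @property
    def pp_offset_mmhg(self) -> float:
        return self.pp_ref_mmhg - self.slopes.pp_per_p2p1_mmhg * self.p2p1_baseline


@dataclass(frozen=True)
class DecompositionConfig:
    """Physiological search windows for the reflection pulses, relative to
    the P1 peak, and validity gates."""

    p2_window_s: tuple = (0.040, 0.180)
    p3_window_s: tuple = (0.180, 0.500)
    highpass_hz: float = 0.5
    min_prominence_frac: float = 0.03   # reflections, relative to P1
    amp_gate: tuple = (0.25, 4.0)       # beat amplitude vs running median


def integrate_cuff(cuff: np.ndarray, rate_hz: float) -> np.ndarray:
    """Cumulative integral of the derivative-coupled cuff signal.

    Recovers a pressure-shaped waveform up to gain and a slow drift; the
    drift is removed per-beat (linear detrend between feet), not here.
    """
    return np.cumsum(np.asarray(cuff, dtype=float)) / rate_hz


def _highpass(x: np.ndarray, rate_hz: float, fc: float) -> np.ndarray:
    sos = _sig.butter(2, fc, btype="highpass", fs=rate_hz, output="sos")
    return _sig.sosfiltfilt(sos, x)


def _bandpass(x: np.ndarray, rate_hz: float, lo: float, hi: float) -> np.ndarray:
    sos = _sig.butter(2, [lo, hi], btype="bandpass", fs=rate_hz, output="sos")
    return _sig.sosfiltfilt(sos, x)


def detect_beats(cuff: np.ndarray, rate_hz: float,
                 config: DecompositionConfig | None = None) -> list[Beat]:
    """Detect cardiac cycles on the cuff channel.

    The derivative-coupled signal is integrated; cycle timing is found on
    a 0.5-3 Hz band-passed copy where the composite pulse is unimodal (the
    reflection bumps live above that band), then each systolic peak and
    its preceding foot are located on the unsmoothed integral.  Beats with
    implausible periods, or with amplitudes far from the running median
    (as inside motion bursts), are discarded.

    Raises if no beats are found at all.
    """
    cfg = config or DecompositionConfig()
    y = integrate_cuff(cuff, rate_hz)
    z = _bandpass(y, rate_hz, cfg.highpass_hz, 3.0)

    amp = np.percentile(z, 98) - np.percentile(z, 2)
    if amp <= 0:
        raise ValueError("no beats found: flat channel")
    cand, props = _sig.find_peaks(z, distance=int(MIN_PERIOD_S * rate_hz),
                                  prominence=0.25 * amp)
    if len(cand) == 0:
        raise ValueError("no beats found")

    prom = props["prominences"]
    # amplitude gate against a running median prominence: rejects the
    # outsized excursions of motion bursts
    k = 15
    med = np.array([np.median(prom[max(0, i - k):i + k + 1])
                    for i in range(len(prom))])
    lo_g, hi_g = cfg.amp_gate
    keep = (prom > lo_g * med) & (prom < hi_g * med)
    cand = cand[keep]
    if len(cand) == 0:
        raise ValueError("no beats found")

    # refine: systolic peak on the raw integral near each band-passed peak
    half = int(0.25 * rate_hz)
    peaks = []
    for p in cand:
        a, b = max(0, p - half), min(len(y), p + half)
        peaks.append(a + int(np.argmax(y[a:b])))
    peaks = np.unique(peaks)

    # feet: the waveform can return to baseline between the ejection pulse
    # and the late iliac reflection, so the foot is sought only in a short
    # window just before each systolic peak (the true diastolic valley)
    pre = int(0.25 * rate_hz)
    feet = np.array([max(0, p - pre) + int(np.argmin(y[max(0, p - pre):p + 1]))
                     for p in peaks])

    # the final peak has no closing foot (incomplete cycle) and is dropped
    beats: list[Beat] = []
    for i, p in enumerate(peaks[:-1]):
        period = (peaks[i + 1] - p) / rate_hz
        if not (MIN_PERIOD_S < period < MAX_PERIOD_S):
            continue
        beats.append(Beat(onset_s=feet[i] / rate_hz, period_s=float(period),
                          start_idx=feet[i],
                          end_idx=max(feet[i + 1], feet[i] + 2)))
    if not beats:
        raise ValueError("no plausible beats found")
    return beats


def _refine_peak(y: np.ndarray, i: int, rate_hz: float):
    """Parabolic (three-point) refinement of a sampled peak."""
    if 0 < i < len(y) - 1:
        a, b, c = y[i - 1], y[i], y[i + 1]
        denom = a - 2 * b + c
        if denom != 0:
            d = 0.5 * (a - c) / denom
            d = float(np.clip(d, -0.5, 0.5))
            return (i + d) / rate_hz, b - 0.25 * (a - c) * d
    return i / rate_hz, y[i]


def decompose_beat(segment: np.ndarray, rate_hz: float, onset_s: float = 0.0,
                   period_s: float | None = None,
                   config: DecompositionConfig | None = None) -> BeatFeatures:
    """Extract P1/P2/P3 amplitudes and delays from one beat segment.

    The segment runs foot-to-foot; a line through its endpoints is removed
    so amplitudes are measured from the diastolic baseline.  P1 is the
    first prominent peak; P2 and P3 are the largest local maxima inside
    their physiological delay windows after P1, with parabolic sub-sample
    refinement.  Beats whose reflections cannot be resolved are flagged
    invalid.
    """
    cfg = config or DecompositionConfig()
    y = np.asarray(segment, dtype=float)
    n = len(y)
    if period_s is None:
        period_s = n / rate_hz
    invalid = lambda note: BeatFeatures(
        onset_s=onset_s, p1=np.nan, p2=np.nan, p3=np.nan, t12_s=np.nan,
        t13_s=np.nan, p2p1=np.nan, hr_bpm=60.0 / period_s, stiffness=np.nan,
        valid=False, note=note)
    if n < 5:
        return invalid("segment too short")

    # remove the foot-to-foot baseline
    base = np.linspace(y[0], y[-1], n)
    z = y - base
    if z.max() <= 0:
        return invalid("no positive excursion")

    peaks, props = _sig.find_peaks(z, prominence=cfg.min_prominence_frac * z.max())
    if len(peaks) == 0:
        return invalid("no P1 peak")
    # P1: the tallest peak (the ejection pulse dominates the composite)
    i1 = peaks[int(np.argmax(z[peaks]))]
    t1, p1 = _refine_peak(z, i1, rate_hz)
    if p1 <= 0:
        return invalid("nonpositive P1")

    def reflection(window):
        lo = i1 + int(window[0] * rate_hz)
        hi = min(i1 + int(window[1] * rate_hz), n - 2)
        cand = [p for p in peaks if lo <= p <= hi and p != i1]
        if not cand:
            return None
        i = cand[int(np.argmax(z[cand]))]
        return _refine_peak(z, i, rate_hz)

    def p2_from_residual(window):
        # The renal reflection usually rides fused on P1's falling edge
        # with no local maximum of its own.  The kernel is symmetric and
        # P1's left flank carries no reflections, so mirroring the beat
        # about the P1 peak and subtracting cancels P1 exactly; the
        # residual inside the search window is an almost pure P2 bump.
        lo = int(np.ceil((t1 + window[0]) * rate_hz))
        hi = min(int((t1 + window[1]) * rate_hz), n - 2)
        if hi - lo < 3:
            return None
        idx = np.arange(lo, hi + 1)
        mirror = 2.0 * t1 * rate_hz - idx
        tail = np.interp(np.clip(mirror, 0, n - 1), np.arange(n), z)
        r = z[lo:hi + 1] - tail
        m, _ = _sig.find_peaks(r)
        if len(m) == 0:
            m = [int(np.argmax(r))]
            if m[0] in (0, len(r) - 1):
                return None
        i = m[int(np.argmax(r[m]))]
        tt, amp = _refine_peak(r, i, rate_hz)
        tt += lo / rate_hz
        if amp < cfg.min_prominence_frac * p1:
            return None
        # width of the residual bump -> correct P1 for P2's own tail
        half = amp / 2.0
        j = i
        while j > 0 and r[j] > half:
            j -= 1
        hwhm = (i - j) / rate_hz
        return tt, float(amp), hwhm

    r2 = p2_from_residual(cfg.p2_window_s)
    r3 = reflection(cfg.p3_window_s)
    if r2 is None or r3 is None:
        return invalid("unresolved reflection")
    t2, p2, hwhm2 = r2
    t3, p3 = r3

    # refine amplitudes by linear least squares: Gaussian kernels at the
    # located component times (widths from flank half-widths) plus a
    # linear baseline that absorbs residual detrending error
    hwhm_to_w = 1.0 / math.sqrt(2.0 * math.log(2.0))
    j = i1
    while j > 0 and z[j] > 0.5 * p1:
        j -= 1
    w1 = max((i1 - j) / rate_hz, 2.0 / rate_hz) * hwhm_to_w
    w2 = max(hwhm2, 2.0 / rate_hz) * hwhm_to_w
    i3 = int(round(t3 * rate_hz))
    j = i3
    while j < n - 1 and z[j] > 0.5 * z[i3]:
        j += 1
    w3 = max((j - i3) / rate_hz, 2.0 / rate_hz) * hwhm_to_w
    tt = np.arange(n) / rate_hz

    def ls_fit(c1, c2, c3):
        design = np.column_stack([
            np.exp(-0.5 * ((tt - c1) / w1) ** 2),
            np.exp(-0.5 * ((tt - c2) / w2) ** 2),
            np.exp(-0.5 * ((tt - c3) / w3) ** 2),
            np.ones(n), tt,
        ])
        coef, *_ = np.linalg.lstsq(design, z, rcond=None)
        return design, coef

    design, coef = ls_fit(t1, t2, t3)
    if coef[0] > 0 and coef[1] > 0 and coef[2] > 0:
        # each component's apparent peak is pulled by its neighbours'
        # tails; re-locate every centre on the residual with the other
        # two fitted components removed, then refit the amplitudes
        centers = [t1, t2, t3]
        new_centers = []
        for k in range(3):
            resid = z - design[:, :3] @ coef[:3] + design[:, k] * coef[k]
            i0 = int(round(centers[k] * rate_hz))
            lo_k = max(1, i0 - int(0.02 * rate_hz))
            hi_k = min(n - 1, i0 + int(0.02 * rate_hz))
            i_new = lo_k + int(np.argmax(resid[lo_k:hi_k + 1]))
            tk, _ = _refine_peak(resid, i_new, rate_hz)
            new_centers.append(tk)
        c1, c2, c3 = new_centers
        if 0 < c2 - c1 < c3 - c1:
            _, coef = ls_fit(c1, c2, c3)
            if coef[0] > 0 and coef[1] > 0 and coef[2] > 0:
                t1, t2, t3 = c1, c2, c3
                t12, t13 = t2 - t1, t3 - t1
        p1, p2, p3 = float(coef[0]), float(coef[1]), float(coef[2])
    elif p1 <= 0 or p2 <= 0:
        return invalid("unresolved reflection")
    t12, t13 = t2 - t1, t3 - t1
    if not (0 < t12 < t13 < period_s):
        return invalid("implausible delays")
    return BeatFeatures(onset_s=onset_s, p1=float(p1), p2=float(p2),
                        p3=float(p3), t12_s=float(t12), t13_s=float(t13),
                        p2p1=float(p2 / p1), hr_bpm=60.0 / period_s,
                        stiffness=float(p2 / p1), valid=True)


def extract_features(cuff: np.ndarray, rate_hz: float,
                     beats: list[Beat] | None = None,
                     config: DecompositionConfig | None = None) -> pd.DataFrame:
    """Detect beats (unless given) and decompose each one.

    Returns a DataFrame with one row per beat:
    onset_s, p1, p2, p3, t12_s, t13_s, p2p1, hr_bpm, stiffness, valid.
    """
    cfg = config or DecompositionConfig()
    if beats is None:
        beats = detect_beats(cuff, rate_hz, cfg)
    y = integrate_cuff(cuff, rate_hz)
    rows = []
    for b in beats:
        f = decompose_beat(y[b.start_idx:b.end_idx], rate_hz,
                           onset_s=b.onset_s, period_s=b.period_s, config=cfg)
        rows.append(vars(f))
    return pd.DataFrame(rows)


def calibrate(features: pd.DataFrame, sbp_ref_mmhg: float, dbp_ref_mmhg: float,
              slopes: ConversionSlopes | None = None,
              window_s: float = 15.0, n_beats: int = 5,
              time_s: float | None = None) -> CalibrationState:
    """One-time calibration against a reference reading.

    Averages the PDA features of the first ``n_beats`` valid beats inside
    the opening ``window_s`` of the supplied feature table and anchors the
    linear conversions so those baseline features map exactly to the
    reference SBP/DBP.  Slopes are population defaults, never fitted.

    Raises if fewer than ``n_beats`` valid beats fall in the window.
    """
    if not (20 <= dbp_ref_mmhg < sbp_ref_mmhg <= 300):
        raise ValueError("reference pressures not physiological")
    slopes = slopes or ConversionSlopes()
    t0 = float(features["onset_s"].iloc[0]) if time_s is None else time_s
    sel = features[(features["onset_s"] >= t0)
                   & (features["onset_s"] < t0 + window_s)
                   & features["valid"]]
    if len(sel) < n_beats:
        raise ValueError(f"need >= {n_beats} valid beats in the "
                         f"{window_s}-s calibration window, got {len(sel)}")
    head = sel.iloc[:n_beats]
    return CalibrationState(
        sbp_ref_mmhg=float(sbp_ref_mmhg), dbp_ref_mmhg=float(dbp_ref_mmhg),
        t13_baseline_s=float(head["t13_s"].mean()),
        p2p1_baseline=float(head["p2p1"].mean()),
        hr_baseline_bpm=float(head["hr_bpm"].mean()),
        stiffness_baseline=float(head["stiffness"].median()),
        slopes=slopes, time_s=t0)


def convert_to_bp(features: pd.DataFrame, cal: CalibrationState,
                  clamp_mmhg: tuple = (20.0, 300.0)) -> pd.DataFrame:
    """Convert per-beat PDA features to SBP/DBP/MAP via the calibrated
    linear equations.

    SBP = slope_S (T13 - T13_baseline) + SBP_ref;
    PP  = slope_P (P2P1 - P2P1_baseline) + PP_ref;
    DBP = SBP - PP;  MAP = DBP + PP/3.  Invalid beats produce no output.
    Outputs are clamped to the physiological range with a flag.
    """
    f = features[features["valid"]].copy()
    s = cal.slopes
    sbp = s.sbp_per_t13_mmhg_per_s * (f["t13_s"] - cal.t13_baseline_s) + cal.sbp_ref_mmhg
    pp = s.pp_per_p2p1_mmhg * (f["p2p1"] - cal.p2p1_baseline) + cal.pp_ref_mmhg
    dbp = sbp - pp
    lo, hi = clamp_mmhg
    clamped = (sbp < lo) | (sbp > hi) | (dbp < lo) | (dbp > hi)
    sbp = sbp.clip(lo, hi)
    dbp = dbp.clip(lo, hi)
    out = pd.DataFrame({
        "onset_s": f["onset_s"],
        "sbp": sbp, "dbp": dbp,
        "map": dbp + (sbp - dbp) / 3.0,
        "clamped": clamped,
    })
    return out.reset_index(drop=True)


def recalibration_trigger(features: pd.DataFrame, cal: CalibrationState,
                          window_s: float = 60.0,
                          threshold: float = 0.30) -> tuple[bool, str]:
    """Decide whether a recalibration is due.

    Compares the windowed medians of heart rate and of the arterial-
    stiffness proxy (the P2/P1 ratio) against their calibration baselines;
    a persistent relative change strictly exceeding the threshold (default
    30%) on either quantity triggers, and the violating quantity is
    reported.  The pipeline responds by refreshing the conversion offsets
    at the next valid reference reading; slopes never change.
    """
    valid = features[features["valid"]]
    if len(valid) == 0:
        return False, ""
    t_end = float(valid["onset_s"].iloc[-1])
    win = valid[valid["onset_s"] > t_end - window_s]
    if len(win) == 0:
        return False, ""
    hr = float(win["hr_bpm"].median())
    st = float(win["stiffness"].median())
    if cal.hr_baseline_bpm > 0:
        rel = abs(hr - cal.hr_baseline_bpm) / cal.hr_baseline_bpm
        if rel > threshold:
            return True, f"heart-rate change {100 * rel:.1f}%"
    if cal.stiffness_baseline > 0 and np.isfinite(st):
        rel = abs(st - cal.stiffness_baseline) / cal.stiffness_baseline
        if rel > threshold:
            return True, f"stiffness change {100 * rel:.1f}%"
    return False, ""
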