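"""Signal/noise factor (SNF) and data-inclusion rules.

The SNF of a window is the ratio of the waveform variance in the
physiological base band (1-10 Hz, the arterial pulse and its propagation
content) to the variance in a high band (100-250 Hz) that carries only
ambient/sensor noise.  It is computed by Fourier spectral estimation over
sliding 8-s windows with a 1-s hop.  Sections of the cuff channel with
SNF below 80 are excluded; the comparison window additionally requires
SNF >= 140.  The reference (arterial-line) channel is screened with
catheter-plausibility rules instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as _sig

SIGNAL_BAND_HZ = (1.0, 10.0)
NOISE_BAND_HZ = (100.0, 250.0)
SNF_EXCLUDE_THRESHOLD = 80.0
SNF_STABLE_THRESHOLD = 140.0

__all__ = [
    "SNFSeries", "InclusionMask", "InclusionThresholds",
    "compute_snf", "apply_inclusion_rules", "find_stable_overlap",
    "SIGNAL_BAND_HZ", "NOISE_BAND_HZ",
    "SNF_EXCLUDE_THRESHOLD", "SNF_STABLE_THRESHOLD",
]


@dataclass
class SNFSeries:
    """Windowed signal/noise factor values.

    One value per full window; windows start at t = 0 and advance by
    ``hop_s``.  Values are dimensionless variance ratios; windows whose
    noise band carries exactly zero variance report ``inf``.
    """

    window_start_s: np.ndarray
    snf: np.ndarray
    window_s: float = 8.0
    hop_s: float = 1.0

    def __len__(self):
        return len(self.snf)

    def at_time(self, t: float) -> float:
        """SNF of the window starting at (or just before) time t."""
        i = int(np.clip(np.searchsorted(self.window_start_s, t, "right") - 1,
                        0, len(self.snf) - 1))
        return float(self.snf[i])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"window_start_s": self.window_start_s,
                             "snf": self.snf})

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)


REASON_LOW_SNF = "low-SNF"
REASON_MOTION = "motion"
REASON_CATHETER = "catheter-failure"


@dataclass
class InclusionMask:
    """Per-second validity of each channel with one reason per exclusion.

    Slot i covers [i, i+1) seconds.  ``cuff_reason``/``ref_reason`` hold an
    empty string for valid slots and exactly one reason code otherwise.
    """

    slot_s: np.ndarray
    cuff_valid: np.ndarray
    ref_valid: np.ndarray
    cuff_reason: np.ndarray
    ref_reason: np.ndarray

    def __len__(self):
        return len(self.slot_s)

    @property
    def both_valid(self) -> np.ndarray:
        return self.cuff_valid & self.ref_valid

    def excluded_fraction(self) -> float:
        return float(1.0 - np.mean(self.both_valid))

    def to_frame(self) -> pd.DataFrame:
        """Excluded spans as (start_s, end_s, channel, reason) rows."""
        rows = []
        for valid, reason, channel in ((self.cuff_valid, self.cuff_reason, "cuff"),
                                       (self.ref_valid, self.ref_reason, "reference")):
            i = 0
            n = len(valid)
            while i < n:
                if not valid[i]:
                    j = i
                    while j < n and not valid[j] and reason[j] == reason[i]:
                        j += 1
                    rows.append({"start_s": float(self.slot_s[i]),
                                 "end_s": float(self.slot_s[j - 1] + 1.0),
                                 "channel": channel, "reason": reason[i]})
                    i = j
                else:
                    i += 1
        return pd.DataFrame(rows, columns=["start_s", "end_s", "channel", "reason"])

    def to_csv(self, path):
        self.to_frame().to_csv(path, index=False)


def _band_variance(freqs: np.ndarray, psd: np.ndarray, band) -> float:
    lo, hi = band
    sel = (freqs >= lo) & (freqs <= hi)
    if not sel.any():
        return 0.0
    df = freqs[1] - freqs[0]
    return float(np.sum(psd[sel]) * df)


def compute_snf(x: np.ndarray, rate_hz: float,
                window_s: float = 8.0, hop_s: float = 1.0) -> SNFSeries:
    """Sliding-window signal/noise factor of a waveform channel.

    Per window the band variances are estimated with a Welch averaged
    periodogram (2-s Hann segments, 50% overlap) and integrated over the
    1-10 Hz signal band and the 100-250 Hz noise band; SNF is their ratio.

    Raises if ``rate_hz`` < 500 (the noise band would extend beyond
    Nyquist) or the signal is shorter than one window.
    """
    if rate_hz < 500:
        raise ValueError("sampling rate must be >= 500 Hz so the 100-250 Hz "
                         "noise band lies at or below Nyquist")
    x = np.asarray(x, dtype=float)
    win = int(round(window_s * rate_hz))
    hop = int(round(hop_s * rate_hz))
    if len(x) < win:
        raise ValueError("signal shorter than one SNF window")

    nperseg = min(int(round(2.0 * rate_hz)), win)
    starts = np.arange(0, len(x) - win + 1, hop)
    snf = np.empty(len(starts))
    for k, s in enumerate(starts):
        seg = x[s:s + win]
        freqs, psd = _sig.welch(seg, fs=rate_hz, nperseg=nperseg,
                                noverlap=nperseg // 2, detrend="constant")
        v_sig = _band_variance(freqs, psd, SIGNAL_BAND_HZ)
        v_noise = _band_variance(freqs, psd, NOISE_BAND_HZ)
        snf[k] = np.inf if v_noise == 0.0 else v_sig / v_noise
    return SNFSeries(window_start_s=starts / rate_hz, snf=snf,
                     window_s=window_s, hop_s=hop_s)


@dataclass(frozen=True)
class InclusionThresholds:
    """Concrete operationalization of the exclusion rules.

    The catheter-plausibility limits implement "obvious catheter failure":
    frozen (flat-line) pressure, values outside a survivable range,
    implausibly small pulse pressure, or nonphysiological beat-to-beat
    systolic jumps.
    """

    snf_min: float = SNF_EXCLUDE_THRESHOLD
    pressure_range_mmhg: tuple = (20.0, 300.0)
    max_beat_sbp_jump_mmhg: float = 60.0
    min_pulse_pressure_mmhg: float = 5.0
    flatline_window_s: float = 5.0
    flatline_sd_mmhg: float = 0.05
    no_beat_gap_s: float = 5.0


def apply_inclusion_rules(recording, snf: SNFSeries,
                          thresholds: InclusionThresholds | None = None,
                          cuff_beat_times_s: np.ndarray | None = None) -> InclusionMask:
    """Build the per-second validity mask for both channels.

    Cuff slots are excluded where the covering SNF window falls below the
    threshold (reason ``low-SNF``) or where beat detection found no beats
    for longer than the gap limit (reason ``motion``; pass the detected
    beat times to enable this rule).  Reference slots are excluded where
    the catheter-plausibility rules fail (reason ``catheter-failure``).
    """
    th = thresholds or InclusionThresholds()
    rate = recording.rate_hz
    n_slots = int(recording.duration_s)
    slots = np.arange(n_slots, dtype=float)

    cuff_valid = np.ones(n_slots, dtype=bool)
    ref_valid = np.ones(n_slots, dtype=bool)
    cuff_reason = np.array([""] * n_slots, dtype=object)
    ref_reason = np.array([""] * n_slots, dtype=object)

    # --- low SNF: slot i carries the verdict of the window starting at i
    for i in range(n_slots):
        if snf.at_time(slots[i]) < th.snf_min:
            cuff_valid[i] = False
            cuff_reason[i] = REASON_LOW_SNF

    # --- motion: no cuff beats for > gap limit
    if cuff_beat_times_s is not None and len(cuff_beat_times_s) > 0:
        t = np.sort(np.asarray(cuff_beat_times_s, dtype=float))
        edges = np.concatenate(([0.0], t, [recording.duration_s]))
        for a, b in zip(edges[:-1], edges[1:]):
            if b - a > th.no_beat_gap_s:
                lo, hi = int(np.ceil(a)), min(int(b), n_slots)
                for i in range(lo, hi):
                    if cuff_valid[i]:
                        cuff_valid[i] = False
                        cuff_reason[i] = REASON_MOTION

    # --- catheter plausibility on the reference channel
    ref = recording.reference_mmhg
    lo_p, hi_p = th.pressure_range_mmhg
    fw = int(th.flatline_window_s * rate)
    for i in range(n_slots):
        s = int(i * rate)
        e = min(int((i + 1) * rate), len(ref))
        seg = ref[s:e]
        bad = bool(np.any((seg < lo_p) | (seg > hi_p)))
        if not bad:
            # flat-line: SD over the surrounding window collapses
            c = min(max(s, 0), len(ref) - 1)
            w0, w1 = max(0, c - fw // 2), min(len(ref), c + fw // 2 + 1)
            if np.std(ref[w0:w1]) < th.flatline_sd_mmhg:
                bad = True
        if bad:
            ref_valid[i] = False
            ref_reason[i] = REASON_CATHETER

    # beat-level plausibility: systolic jumps and pulse pressure
    sys_t, sys_v, dia_v = _reference_beats(ref, rate)
    if len(sys_t) >= 2:
        jumps = np.abs(np.diff(sys_v))
        for k in np.nonzero(jumps > th.max_beat_sbp_jump_mmhg)[0]:
            for i in range(int(sys_t[k]), min(int(sys_t[k + 1]) + 1, n_slots)):
                if ref_valid[i]:
                    ref_valid[i] = False
                    ref_reason[i] = REASON_CATHETER
    if len(sys_t) >= 1:
        pp = sys_v - dia_v
        for k in np.nonzero(pp < th.min_pulse_pressure_mmhg)[0]:
            i = min(int(sys_t[k]), n_slots - 1)
            if ref_valid[i]:
                ref_valid[i] = False
                ref_reason[i] = REASON_CATHETER

    return InclusionMask(slot_s=slots, cuff_valid=cuff_valid,
                         ref_valid=ref_valid, cuff_reason=cuff_reason,
                         ref_reason=ref_reason)


def _reference_beats(ref: np.ndarray, rate: float):
    """Systolic peak times (s) and per-beat systolic/diastolic values.

    Cycle timing is taken from a 0.5-3 Hz band-passed copy (immune to the
    reflection bumps riding on the pulse); the systolic value is the raw
    maximum near each cycle peak and the diastolic value is the preceding
    foot minimum.
    """
    from .pda import _bandpass
    z = _bandpass(ref, rate, 0.5, 3.0)
    amp = np.percentile(z, 98) - np.percentile(z, 2)
    if amp <= 0:
        return np.array([]), np.array([]), np.array([])
    cyc, _ = _sig.find_peaks(z, distance=int(0.24 * rate),
                             prominence=0.25 * amp)
    if len(cyc) == 0:
        return np.array([]), np.array([]), np.array([])
    half = int(0.25 * rate)
    peaks = np.unique([max(0, c - half) + int(np.argmax(ref[max(0, c - half):
                                                           min(len(ref), c + half)]))
                       for c in cyc])
    sys_v = ref[peaks]
    dia_v = np.array([ref[max(0, p - half):p + 1].min() for p in peaks])
    return peaks / rate, sys_v, dia_v


def find_stable_overlap(mask: InclusionMask, snf: SNFSeries,
                        required_s: float = 1800.0,
                        snf_stable: float = SNF_STABLE_THRESHOLD,
                        tolerance_fraction: float = 0.05):
    """Earliest interval of the required length that is stable.

    A stable interval has both channels valid and the cuff SNF at or above
    ``snf_stable`` in (almost) every covering window; a small tolerance
    fraction of sub-threshold seconds is permitted, but the interval must
    open on a fully stable window so a leading contaminated block is never
    straddled.  Returns (start_s, end_s), or None if no such interval
    exists.  Raises if the record is shorter than the required length.
    """
    n = len(mask)
    req = int(round(required_s))
    if n < req:
        raise ValueError("recording shorter than the required overlap")

    bad = np.zeros(n, dtype=bool)
    for i in range(n):
        if not mask.both_valid[i] or snf.at_time(mask.slot_s[i]) < snf_stable:
            bad[i] = True
    cbad = np.concatenate(([0], np.cumsum(bad)))
    max_bad = tolerance_fraction * req
    for s in range(0, n - req + 1):
        if bad[s]:
            continue
        if cbad[s + req] - cbad[s] <= max_bad:
            return float(mask.slot_s[s]), float(mask.slot_s[s] + req)
    return None
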