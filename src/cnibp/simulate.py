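"""Synthetic paired hemodynamic recordings with full ground truth.

Generates the kind of data an operating-room comparison of a finger-cuff
pulse monitor against a radial arterial line produces: a slowly varying
true blood-pressure trajectory (induction-of-anesthesia dynamics), a beat
train built from superposed component pulses (the primary left-ventricular
ejection pulse P1 plus renal and iliac reflection pulses P2, P3), an
invasive reference channel seen through an underdamped catheter-tubing
resonance, and a derivative-coupled cuff channel in arbitrary sensor units.

Every recording embeds its ground truth (trajectory and per-beat component
parameters), so downstream feature extraction and agreement statistics can
be tested without any real recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as _sig

__all__ = [
    "BPTrajectory",
    "ComponentPulseSpec",
    "ArtifactSpec",
    "PairedRecording",
    "ChannelConfig",
    "DynamicsConfig",
    "mean_arterial_pressure",
    "DEFAULT_LINKAGE",
    "ParameterLinkage",
    "generate_bp_trajectory",
    "synthesize_beat",
    "synthesize_recording",
]


# --------------------------------------------------------------------------
# parameter linkage: how component-pulse timing/amplitude track pressure
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ParameterLinkage:
    """Monotone, invertible map from (SBP, PP) to (T13, P2P1).

    T13, the P1→P3 delay, shortens as systolic pressure rises (stiffer,
    faster central arteries); P2P1, the renal-reflection amplitude ratio,
    grows with pulse pressure.  The linear forms are deliberately simple
    so calibration-based inversion is exact; slopes are configurable.
    """

    t13_ref_s: float = 0.40          # T13 at SBP = sbp_ref
    t13_slope_s_per_mmhg: float = -0.0012
    sbp_ref_mmhg: float = 120.0
    p2p1_ref: float = 0.40           # P2P1 at PP = pp_ref
    p2p1_slope_per_mmhg: float = 0.006
    pp_ref_mmhg: float = 40.0

    def t13(self, sbp: np.ndarray | float) -> np.ndarray | float:
        return self.t13_ref_s + self.t13_slope_s_per_mmhg * (np.asarray(sbp) - self.sbp_ref_mmhg)

    def p2p1(self, pp: np.ndarray | float) -> np.ndarray | float:
        return self.p2p1_ref + self.p2p1_slope_per_mmhg * (np.asarray(pp) - self.pp_ref_mmhg)

    def sbp_from_t13(self, t13: np.ndarray | float) -> np.ndarray | float:
        return self.sbp_ref_mmhg + (np.asarray(t13) - self.t13_ref_s) / self.t13_slope_s_per_mmhg

    def pp_from_p2p1(self, p2p1: np.ndarray | float) -> np.ndarray | float:
        return self.pp_ref_mmhg + (np.asarray(p2p1) - self.p2p1_ref) / self.p2p1_slope_per_mmhg


DEFAULT_LINKAGE = ParameterLinkage()


def mean_arterial_pressure(sbp, dbp):
    """MAP = DBP + (SBP - DBP)/3, applied uniformly to both devices."""
    sbp = np.asarray(sbp, dtype=float)
    dbp = np.asarray(dbp, dtype=float)
    return dbp + (sbp - dbp) / 3.0


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class BPTrajectory:
    """Ground-truth blood-pressure trajectory on a coarse time grid.

    All pressures in mmHg, heart rate in beats/min.  ``map`` always follows
    the DBP + PP/3 convention.
    """

    time_s: np.ndarray
    sbp: np.ndarray
    dbp: np.ndarray
    map: np.ndarray
    hr_bpm: np.ndarray

    def __post_init__(self):
        if not np.all(self.sbp > self.dbp):
            raise ValueError("systolic must exceed diastolic everywhere")
        if not (np.all(self.map > self.dbp) and np.all(self.map < self.sbp)):
            raise ValueError("MAP must lie strictly between DBP and SBP")
        if not np.all((self.hr_bpm > 20) & (self.hr_bpm < 250)):
            raise ValueError("heart rate outside (20, 250) bpm")

    def at(self, t):
        """Linear interpolation of all quantities at time(s) t."""
        t = np.asarray(t, dtype=float)
        return {
            "sbp": np.interp(t, self.time_s, self.sbp),
            "dbp": np.interp(t, self.time_s, self.dbp),
            "map": np.interp(t, self.time_s, self.map),
            "hr_bpm": np.interp(t, self.time_s, self.hr_bpm),
        }

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1])


@dataclass(frozen=True)
class ComponentPulseSpec:
    """Amplitudes, onsets and widths of the component pulses of one beat.

    Up to five components are supported (ejection P1, renal reflection P2,
    iliac reflection P3, and optional re-reflections P4/P5); defaults use
    three with the re-reflection amplitudes at zero.  Kernel is a unimodal
    bump; only the Gaussian kernel is currently implemented.
    """

    amplitudes_mmhg: tuple  # A_k, first entry is P1
    onsets_s: tuple         # tau_k, tau_1 == 0 by convention
    widths_s: tuple
    kernel: str = "gaussian"

    def __post_init__(self):
        a, tau, w = self.amplitudes_mmhg, self.onsets_s, self.widths_s
        if not (len(a) == len(tau) == len(w)):
            raise ValueError("amplitudes, onsets, widths must have equal length")
        if a[0] <= 0:
            raise ValueError("P1 amplitude must be positive")
        if tau[0] != 0:
            raise ValueError("P1 onset must be zero")
        if len(tau) >= 3 and not tau[1] < tau[2]:
            raise ValueError("P2 onset must precede P3 onset")
        if any(x <= 0 for x in w):
            raise ValueError("widths must be positive")
        if self.kernel != "gaussian":
            raise ValueError(f"unknown kernel {self.kernel!r}")


@dataclass(frozen=True)
class ArtifactSpec:
    """An injected contamination interval.

    kind: 'motion' (large low-frequency burst that destroys beat structure
    on the cuff channel), 'catheter_failure' (reference channel frozen at a
    constant), or 'broadband' (white noise added to the cuff channel,
    degrading the signal/noise factor).
    """

    kind: str
    start_s: float
    end_s: float
    magnitude: float = 1.0

    KINDS = ("motion", "catheter_failure", "broadband")

    def __post_init__(self):
        if self.kind not in self.KINDS:
            raise ValueError(f"artifact kind must be one of {self.KINDS}")
        if self.end_s <= self.start_s:
            raise ValueError("artifact end must follow start")
        if self.magnitude < 0:
            raise ValueError("artifact magnitude must be non-negative")


@dataclass(frozen=True)
class ChannelConfig:
    """Sensor/transmission models for the two channels.

    The reference channel passes through a linear second-order resonance
    emulating catheter-tubing underdamping (which inflates systolic
    readings); set ``catheter_filter='identity'`` for a transparent
    channel.  The cuff sensor is derivative-coupled: its output is the
    time-derivative of the (scaled) pressure wave, in arbitrary units.
    """

    catheter_filter: str = "resonant"   # 'resonant' | 'identity'
    catheter_fn_hz: float = 15.0        # natural frequency
    catheter_zeta: float = 0.2          # damping ratio (underdamped)
    ref_noise_mmhg: float = 0.3         # white sensor noise, reference
    cuff_gain: float = 0.02             # sensor units per (mmHg/s)
    cuff_noise: float = 0.004           # white noise SD, sensor units
    noise: bool = True                  # master noise switch
    p3p1_ratio: float = 0.30            # A3/A1 default
    t12_fraction: float = 0.35          # tau2 = tau1 + fraction * T13
    tau1_s: float = 0.16                # P1 peak delay after beat foot
    widths_s: tuple = (0.050, 0.060, 0.050)


@dataclass
class PairedRecording:
    """Two synchronized channels plus embedded ground truth."""

    rate_hz: float
    reference_mmhg: np.ndarray     # arterial-line pressure channel
    cuff: np.ndarray               # derivative-coupled pulse channel, a.u.
    time_offset_s: float
    trajectory: BPTrajectory
    beat_onsets_s: np.ndarray      # ground truth, one per beat (foot time)
    beat_specs: list               # ComponentPulseSpec per beat
    beat_truth: "object"           # DataFrame: per-beat true BP / T13 / P2P1
    seed: int
    artifacts: tuple = ()

    def __post_init__(self):
        if len(self.reference_mmhg) != len(self.cuff):
            raise ValueError("channels must have equal length")
        if self.rate_hz < 500:
            raise ValueError("sampling rate must be >= 500 Hz")

    @property
    def duration_s(self) -> float:
        return len(self.cuff) / self.rate_hz

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(len(self.cuff)) / self.rate_hz


# --------------------------------------------------------------------------
# trajectory generation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DynamicsConfig:
    """Parameters of the induction-scale trajectory model.

    The induction model is a baseline pressure, a smooth anesthetic-
    induction dip of random depth, and a band-limited slow wander.  Depth
    distributions are set so that the intra-record systolic range averages
    about 35 mmHg and the diastolic range about 18 mmHg across patients,
    the scale of dynamics seen during induction of general anesthesia.
    """

    mode: str = "induction"          # 'induction' | 'flat'
    sbp0_mmhg: float = 120.0
    dbp0_mmhg: float = 80.0
    hr0_bpm: float = 76.0
    sbp_dip_mean_mmhg: float = 28.0
    sbp_dip_sd_mmhg: float = 19.0
    dbp_dip_ratio_mean: float = 0.47
    dbp_dip_ratio_sd: float = 0.13
    wander_sbp_mmhg: float = 1.5     # slow-wander amplitude
    wander_hr_bpm: float = 5.0
    dip_onset_frac: float = 0.12     # induction dip timing, fraction of record
    dip_width_frac: float = 0.18
    recovery_frac: float = 0.55      # partial recovery level of the dip
    event_rate_per_30min: float = 3.0   # vasoactive boluses / stimulation
    event_amp_mean_mmhg: float = 18.0
    event_amp_sd_mmhg: float = 6.0
    event_rise_s: float = 3.0
    event_decay_s: float = 90.0
    grid_dt_s: float = 0.5


def _smooth_wander(rng: np.random.Generator, n: int, dt: float, amp: float,
                   n_modes: int = 4, period_range=(120.0, 600.0)) -> np.ndarray:
    """Sum of a few slow sinusoids with random phase; SD ~ amp."""
    t = np.arange(n) * dt
    out = np.zeros(n)
    for _ in range(n_modes):
        period = rng.uniform(*period_range)
        phase = rng.uniform(0, 2 * np.pi)
        out += np.sin(2 * np.pi * t / period + phase)
    return amp * out / np.sqrt(n_modes / 2.0)


def generate_bp_trajectory(duration_s: float,
                           dynamics: DynamicsConfig | str = "induction",
                           seed: int = 0) -> BPTrajectory:
    """Generate a smooth ground-truth BP/HR trajectory.

    Parameters
    ----------
    duration_s : record length in seconds (> 0).
    dynamics : a :class:`DynamicsConfig`, or one of ``'induction'`` /
        ``'flat'`` for the defaults.
    seed : deterministic; same (config, seed) gives an identical trajectory.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    if isinstance(dynamics, str):
        dynamics = DynamicsConfig(mode=dynamics)
    cfg = dynamics
    rng = np.random.default_rng(seed)
    n = max(int(round(duration_s / cfg.grid_dt_s)) + 1, 2)
    t = np.linspace(0.0, duration_s, n)

    if cfg.mode == "flat":
        sbp = np.full(n, cfg.sbp0_mmhg)
        dbp = np.full(n, cfg.dbp0_mmhg)
        hr = np.full(n, cfg.hr0_bpm)
    elif cfg.mode == "induction":
        # induction dip: sigmoid drop to full depth, partial recovery
        t_on = cfg.dip_onset_frac * duration_s
        w = max(cfg.dip_width_frac * duration_s, 1.0)
        drop = 1.0 / (1.0 + np.exp(-(t - t_on) / (0.15 * w)))
        recov = 1.0 / (1.0 + np.exp(-(t - (t_on + 2.2 * w)) / (0.35 * w)))
        profile = drop - (1.0 - cfg.recovery_frac) * recov  # in [0, 1]

        depth_s = abs(rng.normal(cfg.sbp_dip_mean_mmhg, cfg.sbp_dip_sd_mmhg))
        depth_s = float(np.clip(depth_s, 4.0, 70.0))
        ratio = float(np.clip(rng.normal(cfg.dbp_dip_ratio_mean,
                                         cfg.dbp_dip_ratio_sd), 0.25, 0.85))
        depth_d = depth_s * ratio

        # vasoactive events: pressor boluses / airway stimulation produce
        # fast rises (seconds) with slow decay, the source of the large
        # consecutive 10-s changes seen during induction
        events = np.zeros(n)
        n_ev = rng.poisson(cfg.event_rate_per_30min * duration_s / 1800.0)
        for _ in range(n_ev):
            t_e = rng.uniform(0.15, 0.95) * duration_s
            amp = float(np.clip(rng.normal(cfg.event_amp_mean_mmhg,
                                           cfg.event_amp_sd_mmhg), 5.0, 30.0))
            rise = 1.0 / (1.0 + np.exp(-(t - t_e) / cfg.event_rise_s))
            decay = np.exp(-np.maximum(t - t_e, 0.0) / cfg.event_decay_s)
            events += amp * rise * decay

        sbp = cfg.sbp0_mmhg - depth_s * profile + events \
            + _smooth_wander(rng, n, cfg.grid_dt_s, cfg.wander_sbp_mmhg)
        dbp = cfg.dbp0_mmhg - depth_d * profile + 0.5 * events \
            + _smooth_wander(rng, n, cfg.grid_dt_s, 0.6 * cfg.wander_sbp_mmhg)
        hr = cfg.hr0_bpm + 6.0 * profile \
            + _smooth_wander(rng, n, cfg.grid_dt_s, cfg.wander_hr_bpm)
    else:
        raise ValueError(f"unknown dynamics mode {cfg.mode!r}")

    # physiological guards: keep PP >= 15 mmHg and pressures in range
    sbp = np.clip(sbp, 70.0, 220.0)
    dbp = np.clip(dbp, 40.0, 120.0)
    dbp = np.minimum(dbp, sbp - 15.0)
    hr = np.clip(hr, 30.0, 180.0)

    return BPTrajectory(time_s=t, sbp=sbp, dbp=dbp,
                        map=mean_arterial_pressure(sbp, dbp), hr_bpm=hr)


# --------------------------------------------------------------------------
# beat synthesis
# --------------------------------------------------------------------------

def _gaussian_sum(t: np.ndarray, spec: ComponentPulseSpec) -> np.ndarray:
    out = np.zeros_like(t)
    for a, tau, w in zip(spec.amplitudes_mmhg, spec.onsets_s, spec.widths_s):
        if a != 0:
            out += a * np.exp(-0.5 * ((t - tau) / w) ** 2)
    return out


def synthesize_beat(spec: ComponentPulseSpec, heart_period_s: float,
                    rate_hz: float, baseline_mmhg: float = 0.0) -> np.ndarray:
    """Sample one beat: baseline plus the sum of component Gaussian pulses.

    The segment spans one heart period.  Raises if the component onsets
    collide with the next beat (heart period must exceed the summed
    onsets, so the last reflection fits inside the cycle).
    """
    if heart_period_s <= sum(spec.onsets_s):
        raise ValueError("heart period too short: component pulses would "
                         "overlap the next beat onset")
    n = int(round(heart_period_s * rate_hz))
    t = np.arange(n) / rate_hz
    return baseline_mmhg + _gaussian_sum(t, spec)


def _beat_spec_for(sbp: float, dbp: float, cfg: ChannelConfig,
                   linkage: ParameterLinkage) -> ComponentPulseSpec:
    """Component spec whose summed waveform peaks exactly at SBP - DBP."""
    pp = sbp - dbp
    t13 = float(linkage.t13(sbp))
    p2p1 = float(linkage.p2p1(pp))
    onsets = (0.0, cfg.t12_fraction * t13, t13)  # relative to P1
    rel_amp = np.array([1.0, max(p2p1, 0.0), cfg.p3p1_ratio])
    # dense evaluation to normalise the summed peak to PP
    tt = np.linspace(-0.05, onsets[-1] + 0.2, 800)
    shape = np.zeros_like(tt)
    for a, tau, w in zip(rel_amp, onsets, cfg.widths_s):
        shape += a * np.exp(-0.5 * ((tt - tau) / w) ** 2)
    scale = pp / shape.max()
    return ComponentPulseSpec(
        amplitudes_mmhg=tuple(scale * rel_amp),
        onsets_s=onsets,
        widths_s=cfg.widths_s,
    )


# --------------------------------------------------------------------------
# full recording synthesis
# --------------------------------------------------------------------------

def _catheter_filter(x: np.ndarray, rate_hz: float, fn_hz: float,
                     zeta: float) -> np.ndarray:
    """Second-order underdamped resonance (catheter-tubing model)."""
    wn = 2 * np.pi * fn_hz
    b, a = _sig.bilinear([wn ** 2], [1.0, 2 * zeta * wn, wn ** 2], fs=rate_hz)
    # zi chosen so a constant input passes through without a start transient
    zi = _sig.lfilter_zi(b, a) * x[0]
    y, _ = _sig.lfilter(b, a, x, zi=zi)
    return y


def synthesize_recording(trajectory: BPTrajectory,
                         artifacts: list[ArtifactSpec] | tuple = (),
                         channel_config: ChannelConfig | None = None,
                         seed: int = 0,
                         rate_hz: float = 500.0,
                         linkage: ParameterLinkage = DEFAULT_LINKAGE) -> PairedRecording:
    """Render a paired (arterial-line, finger-cuff) recording.

    The reference channel is the pressure beat train seen through the
    catheter model plus sensor noise; the cuff channel is the time
    derivative of the scaled beat train plus band-limited noise.  Per-beat
    ground truth (true SBP/DBP/MAP, T13, P2P1, component spec) is embedded.
    """
    import pandas as pd

    cfg = channel_config or ChannelConfig()
    duration = trajectory.duration_s
    for art in artifacts:
        if art.start_s < 0 or art.end_s > duration:
            raise ValueError(f"artifact interval [{art.start_s}, {art.end_s}] "
                             "outside the recording")

    rng = np.random.default_rng(seed)
    # independent sub-streams so adding an artifact never perturbs the others
    rng_beats, rng_ref, rng_cuff, rng_art = rng.spawn(4)

    n = int(round(duration * rate_hz))
    t_axis = np.arange(n) / rate_hz

    # --- beat onsets by integrating heart rate ----------------------------
    onsets = []
    t = 0.0
    while t < duration - 0.3:
        onsets.append(t)
        hr = float(np.interp(t, trajectory.time_s, trajectory.hr_bpm))
        t += 60.0 / hr
    onsets = np.array(onsets)

    # --- pressure beat train on the global grid ---------------------------
    state = trajectory.at(onsets)
    dbp_base = np.interp(t_axis, trajectory.time_s, trajectory.dbp)
    pressure = dbp_base.copy()
    specs = []
    rows = []
    for i, t0 in enumerate(onsets):
        sbp_i, dbp_i = float(state["sbp"][i]), float(state["dbp"][i])
        spec = _beat_spec_for(sbp_i, dbp_i, cfg, linkage)
        specs.append(spec)
        period = (onsets[i + 1] - t0) if i + 1 < len(onsets) else 60.0 / float(state["hr_bpm"][i])
        i0 = int(np.ceil(t0 * rate_hz))
        i1 = min(int(np.ceil((t0 + period + 0.3) * rate_hz)), n)
        tt = t_axis[i0:i1] - t0 - cfg.tau1_s  # component time, P1 at tau1
        pressure[i0:i1] += _gaussian_sum(tt, spec)
        rows.append({
            "onset_s": t0, "period_s": period,
            "sbp_true": sbp_i, "dbp_true": dbp_i,
            "map_true": float(mean_arterial_pressure(sbp_i, dbp_i)),
            "t13_true": spec.onsets_s[2] - spec.onsets_s[0],
            "p2p1_true": spec.amplitudes_mmhg[1] / spec.amplitudes_mmhg[0],
        })
    truth = pd.DataFrame(rows)

    # --- reference channel: catheter dynamics + noise ---------------------
    if cfg.catheter_filter == "resonant":
        reference = _catheter_filter(pressure, rate_hz,
                                     cfg.catheter_fn_hz, cfg.catheter_zeta)
    elif cfg.catheter_filter == "identity":
        reference = pressure.copy()
    else:
        raise ValueError(f"unknown catheter filter {cfg.catheter_filter!r}")
    if cfg.noise and cfg.ref_noise_mmhg > 0:
        reference = reference + rng_ref.normal(0, cfg.ref_noise_mmhg, n)

    # --- cuff channel: derivative coupling + noise ------------------------
    cuff = cfg.cuff_gain * np.gradient(pressure) * rate_hz
    if cfg.noise and cfg.cuff_noise > 0:
        cuff = cuff + rng_cuff.normal(0, cfg.cuff_noise, n)

    # --- artifacts --------------------------------------------------------
    for art in artifacts:
        sl = slice(int(art.start_s * rate_hz), int(art.end_s * rate_hz))
        m = sl.stop - sl.start
        r = rng_art.spawn(1)[0]
        if art.kind == "broadband":
            cuff[sl] += r.normal(0, art.magnitude, m)
        elif art.kind == "motion":
            # large low-frequency excursion + chaos: kills beat structure
            wob = np.cumsum(r.normal(0, 1.0, m))
            wob = wob / (np.abs(wob).max() + 1e-12)
            cuff[sl] = art.magnitude * (wob + 0.3 * r.normal(0, 1.0, m))
        elif art.kind == "catheter_failure":
            reference[sl] = reference[sl.start] if sl.start > 0 else reference[0]

    return PairedRecording(
        rate_hz=rate_hz, reference_mmhg=reference, cuff=cuff,
        time_offset_s=0.0, trajectory=trajectory,
        beat_onsets_s=onsets, beat_specs=specs, beat_truth=truth,
        seed=seed, artifacts=tuple(artifacts),
    )
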