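# Methods

This note records the models implemented in `cnibp`, the defaults and
why they were chosen, the numerical decisions, and what the synthetic
data does and does not establish.

## The pulse decomposition model

The peripheral arterial pressure pulse is treated as a superposition of
component pulses: the primary left-ventricular ejection pulse (P1) and
reflections returning from two central arterial sites — the
thoracic/abdominal aortic juncture at the height of the renal arteries
(P2) and the junction of the abdominal aorta with the common iliac
arteries (P3).  Up to five components are supported (P4/P5 re-reflection
slots exist in the type but default to zero amplitude and are never
extracted).  Two features of the composite shape carry the pressure
information used here:

* **T13** (s): delay between the P1 and P3 arrivals.  Higher systolic
  pressure stiffens the central arteries, speeds the reflected wave and
  shortens T13.
* **P2/P1** (dimensionless): amplitude ratio of the renal reflection to
  the ejection pulse, increasing with pulse pressure.

Conversion to pressure is linear with fixed population slopes and
calibrated offsets:

    SBP = a_S (T13 − T13₀) + SBP_ref
    PP  = a_P (P2P1 − P2P1₀) + PP_ref
    DBP = SBP − PP,  MAP = DBP + PP/3

The linear forms are the minimal model consistent with the feature
semantics above and with an offset-only recalibration policy.  The
slope defaults, `a_S = −1/0.0012 ≈ −833 mmHg/s` and
`a_P = 1/0.006 ≈ 167 mmHg`, are the exact inverses of the simulator's
parameter linkage (below), so that on synthetic data the converter is
correctly specified and parameter-recovery error isolates the
measurement chain.  Both are configuration, not fitted quantities, and
never change during a run.

MAP is formed as DBP + PP/3 uniformly for both devices.  Monitors
differ in whether they report a waveform mean or a derived MAP; using
one convention on both sides keeps the comparison internally consistent.

The **arterial-stiffness proxy** used by the recalibration rule is the
5-beat median of P2/P1.  A pulse-envelope-based stiffness measure exists
in the field but has no published defining formula; the proxy is labelled
as such everywhere and is configurable.  "Persistent" change is
operationalized as the median over a 60-s window; the trigger fires when
that median departs from its calibration baseline by strictly more than
30% (relative), for heart rate or for the stiffness proxy.

## The synthetic-data generator

No recordings are distributed with this package, so the simulator is a
first-class component whose defaults define the study conditions.

**Trajectory model** (`generate_bp_trajectory`).  A patient's true
SBP/DBP/HR evolve on a 0.5-s grid as

* a baseline (120/80 mmHg, 76 bpm),
* an anesthetic-induction dip: sigmoid descent to a random depth with
  partial (55%) recovery.  Depth ~ |N(28, 19)| mmHg clipped to [4, 70];
  the diastolic depth is a random fraction (N(0.47, 0.13), clipped
  [0.25, 0.85]) of the systolic depth,
* vasoactive events: Poisson(3 per 30 min) transients with fast sigmoid
  rise (3 s scale), exponential decay (90 s), amplitude ~ N(18, 6) mmHg
  clipped [5, 30], acting at half strength on DBP.  These emulate
  pressor boluses and airway stimulation — the source of the large
  consecutive 10-s changes that make trending statistics informative,
* band-limited slow wander (sinusoids of 2–10 min period, ~1.5 mmHg).

Pressures are clamped to SBP ∈ [70, 220], DBP ∈ [40, 120], PP ≥ 15 mmHg
(vasopressor support maintained MAP > 60 in the emulated setting).  The
dip and event parameters were calibrated so the intra-record
max-minus-min over 30 min averages ≈ 35 mmHg systolic and ≈ 18 mmHg
diastolic across patients — the dynamic range this kind of induction
cohort exhibits.  The `flat` mode holds 120/80 exactly and exists for
self-consistency tests.

**Beat synthesis.**  Each beat is a sum of Gaussian bumps (the kernel
shape is a modelling choice; any unimodal kernel would do) on the
diastolic baseline, with P1 centred 0.16 s after the pulse foot and
component widths (50, 60, 50) ms.  The P3 width matters: a wide P3 tail
reaching into the next beat's foot tilts the foot-to-foot baseline and
biases small-amplitude features, so it is kept equal to P1's.  Component
timing/amplitude follow the invertible linkage

    T13  = 0.40 s − 0.0012 s/mmHg · (SBP − 120)
    P2P1 = 0.40   + 0.006 /mmHg   · (PP − 40),   T12 = 0.35 · T13

strictly monotone over the physiological range so calibration-based
inversion is well posed.  The summed shape is rescaled so its peak
equals PP exactly; per-beat component specs are embedded as ground
truth.

**Channels.**  The reference (arterial-line) channel passes the pressure
train through a linear second-order resonance (natural frequency 15 Hz,
damping ratio 0.2) emulating catheter-tubing underdamping, which
inflates systolic overshoot, plus white sensor noise (0.3 mmHg SD).  An
identity filter is selectable for ground-truth tests.  The cuff channel
is derivative-coupled — the sensor outputs the time-derivative of the
(scaled) pressure in arbitrary units — plus white noise; the analysis
must therefore be gain-invariant, which the ratio/delay features are.
Artifacts (motion bursts, broadband noise, frozen-catheter failures) are
injected only inside their declared intervals, from an independent
random substream so adding an artifact does not perturb the rest of the
record.  One master seed derives all substreams; regeneration is
bit-identical.

**What the generator does not emulate:** real pulse-shape variability
(non-Gaussian component shapes, respiratory modulation of amplitude),
probe-position and hydrostatic offsets, slow sensor drift, arrhythmia,
and any mismatch between the true physiology→feature map and the
converter's linear model.  Passing tests therefore demonstrate that the
pipeline is correct and self-consistent — that it recovers known ground
truth through a realistic measurement chain — not that the device
modelled here achieves these error levels clinically; the near-perfect
correlations on synthetic cohorts should be read in that light.

## Signal quality

SNF is computed per 8-s window advancing in 1-s hops ("8-s window with
1-s overlap" is read as a 1-s hop; the alternative 7-s-hop reading would
make the stable-overlap logic operate on 1/7 of the data and is less
standard).  Within a window, band variances come from a Welch averaged
periodogram (2-s Hann segments, 50% overlap) integrated over 1–10 Hz
(signal) and 100–250 Hz (noise), both bands closed intervals.  A window
with exactly zero noise-band variance reports `inf`.  Sampling below
500 Hz is rejected because the noise band would extend beyond Nyquist.

Exclusion rules are applied at 1-s resolution (one SNF window starts per
second; slot *i* carries the verdict of the window starting at *i*):

* cuff: SNF < 80 → `low-SNF`; no detected beats for > 5 s → `motion`;
* reference: `catheter-failure` where the waveform leaves [20, 300]
  mmHg, flat-lines (SD < 0.05 mmHg over a 5-s window), shows
  beat-to-beat systolic jumps > 60 mmHg, or pulse pressure < 5 mmHg.
  These concrete thresholds operationalize what a clinician would call
  an obviously nonsensical reading; each is configurable.

The stable 30-min overlap is the earliest interval whose opening window
is valid with SNF ≥ 140 and in which at most 5% of seconds are
sub-threshold or invalid.  Requiring a clean opening window prevents the
tolerance budget from being spent straddling a leading contaminated
block; the 5% tolerance itself is an invented robustness allowance
(strictness configurable, 0 gives the literal rule).

## Feature extraction

The cuff signal is integrated (cumulative sum) to undo the derivative
coupling.  Cycle timing is detected on a 0.5–3 Hz band-passed copy, in
which the composite pulse is unimodal because the reflection structure
lives above that band; each systolic peak is then located on the raw
integral and its foot taken as the minimum within the preceding 0.25 s
(the waveform can return to baseline *between* P1 and P3, so a global
minimum search would split beats).  A prominence gate against the
running median rejects the outsized excursions of motion bursts.  The
final, unclosed cycle of a record is dropped.

Per beat (foot-to-foot segment, endpoint line removed):

1. P1 = tallest peak.
2. P2: usually fused on P1's falling edge with no local maximum.  Since
   the kernel is symmetric and P1's left flank is reflection-free, the
   beat mirrored about the P1 peak and subtracted cancels P1 exactly;
   the residual inside the 40–180 ms search window is an almost pure P2
   bump whose maximum gives location and amplitude.
3. P3 = largest local maximum in the 180–500 ms window.  (The window's
   upper edge covers T13 at the hypotensive end of the supported range;
   180–450 ms would clip beats below ≈ 85 mmHg systolic.)
4. Amplitudes are refined by linear least squares on Gaussian kernels at
   the located times (widths from flank half-widths) plus a linear
   baseline term; then each centre is re-located on the residual with
   the other two fitted components removed (each component's apparent
   peak is pulled by its neighbours' tails), and amplitudes are refit
   once.  All peak locations use three-point parabolic refinement.

Beats whose reflections cannot be resolved (including the degenerate
no-reflection case) are flagged invalid and excluded from averaging —
never imputed.  On noise-free simulator beats across flat and induction
dynamics this chain recovers T13 within ±4 ms and P2/P1 within ±0.03 of
ground truth; accuracy degrades gracefully toward the extreme
hypotension floor (PP near 15 mmHg), where the P2 bump is ~3 mmHg tall.

## Series processing and pairing

Beat values are averaged into half-open 10-s bins anchored at the
overlap start; bins with fewer than 3 beats are invalid (an invented
robustness floor).  A pair of intervals is retained only if both devices
are valid and no second of the interval is mask-excluded; pairs are
dropped, never imputed.

## Agreement statistics

* **Bland–Altman:** bias = mean(test − ref), SD with the n−1
  denominator, limits bias ± 1.96 SD; CIs use t·SD/√n for the bias and
  t·SD·√(3/n) for the limits.
* **Pitman–Morgan:** correlation between pair sums and pair differences,
  t-transformed; its type-I error matches the nominal α in simulation.
* **4-quadrant / polar:** consecutive changes are formed only between
  adjacent retained intervals (gaps are not bridged, and pooled cohort
  data places patients on disjoint grids so changes never span
  patients).  A pair is excluded when its mean absolute change
  (|ΔRef| + |ΔTest|)/2 falls below the zone radius (default 10 mmHg); an
  alternative reading — exclude when both |Δ| are below a cap — is
  available as `zone_mode="cap"`.  Polar angle θ = atan2(ΔTest, ΔRef) −
  45°, wrapped to (−180°, 180°]; the 90%/95% boundaries are empirical
  symmetric half-widths of |θ| about the identity line, not parametric
  intervals.  With all pairs inside the zone the statistics are reported
  as undefined (NaN) and flagged — on low-dynamics data this is the
  correct answer, and diastolic series often land there.
* **Zero-zone:** per test reading, reference values within ±30 s form a
  window; windows whose range exceeds 20 mmHg (systolic) or 12 mmHg
  (diastolic) are excluded from consideration.  The zone is the window
  mean ± 1 SD; readings inside score 0, outside the signed distance to
  the nearest edge.  Defined for SBP and DBP only.
* **AAMI verdict:** pass iff |bias| ≤ 5 mmHg and SD ≤ 8 mmHg, both
  limits inclusive ("not greater than").

## Pipeline and problem sizes

`run_cohort` simulates each patient (default 33 min at 500 Hz — enough
to contain a 30-min stable overlap with margin), screens, calibrates at
the overlap start against a 15-s reference reading, converts with 60-s
recalibration checks, averages, pairs, and pools.  A 15-patient cohort
is the default, matching the minimum cohort the 81060-2 standard
requires for arterial-line comparisons; it runs in about a minute on one
core.  Reports carry a manifest (config hash, seed, counts) and reruns
are byte-identical.

## Known limitations

* The conversion equations and the simulator linkage share their
  functional form by construction; real devices face model mismatch that
  synthetic cohorts cannot expose.
* P2/P1 accuracy deteriorates near the pulse-pressure floor
  (PP ≈ 15 mmHg) and for beats during the fastest transients, where the
  foot-to-foot baseline assumption is weakest.
* The stiffness proxy is a stand-in; recalibration behaviour against
  true arterial-stiffness drift is untested by construction.
* Diastolic trending statistics are usually undefined at the default
  10-mmHg zone; use a smaller zone deliberately if diastolic trending is
  the question.
* No arrhythmia handling: beat detection assumes quasi-periodic rhythm
  (periods 0.24–3 s).
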