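# Methods

## Coordinate conventions and data model

All positions are in centimetres in a cylinder-centred frame: the D-section
cylinder's centre is (0, 0), x increases downstream, y is lateral (positive
toward the fish's right in the ventral view).  A station-holding fish faces
upstream, so forward motion toward the cylinder has negative x-velocity.
Frames are 0-based; the time of frame k is k / frame_rate; all intervals are
half-open [onset, offset), so an event's offset is the time of the first
frame after its run.  Pose files use the DeepLabCut CSV dialect (three header
rows, x/y/likelihood triplets per bodypart, pixel units); reading applies the
affine calibration `cm = px·pixel_to_cm − cylinder_origin`, whose exact
inverse is used when writing, making round trips lossless.

Tracking quality is handled automatically in place of manual correction:
points with likelihood below 0.9 are treated as untracked; untracked runs of
at most 5 frames bounded by tracked samples are linearly interpolated, longer
runs become explicit missing values that event detection skips.  Both knobs
are exposed (`AnalysisParams.likelihood_floor`, `max_interp_gap`).

## Kinematics

**Smoothing.** Digitisation noise is reduced with a centred moving average
whose window is `round(0.2 × frame_rate)` samples (30 frames ≈ 0.2 s at
150 frames/s).  At the edges the window shrinks to the available samples:
this preserves series length with no phantom padding, at the cost of a
conservative estimate of extrema near the edges (and of a ~half-window bias
in derivatives there; velocities are therefore only interpreted in the
interior).  Missing samples are excluded from the window mean rather than
propagated.

**Fin extension** is the perpendicular distance from the fin tip (fin point
3) to the *infinite line* through the fin-base points 1 and 5, divided by
body length L.  The infinite line (rather than the segment) keeps the metric
differentiable when the tip passes an endpoint, and makes it exactly
invariant under rigid motion of the fin.  Base points closer than 1e-6 cm
give a degenerate frame, marked missing.

**COM velocity.**  The third midline point (pectoral-girdle region) proxies
the centre of mass.  Its position is smoothed first, then differentiated with
central differences (one-sided at the ends) — smoothing before
differentiation, never after.

**Body-wave metrics.**  The tail-tip lateral signal is linearly detrended;
the tail-beat frequency is its dominant periodogram peak (zero-padded FFT,
frequencies ≥ 0.5 Hz).  A peak counts as oscillation only if it exceeds 20×
the median spectral power — a flat noise spectrum has a max/median ratio of
roughly ln(n_bins) ≈ 8, so this detects genuine periodicity while a
numerically constant signal (variance < 1e-9 cm²) is short-circuited to "no
oscillation".  The body wavelength comes from a phase-slope regression: each
midline point's phase at the dominant frequency (angle of its complex DFT
coefficient) is unwrapped along the body and regressed on point index;
wavelength = 2π·(L/6)/|slope| in L units, taking the seven midline landmarks
as evenly spaced along the body (spacing L/6).  A travelling wave is declared
when |slope| > 2 standard errors; |slope| below the value corresponding to a
20 L wavelength is treated as rigid-body sway, reported as infinite
wavelength with a flag (it trivially satisfies any long-wavelength
criterion).  Transient high-frequency tail beats are flagged when more than
10% of spectrogram time bins have more energy above 1.5× the reference
frequency (the shedding frequency when known, else the dominant frequency)
than in the band below it.

## Events and behaviour

**Extension events** are maximal runs with smoothed extension ≥ 0.05 L.
Runs separated by gaps shorter than 2 frames are merged, then runs shorter
than 3 frames are discarded — both suppress single-frame jitter at
150 frames/s and are configurable and logged.  t_max is the earliest argmax
in the run; onset ≤ t_max < offset.

**Synchrony.**  A left/right pair is simultaneous when the interval overlap
is at least 50% of the *shorter* event's duration — the strictest symmetric
reading of "50% overlap"; the denominator is configurable.  Pairing is greedy
by largest overlap with each event in at most one pair; unpaired events are
asynchronous.  Note the counting convention: a synchronous pair is two events
but one bilateral extension *episode*; cohort fractions quoted per episode
divide the pair count, as done in `scripts/acceptance.py`.

**Bout classification** evaluates five Kármán-gait flags (|net drift| ≤
0.1 L; travelling wave; tail displacement > 0.5 L; wavelength > 1 L; no
high-frequency transients) and four braking flags (net upstream drift
< −0.1 L; a forward-velocity excursion below −1 cm/s followed within 0.5 s by
a value above +1 cm/s, operationalising "surge then arrest"; no sustained
oscillation, implemented as the oscillation-detection flag being clear; tail
displacement ≤ 0.5 L).  All flags of a class must hold; otherwise the bout is
"other".  Thresholds (drift_tol, v_tol, rise window) are exposed.

**Event position** is the snout (midline point 1) at t_max; the landmark is
configurable (e.g. midline_3).  Zones: suction_zone for x ∈ (0, 15] cm and
|y| ≤ 3 cm, wake for x ∈ (15, 30] cm, otherwise outside; bounds configurable.

## EMG

The digital conditioning is a zero-phase (forward–backward) Butterworth
bandpass of order 10, requested band 100–3000 Hz mirroring the analog
recording chain, with the upper edge clamped to 0.45× the sampling rate
(logged).  Zero-phase filtering is essential because burst onsets feed 0.2 s
association windows and must not be delayed by group delay.  No digital 60 Hz
notch is applied (the analog chain already notched); a flag exists.

The "spikes ≥ 25% of the electrode's mean spike amplitude" rule is circular —
the spikes define the mean that defines the spikes — and is resolved with a
two-pass construction: pass 1 collects rectified peaks above `noise_k = 5`
times the MAD-based noise s.d. (refractory spacing 2 ms); their mean absolute
amplitude is the electrode's mean spike amplitude; pass 2 keeps candidates ≥
`rel_threshold = 0.25` of that mean.  Both knobs are exposed.  The 5σ floor
is calibrated so that a single behavioural recording is almost always clean:
on pure Gaussian noise at 4 kHz the expected false-alarm rate is ~1–2% of
3.5 s channel-recordings, each yielding a lone singleton spike.  Over large
cohorts such singletons therefore occur by design; genuine bursts contain
≥ 10 spikes, so singleton bursts should be interpreted with care (a known
limitation; the recovery tests require every planted burst to be found and
every multi-spike burst to be planted).

Bursts group consecutive spikes with inter-spike intervals ≤ 50 ms; onset and
offset are the first and last spike times, and a singleton's offset is one
refractory period after its onset.  No grouping rule was published for the
reported burst durations; this gap scan is the declared surrogate.

## Coupling and statistics

Pre/post velocities are means over [t_max − 0.2 s, t_max) and
(t_max, t_max + 0.2 s]; windows with ≥ 50% of their samples available are
computed with a truncation flag, emptier ones are missing.  The pre/post
comparison standardises the paired differences, checks normality with a
one-sample Kolmogorov–Smirnov test against the standard normal (the reference
distribution had to be chosen; standardisation is the declared surrogate) and
then runs a *paired* two-tailed Student's t-test — pre and post are measured
on the same event, so pairing is the natural default; an unpaired variant is
available by flag.  All-zero differences report t = 0, p = 1; zero-variance
nonzero differences are reported as degenerate with significance decided by
exact inequality.  Raw p-values are reported; no multiplicity correction is
applied by default (few tests are run), matching common practice at this
scale.

Muscle association flags, per event and per muscle role (ipsi/contra ×
abductor/adductor), record whether any burst overlaps the onset or offset
window; flags are monotone in window length.  Activation patterns split each
event at t_max into an abduction phase [onset, t_max] and an adduction phase
[t_max, offset]; per phase, agonist-only activity is active, no ipsilateral
activity is passive, antagonist-only activity is resistive, and both muscles
active is active with a co-contraction flag — co-contraction is reported, not
collapsed, because braking characteristically shows simultaneous abductor and
adductor activity while the fin is held against the flow.

## The synthetic-trial generator

The generator emulates the statistical structure the analysis assumes; it is
not a fluid simulation (no vortex advection — the wake enters only through
the shedding frequency and amplitude parameters).

* **Wake frequency:** f = St·U/D with St = 0.25 by default, placing f between
  2.25 and 4.25 Hz over the experimental 45–85 cm/s range at D = 5 cm,
  consistent with the observed 2–5 Hz shedding band (a Strouhal number typical
  of D-section cylinders in this Reynolds range).
* **Kármán gait:** midline point i at arclength s_i oscillates laterally as
  A(s_i)·sin(2πft − 2πs_i/λ) about a drifting COM; the amplitude envelope is
  linear from 0.02 L at the snout to 0.28 L at the tail tip so the tail
  peak-to-peak excursion is 0.56 L — comfortably above the 0.5 L
  classification criterion (a 0.25 L amplitude would sit exactly at the
  boundary) — and λ = 1.2 L by default.  No envelope or wavelength values
  were published for these fish; these defaults are declared stand-ins.
* **Braking:** the forward COM velocity follows a piecewise-linear profile —
  surge to an upstream plateau v₁, a linear flip spanning [t_max − 0.2 s,
  t_max + 0.2 s], a downstream plateau v₂, then recovery.  Plateaus are
  solved from the requested window means (v₁ = (3·pre − post)/2,
  v₂ = (3·post − pre)/2, default pre = −4, post = +3 cm/s) so the true 0.2 s
  window means equal the requested values exactly.  The linear flip spanning
  exactly twice the smoothing half-width makes the moving average transparent
  at the windows, so the measured cohort means recover the planted values to
  a few per cent.
* **Fin events:** fins are rigid point sets attached at the pectoral girdle
  and rotated with the local body tangent; fin point 3 moves perpendicular to
  the base so the extension metric equals the planted profile exactly
  (rigid-motion invariance).  The profile places a linear segment spanning
  the smoothing window across each 0.05 L threshold crossing — a centred
  moving average is exact on interior linear segments, so planted onsets and
  offsets survive smoothing to within a frame — and a triangular peak at the
  event midpoint.  This construction requires planted peaks > 2× the
  detection threshold.
* **EMG:** bursts are trains of one-period biphasic 2 ms sine spikes
  (fundamental ≈ 500 Hz, well inside the clamped digital band) at 100
  spikes/s with ±1 ms jitter, amplitude 10 over Gaussian baseline noise of
  s.d. 0.5, on top of a 4 kHz digital rate — a realistic digitisation of the
  100–3000 Hz analog chain (the published digital rate is ambiguous, so the
  sampling rate is required trial metadata everywhere).
* **Cohort structure:** per-trial randomisation plants bilateral (synchronous)
  extensions with probability 35/272 for Kármán gaiting and 9/13 for braking
  (the published episode counts), and draws each Kármán-gait extension's
  muscle pattern as passive 50% / active 35% / resistive 15%, reflecting the
  observation that over half of gaiting extensions proceed without
  ipsilateral muscle activity.  Braking events always recruit the abductor at
  extension and the adductor while the fin is held out (co-contraction).
* **Noise:** independent Gaussian per coordinate per frame (pose, s.d.
  0.05 cm ≈ 1 px) and per sample (EMG).  No autocorrelated noise, no
  occlusions by default, no fin-ray deformation.  All randomness derives from
  one seed through deterministic sub-streams, so identical configurations
  are bit-identical on disk.

What passing the recovery tests does **not** show: robustness to real
tracking pathologies (identity swaps, autocorrelated drift, occlusion), to
EMG artefacts (movement artefact, cross-talk between electrodes), or to fish
whose gait deviates from a single travelling harmonic.  The generator is a
validation harness for the measurement chain, not a model of trout.

Event-level lateral-velocity recovery during Kármán gaiting is intentionally
not a target: at the planted envelope the COM's own gait oscillation
contributes tens of cm/s to 0.2 s lateral window means, dwarfing a ±2 cm/s
per-event shift.  The statistical power of the pre/post test for the lateral
flip is therefore calibrated on the cohort-level velocity-pair sampler
(`sample_velocity_change_pairs`, event scatter s.d. 3.5 cm/s, consistent with
published standard errors), not on full kinematic simulations.

## Problem sizes and numerical choices

Validation cohorts use 200 trials per behaviour (4 s gait / 3.5 s braking
trials), 2000 null replicates for type-I calibration and 200 replicates of
n = 50 events for power — sizes at which the binomial uncertainty on the
checked rates is well inside the asserted bands and the whole suite runs in
well under a minute.  Oracle-equivalence checks run 1000 randomised fixtures
per primitive against independent brute-force implementations; the
integer-indexed primitives (event runs, pairing, burst grouping) must agree
exactly, the moving average to 1e-12 (its oracle sums in a different order).
Ties in t_max go to the earliest frame; greedy synchrony pairing breaks
overlap ties deterministically by event index; spike detection uses
`scipy.signal.find_peaks` with a 2 ms minimum separation so the two lobes of
one biphasic spike count once.
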