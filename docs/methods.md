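# Methods

This note documents the models behind each module, the parameters that
matter, the numerical choices, and what the synthetic data do and do not
emulate.

## Behavioral generator

The fly alternates wake and sleep bouts as a semi-Markov renewal
process. Bout lengths are drawn from an exponential law by default
(`bout_length_law="lognormal"` with log-sd `dispersion` is available);
the exponential is a stand-in — the statistical structure of real
inter-bout intervals is not established, and nothing downstream depends
on the choice beyond the means.

Sleep bouts carry a hard 300-s minimum: the draw is
`min_sleep_s + law(mean − min_sleep_s)`, which preserves the configured
mean (default 1200 s against a 600-s wake mean) while keeping every
generated sleep bout scoreable under the 5-min rule. This makes the
stationary asleep fraction exactly
`sleep_mean / (wake_mean + sleep_mean)` and lets Monte-Carlo calibration
be checked against a closed form. With `enforce_min_sleep=False` the raw
law is drawn and sub-minimum quiescence is emitted as kind `"rest"`
without the asleep label.

The alternation is started ten mean cycles before `t = 0` and the
burn-in discarded, so the observed window samples the stationary
process; without this the always-awake start biases the asleep fraction
low by roughly one cycle per recording day (~2 % for the defaults),
which is visible against a 100-seed standard error.

Diel modulation multiplies the sleep-initiation hazard per clock hour:
a wake bout ends when the time-integral of the hourly multiplier reaches
the drawn exposure. A multiplier of zero makes sleep initiation
impossible in that hour; all-zero modulation is the valid degenerate
case of a fly that never sleeps.

Movements during wake are a Poisson process (default 0.2 s⁻¹) of signed
exponential steps (mean 4 mm) reflected at the walls of the 65-mm tube;
the transverse coordinate jitters only when a movement occurs. Position
is frozen during sleep, so displacement is exactly zero inside every
truth sleep bout — the invariant the tracker and scorer tests rely on.

What the generator does **not** emulate: posture and grooming
micro-movements, position-dependent activity (wall preference), the
inspection-paradox structure of real bout sequences, or any
light-driven startle. Passing tests therefore show that the pipeline
recovers the statistics it was built to measure, not that those
statistics describe real flies.

## Video rendering and tracker

Frames are rendered at 4 px/mm (configurable) as a Gaussian blob of
sigma 0.6 mm — fly-sized — and peak 120 gray levels on a background of
20, with additive Gaussian noise (default sigma 3) and optional
background drift, quantized to 8 or 16 bits. The blob must clear
3 × noise sigma so that default fixtures are detectable.

The tracker maintains an exponential-moving-average background
(`new = (1 − α)·old + α·frame`, α = 0.05 at ~5-Hz framing). The update
runs on every frame, movement or not: a resting fly is absorbed into
the background within ~1 min (time constant 1/α frames), slowly enough
not to suppress bout onsets. The EMA gives the closed form used in
tests: after k constant frames the background error is (1 − α)^k of the
initial error.

The difference image is thresholded at `intensity_threshold` (20 gray
levels by default; the original rig published no numeric thresholds, so
defaults here are fixture-calibrated, not reconstructions). By default
the **signed** difference `frame − background` is used, clipped at
zero: a bright fly arriving somewhere new is a positive deviation,
while the darkening ghost it leaves behind — still present in the slow
background — is negative and ignored. With the absolute difference
(`difference="abs"`, also available) the departure ghost and the
arrival blob decay at identical rates after a jump and the largest-
cluster rule can oscillate between them; the signed form removes this
failure mode without changing behavior on clean scenes.

Connected components use 8-connectivity; clusters below
`min_cluster_px` (5) are discarded; the candidate position is the
intensity-weighted centroid of the largest surviving cluster, with ties
broken by summed intensity and then by label order (deterministic).
Displacement is measured in mm between the candidate and the **last
accepted** position; below 2.5 mm the candidate is discarded and the
position held. The first frame initializes the background, so output
begins at frame 2; an `initial_position` may be supplied (a rig knows
the fly's last location), otherwise the first detected candidate is
adopted without scoring an event.

Oracle-equivalence fixtures use walks over fresh ground. When a hop
lands within ~2 blob sigmas of a spot the background still remembers,
the subtraction sculpts the blob asymmetrically and biases the centroid
by up to ~0.15 mm; this is inherent to background subtraction, not a
detector defect, and the ±0.1-px equivalence claim is scoped to
fresh-ground trajectories.

## Stimulation controller

The closed-loop law is deterministic: for each maximal inactivity gap,
block onsets at `gap_start + 180 s + k·30 s` strictly before the gap's
terminating movement, each block expanding to 3 pulses at 20 Hz (3-ms
width; the ~28 mW/cm² irradiance is metadata, not modeled). Boundary
rules: a block scheduled exactly at the movement is not emitted
(half-open interval); a movement mid-block cancels from the next pulse
onward (`cancellation="block"` lets a started block complete);
stimulation pulses are not movements and never reset the timer, which
runs from the last movement only. Time is continuous double-precision
seconds — no frame quantization.

Correctness is established by dual route: the gap-enumeration
implementation against an independent 1-ms timeline simulation
(memoryless formulation: a block fires when the rest time is
`180 + k·30 s`), exact pulse-for-pulse agreement on 1000 random
schedules.

Light dose credits each pulse's full 3-ms width to the 15-min bin
containing its onset, so dose × bin length sums exactly to
pulse count × pulse width.

## Sleep scoring and rebound

Activity is per-minute counts; a sleep bout is a maximal run of
zero-count minutes of length ≥ 5. Tracker output enters the same scorer
through per-minute movement-event pseudo-counts, so both input paths
share one rule. Gaps in the bin sequence are an error, never silently
imputed.

Bout phase (day/night) follows the onset minute; hourly time courses
credit each bout's overlap minutes to every clock hour it touches, so
the 24-entry vector sums to total sleep. Bouts truncated by the
recording boundary are kept and flagged but excluded from bout-duration
means by default; how the original analysis phase-assigned bouts in
progress at lights-on/off is unpublished, so both choices are explicit
configuration here. SEM uses the n − 1 denominator. Group hypothesis
tests are out of scope; the emitted tables are test-ready.

Rebound accounting: baseline is the 24 h preceding deprivation
(typically 12 h overnight); sleep lost is baseline sleep in the
deprivation-matched clock window minus sleep achieved during
deprivation; sleep regained is the cumulative hour-by-hour excess of
recovery sleep over baseline sleep at the matched clock hour; percent
recovered is defined only when sleep lost is positive. The three series
must be contiguous and clock-aligned.

The arousal assay takes flies asleep at pulse onset as the denominator
and those with ≥ 1 count within the response window (default: the 3-min
pulse itself) as the numerator; a pulse with no sleeping flies yields
an undefined percentage, flagged rather than reported as zero.

Minute binning loses partial boundary minutes of each bout (~1 min per
bout in expectation), so the scored sleep total sits a few percent
below the continuous truth. Tests therefore check the scorer against an
independent minute-binned re-scoring of the truth intervals (exact
agreement) and check the generator's continuous asleep fraction against
the renewal closed form (3-SE agreement over ≥ 100 seeds); the two
comparisons are deliberately not mixed.

## Electrophysiology

The membrane-potential generator places Poisson spikes at the per-state
rates (defaults 16.9 Hz UP, 0.5 Hz DOWN) on baselines separated by
10.9 mV (DOWN at −62 mV), with ~20-ms smoothed state transitions so
that baseline steps do not masquerade as events. EPSPs are a
difference-of-exponentials kernel (4 mV, 1.5-ms rise, 8-ms decay) at
9.44 Hz outside and 15.33 Hz inside stimulation windows, which also
depolarize the baseline by 5.30 mV. Gaussian noise defaults to
0.4 mV at 10 kHz sampling.

Spike detection high-passes at 100 Hz (zero-phase Butterworth) and
takes positive threshold crossings refined to the local peak, with a
2-ms refractory period. The threshold is 5 × the MAD-based noise
estimate with a 5-mV floor (the floor keeps near-noiseless traces from
degenerating to a zero threshold). Sampling below 10 kHz is flagged
with a warning, not an error. At 16.9 Hz, ~1.7 % of Poisson gaps fall
inside the refractory period, so detected rates sit ~2 % below truth;
tests allow for this known loss.

EPSP detection finds peaks in the smoothed derivative of the low-passed
trace: each event's rise produces a slope deflection that stays
distinct even when the event rides on the decay of its predecessor, so
the resolvability limit is ~the rise time (3-ms minimum separation)
rather than the decay. Rate estimates can be corrected for this
detector dead time as a non-paralyzable counter
(`rate = observed/(1 − observed·τ)`); without the correction the
percent change between 9.44 and 15.33 Hz would be biased ~3 points
toward zero, since the faster train loses proportionally more events.

UP/DOWN segmentation thresholds the sliding-window firing rate (5-s
windows, 1-s step) with hysteresis: enter DOWN below 1 Hz — the
near-silence criterion — and return to UP only above 2 Hz, preventing
chatter around the boundary. Adjacent same-label windows merge;
segments tile the trace; boundary accuracy is one window length. When
the raw trace is supplied, each segment's median Vm is recorded so the
~11-mV baseline separation can corroborate the rate-based labels.

Stimulus–bout association: a stimulus associates with a bout if at
least one bout onset falls within the window after it (default 1 s;
the published account names no window, so it is configurable and
reported in all outputs). Bouts not captured by any stimulus are
self-initiated and attributed to the containing UP/DOWN segment.
State-conditioned rates divide events by state occupancy time; the
UP/DOWN fold is reported raw and as the nearest whole fold, and is
flagged undefined (never infinity) when DOWN time or DOWN events are
zero. The denominator times behind the published per-second rates are
unprinted, so only the ~4-fold ratio is used as a check. With zero
stimuli the association probability is undefined, flagged rather than
zero.

## Homeostat

The flasher: a capacitor charges through R toward Vs and, while the
bulb is lit, discharges through R_discharge; the bulb ignites at
V_ignite and extinguishes at V_extinguish. Explicit fixed-step Euler
integration; the charge phase has the closed form
`T = R·C·ln((Vs − V_ext)/(Vs − V_ign))`, and the integrator converges
to it first-order in dt (0.008 % error at dt = RC/10⁴). A supply below
the ignition threshold never flashes — a valid, flagged configuration.

The circuit-level model keeps one scalar, sleep pressure, without
claiming a biological substrate. Pressure grows while the fly is awake
at `pressure_gain × (r2_base_drive + helicon_gain·[helicon UP])` and
decays at `clearance_rate` while asleep. The dFB switches ON at P_on
and OFF at P_off (two thresholds → relaxation oscillation); dFB ON
forces helicon cells DOWN, and the fly is asleep exactly when the
helicon gate is closed — which reduces to "asleep iff dFB ON" in the
unperturbed circuit. All parameters are invented defaults in arbitrary
units: the biology supplies the topology and switching logic, not
numbers, so this module's acceptance is property- and sign-based only
(pressure confined to [P_off, P_on], rebound after forced wake monotone
in deprivation length, immediate quiescence on clamp release, silencing
weakly increases sleep).

Perturbations: `forced_wake` pins the behavioral readout awake while
pressure keeps accumulating past P_on (mechanical deprivation);
`helicon_clamp_up` holds the gate open against dFB inhibition and adds
helicon drive (optogenetic stimulation); `helicon_silenced` holds the
gate closed (Kir2.1). Clamp and silencing may not overlap.

Within a step the dynamics are piecewise linear, so threshold crossings
are located exactly inside the step and the remainder integrated under
the post-switch state. This keeps unperturbed pressure inside
[P_off, P_on] to machine precision and makes the limit-cycle period
match the analytic value `(P_on − P_off)·(1/accumulation + 1/clearance)`
to < 2 % at dt = 0.01; it refines plain Euler without leaving the
fixed-step scheme. A stochastic behavioral readout is deliberately
absent: behavior is slaved to the circuit state for determinism.

## Problem sizes and tolerances

The test suite and the acceptance script use desk-scale problems chosen
to keep every stochastic check at ≥ 3-standard-error resolution:
24-h behavioral days at 0.2–5-Hz sampling over 100–200 seeds for the
asleep fraction; 10–30-s membrane traces at 10 kHz over 60–100 seeds
for firing rates and EPSP modulation; 10-jump rendered walks for the
tracker; 1000 random 10-min schedules for the controller; dt = RC/10⁴
for the flasher. Exact counts (42 pulses, 4-vs-5-minute boundary,
printed-count worked examples) are asserted exactly. Monte-Carlo
assertions use sample SEMs, never fixed magic tolerances, except where
a known detector loss is stated explicitly above.
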