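# Methods

This note documents the models, algorithmic interpretations, numerical
choices and known limitations behind `gaitphase`, in the package's own
words. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Signal model and conventions

All detectors operate on a common uniform evaluation grid of 200 Hz.
Analog channels (gyroscope, accelerometer, raw footswitch forces) are
moved onto it with linear interpolation; binarized footswitch channels
with a zero-order hold, which keeps them in {0, 1}. Units are fixed
internally: deg/s, m/s², seconds.

The sagittal (pitch) angular velocity of the foot is the scalar input of
the S-method and both HMM segmenters. Its sign convention: positive at
the mid-swing dorsiflexion peak, so heel-strike and toe-off appear as
negative ("clockwise") troughs. Sensors mounted with the opposite
handedness are handled by `flip_sign`. Which gyroscope axis is sagittal
is not always recorded in data files; by default the axis of maximal
variance during walking is used, since foot rotation is dominated by the
sagittal plane. This is overridable (`axis=`).

Butterworth low-pass filters default to zero-phase (forward-backward)
application for offline analysis: event timing is then unbiased by group
delay, at the cost of doubling the effective order. A causal option
exists for streaming use. Moving averages use a centred window with
truncation (shrinking window) at the edges, so output length equals input
length.

## Footswitch reference

Contact rules per sample: LR = only heel pressed; FF = all four pressed;
PS = at least one forefoot switch pressed; Sw = none pressed. FF is
checked before PS because "all pressed" logically implies "some forefoot
pressed"; the more specific condition wins. Analog forces are binarized
at 10% of each channel's robust maximum (95th percentile) — robust to
occasional spikes, insensitive to baseline noise an order of magnitude
smaller than contact forces.

Label runs shorter than a debounce window (default 20 ms) are merged into
the preceding phase; whether the original studies conditioned their
footswitch signals is typically unreported, so this is an explicit knob.
Events are emitted at label changes that follow the canonical
HS→TS→HO→TO cycle; residual changes are flagged and kept for diagnostics
but excluded from the accepted event stream. Strides are delimited by
successive heel strikes; the first and last three are discarded
(gait acceleration/deceleration); strides without the full four-phase
progression are excluded from percentage statistics but their events
remain available for transition-level evaluation.

## Threshold segmenters

**S-method** (gyroscope). Pipeline: 15 Hz 2nd-order zero-phase
Butterworth; mid-swing peaks = positive peaks ≥ 50 °/s at least 0.5 s
apart (the mid-swing criterion is this package's concretisation — the
method description we implement references mid-swing without defining
it). Within each inter-peak interval: HS is the most negative extremum in
the first 40% of the interval; TS is the start of the first sustained
(≥ 40 ms) run with |ω| < 30 °/s after HS; HO is the first sample after
that stasis run with |ω| > 30 °/s; TO is the most negative extremum
between HO and the next mid-swing peak. Reading "the second clockwise
maximum after mid-swing" as TO-then-HS flanking the mid-swing peak is the
interpretation consistent with the event order HO < TO < mid-swing < HS.

**R-method** (accelerometer). The five reference signals are the
resultant of the two sagittal-plane acceleration channels and: c50 (6 Hz
2nd-order low-pass of the resultant), its first and second central-
difference derivatives d1 and d2, and two moving averages of the
resultant, cA200 (1.25 s) and cA50 (0.30 s). The published account of
how these signals yield events is a summary, not an algorithm; the
rule-set here is this package's documented interpretation, validated only
against the synthetic generator:

1. flat-foot cores = runs ≥ 100 ms where |c50 − cA200| < 0.5 m/s² and
   |d1| < 2 m/s³;
2. HO = end of a quiescent run, refined to a d2 zero-crossing within
   10 ms;
3. TO = first local maximum of c50 after HO (push-off peak);
4. HS = largest local maximum of c50 after TO that exceeds cA50
   (impact peak);
5. TS = the point after HS where c50 falls back below cA50, refined to
   the nearest inflection.

A cycle missing any of these is dropped whole; the canonical-order filter
then keeps the event stream consistent. On the synthetic cohorts this
detector is systematically the weakest of the four (its flat-foot
quiescence and inflection estimates carry tens of milliseconds of bias),
which reproduces the qualitative ordering reported for these method
families on real parkinsonian gait.

## HMM segmenters

A 4-state hidden Markov model over the phases in cyclic order
LR→FF→PS→Sw→LR. The transition matrix is left-right cyclic: only aᵢᵢ and
aᵢ,ᵢ₊₁ (mod 4) may be non-zero. The cycle is closed (Sw→LR allowed) so
whole multi-stride trials decode continuously. The initial distribution
is uniform over the four phases and is *not* re-estimated — it is part of
the model specification, and a decoder deployed on arbitrary walking
segments should not prefer a starting phase.

The observation is the 17 Hz low-pass filtered sagittal angular velocity
(scalar by construction). Emissions are per-state mixtures of scalar
Gaussians, **three components per state by default**. The within-phase
velocity distributions are strongly multimodal — swing sweeps from a deep
negative trough through a +300…400 °/s peak and back — and a single
Gaussian per state provably mislocates the Viterbi boundaries by tens of
milliseconds on such shapes; mixtures restore boundary alignment.
`n_mix=1` remains available.

Training: supervised initialization from footswitch-referenced labels
(per-phase moments, or a deterministic quantile-seeded 1-D k-means split
for mixtures; self-transitions aᵢᵢ = 1 − 1/(mean phase duration in
samples)), then Baum-Welch over the individual sequences with scaled
forward-backward (numerically stable for arbitrarily long trials). EM
stops when |Δ log-likelihood| ≤ `tol` (default 1e-4) or after `max_iter`
(default 100) iterations. Structural zeros of the transition matrix are
re-imposed, and emission SDs floored, at every M-step;
`freeze_transitions` restricts EM to emissions.

The **SD floor defaults to 10 °/s**. It guards against variance collapse
on the quasi-constant flat-foot segment, and — more importantly — it
keeps EM from drifting the state boundaries away from the footswitch
event semantics: maximum-likelihood segmentation of a low-noise signal is
free to slice state boundaries wherever likelihood is sharpest, which is
not where the contact events are. A floor at the scale of physiological
within-phase variability anchors the supervised initialization. On real,
noisier data a smaller floor is defensible; both are configurable.

Decoding: Viterbi in log space, ties broken toward the lower state index
(determinism). `decode_online` provides the causal alternative — argmax
of the forward-filtered posterior per sample — documented as an
approximation to Viterbi for real-time use.

Two training regimes mirror the two deployment models: *subject-specific*
(`train_sst`: exactly three labeled trials, train on two, decode the
held-out one, rotate folds) and *standard training set* (`train_spt`:
pool a control group's labeled trials once; the resulting model decodes
any trial without retraining, and can be persisted as JSON).

## Evaluation

Reference transitions define centred windows of ±30 ms (60 ms total,
configurable). Predicted transitions of the same event type are matched
one-to-one to windows greedily by ascending time distance (ties: earlier
predicted time), giving TP; unmatched predictions are FP; unmatched
windows FN. **True negatives are counted at sample level**: samples of
the evaluation grid outside every reference window that carry no
predicted transition. The published definition counts "non-transitions
rightly detected" without fixing the unit; the sample-level reading gives
TNR a well-defined denominator and TNR ≤ 1. Because the non-transition
samples vastly outnumber events, TNR sits near 1 for any reasonable
detector and G is dominated by sensitivity; the absolute TNR value is
therefore not comparable across different TN conventions. Counts are
pooled over event types (per-type counts are also emitted). Left and
right are evaluated separately.

G = √((1−TNR)² + (1−TPR)²), classified optimum (≤ 0.25), good (≤ 0.7),
random otherwise. Phase errors are absolute differences of trial-mean
phase percentages. AUC uses the rank-sum (Mann-Whitney) identity with
ties counted half, reported in percent.

## GPQI

The printed formula — a *sum over the two sides* of the 4-D Euclidean
distance to the control-group means — is implemented as printed, although
the accompanying prose describes "the Euclidean distance in a
four-dimensional space" (singular); the formula wins and the discrepancy
is noted here. The default reference distribution is the published
control-group means (6.9, 39.4, 16.2, 37.7)%; these sum to 100.2 because
of printed rounding, so phase-vector validation tolerates 100 ± 0.5.
`control_reference` computes a reference from healthy trials as the grand
mean of per-trial means, sides pooled. The default trial basis is the
trial-mean phase vector; a per-stride basis (strides paired across sides
by temporal index, per-pair GPQI averaged) exists because per-stride GPQI
errors are also of interest.

Reliability: ICC(3,k) is the two-way mixed, *consistency*,
average-measures intraclass correlation, (MS_subjects − MS_error)/
MS_subjects from the subjects × trials ANOVA decomposition (cross-checked
against pingouin's ICC(C,k) in the tests). SEM = SD(subject means)·
√(1 − ICC); MDC95 = 1.96·√2·SEM. An all-equal matrix is defined as
perfectly reliable (ICC = 1, SEM = 0). Note that the average-measures
ICC of pure noise is widely dispersed around 0 for realistic cohort
sizes; only its central tendency is near zero.

## Synthetic gait generator

The generator is the package's test bed and defines its study
conditions. Per stride, a duration and a phase-fraction 4-vector are
drawn (Gaussian jitter around the profile means, renormalized to 100%);
event times are quantized to the 200 Hz grid, so ground-truth labels,
footswitch transitions and event times are mutually exact when switch
chatter is disabled.

The sagittal angular-velocity template per stride:

- a sharp symmetric trough (σ = 12 ms, amplitude A_HS) centred 7.5 ms
  after HS — the foot-slap rotation peaks just after initial contact —
  riding on a broad shallow recovery lobe whose flank decays through
  30 °/s exactly at TS;
- a sharp symmetric trough (σ = 12 ms, amplitude A_TO) centred at TO on
  a shallow approach lobe whose flank rises through 30 °/s exactly at
  HO;
- a wide positive mid-swing hump (amplitude A_MS) plus a moderate
  late-swing dorsiflexion shelf, so swing stays decisively positive
  until the pre-strike dive — real swing-phase foot rotation has no
  flat-foot-like zero plateau, and a scalar-emission HMM relies on that;
- per-stride amplitude factors (~10% SD, emulating stride-to-stride
  vigour differences), white gyroscope noise, and, in the parkinsonian
  presets, a 4–6 Hz additive tremor sinusoid.

The 30 °/s crossings at TS and HO are exact by construction (bump widths
are solved per stride from the drawn phase durations); they are the
anchors the S-method exploits, so its accuracy on clean data — every
event within 15 ms of truth, asserted in the tests — is a property of
template smoothness, not a general claim about real signals.

The accelerometer resultant carries an impact spike at HS, a push-off
peak at TO, quiescence near g during flat foot and a sub-g dip during
swing; spike areas are kept small enough that the 1.25 s moving average
stays within the R-method's 0.5 m/s² quiescence band of g during flat
foot.

Footswitches: heel contact on [HS, HO), forefoot contact on [TS, TO),
rendered as analog force levels (0.45–0.95 a.u. undulation while loaded
plus 0.01 a.u. noise) so that binarization at 10% of the robust maximum
reproduces the contact truth exactly. Optional chatter flips 2–8 ms runs
within 15 ms of contact edges with a per-edge probability — long enough
to survive the hold-resampling to 200 Hz, short enough for the 20 ms
debounce to remove.

Presets: `healthy` uses the published control-group phase means
(6.9, 39.4, 16.2, 37.7)% with a 1.1 s stride; `pd_mild` shifts the
distribution by (0, +4, −2, −2) points with damped peaks and 10 °/s
tremor; `pd_severe` uses (8, 48, 12, 32)% — longer flat foot, shorter
swing — with further damped peaks, 20 °/s tremor and larger jitters.
The parkinsonian numbers beyond the healthy means are plausibility
fixtures motivated by the shuffling-gait literature, not estimates from
any patient population. `subject_profile` draws stable per-subject trait
offsets (1.5 points SD on fractions, 80 ms SD on stride time) so that
test-retest reliability across a subject's repeated trials is meaningful:
without stable individual traits, between-subject variance vanishes and
ICC is degenerate.

### What the generator does not emulate

Turning, freezing-of-gait episodes, festination, variable gait speed
within a trial, sensor drift and mounting misalignment, double-support
asymmetries, and the broadband complexity of real IMU signals. Passing
the closed-loop tests therefore shows that the implementations are
faithful to their specifications and consistent with each other — not
that any method attains the same accuracy on real parkinsonian gait.

## Problem sizes and runtimes

The cohort harnesses use 20-trial healthy cohorts of 30-stride trials
(10 training / 10 test) for the standard-trained HMM and the threshold
methods, and five 3-trial subjects (all leave-one-trial-out folds) for
the subject-specific HMM; EM is capped at 25 iterations there, which is
past the knee of the likelihood trace under supervised initialization.
The full `pipeline` command defaults to 6 trials × 20 strides per preset.
These sizes put the acceptance script at well under a minute and the test
suite at a few minutes on a single CPU; all of them scale linearly if
larger cohorts are wanted.

## Known limitations

- The R-method rule-set is an interpretation of a summary description;
  no claim is made that it reproduces the original implementation.
- The sample-level TN definition makes TNR (and hence G) incomparable
  with studies that count non-transitions differently.
- The HMM's accuracy depends on the SD floor and mixture count as
  discussed above; the defaults are tuned to the boundary-alignment task,
  not to likelihood.
- GPQI stride pairing across sides (per-stride basis) is by temporal
  index; no gait-event-level left/right correspondence is attempted.
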