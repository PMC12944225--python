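# Methods

## Problem and scope

A cheek-mounted triaxial accelerometer (nominal 10 Hz, ±2 g) on a sheep
halter records head and jaw motion. The package classifies each minute of a
recording as rumination, resting/idling or eating; scores that classification
against per-second human observation; and compares 24 h behaviour budgets
between a familiar baseline condition and an unfamiliar housing condition as
a proxy stress read-out. Hardware, live telemetry, video handling and
posture *detection* are out of scope — posture enters only as an annotation
channel alongside the behaviour labels.

## Signal model and features

Raw samples are accelerations in g. The quasi-static component (gravity plus
slow postural drift) is estimated per axis by a centred moving mean
(default **2.5 s**) and subtracted. A moving mean is used instead of a
high-pass filter because it is exactly reproducible, has no ringing, and a
2.5 s window cleanly separates postural drift (≪ 0.4 Hz) from chewing
(~1–3 Hz). All moving statistics use truncated windows at the edges (no
padding), so constants are reproduced exactly and output length equals input
length.

The dynamic resultant `m(t) = √(x_d²+y_d²+z_d²)` is orientation-free: any
axis permutation or sign flip of the sensor leaves it unchanged (tested as an
invariant).

Per non-overlapping window (default **10 s**; must exceed 1 s, be shorter
than 1 min and divide 60 so whole windows tile each minute):

| feature | definition | default parameters | rationale |
|---|---|---|---|
| `sma` (g) | mean of rectified dynamic acceleration summed over axes | — | classic gross-activity measure; time-normalised so thresholds do not depend on window length |
| `msv` (g) | mean of `m` | — | orientation-free activity level |
| `cum_activity` (g·s) | integral of the envelope over the window | envelope = moving max **1 s**, then moving mean **2 s** | the 1 s peak window spans one chew cycle, so the envelope stays near the chew amplitude through a bout; 2 s smoothing bridges single missed strokes |
| `hf_activity` (g) | RMS of `m` minus its **0.5 s** moving mean | — | a 0.5 s mean keeps sub-2 Hz structure and flags jerky transients; low for stereotyped chewing, high for irregular eating motion |
| `break_fraction`, `break_regularity` | movement breaks = maximal runs with envelope < **0.05 g** for ≥ **2 s**; fraction of window inside breaks, CV of inter-break start intervals | — | rumination's bolus pauses are short and near-periodic; regularity is NaN when fewer than two breaks start in the window |

None of the smoothing constants is a reconstruction of the original device's
(unpublished) parameters; they are this package's declared defaults, all
configurable through `FeatureParams`.

## Classifier

Decision rule per window: `cum_activity < θ_low` → resting/idling; otherwise
`hf_activity < θ_noise` → rumination, else eating. The classifier never
emits OTHER; at evaluation time OTHER minutes on the observed side simply
fall into the negative class of each one-vs-rest comparison.

Each window carries a margin — the smaller normalised distance to the two
thresholds — and the minute label is the majority vote over the minute's
windows, ties broken first by largest summed margin among the tied classes,
then by a fixed priority (rumination > eating > resting/idling > other).
The same priority resolves modal ties when reducing per-second annotations
to minute gold labels; the reduction rule itself (mode of the 60 one-second
labels, trailing partial minute dropped) is this package's choice, since
only the one-minute evaluation unit is externally fixed.

Calibration (`ThresholdBehaviourModel.fit`) is an exhaustive grid search
maximising the mean one-vs-rest Cohen's kappa of the three target classes at
minute level. Default grids are 25 quantiles (2–98 %) of the respective
feature, scanned ascending with θ_low outer; the first maximum wins, making
refits bit-identical. This replaces the original system's undocumented
manual tuning with a reproducible procedure.

## Evaluation

One-vs-rest confusion counts per behaviour at minute resolution, then
accuracy, sensitivity, specificity, precision, and Cohen's kappa with the
binary-marginal chance term
`Pc = [(TP+FN)(TP+FP) + (TN+FP)(TN+FN)]/N²`. This construction of `Pc` was
*selected because it reproduces the published validation kappas from their
printed counts* (verified row by row in the regression tests), not assumed a
priori. Zero-denominator metrics return NaN rather than 0 so that sparse
per-animal rows do not silently deflate pooled summaries. A known one-minute
inconsistency in one published pooled row (detected count one less than
TP+FP) is flagged by the test suite, not reconciled.

## Stress analysis

Daily budgets must cover exactly 1440 minutes; partial days are rejected
because budget comparisons are only meaningful over whole days. Paired
comparison per behaviour (optionally per posture):

- **Normality screen.** Shapiro–Wilk on *each condition's sample*; if either
  p ≤ α the exact paired Wilcoxon signed-rank test is used, otherwise the
  paired two-sided t-test. Screening the two samples (rather than the paired
  differences) is a deliberate design choice: it is what the published
  analysis evidently did — it reproduces that analysis's test selection on
  every table row, including the eating row whose unfamiliar sample (three
  near-identical values) fails normality while its differences do not.
  A constant sample is treated as maximally non-normal.
- The variance-ratio F-test is computed and reported as a diagnostic only;
  variance equality has no bearing on a paired design.
- Wilcoxon p-values use the exact signed-rank distribution for n ≤ 25
  (two-sided); for n same-signed pairs this gives p = 2/2ⁿ, cross-checked
  against brute-force sign enumeration in the tests.
- Means and SDs are sample statistics (n−1 denominator), which matches the
  published descriptives. Percent change is `100·(unfamiliar −
  baseline)/baseline` (undefined for zero baseline); note it is *not*
  antisymmetric under exchanging the roles, because the denominator changes.
- Identical conditions produce a degenerate result (p = 1, flagged) rather
  than a test statistic on zero-variance differences.

`deviation_alert` is intentionally minimal: z-score of a new day against the
animal's baseline days, alert at |z| ≥ k (default 2). With fewer than two
baseline days it refuses; with zero baseline SD it degrades to "any
difference" and flags itself degenerate.

## Synthetic generator

The generator emulates what the classifier exploits, not sheep biomechanics:

- **Schedules**: alternating bouts with exponential lengths (floored at
  1 min, capped at each behaviour's remaining quota), so realised daily
  shares equal the requested quotas up to rounding. Default quotas follow
  the published baseline budget (≈34 % rumination, 44 % resting, 19 %
  eating, 3 % other).
- **Rumination**: rotary chew strokes at **1.2 Hz**, amplitude **0.25 g**,
  modelled as elliptical motion (ellipticity 0.6) in the plane orthogonal to
  gravity; bouts of **50 s** separated by **5 s** pauses with 5 % CV jitter.
  The chew rate and bolus cycle sit in the plausible band for small
  ruminants; the elliptical (rather than single-axis) stroke is what keeps
  the resultant magnitude steady within a bout — the defining low-noise
  signature of rumination. A consequence worth knowing: the magnitude
  spectrum peaks at 2× the stroke rate (two acceleration maxima per rotary
  cycle), while individual axes peak at the stroke rate.
- **Eating**: bursts (~12 s, lognormal amplitude around **0.45 g**, random
  direction) at 2.5 Hz with broadband jerk noise (0.15 g SD), short gaps and
  ~6 transients/min of ≥1 g — irregular by construction.
- **Resting**: 0.02 g white noise with rare (0.2/min) posture-shift spikes.
- Gravity (1 g) rides on a configurable orientation vector; sensor noise is
  0.01 g; output clips at ±2 g like the hardware. Posture annotations are
  emitted per bout (eating standing; rumination/resting lying with
  probability 0.6).
- **Duration tables**: Gaussian per-animal budgets, truncated at zero, with
  the OTHER category absorbing the remainder to 1440 min (proportional
  rescale if the three draws overshoot a day). Default means/SDs and stress
  multipliers (0.544 rumination, 1.479 resting, 0.638 eating) follow the
  published baseline and effect sizes.

What a green test does *not* establish: the generator contains none of the
hard parts of field data — wool- and halter-slip artefacts, overlapping
trough competition, inter-individual chewing variation, observer
mislabelling — so pipeline recovery of generator parameters demonstrates
internal consistency, not field performance. Published field-study numbers
enter the test suite only as fixed regression targets for the metric and
statistical engines.

## Numerical choices and degenerate inputs

- Seeds: every stochastic operation takes an explicit seed
  (`numpy.random.default_rng`); the CLI derives per-stage seeds from one
  global seed by fixed offsets.
- Out-of-range samples are clipped (with a warning tally), not rejected —
  the sensor itself saturates.
- Annotation change-point files: an annotation holds until the next one; the
  last one is held for 60 s unless an explicit duration is given. Duplicate
  timestamps are reduced by label priority, which makes minute labels
  invariant to input row order.
- Grid calibration refuses single-class gold labels; traces shorter than one
  analysis window or one minute are data errors, as are non-monotone time
  columns and mismatched series lengths.

## Known limitations

- The two-threshold rule ignores `sma`, `msv` and the break statistics; they
  are computed and exported for analysis and for future rule extensions.
- Calibration transfers across animals only as well as their signal
  amplitudes match; individual calibration is the intended use.
- The stress module's test-selection rule reproduces the published analysis
  on its data but the original selection criterion was never stated; with
  other data the rule is simply "Shapiro–Wilk per sample at α".
- Exact Wilcoxon p-values with n = 4 pairs cannot fall below 0.125; at this
  sample size the signed-rank route can only ever flag trends.
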