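# Methods

## The problem

Surface EMG (sEMG) recorded during dynamic contractions is hard to
interpret: the measured amplitude depends not only on neural drive but
on movement factors — joint angle, contraction type (concentric vs
eccentric), load, speed, posture — and on strong inter-individual
variability. `dynemg` implements a two-arm analysis of such recordings
using elbow flexion/extension and the brachioradialis as the model
system:

1. **Categorization.** Every sample of the normalized sEMG envelope is
   assigned by a decision tree to a combination of *variable* movement
   factors (contraction type × flexion/extension angle interval), while
   *constant* factors (load, speed, forearm posture) are carried as
   metadata. Three analyzing scenarios are supported: contraction type
   only (A), angle interval only (B), and the full combination (C).
2. **Probabilistic arm.** For each subject and each merged 30° angle
   interval, empirical frequency distributions of the concentric and
   eccentric envelope amplitudes are compared by an overlap statistic:
   with `mode_con` and `mode_ecc` the most probable amplitudes of the
   two distributions and `d = |mode_con − mode_ecc|`, an analyzing
   interval `A = (mode_con + mode_ecc)/2 ± 2.5 %MVC` is placed midway
   between the modes, and

   `P_overlap = P_con(A) · P_ecc(A)`

   is the product of the two distributions' probabilities of falling
   inside it. Identical distributions give values near 1; well-separated
   ones give 0. Per-subject probabilities are aggregated across subjects
   by median and range (the mean is also reported).
3. **Deterministic arm.** The same category tables feed conventional
   statistics on subject-level means: a paired t-test (scenario A), a
   one-way repeated-measures ANOVA over the four merged angle intervals
   with Mauchly's sphericity test, conditional Greenhouse–Geisser
   correction and Bonferroni-adjusted adjacent-interval post-hocs
   (scenario B), and a contraction-type × angle-interval two-way
   repeated-measures interaction with per-interval simple main effects
   (scenario C).

Both arms consume the identical categorization pass, so they are a
controlled comparison of analysis style, not of preprocessing.

## Signal processing

* **Envelope**: 4th-order Butterworth band-pass 10–500 Hz applied
  forward–backward (zero phase, so envelope samples stay aligned with
  the kinematic channels; the effective magnitude response is the
  squared 4th-order response), full-wave rectification, then a centered
  100 ms moving average whose window shrinks symmetrically at the trial
  edges (preserves length and alignment).
* **MVC normalization**: five MVC trials per subject; the per-trial
  value is the mean envelope over the central 50 % of the trial
  (avoiding onset/offset transients); all ten 3-subsets of the five
  values are enumerated and the subset with the smallest standard
  deviation *across the three per-trial means* is chosen; the reference
  is the mean of those three values, and envelopes are expressed as
  100·envelope/reference (% MVC, values may exceed 100). Whether the
  "smallest standard deviation" should be computed within trials or
  across the three per-trial means is ambiguous in the protocol; the
  across-means reading is implemented and documented here. Ties break to
  the lexicographically first trial-id subset.
* **Kinematic alignment**: kinematics recorded at 200 Hz are linearly
  interpolated onto the 2000 Hz EMG timebase, endpoints clamped.
* **Contraction type**: angular velocity by central differences on the
  100 ms-smoothed angle; velocity > +2.5 °/s → concentric, < −2.5 °/s →
  eccentric, in between → unassigned. The dead-band (10 % of the nominal
  25 °/s) drops samples near movement reversals instead of labelling
  them arbitrarily.
* **Trial exclusion**: a trial is excluded when the
  pronation/supination angle deviates more than 5° from its value at
  the trial start, or shoulder/wrist more than 10° (strict
  inequalities; prosup checked first). Exclusion is per whole trial and
  always logged.

## Categorization conventions

Angle bins are half-open `[lo, hi)` with a closed top bin, so the 12
fine 10° bins partition [0°, 120°] exactly; merging to 30° bins pools
samples and conserves counts. Scenario B retains samples regardless of
contraction label; scenarios A and C count unassigned-label samples as
excluded, and B/C count out-of-range angles as excluded. A conservation
invariant (retained + excluded = input) is enforced and tested.

## Distribution and overlap conventions

Histograms use 0.5 %MVC bins anchored at 0; the mode is the center of
the highest-count bin with ties broken toward the lowest bin. The bin
width is a package choice: it resolves modes finely relative to the
±2.5 %MVC analyzing interval. Interval probabilities are counted on the
raw samples with a closed interval, so the product rule is exact and
independent of the binning; the histogram is used only to locate the
mode. Categories with fewer than 50 samples (configurable) are computed
but flagged `low_n` — the protocol's "at least 20 repetitions"
motivates a floor without prescribing one.

## Statistical conventions

Subject-level category means are the units of analysis (n = subjects),
matching repeated-measures degrees of freedom such as df = 9 for 10
subjects. The Greenhouse–Geisser correction is applied when Mauchly's
p < α; both corrected and uncorrected results are always reported. The
two-way within-subject interaction for the 2×k design is computed by
the standard reduction to a one-way repeated-measures ANOVA on the
per-subject concentric−eccentric difference scores, which also supplies
the interaction term's sphericity diagnostics; tests verify numerical
identity with a direct two-way implementation. Simple main effects of
contraction type per angle interval are paired comparisons with
F(1, n−1) = t², reported unadjusted. RM-ANOVA, Mauchly and ε
computations are delegated to `pingouin`; t-tests and Shapiro–Wilk to
`scipy.stats`.

Degenerate inputs are reported, not hidden: zero-variance paired
differences yield a flagged no-difference report; a zero-variance ANOVA
yields F = 0, p = 1 with a degenerate flag; single-sample categories
report SD 0 with a flag.

## Synthetic studies

No recordings ship with the package; the `synthetic` module generates
complete studies with known ground truth:

* **Kinematics**: each movement trial is one repetition — a 0→120→0°
  triangle at a nominal 25 °/s (9.6 s per cycle) with 200 ms
  cosine-blended turnarounds that keep the apex exactly at 120°, plus
  Gaussian angle noise (SD 0.5°, electrogoniometer scale).
  Pronation/supination and shoulder/wrist channels follow half-sine
  excursions whose peak equals a configurable drift (default 0.5° /
  1.0°, well inside tolerances; setting `prosup_drift_deg` above 5°
  produces excludable trials by construction).
* **EMG**: an amplitude-modulated band-limited (20–450 Hz) unit-variance
  Gaussian carrier at 2000 Hz. The modulation is
  `m(θ, type) = (b0 + b1·θ/120)·(1 − r·g(θ)·1[eccentric])`, with g = 0
  below the attenuation onset (30°), ramping linearly to 1 over 30°.
  Defaults b0 = 0.03, b1 = 0.25, r = 0.3 are derived from the reported
  group means of the study design this emulates (envelope rising from
  ≈4.7 to ≈23.9 %MVC across the angle range; concentric ≈19 vs
  eccentric ≈14 %MVC overall). Subject random effects multiply b0, b1
  and r by 1 + N(0, 0.2). MVC trials are 5 s of the same carrier at
  m ≡ 1; MVC normalization cancels the rectified-carrier calibration
  constant, so normalized envelopes recover 100·m directly.
* **What it does not emulate**: motor-unit recruitment and firing
  statistics, fatigue, electrode or tissue effects, and — importantly —
  the *peakedness* of real per-interval amplitude distributions. With a
  linear activation surface and a constant-speed protocol, the value
  distribution within a 30° interval is close to uniform over a
  b1·(25 %MVC)-wide support plus multiplicative envelope noise
  (CV ≈ 8 %, set by the carrier bandwidth and the 100 ms average). Real
  recordings show much more concentrated distributions. Consequently the
  synthetic overlap probabilities are compressed toward the middle:
  high-overlap conditions sit near 0.5–0.6 (not ≈0.7) and the partially
  attenuated 30–60° interval stays at high overlap (≈0.65) even though
  its deterministic simple main effect is clearly significant. Passing
  tests therefore demonstrate correctness of the *method* and recovery
  of the *qualitative* pattern (high overlap at small angles,
  overlap collapsing with full attenuation, significance exactly above
  the onset), not the published numeric medians.

## Problem sizes used in tests

The acceptance-style checks run the default design (10 subjects × 20
repetitions; 2000/200 Hz): 20 seeded replicates for pattern recovery and
one full null study plus 100 reduced null replicates (6 repetitions per
subject) for the type-I-error calibration of the scenario A test — the
test's level depends on the number of subjects, not repetitions, so the
reduced size is statistically equivalent. Statistical null calibration
at the module level uses 500 replicates of direct Gaussian
subject-level means.

## Known limitations

* The overlap statistic depends on histogram-mode location; for flat
  distributions the mode (and hence d) is unstable. This is a property
  of the statistic itself and is amplified by the synthetic generator's
  uniform-ish distributions.
* Shift invariance of the overlap statistic is exact only for shifts on
  the 0-anchored histogram lattice (multiples of the bin width);
  off-lattice shifts can move a mode by up to one bin.
* Joint angles are consumed as time series; computing them from marker
  trajectories is out of scope.
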