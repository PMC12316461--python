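# Methods

`sociodyn` implements the quantitative core of a class of systems-neuroscience
experiments that relate dopaminergic projection activity to social behavior in
mice: ethogram-based Markov analysis of a juvenile-intruder session,
pose-geometry detection of cup interactions in a three-chamber arena,
single-neuron response classification from microendoscopic calcium imaging,
intrinsic-property extraction from whole-cell current-clamp recordings, and a
set of scalar behavioral measures. Every analysis is paired with a synthetic
generator that plants known ground truth, so the pipeline's statistical
behavior can be verified end to end without animal data.

## Behavioral transition analysis

A session is annotated as one behavioral code per 1-s bin from a 15-category
ethogram (9 social, 6 nonsocial behaviors); a two-state variant collapses the
alphabet to social/nonsocial. The transition count matrix `O` includes
self-transitions — per-bin labels imply that dwelling in a state is a
transition to itself, and without them the two-state "within-state"
probabilities would be undefined. `P` row-normalizes `O` by each state's
outgoing transitions (the final bin of a sequence has no outgoing transition
and is not counted in the denominator).

Two chi-squared statistics are computed:

* **Order (G) test.** `G = 2 Σ_ij O_ij ln(O_ij / E_ij)` with expected counts
  under a zeroth-order (time-independent) null taken as the product of the
  observed margins, `E_ij = n_i· n_·j / N` — the standard G independence
  test. Zero-count cells contribute nothing (`0·ln 0 := 0`); cells with
  `E_ij = 0` can only occur with `O_ij = 0` and drop out. Degrees of freedom
  are `(k−1)²` for `k` states occurring in the sequence.
* **Stationarity (LRX) test.** The sequence is divided into `S` segments of
  near-equal duration (earlier segments take the extra bin when the length is
  not divisible). With per-segment counts `f_ijs` and probabilities `p̄_ijs`,
  `LRX = 2 Σ_s Σ_ij f_ijs ln(p̄_ijs / p_ij)`, with `p_ij` estimated from the
  counts pooled over segments. Pooling (rather than counting the undivided
  sequence, which additionally contains the `S−1` segment-boundary
  transitions) makes the statistic an exact likelihood ratio: it is zero
  whenever all segments share identical transition counts and nonnegative
  always (per segment and row, `Σ_j f ln(p̄/q) ≥ 0` for any probability row
  `q`). The two conventions differ by `S−1` transitions out of `N` and agree
  asymptotically. Degrees of freedom are `(S−1)·k·(k−1)`.

Both tests are calibrated: on iid (zeroth-order) and stationary-chain nulls at
`T = 10⁴` bins the rejection rate at α = 0.05 lands within 0.05 ± 0.02 over
500 replicates (this is recomputed by the acceptance script, not assumed).

Multi-label bins (annotation may assign several simultaneous codes to one
second) are resolved by a configurable priority list whose default prefers
social over nonsocial codes, matching the analyses' social-engagement focus.

## Pose-geometry interaction detection

A frame counts as an interaction with a cup when (a) the nose lies within
1.3× the cup diameter of the cup center and (b) the cup center falls inside a
90° cone (45° half-angle) in front of the head. The heading vector is
neck→head, with head→nose as fallback when the neck is missing; frames with
an undefined heading or missing nose are negative. Distance is measured to
the cup center by default (`distance_reference="edge"` subtracts the cup
radius); both choices and the keypoint pair used are configuration-surfaced
because tracking setups differ.

Framewise detections are binarized into 40-ms bins by exact interval-overlap
bookkeeping: a bin is positive when any part of it overlaps a positive frame
(a duration-weighted majority rule is available). This handles frame rates
whose frame duration exceeds the bin width (e.g. 20 fps) without aliasing.

Trials are segmented in three steps, in this order: bouts separated by pauses
strictly shorter than 1.5 s merge into one candidate; candidates shorter than
1 s are discarded; a candidate beginning less than 5 s after the end of the
previous *accepted* trial is discarded (rejected candidates do not reset the
refractory reference). Merging before the minimum-duration rule lets brief
fragmented contacts accumulate into a valid trial, which is how a "pause in
interaction" reads most naturally.

## Neural response classification

Each cell's raw calcium trace is z-scored over the whole session and
resampled onto the 40-ms behavior time base by nearest-frame assignment
(linear interpolation optional). For 100 thresholds spanning `[min z, max z]`
(both endpoints included; activity rule `z ≥ t`), the binarized activity is
compared with the behavior vector to give (FPR, TPR) points; the auROC is the
trapezoidal area after sorting by FPR with (0, 0) and (1, 1) appended. On
instances of ≤ 50 bins this agrees with the exhaustive pairwise rank
(Mann-Whitney-style, ties = ½) oracle to about the grid's discretization
(≈ 0.02); the two diverge only when consecutive thresholds skip a positive
and a negative sample simultaneously.

Significance uses a circular-shift permutation null: the behavior vector is
rotated by 1000 offsets drawn uniformly (with replacement) from
`{1, …, T−1}` — the unshifted alignment is excluded by construction — and the
auROC recomputed each time. Rotation preserves the behavior vector's run
structure and autocorrelation while destroying its alignment with the trace,
which is what makes the null appropriate for slow calcium signals. A cell is
*excited* when its auROC strictly exceeds the 97.5th percentile of the null
(linear-interpolation percentiles), *inhibited* below the 2.5th, else *none*.
The implementation evaluates all shifts from one histogram of threshold
slots, which is algebraically identical to recomputing the sweep per shift
(tested against the explicit recomputation) and fast enough to classify
hundreds of cells with 1000 permutations each in seconds.

Peri-event averages take the mean z-scored trace over ±5 s around trial
onsets, excluding trials whose window is truncated by the session edge.
Response-profile clustering concatenates each cell's social and object
peri-event averages and applies Ward-linkage agglomerative clustering
(Euclidean distance) with flat clusters cut at 0.770× the maximum linkage
height. Population summaries compute per-animal excited/inhibited
proportions and the Pearson correlation between the socially excited
proportion and the social:object ratio; the correlation is flagged undefined
with fewer than 3 animals or zero variance.

## Intrinsic electrophysiology

The current-step protocol delivers 1-s steps from −120 pA to +260 pA in
20 pA increments (0.2 s pre/post baseline, 10 kHz sampling in the synthetic
data). Feature definitions:

* **Voltage sag** (mV): steady-state minus peak membrane potential during the
  −120 pA step. Peak = minimum of the 3-ms boxcar-smoothed trace within the
  step (smoothing bounds the extreme-value bias of sampling noise);
  steady state = mean over the final 200 ms of the step.
* **Ramp ratio**: mean deflection 900–1000 ms after step onset divided by the
  mean deflection 100–200 ms after onset, on the largest depolarizing step
  with no detected spikes. Deflections are measured from the pre-step
  baseline because ratios of absolute potentials near rest are
  ill-conditioned.
* **Firing delay** (ms): time from step onset to the first spike on the
  rheobase step (lowest current with ≥ 1 spike). Spikes are upward crossings
  of 0 mV with a 2-ms refractory period (threshold configurable).
* **Max instantaneous frequency** (Hz): maximum of 1/ISI over spike pairs
  that both fall within the first 100 ms of any depolarizing step.
* **Capacitance** (pF, optional): single-exponential fit of the first 150 ms
  of the −20 pA charging curve gives τ and ΔV; `R = |ΔV/I|`, `C = τ/R`. This
  approximates charge-integration estimators and is used in place of ramp
  ratio for clustering cortical-amygdala-like populations where capacitance
  separates pyramidal cells from interneurons.

The optogenetic-response sweep (8 light pulses at 30 Hz, 5-ms width) is
analyzed against the mean of the 5 s before the first pulse. The EPSP peak is
the largest positive deflection within 100 ms of the first pulse (fast
glutamatergic window); the IPSP trough is the largest negative deflection
anywhere within 5.5 s, accommodating slow neuropeptide-like kinetics. A
deflection counts as a PSP when it exceeds 5× the smoothed-baseline noise SD;
this threshold sits above the expected extremum of smoothed noise over the
5.5-s search window (~3.5 SD for the effective number of independent samples),
so flat sweeps classify as *none* while 3–4 mV planted PSPs are detected with
large margin. IPSP decay τ is a single-exponential least-squares fit from the
trough to the first return to baseline, capped at 5.5 s. Voltage area is the
signed trapezoidal integral of the baseline-subtracted trace over 0–5.5 s
after light onset.

Response classes follow a precedence: when a constant-current firing sweep is
available, a decrease in the mean inter-event interval across light onset is
an *excitation* and an increase an *inhibition*; otherwise EPSP-only →
excitation, IPSP-only → inhibition, both → *mixed*, neither → *none*. For
dendrogram annotation only, mixed responses resolve by the sign of the
voltage area.

Baseline clustering max–min normalizes each feature to [0, 1] and applies
Ward linkage on Euclidean distance, reporting the full tree and the two
top-level clusters. Rows with missing features are dropped and reported. A
feature that is constant across varying cells is an error (its normalization
is undefined); a fully degenerate input of identical cells returns the
zero-height tree instead.

## Behavioral metrics

Relative dominance is a subject's win proportion over round-robin tube-test
contests, with the testing-day window exposed as a parameter. In a closed
round robin every contest produces one win and one loss, so cohort dominance
averages exactly 0.5. The social:object ratio divides time on the social side
of the three-chamber arena by time on the object side (raw ratio by default;
a log option exists for symmetry). ON−OFF difference scores and the pairwise
Pearson correlation matrix of baseline measures (unit diagonal, symmetric,
constant columns flagged missing) complete the module.

## Synthetic data: what it emulates and what it does not

All generators are bit-reproducible given their spec and seed, one RNG stream
per call.

* **Markov sequences** sample exactly from the specified chain, starting from
  its stationary distribution (uniform fallback when it is not unique) to
  avoid burn-in bias at short `T`.
* **Pose sessions** place the animal so the detection rule holds by
  construction during planted bouts (nose at 0.8× cup diameter, heading at
  the cup) and fails by construction outside them (nose kept beyond 1.45×
  diameter), with an Ornstein-Uhlenbeck-style wander between bouts and
  optional Gaussian keypoint jitter. Default geometry: 57.5 × 22.5 cm arena,
  two 8-cm cups, 25 fps (which divides the 40-ms bin width exactly). The
  full 15-keypoint skeleton is emitted; only nose/head/neck carry signal.
  Not emulated: realistic gait, tracking dropouts, identity swaps, 3-D
  posture — so passing tests show the *rule logic* is correct, not that real
  tracking noise is handled.
* **Calcium populations** are Gaussian noise plus (for excited cells) a
  single-exponential transient (τ = 0.5 s, GCaMP7f-like) of fixed amplitude
  at each interaction-bout onset; inhibited cells subtract the same kernel.
  Default 20 fps, amplitude 5× noise SD. Not emulated: photobleaching,
  neuropil contamination, bursty baselines — the permutation test's
  calibration on real data depends on trace autocorrelation that this noise
  model lacks, which is exactly why the circular-shift null (not a bin
  shuffle) is used.
* **Ephys cells** synthesize each sweep so that the extractors' definitions
  recover the planted archetype values: the sag sweep descends to its trough
  over a 30-ms half-cosine and relaxes with τ = 100 ms; subthreshold
  depolarizing sweeps share a linear ramp shape whose window means encode the
  planted ramp ratio; the rheobase sweep fires first at the planted delay;
  the strongest sweep opens with a burst at exactly the planted maximum rate
  (weaker steps are rate-capped below it); the −20 pA sweep is a pure RC
  charging curve with τ = R·C. Spikes are stylized templates (1 ms rise to
  +30 mV, 1.5 ms fall); their constant ~0.7 ms template-to-crossing offset
  cancels in ISIs and is far below the ±10 ms delay tolerance. EPSP trains
  depress (0.5 per pulse) so the planted peak lands inside the 100-ms search
  window; IPSPs trough at 0.4 s and decay with an exact exponential of the
  planted τ.
* **Tube contests** draw each pair's winner from a logistic function of the
  latent rank difference, giving deterministic hierarchies at large gaps and
  fair coins at equal ranks.

## Numerical choices and degenerate inputs

Tolerances used by the recovery checks: sag ±0.5 mV, ramp ratio ±0.05,
firing delay ±10 ms, max frequency ±5 Hz, IPSP τ ±10% (all at 0.2 mV
synthetic noise). Degenerate inputs raise informative errors rather than
propagating silently: constant traces (z-score undefined), all-positive or
all-negative behavior vectors (ROC undefined), missing −120 pA sweep (sag
undefined), segments without transitions (LRX undefined), zero object-zone
time (ratio undefined), constant clustering features (normalization
undefined). Probabilistic assertions in the test suite use fixed seeds; the
problem sizes (500 calibration replicates at `T = 10⁴`; 500 null and 100
planted calcium cells at 180-s sessions with 1000 permutations; 100 synthetic
ephys cells; a 12-animal end-to-end cohort with 30 cells each) were chosen so
every check exercises the regime its statistic assumes while the whole suite
runs in a few minutes on one core.

## Known limitations

The package consumes keypoints, traces and sweeps; it does not implement
video preprocessing, source extraction, cross-session cell registration, or
spike sorting. Group-level inference (ANOVA, t-tests) is left to standard
tools. The capacitance estimate is a charging-curve approximation, not a full
charge-integration implementation. The synthetic data validates the analysis
logic and its statistical calibration, not robustness to the artifacts of
real recordings.
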