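# Methods

`eegmvpa` implements a time-resolved multivariate decoding analysis of
epoched EEG with group-level permutation inference, together with a
synthetic-data generator that provides ground truth for every stage.
This note records the model, the numerical choices, and what the
synthetic validation does and does not establish.

## Pipeline model

The unit of data is an epoched dataset: a `trials x channels x time`
tensor in microvolts, with per-trial condition labels, a millisecond
time axis locked to stimulus onset, and explicit channel roles (scalp,
mastoid, EOG).  The emulated study design is 14 subjects, four
conditions (hands, tools, feet, animals) with 128 trials each, 63 scalp
channels plus two mastoids, recorded at 1000 Hz with epochs of
[-500, 500) ms.

Stages run in a fixed order:

1. **Resampling** to 250 Hz by polyphase decimation (integer ratios
   only; Kaiser beta = 8 anti-alias filter, pass-band ripple ~1e-4).
2. **Band-pass filtering** 0.5–40 Hz with a Hamming-window linear-phase
   FIR applied forward-backward (`filtfilt`), so the net phase shift is
   zero.  Nominal transition widths are 0.5 Hz (low edge) and 10 Hz
   (high edge); because filtering is applied per epoch, the filter
   length is capped at a third of the epoch length (reflect padding
   requires 3x the order).  On a 250-sample epoch this widens the
   low-edge transition considerably; the residual DC this admits is
   removed by baseline correction, and a longer recording recovers the
   nominal design.
3. **Re-referencing** to the average of the two mastoids.
4. **Epoch cropping** to the analysis window, half-open `[start, end)`
   everywhere — [-100, 500) ms at 250 Hz is exactly 150 samples.
5. **Baseline correction**: per trial and channel, subtracting the mean
   over [-200, 0) ms.

All stages are pure functions: identical input gives bitwise-identical
output.

## Automatic artifact rejection

Given a group of equal-length signals, every observed peak-to-peak
(p2p) value is a candidate threshold theta; the chosen theta* minimizes

    J(theta) = sum_t ( mean_{p2p <= theta}(x_t) - median_all(x_t) )^2 ,

the squared distance between the mean of the under-threshold signals
and the pointwise median waveform of the whole group.  Signals with
p2p <= theta* (boundary inclusive) are kept.  Ties in J are broken
toward the **largest** threshold, i.e. rejecting the least data.  The
candidate grid is the set of observed unique p2p values because J only
changes at those points, so the argmin is exact.

The two-step procedure applies this rule across trials for each
electrode (pass 1), then across electrodes for each trial (pass 2),
with repair after each pass: a trial with fewer than half of its scalp
electrodes marked is repaired by interpolating the marked electrodes
(inverse-distance weights, `w ~ 1/d`, normalized, on the unit-sphere
montage); a trial with at least half marked is excluded.  Mastoid and
EOG channels are never auto-rejected.

One interaction needed a design decision: an interpolated channel is a
weighted mean of the other channels, so it sits unnaturally close to
the pointwise median waveform, and pass 2's objective could minimize J
by keeping *only* interpolated channels — marking every real channel
bad and excluding a clean trial.  Pass 2 therefore excludes channels
already repaired in pass 1 from its candidate group; they are not raw
data and cannot meaningfully be re-tested.

## Decoding

At each timepoint the feature vector is the pattern over scalp
channels.  Features are z-scored per feature with statistics estimated
on the **training trials only** and the same transform applied to the
test trials — the only leak-free reading of "z-scored signals".  The
classifier is a two-class linear discriminant with equal priors:

    S      = (1 - lam) S_pooled + lam (tr(S_pooled)/p) I
    w      = S^-1 (mu_1 - mu_0),   b = -w.(mu_0 + mu_1)/2

The shrinkage intensity `lam` defaults to an analytic Ledoit–Wolf
estimate toward the scaled identity (63 features against ~200 training
trials makes the raw pooled covariance ill-conditioned); any fixed
`lam` including 0 can be configured.  A discriminant score of exactly
zero is assigned to the control class, making predictions
deterministic.

Standard decoding uses balanced k-fold cross-validation, k = 10: each
class is truncated by seeded random subsampling to the largest size
divisible by k (128 -> 120), and every fold holds the same number of
trials of each class.  The whole analysis is repeated 20 times with
fresh fold assignments *and* fresh balancing subsamples (the
distinction is not meaningful here, so both are reshuffled).

Cross-classification trains on all balanced trials of a condition pair
(no cross-validation is needed because the test condition is disjoint)
and scores the fraction of test-condition trials assigned to the
training target; 0.5 is the no-bias point.  Temporal generalization
applies the classifier trained at t_train to test features at every
t_test; test features at t_test are standardized with training
statistics computed at t_test, so only the classifier — not the
scaler — crosses time.  Under a shared seed the TG diagonal reproduces
the cross-classification timecourse exactly, which is asserted in the
tests.

Implementation note: the production path batches all timepoints, folds
(and, in permutation loops, subjects) into one stacked solve, uses
float32 features and a rank-one Gram update for the pooled scatter.
Permutation inference multiplies the fit count into the hundreds of
thousands, and this is what keeps it tractable on one core.  The public
`lda_fit` and `zscore_train_apply` are plain float64 implementations
used as readable references and checked against the batched path, an
explicit matrix-inverse oracle, and scikit-learn.

## Group inference

The group statistic is the subject-mean accuracy map minus chance
(0.5), enhanced by threshold-free cluster enhancement with E = 0.5,
H = 2 (the standard defaults of the TFCE method) and an adaptive
integration step `dh = range/100`, where the range includes zero so
constant maps remain well-defined.  Negative values are enhanced
separately and recombined with sign, making the transform odd.
Connectivity is 2-neighbor in 1-D and 4-neighbor (no diagonals) in 2-D.

Familywise error is controlled by a maximal-statistic permutation null:
condition labels are permuted across trials independently within each
subject, per-subject accuracy maps are recomputed, group-averaged,
TFCE-transformed, and the maximum and minimum over all points recorded.
With N permutations, observed values map to z through rank p-values
with +1 smoothing, `p+ = (1 + #{null_max >= obs})/(N + 1)`, converted
as `z = max(Phi^-1(1-p+), 0) - max(Phi^-1(1-p-), 0)`.  This form is
monotone in the observed statistic, signed by the dominant tail, zero
when neither tail reaches p < 0.5, and caps |z| at Phi^-1(N/(N+1)) —
2.33 for N = 100, which is why no peak can exceed that value, and why
at least 40 permutations are needed for |z| > 1.96 to be attainable at
all.  For the paired comparison of two decoding analyses on the same
subjects, the exchangeable unit is the subject and the null flips the
sign of each subject's accuracy difference; with a shared seed,
swapping the two inputs negates the z-map exactly.

Because fold assignment is itself random, the complete analysis
(accuracy maps, null, z conversion) is repeated — 20 times at full
scale — and the z-maps averaged; significance is read off the averaged
map at |z| > 1.96.  By default the permutation null is **redrawn** in
every repetition, treating each repetition as a complete analysis.  For
large Monte-Carlo validation (hundreds of simulated studies) the
functions also accept `null_scope="shared"`, drawing the null once and
reusing it across repetitions: the null distribution is the same
object, only the Monte-Carlo coupling between repetitions changes, at
roughly a quarter of the compute.  The large-replicate validation runs
in the test suite and acceptance script use the shared scope; the
pipeline default remains per-repetition.

Clusters are maximal contiguous runs (or 4-connected components) of
|z| > 1.96; each reports onset (first timepoint), offset, peak
location, peak z and the group-mean accuracy at the peak — the layout
used for peak-latency tables.

## Synthetic data

The generator emulates evoked category-selective activity as rank-one
spatiotemporal patterns: a unit-norm random channel topography times a
temporal envelope (boxcar or half-cosine arch) times an amplitude in
microvolts, added to all trials of the conditions carrying the effect.
A pattern attached to {hands, tools} but not animals is the ground
truth for cross-classification: train tools-vs-animals, test hands.
Between-subject variability is Gaussian amplitude jitter (SD = 20% of
the amplitude, truncated at zero).

Noise is AR(1) along time (rho = 0.5, marginal SD = `noise_sd`,
default 1 µV) for EEG-like temporal autocorrelation, with white noise
available for analytic checks.  Channels share a common field giving a
uniform pairwise spatial correlation of 0.3 — real EEG is strongly
spatially correlated, and without this, interpolated channels are
unrealistically clean averages (see the artifact-rejection note).
Artifact trials are implanted by rescaling a trial x electrode segment
so its p2p amplitude is a fixed multiple (default 10) of the 99th
percentile of the clean p2p distribution; since the rejection algorithm
sees only p2p, blink-shaped templates would add nothing testable.

Real-data effect amplitudes in signal space are not identifiable from
decoding accuracies alone; defaults in the examples are chosen to put
peak decoding accuracy in the 0.55–0.70 band typical of group-level
EEG category decoding at these trial counts.

What passing tests show — and what they do not: the synthetic data
validate fold hygiene, calibration (chance level, FWER), latency
recovery, and the algebra of every stage, under rank-one effects,
stationary Gaussian AR(1) noise and uniform spatial correlation.  They
do not establish performance under realistic EEG artifacts (blinks,
drifts, muscle), non-stationary noise, oscillatory activity, or
realistic head-model topographies.

## Reduced scales

Monte-Carlo validations run at reduced problem sizes chosen as the
package's own desk-scale conventions: null calibration uses 200
simulated studies of 8 subjects, 64 trials/condition, 8 channels, 20
timepoints, 50 permutations, 5 repetitions; latency recovery uses 20
studies at 250 Hz with 10 channels; the full design (14 subjects, 63
channels, 100 permutations, 20 repetitions) remains available through
the run configuration.

## Known limitations

* Interpolation is inverse-distance weighting, not spherical splines;
  adequate for p2p-based repair, not for topographic analysis.
* The per-epoch FIR cap trades low-frequency roll-off steepness for
  epoch length; filtering a continuous recording before epoching, when
  available, recovers the nominal design.
* The cross-classification score is reported as the fraction of test
  trials classified as the training target, so 0.5 is the no-bias
  point; other conventions (e.g. signed bias) are not implemented.
* Candidate thresholds in artifact rejection assume at least two
  signals and finite data; NaNs are rejected, not imputed.
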