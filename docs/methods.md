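# Methods

`graphreplay` implements the analysis chain used to study memory reactivation
during cued recall of a graph-structured association task, together with a
synthetic sensor-level data generator that provides ground truth for every
stage.  This note documents the models, the tunable parameters, the numerical
choices, and what the synthetic validation does and does not establish.

## Task model

Ten stimuli occupy the nodes of a directed, cyclic graph with 12 edges.
Eight nodes have in-degree and out-degree 1; two *hub* nodes have in-degree
and out-degree 2.  Because a hub's successor is ambiguous, the task unit is
the *triplet* (predecessor, current, successor): each directed edge maps to
exactly one successor, and the two edges entering a hub map to different
successors, so recall requires the edge context rather than pairwise
associations.

The canonical layout is two overlapping directed cycles of lengths 8 and 4
sharing the two hubs, which are adjacent on both cycles.  This layout was
chosen by exhaustive search over all degree-valid topologies (all partitions
of the eight degree-1 nodes over the four hub-to-hub directed paths, and all
hub successor pairings) as the only family in which **every** triplet admits
both distractor types used by the learning task — a "close" distractor 2–4
steps and a "distal" distractor 5–8 steps from the cue, neither directly
connected to any on-screen item — while every triplet's successor is distinct
from its predecessor and the successor's follower lies exactly two steps
ahead.  Equal-length shared cycles (6+6) fail the distal-distractor rule at
hub cues; the layout is data, not an assumption, and any isomorph (seeded
relabelling) passes the same invariants.  Distances are directed
shortest-path lengths.

## Synthetic data generator

The generator emulates sensor-level MEG structure, not MEG physics:

* **Epochs.** 100 Hz sampling; localizer epochs −0.1…0.5 s around stimulus
  onset; retrieval/learning epochs 0…1.5 s after the second cue.
* **Spatial patterns.** Each stimulus has a fixed random unit-norm pattern
  over `n_sensors` (default 306).  A mixing parameter `overlap` sets the
  expected pairwise pattern correlation (default 0: orthogonal in
  expectation).
* **Noise.** Per-sensor Gaussian noise with AR(1) temporal autocorrelation,
  ρ = 0.5 per 10 ms sample, stationary SD 1.  Band-limited MEG resampled to
  100 Hz is strongly autocorrelated sample-to-sample; white noise would make
  neighbouring time steps unrealistically independent.
* **Evoked response.** The on-screen stimulus' pattern scaled by a Gaussian
  amplitude time course peaking at `evoked_latency` (default 0.21 s, the
  decodability peak the decoders are trained at) with SD `evoked_width`
  (default 0.05 s).  The peak amplitude (default 3.0, in noise-SD units) was
  calibrated once so that cross-validated peak decoding accuracy of a
  default participant falls in the empirically realistic 40–55% band
  (chance 10%), and then frozen.
* **Replay events.** Injected item patterns are convolved with a brief
  half-sine kernel (default 40 ms).  The evoked waveform of a replayed item
  is not observable in real data; kernel shape and duration are therefore
  configuration, not claims.  In `sequential` mode, each retrieval epoch
  receives `replay_events_per_trial` (default 3) replay sequences along the
  triplet-consistent forward path from the current item
  (`replay_path_length` = 4 items), successive items separated by
  `replay_lag_ms` (default 50 ms, a multiple of the 10 ms sample).  The
  replay peak amplitude (default 6.0) was likewise calibrated once: replay
  events must be decodable individually for lag-resolved analysis to be
  meaningful, and because the kernel is much briefer than the evoked
  response, a comparable decoded probability excursion requires a larger
  peak amplitude.  In `clustered` mode, every off-screen item's pattern is
  added simultaneously at `cluster_onset` (default 0.24 s), scaled by a
  distance gradient (default 1.0, 0.8, 0.6, 0.4, 0.2 for distances
  1, 2, 3, 4, ≥5, times the replay amplitude).  The two modes are mutually
  exclusive per cohort.
* **Behavior.** Per-participant retrieval accuracy is drawn from
  `accuracy_range` (default 0.6–1.0, matching a well-trained cohort); choices
  are correct with that probability, errors pick a distractor.  A coupling
  parameter draws the per-participant replay amplitude scale from a latent
  Gaussian correlated with accuracy at the requested value, so
  performance–replay correlations can be injected and recovered.
* **Reproducibility.** All randomness derives from one master seed through
  `numpy.random.SeedSequence` spawning; the same configuration is
  byte-identical across runs, and every injected event is returned in a
  ground-truth log.

What passing tests on this generator shows: the analysis chain recovers the
structure it claims to measure (lags, gradients, couplings, calibrated
nulls) from data with realistic dimensionality, autocorrelation and SNR.
What it does not show: robustness to artifacts, sensor cross-covariance,
pattern drift over a session, source leakage, or any other physics the
generator does not model.

## Decoding

One-vs-all L1-regularized logistic regression on sensor vectors, one binary
decoder per stimulus (scikit-learn liblinear; inverse regularization C = 6,
1000 iteration cap).  Probabilities are read per decoder and never
normalized across states, so all ten states can be simultaneously
improbable.  Cross-validated accuracy is computed per 10 ms step (training
and testing at the same step, folds leaving one trial per class out by
default); predicted class is the argmax of the one-vs-all probabilities with
ties broken toward the lowest state index.  Final decoders are trained at
one latency (default 0.21 s) with a null class — `null_ratio` × total trial
count of sensor vectors sampled from the pre-stimulus −0.1–0 s segment, one
random sample from each selected trial, shared by all ten decoders (a
positives-weighted reading of the same ratio is possible; the shared-pool
reading matches the practice of adding a common rest class).  The null class
lets all decoders report low probabilities in the absence of a matching
pattern.  Null examples never enter cross-validation test folds (they have
no true class) and are used only for final-decoder training.  Optimizer
tolerance is 1e−6 for final decoders and 1e−4 for the cross-validation and
temporal-generalization sweeps, where thousands of fits are made and
accuracy is insensitive to the difference.  Participants are excluded when
peak cross-validated localizer accuracy is below 30% or retrieval
performance below 50%.

## Sequential replay (TDLM)

For each trial's decoded probability matrix Y (time × state) and each lag
Δt in 10…250 ms, each state's series Y_i(t) is regressed on all ten lagged
series Y_j(t−Δt) plus an intercept.  The first Δt samples are dropped rather
than zero-padded, avoiding artifactual structure at the epoch edge.  The
coefficients form an empirical transition matrix Te(Δt); sequenceness is the
Frobenius inner product Z(Δt) = ⟨Te(Δt), T⟩ with the forward task matrix Tf
(Tf[j,i] = 1 iff j→i is an edge) or its transpose Tb.  Z is computed per
trial and averaged (equivalently, Te is trial-averaged first: the projection
is linear).  Rank-deficient designs fall back to the least-norm solution
with a warning; constant series yield zero coefficients.

Inference uses identity-based permutations of the transition matrix: rows
reordered by a uniformly drawn non-identity state permutation (default), or
rows and columns jointly (`mode="relabel"`), the option exposed because row
permutation can place mass on the diagonal where autocorrelation lives,
making thresholds conservative.  The same permutation list is shared across
participants and between Tf/Tb, keeping the group-level null exchangeable.
Lag-resolved thresholds take the maximum of the group-mean null curve over
lags per permutation (reported both as the maximum over permutations and as
their 95th percentile).  The lag-unspecific statistic is the group mean over
participants of the per-participant mean over lags, with a two-sided
permutation p-value under the add-one rule (p is never 0).  Pearson
correlation (t-distribution p, n−2 df) relates per-participant mean
sequenceness to retrieval accuracy.

## Clustered reactivation

Probability time courses are smoothed with a discrete Gaussian (σ = 1
sample, truncation radius 4σ, kernel normalized; edges renormalized over the
valid support — central weight ≈ 40%, ±1 step ≈ 25%, ±2 ≈ 5%).  For each
cued edge the *near* set is the context-valid successor and that successor's
own follower (two items, at directed distances 1 and 2 from the cue); the
*distant* set is every other item except the two on-screen ones, so at a hub
cue the context-invalid successor counts as distant.  The differential time
course is mean(near) − mean(distant) per trial, averaged over (by default
correct-only) trials and participants.  Its null is built by reassigning the
state identities of the probability columns within each trial (10,000
shuffles by default; 1000 as in a lighter variant remains available), giving
a per-time-point p as the add-one fraction of shuffles reaching the observed
differential.

The distance profile evaluates smoothed probabilities at the global peak
time — argmax over time of the mean probability across trials and all
states except each trial's predecessor, ties toward the earliest sample —
grouped into distance levels 1, 2, 3, 4, ≥5 (five levels; with n
participants the repeated-measures ANOVA then has df (4, 4(n−1)), e.g.
(4, 80) at n = 21).  Participants missing a level are dropped from the ANOVA
with a warning.  A paired t-test compares mean differential reactivation
over a window (default 0.22–0.26 s) between learning (pre-consolidation) and
retrieval trials.

## Statistics

The repeated-measures ANOVA uses the classical within-subject decomposition
(SS_effect over level means, SS_subject over participant means, residual
error; F on (k−1, (k−1)(n−1)) df); no sphericity correction is applied.
Pearson and paired-t use the textbook formulas with t/F tail probabilities
from scipy.  The cluster-based permutation test thresholds a 1-D or 2-D
statistic map at the pointwise (1 − cluster α) null quantile, scores
contiguous (1-D) or 4-connected (2-D) supra-threshold clusters by summed
statistic, and compares them with the null distribution of the maximum
cluster mass; this is one standard variant among several.

## Problem sizes and defaults used in validation

The packaged validation uses cohorts of 21 participants (the included-sample
size the pipeline defaults to) for lag-recovery and gradient-recovery
checks, 40 × 5-participant cohorts with 200 permutations for null
calibration, single 250-trial localizers for decoder calibration, and
30-participant cohorts over 20 seeds for coupling recovery.  The full
pipeline default (21 participants, 5-fold cross-validation per time step,
1000 permutations, 10,000 shuffles) completes on one CPU core in well under
15 minutes.

## Known limitations

* The generator's replay waveform, onset distribution and event count are
  stipulations; real replay statistics are unknown.
* Row-mode identity permutations are conservative in the presence of strong
  autocorrelation (see above); relabel mode is provided but not the default.
* A clustered-reactivation window cannot be distinguished from very fast
  (≤30 ms lag) sequential replay contained entirely within that window.
* Only single-step transitions are modelled; multi-step sequence evidence
  and nuisance regressors (e.g. alpha oscillations) are out of scope.
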