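# Methods

`facedyn` implements a complete analysis pipeline for facial Action Unit
(AU) intensity timeseries: low-rank spatiotemporal decomposition, emotion
classification from interpretable timeseries features, and kinematic
substate segmentation with mixed-model characterisation.  Because the
pipeline is developed and validated without access to video recordings, a
first-class synthetic generator produces AU trials with known planted
structure, and every stage is tested as a parameter-recovery problem
against that ground truth.

## Synthetic AU trials

A trial is a non-negative `n_frames x A` matrix of AU intensities (OpenFace
0–5 scale, default `n_frames = 240` at 30 fps, `A = 18` channels) built as

```
X = sum_c g_c * warp(b_c) (x) s_c + noise,  truncated at 0
```

where `s_c >= 0` are spatial loadings (each component dominated by a
disjoint AU block, e.g. upper-face vs lower-face actions, with small
cross-loadings), `b_c` are smooth unit-peak temporal bases (an inverted-U
Gaussian bump, a shifted bump, bimodal Gaussian mixtures for any further
components), and `g` is a non-negative gain vector specific to each
(emotion, condition) cell.  The default mixing makes angry load on the
first two components, happy on the second, and sad moderately on all —
well-separated directions so that classification has signal to find.
Subjects get log-normal multiplicative gain perturbations (sigma 0.15) for
between-subject variability; additive Gaussian noise defaults to
`noise_sd = 0.05` on the 0–5 intensity scale.

A substate schedule tiles each trial into relaxed / transition / sustain
segments with speed scales 0.2 / 2.5 / 1.0 (relaxed slowest, transitions
fastest).  The schedule is realised by piecewise time-rescaling of the
bases (internal time advances at the segment's speed scale, renormalised
over the trial), which modulates local derivative magnitude while keeping
the stacked data matrix exactly rank `k_true` in the noise-free limit —
additive "speed bursts" would break that recoverability.  Trials in the
emotive-speech condition get per-trial randomized schedules (8–12 segments,
adjacent labels distinct), modelling the less stereotyped sequencing of
facial movement during speech; expression-only trials use the fixed
canonical schedule.  This makes transition entropy higher under emotive
speech by construction.

Because the warped bases have smoothly varying slope, the *observable*
speed within a scheduled segment is not homogeneous (the bump's derivative
passes through zero at its peak).  Segmentation recovery is therefore
tested against `make_kinematic_trials`, which plants piecewise speed
regimes directly: transitions are steep monotone ramps (rising before the
trial midpoint, falling after), sustain is a moderate-speed plateau
oscillation, relaxed a near-still jitter.  These trajectories are the
recovery oracle for the substate clustering; the AU-level generator remains
the oracle for decomposition and classification.

What the generator does *not* emulate: head-pose and illumination artefacts
in AU estimation, asymmetric or unilateral actions, dependence between
tracking confidence and expression intensity, and any realistic per-emotion
AU effect sizes (no public norms exist at this granularity).  Passing
recovery tests therefore demonstrates the pipeline's correctness under its
own assumptions, not performance figures transferable to real recordings.

## Preprocessing

Trials with mean tracking confidence not strictly above 0.90 are dropped
("over 90%" read literally).  Frames flagged as tracking failures are
linearly interpolated to keep a regular grid.  Each channel is smoothed
with a centered 3-frame moving average; edge windows truncate to the frames
that exist rather than inventing padding.  Each trial is then reduced to
100 bins by averaging maximally equal contiguous frame groups (sizes differ
by at most one); trials shorter than 100 frames are first interpolated up.
Binned trials are stacked trial-by-trial into the `(n_trials*100) x A`
matrix `M` consumed by the decomposition.

## Decomposition and rank selection

`M ~ T S` is fitted by Lee–Seung multiplicative updates for the Frobenius
objective from seeded uniform(0,1] initialisation scaled by `sqrt(mean(M)/k)`,
stopping at relative objective change `1e-6` or 2000 iterations; the full
objective trace is kept and is non-increasing by construction.  Rows of `S`
(`k x A`) are AU co-activation profiles ("spatial"); `T` carries per-bin
component weights ("temporal").

Stability per candidate rank is measured over random restarts by AU-channel
co-assignment: each run assigns every channel to its dominant component,
the consensus matrix counts co-assignment frequencies, and we report (a)
the cophenetic correlation between consensus distances and their
average-linkage dendrogram and (b) the mean silhouette of the k-way
dendrogram cut.  Consensus is over the `A x A` channel space, not the
thousands of rows — tractable, and directly about which AU groups are
stable.  A block-shuffled null (blocks of 10 bins permuted independently
per trial and channel, preserving per-channel value multisets and local
ordering while destroying cross-channel temporal alignment) is fitted
alongside and reported for audit.

The rank is chosen by best mean rank across (cophenetic ↑, silhouette ↑,
plateau-quantized explained variance ↑), ties toward the smaller k.
Explained variance is quantized in steps of 0.005 so that every k on the
reconstruction plateau ties: this encodes the classical elbow — past the
true rank extra components add negligible explained variance — and lets the
stability indices and the smaller-k preference decide among plateau members.
An earlier variant ranked "evar excess over the shuffled null" instead; it
proved unreliable because the null's explained variance rises roughly in
parallel with the data's, so the excess *decreases* with k and, whenever
the stability indices tie, hair-thin ordinal differences favoured a rank
below the planted one.  The null comparison is retained as a report column
and for the pure-noise sanity check (no evar excess at any k), not as a
selection criterion.

Held-out data are projected onto a trained basis by per-row non-negative
least squares with `S` fixed — deterministic and row-wise optimal, so
projecting the training matrix can never increase its residual.

## Features, PCA and classification

Each trial's `100 x k` trajectory yields 38 named features per component
(catalog `fd38-v1`): location/spread (mean, sd, min, max, range, median,
IQR, 10th/90th percentile), shape (AUC, normalised argmax/argmin, OLS
slope, skewness, kurtosis, proportion above mean, longest monotonic run),
kinematics (mean absolute change, mean and max absolute second difference),
complexity (sample entropy m=2 r=0.2·sd, permutation entropy order 3, CID,
time-reversal asymmetry), autocorrelation (lag 1, lag 5, first zero
crossing), spectral (centroid, entropy, low-band power below 0.1
cycles/bin), energy (RMS, crest factor, first/second-half energy fractions,
Hjorth mobility and complexity), plus peak count (prominence 0.5·sd) and
zero crossings of the detrended series.  Features undefined for a given
series (e.g. sample entropy of a constant) are imputed with 0 so the table
stays dense.

The feature table is z-scored with training statistics (constant columns
zeroed out of the scaling), summarised by SVD-based PCA retaining as many
components as the NMF rank, with loading signs fixed so the
largest-magnitude entry is positive.  Test data are only ever transformed
with the training scaler and loadings — the train/test firewall is
structural, and a test asserts that mutating held-out data cannot change
the fitted PCA.

Classification uses a random forest tuned by stratified 5-fold CV on
balanced accuracy over a deliberately small 3x3x2 grid (50/100/200 trees;
depth unlimited/4/8; sqrt/all features per split).  The held-out report
carries the confusion matrix, accuracy, balanced accuracy (overall and
(sensitivity+specificity)/2 per class), Cohen's kappa, one-vs-rest AUC from
class-probability estimates, the no-information rate (largest test-class
share), an exact upper-tail binomial p against that rate, a
label-permutation p with the add-one estimator, and pairwise two-sided
Fisher exact tests on the 2x2 confusion sub-tables with Bonferroni
correction over the three pairs.  Stratified splitting rounds per-class
train counts half-up, so 76 trials per class at 80% yield exactly 61
training and 15 test trials per class.  Leave-one-group-out CV (one
stimulus or one participant per fold) is provided for rating-style
analyses, with the majority-class rate as the empirical chance baseline.

## Substates

Speed is the bin-wise first difference divided by the bin interval
(default 0.08 s: 240 frames at 30 fps over 100 bins); displacement is the
difference from the trial's first bin.  Overlapping windows (10 bins,
stride 5) over the `2k` channels — absolute speed and displacement per
component — are pooled across trials and clustered by k-medoids (PAM, 5
seeded k-medoids++ restarts keeping the lowest-cost solution) under
dynamic time warping with symmetric steps, Euclidean local cost across
channels, and no global window.  Windows are deliberately not z-normalised:
absolute speed is the signal that distinguishes substates, and
normalisation would erase it.  Each bin takes the vote-weighted majority
cluster over covering windows, with weights triangular in the distance to
the window centre (a window says most about its middle bins; flat voting
measurably blurs segment boundaries), ties toward the earliest covering
window.  Clusters are relabelled by ascending pooled mean absolute speed:
relaxed < sustain < transition.  The substate count is chosen by mean
silhouette under the DTW distance; an all-identical-window (motionless)
input is flagged with silhouette 0.

Transition entropy collapses a label sequence to its run sequence, counts
ordered changed pairs (s -> s', s != s'), and divides the Shannon entropy
of the pair distribution by `log2(S*(S-1))` with S = 3 regardless of the
states visited, so sparse sequences score low; a sequence without
transitions scores 0.  Self-pairs are excluded (state-*change* entropy),
and the measure is invariant to run lengths by construction.

## Mixed models

Per-trial per-substate speed (original scale) and per-trial entropy
(log-transformed as `log(H + 1e-3)`; entropy is right-skewed and can be
exactly 0) are modelled as

```
value ~ emotion * condition * substate + (1 + condition | subject)
```

fitted by REML via statsmodels MixedLM.  If the random-slope fit is
singular or fails to converge the structure falls back to a random
intercept, then to OLS, each step logged.  Type III Wald F tests use the
residual denominator df `n - p` — an asymptotic stand-in for Satterthwaite
df that is accurate for the balanced designs produced here; bit-level
agreement with any particular mixed-model solver is explicitly not a goal,
and correctness is established by simulation (planted contrasts recovered
within 2 SE in >= 90% of replicates; empirical type-I error near nominal on
null data).  Pairwise contrasts are estimated-marginal-mean differences
(fixed-effect predictions averaged over a balanced grid of the remaining
factors), Bonferroni-corrected within each family; interaction slices such
as `emotion@substate=transition` are supported.  Marginal and conditional
R² follow the Nakagawa variance-partition definitions, with the random
contribution of the condition slope averaged over the observed design rows.

## Problem sizes and numerical choices

Default validation sizes are chosen for a single-CPU desk run: rank
recovery uses 12-trial datasets (4 subjects x 3 emotions, expression-only)
over 20 generator seeds with 8 consensus restarts and 3 null copies per
candidate rank; the classification recovery uses 90 trials (15 subjects x
3 emotions x 2 repeats); segmentation recovery uses 9 planted-kinematics
trials; mixed-model recovery uses 50 replicates of 12 subjects.  Tolerances
of note: NMF stopping `tol = 1e-6` relative; objective monotonicity asserted
to `1e-9` relative slack; PCA orthonormality to `1e-8`; DTW and Fisher
tests agree with enumeration oracles to `1e-10`; CSV round-trips to `1e-6`.

## Known limitations

- The feature catalog realises the published feature families but is a
  package-defined set; swapping catalogs changes downstream PCA scores.
- DTW over pooled windows is `O(W^2 * window^2)`; the default pipeline caps
  the number of segmented trials (config `substates.max_trials`).
- Consensus stability is measured over AU channels, so it cannot detect
  instability that reshuffles temporal weights while leaving channel
  dominance intact.
- The mixed-model denominator df is a residual-df approximation; for small,
  unbalanced designs Satterthwaite-style df would be preferable.
- Substate segmentation accuracy is limited at segment boundaries by the
  window length; boundary bins are the dominant error source in the
  recovery simulations.
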