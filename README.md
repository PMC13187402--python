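# facedyn

Spatiotemporal analysis of facial Action Unit (AU) dynamics: how facial
expressions of emotion unfold over time, which low-dimensional movement
patterns carry the emotion signal, and what kinematic "substates" the face
passes through while producing an expression.

The package is aimed at researchers in affective science and computational
behavioural analysis who have per-frame AU intensity timeseries (e.g.
OpenFace output, one CSV per video) and want a tested, reproducible
pipeline from raw traces to statistics — or who want to validate such a
pipeline on synthetic data with known planted structure before touching
real recordings.

## What it computes

1. **Decomposition.** Trials are smoothed, reduced to 100 time bins, and
   stacked into a non-negative matrix `M` ((trials·bins) × AUs), factorised
   as `M ≈ T·S` by non-negative matrix factorisation with multiplicative
   updates.  Rows of `S` are AU co-activation profiles (spatial
   components); `T` carries their per-bin weights (temporal profiles).
   The rank `k` is selected over `k = 2..6` by consensus stability across
   random restarts (cophenetic coefficient and silhouette of AU
   co-assignment) together with the explained-variance plateau, with a
   block-shuffled null fitted alongside for audit.

2. **Classification.** Held-out trials are projected onto the trained
   basis by non-negative least squares; each trial's `100 × k` trajectory
   becomes 38 interpretable timeseries features per component (curvature,
   complexity, entropy, autocorrelation, spectral shape, ...), summarised
   by a train-only PCA, and classified with a cross-validated random
   forest.  The report includes balanced accuracy, Cohen's κ, one-vs-rest
   AUC, exact binomial and permutation p-values against the no-information
   rate, and Bonferroni-corrected pairwise Fisher exact tests on the
   confusion matrix.

3. **Substates.** Component kinematics — speed `v_t = (x_{t+1} − x_t)/Δt`
   and displacement `d_t = x_t − x_0` — are segmented by k-medoids
   clustering of overlapping windows under dynamic time warping, and the
   clusters are labelled relaxed / sustain / transition by ascending mean
   |speed|.  Each trial is summarised by per-substate mean speed and the
   normalised transition entropy `H / log2(S(S−1))` of its substate
   sequence, then characterised with the mixed model
   `value ~ emotion × condition × substate + (1 + condition | subject)`.

A synthetic generator (`facedyn.synthetic`) produces AU trials with planted
spatial loadings, smooth temporal bases, emotion-specific mixing and
substate schedules, so every stage is validated by parameter recovery.

## Worked example

```python
import numpy as np
from facedyn import synthetic as syn, io_preprocess as iop, decomposition as dec
from facedyn import features as feat, classifier as clf, substates as sub

gt = syn.make_ground_truth(k_true=3, n_aus=18, n_bins=100, seed=0)
trials = syn.make_dataset(gt, n_subjects=8, trials_per_cell=2, seed=0,
                          conditions=("expression_only",))
M = iop.stack_trials(iop.preprocess_trials(trials), 100)

report = dec.select_k(M, range(2, 7), n_runs=8, n_null=3, seed=0)
print("selected rank:", report.chosen_k)

y = M.meta["emotion"].to_numpy()
tr, te = clf.split_train_test(y, 0.8, seed=0)
M_tr, M_te = (M.subset([M.trial_ids[i] for i in idx]) for idx in (tr, te))
model = dec.nmf_fit(M_tr, report.chosen_k, seed=0)
traj_tr, _ = dec.trajectories(dec.project(model, M_tr), M_tr)
traj_te, _ = dec.trajectories(dec.project(model, M_te), M_te)
pca = feat.fit_feature_pca(feat.build_feature_table(traj_tr), model.k)
s_tr = feat.apply_feature_pca(pca, feat.build_feature_table(traj_tr))
s_te = feat.apply_feature_pca(pca, feat.build_feature_table(traj_te))
rep = clf.evaluate(clf.train_classifier(s_tr, y[tr], seed=0), s_te, y[te],
                   n_perm=1000, seed=0)
print(f"held-out accuracy {rep.accuracy:.2f}, kappa {rep.kappa:.2f}, "
      f"NIR {rep.no_information_rate:.2f}, binomial p {rep.p_binomial:.2e}")

kins = [sub.compute_kinematics(traj_tr[t], dt=0.08) for t in list(traj_tr)[:12]]
seqs = sub.segment_substates(kins, c=3, seed=0)
print(sub.substate_speed_summary(seqs[0], kins[0]))
```

Output:

```
selected rank: 3
held-out accuracy 1.00, kappa 1.00, NIR 0.33, binomial p 5.08e-05
{'relaxed': 0.375, 'sustain': 0.791, 'transition': 1.587}
```

The selected rank matches the three planted components.  Held-out
classification is perfect on this strongly mixed synthetic set — far above
the 33% no-information rate, with the binomial test confirming it could
not plausibly arise from guessing.  The substate summary shows the
labelling rule at work: transition bins move about four times faster than
relaxed bins (weights per second), with sustain in between.

The same pipeline is available from the shell:

```
facedyn simulate --seed 1 --out run1
facedyn preprocess --out run1
facedyn decompose --k-range 2:6 --out run1
facedyn run --seed 1 --out run2          # everything end to end
```

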