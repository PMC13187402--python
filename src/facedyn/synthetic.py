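"""Synthetic facial action-unit (AU) trial generator.

Produces non-negative AU intensity timeseries with planted low-rank
spatiotemporal structure: a small number of spatial components (AU
co-activation profiles), smooth unit-peak temporal bases, emotion- and
condition-specific component gains, and a substate schedule
(relaxed / transition / sustain) realised by piecewise time-rescaling of
the bases so that local speed follows the scheduled regime.  The planted
structure is returned as ground truth so that decomposition, classification
and segmentation can be tested as parameter-recovery problems.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace

import numpy as np

from .io_preprocess import AUTrial

__all__ = [
    "EMOTIONS",
    "CONDITIONS",
    "DEFAULT_AU_NUMBERS",
    "SubstateSegment",
    "GroundTruth",
    "SUBSTATE_SPEED",
    "make_ground_truth",
    "random_schedule",
    "simulate_trial",
    "make_dataset",
    "make_kinematic_trials",
    "bin_substate_labels",
    "write_openface_csv",
    "write_manifest",
]

EMOTIONS = ("angry", "happy", "sad")
CONDITIONS = ("expression_only", "emotive_speech")

# OpenFace intensity AUs plus AU28, giving the 18-channel default layout.
DEFAULT_AU_NUMBERS = (1, 2, 4, 5, 6, 7, 9, 10, 12, 14, 15, 17, 20, 23, 25, 26, 28, 45)


@dataclass(frozen=True)
class SubstateSegment:
    """One contiguous piece of the substate schedule, ``[start, end)`` in bins."""

    label: str           # relaxed | transition | sustain
    start: int
    end: int
    speed_scale: float   # multiplicative local speed of the warped bases


@dataclass
class GroundTruth:
    """Planted generative structure for a synthetic AU dataset.

    ``S_true`` holds non-negative spatial loadings (components x AUs),
    ``temporal_bases`` holds unit-peak curves (components x bins), and
    ``mixing`` maps ``(emotion, condition)`` to a non-negative gain vector
    over components.  ``substate_schedule`` tiles ``[0, n_bins)``.
    """

    S_true: np.ndarray
    temporal_bases: np.ndarray
    mixing: dict[tuple[str, str], np.ndarray]
    substate_schedule: list[SubstateSegment]
    noise_sd: float
    seed: int
    au_numbers: tuple[int, ...] = DEFAULT_AU_NUMBERS
    subject_gain_sigma: float = 0.15
    confidence_mean: float = 0.97
    schedule_jitter: int = 0
    _rest: dict = field(default_factory=dict)

    @property
    def k_true(self) -> int:
        return self.S_true.shape[0]

    @property
    def n_aus(self) -> int:
        return self.S_true.shape[1]

    @property
    def n_bins(self) -> int:
        return self.temporal_bases.shape[1]

    def validate(self) -> None:
        if np.any(self.S_true < 0):
            raise ValueError("spatial loadings must be non-negative")
        for key, g in self.mixing.items():
            if np.any(np.asarray(g) < 0):
                raise ValueError(f"mixing gains for {key} must be non-negative")
        segs = sorted(self.substate_schedule, key=lambda s: s.start)
        cursor = 0
        for seg in segs:
            if seg.start != cursor:
                raise ValueError("substate segments must tile [0, n_bins) without gaps")
            cursor = seg.end
        if cursor != self.n_bins:
            raise ValueError("substate segments must end at n_bins")
        by_label: dict[str, list[float]] = {}
        for seg in segs:
            by_label.setdefault(seg.label, []).append(seg.speed_scale)
        if "transition" in by_label and "relaxed" in by_label:
            if not (min(by_label["transition"]) > max(v for lab, vs in by_label.items()
                                                      if lab != "transition" for v in vs)):
                raise ValueError("transition segments must have the largest speed scale")


def _gaussian_bump(n_bins: int, center: float, width: float) -> np.ndarray:
    t = np.arange(n_bins, dtype=float)
    curve = np.exp(-0.5 * ((t - center * n_bins) / (width * n_bins)) ** 2)
    return curve / curve.max()


# speed scales of the three kinematic regimes: relaxed periods are nearly
# still, transitions (onset/offset ramps) are the fastest movements
SUBSTATE_SPEED = {"relaxed": 0.2, "sustain": 1.0, "transition": 2.5}


def _default_schedule(n_bins: int) -> list[SubstateSegment]:
    # relaxed onset -> fast transition -> sustained plateau -> fast offset -> relaxed
    edges = [0, int(0.18 * n_bins), int(0.38 * n_bins),
             int(0.68 * n_bins), int(0.85 * n_bins), n_bins]
    labels = ["relaxed", "transition", "sustain", "transition", "relaxed"]
    return [SubstateSegment(lab, a, b, SUBSTATE_SPEED[lab])
            for lab, a, b in zip(labels, edges[:-1], edges[1:])]


def random_schedule(n_bins: int, seed: int, n_segments: int | None = None
                    ) -> list[SubstateSegment]:
    """A randomized substate schedule (adjacent segments always differ).

    Models the less stereotyped sequencing of facial movement when speech
    production keeps reshaping the face: more segments, in a random order,
    with the same per-label speed scales as the canonical schedule.
    """
    rng = np.random.default_rng(seed)
    if n_segments is None:
        n_segments = int(rng.integers(8, 13))
    labels = ["relaxed"]
    states = list(SUBSTATE_SPEED)
    for _ in range(n_segments - 1):
        labels.append(str(rng.choice([s for s in states if s != labels[-1]])))
    cuts = np.sort(rng.choice(np.arange(1, n_bins), size=n_segments - 1,
                              replace=False))
    edges = [0, *cuts.tolist(), n_bins]
    return [SubstateSegment(lab, a, b, SUBSTATE_SPEED[lab])
            for lab, a, b in zip(labels, edges[:-1], edges[1:])]


def _default_mixing(k_true: int, rng: np.random.Generator) -> dict[tuple[str, str], np.ndarray]:
    """Emotion-specific gain vectors with well-separated directions.

    Angry co-activates the first two components, happy is dominated by the
    second, sad spreads moderate weight over all; emotive speech damps the
    separation slightly, mimicking speech-related facial activity.
    """
    base = {
        "angry": np.array([1.3, 1.1] + [0.25] * (k_true - 2) if k_true >= 2 else [1.3][:k_true]),
        "happy": np.array([0.25, 1.5] + [0.45] * (k_true - 2) if k_true >= 2 else [1.5][:k_true]),
        "sad": np.array([0.65, 0.45] + [1.0] * (k_true - 2) if k_true >= 2 else [0.65][:k_true]),
    }
    mixing = {}
    for emo in EMOTIONS:
        g = np.asarray(base[emo], dtype=float)[:k_true]
        if g.size < k_true:  # k_true == 1 edge
            g = np.resize(g, k_true)
        mixing[(emo, "expression_only")] = g.copy()
        mixing[(emo, "emotive_speech")] = 0.55 * g + 0.45 * g.mean()
    return mixing


def make_ground_truth(
    k_true: int,
    n_aus: int = 18,
    n_bins: int = 100,
    seed: int = 0,
    noise_sd: float = 0.05,
    subject_gain_sigma: float = 0.15,
    schedule_jitter: int = 0,
) -> GroundTruth:
    """Build a planted GroundTruth with block-structured loadings.

    Each component is dominated by a disjoint subset of AUs (upper-face vs
    lower-face style blocks) with small cross-loadings.  The first temporal
    basis is an inverted-U bump, the second a shifted bump, and any further
    bases are bimodal Gaussian mixtures.
    """
    if k_true < 1:
        raise ValueError("k_true must be >= 1")
    if n_aus < k_true:
        raise ValueError("need n_aus >= k_true to plant disjoint AU blocks")
    rng = np.random.default_rng(seed)

    blocks = np.array_split(np.arange(n_aus), k_true)
    S = rng.uniform(0.0, 0.04, size=(k_true, n_aus))  # small cross-loadings
    for c, block in enumerate(blocks):
        S[c, block] = rng.uniform(0.8, 1.6, size=block.size)

    bases = np.empty((k_true, n_bins))
    for c in range(k_true):
        if c == 0:
            bases[c] = _gaussian_bump(n_bins, 0.5, 0.16)
        elif c == 1:
            bases[c] = _gaussian_bump(n_bins, 0.62, 0.14)
        else:
            sep = 0.18 + 0.04 * (c - 2)
            two = (_gaussian_bump(n_bins, 0.5 - sep, 0.08)
                   + _gaussian_bump(n_bins, 0.5 + sep, 0.08))
            bases[c] = two / two.max()

    au_numbers = tuple(DEFAULT_AU_NUMBERS[:n_aus]) if n_aus <= len(DEFAULT_AU_NUMBERS) \
        else tuple(DEFAULT_AU_NUMBERS) + tuple(range(50, 50 + n_aus - len(DEFAULT_AU_NUMBERS)))

    gt = GroundTruth(
        S_true=S,
        temporal_bases=bases,
        mixing=_default_mixing(k_true, rng),
        substate_schedule=_default_schedule(n_bins),
        noise_sd=noise_sd,
        seed=seed,
        au_numbers=au_numbers,
        subject_gain_sigma=subject_gain_sigma,
        schedule_jitter=schedule_jitter,
    )
    gt.validate()
    return gt


def _warped_time(schedule: list[SubstateSegment], n_bins: int) -> np.ndarray:
    """Map bin index -> internal base time so local speed follows the schedule.

    Internal time advances at each segment's speed scale; the cumulative
    profile is renormalised to span [0, n_bins - 1], so the bases keep their
    overall shape but are locally compressed (fast segments) or stretched
    (slow segments).
    """
    speed = np.empty(n_bins)
    for seg in schedule:
        speed[seg.start:seg.end] = seg.speed_scale
    u = np.concatenate([[0.0], np.cumsum(speed[:-1])])
    return u / u[-1] * (n_bins - 1)


def bin_substate_labels(schedule: list[SubstateSegment], n_bins: int) -> np.ndarray:
    """Per-bin ground-truth substate label array (dtype object of str)."""
    labels = np.empty(n_bins, dtype=object)
    for seg in schedule:
        labels[seg.start:seg.end] = seg.label
    return labels


def simulate_trial(
    gt: GroundTruth,
    emotion: str,
    condition: str,
    subject_id: str = "s01",
    n_frames: int = 240,
    seed: int = 0,
    trial_id: str | None = None,
    session: int = 1,
    gain_multiplier: np.ndarray | None = None,
    schedule: list[SubstateSegment] | None = None,
) -> AUTrial:
    """Simulate one trial: mixed, time-warped components plus noise.

    The bin-level latent trajectory is sampled onto ``n_frames`` frames by
    linear interpolation, multiplied into the spatial loadings, and truncated
    at zero after additive Gaussian noise.
    """
    key = (emotion, condition)
    if key not in gt.mixing:
        raise KeyError(f"no mixing gains for emotion/condition {key!r}")
    rng = np.random.default_rng(seed)

    schedule = schedule if schedule is not None else gt.substate_schedule
    n_bins = gt.n_bins
    u = _warped_time(schedule, n_bins)
    warped = np.vstack([np.interp(u, np.arange(n_bins), gt.temporal_bases[c])
                        for c in range(gt.k_true)])          # k x n_bins

    gains = np.asarray(gt.mixing[key], dtype=float).copy()
    if gain_multiplier is not None:
        gains = gains * np.asarray(gain_multiplier, dtype=float)

    frame_t = np.linspace(0.0, n_bins - 1, n_frames)
    bases_frames = np.vstack([np.interp(frame_t, np.arange(n_bins), warped[c])
                              for c in range(gt.k_true)])    # k x n_frames
    series = (gains[:, None] * bases_frames).T @ gt.S_true   # n_frames x A
    if gt.noise_sd > 0:
        series = series + rng.normal(0.0, gt.noise_sd, size=series.shape)
    series = np.clip(series, 0.0, None)

    confidence = np.clip(
        gt.confidence_mean + rng.normal(0.0, 0.01, size=n_frames), 0.0, 1.0)
    return AUTrial(
        trial_id=trial_id or f"{subject_id}_{emotion}_{condition}_{seed}",
        subject_id=str(subject_id),
        emotion=emotion,
        condition=condition,
        session=session,
        series=series,
        frame_rate=30.0,
        confidence=confidence,
        au_numbers=gt.au_numbers,
    )


def _jittered_schedule(gt: GroundTruth, rng: np.random.Generator) -> list[SubstateSegment]:
    """Randomly perturb interior segment boundaries by up to schedule_jitter bins."""
    if gt.schedule_jitter <= 0:
        return gt.substate_schedule
    segs = sorted(gt.substate_schedule, key=lambda s: s.start)
    edges = [s.start for s in segs] + [gt.n_bins]
    for i in range(1, len(edges) - 1):
        lo = edges[i - 1] + 1
        hi = edges[i + 1] - 1 if i + 1 < len(edges) else gt.n_bins - 1
        prop = edges[i] + int(rng.integers(-gt.schedule_jitter, gt.schedule_jitter + 1))
        edges[i] = int(np.clip(prop, lo, min(hi, gt.n_bins - 1)))
    return [replace(s, start=a, end=b) for s, a, b in zip(segs, edges[:-1], edges[1:])]


def make_dataset(
    gt: GroundTruth,
    n_subjects: int = 8,
    trials_per_cell: int = 1,
    seed: int = 0,
    n_frames: int = 240,
    emotions: tuple[str, ...] | None = None,
    conditions: tuple[str, ...] | None = None,
    jitter_schedule: bool = False,
    randomize_schedule_conditions: tuple[str, ...] = ("emotive_speech",),
) -> list[AUTrial]:
    """Balanced factorial dataset over emotion x condition x subject.

    Each subject gets a log-normal multiplicative gain perturbation per
    component (sigma ``gt.subject_gain_sigma``), modelling idiosyncratic
    expressiveness.  Deterministic given ``seed``.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if trials_per_cell < 1:
        raise ValueError("trials_per_cell must be >= 1")
    emotions = emotions or tuple(sorted({e for e, _ in gt.mixing}))
    conditions = conditions or tuple(sorted({c for _, c in gt.mixing}))
    rng = np.random.default_rng(seed)

    subj_gain = {
        f"s{i + 1:02d}": np.exp(rng.normal(0.0, gt.subject_gain_sigma, size=gt.k_true))
        for i in range(n_subjects)
    }
    trials = []
    for si, (sid, gmult) in enumerate(subj_gain.items()):
        for emo in emotions:
            for cond in conditions:
                for rep in range(trials_per_cell):
                    tseed = int(rng.integers(0, 2**31 - 1))
                    if cond in randomize_schedule_conditions:
                        sched = random_schedule(gt.n_bins,
                                                seed=int(rng.integers(0, 2**31 - 1)))
                    elif jitter_schedule or gt.schedule_jitter > 0:
                        sched = _jittered_schedule(gt, rng)
                    else:
                        sched = None
                    trials.append(simulate_trial(
                        gt, emo, cond, subject_id=sid, n_frames=n_frames,
                        seed=tseed, session=(rep % 2) + 1,
                        trial_id=f"{sid}_{emo}_{cond}_r{rep}",
                        gain_multiplier=gmult, schedule=sched))
    return trials


def make_kinematic_trials(
    n_trials: int,
    n_bins: int = 100,
    k: int = 3,
    schedule: list[SubstateSegment] | None = None,
    dt: float = 0.08,
    noise: float = 0.05,
    seed: int = 0,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Component trajectories with directly planted kinematic regimes.

    Unlike ``simulate_trial`` (whose speed profile inherits the slope
    variation of the smooth bases), these trajectories have piecewise
    speed-magnitude regimes exactly following the schedule: transitions are
    steep monotone ramps (rising before the trial midpoint, falling after),
    sustain is a moderate-speed plateau oscillation, relaxed a near-still
    jitter.  Returns (trajectories, per-trial bin labels on the speed grid);
    this is the recovery oracle for substate segmentation.
    """
    rng = np.random.default_rng(seed)
    schedule = schedule or _default_schedule(n_bins)
    T = n_bins - 1
    trajs, labels = [], []
    for _ in range(n_trials):
        v = np.zeros((T, k))
        lab = np.empty(T, dtype=object)
        for seg in schedule:
            for t in range(seg.start, min(seg.end, T)):
                lab[t] = seg.label
                mag = seg.speed_scale * (1 + noise * rng.standard_normal(k))
                if seg.label == "transition":
                    sign = 1.0 if t < n_bins / 2 else -1.0
                else:
                    sign = (-1.0) ** t
                v[t] = sign * mag
        traj = np.vstack([np.zeros((1, k)), np.cumsum(v * dt, axis=0)])
        trajs.append(traj)
        labels.append(lab)
    return trajs, labels


def write_openface_csv(trial: AUTrial, path) -> None:
    """Write a trial in the OpenFace CSV dialect.

    Columns: frame, timestamp, confidence, success, then one ``AU<nn>_r``
    column per channel.  Round-trips through ``read_openface_csv`` within 1e-6.
    """
    n = trial.series.shape[0]
    if n < 1:
        raise ValueError("cannot write an empty trial")
    header = ["frame", "timestamp", "confidence", "success"] + [
        f"AU{num:02d}_r" for num in trial.au_numbers]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(header)
        for i in range(n):
            row = [i + 1, f"{i / trial.frame_rate:.6f}",
                   f"{trial.confidence[i]:.6f}", 1]
            row += [f"{v:.6f}" for v in trial.series[i]]
            w.writerow(row)


def write_manifest(trials: list[AUTrial], paths: list, manifest_path) -> None:
    """Tab-separated dataset manifest: trial_id, subject, emotion, condition, session, path."""
    with open(manifest_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["trial_id", "subject_id", "emotion", "condition", "session", "path"])
        for tr, p in zip(trials, paths):
            w.writerow([tr.trial_id, tr.subject_id, tr.emotion, tr.condition,
                        tr.session, str(p)])
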