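"""Kinematic substates of component trajectories.

A trial's component trajectory is turned into kinematics — speed (bin-wise
first difference over the bin interval) and displacement (difference from
the starting value) — and segmented into substates by clustering short
overlapping windows of the multivariate kinematic series under dynamic
time warping (DTW) with k-medoids (PAM).  Windows are deliberately *not*
z-normalised before DTW: absolute speed is the signal the substates differ
by.  Clusters are relabelled by ascending mean absolute speed into
relaxed < sustain < transition, and each trial is summarised by per-substate
mean speed and the normalised transition entropy of its substate sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import silhouette_score

__all__ = [
    "SUBSTATE_LABELS",
    "KinematicSeries",
    "SubstateSequence",
    "compute_kinematics",
    "dtw_distance",
    "segment_substates",
    "select_c",
    "substate_speed_summary",
    "transition_entropy",
]

SUBSTATE_LABELS = ("relaxed", "sustain", "transition")


@dataclass
class KinematicSeries:
    """Speed ((n_bins-1) x k, weight change per bin interval) and
    displacement (n_bins x k, weight relative to bin 0) of one trial."""

    speed: np.ndarray
    displacement: np.ndarray
    dt: float

    @property
    def abs_speed(self) -> np.ndarray:
        return np.abs(self.speed)


@dataclass
class SubstateSequence:
    """Per-bin substate labels of one trial plus the cluster -> label map."""

    labels: np.ndarray            # length n_bins-1 (speed grid), str
    cluster_of_bin: np.ndarray    # raw cluster index per bin
    label_map: dict               # cluster index -> substate name
    cluster_mean_speed: dict      # cluster index -> pooled mean |speed|


def compute_kinematics(traj: np.ndarray, dt: float = 1.0) -> KinematicSeries:
    """First-difference speed and baseline-relative displacement."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    x = np.asarray(traj, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.shape[0] < 2:
        raise ValueError("need at least 2 bins for kinematics")
    speed = np.diff(x, axis=0) / dt
    displacement = x - x[0]
    return KinematicSeries(speed=speed, displacement=displacement, dt=dt)


def dtw_distance(x: np.ndarray, y: np.ndarray) -> float:
    """Classic DTW cost with symmetric (match/insert/delete) steps.

    Local cost is the Euclidean distance across channels; no global window.
    Symmetric in its arguments.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if y.ndim == 1:
        y = y[:, None]
    if x.size == 0 or y.size == 0:
        raise ValueError("DTW of an empty series is undefined")
    if x.shape[1] != y.shape[1]:
        raise ValueError("series must share the channel count")
    n, m = x.shape[0], y.shape[0]
    local = np.sqrt(((x[:, None, :] - y[None, :, :]) ** 2).sum(axis=2))
    D = np.full((n + 1, m + 1), np.inf)
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        row = D[i]
        prev = D[i - 1]
        lc = local[i - 1]
        for j in range(1, m + 1):
            row[j] = lc[j - 1] + min(prev[j], row[j - 1], prev[j - 1])
    return float(D[n, m])


def _windows_of_trial(kin: KinematicSeries, window: int, stride: int
                      ) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Overlapping windows over the 2k kinematic channels (|speed|, displacement).

    Both channels are laid on the speed grid (length n_bins - 1, displacement
    taken from bin 1 onward so the grids align).
    """
    feats = np.hstack([kin.abs_speed, kin.displacement[1:]])
    T = feats.shape[0]
    starts = list(range(0, max(T - window, 0) + 1, stride))
    if starts and starts[-1] + window < T:
        starts.append(T - window)
    wins = [feats[s:s + window] for s in starts]
    covers = [np.arange(s, s + window) for s in starts]
    return wins, covers


def _dtw_matrix(windows: list[np.ndarray]) -> np.ndarray:
    n = len(windows)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = dtw_distance(windows[i], windows[j])
    return D


def _pam(D: np.ndarray, c: int, seed: int = 0, max_iter: int = 100,
         n_init: int = 5) -> np.ndarray:
    """k-medoids (PAM-style alternating) on a precomputed distance matrix.

    Runs ``n_init`` seeded k-medoids++ initialisations and keeps the
    assignment with the lowest total within-cluster cost; ties in medoid
    updates break toward the lowest index.
    """
    best_assign, best_cost = None, np.inf
    rng_master = np.random.default_rng(seed)
    for _ in range(n_init):
        assign = _pam_once(D, c, int(rng_master.integers(0, 2**31 - 1)),
                           max_iter)
        cost = 0.0
        for ci in range(c):
            members = np.flatnonzero(assign == ci)
            if members.size:
                sub_d = D[np.ix_(members, members)]
                cost += float(sub_d.sum(axis=0).min())
        if cost < best_cost - 1e-12:
            best_cost, best_assign = cost, assign
    return best_assign


def _pam_once(D: np.ndarray, c: int, seed: int, max_iter: int
              ) -> np.ndarray:
    n = D.shape[0]
    rng = np.random.default_rng(seed)
    medoids = [int(rng.integers(n))]
    while len(medoids) < c:
        dmin = D[:, medoids].min(axis=1)
        probs = dmin ** 2
        if probs.sum() <= 0:
            remaining = [i for i in range(n) if i not in medoids]
            medoids.append(int(remaining[0]))
            continue
        medoids.append(int(rng.choice(n, p=probs / probs.sum())))
    medoids = np.array(sorted(set(medoids))[:c])
    while len(medoids) < c:  # degenerate duplicates
        extra = [i for i in range(n) if i not in medoids]
        medoids = np.append(medoids, extra[0])

    for _ in range(max_iter):
        assign = np.argmin(D[:, medoids], axis=1)
        new_medoids = medoids.copy()
        for ci in range(c):
            members = np.flatnonzero(assign == ci)
            if members.size == 0:
                continue
            costs = D[np.ix_(members, members)].sum(axis=0)
            new_medoids[ci] = members[int(np.argmin(costs))]
        if np.array_equal(np.sort(new_medoids), np.sort(medoids)):
            break
        medoids = new_medoids
    return np.argmin(D[:, medoids], axis=1)


def _ordered_labels(c: int) -> list[str]:
    if c == 2:
        return ["relaxed", "transition"]
    if c == 3:
        return ["relaxed", "sustain", "transition"]
    mid = [f"sustain_{i + 1}" if c > 4 else "sustain" for i in range(c - 2)]
    if c == 4:
        mid = ["sustain", "sustain_2"]
    return ["relaxed", *mid, "transition"]


def segment_substates(kins: list[KinematicSeries], c: int = 3,
                      window: int = 10, stride: int = 5, seed: int = 0
                      ) -> list[SubstateSequence]:
    """Segment trials into kinematic substates via windowed DTW clustering.

    Windows of ``window`` bins (stride ``stride``) over the |speed| and
    displacement channels of every trial are pooled and clustered with PAM
    under DTW distance; each bin takes the majority cluster over the windows
    covering it (ties toward the earlier window's cluster).  Clusters are
    relabelled by ascending pooled mean |speed|.
    """
    if c < 2:
        raise ValueError("need at least 2 substates")
    all_windows, owners, covers = [], [], []
    for t, kin in enumerate(kins):
        if window > kin.speed.shape[0]:
            raise ValueError("window exceeds the trial's kinematic length")
        wins, cov = _windows_of_trial(kin, window, stride)
        all_windows.extend(wins)
        covers.extend(cov)
        owners.extend([t] * len(wins))
    if len(all_windows) < c:
        raise ValueError("fewer windows than clusters")

    D = _dtw_matrix(all_windows)
    assign = _pam(D, c, seed=seed)

    # per-bin vote over covering windows, weighted by proximity to the
    # window centre (a window is most informative about its central bins);
    # ties resolved toward the earliest covering window's cluster
    seqs_raw = []
    centre = (window - 1) / 2.0
    w_weight = window / 2.0 - np.abs(np.arange(window) - centre) + 0.5
    for t, kin in enumerate(kins):
        T = kin.speed.shape[0]
        votes = np.zeros((T, c))
        first_cluster = np.full(T, -1, dtype=int)
        for w, (own, cov) in enumerate(zip(owners, covers)):
            if own != t:
                continue
            votes[cov, assign[w]] += w_weight[: len(cov)]
            for b in cov:
                if first_cluster[b] < 0:
                    first_cluster[b] = assign[w]
        best = np.argmax(votes, axis=1)
        top = votes[np.arange(T), best]
        tie = np.isclose(votes, top[:, None]).sum(axis=1) > 1
        best[tie] = first_cluster[tie]
        seqs_raw.append(best)

    # relabel clusters by pooled mean |speed| within their bins
    pooled = {ci: [] for ci in range(c)}
    for t, raw in enumerate(seqs_raw):
        sp = np.abs(kins[t].speed).mean(axis=1)
        for ci in range(c):
            pooled[ci].extend(sp[raw == ci])
    mean_speed = {ci: (float(np.mean(v)) if v else np.inf)
                  for ci, v in pooled.items()}
    order = sorted(range(c), key=lambda ci: (mean_speed[ci], ci))
    names = _ordered_labels(c)
    label_map = {ci: names[rank] for rank, ci in enumerate(order)}

    out = []
    for raw in seqs_raw:
        labels = np.array([label_map[ci] for ci in raw], dtype=object)
        out.append(SubstateSequence(labels=labels, cluster_of_bin=raw,
                                    label_map=label_map,
                                    cluster_mean_speed=mean_speed))
    return out


def select_c(kins: list[KinematicSeries], c_range=range(2, 5),
             window: int = 10, stride: int = 5, seed: int = 0) -> dict:
    """Silhouette-based choice of the substate count.

    For each candidate c, PAM cluster the pooled windows and score the mean
    silhouette under DTW distance; c* is the argmax.
    """
    all_windows = []
    for kin in kins:
        wins, _ = _windows_of_trial(kin, window, stride)
        all_windows.extend(wins)
    D = _dtw_matrix(all_windows)
    table = []
    for c in c_range:
        if c >= len(all_windows):
            continue
        assign = _pam(D, c, seed=seed)
        if len(np.unique(assign)) < 2 or D.max() == 0:
            sil = 0.0 if D.max() == 0 else -1.0  # degenerate: no structure
        else:
            sil = float(silhouette_score(D, assign, metric="precomputed"))
        table.append({"c": c, "silhouette": sil})
    tab = pd.DataFrame(table)
    best = int(tab.loc[tab["silhouette"].idxmax(), "c"])
    return {"c_star": best, "table": tab}


def substate_speed_summary(seq: SubstateSequence, kin: KinematicSeries
                           ) -> dict[str, float]:
    """Mean |speed| (averaged over components) within each substate's bins.

    Substates the trial never visits get NaN.
    """
    sp = np.abs(kin.speed).mean(axis=1)
    out = {}
    for name in SUBSTATE_LABELS:
        mask = seq.labels == name
        out[name] = float(sp[mask].mean()) if mask.any() else float("nan")
    return out


def transition_entropy(labels, n_states: int = 3) -> float:
    """Normalised state-change entropy of a substate sequence.

    Consecutive runs are collapsed, ordered changed pairs (s -> s', s != s')
    are counted, and the Shannon entropy of the pair distribution is divided
    by log2(S * (S - 1)) with S = ``n_states`` regardless of the states
    actually visited.  A sequence with no transitions scores 0.
    """
    labs = list(labels)
    if not labs:
        raise ValueError("empty sequence")
    known = set(SUBSTATE_LABELS) | {f"sustain_{i}" for i in range(2, 9)}
    for lab in labs:
        if lab not in known:
            raise ValueError(f"unknown substate label {lab!r}")
    collapsed = [labs[0]]
    for lab in labs[1:]:
        if lab != collapsed[-1]:
            collapsed.append(lab)
    pairs = list(zip(collapsed[:-1], collapsed[1:]))
    if not pairs:
        return 0.0
    _, counts = np.unique([f"{a}->{b}" for a, b in pairs], return_counts=True)
    p = counts / counts.sum()
    h = float(-np.sum(p * np.log2(p)))
    h_max = np.log2(n_states * (n_states - 1))
    return h / h_max
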