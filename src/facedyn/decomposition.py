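"""Non-negative matrix factorization of stacked AU timeseries.

The stacked matrix M ((trials * bins) x AUs) is factorized as M ~ T @ S with
T the temporal weights (one row per time bin of each trial) and S the
spatial weights (one row per component, one column per AU channel).
Fitting uses the classic Lee-Seung multiplicative update rule for the
Frobenius objective, which preserves non-negativity and never increases the
objective.  Rank selection combines reconstruction quality (RSS / explained
variance) with the stability of AU co-assignment across random restarts
(consensus silhouette and cophenetic coefficient), benchmarked against a
block-shuffled null that destroys cross-channel temporal structure while
retaining local ordering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, cophenet, fcluster
from scipy.optimize import nnls
from scipy.spatial.distance import squareform
from sklearn.metrics import silhouette_score

from .io_preprocess import StackedMatrix

__all__ = [
    "NMFModel",
    "KSelectionReport",
    "nmf_fit",
    "reconstruct",
    "explained_variance",
    "consensus_metrics",
    "block_shuffle",
    "select_k",
    "project",
    "trajectories",
]

_EPS = 1e-12


@dataclass
class NMFModel:
    """A fitted rank-k factorization M ~ T @ S (all entries >= 0)."""

    k: int
    S: np.ndarray                 # k x A spatial weights
    T: np.ndarray                 # rows x k temporal weights
    objective_trace: np.ndarray   # per-iteration Frobenius loss ||M - TS||_F^2
    seed: int
    n_iter: int


@dataclass
class KSelectionReport:
    """Fit indices per candidate rank, on the data and on shuffled nulls."""

    table: pd.DataFrame           # columns: k, rss, evar, silhouette, cophenetic
    null_table: pd.DataFrame      # same metrics per (k, shuffle replicate)
    chosen_k: int


def _as_matrix(M) -> np.ndarray:
    X = M.M if isinstance(M, StackedMatrix) else np.asarray(M, dtype=float)
    if np.any(X < 0):
        raise ValueError("NMF input must be non-negative")
    return X


def nmf_fit(M, k: int, seed: int = 0, max_iter: int = 2000,
            tol: float = 1e-6) -> NMFModel:
    """Fit rank-k NMF by Lee-Seung multiplicative updates.

    T and S are initialised with seeded uniform(0, 1] values scaled by the
    matrix mean; updates alternate T and S and stop when the relative change
    of the Frobenius objective falls below ``tol`` or after ``max_iter``
    iterations.  The full objective trace is returned for audit.
    """
    X = _as_matrix(M)
    n, A = X.shape
    if not 1 <= k <= A:
        raise ValueError(f"rank k={k} must be in [1, {A}]")
    rng = np.random.default_rng(seed)
    scale = np.sqrt(max(X.mean(), _EPS) / k)
    T = scale * (1.0 - rng.random((n, k)))   # uniform (0, 1]
    S = scale * (1.0 - rng.random((k, A)))

    trace = []
    prev = np.inf
    it = 0
    for it in range(1, max_iter + 1):
        # T <- T * (X S^T) / (T S S^T)
        numer = X @ S.T
        denom = T @ (S @ S.T) + _EPS
        T *= numer / denom
        # S <- S * (T^T X) / (T^T T S)
        numer = T.T @ X
        denom = (T.T @ T) @ S + _EPS
        S *= numer / denom
        obj = float(np.linalg.norm(X - T @ S) ** 2)
        trace.append(obj)
        if prev < np.inf and prev - obj < tol * max(prev, _EPS):
            break
        prev = obj
    return NMFModel(k=k, S=S, T=T, objective_trace=np.asarray(trace),
                    seed=seed, n_iter=it)


def reconstruct(model: NMFModel) -> np.ndarray:
    """Low-rank reconstruction M' = T @ S."""
    return model.T @ model.S


def explained_variance(X, model: NMFModel) -> float:
    """evar = 1 - RSS / TSS of the reconstruction (TSS about zero)."""
    X = _as_matrix(X)
    rss = float(np.linalg.norm(X - reconstruct(model)) ** 2)
    tss = float(np.linalg.norm(X) ** 2)
    return 1.0 - rss / max(tss, _EPS)


def _channel_assignments(model: NMFModel) -> np.ndarray:
    """Dominant component per AU channel (argmax over S columns)."""
    return np.argmax(model.S, axis=0)


def consensus_metrics(M, k: int, n_runs: int = 30, seed: int = 0
                      ) -> tuple[float, float]:
    """Stability of AU-channel co-assignment across random NMF restarts.

    Each run assigns every AU channel to its dominant component; the
    consensus matrix is the fraction of runs in which two channels
    co-assign.  The cophenetic coefficient correlates consensus distances
    (1 - consensus) with the cophenetic distances of their average-linkage
    dendrogram; the silhouette scores the k-way cut of that dendrogram under
    consensus distance.  Returns (silhouette, cophenetic); silhouette is NaN
    when k == 1 or the cut is degenerate.
    """
    X = _as_matrix(M)
    A = X.shape[1]
    if k > A:
        raise ValueError("k cannot exceed the number of AU channels")
    if n_runs < 2:
        raise ValueError("need at least 2 runs for a consensus")
    rng = np.random.default_rng(seed)
    C = np.zeros((A, A))
    for _ in range(n_runs):
        model = nmf_fit(X, k, seed=int(rng.integers(0, 2**31 - 1)))
        a = _channel_assignments(model)
        C += (a[:, None] == a[None, :]).astype(float)
    C /= n_runs

    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    condensed = squareform(D, checks=False)
    Z = average(condensed)
    if condensed.std() < _EPS:
        coph = 1.0  # perfectly stable co-assignment: all distances 0 or identical
    else:
        coph, _ = cophenet(Z, condensed)
        coph = float(coph)

    if k == 1:
        return float("nan"), coph
    labels = fcluster(Z, t=k, criterion="maxclust")
    if len(np.unique(labels)) < 2:
        return float("nan"), coph
    sil = float(silhouette_score(D, labels, metric="precomputed"))
    return sil, coph


def block_shuffle(M, block_len: int, seed: int = 0):
    """Permute consecutive time blocks independently per trial and channel.

    Within each trial and each AU channel the bin sequence is cut into
    blocks of ``block_len`` (last block may be shorter) and the blocks are
    permuted uniformly at random, preserving each channel's value multiset
    while destroying cross-channel temporal alignment.
    """
    if block_len < 1:
        raise ValueError("block_len must be >= 1")
    is_stacked = isinstance(M, StackedMatrix)
    X = (M.M if is_stacked else np.asarray(M, dtype=float)).copy()
    n_bins = M.n_bins if is_stacked else X.shape[0]
    if block_len > n_bins:
        raise ValueError("block_len cannot exceed the bins per trial")
    rng = np.random.default_rng(seed)
    starts = np.arange(0, n_bins, block_len)
    for t0 in range(0, X.shape[0], n_bins):
        for j in range(X.shape[1]):
            blocks = [X[t0 + a:t0 + min(a + block_len, n_bins), j].copy()
                      for a in starts]
            order = rng.permutation(len(blocks))
            X[t0:t0 + n_bins, j] = np.concatenate([blocks[i] for i in order])
    if is_stacked:
        return StackedMatrix(X, list(M.trial_ids), M.n_bins, M.au_numbers, M.meta)
    return X


def select_k(M, k_range=range(2, 7), n_runs: int = 30, n_null: int = 20,
             block_len: int = 10, seed: int = 0,
             evar_tol: float = 0.005) -> KSelectionReport:
    """Choose the factorization rank from fit and stability indices.

    For each candidate k the data yield RSS, explained variance, consensus
    silhouette and cophenetic coefficient; the same metrics are computed on
    ``n_null`` block-shuffled copies (reported for audit and null
    benchmarking).  The chosen k has the best mean rank across
    (cophenetic up, silhouette up, plateau-quantized evar up), with ties
    broken toward the smaller k.  Quantizing evar in steps of ``evar_tol``
    makes every k on the explained-variance plateau tie, so the elbow of
    the reconstruction curve and the stability indices jointly pick the
    smallest adequate rank.
    """
    ks = list(k_range)
    if not ks:
        raise ValueError("k_range is empty")
    X = _as_matrix(M)
    rng = np.random.default_rng(seed)

    rows, null_rows = [], []
    nulls = [block_shuffle(M, block_len, seed=int(rng.integers(0, 2**31 - 1)))
             for _ in range(n_null)]
    for k in ks:
        model = nmf_fit(X, k, seed=int(rng.integers(0, 2**31 - 1)))
        rss = float(model.objective_trace[-1])
        evar = 1.0 - rss / max(float(np.linalg.norm(X) ** 2), _EPS)
        sil, coph = consensus_metrics(X, k, n_runs=n_runs,
                                      seed=int(rng.integers(0, 2**31 - 1)))
        rows.append({"k": k, "rss": rss, "evar": evar,
                     "silhouette": sil, "cophenetic": coph})
        for b, Mn in enumerate(nulls):
            Xn = _as_matrix(Mn)
            mn = nmf_fit(Xn, k, seed=int(rng.integers(0, 2**31 - 1)))
            rss_n = float(mn.objective_trace[-1])
            evar_n = 1.0 - rss_n / max(float(np.linalg.norm(Xn) ** 2), _EPS)
            sil_n, coph_n = consensus_metrics(
                Xn, k, n_runs=max(2, n_runs // 3),
                seed=int(rng.integers(0, 2**31 - 1)))
            null_rows.append({"k": k, "replicate": b, "rss": rss_n,
                              "evar": evar_n, "silhouette": sil_n,
                              "cophenetic": coph_n})

    table = pd.DataFrame(rows)
    null_table = pd.DataFrame(null_rows)
    evar = table.set_index("k")["evar"]
    crit = pd.DataFrame({
        "cophenetic": table.set_index("k")["cophenetic"],
        "silhouette": table.set_index("k")["silhouette"],
        "evar_plateau": np.floor(evar / evar_tol),
    })
    # higher is better on every criterion; mean rank, ties toward smaller k
    ranks = crit.rank(ascending=False, axis=0, na_option="bottom").mean(axis=1)
    chosen = int(ranks.index[np.lexsort((ranks.index, ranks.values))[0]])
    return KSelectionReport(table=table, null_table=null_table, chosen_k=chosen)


def project(model: NMFModel, M_new) -> np.ndarray:
    """Temporal weights of new data under a trained spatial basis.

    S is held fixed; each row of M_new gets non-negative least-squares
    weights minimising ||row - w @ S||, solved independently per row (NNLS
    is deterministic and optimal per row).
    """
    X = _as_matrix(M_new)
    if X.shape[1] != model.S.shape[1]:
        raise ValueError(
            f"channel mismatch: data has {X.shape[1]} channels, "
            f"model expects {model.S.shape[1]}")
    At = model.S.T  # A x k
    W = np.empty((X.shape[0], model.k))
    for i in range(X.shape[0]):
        W[i], _ = nnls(At, X[i])
    return W


def trajectories(T: np.ndarray, stacked: StackedMatrix
                 ) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """Reshape stacked temporal weights into per-trial component curves.

    Returns (per-trial dict of n_bins x k curves, per-emotion bin-wise mean
    curves in long format).  Requires the index to cover every row of T.
    """
    T = np.asarray(T, dtype=float)
    expected = len(stacked.trial_ids) * stacked.n_bins
    if T.shape[0] != expected:
        raise IndexError(f"index covers {expected} rows, T has {T.shape[0]}")
    per_trial = {tid: T[stacked.rows_of(tid)].copy() for tid in stacked.trial_ids}

    means = []
    if stacked.meta is not None:
        emo_of = dict(zip(stacked.meta["trial_id"], stacked.meta["emotion"]))
        for emo in sorted(set(emo_of.values())):
            curves = [per_trial[t] for t in stacked.trial_ids if emo_of[t] == emo]
            avg = np.mean(curves, axis=0)
            for c in range(avg.shape[1]):
                for b in range(avg.shape[0]):
                    means.append({"emotion": emo, "component": c,
                                  "bin": b, "mean_weight": avg[b, c]})
    return per_trial, pd.DataFrame(means)
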