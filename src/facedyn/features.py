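"""Interpretable timeseries features of component trajectories, plus PCA.

Each trial's n_bins x k component trajectory is summarised by a fixed,
versioned catalog of 38 per-component features spanning location, spread,
shape, kinematics (slope, curvature), complexity (sample and permutation
entropy, CID), autocorrelation, and spectral structure — the families used
by established multivariate-timeseries classification frameworks.  The
feature table is then summarised by a PCA fitted strictly on training
data: z-scoring statistics and loadings come from the train split and are
only ever *applied* to test data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats

__all__ = [
    "CATALOG_VERSION",
    "FEATURE_NAMES",
    "extract_features",
    "build_feature_table",
    "FeaturePCA",
    "fit_feature_pca",
    "apply_feature_pca",
]

CATALOG_VERSION = "fd38-v1"

FEATURE_NAMES = [
    "mean", "sd", "min", "max", "range", "median", "iqr", "auc",
    "argmax_norm", "argmin_norm", "ols_slope", "mean_abs_change",
    "mean_abs_diff2", "max_abs_diff2", "peak_count", "zero_crossings",
    "acf_lag1", "acf_lag5", "acf_first_zero", "sample_entropy",
    "permutation_entropy", "spectral_centroid", "spectral_entropy",
    "low_band_power", "cid", "time_reversal_asym", "longest_mono_run",
    "prop_above_mean", "skewness", "kurtosis", "rms", "crest_factor",
    "first_half_energy", "second_half_energy", "hjorth_mobility",
    "hjorth_complexity", "p10", "p90",
]

_SENTINEL = 0.0  # imputation for features undefined on the given series

_FEATURE_PARAMS = {
    "auc": {"rule": "trapezoid"},
    "peak_count": {"prominence": "0.5*sd"},
    "sample_entropy": {"m": 2, "r": "0.2*sd"},
    "permutation_entropy": {"order": 3},
    "low_band_power": {"cutoff_cycles_per_bin": 0.1},
    "time_reversal_asym": {"lag": 1},
    "acf_lag1": {"lag": 1},
    "acf_lag5": {"lag": 5},
    "p10": {"percentile": 10},
    "p90": {"percentile": 90},
}


def catalog_descriptor() -> list[dict]:
    """Machine-readable description of the feature catalog."""
    return [{"name": name, "catalog": CATALOG_VERSION,
             "parameters": _FEATURE_PARAMS.get(name, {})}
            for name in FEATURE_NAMES]


def _acf(x: np.ndarray, max_lag: int) -> np.ndarray:
    x = x - x.mean()
    denom = float(x @ x)
    if denom == 0:
        return np.full(max_lag + 1, np.nan)
    return np.array([float(x[: len(x) - h] @ x[h:]) / denom
                     for h in range(max_lag + 1)])


def _sample_entropy(x: np.ndarray, m: int = 2, r_frac: float = 0.2) -> float:
    sd = x.std()
    if sd == 0:
        return np.nan
    r = r_frac * sd
    n = len(x)

    def count(mm: int) -> int:
        templ = np.lib.stride_tricks.sliding_window_view(x, mm)
        d = np.max(np.abs(templ[:, None, :] - templ[None, :, :]), axis=2)
        iu = np.triu_indices(len(templ), k=1)
        return int(np.sum(d[iu] <= r))

    b = count(m)
    a = count(m + 1)
    if a == 0 or b == 0:
        return np.nan
    return -np.log(a / b)


def _permutation_entropy(x: np.ndarray, order: int = 3) -> float:
    n = len(x)
    if n < order:
        return np.nan
    windows = np.lib.stride_tricks.sliding_window_view(x, order)
    patterns = np.argsort(windows, axis=1, kind="stable")
    _, counts = np.unique(patterns, axis=0, return_counts=True)
    p = counts / counts.sum()
    h = -np.sum(p * np.log2(p))
    return float(h / np.log2(math.factorial(order)))


def _spectral(x: np.ndarray) -> tuple[float, float, float]:
    """(centroid, entropy, fraction of power below 0.1 cycles/bin)."""
    xc = x - x.mean()
    if np.allclose(xc, 0):
        return np.nan, np.nan, np.nan
    psd = np.abs(np.fft.rfft(xc)) ** 2
    freqs = np.fft.rfftfreq(len(x), d=1.0)
    total = psd.sum()
    if total == 0:
        return np.nan, np.nan, np.nan
    p = psd / total
    centroid = float(freqs @ p)
    nz = p[p > 0]
    ent = float(-np.sum(nz * np.log2(nz)) / max(np.log2(len(p)), 1e-12))
    low = float(p[freqs < 0.1].sum())
    return centroid, ent, low


def _hjorth(x: np.ndarray) -> tuple[float, float]:
    v0 = x.var()
    if v0 == 0:
        return np.nan, np.nan
    d1 = np.diff(x)
    v1 = d1.var()
    mobility = np.sqrt(v1 / v0)
    if v1 == 0:
        return mobility, np.nan
    d2 = np.diff(d1)
    mob_d = np.sqrt(d2.var() / v1)
    return float(mobility), float(mob_d / mobility) if mobility > 0 else np.nan


def _longest_monotonic_run(x: np.ndarray) -> int:
    d = np.sign(np.diff(x))
    best = run = 1
    for i in range(1, len(d)):
        run = run + 1 if d[i] == d[i - 1] and d[i] != 0 else 1
        best = max(best, run)
    return best + 1  # runs measured in samples, not steps


def _single_channel_features(x: np.ndarray) -> dict[str, float]:
    n = len(x)
    t = np.arange(n, dtype=float)
    sd = float(x.std())
    mean = float(x.mean())
    d1 = np.diff(x)
    d2 = np.diff(x, n=2)
    detrended = signal.detrend(x) if sd > 0 else x - mean
    acf = _acf(x, 5)
    first_zero = np.nan
    if not np.isnan(acf).all():
        below = np.flatnonzero(acf[1:] <= 0)
        if below.size:
            first_zero = float(below[0] + 1)
    peaks, _ = signal.find_peaks(x, prominence=0.5 * sd if sd > 0 else None)
    centroid, spec_ent, low_band = _spectral(x)
    mob, comp = _hjorth(x)
    rms = float(np.sqrt(np.mean(x ** 2)))
    # time-reversal asymmetry, lag 1: E[(x_{t+1} - x_t)^3], sd-normalised
    trev = (float(np.mean(d1 ** 3)) / (sd ** 3)) if sd > 0 else np.nan
    return {
        "mean": mean,
        "sd": sd,
        "min": float(x.min()),
        "max": float(x.max()),
        "range": float(x.max() - x.min()),
        "median": float(np.median(x)),
        "iqr": float(np.percentile(x, 75) - np.percentile(x, 25)),
        "auc": float(np.trapezoid(x)),
        "argmax_norm": float(np.argmax(x)) / (n - 1),
        "argmin_norm": float(np.argmin(x)) / (n - 1),
        "ols_slope": float(np.polyfit(t, x, 1)[0]) if sd > 0 else 0.0,
        "mean_abs_change": float(np.mean(np.abs(d1))),
        "mean_abs_diff2": float(np.mean(np.abs(d2))) if len(d2) else np.nan,
        "max_abs_diff2": float(np.max(np.abs(d2))) if len(d2) else np.nan,
        "peak_count": float(len(peaks)),
        "zero_crossings": float(np.sum(np.diff(np.sign(detrended)[
            np.sign(detrended) != 0]) != 0)),
        "acf_lag1": float(acf[1]) if len(acf) > 1 else np.nan,
        "acf_lag5": float(acf[5]) if len(acf) > 5 else np.nan,
        "acf_first_zero": first_zero,
        "sample_entropy": _sample_entropy(x),
        "permutation_entropy": _permutation_entropy(x),
        "spectral_centroid": centroid,
        "spectral_entropy": spec_ent,
        "low_band_power": low_band,
        "cid": float(np.sqrt(np.sum(d1 ** 2))),
        "time_reversal_asym": trev,
        "longest_mono_run": float(_longest_monotonic_run(x)),
        "prop_above_mean": float(np.mean(x > mean)),
        "skewness": float(stats.skew(x)) if sd > 0 else np.nan,
        "kurtosis": float(stats.kurtosis(x)) if sd > 0 else np.nan,
        "rms": rms,
        "crest_factor": float(np.max(np.abs(x)) / rms) if rms > 0 else np.nan,
        "first_half_energy": float(np.sum(x[: n // 2] ** 2) /
                                   max(np.sum(x ** 2), 1e-12)),
        "second_half_energy": float(np.sum(x[n // 2:] ** 2) /
                                    max(np.sum(x ** 2), 1e-12)),
        "hjorth_mobility": mob,
        "hjorth_complexity": comp,
        "p10": float(np.percentile(x, 10)),
        "p90": float(np.percentile(x, 90)),
    }


def extract_features(traj: np.ndarray) -> pd.Series:
    """Extract the 38-feature catalog per component of one trajectory.

    ``traj`` is n_bins x k.  Returns a flat Series indexed
    ``c<j>__<feature>``; features undefined for the series at hand (e.g.
    sample entropy of a constant) are imputed with 0 and remain flagged by
    the catalog's sentinel convention.
    """
    traj = np.asarray(traj, dtype=float)
    if traj.ndim == 1:
        traj = traj[:, None]
    if traj.shape[0] < 8:
        raise ValueError("need at least 8 bins to compute the feature catalog")
    out = {}
    for j in range(traj.shape[1]):
        feats = _single_channel_features(traj[:, j])
        for name in FEATURE_NAMES:
            v = feats[name]
            out[f"c{j}__{name}"] = _SENTINEL if (v is None or np.isnan(v)) else v
    return pd.Series(out)


def build_feature_table(per_trial: dict[str, np.ndarray]) -> pd.DataFrame:
    """Feature table for a set of trials (rows = trials, deterministic column order)."""
    rows = {tid: extract_features(tr) for tid, tr in per_trial.items()}
    table = pd.DataFrame(rows).T
    table.index.name = "trial_id"
    table.attrs["catalog_version"] = CATALOG_VERSION
    return table


@dataclass
class FeaturePCA:
    """Train-set scaler + orthonormal loadings for feature summarisation."""

    mean_: np.ndarray
    scale_: np.ndarray            # 0 marks constant (excluded) columns
    loadings: np.ndarray          # n_features x n_components, orthonormal
    variance_explained: np.ndarray
    columns: list[str]

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def fit_feature_pca(train: pd.DataFrame, n_components: int) -> FeaturePCA:
    """PCA of the z-scored training feature table.

    Constant columns are zeroed out of the standardisation (they carry no
    variance and would divide by zero).  Loadings come from the SVD of the
    standardized table; each loading's sign is fixed so its largest-magnitude
    entry is positive.
    """
    X = train.to_numpy(dtype=float)
    n, p = X.shape
    if n_components > min(n, p):
        raise ValueError("n_components exceeds the feature table rank bound")
    if n <= n_components:
        raise ValueError("need more training rows than components")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    scale = np.where(sd > 0, sd, 0.0)
    Z = np.where(scale > 0, (X - mean) / np.where(scale > 0, scale, 1.0), 0.0)

    _, sing, Vt = np.linalg.svd(Z, full_matrices=False)
    V = Vt[:n_components].T
    # deterministic sign: largest-|loading| entry positive per component
    for j in range(V.shape[1]):
        i = np.argmax(np.abs(V[:, j]))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
    var = sing ** 2 / max(n - 1, 1)
    ve = var[:n_components] / max(var.sum(), 1e-12)
    return FeaturePCA(mean_=mean, scale_=scale, loadings=V,
                      variance_explained=ve, columns=list(train.columns))


def apply_feature_pca(pca: FeaturePCA, table: pd.DataFrame) -> np.ndarray:
    """Project a feature table through the trained scaler and loadings.

    Never refits: the test set is transformed with training statistics only.
    """
    if list(table.columns) != pca.columns:
        raise ValueError("feature table columns do not match the fitted PCA")
    X = table.to_numpy(dtype=float)
    Z = np.where(pca.scale_ > 0,
                 (X - pca.mean_) / np.where(pca.scale_ > 0, pca.scale_, 1.0),
                 0.0)
    return Z @ pca.loadings
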