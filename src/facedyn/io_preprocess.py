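"""Reading, filtering, smoothing, binning and stacking of AU timeseries.

Trials arrive as OpenFace-dialect CSV files (one per video) with per-frame
AU intensities on the 0-5 scale and tracking confidence.  Preprocessing
follows the standard recipe for face-tracking output: drop poorly tracked
trials, smooth frame-level jitter with a short centered moving average,
reduce every trial to a fixed number of time bins, and stack the binned
trials row-wise into the non-negative matrix that the decomposition
consumes.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "AUTrial",
    "StackedMatrix",
    "read_openface_csv",
    "filter_by_confidence",
    "smooth_moving_average",
    "bin_to_fixed_length",
    "stack_trials",
    "unstack",
    "preprocess_trials",
]

_AU_R = re.compile(r"^\s*AU(\d+)_r\s*$")


@dataclass
class AUTrial:
    """One video's AU intensity timeseries plus metadata."""

    trial_id: str
    subject_id: str
    emotion: str
    condition: str
    session: int
    series: np.ndarray            # n_frames x A, non-negative
    frame_rate: float = 30.0
    confidence: np.ndarray = None  # per-frame fraction in [0, 1]
    au_numbers: tuple[int, ...] = ()
    success: np.ndarray = None     # per-frame tracking success flag

    def __post_init__(self):
        self.series = np.asarray(self.series, dtype=float)
        if self.confidence is None:
            self.confidence = np.ones(self.series.shape[0])
        self.confidence = np.asarray(self.confidence, dtype=float)
        if self.success is None:
            self.success = np.ones(self.series.shape[0])
        self.success = np.asarray(self.success, dtype=float)

    @property
    def n_frames(self) -> int:
        return self.series.shape[0]

    @property
    def n_channels(self) -> int:
        return self.series.shape[1]

    @property
    def mean_confidence(self) -> float:
        return float(np.mean(self.confidence))

    @property
    def success_fraction(self) -> float:
        return float(np.mean(self.success != 0))


@dataclass
class StackedMatrix:
    """Trials stacked row-wise: (n_trials * n_bins) x A non-negative matrix.

    ``index`` maps each row to its ``(trial_id, bin)``; every trial occupies
    ``n_bins`` consecutive rows in a fixed order.
    """

    M: np.ndarray
    trial_ids: list[str]
    n_bins: int
    au_numbers: tuple[int, ...] = ()
    meta: pd.DataFrame = field(default=None)

    def row_index(self) -> list[tuple[str, int]]:
        return [(tid, b) for tid in self.trial_ids for b in range(self.n_bins)]

    def rows_of(self, trial_id: str) -> slice:
        i = self.trial_ids.index(trial_id)
        return slice(i * self.n_bins, (i + 1) * self.n_bins)

    def subset(self, trial_ids: list[str]) -> "StackedMatrix":
        parts = [self.M[self.rows_of(t)] for t in trial_ids]
        meta = None
        if self.meta is not None:
            meta = self.meta.set_index("trial_id").loc[list(trial_ids)].reset_index()
        return StackedMatrix(np.vstack(parts), list(trial_ids), self.n_bins,
                             self.au_numbers, meta)


def read_openface_csv(path) -> AUTrial:
    """Read one OpenFace-dialect CSV into an AUTrial.

    Keeps only the AU intensity (``AU<nn>_r``) columns, sorted by AU number.
    Frames flagged ``success == 0`` are linearly interpolated from their
    successful neighbours so the time grid stays regular.
    """
    try:
        df = pd.read_csv(path, skipinitialspace=True)
    except ValueError as e:
        raise ValueError(f"cannot parse {path}: {e}") from e
    df.columns = [c.strip() for c in df.columns]

    au_cols = sorted(
        ((int(m.group(1)), c) for c in df.columns if (m := _AU_R.match(c))),
    )
    if not au_cols:
        raise ValueError(f"{path}: no AU intensity (_r) columns found")
    au_numbers = tuple(n for n, _ in au_cols)
    cols = [c for _, c in au_cols]

    for c in cols:
        bad = pd.to_numeric(df[c], errors="coerce").isna() & df[c].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(f"{path}: non-numeric value in column {c}, row {row}")
    series = df[cols].to_numpy(dtype=float)

    confidence = (df["confidence"].to_numpy(dtype=float)
                  if "confidence" in df.columns else np.ones(len(df)))
    success = (df["success"].to_numpy(dtype=float)
               if "success" in df.columns else np.ones(len(df)))

    failed = success == 0
    if failed.any() and not failed.all():
        t = np.arange(len(df))
        good = ~failed
        for j in range(series.shape[1]):
            series[failed, j] = np.interp(t[failed], t[good], series[good, j])

    stem = getattr(path, "stem", None) or str(path)
    return AUTrial(trial_id=stem, subject_id="", emotion="", condition="",
                   session=1, series=np.clip(series, 0.0, None),
                   confidence=confidence, au_numbers=au_numbers,
                   success=success)


def filter_by_confidence(trials: list[AUTrial], threshold: float = 0.90,
                         metric: str = "mean_confidence") -> list[AUTrial]:
    """Keep trials whose tracking quality is strictly above threshold.

    ``metric`` selects the quality statistic: ``mean_confidence`` (default)
    or ``success_fraction`` (share of successfully tracked frames).
    """
    if metric not in {"mean_confidence", "success_fraction"}:
        raise ValueError("metric must be mean_confidence or success_fraction")
    kept = [t for t in trials if getattr(t, metric) > threshold]
    log.info("tracking filter (%s > %.2f): kept %d / %d trials",
             metric, threshold, len(kept), len(trials))
    return kept


def smooth_moving_average(series: np.ndarray, window: int = 3) -> np.ndarray:
    """Centered moving average per channel; edge windows shrink at boundaries.

    Near the edges the window is truncated to the frames that exist, so no
    padding values are invented and the output length equals the input
    length.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    x = np.asarray(series, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    n = x.shape[0]
    half = window // 2
    out = np.empty_like(x)
    csum = np.vstack([np.zeros((1, x.shape[1])), np.cumsum(x, axis=0)])
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        out[i] = (csum[hi] - csum[lo]) / (hi - lo)
    return out[:, 0] if squeeze else out


def bin_to_fixed_length(series: np.ndarray, n_bins: int = 100) -> np.ndarray:
    """Reduce a trial to ``n_bins`` bins by averaging contiguous frame groups.

    Frames are partitioned into maximally equal contiguous groups (sizes
    differ by at most one); each bin is the mean of its frames.  Trials
    shorter than ``n_bins`` are first linearly interpolated up to ``n_bins``
    points.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    x = np.asarray(series, dtype=float)
    squeeze = x.ndim == 1
    if squeeze:
        x = x[:, None]
    n = x.shape[0]
    if n < n_bins:
        t_new = np.linspace(0, n - 1, n_bins)
        x = np.vstack([np.interp(t_new, np.arange(n), x[:, j])
                       for j in range(x.shape[1])]).T
        n = n_bins
    bounds = np.linspace(0, n, n_bins + 1).astype(int)
    out = np.vstack([x[a:b].mean(axis=0) for a, b in zip(bounds[:-1], bounds[1:])])
    return out[:, 0] if squeeze else out


def preprocess_trials(trials: list[AUTrial], window: int = 3,
                      n_bins: int = 100) -> list[AUTrial]:
    """Smooth then bin every trial, returning new trials with binned series."""
    out = []
    for t in trials:
        binned = bin_to_fixed_length(smooth_moving_average(t.series, window), n_bins)
        conf = bin_to_fixed_length(t.confidence, n_bins)
        out.append(AUTrial(t.trial_id, t.subject_id, t.emotion, t.condition,
                           t.session, binned, t.frame_rate, conf, t.au_numbers))
    return out


def stack_trials(trials: list[AUTrial], n_bins: int | None = None) -> StackedMatrix:
    """Stack (already binned) trials into the decomposition input matrix.

    Rows are ordered trial-by-trial, bin-by-bin.  All trials must share the
    same channel set.
    """
    if not trials:
        raise ValueError("no trials to stack")
    chans = {t.au_numbers for t in trials}
    if len(chans) != 1:
        raise ValueError(f"inconsistent AU channel sets across trials: {chans}")
    lengths = {t.n_frames for t in trials}
    if n_bins is None:
        if len(lengths) != 1:
            raise ValueError("trials have differing lengths; bin them first")
        n_bins = lengths.pop()
    elif lengths != {n_bins}:
        raise ValueError(f"trials are not binned to {n_bins} bins")
    M = np.vstack([t.series for t in trials])
    meta = pd.DataFrame({
        "trial_id": [t.trial_id for t in trials],
        "subject_id": [t.subject_id for t in trials],
        "emotion": [t.emotion for t in trials],
        "condition": [t.condition for t in trials],
        "session": [t.session for t in trials],
    })
    return StackedMatrix(M, [t.trial_id for t in trials], n_bins,
                         trials[0].au_numbers, meta)


def unstack(stacked: StackedMatrix) -> dict[str, np.ndarray]:
    """Inverse of stack_trials: per-trial binned series keyed by trial id."""
    return {tid: stacked.M[stacked.rows_of(tid)].copy() for tid in stacked.trial_ids}
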