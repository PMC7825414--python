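"""Accuracy metrics, signal importance and unit conversions.

The headline accuracy metric is the coefficient of determination
r² = 1 − SS_res/SS_tot, computed per participant across all of that
participant's time samples and averaged across participants.  RMSE is
reported both in BW×BH units and converted to N·m with the cohort-mean
body weight and height; MAPE is restricted to samples whose true moment
exceeds a threshold (default 0.05 BW×BH) because percent errors blow up
near zero.  Signal importance is permutation importance: the drop in
held-out r² (Δr²) when one channel is shuffled, averaged over repeats and
folds.  Note that Δr² of strongly correlated channels understates their
joint contribution — shuffling one leaves its twin intact — so per-channel
Δr² does not sum to the baseline r².
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.inspection import permutation_importance as _sk_permutation_importance

from .anthropometry import G, Anthropometry, cohort_mean_bwbh
from .estimator import CvPrediction, MomentEstimator
from .features import FeatureMatrix, apply_normalizer

__all__ = [
    "r2_score",
    "r2_by_participant",
    "rmse",
    "mape_thresholded",
    "permutation_importance",
    "cv_permutation_importance",
    "moment_to_compression",
    "force_to_bw",
    "wilcoxon_paired",
    "AccuracyReport",
    "accuracy_report",
    "ImportanceTable",
]

MAPE_THRESHOLD_BWBH = 0.05
LUMBAR_MOMENT_ARM_M = 0.07


def r2_score(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Coefficient of determination, 1 - SS_res/SS_tot."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    ss_tot = np.sum((y_true - y_true.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("zero-variance target")
    return float(1.0 - np.sum((y_true - y_pred) ** 2) / ss_tot)


def r2_by_participant(cv: CvPrediction) -> tuple[dict[str, float], float]:
    """Per-participant r² over all that participant's samples, plus the mean."""
    per = {pid: r2_score(*cv.fold(pid)) for pid in cv.participants}
    return per, float(np.mean(list(per.values())))


def rmse(
    y_true: np.ndarray, y_pred: np.ndarray, cohort: list[Anthropometry]
) -> tuple[float, float]:
    """RMSE in BW×BH units and converted to N·m with cohort-mean BW·BH."""
    y_true = np.asarray(y_true, dtype=float)
    if y_true.size == 0:
        raise ValueError("empty input")
    val = float(np.sqrt(np.mean((y_true - np.asarray(y_pred, dtype=float)) ** 2)))
    return val, val * cohort_mean_bwbh(cohort)


def mape_thresholded(
    y_true: np.ndarray, y_pred: np.ndarray, threshold: float = MAPE_THRESHOLD_BWBH
) -> float:
    """Mean absolute percent error over samples with true moment > threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    mask = y_true > threshold
    if not np.any(mask):
        raise ValueError("no samples above threshold")
    return float(np.mean(np.abs(y_pred[mask] - y_true[mask]) / y_true[mask]) * 100.0)


@dataclass
class ImportanceTable:
    """Per-channel Δr² (mean and sd over repeats and folds) with ranking."""

    table: pd.DataFrame  # columns: channel, delta_r2, delta_r2_sd; sorted descending

    @property
    def ranking(self) -> list[str]:
        return self.table["channel"].tolist()

    def top(self, n: int) -> list[str]:
        return self.ranking[:n]


def permutation_importance(
    model: MomentEstimator,
    X,
    y: np.ndarray,
    repeats: int = 5,
    seed: int = 0,
    channel_names: list[str] | None = None,
) -> ImportanceTable:
    """Δr² per channel when that channel is shuffled across the given samples."""
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    if isinstance(X, FeatureMatrix):
        channel_names = X.channel_names
        X = X.values
    X = np.asarray(X)
    if X.shape[0] < 2:
        raise ValueError("need more than one sample to permute")
    estimator = getattr(model, "_model", model)  # unwrap to the sklearn regressor
    res = _sk_permutation_importance(
        estimator, X, np.asarray(y), scoring="r2", n_repeats=repeats, random_state=seed)
    names = channel_names or [f"ch{i}" for i in range(X.shape[1])]
    df = pd.DataFrame({
        "channel": names,
        "delta_r2": res.importances_mean,
        "delta_r2_sd": res.importances_std,
    }).sort_values("delta_r2", ascending=False, ignore_index=True)
    return ImportanceTable(df)


def cv_permutation_importance(
    cv: CvPrediction,
    fm: FeatureMatrix,
    y: np.ndarray,
    repeats: int = 5,
    seed: int = 0,
) -> ImportanceTable:
    """Permutation importance per held-out fold, averaged across folds.

    Shuffling is performed within each held-out participant, preserving the
    fold structure.
    """
    per_fold = []
    for k, pid in enumerate(cv.participants):
        idx = cv.indices[pid]
        Xn = apply_normalizer(cv.normalizers[pid], fm.values[idx])
        t = permutation_importance(cv.models[pid], Xn, np.asarray(y)[idx],
                                   repeats=repeats, seed=seed + k,
                                   channel_names=fm.channel_names)
        per_fold.append(t.table.set_index("channel"))
    stacked = pd.concat(per_fold)
    agg = stacked.groupby("channel").agg(
        delta_r2=("delta_r2", "mean"), delta_r2_sd=("delta_r2", "std"))
    df = agg.sort_values("delta_r2", ascending=False).reset_index()
    return ImportanceTable(df)


def moment_to_compression(moment_nm: float, moment_arm: float = LUMBAR_MOMENT_ARM_M) -> float:
    """Spine compression force (N) from a lumbar moment via the extensor moment arm."""
    if moment_arm <= 0:
        raise ValueError("moment arm must be positive")
    return moment_nm / moment_arm

def force_to_bw(force_n: float, mean_mass_kg: float) -> tuple[float, float]:
    """Force in units of body weight; returns (exact, rounded-to-1-decimal)."""
    if mean_mass_kg <= 0:
        raise ValueError("mass must be positive")
    exact = force_n / (mean_mass_kg * G)
    # round half away from zero for report display
    rounded = float(np.floor(abs(exact) * 10.0 + 0.5) / 10.0 * np.sign(exact))
    return float(exact), rounded


def wilcoxon_paired(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Wilcoxon signed-rank p-value on paired per-participant accuracies.

    Exact null distribution for n <= 25, normal approximation above.
    Identical vectors (all zero differences) are a degenerate case and raise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    d = a - b
    if np.all(d == 0):
        raise ValueError("all paired differences are zero; the test is undefined")
    method = "exact" if (len(d) <= 25 and not np.any(d == 0) and
                         len(np.unique(np.abs(d))) == len(d)) else "approx"
    return float(stats.wilcoxon(a, b, alternative="two-sided", method=method).pvalue)


@dataclass
class AccuracyReport:
    """Accuracy summary for one sensor subset."""

    r2_per_participant: dict[str, float]
    r2_mean: float
    rmse_bwbh: float
    rmse_nm: float
    mape_pct: float
    mape_threshold: float
    n_included: int
    n_total: int


def accuracy_report(
    cv: CvPrediction,
    cohort: list[Anthropometry],
    mape_threshold: float = MAPE_THRESHOLD_BWBH,
) -> AccuracyReport:
    per, mean = r2_by_participant(cv)
    rm_bwbh, rm_nm = rmse(cv.y_true, cv.y_pred, cohort)
    mask = cv.y_true > mape_threshold
    # a target with no samples above threshold (e.g. lateral bending on a
    # mostly sagittal battery) gets an undefined MAPE, not a crash
    mape = mape_thresholded(cv.y_true, cv.y_pred, mape_threshold) if mask.any() else float("nan")
    return AccuracyReport(
        r2_per_participant=per,
        r2_mean=mean,
        rmse_bwbh=rm_bwbh,
        rmse_nm=rm_nm,
        mape_pct=mape,
        mape_threshold=mape_threshold,
        n_included=int(mask.sum()),
        n_total=int(mask.size),
    )
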