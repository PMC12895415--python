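"""Regression metrics, error-distribution analyses, visible-range screening
and oscillator-strength classification."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "EvalReport",
    "BinnedErrorReport",
    "ScreeningSummary",
    "ConfusionCounts",
    "regression_metrics",
    "binned_median_errors",
    "visible_range_screen",
    "oscillator_classification",
]


@dataclass
class EvalReport:
    """Headline regression metrics of predicted vs true S1 energies (eV).

    ``p95_abs_err`` is the error below which 95% of predictions fall."""

    pearson_r: float
    mae: float
    rmse: float
    median_abs_err: float
    p95_abs_err: float
    n: int
    r_defined: bool = True

    def summary(self) -> str:
        r_str = f"{self.pearson_r:.4f}" if self.r_defined else "undefined (zero variance)"
        return "\n".join(
            [
                f"n                 {self.n}",
                f"Pearson r         {r_str}",
                f"MAE (eV)          {self.mae:.4f}",
                f"RMSE (eV)         {self.rmse:.4f}",
                f"median |err| (eV) {self.median_abs_err:.4f}",
                f"95% |err| < (eV)  {self.p95_abs_err:.4f}",
            ]
        )


def regression_metrics(pred, true) -> EvalReport:
    """Pearson r, MAE, RMSE and the median/95th-percentile absolute error of
    the prediction residual (pred − true)."""
    pred = np.asarray(pred, dtype=float)
    true = np.asarray(true, dtype=float)
    if pred.size == 0 or pred.shape != true.shape:
        raise ValueError("pred and true must be equal-length and nonempty")
    err = pred - true
    abs_err = np.abs(err)
    r_defined = np.ptp(pred) > 0 and np.ptp(true) > 0
    r = float(stats.pearsonr(pred, true).statistic) if r_defined else np.nan
    return EvalReport(
        pearson_r=r,
        mae=float(abs_err.mean()),
        rmse=float(np.sqrt(np.mean(err**2))),
        median_abs_err=float(np.median(abs_err)),
        p95_abs_err=float(np.percentile(abs_err, 95)),
        n=pred.size,
        r_defined=bool(r_defined),
    )


@dataclass
class BinnedErrorReport:
    """Median absolute error within intervals of the true energy."""

    edges: np.ndarray
    medians: list[float | None]          # None marks an empty bin
    counts: np.ndarray
    overflow: int = 0

    @property
    def n(self) -> int:
        return int(self.counts.sum()) + self.overflow


def binned_median_errors(pred, true, edges) -> BinnedErrorReport:
    """Assign points to bins by their *true* value (half-open [lo, hi), last
    bin closed) and report the per-bin median |pred − true|; points outside
    the edge range are counted in an overflow bucket."""
    pred = np.asarray(pred, dtype=float)
    true = np.asarray(true, dtype=float)
    edges = np.asarray(edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("edges must be strictly increasing with >= 2 entries")
    abs_err = np.abs(pred - true)
    nbins = len(edges) - 1
    idx = np.searchsorted(edges, true, side="right") - 1
    idx[true == edges[-1]] = nbins - 1  # last bin closed at the right edge
    in_range = (idx >= 0) & (idx < nbins)
    medians: list[float | None] = []
    counts = np.zeros(nbins, dtype=int)
    for b in range(nbins):
        mask = in_range & (idx == b)
        counts[b] = mask.sum()
        medians.append(float(np.median(abs_err[mask])) if counts[b] else None)
    return BinnedErrorReport(
        edges=edges, medians=medians, counts=counts, overflow=int((~in_range).sum())
    )


@dataclass
class ScreeningSummary:
    """Visible-range screening outcome.

    ``range_recall`` — of molecules truly inside (lo, hi), the fraction also
    predicted inside; ``within_tol`` — among those recovered, the fraction
    with relative error below ``rel_tol``; ``prevalence`` — fraction of all
    molecules truly inside the window."""

    lo: float
    hi: float
    rel_tol: float
    n_true_in_range: int
    n_recovered: int
    n_within_tol: int
    prevalence: float
    n_excluded_nonpositive: int = 0

    @property
    def range_recall(self) -> float:
        return self.n_recovered / self.n_true_in_range if self.n_true_in_range else np.nan

    @property
    def within_tol(self) -> float:
        return self.n_within_tol / self.n_recovered if self.n_recovered else np.nan


def visible_range_screen(
    pred, true, lo: float = 1.7, hi: float = 3.3, rel_tol: float = 0.10
) -> ScreeningSummary:
    """Screening summary over the visible window (default 1.7–3.3 eV).

    Relative error uses the true energy as denominator; non-positive true
    energies are excluded from the relative-error count and flagged."""
    if rel_tol <= 0:
        raise ValueError("rel_tol must be positive")
    pred = np.asarray(pred, dtype=float)
    true = np.asarray(true, dtype=float)
    true_in = (true > lo) & (true < hi)
    pred_in = (pred > lo) & (pred < hi)
    recovered = true_in & pred_in
    positive = true > 0
    rel_ok = np.zeros_like(true, dtype=bool)
    rel_ok[positive] = np.abs(pred[positive] - true[positive]) / true[positive] < rel_tol
    return ScreeningSummary(
        lo=lo,
        hi=hi,
        rel_tol=rel_tol,
        n_true_in_range=int(true_in.sum()),
        n_recovered=int(recovered.sum()),
        n_within_tol=int((recovered & rel_ok).sum()),
        prevalence=float(true_in.mean()) if true.size else np.nan,
        n_excluded_nonpositive=int((recovered & ~positive).sum()),
    )


@dataclass
class ConfusionCounts:
    """2x2 confusion matrix for emitter classification, with derived rates."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def recall(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else np.nan

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else np.nan

    @property
    def specificity(self) -> float:
        d = self.tn + self.fp
        return self.tn / d if d else np.nan

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total if self.total else np.nan


def oscillator_classification(pred_f, true_f, threshold: float = 0.4) -> ConfusionCounts:
    """Classify molecules as emissive by oscillator strength strictly above
    ``threshold`` (default f > 0.4), applied to predictions and truths
    independently; a value exactly at the threshold is negative."""
    pred_f = np.asarray(pred_f, dtype=float)
    true_f = np.asarray(true_f, dtype=float)
    if np.any(pred_f < 0) or np.any(true_f < 0):
        raise ValueError("oscillator strengths must be >= 0")
    pp = pred_f > threshold
    tt = true_f > threshold
    return ConfusionCounts(
        tp=int(np.sum(pp & tt)),
        fp=int(np.sum(pp & ~tt)),
        fn=int(np.sum(~pp & tt)),
        tn=int(np.sum(~pp & ~tt)),
    )
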