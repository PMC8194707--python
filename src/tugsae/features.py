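"""Statistical-feature baseline: 15 features, t-test screening, LDA under LOOCV.

Per axis (V, ML, AP) of the full TUG trace, five summary features are
computed — mean, standard deviation (unbiased, divisor T-1), maximum,
minimum and mean crossing rate (MCR, the fraction of consecutive sample
pairs strictly straddling the signal mean). Features are screened with a
two-sample pooled-variance Student t-test at alpha = 0.05 (Kolmogorov-
Smirnov normality p-values are reported alongside, informational only),
and the surviving features feed a two-class linear discriminant analysis
evaluated by leave-one-out cross-validation. Screening is done once on the
full table, before cross-validation; this mirrors the sequential protocol
it reproduces and carries the usual optimistic selection bias.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .synthetic import AXES, SubjectRecord

__all__ = [
    "FEATURE_NAMES",
    "AxisFeatures",
    "SelectionResult",
    "ConfusionSummary",
    "extract_features",
    "feature_table",
    "select_features",
    "loocv_lda",
]

_STATS = ("mean", "std", "max", "min", "mcr")

#: Column order of the 15-feature table: mean_v .. mcr_v, mean_ml .. mcr_ap.
FEATURE_NAMES = tuple(f"{s}_{a}" for a in AXES for s in _STATS)


class AxisFeatures(NamedTuple):
    mean: float
    std: float
    max: float
    min: float
    mcr: float


@dataclass(frozen=True)
class SelectionResult:
    """t-test screening outcome over the 15 features."""

    p_values: np.ndarray
    normality_p: np.ndarray  # min over the two classes of the KS p-value
    selected: np.ndarray  # boolean, p <= alpha
    alpha: float

    def selected_names(self) -> list[str]:
        return [n for n, s in zip(FEATURE_NAMES, self.selected) if s]


@dataclass(frozen=True)
class ConfusionSummary:
    """Aggregate confusion matrix; positive class = at_risk."""

    tp: int
    fp: int
    tn: int
    fn: int

    @classmethod
    def from_predictions(cls, y_true: np.ndarray, y_pred: np.ndarray) -> "ConfusionSummary":
        y_true = np.asarray(y_true).astype(int)
        y_pred = np.asarray(y_pred).astype(int)
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        )

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")


def extract_features(trace_axis: np.ndarray) -> AxisFeatures:
    """Five summary statistics of one axis of a trace.

    MCR counts consecutive sample pairs strictly straddling the mean,
    normalised by the number of pairs (T - 1), giving a dimensionless
    per-sample crossing rate.
    """
    x = np.asarray(trace_axis, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("trace axis must be 1-D with at least 2 samples")
    m = x.mean()
    d = x - m
    crossings = int(np.sum(d[:-1] * d[1:] < 0))
    return AxisFeatures(
        mean=float(m),
        std=float(x.std(ddof=1)),
        max=float(x.max()),
        min=float(x.min()),
        mcr=crossings / (x.size - 1),
    )


def feature_table(cohort: Sequence[SubjectRecord]) -> pd.DataFrame:
    """15-feature table for a cohort, one row per subject.

    Columns: ``subject_id``, ``label``, then :data:`FEATURE_NAMES`.
    """
    rows = []
    for rec in cohort:
        row: dict = {"subject_id": rec.subject_id, "label": rec.label}
        for axis in AXES:
            f = extract_features(rec.axis(axis))
            for stat in _STATS:
                row[f"{stat}_{axis}"] = getattr(f, stat)
        rows.append(row)
    return pd.DataFrame(rows, columns=["subject_id", "label", *FEATURE_NAMES])


def _split_classes(X: np.ndarray, labels: np.ndarray):
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("both classes (0 and 1) must be present")
    return X[labels == 1], X[labels == 0]


def select_features(
    table: pd.DataFrame | np.ndarray,
    labels: np.ndarray,
    alpha: float = 0.05,
) -> SelectionResult:
    """Screen features with a pooled-variance two-sample Student t-test.

    A feature is selected when its two-sided p-value is <= ``alpha``.
    KS normality p-values (each class standardised against a fitted
    normal; the per-feature minimum over classes is reported) are
    informational and do not gate selection.
    """
    X = np.asarray(table[list(FEATURE_NAMES)] if isinstance(table, pd.DataFrame) else table, dtype=float)
    if X.shape[0] < 4:
        raise ValueError("need at least 4 subjects")
    pos, neg = _split_classes(X, labels)
    p_values = stats.ttest_ind(pos, neg, axis=0, equal_var=True).pvalue
    normality = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        ps = []
        for cls in (pos, neg):
            v = cls[:, j]
            sd = v.std(ddof=1)
            z = (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)
            ps.append(stats.kstest(z, "norm").pvalue)
        normality[j] = min(ps)
    return SelectionResult(
        p_values=np.asarray(p_values),
        normality_p=normality,
        selected=np.asarray(p_values) <= alpha,
        alpha=alpha,
    )


def loocv_lda(X: np.ndarray, labels: np.ndarray) -> ConfusionSummary:
    """Leave-one-out LDA (shared covariance, empirical priors).

    Each subject is predicted by a two-class LDA fitted on all others;
    the n predictions form one aggregate confusion matrix.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels).astype(int)
    if X.shape[0] < 4:
        raise ValueError("need at least 4 subjects")
    _split_classes(X, y)
    pooled = _pooled_covariance(X, y)
    if np.linalg.cond(np.atleast_2d(pooled)) > 1e12:
        raise np.linalg.LinAlgError(
            "pooled covariance is singular; reduce or decorrelate features, "
            "or add regularization"
        )
    n = X.shape[0]
    preds = np.empty(n, dtype=int)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        clf = LinearDiscriminantAnalysis(solver="svd")
        clf.fit(X[mask], y[mask])
        preds[i] = clf.predict(X[i : i + 1])[0]
        mask[i] = True
    return ConfusionSummary.from_predictions(y, preds)


def _pooled_covariance(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    covs = []
    for cls in (0, 1):
        G = X[y == cls]
        covs.append((G - G.mean(axis=0)).T @ (G - G.mean(axis=0)))
    return (covs[0] + covs[1]) / (X.shape[0] - 2)
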