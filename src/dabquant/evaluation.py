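"""Agreement statistics: confusion matrices, per-class F-scores and ICC.

These are the statistics used to compare block-level automatic Allred
classification against expert ratings: a K x K cross-tabulation with
per-class F-scores (harmonic mean of precision and recall, which is
invariant to transposing the matrix), and the intraclass correlation
coefficient ICC(2,1) — two-way random effects, absolute agreement, single
rater — with the conventional poor/moderate/good/excellent interpretation
bands at 0.50 / 0.75 / 0.90.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

#: ICC interpretation bands: (inclusive lower bound, label), evaluated top-down.
ICC_BANDS = ((0.90, "excellent"), (0.75, "good"), (0.50, "moderate"))


@dataclass(frozen=True)
class ConfusionMatrix:
    """K x K cross-tabulation of two raters' class labels.

    ``counts[i, j]`` is the number of items the row rater put in class
    ``classes[i]`` and the column rater in ``classes[j]``.
    """

    classes: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.classes), len(self.classes)):
            raise ValueError("counts must be square with one row per class")
        if (counts < 0).any():
            raise ValueError("counts must be nonnegative")
        object.__setattr__(self, "counts", counts.astype(int))

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.classes), columns=list(self.classes))


def confusion_matrix(
    pred: Sequence[str], ref: Sequence[str], classes: Sequence[str]
) -> ConfusionMatrix:
    """Cross-tabulate predicted (rows) against reference (columns) labels."""
    if len(pred) != len(ref):
        raise ValueError(f"length mismatch: {len(pred)} predictions vs {len(ref)} references")
    classes = tuple(classes)
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for p, r in zip(pred, ref):
        if p not in index:
            raise ValueError(f"unknown predicted label {p!r}")
        if r not in index:
            raise ValueError(f"unknown reference label {r!r}")
        counts[index[p], index[r]] += 1
    return ConfusionMatrix(classes=classes, counts=counts)


def per_class_f_score(cm: ConfusionMatrix) -> dict[str, float]:
    """F-score per class: harmonic mean of precision and recall.

    For class i, TP is the diagonal entry, precision TP over the column sum,
    recall TP over the row sum; F is 0 by convention when TP is 0.  The
    result is invariant to transposing the matrix, so it does not depend on
    which rater indexes the rows.
    """
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    out = {}
    for i, cls in enumerate(cm.classes):
        tp = cm.counts[i, i]
        col = cm.counts[:, i].sum()
        row = cm.counts[i, :].sum()
        if tp == 0:
            out[cls] = 0.0
            continue
        precision = tp / col
        recall = tp / row
        out[cls] = 2.0 * precision * recall / (precision + recall)
    return out


def macro_f_score(cm: ConfusionMatrix) -> float:
    """Unweighted mean of the per-class F-scores."""
    scores = per_class_f_score(cm)
    return float(np.mean(list(scores.values())))


def icc(ratings: np.ndarray, variant: str = "icc2_1") -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    *ratings* is an (n subjects x k raters) numeric table with no missing
    cells.  From the two-way ANOVA mean squares (MSR between subjects, MSC
    between raters, MSE residual)::

        ICC(2,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

    Raises ``ValueError`` when the table is degenerate (zero total
    variance), rather than returning NaN.
    """
    if variant != "icc2_1":
        raise ValueError(f"unsupported ICC variant {variant!r}")
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ValueError("ratings must be a 2-D subjects x raters table")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError(f"need at least 2 subjects and 2 raters, got {n}x{k}")
    if np.isnan(x).any():
        raise ValueError("ratings table contains missing cells")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((x - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    if ss_total == 0.0:
        raise ValueError("ICC undefined: ratings have zero total variance")

    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0.0:
        raise ValueError("ICC undefined: zero denominator in variance decomposition")
    return float((msr - mse) / denom)


def interpret_icc(value: float) -> str:
    """Map an ICC point estimate to its agreement band.

    Below 0.50 poor, then moderate, good from 0.75 and excellent from 0.90;
    boundary values fall in the upper band.
    """
    if not -1.0 <= value <= 1.0:
        raise ValueError(f"ICC must be in [-1, 1], got {value}")
    for lower, label in ICC_BANDS:
        if value >= lower:
            return label
    return "poor"
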