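"""Outlier screening prior to reference-interval estimation.

Two screens are provided: Tukey fences computed from the hinges
(quartile +/- k * IQR, with k = 1.5 for the inner and 3.0 for the far
fences), and the Dixon-Reed gap criterion that flags an extreme value
when its gap to the nearest neighbour exceeds one third of the range.

Policy: "suspect" values (beyond an inner fence but within the far fence)
are retained; only "far" values are removed, in a single pass without
re-fencing. Dixon-Reed flags are reported alongside but do not remove
values unless explicitly requested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

LABEL_INSIDE = "inside"
LABEL_SUSPECT = "suspect"
LABEL_FAR = "far"


@dataclass(frozen=True)
class TukeyClassification:
    q1: float
    median: float
    q3: float
    iqr: float
    inner_fences: tuple[float, float]
    far_fences: tuple[float, float]
    labels: np.ndarray  # dtype object, one of inside/suspect/far per value

    def __post_init__(self) -> None:
        assert self.iqr >= 0
        assert self.far_fences[0] <= self.inner_fences[0]
        assert self.far_fences[1] >= self.inner_fences[1]


@dataclass(frozen=True)
class DixonReedFlags:
    low_ratio: float
    high_ratio: float
    low_flagged: bool
    high_flagged: bool


@dataclass(frozen=True)
class OutlierReport:
    retained: np.ndarray
    removed: np.ndarray
    removed_labels: np.ndarray
    dixon_flagged: np.ndarray
    classification: TukeyClassification
    dixon: DixonReedFlags
    input_values: np.ndarray = None
    removed_mask: np.ndarray = None


def _check(values) -> np.ndarray:
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 3:
        raise ValueError(f"need at least 3 values, got {x.size}")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    return x


def quartiles(values) -> tuple[float, float, float]:
    """Tukey hinges: median of the lower/upper half, halves including the
    overall median when n is odd. Returns (q1, median, q3)."""
    x = np.sort(_check(values))
    n = x.size
    m = n // 2
    med = float(np.median(x))
    if n % 2:
        lower, upper = x[: m + 1], x[m:]
    else:
        lower, upper = x[:m], x[m:]
    return float(np.median(lower)), med, float(np.median(upper))


def tukey_classify(
    values, inner_k: float = 1.5, far_k: float = 3.0
) -> TukeyClassification:
    """Label each value inside / suspect / far relative to the Tukey fences.

    A value exactly on a fence takes the milder label; when the IQR is zero
    every value is labelled inside (tied data never become outliers).
    """
    if not 0 < inner_k <= far_k:
        raise ValueError("require 0 < inner_k <= far_k")
    x = _check(values)
    q1, med, q3 = quartiles(x)
    iqr = q3 - q1
    inner = (q1 - inner_k * iqr, q3 + inner_k * iqr)
    far = (q1 - far_k * iqr, q3 + far_k * iqr)
    labels = np.full(x.shape, LABEL_INSIDE, dtype=object)
    if iqr > 0:
        beyond_inner = (x < inner[0]) | (x > inner[1])
        beyond_far = (x < far[0]) | (x > far[1])
        labels[beyond_inner] = LABEL_SUSPECT
        labels[beyond_far] = LABEL_FAR
    return TukeyClassification(
        q1=q1, median=med, q3=q3, iqr=iqr, inner_fences=inner, far_fences=far,
        labels=labels,
    )


def dixon_reed_flag(values) -> DixonReedFlags:
    """Gap-to-range ratios for the sample extremes; an extreme is flagged
    when its ratio strictly exceeds 1/3. A zero range yields no flags."""
    x = np.sort(_check(values))
    rng = x[-1] - x[0]
    if rng == 0:
        return DixonReedFlags(0.0, 0.0, False, False)
    low = float((x[1] - x[0]) / rng)
    high = float((x[-1] - x[-2]) / rng)
    third = 1.0 / 3.0
    return DixonReedFlags(low, high, low > third, high > third)


def remove_far_outliers(
    values,
    inner_k: float = 1.5,
    far_k: float = 3.0,
    remove_dixon: bool = False,
) -> OutlierReport:
    """Single-pass removal of Tukey-far values (and, optionally, Dixon-Reed
    flagged extremes). Fences are not recomputed after removal."""
    x = _check(values)
    cls = tukey_classify(x, inner_k=inner_k, far_k=far_k)
    dixon = dixon_reed_flag(x)
    remove = cls.labels == LABEL_FAR
    srt = np.sort(x)
    dixon_vals = []
    if dixon.low_flagged:
        dixon_vals.append(srt[0])
    if dixon.high_flagged:
        dixon_vals.append(srt[-1])
    if remove_dixon:
        for v in dixon_vals:
            # remove one instance of the flagged extreme
            idx = np.flatnonzero((x == v) & ~remove)
            if idx.size:
                remove[idx[0]] = True
    return OutlierReport(
        retained=x[~remove],
        removed=x[remove],
        removed_labels=cls.labels[remove],
        dixon_flagged=np.asarray(dixon_vals, dtype=float),
        classification=cls,
        dixon=dixon,
        input_values=x,
        removed_mask=remove,
    )


def outlier_report_frame(report: OutlierReport):
    """Tabular (CSV-ready) view of an outlier report: value, label, action."""
    import pandas as pd

    flagged = set(np.asarray(report.dixon_flagged).tolist())
    return pd.DataFrame(
        {
            "value": report.input_values,
            "label": report.classification.labels,
            "test": [
                "tukey+dixon-reed" if v in flagged else "tukey"
                for v in report.input_values
            ],
            "action": np.where(report.removed_mask, "removed", "retained"),
        }
    )
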