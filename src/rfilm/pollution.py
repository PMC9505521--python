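"""Residual-film pollution evaluation.

The pollution index is the film coverage rate

    L = 100 * (number of film pixels) / (M * N)            [percent]

computed exactly from integer pixel counts.  Predicted coverage (L1) is
validated against true coverage (L2) with a prediction R-squared

    R2 = 1 - sum (L2 - L1)^2 / sum (L2 - mean(L2))^2,

the root-mean-square error of L1 vs. L2, and the mean relative error
MRE = mean(|L1 - L2| / L2) * 100%.  Note R2 is computed on the raw
prediction residuals, not on a fitted line, so it can be negative for poor
predictors; the slope and intercept of an ordinary least-squares fit of L1
on L2 are reported separately.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from rfilm.dataio import BinaryMask, FieldImage

logger = logging.getLogger(__name__)

__all__ = [
    "CoverageRecord",
    "RegressionReport",
    "coverage_rate",
    "regression_eval",
    "pollution_report",
    "PollutionReport",
]


@dataclass(frozen=True)
class CoverageRecord:
    """Coverage rate of one image, with the exact pixel counts behind it."""

    source_id: str
    l_pct: float
    n_film_pixels: int
    n_total_pixels: int


@dataclass(frozen=True)
class RegressionReport:
    """Agreement of predicted vs. true coverage rates over a test set."""

    n: int
    r_squared: float
    rmse: float
    mre_pct: float
    slope: float
    intercept: float
    n_excluded_zero_truth: int = 0


@dataclass
class PollutionReport:
    coverage: list[CoverageRecord]
    regression: RegressionReport | None = None
    degree_labels: list[str] | None = None


def coverage_rate(mask: BinaryMask | np.ndarray, source_id: str = "") -> CoverageRecord:
    """Exact film coverage rate of a binary mask, in percent."""
    labels = mask.labels if isinstance(mask, BinaryMask) else np.asarray(mask)
    if labels.size == 0:
        raise ValueError("empty mask")
    n_film = int(np.count_nonzero(labels))
    n_total = int(labels.size)
    return CoverageRecord(source_id, 100.0 * n_film / n_total, n_film, n_total)


def regression_eval(pred: list[float], truth: list[float]) -> RegressionReport:
    """Validate predicted coverage rates (L1) against true ones (L2).

    Pairs with zero true coverage are excluded from the MRE (relative error
    is undefined there) with a logged warning; they still enter R2, RMSE
    and the OLS fit.
    """
    l1 = np.asarray(pred, dtype=float)
    l2 = np.asarray(truth, dtype=float)
    if l1.shape != l2.shape:
        raise ValueError("pred and truth must have equal length")
    n = l1.size
    if n < 2:
        raise ValueError("need at least 2 pairs for regression")
    ss_tot = float(np.sum((l2 - l2.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("true coverage values are all identical; R2 undefined")
    r_squared = 1.0 - float(np.sum((l2 - l1) ** 2)) / ss_tot
    rmse = float(np.sqrt(np.mean((l1 - l2) ** 2)))
    nonzero = l2 > 0
    n_excluded = int(np.count_nonzero(~nonzero))
    if n_excluded == n:
        raise ValueError("all true coverage values are zero; MRE undefined")
    if n_excluded:
        msg = f"excluding {n_excluded} zero-truth pair(s) from MRE"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    mre_pct = 100.0 * float(np.mean(np.abs(l1[nonzero] - l2[nonzero]) / l2[nonzero]))
    slope, intercept = np.polyfit(l2, l1, 1)
    return RegressionReport(n, r_squared, rmse, mre_pct, float(slope), float(intercept), n_excluded)


def assign_degree(l_pct: float, thresholds: list[float], labels: list[str]) -> str:
    """Map a coverage rate to a user-defined pollution-degree label.

    ``thresholds`` are strictly increasing upper bounds; ``labels`` has one
    more entry than ``thresholds`` (the last label is open-ended).
    """
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError(f"thresholds must be strictly increasing, got {thresholds}")
    if len(labels) != len(thresholds) + 1:
        raise ValueError("need exactly one more label than thresholds")
    for bound, label in zip(thresholds, labels):
        if l_pct < bound:
            return label
    return labels[-1]


def pollution_report(
    model,
    images: list[FieldImage],
    truth_masks: list[BinaryMask] | None = None,
    degree_thresholds: list[float] | None = None,
    degree_labels: list[str] | None = None,
) -> PollutionReport:
    """Predict masks for ``images`` and summarise the pollution they show.

    When ground-truth masks are supplied a :class:`RegressionReport` of
    predicted vs. true coverage is included.  Optional strictly increasing
    ``degree_thresholds`` map each coverage rate to a pollution-degree
    label.
    """
    from rfilm.model import predict_mask

    records = []
    preds = []
    for img in images:
        mask = predict_mask(model, img)
        preds.append(mask)
        records.append(coverage_rate(mask, source_id=img.source_id))

    regression = None
    if truth_masks is not None:
        if len(truth_masks) != len(images):
            raise ValueError("truth_masks length must match images")
        l1 = [r.l_pct for r in records]
        l2 = [coverage_rate(m).l_pct for m in truth_masks]
        regression = regression_eval(l1, l2)

    degrees = None
    if degree_thresholds is not None:
        if degree_labels is None:
            degree_labels = [f"degree_{i}" for i in range(len(degree_thresholds) + 1)]
        degrees = [assign_degree(r.l_pct, degree_thresholds, degree_labels) for r in records]

    return PollutionReport(coverage=records, regression=regression, degree_labels=degrees)
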