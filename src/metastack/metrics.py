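"""Scalar performance metrics and their comparison arithmetic.

MAE for the continuous outcome; AUC (Mann-Whitney, ties at 1/2) and
calibration-in-the-large for the binary outcome; percentile bootstrap
confidence intervals; and the two percent-change conventions used in
reporting — plain relative change for MAE, and baseline-adjusted change
for AUC, where 0.5 (chance discrimination) is subtracted from both AUCs
before the relative change is taken.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

from .exceptions import InvalidArgument, UndefinedAUC, UndefinedChange


@dataclass(frozen=True)
class MetricValue:
    name: str
    value: float
    n: int


def mae(y, yhat) -> MetricValue:
    """Mean absolute error."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise InvalidArgument("y and yhat must have equal length")
    if y.size == 0:
        raise InvalidArgument("MAE of an empty vector is undefined")
    return MetricValue("MAE", float(np.mean(np.abs(y - yhat))), y.size)


def auc(y, p) -> MetricValue:
    """Area under the ROC curve (Mann-Whitney form; ties count 1/2)."""
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if y.shape != p.shape or y.size == 0:
        raise InvalidArgument("y and p must be equal-length, non-empty")
    if np.unique(y).size < 2:
        raise UndefinedAUC("AUC needs both outcome classes present")
    return MetricValue("AUC", float(roc_auc_score(y, p)), y.size)


def calibration_in_the_large(y, p) -> tuple[float, float, float]:
    """Return (mean predicted probability, observed event rate, difference).

    No recalibration is performed; the difference (mean_pred - rate) is the
    average over- or under-estimation of risk.
    """
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if y.shape != p.shape or y.size == 0:
        raise InvalidArgument("y and p must be equal-length, non-empty")
    if np.any((p < 0) | (p > 1)):
        raise InvalidArgument("predicted probabilities must lie in [0, 1]")
    mean_pred = float(np.mean(p))
    rate = float(np.mean(y))
    return mean_pred, rate, mean_pred - rate


def adjusted_auc_pct_change(auc_ref: float, auc_new: float) -> float:
    """Percent change in AUC after subtracting the 0.5 chance baseline.

    100 * [(auc_new - 0.5) - (auc_ref - 0.5)] / (auc_ref - 0.5); positive
    means the new model discriminates better.
    """
    if auc_ref <= 0.5:
        raise UndefinedChange("baseline-adjusted change undefined for reference AUC <= 0.5")
    return 100.0 * ((auc_new - 0.5) - (auc_ref - 0.5)) / (auc_ref - 0.5)


def pct_change_mae(mae_ref: float, mae_new: float) -> float:
    """Plain relative MAE change, positive = improvement (error went down)."""
    if mae_ref <= 0:
        raise InvalidArgument("reference MAE must be > 0")
    return 100.0 * (mae_ref - mae_new) / mae_ref


def percentile_ci(values, lo: float = 2.5, hi: float = 97.5) -> tuple[float, float]:
    """Percentile bootstrap interval, linear-interpolation quantile rule."""
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < 2:
        raise InvalidArgument("percentile CI needs >= 2 finite replicate values")
    if not (0.0 <= lo < hi <= 100.0):
        raise InvalidArgument("percentile bounds must satisfy 0 <= lo < hi <= 100")
    low, high = np.quantile(values, [lo / 100.0, hi / 100.0], method="linear")
    return float(low), float(high)
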