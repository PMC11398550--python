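"""Regression metrics and paired model comparison.

Thin wrappers over scikit-learn and scipy.stats that add explicit flagging of
degenerate cases (zero-variance vectors) instead of silently returning 0 or
raising deep inside a pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats
from sklearn.metrics import mean_absolute_error, mean_squared_error, r2_score

from .errors import ContractError


@dataclass(frozen=True)
class MetricsRecord:
    """RMSE, MAE, R² and Pearson correlation for one prediction set.

    Undefined quantities are NaN with the reason recorded in ``flags``
    (``r2_undefined`` when the targets have zero variance;
    ``pearson_undefined`` when either vector is constant).
    """

    rmse: float
    mae: float
    r2: float
    pearson: float
    flags: tuple = ()


def compute_metrics(y_true, y_pred) -> MetricsRecord:
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ContractError("y_true and y_pred must be equal-length 1-D vectors")
    if len(y_true) < 2:
        raise ContractError("need at least 2 observations")
    flags = []
    rmse = float(np.sqrt(mean_squared_error(y_true, y_pred)))
    mae = float(mean_absolute_error(y_true, y_pred))
    if np.var(y_true) == 0.0:
        r2 = float("nan")
        flags.append("r2_undefined")
    else:
        r2 = float(r2_score(y_true, y_pred))
    if np.var(y_true) == 0.0 or np.var(y_pred) == 0.0:
        pearson = float("nan")
        flags.append("pearson_undefined")
    else:
        pearson = float(stats.pearsonr(y_true, y_pred).statistic)
    return MetricsRecord(rmse=rmse, mae=mae, r2=r2, pearson=pearson,
                         flags=tuple(flags))


class ComparisonResult(NamedTuple):
    p_value: float
    degenerate: bool


def compare_models(metric_a, metric_b, test: str = "wilcoxon") -> ComparisonResult:
    """Two-sided paired test on per-fold metric differences.

    Wilcoxon signed-rank by default (robust for small fold counts); a paired
    t-test is selectable.  All-zero differences are degenerate: p = 1 by
    convention with the flag set.
    """
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ContractError("paired metric vectors must have equal length")
    if len(a) < 5:
        raise ContractError("need at least 5 paired folds")
    diffs = a - b
    if np.all(diffs == 0):
        return ComparisonResult(p_value=1.0, degenerate=True)
    if test == "wilcoxon":
        p = float(stats.wilcoxon(a, b, alternative="two-sided").pvalue)
    elif test == "ttest":
        p = float(stats.ttest_rel(a, b).pvalue)
    else:
        raise ContractError(f"unknown test {test!r}")
    return ComparisonResult(p_value=min(max(p, 0.0), 1.0), degenerate=False)
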