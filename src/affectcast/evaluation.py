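"""Evaluation protocol: pooled Pearson r, paired significance, order sweeps,
seasonal error breakdown.

Pearson correlation between forecasts and realized changes is the headline
metric: it is invariant to the scale of the target, so forecasting
difficulty is directly comparable across affect dimensions.  Model pairs
are compared with a paired t-test on per-prediction squared errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, sem, ttest_rel

__all__ = [
    "Prediction",
    "EvalReport",
    "predictions_frame",
    "pearson_r",
    "compare_models",
    "order_sweep",
    "seasonal_error",
]


@dataclass
class Prediction:
    """One aligned forecast/truth pair."""

    user_id: str
    target_index: int
    y_hat: float
    y_true: float
    model_id: str = ""
    calendar: Optional[tuple] = None  # (year, month)


@dataclass
class EvalReport:
    """Summary of one model on one split."""

    model_id: str
    split: str
    r: float
    n: int
    per_fold_r: list = field(default_factory=list)
    significance: dict = field(default_factory=dict)


def predictions_frame(predictions: Sequence[Prediction]) -> pd.DataFrame:
    """Delimited-table form: user_id, target_index, y_hat, y_true, model_id."""
    return pd.DataFrame(
        [
            (p.user_id, p.target_index, p.y_hat, p.y_true, p.model_id)
            for p in predictions
        ],
        columns=["user_id", "target_index", "y_hat", "y_true", "model_id"],
    )


def _arrays(predictions) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(predictions, pd.DataFrame):
        return predictions["y_hat"].to_numpy(), predictions["y_true"].to_numpy()
    return (
        np.array([p.y_hat for p in predictions]),
        np.array([p.y_true for p in predictions]),
    )


def pearson_r(predictions) -> float:
    """Sample Pearson correlation pooled over all (user, time) pairs.

    Accepts a sequence of :class:`Prediction` or a predictions DataFrame.
    """
    y_hat, y_true = _arrays(predictions)
    if len(y_hat) < 3:
        raise ValueError("need at least 3 prediction pairs")
    if np.std(y_hat) == 0 or np.std(y_true) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(pearsonr(y_hat, y_true)[0])


def compare_models(preds_a, preds_b) -> float:
    """Two-sided paired t-test p-value on per-prediction squared errors.

    Prediction sets must cover identical (user_id, target_index) keys;
    identical error vectors give p = 1.0 (zero mean difference carries no
    evidence of a difference).
    """
    fa = preds_a if isinstance(preds_a, pd.DataFrame) else predictions_frame(preds_a)
    fb = preds_b if isinstance(preds_b, pd.DataFrame) else predictions_frame(preds_b)
    fa = fa.set_index(["user_id", "target_index"]).sort_index()
    fb = fb.set_index(["user_id", "target_index"]).sort_index()
    if not fa.index.equals(fb.index):
        raise ValueError("prediction sets are not aligned on (user, target_index)")
    if len(fa) < 3:
        raise ValueError("need at least 3 paired predictions")
    err_a = (fa["y_hat"] - fa["y_true"]).to_numpy() ** 2
    err_b = (fb["y_hat"] - fb["y_true"]).to_numpy() ** 2
    diffs = err_a - err_b
    if np.allclose(diffs, 0.0):
        return 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(ttest_rel(err_a, err_b)[1])


def order_sweep(
    base_spec,
    p_values: Sequence[int],
    series,
    plan,
    modes: Sequence[str] = ("fixed", "dynamic"),
) -> pd.DataFrame:
    """Train one model per (order p, order mode) and evaluate OOS-Time r.

    Orders exceeding the usable history are skipped with a warning.
    Returns a tidy frame with columns p, mode, r, n.
    """
    from dataclasses import replace

    from .pipeline import run_fold

    rows = []
    for mode in modes:
        for p in p_values:
            spec = replace(base_spec, order_p=p, order_mode=mode)
            try:
                result = run_fold(series, plan, spec)
            except ValueError as exc:
                warnings.warn(f"skipping p={p} mode={mode}: {exc}")
                continue
            frame = result["oos_time"]
            rows.append((p, mode, pearson_r(frame), len(frame)))
    return pd.DataFrame(rows, columns=["p", "mode", "r", "n"])


def seasonal_error(predictions, calendar=None) -> pd.DataFrame:
    """Mean squared error grouped by calendar month (across years).

    ``calendar`` supplies (year, month) labels when the predictions do not
    carry them.  Returns one row per observed month with the mean squared
    error, its standard error, the prediction count and distinct users.
    """
    if isinstance(predictions, pd.DataFrame):
        df = predictions.copy()
        if "month" not in df.columns:
            raise ValueError("DataFrame input needs a 'month' column")
    else:
        cal = (
            [p.calendar for p in predictions]
            if calendar is None
            else list(calendar)
        )
        if any(c is None for c in cal):
            raise ValueError("calendar labels are required for seasonal grouping")
        df = predictions_frame(predictions)
        df["month"] = [c[1] for c in cal]
    df["sq_error"] = (df["y_hat"] - df["y_true"]) ** 2
    out = (
        df.groupby("month")
        .agg(
            mse=("sq_error", "mean"),
            se=("sq_error", lambda v: sem(v) if len(v) > 1 else 0.0),
            n=("sq_error", "size"),
            n_users=("user_id", "nunique"),
        )
        .reset_index()
    )
    return out
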