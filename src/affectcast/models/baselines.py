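"""Zero-rule baselines: repeat the last change, or average past changes."""

from __future__ import annotations

import numpy as np

from ..dataset import TrainingExample

__all__ = ["predict_last", "predict_mean", "LastBaseline", "MeanBaseline"]


def predict_last(ex: TrainingExample) -> float:
    """Most recent *observed* history change (the last(1) baseline)."""
    obs = np.flatnonzero(ex.history_mask > 0)
    if obs.size == 0:
        raise ValueError("all history steps are masked; nothing to repeat")
    return float(ex.history_Y[obs[-1]])


def predict_mean(ex: TrainingExample, window: int = 14) -> float:
    """Mean of observed history changes over the trailing window (mean(14))."""
    y = ex.history_Y[-window:]
    m = ex.history_mask[-window:] > 0
    if not m.any():
        raise ValueError("all history steps in the window are masked")
    return float(y[m].mean())


class LastBaseline:
    """Fit-free forecaster wrapping :func:`predict_last`.

    A fully masked history window falls back to predicting 0: baselines
    have no missing-data machinery, so an unobserved change reads as
    "no change".
    """

    def __init__(self, spec=None):
        self.spec = spec

    def fit(self, examples, validation_examples=None):
        return self

    def predict(self, examples) -> np.ndarray:
        out = np.empty(len(examples))
        for i, ex in enumerate(examples):
            try:
                out[i] = predict_last(ex)
            except ValueError:
                out[i] = 0.0
        return out


class MeanBaseline:
    """Fit-free forecaster wrapping :func:`predict_mean` (same no-change
    fallback as :class:`LastBaseline` for fully masked windows)."""

    def __init__(self, spec=None, window: int = 14):
        self.spec = spec
        self.window = window

    def fit(self, examples, validation_examples=None):
        return self

    def predict(self, examples) -> np.ndarray:
        out = np.empty(len(examples))
        for i, ex in enumerate(examples):
            try:
                out[i] = predict_mean(ex, self.window)
            except ValueError:
                out[i] = 0.0
        return out
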