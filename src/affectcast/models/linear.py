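"""Lagged-feature regressors: ridge autoregression, linear SVR, gradient boosting.

These consume flattened length-p lag vectors (target changes, plus
covariate changes when multivariate), standardized with training-fold
statistics, masked cells zero-filled.  Regularization strength is chosen
on validation examples by Pearson correlation when they are provided.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import pearsonr
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.linear_model import Ridge
from sklearn.svm import SVR

from ..dataset import Standardizer, TrainingExample
from .spec import ModelSpec

__all__ = ["LinearForecaster", "fit_linear_family"]

_RIDGE_ALPHAS = (0.01, 0.1, 1.0, 10.0, 100.0)
_SVR_CS = (0.01, 0.1, 1.0, 10.0)


def _features(examples, spec: ModelSpec, standardizer: Standardizer) -> np.ndarray:
    rows = []
    for ex in examples:
        if ex.order != spec.order_p:
            raise ValueError(
                f"example order {ex.order} does not match spec order {spec.order_p}"
            )
        obs = ex.history_mask > 0
        y = standardizer.transform_y(ex.history_Y) * obs
        parts = [y]
        if spec.input_mode == "multivariate" and ex.history_X is not None:
            x = standardizer.transform_x(ex.history_X) * obs[:, None]
            parts.append(x.ravel())
        rows.append(np.concatenate(parts))
    return np.vstack(rows)


class LinearForecaster:
    """Ridge / linear-kernel SVR / gradient-boosting forecaster on lag features."""

    def __init__(self, spec: ModelSpec):
        if spec.family not in ("ar_ridge", "svr", "gbr"):
            raise ValueError(f"not a lagged-feature family: {spec.family}")
        self.spec = spec
        self.standardizer = Standardizer()
        self.estimator = None
        self.chosen_hyper = None

    def _make(self, strength: float):
        if self.spec.family == "ar_ridge":
            return Ridge(alpha=strength)
        if self.spec.family == "svr":
            return SVR(kernel="linear", C=strength)
        return GradientBoostingRegressor(random_state=self.spec.seed)

    def fit(self, examples, validation_examples=None) -> "LinearForecaster":
        if not examples:
            raise ValueError("no training examples")
        self.standardizer.fit(examples)
        X = _features(examples, self.spec, self.standardizer)
        y = np.array([ex.target for ex in examples])
        if self.spec.family == "gbr":
            grid = [None]
        elif "alpha" in self.spec.hyperparams:
            grid = [float(self.spec.hyperparams["alpha"])]
        else:
            grid = list(_RIDGE_ALPHAS if self.spec.family == "ar_ridge" else _SVR_CS)
        best, best_r = None, -np.inf
        for strength in grid:
            est = self._make(strength if strength is not None else 0.0)
            est.fit(X, y)
            if len(grid) == 1 or not validation_examples:
                best, self.chosen_hyper = est, strength
                break
            val_pred = est.predict(
                _features(validation_examples, self.spec, self.standardizer)
            )
            val_true = np.array([ex.target for ex in validation_examples])
            if np.std(val_pred) == 0 or np.std(val_true) == 0:
                r = -np.inf
            else:
                r = pearsonr(val_pred, val_true)[0]
            if r > best_r:
                best, best_r, self.chosen_hyper = est, r, strength
        self.estimator = best
        return self

    def predict(self, examples) -> np.ndarray:
        if self.estimator is None:
            raise RuntimeError("forecaster is not fitted")
        return self.estimator.predict(_features(examples, self.spec, self.standardizer))

    @property
    def coefficients(self) -> np.ndarray:
        """Linear coefficients on the *raw* change scale (ridge/SVR only).

        Features are standardized internally, so coefficients are mapped
        back by dividing by the feature scale; lag order matches
        ``history_Y`` (oldest first).
        """
        coef = getattr(self.estimator, "coef_", None)
        if coef is None:
            raise AttributeError("estimator exposes no linear coefficients")
        coef = np.ravel(coef)
        p = self.spec.order_p
        scaled = coef.copy()
        scaled[:p] = coef[:p] / self.standardizer.y_std
        return scaled


def fit_linear_family(
    examples, spec: ModelSpec, validation_examples=None
) -> LinearForecaster:
    """Fit one of the lagged-feature regressors per ``spec``."""
    return LinearForecaster(spec).fit(examples, validation_examples)
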