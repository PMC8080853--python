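"""Deep averaging network: a non-sequential neural comparator.

The DAN discards order entirely: it consumes the per-dimension mean of the
observed history changes (the same information as the mean(14) baseline)
through two dense layers with a sigmoid between them.  Hidden width is 2
for univariate input and 35 for multivariate.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .._autodiff import Tensor
from ..dataset import Standardizer, TrainingExample
from .spec import ModelSpec

__all__ = ["DANForecaster", "dan_forward"]


def dan_forward(mean_features: np.ndarray, params) -> float:
    """Affine -> sigmoid -> affine on a window-mean feature vector.

    ``params`` is a :class:`DANForecaster` or a (W1, b1, W2, b2) tuple.
    """
    if isinstance(params, DANForecaster):
        w1, b1, w2, b2 = (p.data for p in params.parameters())
    else:
        w1, b1, w2, b2 = (np.asarray(p, dtype=float) for p in params)
    x = np.atleast_2d(np.asarray(mean_features, dtype=float))
    hidden = 1.0 / (1.0 + np.exp(-(x @ w1 + b1)))
    return float((hidden @ w2 + b2)[0, 0])


class DANForecaster:
    """Trainable deep averaging network over window-mean change features."""

    def __init__(self, spec: ModelSpec, n_covariates: int = 0):
        if spec.family != "dan":
            raise ValueError("spec.family must be 'dan'")
        self.spec = spec
        self.n_covariates = n_covariates
        self.standardizer = Standardizer()
        d = 1 + (n_covariates if spec.input_mode == "multivariate" else 0)
        hidden = spec.hyperparams.get(
            "dan_hidden", 2 if spec.input_mode == "univariate" else 35
        )
        rng = np.random.default_rng(spec.seed)
        a = 1.0 / np.sqrt(max(hidden, 1))
        self.W1 = Tensor(rng.uniform(-a, a, (d, hidden)), requires_grad=True)
        self.b1 = Tensor(np.zeros(hidden), requires_grad=True)
        self.W2 = Tensor(rng.uniform(-a, a, (hidden, 1)), requires_grad=True)
        self.b2 = Tensor(np.zeros(1), requires_grad=True)

    def parameters(self) -> list[Tensor]:
        return [self.W1, self.b1, self.W2, self.b2]

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def setup(self, train_examples: Sequence[TrainingExample]) -> None:
        self.standardizer.fit(train_examples)

    def _features(self, ex: TrainingExample) -> np.ndarray:
        obs = ex.history_mask > 0
        if not obs.any():
            raise ValueError("all history steps are masked")
        parts = [self.standardizer.transform_y(ex.history_Y[obs]).mean(keepdims=True)]
        if self.spec.input_mode == "multivariate":
            if ex.history_X is None:
                raise ValueError("multivariate DAN given univariate example")
            parts.append(self.standardizer.transform_x(ex.history_X[obs]).mean(axis=0))
        return np.concatenate(parts)

    def _batch_arrays(self, examples: Sequence[TrainingExample]):
        feats = np.vstack([self._features(ex) for ex in examples])
        targets = self.standardizer.transform_y(
            np.array([ex.target for ex in examples])
        )
        return [
            {
                "x": feats,
                "target": targets,
                "index": np.arange(len(examples)),
            }
        ]

    def _forward_arrays(self, x: np.ndarray) -> Tensor:
        hidden = (Tensor(x) @ self.W1 + self.b1).sigmoid()
        return hidden @ self.W2 + self.b2

    def loss_on(self, batch) -> Tensor:
        pred = self._forward_arrays(batch["x"])
        err = pred.reshape(-1) - Tensor(batch["target"])
        return (err * err).mean()

    def predict(self, examples: Sequence[TrainingExample]) -> np.ndarray:
        out = np.empty(len(examples))
        for batch in self._batch_arrays(examples):
            pred = self._forward_arrays(batch["x"])
            out[batch["index"]] = self.standardizer.inverse_y(pred.data.ravel())
        return out

    def fit(self, examples, validation_examples=None) -> "DANForecaster":
        from .training import train

        train(self, examples, validation_examples, self.spec)
        return self
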