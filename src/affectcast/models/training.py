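"""Shared gradient-descent training loop for the neural forecasters.

Minimizes one-step-ahead mean squared error with Adam; model selection is
early stopping on validation Pearson r (the task's evaluation metric).
Fully deterministic given the spec's seed.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy.stats import pearsonr

from .._autodiff import Adam
from ..dataset import TrainingExample
from .spec import ModelSpec

__all__ = ["train"]


def _validation_r(model, examples) -> float:
    pred = model.predict(examples)
    truth = np.array([ex.target for ex in examples])
    if np.std(pred) == 0 or np.std(truth) == 0 or not np.all(np.isfinite(pred)):
        return -np.inf
    return float(pearsonr(pred, truth)[0])


def _snapshot(params) -> list[np.ndarray]:
    return [p.data.copy() for p in params]


def _restore(params, snap) -> None:
    for p, s in zip(params, snap):
        p.data = s.copy()


def train(
    model,
    examples: Sequence[TrainingExample],
    validation_examples: Optional[Sequence[TrainingExample]],
    spec: ModelSpec,
) -> dict:
    """Fit ``model`` in place; returns the training history.

    The model must expose ``setup``, ``parameters``, ``_batch_arrays``,
    ``loss_on`` and ``predict``.  When validation examples are given, the
    parameters attaining the best validation Pearson r are kept and
    training stops after ``spec.patience`` epochs without improvement;
    otherwise the final epoch's parameters are kept.  A non-finite loss
    aborts training, restoring the last finite-loss parameters.
    """
    if not examples:
        raise ValueError("no training examples")
    rng = np.random.default_rng(spec.seed)
    model.setup(examples)
    params = model.parameters()
    opt = Adam(params, lr=spec.learning_rate)
    groups = model._batch_arrays(examples)

    history = {"train_loss": [], "val_r": [], "best_epoch": None, "stopped_epoch": None}
    best_snap = _snapshot(params)
    best_r = -np.inf
    last_good = _snapshot(params)
    stale = 0

    for epoch in range(spec.max_epochs):
        epoch_loss, n_batches = 0.0, 0
        for g in groups:
            n = len(g["target"])
            order = rng.permutation(n)
            for lo in range(0, n, spec.batch_size):
                sel = order[lo : lo + spec.batch_size]
                batch = {
                    k: v[sel] for k, v in g.items() if isinstance(v, np.ndarray)
                }
                loss = model.loss_on(batch)
                if not np.isfinite(loss.data):
                    _restore(params, last_good)
                    history["stopped_epoch"] = epoch
                    history["aborted"] = True
                    return history
                opt.zero_grad()
                loss.backward()
                opt.step()
                epoch_loss += float(loss.data)
                n_batches += 1
        history["train_loss"].append(epoch_loss / max(n_batches, 1))
        last_good = _snapshot(params)

        if validation_examples:
            r = _validation_r(model, validation_examples)
            history["val_r"].append(r)
            if r > best_r:
                best_r, best_snap = r, _snapshot(params)
                history["best_epoch"] = epoch
                stale = 0
            else:
                stale += 1
                if stale >= spec.patience:
                    history["stopped_epoch"] = epoch
                    break

    if validation_examples and history["best_epoch"] is not None:
        _restore(params, best_snap)
    if history["stopped_epoch"] is None:
        history["stopped_epoch"] = len(history["train_loss"]) - 1
    return history
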