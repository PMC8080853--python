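"""Attention-GRU forecasters with hidden-state and input decay.

The recurrent ladder: a gated recurrent unit unrolled over the history of
changes, a learned shared initial hidden state, attention pooling over the
per-step hidden states, and an affine output head.  Two decay variants
handle irregular observation:

* GRU-DS decays the carried hidden state across time gaps,
  ``h_hat = gamma_h * h`` with ``gamma = exp(-max(0, W delta + b))``;
* GRU-D additionally imputes unobserved inputs toward the training mean,
  ``x_hat = m*x + (1-m)*(gamma_x*x_last + (1-gamma_x)*x_mean)``.

The dual-sequence architecture runs two parallel branches — a pure
autoregression over past target changes and a covariate branch — each with
its own attention and output head, combined by a learned scalar weight
initialized at 0.6/0.4 (target/context).

Gate convention (one step, input x, carried state h):

    z = sigmoid(x Wz + h Uz + bz)          update gate
    r = sigmoid(x Wr + h Ur + br)          reset gate, bias initialized -1
    n = tanh(x Wn + r * (h Un) + bn)       candidate state
    h' = z * h + (1 - z) * n
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .._autodiff import Adam, Tensor, softmax
from ..dataset import Standardizer, TrainingExample
from .spec import GRU_FAMILIES, ModelSpec

__all__ = [
    "RecurrentState",
    "init_state",
    "attention_pool",
    "apply_decay",
    "gru_forward",
    "dual_forward",
    "GRUForecaster",
]


@dataclass
class RecurrentState:
    """Parameters (and current hidden state) of one recurrent branch."""

    Wz: Tensor
    Uz: Tensor
    bz: Tensor
    Wr: Tensor
    Ur: Tensor
    br: Tensor
    Wn: Tensor
    Un: Tensor
    bn: Tensor
    h0: Tensor  # shared learnable initial hidden state, (1, H)
    Wa: Tensor  # attention score weights, (H, 1)
    Ba: Tensor  # attention score bias, (1,)
    Wo: Tensor  # output head, (H, 1)
    bo: Tensor  # output bias, (1,)
    w_gx: Optional[Tensor] = None  # input-decay weights, per input dim
    b_gx: Optional[Tensor] = None
    W_gh: Optional[Tensor] = None  # hidden-decay weights, (D, H)
    b_gh: Optional[Tensor] = None
    hidden: Optional[Tensor] = None  # current hidden state during unrolling

    def parameters(self) -> list[Tensor]:
        named = [
            self.Wz, self.Uz, self.bz, self.Wr, self.Ur, self.br,
            self.Wn, self.Un, self.bn, self.h0, self.Wa, self.Ba,
            self.Wo, self.bo, self.w_gx, self.b_gx, self.W_gh, self.b_gh,
        ]
        return [p for p in named if p is not None]

    @property
    def hidden_size(self) -> int:
        return self.h0.shape[1]

    @property
    def input_size(self) -> int:
        return self.Wz.shape[0]


def init_state(
    input_dim: int,
    hidden_size: int,
    rng: np.random.Generator,
    input_decay: bool = False,
    hidden_decay: bool = False,
) -> RecurrentState:
    """Freshly initialized branch parameters.

    Weights are uniform in +-1/sqrt(H); reset-gate biases start at -1
    (favoring retention of the carried state); the learned initial hidden
    state starts at zero.  Decay parameters start small but positive:
    gamma = exp(-max(0, W delta + b)) has a dead gradient at exactly zero,
    so a zero start could never learn to decay, while a small positive
    start (gamma near 0.9 at unit gaps) keeps the behavior close to a
    plain GRU and trainable.
    """
    a = 1.0 / np.sqrt(hidden_size)

    def u(*shape):
        return Tensor(rng.uniform(-a, a, shape), requires_grad=True)

    def z(*shape):
        return Tensor(np.zeros(shape), requires_grad=True)

    def dk(*shape):
        return Tensor(rng.uniform(0.01, 0.1, shape), requires_grad=True)

    return RecurrentState(
        Wz=u(input_dim, hidden_size), Uz=u(hidden_size, hidden_size), bz=z(hidden_size),
        Wr=u(input_dim, hidden_size), Ur=u(hidden_size, hidden_size),
        br=Tensor(-np.ones(hidden_size), requires_grad=True),
        Wn=u(input_dim, hidden_size), Un=u(hidden_size, hidden_size), bn=z(hidden_size),
        h0=z(1, hidden_size),
        Wa=u(hidden_size, 1), Ba=z(1),
        Wo=u(hidden_size, 1), bo=z(1),
        w_gx=dk(input_dim) if input_decay else None,
        b_gx=dk(input_dim) if input_decay else None,
        W_gh=dk(input_dim, hidden_size) if hidden_decay else None,
        b_gh=dk(hidden_size) if hidden_decay else None,
    )


def _gru_step(state: RecurrentState, x: Tensor, h: Tensor) -> Tensor:
    zg = (x @ state.Wz + h @ state.Uz + state.bz).sigmoid()
    rg = (x @ state.Wr + h @ state.Ur + state.br).sigmoid()
    n = (x @ state.Wn + rg * (h @ state.Un) + state.bn).tanh()
    return zg * h + (1.0 - zg) * n


def _attend(state: RecurrentState, hs: Sequence[Tensor]) -> Tensor:
    """Attention pooling over the per-step hidden states (batched)."""
    scores = [h.tanh() @ state.Wa + state.Ba for h in hs]
    weights = softmax(Tensor.concat(scores, axis=1), axis=1)
    pooled = weights[:, 0:1] * hs[0]
    for t in range(1, len(hs)):
        pooled = pooled + weights[:, t : t + 1] * hs[t]
    return pooled


def attention_pool(H: np.ndarray, params) -> np.ndarray:
    """Pool a p x H hidden stack into one vector.

    Scores each time-step's tanh-squashed hidden state to a scalar, takes a
    softmax over time, and returns the weighted sum of the (raw) hidden
    states.  ``params`` is a :class:`RecurrentState` or a ``(W, B)`` pair.
    """
    if isinstance(params, RecurrentState):
        w, b = params.Wa.data, params.Ba.data
    else:
        w, b = (np.asarray(p, dtype=float) for p in params)
    H = np.atleast_2d(np.asarray(H, dtype=float))
    scores = np.tanh(H) @ w.reshape(-1, 1) + b.reshape(1, 1)
    scores = scores.ravel()
    e = np.exp(scores - scores.max())
    weights = e / e.sum()
    return weights @ H


def apply_decay(
    state: RecurrentState,
    delta,
    mask,
    x,
    x_last,
    x_mean,
    mode: str = "full_d",
):
    """Decay-adjust one step's input and the carried hidden state.

    ``full_d`` imputes unobserved inputs toward the training mean and
    decays the hidden state; ``ds`` decays the hidden state only, passing
    inputs through.  All array arguments broadcast against (batch, D).
    Returns ``(x_hat, h_hat)`` as Tensors.
    """
    if mode not in ("full_d", "ds"):
        raise ValueError(f"unknown decay mode: {mode!r}")
    delta_a = np.atleast_2d(np.asarray(delta, dtype=float))
    if np.any(delta_a < 0):
        raise ValueError("negative time gaps are not meaningful")
    delta_t = Tensor(delta_a)
    x_t = x if isinstance(x, Tensor) else Tensor(np.atleast_2d(x))

    if mode == "full_d":
        if state.w_gx is None:
            raise ValueError("state has no input-decay parameters")
        m = Tensor(np.atleast_2d(np.asarray(mask, dtype=float)))
        gx = (-(delta_t * state.w_gx + state.b_gx).relu()).exp()
        x_hat = m * x_t + (1.0 - m) * (
            gx * Tensor(np.atleast_2d(x_last)) + (1.0 - gx) * Tensor(np.atleast_2d(x_mean))
        )
    else:
        x_hat = x_t

    h = state.hidden if state.hidden is not None else state.h0
    if state.W_gh is not None:
        gh = (-(delta_t @ state.W_gh + state.b_gh).relu()).exp()
        h_hat = gh * h
    else:
        h_hat = h
    return x_hat, h_hat


def _branch_forward(
    state: RecurrentState,
    inputs: np.ndarray,  # (B, T, D)
    mask: np.ndarray,
    delta: np.ndarray,
    x_last: np.ndarray,
    x_mean: np.ndarray,
    family: str,
) -> Tensor:
    """Unroll one branch over T steps and return (B, 1) predictions."""
    b, t_len, _ = inputs.shape
    state.hidden = None
    hs: list[Tensor] = []
    for t in range(t_len):
        if family == "gru_d":
            x_hat, h = apply_decay(
                state, delta[:, t], mask[:, t], inputs[:, t], x_last[:, t], x_mean,
                mode="full_d",
            )
        elif family == "gru_ds":
            x_hat, h = apply_decay(
                state, delta[:, t], mask[:, t], inputs[:, t], x_last[:, t], x_mean,
                mode="ds",
            )
        else:
            x_hat = Tensor(inputs[:, t])
            h = state.hidden if state.hidden is not None else state.h0
        state.hidden = _gru_step(state, x_hat, h)
        hs.append(state.hidden)
    pooled = _attend(state, hs)
    out = pooled @ state.Wo + state.bo
    if not np.all(np.isfinite(out.data)):
        raise FloatingPointError(
            f"non-finite branch output (family={family}, T={t_len}, B={b})"
        )
    state.hidden = None
    return out


def _example_arrays(ex: TrainingExample, multivariate: bool):
    """Stack one example into (1, T, D) input/mask/delta/x_last arrays."""
    y = ex.history_Y[:, None]
    if multivariate:
        if ex.history_X is None:
            raise ValueError("multivariate forward needs covariate history")
        x = np.concatenate([y, ex.history_X], axis=1)
    else:
        x = y
    t_len, d = x.shape
    m = np.repeat(ex.history_mask[:, None], d, axis=1)
    delta = np.repeat(ex.history_delta[:, None], d, axis=1)
    x_mean = np.zeros(d)
    x_last = np.empty((t_len, d))
    last = x_mean.copy()
    for t in range(t_len):
        x_last[t] = last
        obs = m[t] > 0
        last[obs] = x[t, obs]
    return x[None], m[None], delta[None], x_last[None], x_mean


def gru_forward(
    ex: TrainingExample, state: RecurrentState, spec: ModelSpec
) -> float:
    """Run one example through a single (joint) recurrent branch.

    The input at each step is the change ``Y`` alone (univariate) or the
    concatenation ``[Y; X]`` (multivariate); missing steps use a training
    mean of zero unless the caller standardized otherwise.
    """
    if spec.family not in GRU_FAMILIES:
        raise ValueError(f"not a recurrent family: {spec.family}")
    x, m, delta, x_last, x_mean = _example_arrays(
        ex, spec.input_mode == "multivariate"
    )
    if x.shape[2] != state.input_size:
        raise ValueError(
            f"example has {x.shape[2]} input dims, state expects {state.input_size}"
        )
    out = _branch_forward(state, x, m, delta, x_last, x_mean, spec.family)
    return float(out.data[0, 0])


def dual_forward(
    ex: TrainingExample,
    state_y: RecurrentState,
    state_x: RecurrentState,
    spec: ModelSpec,
    w: Optional[float] = None,
) -> float:
    """Dual-sequence prediction: w * target-branch + (1-w) * covariate-branch.

    The target branch consumes only past target changes (pure
    autoregression); the covariate branch consumes only past covariates;
    each has its own attention and output head.  ``w`` defaults to the
    spec's initial combination weight (0.6 target / 0.4 context).
    """
    if spec.input_mode != "multivariate" or ex.history_X is None:
        raise ValueError("dual sequence mode requires multivariate input")
    if w is None:
        w = spec.dual_init_weights[0]
    y, m, delta, y_last, y_mean = _example_arrays(ex, multivariate=False)
    y_out = _branch_forward(state_y, y, m, delta, y_last, y_mean, spec.family)

    x = ex.history_X[None]
    d = x.shape[2]
    mx = np.repeat(ex.history_mask[:, None], d, axis=1)[None]
    dx = np.repeat(ex.history_delta[:, None], d, axis=1)[None]
    x_mean = np.zeros(d)
    x_last = np.empty_like(x)
    last = x_mean.copy()
    for t in range(x.shape[1]):
        x_last[0, t] = last
        obs = mx[0, t] > 0
        last[obs] = x[0, t, obs]
    x_out = _branch_forward(state_x, x, mx, dx, x_last, x_mean, spec.family)
    return float(w * y_out.data[0, 0] + (1.0 - w) * x_out.data[0, 0])


class GRUForecaster:
    """Trainable attention-GRU forecaster (joint or dual, with decay variants)."""

    def __init__(self, spec: ModelSpec, n_covariates: int = 0):
        if spec.family not in GRU_FAMILIES:
            raise ValueError(f"not a recurrent family: {spec.family}")
        if spec.input_mode == "multivariate" and n_covariates < 1:
            raise ValueError("multivariate spec needs n_covariates >= 1")
        self.spec = spec
        self.n_covariates = n_covariates
        self.standardizer = Standardizer()
        self._x_mean_by_dim: Optional[np.ndarray] = None
        rng = np.random.default_rng(spec.seed)
        decay_in = spec.family == "gru_d"
        decay_h = spec.family in ("gru_d", "gru_ds")
        if spec.sequence_mode == "dual":
            self.state_y = init_state(1, spec.hidden_size, rng, decay_in, decay_h)
            self.state_x = init_state(
                n_covariates, spec.hidden_size, rng, decay_in, decay_h
            )
            self.state = None
            self.w = Tensor(np.array([spec.dual_init_weights[0]]), requires_grad=True)
        else:
            d = 1 + (n_covariates if spec.input_mode == "multivariate" else 0)
            self.state = init_state(d, spec.hidden_size, rng, decay_in, decay_h)
            self.state_y = self.state_x = None
            self.w = None

    # -- parameter access -------------------------------------------------

    def parameters(self) -> list[Tensor]:
        if self.spec.sequence_mode == "dual":
            return self.state_y.parameters() + self.state_x.parameters() + [self.w]
        return self.state.parameters()

    @property
    def combination_weight(self) -> float:
        """Current dual-sequence target-branch weight."""
        if self.w is None:
            raise AttributeError("joint model has no combination weight")
        return float(self.w.data[0])

    # -- data preparation -------------------------------------------------

    def setup(self, train_examples: Sequence[TrainingExample]) -> None:
        """Fit standardization and per-dimension training means."""
        self.standardizer.fit(train_examples)
        dims = self._total_dims()
        sums = np.zeros(dims)
        counts = np.zeros(dims)
        for ex in train_examples:
            x = self._standardized_input(ex)
            obs = ex.history_mask > 0
            sums += x[obs].sum(axis=0)
            counts += obs.sum()
        counts[counts == 0] = 1.0
        self._x_mean_by_dim = sums / counts

    def _total_dims(self) -> int:
        if self.spec.input_mode == "multivariate":
            return 1 + self.n_covariates
        return 1

    def _standardized_input(self, ex: TrainingExample) -> np.ndarray:
        y = self.standardizer.transform_y(ex.history_Y)[:, None]
        if self.spec.input_mode == "multivariate":
            if ex.history_X is None:
                raise ValueError("multivariate model given univariate example")
            x = self.standardizer.transform_x(ex.history_X)
            out = np.concatenate([y, x], axis=1)
        else:
            out = y
        return out * (ex.history_mask[:, None] > 0)  # masked cells -> 0

    def _pad_length(self) -> Optional[int]:
        # GRU-D consumes fixed-shape input under dynamic orders: shorter
        # histories are left-padded and the padding marked missing.
        if self.spec.family == "gru_d" and self.spec.order_mode == "dynamic":
            return self.spec.order_p
        return None

    def _batch_arrays(self, examples: Sequence[TrainingExample]):
        """Group examples by unrolled length into constant input arrays."""
        if self._x_mean_by_dim is None:
            raise RuntimeError("call setup() (or fit) before forward passes")
        pad_to = self._pad_length()
        groups: dict[int, dict] = {}
        d = self._total_dims()
        for idx, ex in enumerate(examples):
            t_raw = ex.order
            t_len = max(pad_to, t_raw) if pad_to is not None else t_raw
            g = groups.setdefault(
                t_len, {"x": [], "m": [], "delta": [], "target": [], "index": []}
            )
            x = self._standardized_input(ex)
            m = np.repeat((ex.history_mask[:, None] > 0).astype(float), d, axis=1)
            delta = np.repeat(ex.history_delta[:, None], d, axis=1)
            n_pad = t_len - t_raw
            if n_pad > 0:
                x = np.vstack([np.zeros((n_pad, d)), x])
                m = np.vstack([np.zeros((n_pad, d)), m])
                pad_delta = np.repeat(
                    np.arange(1, n_pad + 1, dtype=float)[:, None], d, axis=1
                )
                delta = np.vstack([pad_delta, delta])
            g["x"].append(x)
            g["m"].append(m)
            g["delta"].append(delta)
            g["target"].append(self.standardizer.transform_y(ex.target))
            g["index"].append(idx)
        out = []
        for t_len, g in sorted(groups.items()):
            x = np.stack(g["x"])
            m = np.stack(g["m"])
            delta = np.stack(g["delta"])
            x_last = np.empty_like(x)
            last = np.tile(self._x_mean_by_dim, (x.shape[0], 1))
            for t in range(t_len):
                x_last[:, t] = last
                obs = m[:, t] > 0
                last = np.where(obs, x[:, t], last)
            out.append(
                {
                    "x": x,
                    "m": m,
                    "delta": delta,
                    "x_last": x_last,
                    "target": np.asarray(g["target"], dtype=float),
                    "index": np.asarray(g["index"], dtype=int),
                }
            )
        return out

    # -- forward ----------------------------------------------------------

    def _forward_arrays(self, x, m, delta, x_last) -> Tensor:
        if self.spec.sequence_mode == "dual":
            y_out = _branch_forward(
                self.state_y,
                x[:, :, :1], m[:, :, :1], delta[:, :, :1], x_last[:, :, :1],
                self._x_mean_by_dim[:1], self.spec.family,
            )
            x_out = _branch_forward(
                self.state_x,
                x[:, :, 1:], m[:, :, 1:], delta[:, :, 1:], x_last[:, :, 1:],
                self._x_mean_by_dim[1:], self.spec.family,
            )
            return self.w * y_out + (1.0 - self.w) * x_out
        return _branch_forward(
            self.state, x, m, delta, x_last, self._x_mean_by_dim, self.spec.family
        )

    def loss_on(self, batch) -> Tensor:
        """Mean squared error on one prepared batch (standardized scale)."""
        pred = self._forward_arrays(
            batch["x"], batch["m"], batch["delta"], batch["x_last"]
        )
        err = pred.reshape(-1) - Tensor(batch["target"])
        return (err * err).mean()

    def predict(self, examples: Sequence[TrainingExample]) -> np.ndarray:
        out = np.empty(len(examples))
        for batch in self._batch_arrays(examples):
            pred = self._forward_arrays(
                batch["x"], batch["m"], batch["delta"], batch["x_last"]
            )
            out[batch["index"]] = self.standardizer.inverse_y(pred.data.ravel())
        return out

    def fit(self, examples, validation_examples=None) -> "GRUForecaster":
        from .training import train

        train(self, examples, validation_examples, self.spec)
        return self
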