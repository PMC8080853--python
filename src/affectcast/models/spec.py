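"""Model specification: one forecaster's architecture and hyperparameters."""

from __future__ import annotations

from dataclasses import dataclass, field

FAMILIES = ("last", "mean", "ar_ridge", "svr", "gbr", "dan", "gru", "gru_ds", "gru_d")
GRU_FAMILIES = ("gru", "gru_ds", "gru_d")


@dataclass
class ModelSpec:
    """Architecture and hyperparameters of one forecaster.

    ``order_p`` is the regression order: how many lagged change
    observations feed one prediction.  ``order_mode`` selects fixed
    sliding windows or dynamic growing windows (one training example per
    history length from ``min_order`` up).  ``sequence_mode`` selects the
    joint architecture (one recurrent stack over concatenated
    [target; covariates]) or the dual architecture (a pure autoregressive
    branch on the target plus a covariate branch, combined by a learned
    weighted average initialized at ``dual_init_weights``).
    """

    family: str
    sequence_mode: str = "joint"
    order_p: int = 14
    order_mode: str = "fixed"
    hidden_size: int = 32
    input_mode: str = "univariate"
    dual_init_weights: tuple = (0.6, 0.4)
    seed: int = 0
    min_order: int = 3
    learning_rate: float = 0.01
    batch_size: int = 32
    max_epochs: int = 200
    patience: int = 15
    hyperparams: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family: {self.family!r}")
        if self.sequence_mode not in ("joint", "dual"):
            raise ValueError(f"unknown sequence_mode: {self.sequence_mode!r}")
        if self.input_mode not in ("univariate", "multivariate"):
            raise ValueError(f"unknown input_mode: {self.input_mode!r}")
        if self.order_mode not in ("fixed", "dynamic"):
            raise ValueError(f"unknown order_mode: {self.order_mode!r}")
        if self.sequence_mode == "dual":
            if self.input_mode != "multivariate":
                raise ValueError("dual sequence mode requires multivariate input")
            if self.family not in GRU_FAMILIES:
                raise ValueError("dual sequence mode applies to recurrent families")
        if abs(sum(self.dual_init_weights) - 1.0) > 1e-9:
            raise ValueError("dual_init_weights must sum to 1")
        if self.family == "last":
            self.order_p = 1  # repeating the last change needs exactly one lag
        if self.order_p < 1:
            raise ValueError("order_p must be >= 1")

    @property
    def model_id(self) -> str:
        tag = self.family + ("+" if self.order_mode == "dynamic" else "")
        prefix = "dual-" if self.sequence_mode == "dual" else ""
        return f"{prefix}{tag}({self.order_p})"
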