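"""The forecaster ladder: baselines, lagged-feature regressors, DAN, and
attention-GRUs with decay variants and the dual-sequence architecture."""

from .baselines import LastBaseline, MeanBaseline, predict_last, predict_mean
from .dan import DANForecaster, dan_forward
from .linear import LinearForecaster, fit_linear_family
from .recurrent import (
    GRUForecaster,
    RecurrentState,
    apply_decay,
    attention_pool,
    dual_forward,
    gru_forward,
    init_state,
)
from .spec import FAMILIES, GRU_FAMILIES, ModelSpec
from .training import train

__all__ = [
    "ModelSpec",
    "FAMILIES",
    "GRU_FAMILIES",
    "predict_last",
    "predict_mean",
    "LastBaseline",
    "MeanBaseline",
    "LinearForecaster",
    "fit_linear_family",
    "DANForecaster",
    "dan_forward",
    "GRUForecaster",
    "RecurrentState",
    "init_state",
    "attention_pool",
    "apply_decay",
    "gru_forward",
    "dual_forward",
    "train",
    "build_model",
]


def build_model(spec: ModelSpec, n_covariates: int = 0):
    """Instantiate the forecaster a :class:`ModelSpec` describes."""
    if spec.family == "last":
        return LastBaseline(spec)
    if spec.family == "mean":
        return MeanBaseline(spec, window=spec.hyperparams.get("mean_window", 14))
    if spec.family in ("ar_ridge", "svr", "gbr"):
        return LinearForecaster(spec)
    if spec.family == "dan":
        return DANForecaster(spec, n_covariates)
    return GRUForecaster(spec, n_covariates)
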