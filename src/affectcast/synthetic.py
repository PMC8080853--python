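"""Synthetic users, series and corpora with the statistical structure the
forecasting task assumes.

`simulate_series` draws per-user affect *change* series from a stationary
autoregressive process, optionally couples covariates to the latent
changes, and (at daily resolution) drops bins independently to emulate
users who do not post every day.  `simulate_corpus` renders weekly latent
affect as actual token streams: each message mixes emotion-lexicon words
and filler words, with the lexicon-word rate tracking the user's latent
affect level, so scoring the corpus recovers series correlated with the
latent truth.

Default corpus shape follows a large public Twitter collection of this
kind: roughly 22 messages per user-week (3 plus a Poisson(19) count) of
about 15 tokens each, 20 weeks per user.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta
from typing import Optional, Sequence

import numpy as np

from .dataset import UserSeries, difference_series
from .lexicon import Lexicon
from .scoring import MessageRecord

__all__ = ["SimConfig", "simulate_series", "simulate_corpus"]

_EPOCH = datetime(2009, 1, 5)  # a Monday; user start weeks offset from here
_START_WEEK_SPAN = 260  # users start anywhere in a five-year window


def _check_stationary(coeffs: Sequence[float]) -> None:
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.size == 0 or np.all(coeffs == 0):
        return
    companion = np.zeros((len(coeffs), len(coeffs)))
    companion[0] = coeffs
    if len(coeffs) > 1:
        companion[np.arange(1, len(coeffs)), np.arange(len(coeffs) - 1)] = 1.0
    if np.max(np.abs(np.linalg.eigvals(companion))) >= 1.0:
        raise ValueError(f"non-stationary AR coefficients: {list(coeffs)}")


@dataclass
class SimConfig:
    """Generator settings.

    ``ar_coefficients`` holds one coefficient tuple per affect dimension
    (each must define a stationary AR process).  ``covariate_loading`` is a
    (C x A) matrix coupling covariates to the latent affect changes; None
    means no covariates.  ``msgs_per_week_dist`` is (minimum, Poisson
    rate): the weekly message count is min + Poisson(rate).
    ``corpus_coupling`` is the slope tying the lexicon-word rate to the
    latent affect level.
    """

    n_users: int = 100
    n_weeks: int = 20
    resolution: str = "weekly"
    ar_coefficients: tuple = ((0.6,),)
    noise_sd: float = 0.15
    covariate_loading: Optional[np.ndarray] = None
    covariate_noise_sd: float = 0.5
    missing_rate: float = 0.0
    msgs_per_week_dist: tuple = (3, 19.0)
    tokens_per_msg_dist: tuple = (8, 7.0)
    corpus_coupling: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.resolution not in ("weekly", "daily"):
            raise ValueError(f"unknown resolution: {self.resolution!r}")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        for coeffs in self.ar_coefficients:
            _check_stationary(coeffs)
        if self.covariate_loading is not None:
            self.covariate_loading = np.atleast_2d(
                np.asarray(self.covariate_loading, dtype=float)
            )
            if self.covariate_loading.shape[1] != len(self.ar_coefficients):
                raise ValueError(
                    "covariate_loading must have one column per affect dimension"
                )

    @property
    def n_affect(self) -> int:
        return len(self.ar_coefficients)

    @property
    def n_bins(self) -> int:
        return self.n_weeks if self.resolution == "weekly" else self.n_weeks * 7


def _ar_draw(coeffs, t_len: int, sd: float, rng: np.random.Generator) -> np.ndarray:
    coeffs = np.asarray(coeffs, dtype=float)
    p = len(coeffs)
    burn = 50 + 10 * p
    eps = rng.normal(0.0, sd, t_len + burn)
    out = np.zeros(t_len + burn)
    for t in range(t_len + burn):
        ar = sum(coeffs[i] * out[t - 1 - i] for i in range(min(p, t)))
        out[t] = ar + eps[t]
    return out[burn:]


def simulate_series(cfg: SimConfig) -> tuple[list[UserSeries], dict]:
    """Draw per-user change-series (and covariates) from the configured AR process.

    Returns (series, truth) where truth records the generating
    coefficients, the loading, each user's latent changes, and the
    per-user raw-bin observation patterns (daily mode).  Byte-identical
    output for identical seeds.
    """
    rng = np.random.default_rng(cfg.seed)
    n_bins = cfg.n_bins
    t_len = n_bins - 1
    series: list[UserSeries] = []
    truth = {
        "ar_coefficients": cfg.ar_coefficients,
        "covariate_loading": cfg.covariate_loading,
        "latent": {},
        "observed_bins": {},
        "start_week": {},
    }
    for u in range(cfg.n_users):
        user = f"user{u:04d}"
        latent = np.column_stack(
            [_ar_draw(c, t_len, cfg.noise_sd, rng) for c in cfg.ar_coefficients]
        )
        cols = [latent]
        if cfg.covariate_loading is not None:
            n_cov = cfg.covariate_loading.shape[0]
            cov = latent @ cfg.covariate_loading.T + rng.normal(
                0.0, cfg.covariate_noise_sd, (t_len, n_cov)
            )
            cols.append(cov)
        changes = np.hstack(cols)
        raw = np.vstack([np.zeros(changes.shape[1]), np.cumsum(changes, axis=0)])
        if cfg.resolution == "daily" and cfg.missing_rate > 0:
            observed = rng.random(n_bins) >= cfg.missing_rate
            observed[0] = True
            if observed.sum() < 2:
                observed[1] = True
        else:
            observed = np.ones(n_bins, dtype=bool)
        start_week = int(rng.integers(0, _START_WEEK_SPAN))
        step = timedelta(weeks=1) if cfg.resolution == "weekly" else timedelta(days=1)
        origin = _EPOCH + timedelta(weeks=start_week)
        calendar = [
            ((origin + b * step).year, (origin + b * step).month)
            for b in range(n_bins)
        ]
        s = difference_series(raw, user_id=user, observed=observed, calendar=calendar)
        series.append(s)
        truth["latent"][user] = latent
        truth["observed_bins"][user] = observed
        truth["start_week"][user] = start_week
    return series, truth


def _filler_pool(n: int = 400) -> list[str]:
    return [f"flw{i:03d}" for i in range(n)]


def simulate_corpus(
    cfg: SimConfig, lexicon: Lexicon
) -> tuple[list[MessageRecord], dict]:
    """Render weekly latent affect as per-user message streams.

    Affect dimension ``i`` is tied to lexicon category ``i``: each token
    is a word of that category with probability
    ``clip(base + corpus_coupling * z, 0.02, cap)`` where ``z`` is the
    user's latent level (cumulative latent changes) standardized within
    the user.  The per-user standardization emulates user-specific
    baseline emotional-word usage: each user's latent trajectory maps into
    the feasible word-frequency range instead of saturating it.  Every
    user's first message sits exactly at their week-0 start, so ordinal
    weekly binning reproduces the generator's weeks.

    Returns (messages, truth); truth additionally maps each user to their
    latent level matrix.
    """
    if cfg.resolution != "weekly":
        raise ValueError("corpus generation is defined for weekly resolution")
    a = cfg.n_affect
    if a > len(lexicon.categories):
        raise ValueError("more affect dimensions than lexicon categories")
    series, truth = simulate_series(cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    cat_words = [lexicon.words_in(c) for c in lexicon.categories[:a]]
    if any(not w for w in cat_words):
        raise ValueError("each coupled category needs at least one lexicon word")
    fillers = _filler_pool()
    base = 0.5 / a
    cap = 0.95 / a
    min_msgs, lam = cfg.msgs_per_week_dist
    min_tok, tok_lam = cfg.tokens_per_msg_dist

    messages: list[MessageRecord] = []
    truth["levels"] = {}
    # One cohort-level scale per dimension: the latent-affect -> word-rate
    # mapping is a population calibration.  (A per-user realized scale would
    # down-weight exactly the users with strongly autocorrelated
    # realizations and bias pooled autoregression estimates low.)
    all_levels = {
        u: np.vstack([np.zeros(a), np.cumsum(lat, axis=0)])
        for u, lat in truth["latent"].items()
    }
    scale = np.maximum(
        np.median([lv.std(axis=0) for lv in all_levels.values()], axis=0), 1e-9
    )
    for s in series:
        levels = all_levels[s.user_id]  # per raw bin
        truth["levels"][s.user_id] = levels
        origin = _EPOCH + timedelta(weeks=truth["start_week"][s.user_id])
        z_levels = (levels - levels.mean(axis=0)) / scale
        for week in range(cfg.n_weeks):
            probs = np.clip(base + (cfg.corpus_coupling / a) * z_levels[week], 0.02, cap)
            n_msgs = min_msgs + (int(rng.poisson(lam)) if lam > 0 else 0)
            for j in range(n_msgs):
                n_tok = min_tok + (int(rng.poisson(tok_lam)) if tok_lam > 0 else 0)
                # Stochastically rounded per-category token counts: the
                # expected lexicon-word frequency equals probs exactly, with
                # sub-binomial dispersion so the weekly lexicon score tracks
                # the latent level instead of drowning in sampling noise.
                ideal = n_tok * probs
                counts = np.floor(ideal).astype(int)
                counts += rng.random(a) < (ideal - counts)
                counts = np.minimum(counts, n_tok)
                while counts.sum() > n_tok:  # pathological overlap only
                    counts[np.argmax(counts)] -= 1
                tokens = []
                for cat, k in enumerate(counts):
                    words = cat_words[cat]
                    tokens += [
                        words[int(rng.integers(len(words)))] for _ in range(k)
                    ]
                tokens += [
                    fillers[int(rng.integers(len(fillers)))]
                    for _ in range(n_tok - counts.sum())
                ]
                rng.shuffle(tokens)
                if week == 0 and j == 0:
                    ts = origin  # anchor bin 0 at the user's first message
                else:
                    ts = origin + timedelta(
                        days=int(week * 7 + rng.integers(0, 7)),
                        seconds=int(rng.integers(0, 86400)),
                    )
                messages.append(MessageRecord(s.user_id, ts, " ".join(tokens)))
    return messages, truth
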