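"""Change-series construction, train/test splits, and example generation.

Per-bin affect scores become *change* series by differencing neighboring
bins (which detrends the data and increases stationarity); changes touching
an unobserved bin are masked and zero-filled, with per-dimension time-gap
vectors recording how long each dimension has gone unobserved.  Change
indices are 1-based: a series over bins 0..n-1 yields change steps 1..n-1,
so 20 weekly bins give 19 change points.

Splits follow the dual evaluation paradigm: for each fold, training users
contribute early weeks for fitting; the same users' later weeks form the
out-of-sample-time (OOS-Time) test set; disjoint held-out users' later
weeks form the out-of-sample-user (OOS-User) test set and the validation
set used for tuning.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .scoring import BinScore

__all__ = [
    "UserSeries",
    "TrainingExample",
    "SplitPlan",
    "difference_series",
    "series_from_bins",
    "reconstruct_raw",
    "make_split_plan",
    "build_examples",
    "Standardizer",
]


@dataclass
class UserSeries:
    """One user's ordered change-series with missingness bookkeeping.

    ``values[t-1]`` holds the change at 1-based index ``t`` (zero-filled
    where masked); ``mask`` is 1 where the change was observed (both
    endpoint bins present); ``delta`` counts bins since each dimension was
    last observed (1 for consecutive observations, accumulating across
    missing runs).  ``first_raw`` retains the first raw bin so the raw
    series can be reconstructed by cumulative summation.
    """

    user_id: str
    values: np.ndarray  # (T, D)
    mask: np.ndarray  # (T, D) in {0, 1}
    delta: np.ndarray  # (T, D), >= 1
    calendar: Optional[list] = None  # (year, month) per change step
    first_raw: Optional[np.ndarray] = None

    def __post_init__(self):
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.mask = np.atleast_2d(np.asarray(self.mask, dtype=float))
        self.delta = np.atleast_2d(np.asarray(self.delta, dtype=float))
        if not (self.values.shape == self.mask.shape == self.delta.shape):
            raise ValueError("values, mask and delta must share a shape")
        if not np.all(np.isfinite(self.values[self.mask > 0])):
            raise ValueError("observed changes must be finite")

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def n_dims(self) -> int:
        return self.values.shape[1]


@dataclass
class TrainingExample:
    """A history window plus the next-step change to forecast.

    ``history_Y`` is the target dimension's past changes (length p);
    ``history_X`` the covariate changes (p x C, or None when univariate).
    ``history_mask`` / ``history_delta`` are bin-level and apply to all
    dimensions of the step (missingness here comes from empty bins, which
    hit every dimension at once).  ``target`` is the change at
    ``target_index`` = last history index + 1.
    """

    history_Y: np.ndarray
    history_X: Optional[np.ndarray]
    history_mask: np.ndarray
    history_delta: np.ndarray
    target: float
    user_id: str
    target_index: int
    calendar: Optional[tuple] = None

    @property
    def order(self) -> int:
        return len(self.history_Y)


@dataclass
class SplitPlan:
    """One fold's user assignment and week ranges."""

    fold_id: int
    train_users: tuple
    oos_users: tuple
    validation_users: tuple
    train_weeks: range
    test_weeks: range

    def __post_init__(self):
        groups = [set(self.train_users), set(self.oos_users), set(self.validation_users)]
        for i in range(3):
            for j in range(i + 1, 3):
                if groups[i] & groups[j]:
                    raise ValueError("user groups must be pairwise disjoint")
        if min(self.test_weeks) <= max(self.train_weeks):
            raise ValueError("test weeks must be strictly after train weeks")

    def to_json(self) -> str:
        return json.dumps(
            {
                "fold_id": self.fold_id,
                "train_users": list(self.train_users),
                "oos_users": list(self.oos_users),
                "validation_users": list(self.validation_users),
                "train_weeks": [self.train_weeks.start, self.train_weeks.stop],
                "test_weeks": [self.test_weeks.start, self.test_weeks.stop],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "SplitPlan":
        d = json.loads(text)
        return cls(
            d["fold_id"],
            tuple(d["train_users"]),
            tuple(d["oos_users"]),
            tuple(d["validation_users"]),
            range(*d["train_weeks"]),
            range(*d["test_weeks"]),
        )


def difference_series(
    raw: np.ndarray,
    user_id: str = "user",
    observed: Optional[np.ndarray] = None,
    calendar: Optional[Sequence] = None,
) -> UserSeries:
    """Difference neighboring bins into a masked change-series.

    ``raw`` is (n_bins, D) (or 1-D for a single dimension); ``observed``
    flags bins with data (default: all).  A change into or out of an
    unobserved bin is masked and stored as 0 ("no change" for models
    without missing-data support); ``delta`` follows the
    time-since-last-observation recursion: 1 after an observed step,
    previous delta + 1 across a missing run, and 1 at the first step.
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim == 1:
        raw = raw[:, None]
    n_bins, d = raw.shape
    if observed is None:
        observed = np.ones(n_bins, dtype=bool)
    observed = np.asarray(observed, dtype=bool)
    if observed.sum() < 2:
        raise ValueError("need at least 2 observed bins to difference")
    t = n_bins - 1
    values = np.zeros((t, d))
    mask = np.zeros((t, d))
    delta = np.ones((t, d))
    for i in range(t):  # change step i+1 spans bins i -> i+1
        if observed[i] and observed[i + 1]:
            values[i] = raw[i + 1] - raw[i]
            mask[i] = 1.0
        if i > 0:
            delta[i] = np.where(mask[i - 1] > 0, 1.0, delta[i - 1] + 1.0)
    cal = list(calendar[1:]) if calendar is not None else None
    return UserSeries(user_id, values, mask, delta, cal, raw[0].copy())


def series_from_bins(
    bins: Sequence[BinScore],
    window: Optional[range] = None,
    include_covariates: bool = True,
) -> UserSeries:
    """Build a change-series from one user's ordered :class:`BinScore` list."""
    if window is not None:
        bins = [b for b in bins if b.bin_index in window]
    if not bins:
        raise ValueError("no bins in window")
    idx = [b.bin_index for b in bins]
    lo, hi = min(idx), max(idx)
    by_index = {b.bin_index: b for b in bins}
    n_scores = next(len(b.scores) for b in bins if not b.empty)
    has_cov = include_covariates and any(
        b.covariates is not None for b in bins if not b.empty
    )
    n_cov = (
        next(len(b.covariates) for b in bins if not b.empty and b.covariates is not None)
        if has_cov
        else 0
    )
    d = n_scores + n_cov
    raw = np.zeros((hi - lo + 1, d))
    observed = np.zeros(hi - lo + 1, dtype=bool)
    calendar = [None] * (hi - lo + 1)
    for j in range(lo, hi + 1):
        b = by_index.get(j)
        if b is None or b.empty:
            continue
        row = list(b.scores) + (list(b.covariates) if has_cov else [])
        raw[j - lo] = row
        observed[j - lo] = True
        calendar[j - lo] = b.calendar
    # trim to the first/last observed bin
    first, last = np.flatnonzero(observed)[[0, -1]]
    return difference_series(
        raw[first : last + 1],
        user_id=bins[0].user_id,
        observed=observed[first : last + 1],
        calendar=calendar[first : last + 1],
    )


def reconstruct_raw(series: UserSeries) -> np.ndarray:
    """Invert differencing: first raw bin plus the cumulative sum of changes.

    Exact at every bin for fully observed series; after a masked run the
    zero-filled changes leave the unobservable offset out.
    """
    if series.first_raw is None:
        raise ValueError("series lacks its first raw bin")
    return np.vstack([series.first_raw, series.first_raw + np.cumsum(series.values, axis=0)])


def make_split_plan(
    users: Sequence[str],
    k: int = 5,
    train_weeks: range = range(1, 15),
    test_weeks: range = range(15, 20),
    seed: int = 0,
    proportions: tuple = (0.7, 0.1, 0.2),
) -> list[SplitPlan]:
    """Deterministic k-fold assignment of users to train/validation/OOS groups.

    Users are shuffled once by ``seed``; each fold rotates the shuffled
    list by n/k and takes ``proportions`` = (train, validation, OOS-user)
    contiguous blocks, so across k folds with a 30% held-out block and a
    20% rotation every user is held out (OOS or validation) at least once.
    """
    users = list(users)
    n = len(users)
    if k < 2:
        raise ValueError("k must be >= 2")
    p_train, p_val, p_oos = proportions
    n_train = int(round(p_train * n))
    n_val = max(1, int(round(p_val * n)))
    n_oos = n - n_train - n_val
    if n_train < 1 or n_oos < 1:
        raise ValueError("too few users to populate three disjoint groups")
    rng = np.random.default_rng(seed)
    perm = [users[i] for i in rng.permutation(n)]
    plans = []
    for fold in range(k):
        rotated = np.roll(perm, -((fold * n) // k)).tolist()
        plans.append(
            SplitPlan(
                fold_id=fold,
                train_users=tuple(rotated[:n_train]),
                validation_users=tuple(rotated[n_train : n_train + n_val]),
                oos_users=tuple(rotated[n_train + n_val :]),
                train_weeks=train_weeks,
                test_weeks=test_weeks,
            )
        )
    return plans


def build_examples(
    series: UserSeries,
    order_p: int,
    mode: str = "fixed",
    min_order: int = 3,
    week_range: range = range(1, 16),
    target_dim: int = 0,
) -> list[TrainingExample]:
    """Generate forecasting examples from one user's change-series.

    ``week_range`` is the contiguous span of 1-based change indices the
    examples may touch — histories *and* targets.  Fixed mode slides a
    length-``order_p`` window (one example per in-range target with a full
    history); dynamic mode anchors at the start of the span and emits one
    example per history length from ``min_order`` up to the span maximum
    (the growing-window scheme: steps 1..3 predict 4, 1..4 predict 5, and
    so on).  Examples whose target change is unobserved are skipped, so
    unobserved days never enter training or test targets.
    """
    weeks = sorted(week_range)
    if not weeks or weeks != list(range(weeks[0], weeks[-1] + 1)):
        raise ValueError("week_range must be a contiguous index span")
    t_len = len(series)
    weeks = [w for w in weeks if 1 <= w <= t_len]
    examples: list[TrainingExample] = []
    cov_dims = [j for j in range(series.n_dims) if j != target_dim]

    def _emit(hist: list[int], target: int) -> None:
        if series.mask[target - 1, target_dim] <= 0:
            return
        rows = [h - 1 for h in hist]
        examples.append(
            TrainingExample(
                history_Y=series.values[rows, target_dim].copy(),
                history_X=series.values[np.ix_(rows, cov_dims)].copy()
                if cov_dims
                else None,
                history_mask=series.mask[rows, target_dim].copy(),
                history_delta=series.delta[rows, target_dim].copy(),
                target=float(series.values[target - 1, target_dim]),
                user_id=series.user_id,
                target_index=target,
                calendar=series.calendar[target - 1]
                if series.calendar is not None
                else None,
            )
        )

    if mode == "fixed":
        if order_p < 1:
            raise ValueError("order_p must be >= 1")
        if len(weeks) < order_p + 1:
            raise ValueError(
                f"week range of {len(weeks)} steps cannot host order {order_p}"
            )
        for target in weeks:
            hist = list(range(target - order_p, target))
            if hist and hist[0] >= weeks[0]:
                _emit(hist, target)
    elif mode == "dynamic":
        if min_order < 1 or min_order > order_p:
            raise ValueError("need 1 <= min_order <= order_p")
        if len(weeks) < min_order + 1:
            raise ValueError("week range shorter than min_order + 1")
        anchor = weeks[0]
        max_len = min(order_p, len(weeks) - 1)
        for length in range(min_order, max_len + 1):
            hist = list(range(anchor, anchor + length))
            _emit(hist, anchor + length)
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    return examples


class Standardizer:
    """Per-dimension z-scoring fitted on training-fold examples only.

    Masked history cells are excluded from the statistics and mapped to 0
    after standardization (the padding value decay-aware models ignore via
    their masks and other models read as "no change").
    """

    def __init__(self):
        self.y_mean = 0.0
        self.y_std = 1.0
        self.x_mean = None
        self.x_std = None

    def fit(self, examples: Sequence[TrainingExample]) -> "Standardizer":
        ys, targets = [], []
        xs = []
        for ex in examples:
            obs = ex.history_mask > 0
            ys.append(ex.history_Y[obs])
            targets.append(ex.target)
            if ex.history_X is not None:
                xs.append(ex.history_X[obs])
        pooled_y = np.concatenate(ys + [np.asarray(targets)])
        self.y_mean = float(pooled_y.mean())
        self.y_std = float(pooled_y.std()) or 1.0
        if xs:
            pooled_x = np.vstack(xs)
            self.x_mean = pooled_x.mean(axis=0)
            self.x_std = pooled_x.std(axis=0)
            self.x_std[self.x_std == 0] = 1.0
        return self

    def transform_y(self, y: np.ndarray) -> np.ndarray:
        return (np.asarray(y, dtype=float) - self.y_mean) / self.y_std

    def inverse_y(self, y: np.ndarray) -> np.ndarray:
        return np.asarray(y, dtype=float) * self.y_std + self.y_mean

    def transform_x(self, x: np.ndarray) -> np.ndarray:
        if self.x_mean is None:
            return np.asarray(x, dtype=float)
        return (np.asarray(x, dtype=float) - self.x_mean) / self.x_std
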