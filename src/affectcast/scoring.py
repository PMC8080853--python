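"""Per-message lexicon scoring and per-user time binning.

Raw message streams become per-user, per-bin affect scores: each message is
scored as the fraction of its tokens carrying each emotion category, message
scores are averaged inside each weekly or daily bin, and optional message
embeddings are averaged into per-bin covariate vectors.  Users are then
filtered to those with a sufficiently long contiguous run of active weeks,
and high-dimensional covariates can be reduced with non-negative matrix
factorization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import datetime
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.decomposition import NMF

from .lexicon import Lexicon, contains_url, tokenize

__all__ = [
    "MessageRecord",
    "BinScore",
    "UnscorableMessageError",
    "score_message",
    "aggregate_bins",
    "filter_users",
    "reduce_covariates",
    "CovariateReducer",
    "bins_to_frame",
    "read_messages",
]


class UnscorableMessageError(ValueError):
    """Raised for a message with no tokens after tokenization."""


@dataclass
class MessageRecord:
    """One message: author, calendar timestamp, text, optional embedding."""

    user_id: str
    timestamp: datetime
    text: str
    embedding: Optional[np.ndarray] = None


@dataclass
class BinScore:
    """Aggregated affect scores for one user in one time bin."""

    user_id: str
    bin_index: int
    scores: np.ndarray
    covariates: Optional[np.ndarray] = None
    n_messages: int = 0
    empty: bool = False
    calendar: Optional[tuple] = None  # (year, month) of the bin start

    def __post_init__(self):
        if self.bin_index < 0:
            raise ValueError("bin_index must be non-negative")
        if not self.empty and not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite for observed bins")


def score_message(msg: MessageRecord, lex: Lexicon) -> np.ndarray:
    """Fraction of a message's tokens carrying each emotion category.

    Each component is (tokens carrying that category) / (total tokens), so
    the result lies in [0, 1] per category; a word carrying several
    categories counts once for each.

    Raises
    ------
    UnscorableMessageError
        If the message has no tokens after tokenization.
    """
    tokens = tokenize(msg.text)
    if not tokens:
        raise UnscorableMessageError(f"message has no tokens: {msg.text!r}")
    counts = np.zeros(len(lex.categories))
    index = {c: i for i, c in enumerate(lex.categories)}
    for tok in tokens:
        for cat in lex.categories_of(tok):
            counts[index[cat]] += 1.0
    return counts / len(tokens)


def _bin_index(ts: datetime, origin: datetime, resolution: str) -> int:
    days = (ts.date() - origin.date()).days
    return days // 7 if resolution == "weekly" else days


def _bin_start(origin: datetime, idx: int, resolution: str) -> tuple:
    step = 7 if resolution == "weekly" else 1
    start = origin + pd.Timedelta(days=idx * step)
    return (start.year, start.month)


def aggregate_bins(
    msgs: Iterable[MessageRecord],
    resolution: str,
    lex: Lexicon,
    drop_urls: bool = True,
) -> dict[str, list[BinScore]]:
    """Group messages into per-user ordinal time bins and average scores.

    Bins are ordinal positions counted from each user's first retained
    message (weekly: 7-day blocks, daily: single days).  Daily resolution
    emits explicit empty bins (``empty=True``, ``n_messages=0``) for gap
    days so downstream differencing can mask them; weekly gap bins are also
    emitted empty and handled by the contiguity filter.  Messages that are
    unscorable (no tokens) or contain URLs (when ``drop_urls``) are skipped.

    Returns a dict ``user_id -> list of BinScore`` ordered by bin index.
    """
    if resolution not in ("weekly", "daily"):
        raise ValueError(f"unknown resolution: {resolution!r}")
    per_user: dict[str, list[MessageRecord]] = {}
    for m in msgs:
        if drop_urls and contains_url(m.text):
            continue
        per_user.setdefault(m.user_id, []).append(m)

    out: dict[str, list[BinScore]] = {}
    n_cat = len(lex.categories)
    for user, records in per_user.items():
        records.sort(key=lambda m: m.timestamp)
        origin = records[0].timestamp
        acc: dict[int, list[tuple[np.ndarray, Optional[np.ndarray]]]] = {}
        for m in records:
            try:
                s = score_message(m, lex)
            except UnscorableMessageError:
                continue
            acc.setdefault(_bin_index(m.timestamp, origin, resolution), []).append(
                (s, m.embedding)
            )
        if not acc:
            continue
        bins: list[BinScore] = []
        for idx in range(min(acc), max(acc) + 1):
            cal = _bin_start(origin, idx, resolution)
            if idx not in acc:
                bins.append(
                    BinScore(user, idx, np.full(n_cat, np.nan), None, 0, True, cal)
                )
                continue
            scores = np.mean([s for s, _ in acc[idx]], axis=0)
            embs = [e for _, e in acc[idx] if e is not None]
            cov = np.mean(embs, axis=0) if embs else None
            bins.append(BinScore(user, idx, scores, cov, len(acc[idx]), False, cal))
        out[user] = bins
    return out


def filter_users(
    bins: Mapping[str, Sequence[BinScore]],
    min_msgs_per_week: int = 3,
    min_contig_weeks: int = 20,
) -> dict[str, range]:
    """Retain users with a long enough contiguous run of active weeks.

    A week qualifies when ``n_messages >= min_msgs_per_week``.  A user is
    retained when some run of ``min_contig_weeks`` consecutive bin indices
    all qualify; the first such window is kept.  Returns
    ``user_id -> range(start, start + min_contig_weeks)`` of retained bin
    indices (the dict's keys are the retained user set).
    """
    retained: dict[str, range] = {}
    for user, user_bins in bins.items():
        ok = {
            b.bin_index
            for b in user_bins
            if not b.empty and b.n_messages >= min_msgs_per_week
        }
        if not ok:
            continue
        run_start, prev = None, None
        for idx in sorted(ok):
            if prev is None or idx != prev + 1:
                run_start = idx
            prev = idx
            if idx - run_start + 1 >= min_contig_weeks:
                retained[user] = range(run_start, run_start + min_contig_weeks)
                break
    return retained


@dataclass
class CovariateReducer:
    """Fitted NMF reducer with the column shifts that made the data non-negative."""

    nmf: NMF
    offsets: np.ndarray
    k: int = field(init=False)

    def __post_init__(self):
        self.k = self.nmf.n_components_

    def transform(self, X: np.ndarray) -> np.ndarray:
        shifted = np.clip(np.asarray(X, dtype=float) - self.offsets, 0.0, None)
        return self.nmf.transform(shifted)


def reduce_covariates(
    X: np.ndarray,
    k: int = 50,
    fit_subset_size: Optional[int] = None,
    random_state: int = 0,
) -> tuple[np.ndarray, CovariateReducer]:
    """Reduce embedding covariates to ``k`` dimensions with NMF.

    Contextual embeddings can be negative, so each column is shifted by its
    minimum over the fitting subset (values that still fall below zero on
    out-of-subset rows are clipped).  The factorization is fitted once on a
    row subset (evenly strided, which keeps any user-sorted input
    stratified) and applied to all rows.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (rows = messages or bins)")
    if k > X.shape[1]:
        raise ValueError(f"k={k} exceeds input dimension {X.shape[1]}")
    n = X.shape[0]
    if fit_subset_size is None or fit_subset_size >= n:
        subset = X
    else:
        stride = max(1, n // fit_subset_size)
        subset = X[::stride][:fit_subset_size]
    offsets = subset.min(axis=0)
    shifted = np.clip(subset - offsets, 0.0, None)
    nmf = NMF(
        n_components=k,
        init="nndsvda",
        max_iter=2000,
        tol=1e-8,
        random_state=random_state,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # NMF convergence chatter on easy inputs
        nmf.fit(shifted)
        reducer = CovariateReducer(nmf, offsets)
        reduced = reducer.transform(X)
    return reduced, reducer


# ---------------------------------------------------------------------------
# I/O helpers: tidy long-format tables and delimited message files.


def bins_to_frame(bins: Mapping[str, Sequence[BinScore]], lex: Lexicon) -> pd.DataFrame:
    """Tidy long table: user_id, bin_index, dimension, value (+ n_messages)."""
    rows = []
    for user, user_bins in bins.items():
        for b in user_bins:
            if b.empty:
                continue
            for dim, val in zip(lex.categories, b.scores):
                rows.append((user, b.bin_index, dim, float(val), b.n_messages))
            if b.covariates is not None:
                for j, val in enumerate(b.covariates):
                    rows.append((user, b.bin_index, f"cov_{j}", float(val), b.n_messages))
    return pd.DataFrame(
        rows, columns=["user_id", "bin_index", "dimension", "value", "n_messages"]
    )


def read_messages(path, embedding_path=None) -> list[MessageRecord]:
    """Read a delimited message table (user_id, timestamp, text).

    ``embedding_path`` optionally points to a headerless numeric table with
    one row per message row, used as the message embedding.
    """
    df = pd.read_csv(path)
    emb = None
    if embedding_path is not None:
        emb = pd.read_csv(embedding_path, header=None).to_numpy(dtype=float)
        if len(emb) != len(df):
            raise ValueError("embedding sidecar row count does not match messages")
    records = []
    for i, row in df.iterrows():
        records.append(
            MessageRecord(
                user_id=str(row["user_id"]),
                timestamp=pd.Timestamp(row["timestamp"]).to_pydatetime(),
                text=str(row["text"]),
                embedding=None if emb is None else emb[i],
            )
        )
    return records
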