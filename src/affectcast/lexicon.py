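"""Word–emotion lexicons and tweet tokenization.

A :class:`Lexicon` maps lower-cased words to the set of emotion categories
they carry, in the style of the NRC word–emotion association lexicon: one
row per (word, category) association.  Loading also accepts the three-column
distribution layout ``word<TAB>category<TAB>0/1``, keeping flagged rows.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

# Six basic emotions used as the default category inventory.
BASIC_EMOTIONS = ("anger", "disgust", "fear", "joy", "sadness", "surprise")

_TOKEN_SPLIT = re.compile(r"[^a-z0-9]+")
_MENTION = re.compile(r"@\w+")
_URL = re.compile(r"(?:https?://|www\.)\S+", re.IGNORECASE)


def tokenize(text: str) -> list[str]:
    """Deterministic tweet tokenizer.

    Lower-cases, removes @-mentions entirely, strips the ``#`` from hashtags
    (keeping the body), and splits on runs of non-alphanumerics.
    """
    text = _MENTION.sub(" ", text.lower())
    text = text.replace("#", " ")
    return [t for t in _TOKEN_SPLIT.split(text) if t]


def contains_url(text: str) -> bool:
    return bool(_URL.search(text))


@dataclass(frozen=True)
class Lexicon:
    """Word → emotion-category association table.

    Attributes
    ----------
    entries:
        Mapping from lower-cased word to the frozen set of category labels
        it carries.  A word may carry several categories; it counts once per
        category.
    categories:
        Ordered category names; every label in ``entries`` appears here.
    """

    entries: Mapping[str, frozenset]
    categories: tuple = field(default=BASIC_EMOTIONS)

    def __post_init__(self):
        known = set(self.categories)
        for word, cats in self.entries.items():
            if word != word.lower():
                raise ValueError(f"lexicon word not lower-cased: {word!r}")
            unknown = set(cats) - known
            if unknown:
                raise ValueError(f"unknown categories for {word!r}: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.entries)

    def categories_of(self, word: str) -> frozenset:
        return self.entries.get(word, frozenset())

    def words_in(self, category: str) -> list[str]:
        return sorted(w for w, cats in self.entries.items() if category in cats)

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]], categories=None) -> "Lexicon":
        entries: dict[str, set] = {}
        seen_cats: list[str] = []
        for word, cat in pairs:
            word = word.strip().lower()
            cat = cat.strip().lower()
            if not word or not cat:
                continue
            entries.setdefault(word, set()).add(cat)
            if cat not in seen_cats:
                seen_cats.append(cat)
        cats = tuple(categories) if categories is not None else tuple(seen_cats)
        return cls({w: frozenset(c) for w, c in entries.items()}, cats)

    @classmethod
    def from_file(cls, path, categories=None) -> "Lexicon":
        """Read a delimited word/category table (NRC layout).

        Two-column rows are taken as (word, category); three-column rows as
        (word, category, flag) keeping flag == 1.
        """
        pairs = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = re.split(r"[\t,]", line)
            if len(fields) >= 3:
                if fields[2].strip() not in ("1", "1.0"):
                    continue
            if len(fields) < 2:
                continue
            pairs.append((fields[0], fields[1]))
        return cls.from_pairs(pairs, categories=categories)

    def to_file(self, path) -> None:
        lines = []
        for word in sorted(self.entries):
            for cat in self.categories:
                if cat in self.entries[word]:
                    lines.append(f"{word}\t{cat}")
        Path(path).write_text("\n".join(lines) + "\n")
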