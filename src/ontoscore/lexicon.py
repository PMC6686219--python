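"""Word-sense lookup against a pluggable lexical database.

The semantic metrics need, for every unique label token, the number of word
senses the lexical database records for it.  Two backends implement the
same contract: a fixture lexicon backed by a plain token→count mapping
(loadable from two-column CSV), and a WordNet backend that aggregates synset
counts across all parts of speech when a WordNet corpus is importable at
runtime.  Lookups are case-insensitive and deterministic; unknown tokens
have zero senses.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from typing import Protocol, runtime_checkable

from .labels import TokenCensus
from .model import LexiconUnavailableError, UndefinedScoreError


@runtime_checkable
class LexicalDatabase(Protocol):
    """Contract: deterministic, case-insensitive token → sense count."""

    name: str

    def sense_count(self, token: str) -> int: ...


@dataclass
class FixtureLexicon:
    """In-memory lexicon over an explicit token → sense-count mapping."""

    senses: dict[str, int]
    name: str = "fixture"

    def __post_init__(self) -> None:
        folded: dict[str, int] = {}
        for token, count in self.senses.items():
            if count < 0:
                raise ValueError(f"negative sense count for {token!r}: {count}")
            folded[token.lower()] = int(count)
        self.senses = folded

    def sense_count(self, token: str) -> int:
        return self.senses.get(token.lower(), 0)

    @classmethod
    def from_csv(cls, path) -> "FixtureLexicon":
        """Load a two-column (token, sense_count) CSV."""
        senses: dict[str, int] = {}
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.reader(fh):
                if not row or row[0].startswith("#"):
                    continue
                if row[0] == "token" and not row[1].isdigit():
                    continue  # optional header
                senses[row[0]] = int(row[1])
        return cls(senses)


class WordNetLexicon:
    """Sense counts from a WordNet corpus, summed over all parts of speech.

    Requires the nltk WordNet corpus (or the `wn` package) importable at
    runtime; tests and offline sessions should use :class:`FixtureLexicon`.
    """

    name = "wordnet"

    def __init__(self) -> None:
        try:
            from nltk.corpus import wordnet  # type: ignore

            wordnet.synsets("heart")  # force corpus load
            self._wordnet = wordnet
        except Exception as exc:
            raise LexiconUnavailableError(
                "no WordNet backend is available in this environment; "
                "use a FixtureLexicon (CSV token,sense_count mapping) instead"
            ) from exc

    def sense_count(self, token: str) -> int:
        return len(self._wordnet.synsets(token.lower()))


@dataclass(frozen=True)
class SenseStats:
    """Sense statistics over the *unique* tokens of a census."""

    t: int
    t_sense: int
    total_senses: int

    def __post_init__(self) -> None:
        if self.t <= 0:
            raise UndefinedScoreError(
                "sense statistics are undefined for an empty token census"
            )
        assert 0 <= self.t_sense <= self.t

    @property
    def t_avg_sense(self) -> float:
        return self.total_senses / self.t


def sense_count(db: LexicalDatabase, token: str) -> int:
    """Total sense count for one token; 0 when out of vocabulary."""
    if not token:
        raise ValueError("token must be non-empty")
    return db.sense_count(token)


def label_sense_total(db: LexicalDatabase, tokens: list[str]) -> int:
    """Accumulated word-sense total of a multi-token label (with repeats)."""
    return sum(db.sense_count(tok) for tok in tokens)


def sense_stats(db: LexicalDatabase, census: TokenCensus) -> SenseStats:
    """Sense statistics over the unique tokens of a token census.

    Statistics depend only on the set of unique tokens, never on their
    occurrence multiplicities.
    """
    if census.t == 0:
        raise UndefinedScoreError(
            "sense statistics are undefined when no tokens were collected"
        )
    t_sense = 0
    total = 0
    for token, _count in census.per_token_counts:
        n = db.sense_count(token)
        total += n
        if n >= 1:
            t_sense += 1
    return SenseStats(t=census.t, t_sense=t_sense, total_senses=total)
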