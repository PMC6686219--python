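"""Label normalization and token tallies.

Raw labels harvested from the ontology are normalized through a fixed rule
pipeline (bracket stripping, separator replacement, camel-case splitting,
lowercasing, determiner removal, whitespace collapse) and tokenized.  The
corpus-wide token census — total occurrences, unique tokens ``t`` and
duplicate occurrences ``d = occurrences − t`` — feeds the semantic metrics.
"""

from __future__ import annotations

import csv
import re
from collections import Counter
from dataclasses import dataclass, field

#: Marker recorded when a raw label normalizes to nothing; such records are
#: excluded from the token tallies.
EMPTY_AFTER_PROCESSING = "empty-after-processing"

_DETERMINERS = frozenset({"a", "an", "the"})

_BRACKETS = str.maketrans({c: " " for c in "()[]{}"})
_CAMEL_LOWER_UPPER = re.compile(r"(?<=[a-z0-9])(?=[A-Z])")
_CAMEL_ACRONYM = re.compile(r"(?<=[A-Z])(?=[A-Z][a-z])")


@dataclass(frozen=True)
class ParseOptions:
    """Which normalization rules are applied; all default on."""

    split_camel_case: bool = True
    remove_determiners: bool = True
    strip_brackets: bool = True
    replace_underscores: bool = True
    replace_dashes: bool = True
    lowercase: bool = True
    #: documented alternative to bracket stripping: drop the enclosed text
    drop_bracketed_text: bool = False


@dataclass
class LabelRecord:
    """One label of one entity, raw and (after processing) normalized."""

    entity_iri: str
    raw_label: str
    processed_label: str = ""
    tokens: list[str] = field(default_factory=list)
    accumulated_senses: int = 0

    @property
    def empty_after_processing(self) -> bool:
        return self.processed_label == "" and self.raw_label != ""


@dataclass(frozen=True)
class TokenCensus:
    """Corpus-wide token tallies over all processed labels."""

    occurrences: int
    t: int
    d: int
    per_token_counts: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        assert self.d == self.occurrences - self.t
        assert sum(c for _, c in self.per_token_counts) == self.occurrences

    def counts(self) -> dict[str, int]:
        return dict(self.per_token_counts)


def normalize_label(raw: str, options: ParseOptions | None = None) -> str:
    """Normalize one raw label under the given parse options.

    Rules apply in a fixed, documented order: bracket handling, underscore
    and dash replacement, camel-case splitting, lowercasing, determiner
    removal, whitespace collapse.  The order matters (e.g. "theHeart" must be
    camel-split before "the" can be recognized as a determiner).  A label
    that normalizes to nothing yields the empty string; callers record the
    ``EMPTY_AFTER_PROCESSING`` marker and exclude it from tallies.
    """
    if options is None:
        options = ParseOptions()
    text = raw
    if options.strip_brackets:
        if options.drop_bracketed_text:
            text = re.sub(r"[(\[{][^)\]}]*[)\]}]", " ", text)
        else:
            text = text.translate(_BRACKETS)
    if options.replace_underscores:
        text = text.replace("_", " ")
    if options.replace_dashes:
        text = text.replace("-", " ")
    if options.split_camel_case:
        text = _CAMEL_LOWER_UPPER.sub(" ", text)
        text = _CAMEL_ACRONYM.sub(" ", text)
    if options.lowercase:
        text = text.lower()
    if options.remove_determiners:
        kept = [
            tok
            for tok in text.split()
            if tok.lower() not in _DETERMINERS
        ]
        text = " ".join(kept)
    return " ".join(text.split())


def tokenize_label(processed: str) -> list[str]:
    """Split a processed label on whitespace, preserving order."""
    return processed.split()


def process_records(
    records: list[LabelRecord], options: ParseOptions | None = None
) -> list[LabelRecord]:
    """Fill ``processed_label`` and ``tokens`` for every record, in place."""
    for record in records:
        record.processed_label = normalize_label(record.raw_label, options)
        record.tokens = tokenize_label(record.processed_label)
    return records


def census_tokens(records: list[LabelRecord]) -> TokenCensus:
    """Tally tokens corpus-wide over all processed label records.

    Each label contributes each of its tokens once per occurrence;
    uniqueness is exact text equality after normalization.  Records that
    normalized to nothing contribute no tokens.
    """
    counter: Counter[str] = Counter()
    for record in records:
        counter.update(record.tokens)
    occurrences = sum(counter.values())
    t = len(counter)
    return TokenCensus(
        occurrences=occurrences,
        t=t,
        d=occurrences - t,
        per_token_counts=tuple(sorted(counter.items())),
    )


def humanize_fragment(fragment: str) -> str:
    """Render an IRI fragment as lowercase words (camel split, separators)."""
    return normalize_label(
        fragment,
        ParseOptions(remove_determiners=False),
    )


def export_label_grid(records: list[LabelRecord], destination) -> None:
    """Write the processed-label grid as CSV (the review/processing view)."""
    with open(destination, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            ["entity_iri", "raw_label", "processed_label", "accumulated_senses"]
        )
        for record in records:
            writer.writerow(
                [
                    record.entity_iri,
                    record.raw_label,
                    record.processed_label,
                    record.accumulated_senses,
                ]
            )
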