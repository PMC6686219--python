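"""Expert-review round trip: statement export, verdict import, accuracy.

Each reviewer receives a CSV of verbalized statements, marks each one true
or false (optionally with a note), and returns the file.  Imported verdicts
become per-reviewer true counts that feed the accuracy sub-score: the
fraction of logical axioms judged true, averaged over reviewers.  By
default an unjudged statement counts against accuracy (the denominator is
all logical axioms); a judged-only denominator is available as an option.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field

from .metrics import accuracy
from .model import DataError, UndefinedScoreError
from .verbalize import StatementSet

#: Byte-exact header contract for review CSV interop.
REVIEW_HEADER = ["statement_id", "axiom_type", "sentence", "verdict", "note"]

VERDICTS = ("true", "false", "unjudged")


@dataclass(frozen=True)
class Judgment:
    """One reviewer's verdict on one statement."""

    reviewer_id: str
    statement_id: str
    verdict: str
    note: str = ""

    def __post_init__(self) -> None:
        if self.verdict not in VERDICTS:
            raise DataError(
                f"verdict must be one of {VERDICTS}, got {self.verdict!r}"
            )


@dataclass
class ReviewSet:
    """All judgments collected for one statement set."""

    n_statements: int
    judgments: list[Judgment] = field(default_factory=list)

    @property
    def reviewers(self) -> list[str]:
        return sorted({j.reviewer_id for j in self.judgments})

    def add(self, contributions: list[Judgment]) -> None:
        seen = {(j.reviewer_id, j.statement_id) for j in self.judgments}
        for j in contributions:
            key = (j.reviewer_id, j.statement_id)
            if key in seen:
                raise DataError(
                    f"duplicate judgment for reviewer {j.reviewer_id!r}, "
                    f"statement {j.statement_id}"
                )
            seen.add(key)
            self.judgments.append(j)

    def true_counts(self) -> dict[str, int]:
        counts = {r: 0 for r in self.reviewers}
        for j in self.judgments:
            if j.verdict == "true":
                counts[j.reviewer_id] += 1
        return counts

    def judged_counts(self) -> dict[str, int]:
        counts = {r: 0 for r in self.reviewers}
        for j in self.judgments:
            if j.verdict != "unjudged":
                counts[j.reviewer_id] += 1
        return counts

    @property
    def coverage(self) -> dict[str, float]:
        if self.n_statements == 0:
            return {r: 0.0 for r in self.reviewers}
        judged = self.judged_counts()
        return {r: judged[r] / self.n_statements for r in self.reviewers}


def export_statements(statement_set: StatementSet, destination) -> None:
    """Write the review CSV: statements with blank verdict/note columns."""
    try:
        fh = open(destination, "w", newline="", encoding="utf-8")
    except OSError as exc:
        raise IOError(f"cannot write review file {destination}: {exc}") from exc
    with fh:
        writer = csv.writer(fh)
        writer.writerow(REVIEW_HEADER)
        for stmt in statement_set.statements:
            writer.writerow([stmt.statement_id, stmt.axiom_type, stmt.sentence, "", ""])


def import_judgments(
    path, reviewer_id: str, statement_set: StatementSet
) -> list[Judgment]:
    """Parse one reviewer's filled-in CSV back into judgments.

    Verdicts parse case-insensitively ("true"/"false"; blank = unjudged);
    any other value is a parse error naming the row.  Statement ids not in
    the statement set are rejected with a listing.  Row order is irrelevant.
    """
    known = {s.statement_id for s in statement_set.statements}
    judgments: list[Judgment] = []
    seen_ids: set[str] = set()
    unknown: list[str] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != REVIEW_HEADER:
            raise DataError(
                f"review file {path} has header {header!r}; "
                f"expected {REVIEW_HEADER!r}"
            )
        for row_number, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(REVIEW_HEADER):
                raise DataError(
                    f"{path} row {row_number}: expected "
                    f"{len(REVIEW_HEADER)} columns, got {len(row)}"
                )
            stmt_id, _axiom_type, _sentence, verdict_raw, note = row
            verdict = verdict_raw.strip().lower()
            if verdict == "":
                verdict = "unjudged"
            if verdict not in ("true", "false", "unjudged"):
                raise DataError(
                    f"{path} row {row_number}: unparseable verdict "
                    f"{verdict_raw!r} (expected true/false/blank)"
                )
            if stmt_id in seen_ids:
                raise DataError(
                    f"{path} row {row_number}: duplicate statement_id {stmt_id}"
                )
            seen_ids.add(stmt_id)
            if stmt_id not in known:
                unknown.append(stmt_id)
                continue
            judgments.append(
                Judgment(
                    reviewer_id=reviewer_id,
                    statement_id=stmt_id,
                    verdict=verdict,
                    note=note,
                )
            )
    if unknown:
        raise DataError(
            f"{path}: statement ids not in the statement set: {unknown}"
        )
    return judgments


def accuracy_from_review(
    review_set: ReviewSet,
    n_logical: int,
    denominator: str = "all_logical",
) -> tuple[float, dict[str, float]]:
    """Accuracy PU plus the per-reviewer breakdown.

    ``denominator="all_logical"`` (default) divides each reviewer's true
    count by the full logical-axiom count, so unjudged statements count as
    not-true (a warning flags partial coverage).  ``"judged_only"`` divides
    by the number of statements the reviewer actually judged.
    """
    if not review_set.reviewers:
        raise UndefinedScoreError("accuracy undefined: no reviewers")
    if denominator not in ("all_logical", "judged_only"):
        raise DataError(f"unknown denominator policy {denominator!r}")
    true_counts = review_set.true_counts()
    judged_counts = review_set.judged_counts()
    per_reviewer: dict[str, float] = {}
    if denominator == "all_logical":
        partial = [
            r for r, cov in review_set.coverage.items() if cov < 1.0
        ]
        if partial:
            warnings.warn(
                "unjudged statements count against accuracy for reviewers: "
                + ", ".join(partial),
                stacklevel=2,
            )
        for reviewer in review_set.reviewers:
            per_reviewer[reviewer] = accuracy([true_counts[reviewer]], n_logical)
    else:
        for reviewer in review_set.reviewers:
            judged = judged_counts[reviewer]
            if judged == 0:
                raise UndefinedScoreError(
                    f"reviewer {reviewer!r} judged no statements"
                )
            per_reviewer[reviewer] = accuracy([true_counts[reviewer]], judged)
    pu = sum(per_reviewer.values()) / len(per_reviewer)
    return pu, per_reviewer
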