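"""Review CSV round trip and the accuracy computation it feeds."""

import csv
import warnings

import pytest

from ontoscore.model import DataError, UndefinedScoreError
from ontoscore.review import (
    REVIEW_HEADER,
    Judgment,
    ReviewSet,
    accuracy_from_review,
    export_statements,
    import_judgments,
)
from ontoscore.model import Axiom, AxiomType
from ontoscore.verbalize import Statement, StatementSet, statement_id


def _statement_set(n=10):
    statements = []
    for i in range(n):
        axiom = Axiom(
            AxiomType.SUB_CLASS_OF, (f"http://x#A{i}", f"http://x#B{i}")
        )
        statements.append(
            Statement(
                statement_id=statement_id(axiom),
                axiom_type="SubClassOf",
                sentence=f"Every a{i} is a b{i}.",
                source=axiom,
            )
        )
    statements.sort(key=lambda s: s.statement_id)
    return StatementSet(
        ontology_iri="http://x", statements=tuple(statements), n_unsupported=0
    )


def _fill(path, out, verdicts):
    rows = list(csv.reader(open(path)))
    for row, verdict in zip(rows[1:], verdicts):
        row[3] = verdict
    with open(out, "w", newline="") as fh:
        csv.writer(fh).writerows(rows)


def test_export_has_exact_header_and_rows(tmp_path):
    path = tmp_path / "r.csv"
    export_statements(_statement_set(3), path)
    rows = list(csv.reader(open(path)))
    assert rows[0] == REVIEW_HEADER
    assert len(rows) == 4
    assert all(row[3] == "" and row[4] == "" for row in rows[1:])


def test_export_empty_set_header_only(tmp_path):
    path = tmp_path / "r.csv"
    export_statements(
        StatementSet(ontology_iri=None, statements=(), n_unsupported=0), path
    )
    assert list(csv.reader(open(path))) == [REVIEW_HEADER]


def test_unedited_round_trip_is_all_unjudged(tmp_path):
    statement_set = _statement_set(4)
    path = tmp_path / "r.csv"
    export_statements(statement_set, path)
    judgments = import_judgments(path, "alice", statement_set)
    assert all(j.verdict == "unjudged" for j in judgments)


def test_import_parses_verdicts_case_insensitively(tmp_path):
    statement_set = _statement_set(10)
    raw, filled = tmp_path / "raw.csv", tmp_path / "filled.csv"
    export_statements(statement_set, raw)
    _fill(raw, filled, ["true"] * 4 + ["TRUE"] * 4 + ["False", "FALSE"])
    review_set = ReviewSet(n_statements=10)
    review_set.add(import_judgments(filled, "alice", statement_set))
    assert review_set.true_counts()["alice"] == 8
    assert review_set.coverage["alice"] == 1.0


def test_partial_coverage(tmp_path):
    statement_set = _statement_set(10)
    raw, filled = tmp_path / "raw.csv", tmp_path / "filled.csv"
    export_statements(statement_set, raw)
    _fill(raw, filled, ["true"] * 5)
    review_set = ReviewSet(n_statements=10)
    review_set.add(import_judgments(filled, "bob", statement_set))
    assert review_set.coverage["bob"] == 0.5


def test_unparseable_verdict_names_row(tmp_path):
    statement_set = _statement_set(3)
    raw, filled = tmp_path / "raw.csv", tmp_path / "filled.csv"
    export_statements(statement_set, raw)
    _fill(raw, filled, ["true", "maybe", "false"])
    with pytest.raises(DataError, match="row 3"):
        import_judgments(filled, "alice", statement_set)


def test_unknown_statement_id_rejected(tmp_path):
    statement_set = _statement_set(2)
    path = tmp_path / "r.csv"
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(REVIEW_HEADER)
        writer.writerow(["deadbeef00000000", "SubClassOf", "x", "true", ""])
    with pytest.raises(DataError, match="deadbeef00000000"):
        import_judgments(path, "alice", statement_set)


def test_duplicate_statement_id_rejected(tmp_path):
    statement_set = _statement_set(2)
    sid = statement_set.statements[0].statement_id
    path = tmp_path / "r.csv"
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(REVIEW_HEADER)
        writer.writerow([sid, "SubClassOf", "x", "true", ""])
        writer.writerow([sid, "SubClassOf", "x", "false", ""])
    with pytest.raises(DataError, match="duplicate"):
        import_judgments(path, "alice", statement_set)


def test_wrong_header_rejected(tmp_path):
    path = tmp_path / "r.csv"
    path.write_text("id,type,text\n")
    with pytest.raises(DataError, match="header"):
        import_judgments(path, "alice", _statement_set(1))


def test_import_insensitive_to_row_order(tmp_path):
    statement_set = _statement_set(5)
    raw = tmp_path / "raw.csv"
    export_statements(statement_set, raw)
    rows = list(csv.reader(open(raw)))
    verdicts = ["true", "false", "true", "", "true"]
    for row, verdict in zip(rows[1:], verdicts):
        row[3] = verdict
    forward, backward = tmp_path / "f.csv", tmp_path / "b.csv"
    with open(forward, "w", newline="") as fh:
        csv.writer(fh).writerows([rows[0]] + rows[1:])
    with open(backward, "w", newline="") as fh:
        csv.writer(fh).writerows([rows[0]] + list(reversed(rows[1:])))
    a = sorted(
        (j.statement_id, j.verdict)
        for j in import_judgments(forward, "r", statement_set)
    )
    b = sorted(
        (j.statement_id, j.verdict)
        for j in import_judgments(backward, "r", statement_set)
    )
    assert a == b


class TestAccuracyFromReview:
    def _review_set(self, counts_per_reviewer, n_statements):
        review_set = ReviewSet(n_statements=n_statements)
        statement_set = _statement_set(n_statements)
        for reviewer, (n_true, n_judged) in counts_per_reviewer.items():
            judgments = []
            for i, statement in enumerate(statement_set.statements):
                if i < n_true:
                    verdict = "true"
                elif i < n_judged:
                    verdict = "false"
                else:
                    verdict = "unjudged"
                judgments.append(
                    Judgment(reviewer, statement.statement_id, verdict)
                )
            review_set.add(judgments)
        return review_set

    def test_two_reviewers_average(self):
        review_set = self._review_set({"a": (8, 10), "b": (6, 10)}, 10)
        pu, breakdown = accuracy_from_review(review_set, 10)
        assert pu == pytest.approx(0.7)
        assert breakdown == {"a": pytest.approx(0.8), "b": pytest.approx(0.6)}

    def test_default_denominator_counts_unjudged_against(self):
        review_set = self._review_set({"a": (5, 10)}, 20)
        with pytest.warns(UserWarning, match="unjudged"):
            pu, _ = accuracy_from_review(review_set, 20)
        assert pu == pytest.approx(0.25)

    def test_judged_only_denominator(self):
        review_set = self._review_set({"a": (5, 10)}, 20)
        pu, _ = accuracy_from_review(review_set, 20, denominator="judged_only")
        assert pu == pytest.approx(0.5)

    def test_default_never_exceeds_judged_only(self):
        for n_true, n_judged in [(3, 5), (0, 4), (7, 7), (2, 9)]:
            review_set = self._review_set({"a": (n_true, n_judged)}, 10)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                default, _ = accuracy_from_review(review_set, 10)
            judged, _ = accuracy_from_review(
                review_set, 10, denominator="judged_only"
            )
            assert default <= judged + 1e-12

    def test_no_reviewers_undefined(self):
        with pytest.raises(UndefinedScoreError):
            accuracy_from_review(ReviewSet(n_statements=5), 5)
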