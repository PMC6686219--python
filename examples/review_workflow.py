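"""Round-trip the expert-review workflow and compute accuracy.

Exports the review CSV two experts would receive, fills in their verdicts
programmatically (one judges 8 of 10 statements true, the other 6), imports
both files and averages the per-reviewer true fractions into the accuracy
sub-score: (0.8 + 0.6) / 2 = 0.7.
"""

import csv
import tempfile
from pathlib import Path

from ontoscore import (
    ReviewSet,
    accuracy_from_review,
    export_statements,
    import_judgments,
    load_ontology,
    verbalize_ontology,
)
from ontoscore.synth import SynthSpec, generate_ontology
from ontoscore.verbalize import StatementSet

with tempfile.TemporaryDirectory() as tmp:
    tmp_path = Path(tmp)
    ttl_path = tmp_path / "demo.ttl"
    generate_ontology(SynthSpec(seed=1), ttl_path)
    statements = verbalize_ontology(load_ontology(ttl_path))
    # keep ten statements so the arithmetic is easy to follow
    subset = StatementSet(
        ontology_iri=statements.ontology_iri,
        statements=statements.statements[:10],
        n_unsupported=0,
    )

    review_set = ReviewSet(n_statements=10)
    for reviewer, n_true in (("alice", 8), ("bob", 6)):
        blank = tmp_path / f"{reviewer}_blank.csv"
        export_statements(subset, blank)
        rows = list(csv.reader(open(blank)))
        for i, row in enumerate(rows[1:]):
            row[3] = "true" if i < n_true else "false"
        filled = tmp_path / f"{reviewer}.csv"
        with open(filled, "w", newline="") as fh:
            csv.writer(fh).writerows(rows)
        review_set.add(import_judgments(filled, reviewer, subset))

    accuracy, per_reviewer = accuracy_from_review(review_set, n_logical=10)

for reviewer, score in sorted(per_reviewer.items()):
    print(f"{reviewer}: fraction judged true = {score:.2f}")
print(f"accuracy sub-score PU = {accuracy:.2f}  (average over reviewers)")
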