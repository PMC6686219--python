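"""Independent straight-line recomputation of every sub-score.

Deliberately bypasses the package's loading and label pipeline: labels are
read straight off the Turtle file with rdflib, tokenized with a private
regex per label style, and every sub-score is computed from raw counts in
one line of arithmetic each.  Used as the second route in dual-route
equivalence tests.
"""

from __future__ import annotations

import re

from rdflib import Graph
from rdflib.namespace import RDFS


def tokens_from_file(ttl_path, style: str) -> list[str]:
    g = Graph()
    g.parse(str(ttl_path), format="turtle")
    tokens: list[str] = []
    for label in (str(o) for o in g.objects(None, RDFS.label)):
        if style == "camel":
            tokens.extend(w.lower() for w in re.findall(r"[A-Z][a-z]*", label))
        elif style == "underscore":
            tokens.extend(label.split("_"))
        else:
            tokens.extend(label.split(" "))
    return tokens


def subscores(ttl_path, spec, baseline: float, true_counts=None) -> dict:
    """Every sub-score from raw counts, in both equation modes."""
    tokens = tokens_from_file(ttl_path, spec.label_style)
    unique = sorted(set(tokens))
    t = len(unique)
    occurrences = len(tokens)
    d = occurrences - t
    sense_of = {w: spec.vocabulary.get(w, 0) for w in unique}
    t_sense = sum(1 for w in unique if sense_of[w] >= 1)
    total_senses = sum(sense_of.values())

    ax = spec.expected_axiom_census()
    n_elements = spec.expected_element_census().n_elements
    out = {
        "SL_literal": spec.expected_violations() / ax.n_total,
        "SR": len(spec.expected_features()) / 39,
        "EI_classic": t_sense / t,
        "EA": max(0.0, 1 - (total_senses / t) / t),
        "EC": max(0.0, 1 - d / t),
        "PO": n_elements / baseline,
    }
    out["SL_classic"] = 1 - out["SL_literal"]
    out["EI_literal"] = 1 - out["EI_classic"]
    if true_counts is not None:
        fractions = [c / ax.n_logical for c in true_counts]
        out["PU"] = sum(fractions) / len(fractions)
    return out
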