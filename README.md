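# ontoscore

Semiotic quality scoring for OWL ontologies.

Ontology engineers — in biomedical informatics especially — need a fast,
repeatable answer to "how good is this ontology?" before shipping it to a
repository or building applications on it. `ontoscore` grades an OWL 2
ontology on the four layers of the semiotic metric framework and rolls them
into one weighted quality score, and it translates the ontology's logical
axioms into plain English so domain experts who do not read description
logic can audit its factual accuracy.

## The scoring model

Each aspect is a weighted sum of sub-scores, and the overall quality is a
weighted sum of the aspects:

```
syntactic   S = w_s1·SL + w_s2·SR
semantic    E = w_e1·EI + w_e2·EC + w_e3·EA
pragmatic   P = w_p1·PO + w_p2·PU + w_p3·PR
social      O = w_o1·OT + w_o2·OH
quality     Q = w_q1·S + w_q2·E + w_q3·P + w_q4·O
```

| sub-score | name | definition |
|---|---|---|
| SL | lawfulness | complement of the OWL 2 DL violation fraction, 1 − v/AX (literal mode: v/AX) |
| SR | richness | fraction of the 39 possible OWL constructs used |
| EI | interpretability | fraction of unique label tokens with ≥ 1 word sense in the lexical database (literal mode: its complement) |
| EC | consistency | 1 − d/t, where d = duplicate token occurrences, t = unique tokens |
| EA | clarity | 1 − (average senses per unique token)/t |
| PO | comprehensiveness | element count / library-baseline average (may exceed 1) |
| PU | accuracy | fraction of verbalized logical axioms judged true by experts, averaged over reviewers |
| PR | relevancy | user-supplied task-fit score in [0, 1] |
| OT, OH | authority, history | manual social-layer inputs in [0, 1] |

Label tokens come from a configurable normalization pipeline (camel-case
splitting, bracket/underscore/dash handling, determiner removal,
lowercasing); word senses come from a pluggable lexical database — a
CSV-backed fixture lexicon, or WordNet when a corpus is installed.
Aspects can be excluded (their weight is redistributed or zeroed), and the
two defect-oriented equations are available in both a `literal` and the
default `classic` (complemented) reading.

## Worked example

```python
from ontoscore import Weights, lawfulness, overall_quality
from ontoscore.model import AxiomCensus

weights = Weights(aspect=(0.15, 0.51, 0.33, 0.0), auto_normalize=False)
print(overall_quality(1.0, 1.0, 1.0, None, weights))   # 0.99

census = AxiomCensus(n_logical=80, n_non_logical=20)   # 100 axioms
print(lawfulness(census, 5, "literal"))                # 0.05
print(lawfulness(census, 5, "classic"))                # 0.95
```

With the social aspect excluded and explicit weights 0.15/0.51/0.33 used
as-is, perfect aspect scores give Q = 0.99 (the weights sum to 0.99, not
1).  Five violations among 100 axioms are a violation fraction of 0.05;
the classic lawfulness score is its complement, 0.95.

Scoring a generated ontology end to end
(`python examples/score_synthetic_ontology.py`) prints:

```
Semiotic quality report
=======================
syntactic S = 0.641026  (aspect weight 0.3333)
  lawfulness SL = 1.000000  (weight 0.5, mode classic)
  richness   SR = 0.282051  (weight 0.5)
semantic  E = 0.539259  (aspect weight 0.3333)
  interpretability EI = 0.866667  (weight 0.3333, mode classic)
  consistency      EC = 0.000000  (weight 0.3333)
  clarity          EA = 0.751111  (weight 0.3333)
pragmatic P = 0.046000  (aspect weight 0.3333)
  comprehensiveness PO = 0.046000  (weight 0.3333)
  ...
overall quality Q = 0.408762
excluded aspects: social
flag: consistency clamped to 0 (raw -1.0667)
```

Lawfulness 1.0: no DL violations.  Richness 11/39 ≈ 0.28: the ontology
uses 11 of the 39 cataloged OWL constructs.  Comprehensiveness 0.046: 23
elements against a 500-element baseline.  The consistency flag shows the
raw value behind the clamped 0 — the small demo vocabulary repeats tokens
heavily.

The other `examples/` scripts demonstrate axiom verbalization
(`verbalize_axioms.py`), the expert-review CSV round trip and the accuracy
average (`review_workflow.py`), and weighting/equation modes
(`weights_and_modes.py`).

## Command line

```
ontoscore score --ontology onto.ttl --lexicon senses.csv --baseline 500 \
    --exclude social
ontoscore verbalize onto.ttl --out statements.csv
ontoscore review export onto.ttl review.csv
ontoscore review import onto.ttl review_filled.csv --reviewer alice
ontoscore snapshot show snapshot.json
```

All options can also live in a YAML/JSON config file (`--config`);
command-line flags override it.

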