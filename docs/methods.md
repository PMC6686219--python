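# Methods

## The semiotic quality model

The package treats an ontology as a sign system and grades it on four
layers: **syntactic** (is it well-formed and expressive?), **semantic**
(are its names understandable?), **pragmatic** (is it useful — big enough,
factually accurate, relevant?), and **social** (is it trusted by the
community?).  Each layer is a weighted sum of sub-scores and the layers
combine into one composite Q; all weighting is linear, so Q is monotone in
every sub-score with non-negative weights.

### Syntactic

*Lawfulness* compares the number of OWL 2 DL profile violations to the
total axiom count AX (logical plus non-logical).  The violation checker
implements a documented subset of the OWL 2 global restrictions:
reserved-vocabulary misuse in declarations, class/datatype punning,
undeclared named classes in class axioms, and transitive (non-simple)
properties inside cardinality restrictions.  Full profile checking is
unbounded scope; the subset is deterministic and testable, and only the
count feeds the score.

*Richness* divides the number of distinct OWL constructs the ontology uses
by the 39 constructs an OWL ontology can use.  The catalog behind that
denominator is an explicit constant (`FEATURE_CATALOG`): the 31 logical
axiom types of the structural model plus eight class-expression constructs
(intersection, union, complement, enumeration, existential and universal
restriction, value restriction, and cardinality — the min/max/exact
variants fold into one feature).  Fixing the catalog in code makes the
denominator auditable and the score reproducible.

### Semantic

All three semantic sub-scores are computed over the tokens of the
ontology's labels after normalization.  The pipeline applies, in a fixed
order: bracket-character removal (keeping enclosed text; dropping it is a
documented flag), underscore/dash → space, camel-case splitting,
lowercasing, determiner removal ("a", "an", "the" as standalone tokens),
whitespace collapse.  The order is pinned because it changes outcomes
("theHeart" must be camel-split before the determiner is visible).  Labels
that normalize to nothing are marked and excluded from tallies.
Uniqueness is case-folded exact match — no stemming or lemmatization.

With t unique tokens, d duplicate occurrences (total occurrences minus t,
counted corpus-wide across all labels), sense counts from the lexical
database summed over all parts of speech:

* interpretability EI = t_sense/t (classic) or 1 − t_sense/t (literal),
  where t_sense is the number of unique tokens with at least one sense;
* consistency EC = 1 − d/t;
* clarity EA = 1 − (total_senses/t)/t.

EC and EA can go negative (more duplicates than unique tokens; average
sense count exceeding t).  `clamp_to_unit` (default on) floors them at 0;
the raw value is kept in the score card's inputs and flagged in reports.

### Pragmatic

*Comprehensiveness* PO divides the ontology's element count (declared
classes, individuals, object properties, data properties) by a
user-supplied library-baseline average — classically 500, but modern
repository averages run far higher (e.g. 169,862 for a drug-ontology set),
so PO is deliberately **not** clamped and reports flag PO > 1.

*Accuracy* PU comes from the expert-review loop: every supported logical
axiom is verbalized to English, reviewers mark statements true or false,
and each reviewer's true count is divided by the logical-axiom count, then
averaged over reviewers.  By default an unjudged statement counts as
not-true (the denominator is all logical axioms); `judged_only` is the
alternative policy, and the default is never above it.

*Relevancy* PR is inherently task-specific (e.g. competency-question
adherence) and is a manual input in [0, 1]; absent sub-scores have their
weight redistributed when auto-normalization is on.

### Social

Authority (inter-ontology links) and history (access counts) require a
repository census outside this package's scope; both are manual inputs in
[0, 1].  If the social aspect is active but neither input is given, the
aspect is dropped with a warning rather than scored as zero.

## Equation modes

Two printed forms of the suite read as defect fractions: lawfulness as
violations/AX and interpretability as 1 − coverage.  Both contradict the
convention that higher scores are better, and the complemented forms match
the classic semiotic metric suite this model descends from.  The package
makes both first-class: `literal` evaluates the defect-fraction form
bit-for-bit, `classic` (default) its complement; the mode used is recorded
in every score card, and the two are verified complements in the test
suite.  Neither is asserted to be "the original tool's" behavior — that
cannot be settled from the published description.

## Weighting

Weights are two-level: within each aspect and across aspects.  With
`auto_normalize` (default) the weights of the *active* members of a group
are rescaled to sum to one, so excluding an aspect and renormalizing
equals computing Q over the remaining aspects directly, and Q is invariant
under positive rescaling of the raw weights.  Explicit weights pass
through unrescaled when auto-normalization is off — the demonstration
weighting 0.15/0.51/0.33 with social excluded yields Q = 0.99 for perfect
aspects, not 1.

## Ontology reading

Parsing is structural, over rdflib: triples map onto a closed enumeration
of 33 axiom types (31 logical, plus declarations and annotation
assertions, which are non-logical — the OWL structural-specification
convention).  Class expressions decode recursively into tagged tuples.
Named-entity censuses count declared entities only; anonymous expressions
are excluded.  Labels default to `rdfs:label` with `skos:prefLabel` as
opt-in, preferring untagged then English literals; unlabeled entities fall
back to their IRI fragment.  `owl:imports` is not followed by default
(scores then reflect only what is local to the file, with a warning);
following is a flag and resolves only local files, `file://` IRIs, or an
explicit IRI→path map — never the network.

## Verbalization

Twenty-five logical axiom types have English templates (the six without —
disjoint union, data-property equivalence/disjointness, irreflexivity, and
the two negative assertions — are counted as unsupported, preserving the
accounting invariant statements + unsupported = logical axioms).  The
template table is this package's own: one fixed sentence pattern per type,
nested expressions rendered recursively, indefinite articles by
initial-letter heuristic, no pluralization engine.  Sentences are pure
functions of the axiom and label map, and never contain a raw URI.

## Synthetic test ontologies

`SynthSpec` generates Turtle ontologies whose censuses are known *by
construction*: entity counts, an axiom recipe (type → count), expression
features to exercise (each carried by one extra subclass axiom), one label
per entity drawn from a vocabulary with per-word sense counts, and injected
violations (class/datatype punning, one per injection).  Output is sorted
text with inlined anonymous nodes, so a seed fixes the bytes.  Defaults
model a small curated biomedical module: 12 classes, 6 individuals, 3
object and 2 data properties, a subclass backbone with assertions and
property axioms, and a 17-word clinically flavored vocabulary whose sense
counts span WordNet-like magnitudes (0–10), including out-of-vocabulary
coinages so sense coverage stays realistically below 1.

What the generator does *not* emulate: real biomedical label length and
Zipfian token distributions, multilingual labels, annotation richness,
deep class hierarchies, or genuinely malformed RDF.  Passing tests
therefore demonstrate correctness of the arithmetic and the parsing
contract on well-formed input, not robustness to arbitrary ontologies in
the wild.

Test suites sweep seeds 1–50 through a randomized spec space (6–20
classes, varied recipes, styles and injections) and compare every
sub-score against an independent straight-line recomputation that reads
labels directly off the Turtle file; sizes are kept small so the whole
suite runs in seconds on one CPU.

## Numerical and design choices

* Duplicate count d = occurrences − unique: each repeat beyond a token's
  first occurrence counts once, keeping EC ≤ 1 with equality exactly when
  all tokens are unique.  Duplicates are counted corpus-wide, not
  per-label.
* Sense lookups are per-token; multi-word collocations are not attempted.
  No lemmatization is applied before lookup.
* Scores with zero denominators (no axioms, no tokens, no reviewers) raise
  an undefined-score error rather than returning a sentinel.
* Snapshots are schema-versioned JSON; scores round-trip to 1e−12.
  Reports (text or JSON) trace every number to a recorded census.
* The WordNet backend requires an importable WordNet corpus at runtime and
  raises a clear environment error pointing to the fixture lexicon
  otherwise; the test suite runs entirely on fixture lexicons.

## Known limitations

* The DL violation count is a lower bound: the checker covers four global
  restrictions, not the full OWL 2 DL profile.
* The structural reader handles the common RDF mapping of OWL axioms;
  exotic reifications (axiom annotations carrying the only copy of an
  axiom, n-ary equivalence chains) may be under-counted.
* Verbalization quality is template-bound; fluency degrades for deeply
  nested expressions.
* OBO serialization, SPARQL endpoints and remote ontology repositories are
  out of scope.
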