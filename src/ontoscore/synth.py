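"""Synthetic test ontologies with fully known censuses.

A :class:`SynthSpec` is a recipe — entity counts, an axiom recipe, optional
class-expression features to exercise, a label vocabulary with per-word
sense counts, and a number of injected DL violations — that deterministically
generates a Turtle ontology.  Because the recipe fixes every census in
advance (``expected_axiom_census`` etc.), the generated files serve as exact
oracles for the whole loading-and-scoring pipeline.  The same seed always
produces byte-identical output: triples are emitted as sorted text lines,
and anonymous expression nodes are inlined.

Violations are injected as class/datatype punning (declaring an existing
class IRI also as ``rdfs:Datatype``), the canonical detectable violation.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .lexicon import FixtureLexicon
from .model import (
    AxiomCensus,
    AxiomType,
    DataError,
    ElementCensus,
    EXPRESSION_FEATURES,
    LOGICAL_AXIOM_TYPES,
)

#: Default label vocabulary: clinically flavored words with sense counts of
#: realistic WordNet magnitude, plus coined out-of-vocabulary terms (0
#: senses) so sense coverage stays below 1 as in real biomedical labels.
DEFAULT_VOCABULARY: dict[str, int] = {
    "heart": 10,
    "attack": 9,
    "disease": 3,
    "organ": 5,
    "blood": 4,
    "pressure": 7,
    "cell": 7,
    "tissue": 4,
    "muscle": 2,
    "failure": 5,
    "acute": 4,
    "chronic": 2,
    "therapy": 1,
    "gene": 1,
    "protein": 1,
    "angiomir": 0,
    "cardiotox": 0,
}

_BASE = "http://example.org/synth"
_NS = _BASE + "#"

_PREAMBLE = [
    "@prefix ex: <http://example.org/synth#> .",
    "@prefix owl: <http://www.w3.org/2002/07/owl#> .",
    "@prefix rdf: <http://www.w3.org/1999/02/22-rdf-syntax-ns#> .",
    "@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .",
    "@prefix xsd: <http://www.w3.org/2001/XMLSchema#> .",
    "",
    "<http://example.org/synth> a owl:Ontology .",
    "",
]

_PAIR_TYPES = {
    "SubClassOf": ("class", "rdfs:subClassOf"),
    "EquivalentClasses": ("class", "owl:equivalentClass"),
    "DisjointClasses": ("class", "owl:disjointWith"),
    "SubObjectPropertyOf": ("object_property", "rdfs:subPropertyOf"),
    "EquivalentObjectProperties": ("object_property", "owl:equivalentProperty"),
    "DisjointObjectProperties": ("object_property", "owl:propertyDisjointWith"),
    "InverseObjectProperties": ("object_property", "owl:inverseOf"),
    "SubDataPropertyOf": ("data_property", "rdfs:subPropertyOf"),
    "EquivalentDataProperties": ("data_property", "owl:equivalentProperty"),
    "DisjointDataProperties": ("data_property", "owl:propertyDisjointWith"),
    "SameIndividual": ("individual", "owl:sameAs"),
    "DifferentIndividuals": ("individual", "owl:differentFrom"),
}

_CHARACTERISTIC_TYPES = {
    "FunctionalObjectProperty": ("object_property", "owl:FunctionalProperty"),
    "InverseFunctionalObjectProperty": (
        "object_property",
        "owl:InverseFunctionalProperty",
    ),
    "TransitiveObjectProperty": ("object_property", "owl:TransitiveProperty"),
    "SymmetricObjectProperty": ("object_property", "owl:SymmetricProperty"),
    "AsymmetricObjectProperty": ("object_property", "owl:AsymmetricProperty"),
    "ReflexiveObjectProperty": ("object_property", "owl:ReflexiveProperty"),
    "IrreflexiveObjectProperty": ("object_property", "owl:IrreflexiveProperty"),
    "FunctionalDataProperty": ("data_property", "owl:FunctionalProperty"),
}

_LOGICAL_TAGS = {t.value for t in LOGICAL_AXIOM_TYPES}

_DEFAULT_RECIPE: dict[str, int] = {
    "SubClassOf": 8,
    "DisjointClasses": 2,
    "ObjectPropertyDomain": 2,
    "ObjectPropertyRange": 2,
    "ClassAssertion": 4,
    "ObjectPropertyAssertion": 3,
    "DataPropertyAssertion": 2,
    "FunctionalObjectProperty": 1,
    "TransitiveObjectProperty": 1,
}


@dataclass(frozen=True)
class SynthSpec:
    """Recipe for one synthetic ontology; the seed fixes the output bytes."""

    seed: int
    n_classes: int = 12
    n_individuals: int = 6
    n_object_properties: int = 3
    n_data_properties: int = 2
    axiom_recipe: dict[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_RECIPE)
    )
    features: tuple[str, ...] = ("ObjectSomeValuesFrom", "ObjectIntersectionOf")
    vocabulary: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_VOCABULARY)
    )
    violation_injections: int = 0
    label_style: str = "camel"  # camel | underscore | plain

    # -- expected censuses (the oracle side of the round trip)

    @property
    def n_entities(self) -> int:
        return (
            self.n_classes
            + self.n_individuals
            + self.n_object_properties
            + self.n_data_properties
        )

    def expected_axiom_census(self) -> AxiomCensus:
        n_logical = sum(self.axiom_recipe.values()) + len(self.features)
        # declarations (one per entity, plus one datatype per injection)
        # and one label annotation per entity
        n_non_logical = 2 * self.n_entities + self.violation_injections
        return AxiomCensus(n_logical=n_logical, n_non_logical=n_non_logical)

    def expected_element_census(self) -> ElementCensus:
        return ElementCensus(
            n_classes=self.n_classes,
            n_individuals=self.n_individuals,
            n_object_properties=self.n_object_properties,
            n_data_properties=self.n_data_properties,
        )

    def expected_features(self) -> frozenset[str]:
        used = {t for t, n in self.axiom_recipe.items() if n > 0}
        used |= set(self.features)
        if self.features:
            used.add("SubClassOf")  # feature carriers are SubClassOf axioms
        return frozenset(used)

    def expected_violations(self) -> int:
        return self.violation_injections

    # -- validation

    def validate(self) -> None:
        errors: list[str] = []
        counts = {
            "class": self.n_classes,
            "individual": self.n_individuals,
            "object_property": self.n_object_properties,
            "data_property": self.n_data_properties,
        }
        if any(n < 0 for n in counts.values()):
            errors.append("entity counts must be non-negative")
        for word in self.vocabulary:
            if not word.isalpha() or word != word.lower():
                errors.append(f"vocabulary word {word!r} must be lowercase alphabetic")
        if not self.vocabulary:
            errors.append("vocabulary must be non-empty")
        if self.label_style not in ("camel", "underscore", "plain"):
            errors.append(f"unknown label_style {self.label_style!r}")
        for tag, n in self.axiom_recipe.items():
            if tag not in _LOGICAL_TAGS:
                errors.append(f"recipe type {tag!r} is not a logical axiom type")
                continue
            if n < 0:
                errors.append(f"recipe count for {tag} must be non-negative")
                continue
            cap = self._capacity(tag, counts)
            if n > cap:
                errors.append(
                    f"recipe asks for {n} {tag} axioms but entity counts "
                    f"support at most {cap}"
                )
        for feat in self.features:
            if feat not in EXPRESSION_FEATURES:
                errors.append(f"unknown expression feature {feat!r}")
        if self.features and self.n_classes < 3:
            errors.append("expression features need at least 3 classes")
        needs_prop = {
            "ObjectSomeValuesFrom",
            "ObjectAllValuesFrom",
            "ObjectHasValue",
            "ObjectCardinality",
        }
        if set(self.features) & needs_prop and self.n_object_properties < 1:
            errors.append("restriction features need an object property")
        if (
            set(self.features) & {"ObjectHasValue", "ObjectOneOf"}
            and self.n_individuals < 2
        ):
            errors.append("ObjectHasValue/ObjectOneOf need at least 2 individuals")
        if "ObjectCardinality" in self.features:
            n_transitive = self.axiom_recipe.get("TransitiveObjectProperty", 0)
            if n_transitive >= self.n_object_properties:
                errors.append(
                    "ObjectCardinality feature requires a non-transitive "
                    "object property (it would otherwise inject an "
                    "unplanned DL violation)"
                )
        if self.violation_injections < 0:
            errors.append("violation_injections must be non-negative")
        if self.violation_injections > self.n_classes:
            errors.append("violation injections need one class each")
        if errors:
            raise DataError("inconsistent SynthSpec: " + "; ".join(errors))

    def _capacity(self, tag: str, counts: dict[str, int]) -> int:
        if tag in _PAIR_TYPES:
            kind, _ = _PAIR_TYPES[tag]
            n = counts[kind]
            return n * (n - 1)
        if tag in _CHARACTERISTIC_TYPES:
            kind, _ = _CHARACTERISTIC_TYPES[tag]
            return counts[kind]
        if tag in ("ObjectPropertyDomain", "ObjectPropertyRange"):
            return counts["object_property"] * counts["class"]
        if tag in ("DataPropertyDomain",):
            return counts["data_property"] * counts["class"]
        if tag == "DataPropertyRange":
            return counts["data_property"]
        if tag == "ClassAssertion":
            return counts["individual"] * counts["class"]
        if tag in ("ObjectPropertyAssertion", "NegativeObjectPropertyAssertion"):
            return (
                counts["individual"]
                * max(0, counts["individual"] - 1)
                * counts["object_property"]
            )
        if tag in ("DataPropertyAssertion", "NegativeDataPropertyAssertion"):
            return counts["individual"] * counts["data_property"] * 100
        if tag == "DisjointUnion":
            return counts["class"] if counts["class"] >= 3 else 0
        if tag == "HasKey":
            return counts["class"] if counts["object_property"] >= 1 else 0
        return 0  # pragma: no cover


def _iri(kind: str, i: int) -> str:
    prefix = {"class": "C", "individual": "I", "object_property": "P", "data_property": "D"}[kind]
    return f"ex:{prefix}{i + 1}"


def _style_label(words: list[str], style: str) -> str:
    if style == "camel":
        return "".join(w.capitalize() for w in words)
    if style == "underscore":
        return "_".join(words)
    return " ".join(words)


def generate_ontology(spec: SynthSpec, path=None) -> str:
    """Render the spec as deterministic Turtle text (optionally to a file).

    Parsing the output back yields censuses exactly equal to the spec's
    expected values; the same spec always produces identical bytes.
    """
    spec.validate()
    rng = random.Random(spec.seed)
    lines: list[str] = []

    counts = {
        "class": spec.n_classes,
        "individual": spec.n_individuals,
        "object_property": spec.n_object_properties,
        "data_property": spec.n_data_properties,
    }
    decl_class = {
        "class": "owl:Class",
        "individual": "owl:NamedIndividual",
        "object_property": "owl:ObjectProperty",
        "data_property": "owl:DatatypeProperty",
    }
    vocab = sorted(spec.vocabulary)
    for kind in ("class", "individual", "object_property", "data_property"):
        for i in range(counts[kind]):
            iri = _iri(kind, i)
            lines.append(f"{iri} a {decl_class[kind]} .")
            n_words = 2 if len(vocab) >= 2 else 1
            words = rng.sample(vocab, n_words)
            label = _style_label(words, spec.label_style)
            lines.append(f'{iri} rdfs:label "{label}" .')

    for tag in sorted(spec.axiom_recipe):
        n = spec.axiom_recipe[tag]
        if n == 0:
            continue
        lines.extend(_emit_axioms(tag, n, counts, rng))

    for idx, feat in enumerate(spec.features):
        subject = _iri("class", idx % spec.n_classes)
        lines.append(f"{subject} rdfs:subClassOf {_feature_expr(feat, counts)} .")

    for i in range(spec.violation_injections):
        lines.append(f'{_iri("class", i)} a rdfs:Datatype .')

    text = "\n".join(_PREAMBLE + sorted(lines)) + "\n"
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text


def _emit_axioms(
    tag: str, n: int, counts: dict[str, int], rng: random.Random
) -> list[str]:
    lines: list[str] = []
    if tag in _PAIR_TYPES:
        kind, predicate = _PAIR_TYPES[tag]
        total = counts[kind]
        pairs = [(i, j) for i in range(total) for j in range(total) if i != j]
        for i, j in rng.sample(pairs, n):
            lines.append(f"{_iri(kind, i)} {predicate} {_iri(kind, j)} .")
    elif tag in _CHARACTERISTIC_TYPES:
        kind, owl_class = _CHARACTERISTIC_TYPES[tag]
        for i in range(n):
            lines.append(f"{_iri(kind, i)} a {owl_class} .")
    elif tag in ("ObjectPropertyDomain", "ObjectPropertyRange"):
        predicate = "rdfs:domain" if tag.endswith("Domain") else "rdfs:range"
        pairs = [
            (p, c)
            for p in range(counts["object_property"])
            for c in range(counts["class"])
        ]
        for p, c in rng.sample(pairs, n):
            lines.append(
                f"{_iri('object_property', p)} {predicate} {_iri('class', c)} ."
            )
    elif tag == "DataPropertyDomain":
        pairs = [
            (d, c)
            for d in range(counts["data_property"])
            for c in range(counts["class"])
        ]
        for d, c in rng.sample(pairs, n):
            lines.append(
                f"{_iri('data_property', d)} rdfs:domain {_iri('class', c)} ."
            )
    elif tag == "DataPropertyRange":
        for d in range(n):
            lines.append(f"{_iri('data_property', d)} rdfs:range xsd:string .")
    elif tag == "ClassAssertion":
        pairs = [
            (i, c)
            for i in range(counts["individual"])
            for c in range(counts["class"])
        ]
        for i, c in rng.sample(pairs, n):
            lines.append(f"{_iri('individual', i)} a {_iri('class', c)} .")
    elif tag == "ObjectPropertyAssertion":
        triples = [
            (s, p, o)
            for s in range(counts["individual"])
            for o in range(counts["individual"])
            if s != o
            for p in range(counts["object_property"])
        ]
        for s, p, o in rng.sample(triples, n):
            lines.append(
                f"{_iri('individual', s)} {_iri('object_property', p)} "
                f"{_iri('individual', o)} ."
            )
    elif tag == "DataPropertyAssertion":
        for k in range(n):
            s = rng.randrange(counts["individual"])
            d = rng.randrange(counts["data_property"])
            lines.append(
                f'{_iri("individual", s)} {_iri("data_property", d)} "v{k}" .'
            )
    elif tag == "NegativeObjectPropertyAssertion":
        triples = [
            (s, p, o)
            for s in range(counts["individual"])
            for o in range(counts["individual"])
            if s != o
            for p in range(counts["object_property"])
        ]
        for s, p, o in rng.sample(triples, n):
            lines.append(
                "[] a owl:NegativePropertyAssertion ; "
                f"owl:sourceIndividual {_iri('individual', s)} ; "
                f"owl:assertionProperty {_iri('object_property', p)} ; "
                f"owl:targetIndividual {_iri('individual', o)} ."
            )
    elif tag == "NegativeDataPropertyAssertion":
        for k in range(n):
            s = rng.randrange(counts["individual"])
            d = rng.randrange(counts["data_property"])
            lines.append(
                "[] a owl:NegativePropertyAssertion ; "
                f"owl:sourceIndividual {_iri('individual', s)} ; "
                f"owl:assertionProperty {_iri('data_property', d)} ; "
                f'owl:targetValue "nv{k}" .'
            )
    elif tag == "DisjointUnion":
        for i in range(n):
            members = rng.sample(
                [j for j in range(counts["class"]) if j != i], 2
            )
            union = " ".join(_iri("class", j) for j in members)
            lines.append(f"{_iri('class', i)} owl:disjointUnionOf ( {union} ) .")
    elif tag == "HasKey":
        for i in range(n):
            p = rng.randrange(counts["object_property"])
            lines.append(
                f"{_iri('class', i)} owl:hasKey ( {_iri('object_property', p)} ) ."
            )
    else:  # pragma: no cover - validate() rejects unknown tags
        raise DataError(f"cannot generate axioms of type {tag}")
    return lines


def _feature_expr(feature: str, counts: dict[str, int]) -> str:
    last_prop = _iri("object_property", counts["object_property"] - 1)
    if feature == "ObjectIntersectionOf":
        return f"[ owl:intersectionOf ( {_iri('class', 1)} {_iri('class', 2)} ) ]"
    if feature == "ObjectUnionOf":
        return f"[ owl:unionOf ( {_iri('class', 1)} {_iri('class', 2)} ) ]"
    if feature == "ObjectComplementOf":
        return f"[ owl:complementOf {_iri('class', 1)} ]"
    if feature == "ObjectOneOf":
        return f"[ owl:oneOf ( {_iri('individual', 0)} {_iri('individual', 1)} ) ]"
    if feature == "ObjectSomeValuesFrom":
        return (
            f"[ a owl:Restriction ; owl:onProperty {last_prop} ; "
            f"owl:someValuesFrom {_iri('class', 1)} ]"
        )
    if feature == "ObjectAllValuesFrom":
        return (
            f"[ a owl:Restriction ; owl:onProperty {last_prop} ; "
            f"owl:allValuesFrom {_iri('class', 2)} ]"
        )
    if feature == "ObjectHasValue":
        return (
            f"[ a owl:Restriction ; owl:onProperty {last_prop} ; "
            f"owl:hasValue {_iri('individual', 0)} ]"
        )
    if feature == "ObjectCardinality":
        return (
            f"[ a owl:Restriction ; owl:onProperty {last_prop} ; "
            'owl:minCardinality "2"^^xsd:nonNegativeInteger ]'
        )
    raise DataError(f"unknown expression feature {feature}")  # pragma: no cover


def fixture_lexicon(vocabulary: dict[str, int]) -> FixtureLexicon:
    """Build the fixture lexical database for a spec's vocabulary."""
    try:
        return FixtureLexicon(dict(vocabulary))
    except ValueError as exc:
        raise DataError(str(exc)) from exc


def random_spec(seed: int) -> SynthSpec:
    """A randomized but always-consistent spec, for seed-sweep suites."""
    rng = random.Random(seed)
    n_classes = rng.randint(6, 20)
    n_individuals = rng.randint(3, 10)
    n_object_properties = rng.randint(2, 4)
    n_data_properties = rng.randint(1, 3)
    recipe = {
        "SubClassOf": rng.randint(1, n_classes),
        "DisjointClasses": rng.randint(0, 3),
        "EquivalentClasses": rng.randint(0, 2),
        "ObjectPropertyDomain": rng.randint(0, n_object_properties),
        "ObjectPropertyRange": rng.randint(0, n_object_properties),
        "ClassAssertion": rng.randint(1, n_individuals),
        "ObjectPropertyAssertion": rng.randint(0, n_individuals - 1),
        "DataPropertyAssertion": rng.randint(0, 4),
        "FunctionalObjectProperty": rng.randint(0, 1),
        "TransitiveObjectProperty": rng.randint(0, 1),
        "SubObjectPropertyOf": rng.randint(0, 1),
        "SameIndividual": rng.randint(0, 1),
        "DifferentIndividuals": rng.randint(0, 1),
        "HasKey": rng.randint(0, 1),
        "DisjointUnion": rng.randint(0, 1),
        "NegativeObjectPropertyAssertion": rng.randint(0, 1),
    }
    all_features = list(EXPRESSION_FEATURES)
    n_feat = rng.randint(0, 4)
    features = tuple(sorted(rng.sample(all_features, n_feat)))
    if "ObjectCardinality" in features:
        recipe["TransitiveObjectProperty"] = 0
    return SynthSpec(
        seed=seed,
        n_classes=n_classes,
        n_individuals=n_individuals,
        n_object_properties=n_object_properties,
        n_data_properties=n_data_properties,
        axiom_recipe=recipe,
        features=features,
        violation_injections=rng.randint(0, 2),
        label_style=rng.choice(["camel", "underscore", "plain"]),
    )
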