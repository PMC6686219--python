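"""Core domain types: the parsed ontology model, axioms, and censuses.

An ontology is represented structurally: a set of declared named entities
partitioned by kind, plus a list of typed axioms.  Axiom payloads are plain
nested tuples (IRIs as strings, class expressions as tagged tuples), which
keeps them hashable, order-stable and trivially serializable — properties the
verbalizer and the synthetic generator both rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum


class OntoscoreError(Exception):
    """Base class for all package errors."""


class FormatError(OntoscoreError):
    """The input could not be parsed as an ontology serialization."""


class ResolutionError(OntoscoreError):
    """An owl:imports target could not be resolved to a readable source."""


class UndefinedScoreError(OntoscoreError):
    """A score's denominator is zero or its inputs are absent."""


class ParameterError(OntoscoreError):
    """A weight, baseline or mode argument is out of its legal range."""


class DataError(OntoscoreError):
    """User-supplied data (review file, axiom payload) violates its schema."""


class LexiconUnavailableError(OntoscoreError):
    """The requested lexical-database backend cannot be loaded."""


class ConfigError(OntoscoreError):
    """A session configuration is incomplete or inconsistent."""


class SnapshotError(OntoscoreError):
    """A snapshot file is unreadable or has an incompatible schema version."""


class AxiomType(str, Enum):
    """Closed enumeration of the axiom types the structural reader emits.

    The first 31 members are logical axioms (they carry entailment
    semantics); declarations and annotation assertions are non-logical.
    """

    # -- class axioms
    SUB_CLASS_OF = "SubClassOf"
    EQUIVALENT_CLASSES = "EquivalentClasses"
    DISJOINT_CLASSES = "DisjointClasses"
    DISJOINT_UNION = "DisjointUnion"
    # -- object property axioms
    SUB_OBJECT_PROPERTY_OF = "SubObjectPropertyOf"
    EQUIVALENT_OBJECT_PROPERTIES = "EquivalentObjectProperties"
    DISJOINT_OBJECT_PROPERTIES = "DisjointObjectProperties"
    INVERSE_OBJECT_PROPERTIES = "InverseObjectProperties"
    OBJECT_PROPERTY_DOMAIN = "ObjectPropertyDomain"
    OBJECT_PROPERTY_RANGE = "ObjectPropertyRange"
    FUNCTIONAL_OBJECT_PROPERTY = "FunctionalObjectProperty"
    INVERSE_FUNCTIONAL_OBJECT_PROPERTY = "InverseFunctionalObjectProperty"
    TRANSITIVE_OBJECT_PROPERTY = "TransitiveObjectProperty"
    SYMMETRIC_OBJECT_PROPERTY = "SymmetricObjectProperty"
    ASYMMETRIC_OBJECT_PROPERTY = "AsymmetricObjectProperty"
    REFLEXIVE_OBJECT_PROPERTY = "ReflexiveObjectProperty"
    IRREFLEXIVE_OBJECT_PROPERTY = "IrreflexiveObjectProperty"
    # -- data property axioms
    SUB_DATA_PROPERTY_OF = "SubDataPropertyOf"
    EQUIVALENT_DATA_PROPERTIES = "EquivalentDataProperties"
    DISJOINT_DATA_PROPERTIES = "DisjointDataProperties"
    DATA_PROPERTY_DOMAIN = "DataPropertyDomain"
    DATA_PROPERTY_RANGE = "DataPropertyRange"
    FUNCTIONAL_DATA_PROPERTY = "FunctionalDataProperty"
    # -- assertions
    CLASS_ASSERTION = "ClassAssertion"
    OBJECT_PROPERTY_ASSERTION = "ObjectPropertyAssertion"
    DATA_PROPERTY_ASSERTION = "DataPropertyAssertion"
    NEGATIVE_OBJECT_PROPERTY_ASSERTION = "NegativeObjectPropertyAssertion"
    NEGATIVE_DATA_PROPERTY_ASSERTION = "NegativeDataPropertyAssertion"
    SAME_INDIVIDUAL = "SameIndividual"
    DIFFERENT_INDIVIDUALS = "DifferentIndividuals"
    HAS_KEY = "HasKey"
    # -- non-logical axioms
    DECLARATION = "Declaration"
    ANNOTATION_ASSERTION = "AnnotationAssertion"


#: Logical axiom types, in declaration order (31 of them).
LOGICAL_AXIOM_TYPES: tuple[AxiomType, ...] = tuple(
    t for t in AxiomType
    if t not in (AxiomType.DECLARATION, AxiomType.ANNOTATION_ASSERTION)
)

NON_LOGICAL_AXIOM_TYPES: tuple[AxiomType, ...] = (
    AxiomType.DECLARATION,
    AxiomType.ANNOTATION_ASSERTION,
)

#: Entity kinds used in Declaration payloads.
ENTITY_KINDS = (
    "class",
    "individual",
    "object_property",
    "data_property",
    "annotation_property",
    "datatype",
)

#: Class-expression construct tags (tagged-tuple first elements).
EXPR_INTERSECTION = "ObjectIntersectionOf"
EXPR_UNION = "ObjectUnionOf"
EXPR_COMPLEMENT = "ObjectComplementOf"
EXPR_ONE_OF = "ObjectOneOf"
EXPR_SOME = "ObjectSomeValuesFrom"
EXPR_ALL = "ObjectAllValuesFrom"
EXPR_HAS_VALUE = "ObjectHasValue"
EXPR_MIN_CARD = "ObjectMinCardinality"
EXPR_MAX_CARD = "ObjectMaxCardinality"
EXPR_EXACT_CARD = "ObjectExactCardinality"

#: Expression-construct features counted by the richness survey.  The three
#: cardinality variants fold into one "ObjectCardinality" feature.
EXPRESSION_FEATURES: tuple[str, ...] = (
    EXPR_INTERSECTION,
    EXPR_UNION,
    EXPR_COMPLEMENT,
    EXPR_ONE_OF,
    EXPR_SOME,
    EXPR_ALL,
    EXPR_HAS_VALUE,
    "ObjectCardinality",
)

_CARDINALITY_TAGS = frozenset({EXPR_MIN_CARD, EXPR_MAX_CARD, EXPR_EXACT_CARD})

#: The fixed 39-item OWL construct catalog that forms the richness
#: denominator: every logical axiom type plus the eight class-expression
#: constructs above.  The total, 39, is the possible-feature count for OWL
#: used by the scoring model; the catalog itself is this package's explicit,
#: auditable enumeration of those constructs.
FEATURE_CATALOG: tuple[str, ...] = tuple(
    t.value for t in LOGICAL_AXIOM_TYPES
) + EXPRESSION_FEATURES

assert len(FEATURE_CATALOG) == 39, "richness denominator must stay fixed"


@dataclass(frozen=True)
class Axiom:
    """A typed axiom: a tag plus a structured, hashable payload tuple."""

    type: AxiomType
    payload: tuple

    def feature(self) -> str:
        return self.type.value


@dataclass(frozen=True)
class LabelAnnotation:
    """One label literal attached to an entity."""

    property_iri: str
    text: str
    lang: str | None = None


@dataclass
class OntologyModel:
    """Structural view of a parsed ontology."""

    ontology_iri: str | None = None
    classes: set[str] = field(default_factory=set)
    individuals: set[str] = field(default_factory=set)
    object_properties: set[str] = field(default_factory=set)
    data_properties: set[str] = field(default_factory=set)
    annotation_properties: set[str] = field(default_factory=set)
    datatypes: set[str] = field(default_factory=set)
    axioms: list[Axiom] = field(default_factory=list)
    label_annotations: dict[str, list[LabelAnnotation]] = field(default_factory=dict)
    imports: list[str] = field(default_factory=list)

    @property
    def label_map(self) -> dict[str, list[str]]:
        """IRI → list of label texts (rdfs:label and configured properties)."""
        return {
            iri: [a.text for a in anns]
            for iri, anns in self.label_annotations.items()
        }

    def logical_axioms(self) -> list[Axiom]:
        return [a for a in self.axioms if a.type in LOGICAL_AXIOM_TYPES]

    def entity_sets(self) -> dict[str, set[str]]:
        return {
            "class": self.classes,
            "individual": self.individuals,
            "object_property": self.object_properties,
            "data_property": self.data_properties,
            "annotation_property": self.annotation_properties,
            "datatype": self.datatypes,
        }


@dataclass(frozen=True)
class AxiomCensus:
    """Counts of logical vs non-logical axioms (the AX totals)."""

    n_logical: int
    n_non_logical: int

    @property
    def n_total(self) -> int:
        return self.n_logical + self.n_non_logical

    def __post_init__(self) -> None:
        if self.n_logical < 0 or self.n_non_logical < 0:
            raise DataError("axiom counts must be non-negative")


@dataclass(frozen=True)
class ElementCensus:
    """Counts of declared named elements (classes, individuals, properties)."""

    n_classes: int
    n_individuals: int
    n_object_properties: int
    n_data_properties: int

    @property
    def n_elements(self) -> int:
        return (
            self.n_classes
            + self.n_individuals
            + self.n_object_properties
            + self.n_data_properties
        )


@dataclass(frozen=True)
class FeatureInventory:
    """The fixed 39-construct catalog and the subset observed in a model."""

    used: frozenset[str]
    catalog: tuple[str, ...] = FEATURE_CATALOG

    def __post_init__(self) -> None:
        if not self.used <= set(self.catalog):
            unknown = sorted(self.used - set(self.catalog))
            raise DataError(f"features outside the catalog: {unknown}")

    @property
    def n_used(self) -> int:
        return len(self.used)

    @property
    def n_possible(self) -> int:
        return len(self.catalog)


def expression_features_used(payload: object) -> set[str]:
    """Collect expression-construct features from a nested axiom payload.

    Walks tagged tuples recursively; cardinality variants all map onto the
    single ``ObjectCardinality`` feature.
    """
    found: set[str] = set()
    _walk_expr(payload, found)
    return found


def _walk_expr(node: object, found: set[str]) -> None:
    if isinstance(node, tuple) and node and isinstance(node[0], str):
        tag = node[0]
        if tag in _CARDINALITY_TAGS:
            found.add("ObjectCardinality")
        elif tag in EXPRESSION_FEATURES:
            found.add(tag)
        for part in node[1:]:
            _walk_expr(part, found)
    elif isinstance(node, tuple):
        for part in node:
            _walk_expr(part, found)
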