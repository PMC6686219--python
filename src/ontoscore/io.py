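"""Ontology loading and raw censuses.

A structural reader over rdflib: triples are mapped onto typed axioms
(:class:`~ontoscore.model.Axiom`), declared entities are partitioned by
kind, and the censuses that feed every metric (axiom counts, element counts,
language-feature usage, DL-profile violations, label inventory) are derived
from that structural view.

Classification is documented and fixed: declarations and annotation
assertions are non-logical, everything else is logical — the convention of
the OWL 2 structural specification.
"""

from __future__ import annotations

import os
import warnings
from pathlib import Path

from rdflib import BNode, Graph, Literal, URIRef
from rdflib.namespace import OWL, RDF, RDFS, SKOS, XSD

from .labels import LabelRecord, humanize_fragment
from .model import (
    Axiom,
    AxiomCensus,
    AxiomType,
    ElementCensus,
    FeatureInventory,
    FormatError,
    LabelAnnotation,
    OntologyModel,
    ResolutionError,
    expression_features_used,
    EXPR_ALL,
    EXPR_COMPLEMENT,
    EXPR_EXACT_CARD,
    EXPR_HAS_VALUE,
    EXPR_INTERSECTION,
    EXPR_MAX_CARD,
    EXPR_MIN_CARD,
    EXPR_ONE_OF,
    EXPR_SOME,
    EXPR_UNION,
)

_DECLARATION_CLASSES = {
    OWL.Class: "class",
    OWL.NamedIndividual: "individual",
    OWL.ObjectProperty: "object_property",
    OWL.DatatypeProperty: "data_property",
    OWL.AnnotationProperty: "annotation_property",
    RDFS.Datatype: "datatype",
}

_CHARACTERISTIC_CLASSES = {
    OWL.FunctionalProperty: "functional",
    OWL.InverseFunctionalProperty: AxiomType.INVERSE_FUNCTIONAL_OBJECT_PROPERTY,
    OWL.TransitiveProperty: AxiomType.TRANSITIVE_OBJECT_PROPERTY,
    OWL.SymmetricProperty: AxiomType.SYMMETRIC_OBJECT_PROPERTY,
    OWL.AsymmetricProperty: AxiomType.ASYMMETRIC_OBJECT_PROPERTY,
    OWL.ReflexiveProperty: AxiomType.REFLEXIVE_OBJECT_PROPERTY,
    OWL.IrreflexiveProperty: AxiomType.IRREFLEXIVE_OBJECT_PROPERTY,
}

#: rdf:type objects that never produce a ClassAssertion.
_STRUCTURAL_CLASSES = (
    set(_DECLARATION_CLASSES)
    | set(_CHARACTERISTIC_CLASSES)
    | {
        OWL.Ontology,
        OWL.Restriction,
        OWL.AllDisjointClasses,
        OWL.AllDifferent,
        OWL.AllDisjointProperties,
        OWL.NegativePropertyAssertion,
        OWL.Axiom,
        OWL.Annotation,
        OWL.DeprecatedClass,
        OWL.DeprecatedProperty,
        RDF.List,
        RDF.Statement,
    }
)

_RESERVED_NAMESPACES = (str(OWL), str(RDF), str(RDFS), str(XSD))

#: Annotation properties recognized without declaration.
_BUILTIN_ANNOTATION_PROPERTIES = {
    RDFS.label,
    RDFS.comment,
    RDFS.seeAlso,
    RDFS.isDefinedBy,
    OWL.versionInfo,
    OWL.deprecated,
    SKOS.prefLabel,
    SKOS.altLabel,
    SKOS.definition,
}

RDFS_LABEL = str(RDFS.label)
SKOS_PREF_LABEL = str(SKOS.prefLabel)

_CARDINALITY_PREDICATES = {
    OWL.minCardinality: EXPR_MIN_CARD,
    OWL.minQualifiedCardinality: EXPR_MIN_CARD,
    OWL.maxCardinality: EXPR_MAX_CARD,
    OWL.maxQualifiedCardinality: EXPR_MAX_CARD,
    OWL.cardinality: EXPR_EXACT_CARD,
    OWL.qualifiedCardinality: EXPR_EXACT_CARD,
}


def _guess_format(path: str, hint: str | None) -> list[str]:
    if hint:
        return [hint]
    suffix = Path(path).suffix.lower()
    if suffix in (".ttl", ".n3"):
        return ["turtle"]
    if suffix in (".owl", ".rdf", ".xml"):
        return ["xml"]
    return ["turtle", "xml"]


def load_ontology(source: str | os.PathLike, format_hint: str | None = None) -> OntologyModel:
    """Parse an RDF/XML or Turtle ontology file into an :class:`OntologyModel`.

    The serialization format is auto-detected from the file extension when
    ``format_hint`` is absent.  Parsing is deterministic for a fixed file:
    the resulting axiom list is canonically sorted.
    """
    path = os.fspath(source)
    if not os.path.exists(path):
        raise IOError(f"ontology source not found: {path}")
    graph = Graph()
    errors = []
    for fmt in _guess_format(path, format_hint):
        try:
            graph.parse(path, format=fmt)
            break
        except Exception as exc:  # rdflib raises several parser exceptions
            errors.append(f"{fmt}: {exc}")
    else:
        raise FormatError(
            f"could not parse {path} as any of the attempted formats: "
            + "; ".join(errors)
        )
    return model_from_graph(graph)


def model_from_graph(graph: Graph) -> OntologyModel:
    """Map a parsed RDF graph onto the structural ontology model."""
    model = OntologyModel()
    axioms: list[Axiom] = []

    for s in graph.subjects(RDF.type, OWL.Ontology):
        if isinstance(s, URIRef):
            model.ontology_iri = str(s)
            break
    model.imports = sorted(
        str(o) for o in graph.objects(None, OWL.imports) if isinstance(o, URIRef)
    )

    # pass 1 — declarations, so property kinds are known before assertions
    for rdf_class, kind in _DECLARATION_CLASSES.items():
        for s in graph.subjects(RDF.type, rdf_class):
            if not isinstance(s, URIRef):
                continue
            iri = str(s)
            model.entity_sets()[kind].add(iri)
            axioms.append(Axiom(AxiomType.DECLARATION, (kind, iri)))

    annotation_props = set(model.annotation_properties) | {
        str(p) for p in _BUILTIN_ANNOTATION_PROPERTIES
    }

    # pass 2 — everything else
    for s, p, o in graph:
        if isinstance(s, BNode) and _is_structural_bnode(graph, s):
            if p == RDF.type:
                ax = _parse_structural_bnode(graph, s)
                if ax is not None:
                    axioms.append(ax)
            continue
        if p == RDF.type:
            if o in _CHARACTERISTIC_CLASSES:
                if isinstance(s, URIRef):
                    tag = _CHARACTERISTIC_CLASSES[o]
                    if tag == "functional":
                        ax_type = (
                            AxiomType.FUNCTIONAL_DATA_PROPERTY
                            if str(s) in model.data_properties
                            else AxiomType.FUNCTIONAL_OBJECT_PROPERTY
                        )
                    else:
                        ax_type = tag
                    axioms.append(Axiom(ax_type, (str(s),)))
            elif o in _DECLARATION_CLASSES or o in _STRUCTURAL_CLASSES:
                pass  # declarations handled in pass 1; structural nodes skipped
            elif isinstance(s, URIRef) and not _is_reserved(o):
                axioms.append(
                    Axiom(
                        AxiomType.CLASS_ASSERTION,
                        (str(s), _class_expr(graph, o)),
                    )
                )
            continue
        if p == RDFS.subClassOf:
            axioms.append(
                Axiom(
                    AxiomType.SUB_CLASS_OF,
                    (_class_expr(graph, s), _class_expr(graph, o)),
                )
            )
        elif p == OWL.equivalentClass:
            axioms.append(
                Axiom(
                    AxiomType.EQUIVALENT_CLASSES,
                    (_class_expr(graph, s), _class_expr(graph, o)),
                )
            )
        elif p == OWL.disjointWith:
            axioms.append(
                Axiom(
                    AxiomType.DISJOINT_CLASSES,
                    (_class_expr(graph, s), _class_expr(graph, o)),
                )
            )
        elif p == OWL.disjointUnionOf:
            members = tuple(_class_expr(graph, m) for m in graph.items(o))
            axioms.append(
                Axiom(AxiomType.DISJOINT_UNION, (_class_expr(graph, s), members))
            )
        elif p == RDFS.subPropertyOf and isinstance(s, URIRef):
            ax_type = (
                AxiomType.SUB_DATA_PROPERTY_OF
                if str(s) in model.data_properties
                else AxiomType.SUB_OBJECT_PROPERTY_OF
            )
            axioms.append(Axiom(ax_type, (str(s), str(o))))
        elif p == OWL.equivalentProperty and isinstance(s, URIRef):
            ax_type = (
                AxiomType.EQUIVALENT_DATA_PROPERTIES
                if str(s) in model.data_properties
                else AxiomType.EQUIVALENT_OBJECT_PROPERTIES
            )
            axioms.append(Axiom(ax_type, (str(s), str(o))))
        elif p == OWL.propertyDisjointWith and isinstance(s, URIRef):
            ax_type = (
                AxiomType.DISJOINT_DATA_PROPERTIES
                if str(s) in model.data_properties
                else AxiomType.DISJOINT_OBJECT_PROPERTIES
            )
            axioms.append(Axiom(ax_type, (str(s), str(o))))
        elif p == OWL.inverseOf and isinstance(s, URIRef) and isinstance(o, URIRef):
            axioms.append(
                Axiom(AxiomType.INVERSE_OBJECT_PROPERTIES, (str(s), str(o)))
            )
        elif p == RDFS.domain and isinstance(s, URIRef):
            iri = str(s)
            if iri in annotation_props:
                continue
            ax_type = (
                AxiomType.DATA_PROPERTY_DOMAIN
                if iri in model.data_properties
                else AxiomType.OBJECT_PROPERTY_DOMAIN
            )
            axioms.append(Axiom(ax_type, (iri, _class_expr(graph, o))))
        elif p == RDFS.range and isinstance(s, URIRef):
            iri = str(s)
            if iri in annotation_props:
                continue
            if iri in model.data_properties:
                axioms.append(Axiom(AxiomType.DATA_PROPERTY_RANGE, (iri, str(o))))
            else:
                axioms.append(
                    Axiom(
                        AxiomType.OBJECT_PROPERTY_RANGE,
                        (iri, _class_expr(graph, o)),
                    )
                )
        elif p == OWL.sameAs and isinstance(s, URIRef):
            axioms.append(Axiom(AxiomType.SAME_INDIVIDUAL, (str(s), str(o))))
        elif p == OWL.differentFrom and isinstance(s, URIRef):
            axioms.append(Axiom(AxiomType.DIFFERENT_INDIVIDUALS, (str(s), str(o))))
        elif p == OWL.hasKey and isinstance(s, URIRef):
            props = tuple(str(m) for m in graph.items(o))
            axioms.append(Axiom(AxiomType.HAS_KEY, (str(s), props)))
        elif str(p) in annotation_props and isinstance(s, URIRef):
            axioms.append(
                Axiom(
                    AxiomType.ANNOTATION_ASSERTION,
                    (str(s), str(p), str(o)),
                )
            )
            if isinstance(o, Literal) and str(p) in (RDFS_LABEL, SKOS_PREF_LABEL):
                model.label_annotations.setdefault(str(s), []).append(
                    LabelAnnotation(str(p), str(o), o.language)
                )
        elif str(p) in model.object_properties and isinstance(s, URIRef):
            axioms.append(
                Axiom(
                    AxiomType.OBJECT_PROPERTY_ASSERTION,
                    (str(p), str(s), str(o)),
                )
            )
        elif str(p) in model.data_properties and isinstance(s, URIRef):
            axioms.append(
                Axiom(
                    AxiomType.DATA_PROPERTY_ASSERTION,
                    (str(p), str(s), str(o)),
                )
            )

    for anns in model.label_annotations.values():
        anns.sort(key=lambda a: (a.property_iri, a.lang or "", a.text))
    model.axioms = sorted(axioms, key=lambda a: (a.type.value, repr(a.payload)))
    return model


def _is_reserved(node) -> bool:
    return isinstance(node, URIRef) and str(node).startswith(_RESERVED_NAMESPACES)


def _is_structural_bnode(graph: Graph, node: BNode) -> bool:
    types = set(graph.objects(node, RDF.type))
    return bool(
        types
        & {
            OWL.AllDisjointClasses,
            OWL.AllDifferent,
            OWL.NegativePropertyAssertion,
            OWL.Axiom,
        }
    )


def _parse_structural_bnode(graph: Graph, node: BNode) -> Axiom | None:
    types = set(graph.objects(node, RDF.type))
    if OWL.AllDisjointClasses in types:
        members = graph.value(node, OWL.members)
        if members is not None:
            payload = tuple(_class_expr(graph, m) for m in graph.items(members))
            return Axiom(AxiomType.DISJOINT_CLASSES, payload)
    if OWL.AllDifferent in types:
        members = graph.value(node, OWL.distinctMembers) or graph.value(
            node, OWL.members
        )
        if members is not None:
            payload = tuple(str(m) for m in graph.items(members))
            return Axiom(AxiomType.DIFFERENT_INDIVIDUALS, payload)
    if OWL.NegativePropertyAssertion in types:
        src = graph.value(node, OWL.sourceIndividual)
        prop = graph.value(node, OWL.assertionProperty)
        target_ind = graph.value(node, OWL.targetIndividual)
        target_val = graph.value(node, OWL.targetValue)
        if src is None or prop is None:
            return None
        if target_ind is not None:
            return Axiom(
                AxiomType.NEGATIVE_OBJECT_PROPERTY_ASSERTION,
                (str(prop), str(src), str(target_ind)),
            )
        if target_val is not None:
            return Axiom(
                AxiomType.NEGATIVE_DATA_PROPERTY_ASSERTION,
                (str(prop), str(src), str(target_val)),
            )
    return None


def _class_expr(graph: Graph, node):
    """Recursively decode a class expression into a tagged tuple (or IRI)."""
    if isinstance(node, URIRef):
        return str(node)
    if isinstance(node, Literal):
        return str(node)
    if not isinstance(node, BNode):
        return str(node)
    prop = graph.value(node, OWL.onProperty)
    if (node, RDF.type, OWL.Restriction) in graph or prop is not None:
        prop_iri = str(prop) if prop is not None else ""
        filler = graph.value(node, OWL.someValuesFrom)
        if filler is not None:
            return (EXPR_SOME, prop_iri, _class_expr(graph, filler))
        filler = graph.value(node, OWL.allValuesFrom)
        if filler is not None:
            return (EXPR_ALL, prop_iri, _class_expr(graph, filler))
        value = graph.value(node, OWL.hasValue)
        if value is not None:
            return (EXPR_HAS_VALUE, prop_iri, str(value))
        for pred, tag in _CARDINALITY_PREDICATES.items():
            n = graph.value(node, pred)
            if n is not None:
                on_class = graph.value(node, OWL.onClass)
                filler_expr = (
                    _class_expr(graph, on_class) if on_class is not None else None
                )
                return (tag, int(n), prop_iri, filler_expr)
    members = graph.value(node, OWL.intersectionOf)
    if members is not None:
        return (
            EXPR_INTERSECTION,
            tuple(_class_expr(graph, m) for m in graph.items(members)),
        )
    members = graph.value(node, OWL.unionOf)
    if members is not None:
        return (
            EXPR_UNION,
            tuple(_class_expr(graph, m) for m in graph.items(members)),
        )
    complement = graph.value(node, OWL.complementOf)
    if complement is not None:
        return (EXPR_COMPLEMENT, _class_expr(graph, complement))
    members = graph.value(node, OWL.oneOf)
    if members is not None:
        return (EXPR_ONE_OF, tuple(str(m) for m in graph.items(members)))
    return ("UnknownExpression", str(node))


# ---------------------------------------------------------------------------
# imports


def merge_imports(
    model: OntologyModel,
    follow: bool = False,
    import_map: dict[str, str] | None = None,
) -> OntologyModel:
    """Merge the owl:imports closure into a single model.

    With ``follow=False`` (the default) the model is returned unchanged and a
    warning lists the unresolved imports — scores are then computed from what
    is local to the file.  With ``follow=True`` every import is resolved (via
    ``import_map``, a ``file://`` IRI, or a local path) and the axiom sets are
    unioned and de-duplicated over the whole closure.
    """
    if not follow:
        if model.imports:
            warnings.warn(
                "imports not followed; scoring local axioms only: "
                + ", ".join(model.imports),
                stacklevel=2,
            )
        return model
    if not model.imports:
        return model
    merged = _copy_model(model)
    seen: set[str] = set(filter(None, [model.ontology_iri]))
    queue = list(model.imports)
    while queue:
        iri = queue.pop(0)
        if iri in seen:
            continue
        seen.add(iri)
        imported = load_ontology(_resolve_import(iri, import_map))
        for kind, entities in imported.entity_sets().items():
            merged.entity_sets()[kind].update(entities)
        merged.axioms.extend(imported.axioms)
        for ent, anns in imported.label_annotations.items():
            existing = merged.label_annotations.setdefault(ent, [])
            for ann in anns:
                if ann not in existing:
                    existing.append(ann)
        queue.extend(i for i in imported.imports if i not in seen)
    unique = sorted(set(merged.axioms), key=lambda a: (a.type.value, repr(a.payload)))
    merged.axioms = unique
    merged.imports = []
    return merged


def _resolve_import(iri: str, import_map: dict[str, str] | None) -> str:
    if import_map and iri in import_map:
        return import_map[iri]
    if iri.startswith("file://"):
        return iri[len("file://"):]
    if os.path.exists(iri):
        return iri
    raise ResolutionError(f"cannot resolve owl:imports target: {iri}")


def _copy_model(model: OntologyModel) -> OntologyModel:
    return OntologyModel(
        ontology_iri=model.ontology_iri,
        classes=set(model.classes),
        individuals=set(model.individuals),
        object_properties=set(model.object_properties),
        data_properties=set(model.data_properties),
        annotation_properties=set(model.annotation_properties),
        datatypes=set(model.datatypes),
        axioms=list(model.axioms),
        label_annotations={k: list(v) for k, v in model.label_annotations.items()},
        imports=list(model.imports),
    )


# ---------------------------------------------------------------------------
# censuses


def census_axioms(model: OntologyModel) -> AxiomCensus:
    """Count logical vs non-logical axioms.

    Declarations and annotation assertions are non-logical; every other
    axiom type carries entailment semantics and is logical.
    """
    n_non_logical = sum(
        1
        for a in model.axioms
        if a.type in (AxiomType.DECLARATION, AxiomType.ANNOTATION_ASSERTION)
    )
    n_logical = len(model.axioms) - n_non_logical
    return AxiomCensus(n_logical=n_logical, n_non_logical=n_non_logical)


def census_elements(model: OntologyModel) -> ElementCensus:
    """Count declared named elements; anonymous expressions are excluded."""
    return ElementCensus(
        n_classes=len(model.classes),
        n_individuals=len(model.individuals),
        n_object_properties=len(model.object_properties),
        n_data_properties=len(model.data_properties),
    )


def survey_features(model: OntologyModel) -> FeatureInventory:
    """Which of the 39 cataloged OWL constructs the ontology uses."""
    used: set[str] = set()
    for axiom in model.axioms:
        if axiom.type in (AxiomType.DECLARATION, AxiomType.ANNOTATION_ASSERTION):
            continue
        used.add(axiom.feature())
        used |= expression_features_used(axiom.payload)
    return FeatureInventory(used=frozenset(used))


def count_dl_violations(model: OntologyModel) -> int:
    """Count OWL 2 DL profile violations under this package's rule set.

    The rules checked are a documented subset of the OWL 2 DL global
    restrictions:

    1. reserved-vocabulary misuse — a declaration whose IRI lies in the
       owl/rdf/rdfs/xsd namespaces (one violation per declaration);
    2. illegal punning — one IRI declared as both a class and a datatype
       (one violation per punned IRI);
    3. undeclared entity use — a named IRI used in a class position of a
       class axiom without a class declaration (one per distinct IRI);
    4. non-simple property misuse — a transitive object property used in a
       cardinality restriction (one per occurrence).

    Only the count feeds the lawfulness score.
    """
    violations = 0
    # rule 1: reserved vocabulary in declarations
    for axiom in model.axioms:
        if axiom.type is AxiomType.DECLARATION:
            _, iri = axiom.payload
            if iri.startswith(_RESERVED_NAMESPACES):
                violations += 1
    # rule 2: class/datatype punning
    violations += len(model.classes & model.datatypes)
    # rule 3: undeclared named classes in class axioms
    undeclared: set[str] = set()
    builtin = {str(OWL.Thing), str(OWL.Nothing)}
    class_axiom_types = {
        AxiomType.SUB_CLASS_OF,
        AxiomType.EQUIVALENT_CLASSES,
        AxiomType.DISJOINT_CLASSES,
    }
    for axiom in model.axioms:
        if axiom.type in class_axiom_types:
            for part in axiom.payload:
                if (
                    isinstance(part, str)
                    and part not in model.classes
                    and part not in builtin
                    and not part.startswith(_RESERVED_NAMESPACES)
                ):
                    undeclared.add(part)
    violations += len(undeclared)
    # rule 4: transitive (non-simple) property inside a cardinality restriction
    transitive = {
        a.payload[0]
        for a in model.axioms
        if a.type is AxiomType.TRANSITIVE_OBJECT_PROPERTY
    }
    if transitive:
        for axiom in model.axioms:
            violations += _transitive_in_cardinality(axiom.payload, transitive)
    return violations


def _transitive_in_cardinality(node, transitive: set[str]) -> int:
    count = 0
    if isinstance(node, tuple):
        if (
            len(node) == 4
            and node[0] in (EXPR_MIN_CARD, EXPR_MAX_CARD, EXPR_EXACT_CARD)
            and node[2] in transitive
        ):
            count += 1
        for part in node:
            count += _transitive_in_cardinality(part, transitive)
    return count


# ---------------------------------------------------------------------------
# labels


def extract_labels(
    model: OntologyModel,
    label_properties: list[str] | None = None,
    language_preference: list[str | None] | None = None,
) -> list[LabelRecord]:
    """Collect one raw-label record per entity per selected label.

    ``label_properties`` defaults to rdfs:label (skos:prefLabel is the
    documented opt-in); ``language_preference`` defaults to untagged labels
    first, then ``"en"``.  Entities without any matching label fall back to
    the IRI fragment verbatim as the raw label.
    """
    if label_properties is None:
        label_properties = [RDFS_LABEL]
    if language_preference is None:
        language_preference = [None, "en"]
    records: list[LabelRecord] = []
    entities = sorted(
        set().union(*model.entity_sets().values()) if model.entity_sets() else set()
    )
    for iri in entities:
        anns = model.label_annotations.get(iri, [])
        chosen: list[LabelAnnotation] = []
        for prop in label_properties:
            prop_anns = [a for a in anns if a.property_iri == prop]
            if not prop_anns:
                continue
            for lang in language_preference:
                lang_anns = [a for a in prop_anns if a.lang == lang]
                if lang_anns:
                    chosen.extend(lang_anns)
                    break
            else:
                chosen.extend(prop_anns)
        if chosen:
            for ann in chosen:
                records.append(LabelRecord(entity_iri=iri, raw_label=ann.text))
        else:
            records.append(
                LabelRecord(entity_iri=iri, raw_label=_iri_fragment(iri))
            )
    return records


def _iri_fragment(iri: str) -> str:
    if "#" in iri:
        return iri.rsplit("#", 1)[1]
    return iri.rstrip("/").rsplit("/", 1)[-1]


def humanized_fragment(iri: str) -> str:
    """Fragment of an IRI rendered as human words (camel split, lowercased)."""
    return humanize_fragment(_iri_fragment(iri))
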