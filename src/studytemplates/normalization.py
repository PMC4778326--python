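"""Inheritance materialization: the flattened SPIN-style class representation.

The domain model is authored object-oriented style — a class inherits every
attribute and association asserted on its ancestors via ``rdfs:subClassOf``.
So that browse and template queries never have to walk the hierarchy,
:func:`normalize` copies each ancestor's local declarations onto every
descendant and emits the result as RDF: one metadata node (typed
``spl:Attribute``, carrying name, value type / target class, cardinality and
an inheritance flag) per flattened entry, attached to the class through
``bridg:attributeProperty`` / ``bridg:associationProperty``, with
``bridg:isInherited`` recording provenance.

Multiple inheritance is supported as a union over all ancestor paths: a
diamond contributes each declaration once (deduplicated by owner and name).
Two *distinct* owners contributing the same attribute name is an error by
default (:class:`NameCollisionError`) because the source model defines no
override semantics; ``on_collision="keep"`` retains both, distinguished by
owner.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

import networkx as nx
from rdflib import BNode, Graph, Literal, URIRef

from .errors import CycleError, NameCollisionError, NotFoundError
from .model_io import (
    AssociationSpec,
    AttributeSpec,
    ClassDef,
    ModelGraph,
    NamespacePolicy,
)
from .vocab import BRIDG, DEFAULT_PREFIXES, OWL, RDF, RDFS, SPL


@dataclass
class NormalizationVocab:
    """Output predicate IRIs; defaults follow the bridg:/spl: conventions."""

    attribute_property: URIRef = BRIDG.attributeProperty
    association_property: URIRef = BRIDG.associationProperty
    is_inherited: URIRef = BRIDG.isInherited
    owner_class: URIRef = BRIDG.ownerClass
    target_class: URIRef = BRIDG.targetClass
    attribute_template: URIRef = SPL.Attribute


@dataclass
class FlattenedClass:
    """One class with all inherited declarations materialized."""

    iri: str
    attributes: list[AttributeSpec] = field(default_factory=list)
    associations: list[AssociationSpec] = field(default_factory=list)

    def attribute(self, name: str) -> AttributeSpec:
        for a in self.attributes:
            if a.name == name:
                return a
        raise NotFoundError(f"class <{self.iri}> has no attribute {name!r}")

    def association(self, role_name: str,
                    target: Optional[str] = None) -> AssociationSpec:
        for a in self.associations:
            if a.role_name == role_name and (target is None or a.target_class == target):
                return a
        raise NotFoundError(
            f"class <{self.iri}> has no association {role_name!r}"
            + (f" targeting <{target}>" if target else ""))


class NormalizedGraph:
    """Result of :func:`normalize`: flattened classes plus emitted triples."""

    def __init__(self, base: ModelGraph, flattened: dict[str, FlattenedClass],
                 graph: Graph, vocab: NormalizationVocab):
        self.base = base
        self.flattened = flattened
        self.graph = graph
        self.vocab = vocab

    def serialize(self, destination: Union[str, Path, None] = None) -> str:
        text = self.graph.serialize(format="turtle")
        if destination is not None:
            Path(destination).write_text(text)
        return text

    def as_model(self) -> ModelGraph:
        """Re-express the flattened output as a loadable model.

        Each class's local declarations become its non-inherited flattened
        entries; re-normalizing the result must be a fixed point.
        """
        model = ModelGraph(self.graph, self.base.policy)
        for dt in self.base.datatypes.values():
            model._index_datatype(dt)
        for iri, flat in self.flattened.items():
            src = self.base.classes[iri]
            cdef = ClassDef(iri, src.name, list(src.parents),
                            definition_text=src.definition_text)
            cdef.local_attributes = [a for a in flat.attributes if not a.is_inherited]
            cdef.local_associations = [a for a in flat.associations if not a.is_inherited]
            model._index_class(cdef)
        return model


def _subclass_digraph(model: ModelGraph) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(model.classes)
    for cdef in model.classes.values():
        for p in cdef.parents:
            if p in model.classes:
                g.add_edge(cdef.iri, p)  # child -> parent
    return g


def ancestors(model: ModelGraph, class_iri: str) -> list[str]:
    """All transitive ancestors of a class, excluding itself.

    Order is deterministic: breadth-first from the class, ties within a
    level broken lexicographically by IRI, first occurrence kept.
    """
    cdef = model.resolve_class(class_iri)
    seen: set[str] = set()
    order: list[str] = []
    frontier = sorted(p for p in cdef.parents if p in model.classes)
    while frontier:
        nxt: list[str] = []
        for iri in frontier:
            if iri == cdef.iri:
                raise CycleError(_find_cycle(model, cdef.iri))
            if iri in seen:
                continue
            seen.add(iri)
            order.append(iri)
            nxt.extend(p for p in model.classes[iri].parents if p in model.classes)
        frontier = sorted(set(nxt) - seen)
    if cdef.iri in seen:  # pragma: no cover - defensive; caught above
        raise CycleError(_find_cycle(model, cdef.iri))
    return order


def _find_cycle(model: ModelGraph, class_iri: str) -> list[str]:
    g = _subclass_digraph(model)
    try:
        edges = nx.find_cycle(g, source=class_iri)
    except nx.NetworkXNoCycle:  # pragma: no cover
        return [class_iri]
    return [e[0] for e in edges] + [edges[-1][1]]


def normalize(model: ModelGraph, vocab: Optional[NormalizationVocab] = None,
              on_collision: str = "error") -> NormalizedGraph:
    """Materialize inherited attributes and associations for every class.

    ``on_collision`` controls what happens when two distinct owner classes
    contribute an attribute (or an association role/target pair) with the
    same name to one flattened class: ``"error"`` raises
    :class:`NameCollisionError`, ``"keep"`` retains both entries qualified
    by owner.
    """
    if on_collision not in ("error", "keep"):
        raise ValueError(f"on_collision must be 'error' or 'keep', got {on_collision!r}")
    vocab = vocab or NormalizationVocab()

    digraph = _subclass_digraph(model)
    if not nx.is_directed_acyclic_graph(digraph):
        edges = nx.find_cycle(digraph)
        raise CycleError([e[0] for e in edges] + [edges[-1][1]])

    flattened: dict[str, FlattenedClass] = {}
    for iri in sorted(model.classes):
        flat = FlattenedClass(iri)
        owners = [iri] + ancestors(model, iri)
        seen_attrs: dict[tuple[str, str], AttributeSpec] = {}
        name_owner: dict[str, str] = {}
        for owner in owners:
            for attr in model.classes[owner].local_attributes:
                key = (attr.owner_class, attr.name)
                if key in seen_attrs:  # diamond: same declaration, once
                    continue
                prev = name_owner.get(attr.name)
                if prev is not None and prev != attr.owner_class and on_collision == "error":
                    raise NameCollisionError(iri, attr.name,
                                             [prev, attr.owner_class])
                name_owner.setdefault(attr.name, attr.owner_class)
                spec = attr if owner == iri else attr.copy_inherited()
                seen_attrs[key] = spec
                flat.attributes.append(spec)
        seen_assocs: set[tuple[str, str, str]] = set()
        for owner in owners:
            for assoc in model.classes[owner].local_associations:
                key = (assoc.owner_class, assoc.role_name, assoc.target_class)
                if key in seen_assocs:
                    continue
                seen_assocs.add(key)
                flat.associations.append(
                    assoc if owner == iri else assoc.copy_inherited())
        flattened[iri] = flat

    graph = _emit(model, flattened, vocab)
    return NormalizedGraph(model, flattened, graph, vocab)


def is_inherited(normalized: NormalizedGraph, class_iri: str, attr_name: str) -> bool:
    """Whether the named attribute of a class was inherited from an ancestor."""
    cdef = normalized.base.resolve_class(class_iri)
    flat = normalized.flattened[cdef.iri]
    return flat.attribute(attr_name).is_inherited


# ---------------------------------------------------------------------------
# RDF emission


def _skolem_bnode(*parts: str) -> BNode:
    digest = hashlib.sha1("|".join(parts).encode()).hexdigest()[:20]
    return BNode("n" + digest)


def _emit(model: ModelGraph, flattened: dict[str, FlattenedClass],
          vocab: NormalizationVocab) -> Graph:
    g = Graph()
    for prefix, ns in sorted(DEFAULT_PREFIXES.items()):
        g.bind(prefix, ns)
    for iri in sorted(flattened):
        c = URIRef(iri)
        cdef = model.classes[iri]
        g.add((c, RDF.type, OWL.Class))
        g.add((c, RDFS.label, Literal(cdef.name)))
        for p in cdef.parents:
            g.add((c, RDFS.subClassOf, URIRef(p)))
        flat = flattened[iri]
        # serialization order: non-inherited first, then by name/owner
        for attr in sorted(flat.attributes,
                           key=lambda a: (a.is_inherited, a.name, a.owner_class)):
            node = _skolem_bnode("attr", iri, attr.owner_class, attr.name)
            g.add((c, vocab.attribute_property, node))
            g.add((node, RDF.type, vocab.attribute_template))
            g.add((node, SPL.predicate, Literal(attr.name)))
            g.add((node, SPL.valueType, URIRef(attr.datatype)))
            _emit_cardinality(g, node, attr.cardinality)
            g.add((node, vocab.is_inherited, Literal(attr.is_inherited)))
            g.add((node, vocab.owner_class, URIRef(attr.owner_class)))
        for assoc in sorted(flat.associations,
                            key=lambda a: (a.is_inherited, a.role_name,
                                           a.target_class, a.owner_class)):
            node = _skolem_bnode("assoc", iri, assoc.owner_class,
                                 assoc.role_name, assoc.target_class)
            g.add((c, vocab.association_property, node))
            g.add((node, RDF.type, vocab.attribute_template))
            g.add((node, SPL.predicate, Literal(assoc.role_name)))
            g.add((node, vocab.target_class, URIRef(assoc.target_class)))
            _emit_cardinality(g, node, assoc.cardinality)
            g.add((node, vocab.is_inherited, Literal(assoc.is_inherited)))
            g.add((node, vocab.owner_class, URIRef(assoc.owner_class)))
    return g


def _emit_cardinality(g: Graph, node, card) -> None:
    g.add((node, SPL.minCount, Literal(card.min)))
    if not card.unbounded:
        g.add((node, SPL.maxCount, Literal(card.max)))
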