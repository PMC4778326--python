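"""The browse surface: class tree, per-class metadata, and SPARQL retrieval.

Mirrors what the model browser shows — a hierarchical class tree on the
left, and for each class a metadata structure of Children, Attributes and
Associations, with local and inherited entries distinguished.  Because the
normalization step materialized inheritance, the per-class SPARQL queries
are flat single-class lookups over ``bridg:attributeProperty`` /
``bridg:associationProperty`` metadata nodes; :func:`sparql_for_attributes`
returns the query text and :func:`run_attribute_query` executes it against
any graph loaded with the emitted Turtle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from rdflib import Graph

from .datatypes import UNBOUNDED, Cardinality, _local_name
from .model_io import AssociationSpec, AttributeSpec
from .normalization import NormalizationVocab, NormalizedGraph
from .vocab import BRIDG, SPL


@dataclass
class ClassTreeNode:
    iri: str
    name: str
    children: list["ClassTreeNode"] = field(default_factory=list)

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()


@dataclass
class ClassMetadata:
    """Children / Attributes / Associations of one class."""

    iri: str
    name: str
    children: list[tuple[str, str]]  # (iri, name), sorted by name
    attributes: list[AttributeSpec]
    associations: list[AssociationSpec]

    def to_dict(self) -> dict:
        return {
            "iri": self.iri,
            "name": self.name,
            "children": [{"iri": i, "name": n} for i, n in self.children],
            "attributes": [
                {"name": a.name, "datatype": a.datatype,
                 "datatypeName": _local_name(a.datatype),
                 "cardinality": a.cardinality.render(),
                 "isInherited": a.is_inherited, "owner": a.owner_class}
                for a in self.attributes],
            "associations": [
                {"role": a.role_name, "target": a.target_class,
                 "targetName": _local_name(a.target_class),
                 "cardinality": a.cardinality.render(),
                 "isInherited": a.is_inherited, "owner": a.owner_class}
                for a in self.associations],
        }


def class_tree(normalized: NormalizedGraph) -> list[ClassTreeNode]:
    """Root-down class tree; a multi-parent class appears under each parent."""
    model = normalized.base
    children_of: dict[str, list[str]] = {iri: [] for iri in model.classes}
    roots: list[str] = []
    for iri, cdef in model.classes.items():
        parents = [p for p in cdef.parents if p in model.classes]
        if parents:
            for p in parents:
                children_of[p].append(iri)
        else:
            roots.append(iri)

    def build(iri: str) -> ClassTreeNode:
        cdef = model.classes[iri]
        kids = sorted(children_of[iri], key=lambda i: (model.classes[i].name, i))
        return ClassTreeNode(iri, cdef.name, [build(k) for k in kids])

    return [build(r) for r in sorted(roots, key=lambda i: (model.classes[i].name, i))]


def class_metadata(normalized: NormalizedGraph, class_iri: str) -> ClassMetadata:
    """The Children/Attributes/Associations structure for one class."""
    model = normalized.base
    cdef = model.resolve_class(class_iri)
    flat = normalized.flattened[cdef.iri]
    kids = sorted(
        ((c.iri, c.name) for c in model.classes.values() if cdef.iri in c.parents),
        key=lambda t: (t[1], t[0]))
    return ClassMetadata(cdef.iri, cdef.name, kids,
                         list(flat.attributes), list(flat.associations))


# ---------------------------------------------------------------------------
# SPARQL generation


_PROLOGUE = f"""\
PREFIX bridg: <{BRIDG}>
PREFIX spl: <{SPL}>
"""


def sparql_for_attributes(class_iri: str,
                          vocab: Optional[NormalizationVocab] = None) -> str:
    """SPARQL 1.1 SELECT retrieving every (flattened) attribute of a class.

    Unbounded upper cardinalities are emitted without a ``spl:maxCount``
    triple, hence the OPTIONAL.
    """
    v = vocab or NormalizationVocab()
    return f"""{_PROLOGUE}
SELECT ?attribute ?datatype ?minCount ?maxCount ?isInherited ?owner
WHERE {{
  <{class_iri}> <{v.attribute_property}> ?node .
  ?node a <{v.attribute_template}> ;
        spl:predicate ?attribute ;
        spl:valueType ?datatype ;
        spl:minCount ?minCount ;
        <{v.is_inherited}> ?isInherited ;
        <{v.owner_class}> ?owner .
  OPTIONAL {{ ?node spl:maxCount ?maxCount }}
}}
ORDER BY ?isInherited ?attribute ?owner
"""


def sparql_for_associations(class_iri: str,
                            vocab: Optional[NormalizationVocab] = None) -> str:
    """SPARQL 1.1 SELECT retrieving every (flattened) association of a class."""
    v = vocab or NormalizationVocab()
    return f"""{_PROLOGUE}
SELECT ?role ?target ?minCount ?maxCount ?isInherited ?owner
WHERE {{
  <{class_iri}> <{v.association_property}> ?node .
  ?node a <{v.attribute_template}> ;
        spl:predicate ?role ;
        <{v.target_class}> ?target ;
        spl:minCount ?minCount ;
        <{v.is_inherited}> ?isInherited ;
        <{v.owner_class}> ?owner .
  OPTIONAL {{ ?node spl:maxCount ?maxCount }}
}}
ORDER BY ?isInherited ?role ?target ?owner
"""


def _card(min_term, max_term) -> Cardinality:
    return Cardinality(int(min_term),
                       UNBOUNDED if max_term is None else int(max_term))


def run_attribute_query(graph: Graph, class_iri: str,
                        vocab: Optional[NormalizationVocab] = None) -> list[AttributeSpec]:
    """Execute the attribute query against a graph holding emitted Turtle."""
    rows = graph.query(sparql_for_attributes(class_iri, vocab))
    return [AttributeSpec(str(r.owner), str(r.attribute), str(r.datatype),
                          _card(r.minCount, r.maxCount),
                          bool(r.isInherited.toPython()))
            for r in rows]


def run_association_query(graph: Graph, class_iri: str,
                          vocab: Optional[NormalizationVocab] = None) -> list[AssociationSpec]:
    """Execute the association query against a graph holding emitted Turtle."""
    rows = graph.query(sparql_for_associations(class_iri, vocab))
    return [AssociationSpec(str(r.owner), str(r.role), str(r.target),
                            _card(r.minCount, r.maxCount),
                            bool(r.isInherited.toPython()))
            for r in rows]
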