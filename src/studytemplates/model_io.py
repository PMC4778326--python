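"""Loading the domain model and data-type ontology into structured indices.

The domain-analysis model (a BRIDG-style class hierarchy) and the data-type
ontology (HL7 V3 / ISO 21090-style complex types) arrive as two separate
OWL/RDF files.  :func:`load_model` parses both, merges them into a single
:class:`ModelGraph` under a namespace-unification policy, and indexes

* classes with their direct parents and *local* (non-inherited) attribute
  and association declarations, and
* data types with their named components.

Two declaration dialects are accepted and normalized to the same structured
view:

* **restriction style** — ``rdfs:subClassOf [ a owl:Restriction ;
  owl:onProperty :educationLevelCode ; owl:allValuesFrom dt:CD ;
  owl:minCardinality 0 ; owl:maxCardinality 1 ]``.  The filler decides the
  kind: a domain class makes the restriction an association (role name =
  the property's label), anything else an attribute.
* **annotation-instance style** — ``:Person stv:attribute [ a
  stv:Attribute ; stv:name "educationLevelCode" ; stv:datatype dt:CD ;
  stv:minCardinality 0 ; stv:maxCardinality 1 ]`` and the analogous
  ``stv:association`` nodes with ``stv:roleName`` / ``stv:targetClass``.

Because the two source ontologies historically use different IRI bases for
the *same* data types, the :class:`NamespacePolicy` carries a declarative
prefix-rewrite table applied to every IRI during the merge; references that
still fail to resolve afterwards are collected on the model (and raised
under ``strict=True``), never silently dropped.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

import yaml
from rdflib import BNode, Graph, Literal, URIRef
from rdflib.util import guess_format

from .datatypes import UNBOUNDED, Cardinality, ComponentDef, DataTypeDef, _local_name
from .errors import (
    AmbiguousNameError,
    NotFoundError,
    ParseError,
    UnresolvedTypeError,
)
from .vocab import DEFAULT_PREFIXES, OWL, RDF, RDFS, STV

logger = logging.getLogger(__name__)

#: Default rewrite table: maps the data-type reference bases used by the
#: bundled fixtures and the synthetic generator onto the base under which
#: the data-type ontology defines its types.
DEFAULT_REWRITES = {
    "http://www.bridgmodel.org/iso-datatypes#": "http://www.hl7.org/owl/iso-datatypes#",
    "http://example.org/synth/typeref#": "http://example.org/synth/datatypes#",
}


@dataclass
class NamespacePolicy:
    """Declarative namespace unification: prefix-base rewrites + strictness."""

    rewrites: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_REWRITES))
    strict: bool = False

    def apply(self, iri: str) -> str:
        for src, dst in self.rewrites.items():
            if iri.startswith(src):
                return dst + iri[len(src):]
        return iri

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "NamespacePolicy":
        """Read a YAML/JSON config: ``{"rewrites": {...}, "strict": bool}``."""
        text = Path(path).read_text()
        data = yaml.safe_load(text) if not str(path).endswith(".json") else json.loads(text)
        data = data or {}
        rewrites = dict(DEFAULT_REWRITES)
        rewrites.update(data.get("rewrites", {}))
        return cls(rewrites=rewrites, strict=bool(data.get("strict", False)))


@dataclass
class AttributeSpec:
    """One attribute declaration, local to ``owner_class``."""

    owner_class: str
    name: str
    datatype: str
    cardinality: Cardinality = field(default_factory=Cardinality)
    is_inherited: bool = False

    def copy_inherited(self) -> "AttributeSpec":
        return AttributeSpec(self.owner_class, self.name, self.datatype,
                             self.cardinality, is_inherited=True)


@dataclass
class AssociationSpec:
    """One association declaration: a named role to a target class."""

    owner_class: str
    role_name: str
    target_class: str
    cardinality: Cardinality = field(default_factory=Cardinality)
    is_inherited: bool = False

    def copy_inherited(self) -> "AssociationSpec":
        return AssociationSpec(self.owner_class, self.role_name, self.target_class,
                               self.cardinality, is_inherited=True)


@dataclass
class ClassDef:
    """Structured view of one class with only its local declarations."""

    iri: str
    name: str
    parents: list[str] = field(default_factory=list)
    local_attributes: list[AttributeSpec] = field(default_factory=list)
    local_associations: list[AssociationSpec] = field(default_factory=list)
    definition_text: Optional[str] = None


class ModelGraph:
    """The merged, namespace-unified RDF view of domain model + data types.

    Holds the merged :class:`rdflib.Graph` alongside structured indices;
    bare-name lookups resolve through labels and IRI local names and raise
    :class:`AmbiguousNameError` when a name maps to several IRIs.
    """

    def __init__(self, graph: Graph, policy: NamespacePolicy):
        self.graph = graph
        self.policy = policy
        self.classes: dict[str, ClassDef] = {}
        self.datatypes: dict[str, DataTypeDef] = {}
        #: (class-IRI, attribute-name, unresolved type IRI) triples
        self.unresolved: list[tuple[str, str, str]] = []
        self._class_names: dict[str, set[str]] = {}
        self._type_names: dict[str, set[str]] = {}

    # -- index construction -------------------------------------------------

    def _index_class(self, cdef: ClassDef) -> None:
        self.classes[cdef.iri] = cdef
        for alias in {cdef.name, _local_name(cdef.iri)}:
            self._class_names.setdefault(alias, set()).add(cdef.iri)

    def _index_datatype(self, dt: DataTypeDef) -> None:
        self.datatypes[dt.iri] = dt
        for alias in {dt.name, _local_name(dt.iri)}:
            self._type_names.setdefault(alias, set()).add(dt.iri)

    # -- lookups ------------------------------------------------------------

    @staticmethod
    def _resolve(key: str, by_iri: dict, by_name: dict[str, set[str]],
                 kind: str) -> str:
        if key in by_iri:
            return key
        iris = by_name.get(key, set())
        if not iris:
            raise NotFoundError(f"no {kind} named or identified by {key!r}")
        if len(iris) > 1:
            raise AmbiguousNameError(key, sorted(iris))
        return next(iter(iris))

    def resolve_class(self, iri_or_name: str) -> ClassDef:
        return self.classes[self._resolve(iri_or_name, self.classes,
                                          self._class_names, "class")]

    def resolve_datatype(self, iri_or_name: str) -> DataTypeDef:
        return self.datatypes[self._resolve(iri_or_name, self.datatypes,
                                            self._type_names, "data type")]

    def has_class(self, iri_or_name: str) -> bool:
        try:
            self.resolve_class(iri_or_name)
            return True
        except (NotFoundError, AmbiguousNameError):
            return False

    @property
    def namespace_map(self) -> dict[str, str]:
        return {prefix: str(ns) for prefix, ns in self.graph.namespaces()}

    # -- serialization ------------------------------------------------------

    def serialize(self, destination: Union[str, Path, None] = None) -> str:
        text = self.graph.serialize(format="turtle")
        if destination is not None:
            Path(destination).write_text(text)
        return text


def get_class(model: ModelGraph, iri_or_name: str) -> ClassDef:
    """Look up one class; the returned view holds only local declarations."""
    return model.resolve_class(iri_or_name)


# ---------------------------------------------------------------------------
# loading


def _parse_file(path: Union[str, Path]) -> Graph:
    g = Graph()
    fmt = guess_format(str(path)) or "turtle"
    try:
        g.parse(str(path), format=fmt)
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise ParseError(f"cannot parse {path} as RDF ({fmt}): {exc}") from exc
    return g


def _parse_text(text: str, fmt: str = "turtle") -> Graph:
    g = Graph()
    try:
        g.parse(data=text, format=fmt)
    except Exception as exc:
        raise ParseError(f"cannot parse document as RDF ({fmt}): {exc}") from exc
    return g


def _rewrite_graph(src: Graph, policy: NamespacePolicy, dest: Graph) -> None:
    for s, p, o in src:
        s2 = URIRef(policy.apply(str(s))) if isinstance(s, URIRef) else s
        p2 = URIRef(policy.apply(str(p))) if isinstance(p, URIRef) else p
        o2 = URIRef(policy.apply(str(o))) if isinstance(o, URIRef) else o
        dest.add((s2, p2, o2))


def _name_of(g: Graph, node) -> str:
    label = g.value(node, RDFS.label)
    return str(label) if label is not None else _local_name(str(node))


def _int_value(g: Graph, node, pred) -> Optional[int]:
    v = g.value(node, pred)
    return int(v) if v is not None else None


def _cardinality_of(g: Graph, node, min_pred, max_pred, context: str) -> Cardinality:
    """Read a min/max pair; a fully absent cardinality defaults to 0..1."""
    lo = _int_value(g, node, min_pred)
    hi_term = g.value(node, max_pred)
    if lo is None and hi_term is None:
        logger.warning("no cardinality on %s; defaulting to 0..1", context)
        return Cardinality(0, 1)
    if hi_term is None:
        hi: int | object = UNBOUNDED  # explicit min, open upper bound
    elif str(hi_term).strip() == "*":
        hi = UNBOUNDED
    else:
        hi = int(hi_term)
    return Cardinality(lo or 0, hi)


def load_model(domain_path: Union[str, Path], datatype_path: Union[str, Path],
               namespace_policy: Optional[NamespacePolicy] = None) -> ModelGraph:
    """Load and merge the domain model and the data-type ontology.

    Raises :class:`ParseError` on malformed RDF and, when
    ``namespace_policy.strict`` is set, :class:`UnresolvedTypeError` if any
    attribute's data type still fails to resolve after unification.
    """
    policy = namespace_policy or NamespacePolicy()
    return _build_model(_parse_file(domain_path), _parse_file(datatype_path), policy)


def load_model_from_texts(domain_ttl: str, datatype_ttl: str,
                          namespace_policy: Optional[NamespacePolicy] = None,
                          fmt: str = "turtle") -> ModelGraph:
    """Like :func:`load_model`, from in-memory documents (generator output)."""
    policy = namespace_policy or NamespacePolicy()
    return _build_model(_parse_text(domain_ttl, fmt), _parse_text(datatype_ttl, fmt),
                        policy)


def _build_model(domain_raw: Graph, dt_raw: Graph,
                 policy: NamespacePolicy) -> ModelGraph:
    merged = Graph()
    for prefix, ns in DEFAULT_PREFIXES.items():
        merged.bind(prefix, ns)
    for raw in (domain_raw, dt_raw):
        for prefix, ns in raw.namespaces():
            if prefix and not prefix.startswith("default"):
                merged.bind(prefix, URIRef(policy.apply(str(ns))), override=False)
    _rewrite_graph(domain_raw, policy, merged)
    _rewrite_graph(dt_raw, policy, merged)

    model = ModelGraph(merged, policy)

    # Data types first: attribute resolution depends on them.  A type is any
    # named owl:Class in the data-type graph; components come from
    # stv:component nodes, ordered by stv:index then name.
    dt_view = Graph()
    _rewrite_graph(dt_raw, policy, dt_view)
    for t in sorted(set(dt_view.subjects(RDF.type, OWL.Class))):
        if isinstance(t, BNode):
            continue
        comps = []
        for cnode in dt_view.objects(t, STV.component):
            cname = dt_view.value(cnode, STV.name)
            ctype = dt_view.value(cnode, STV.datatype)
            if cname is None or ctype is None:
                continue
            idx = _int_value(dt_view, cnode, STV["index"])
            card = _cardinality_of(dt_view, cnode, STV.minCardinality,
                                   STV.maxCardinality,
                                   f"component {cname} of {t}")
            comps.append((idx if idx is not None else 10 ** 9, str(cname),
                          ComponentDef(str(cname), str(ctype), card)))
        comps.sort(key=lambda c: (c[0], c[1]))
        model._index_datatype(
            DataTypeDef(str(t), _name_of(dt_view, t), [c[2] for c in comps]))

    # Domain classes.
    dom_view = Graph()
    _rewrite_graph(domain_raw, policy, dom_view)
    class_iris = {str(c) for c in dom_view.subjects(RDF.type, OWL.Class)
                  if isinstance(c, URIRef)}
    for iri in sorted(class_iris):
        c = URIRef(iri)
        parents = sorted({str(p) for p in dom_view.objects(c, RDFS.subClassOf)
                          if isinstance(p, URIRef) and str(p) != iri})
        comment = dom_view.value(c, RDFS.comment)
        cdef = ClassDef(iri, _name_of(dom_view, c), parents,
                        definition_text=str(comment) if comment else None)

        # annotation-instance dialect
        for node in _ordered_decl_nodes(dom_view, c, STV.attribute):
            name = dom_view.value(node, STV.name)
            dtype = dom_view.value(node, STV.datatype)
            if name is None or dtype is None:
                continue
            card = _cardinality_of(dom_view, node, STV.minCardinality,
                                   STV.maxCardinality, f"{iri}.{name}")
            cdef.local_attributes.append(
                AttributeSpec(iri, str(name), str(dtype), card))
        for node in _ordered_decl_nodes(dom_view, c, STV.association):
            role = dom_view.value(node, STV.roleName)
            target = dom_view.value(node, STV.targetClass)
            if role is None or target is None:
                continue
            card = _cardinality_of(dom_view, node, STV.minCardinality,
                                   STV.maxCardinality, f"{iri} -[{role}]->")
            cdef.local_associations.append(
                AssociationSpec(iri, str(role), str(target), card))

        # restriction dialect (appended after annotation-style declarations,
        # sorted by property name for load determinism)
        restr_attrs: list[AttributeSpec] = []
        restr_assocs: list[AssociationSpec] = []
        for node in dom_view.objects(c, RDFS.subClassOf):
            if not isinstance(node, BNode):
                continue
            if (node, RDF.type, OWL.Restriction) not in dom_view:
                continue
            prop = dom_view.value(node, OWL.onProperty)
            filler = dom_view.value(node, OWL.allValuesFrom) \
                or dom_view.value(node, OWL.someValuesFrom)
            if prop is None or filler is None:
                continue
            card = _cardinality_of(dom_view, node, OWL.minCardinality,
                                   OWL.maxCardinality, f"{iri} on {prop}")
            if str(filler) in class_iris:
                restr_assocs.append(
                    AssociationSpec(iri, _name_of(dom_view, prop),
                                    str(filler), card))
            else:
                restr_attrs.append(
                    AttributeSpec(iri, _name_of(dom_view, prop),
                                  str(filler), card))
        cdef.local_attributes.extend(sorted(restr_attrs, key=lambda a: a.name))
        cdef.local_associations.extend(
            sorted(restr_assocs, key=lambda a: (a.role_name, a.target_class)))

        model._index_class(cdef)

    # Resolution audit: every referenced data type must resolve after
    # unification or be recorded.
    for cdef in model.classes.values():
        for attr in cdef.local_attributes:
            if attr.datatype not in model.datatypes:
                model.unresolved.append((cdef.iri, attr.name, attr.datatype))
        for assoc in cdef.local_associations:
            if assoc.target_class not in model.classes:
                model.unresolved.append(
                    (cdef.iri, assoc.role_name, assoc.target_class))
    if model.unresolved and policy.strict:
        raise UnresolvedTypeError(model.unresolved)
    for c, a, t in model.unresolved:
        logger.warning("unresolved reference %s.%s -> %s", c, a, t)

    return model


def _ordered_decl_nodes(g: Graph, subject, predicate) -> Iterable:
    """Declaration nodes for one class, ordered by stv:index then name."""
    nodes = []
    for node in g.objects(subject, predicate):
        idx = _int_value(g, node, STV["index"])
        name = g.value(node, STV.name) or g.value(node, STV.roleName) or Literal("")
        nodes.append((idx if idx is not None else 10 ** 9, str(name), node))
    nodes.sort(key=lambda t: (t[0], t[1]))
    return [n for _, _, n in nodes]
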