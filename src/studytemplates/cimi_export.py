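"""CIMI-shaped RDF serialization of templates, and parsing it back.

The mapping follows the CIMI reference model: a domain-specific template is
an ``ENTRY`` (the logical root of a single clinical statement), each
selected class becomes a ``CLUSTER`` (a set of elements), and each selected
attribute path becomes an ``ELEMENT`` (an atomic data item).  Containment
is expressed with ``cimi:CLUSTER.item`` at both levels, and every ELEMENT
carries a SPIN-style metadata node (``spl:attribute`` → a node typed
``spl:Attribute``) holding the full selection path as its name, the
cardinality, the inheritance flag and, for association-mediated elements,
the role name.

RDF triples are unordered, so cluster and element positions are preserved
with explicit ``tmpl:index`` literals; node IRIs are skolemized
deterministically from the template name and path strings, making the
Turtle output reproducible byte for byte.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from rdflib import Graph, Literal, URIRef

from .datatypes import UNBOUNDED, Cardinality, SelectionPath
from .errors import EmptyTemplateError, ParseError, PathError, StructureError
from .template_builder import Template, TemplateCluster, TemplateElement
from .vocab import BRIDG, CIMI, DEFAULT_PREFIXES, RDF, RDFS, SPL, TMPL


@dataclass
class CimiConfig:
    """Term IRIs for the CIMI serialization (all overridable)."""

    entry_type: URIRef = CIMI.ENTRY
    cluster_type: URIRef = CIMI.CLUSTER
    element_type: URIRef = CIMI.ELEMENT
    item: URIRef = CIMI["CLUSTER.item"]
    attribute_link: URIRef = SPL.attribute
    attribute_template: URIRef = SPL.Attribute
    base: str = str(TMPL)


@dataclass
class CimiDocument:
    """One serialized template: an RDF graph rooted at a single ENTRY node."""

    entry_node: URIRef
    graph: Graph
    config: CimiConfig = field(default_factory=CimiConfig)

    def serialize(self, destination: Union[str, Path, None] = None) -> str:
        text = self.graph.serialize(format="turtle")
        if destination is not None:
            Path(destination).write_text(text)
        return text

    def count(self, rdf_type: URIRef) -> int:
        return len(set(self.graph.subjects(RDF.type, rdf_type)))


def _slug(text: str) -> str:
    return re.sub(r"[^A-Za-z0-9._-]+", "_", text).strip("_") or "x"


def to_cimi(template: Template, config: Optional[CimiConfig] = None) -> CimiDocument:
    """Serialize a template as a CIMI ENTRY/CLUSTER/ELEMENT graph."""
    if not template.clusters or not any(c.elements for c in template.clusters):
        raise EmptyTemplateError(f"template {template.name!r} has no elements")
    cfg = config or CimiConfig()
    g = Graph()
    for prefix, ns in sorted(DEFAULT_PREFIXES.items()):
        g.bind(prefix, ns)

    entry = URIRef(cfg.base + "template/" + _slug(template.name))
    g.add((entry, RDF.type, cfg.entry_type))
    g.add((entry, RDFS.label, Literal(template.name)))

    for i, cluster in enumerate(template.clusters):
        cnode = URIRef(f"{entry}/cluster/{i}-{_slug(cluster.class_name)}")
        g.add((entry, cfg.item, cnode))
        g.add((cnode, RDF.type, cfg.cluster_type))
        g.add((cnode, RDFS.label, Literal(cluster.class_name)))
        g.add((cnode, TMPL.classIri, URIRef(cluster.class_iri)))
        g.add((cnode, TMPL["index"], Literal(i)))
        for j, elem in enumerate(cluster.elements):
            enode = URIRef(f"{cnode}/element/{j}-{_slug(elem.path.render())}")
            g.add((cnode, cfg.item, enode))
            g.add((enode, RDF.type, cfg.element_type))
            g.add((enode, TMPL["index"], Literal(j)))
            meta = URIRef(str(enode) + "/meta")
            g.add((enode, cfg.attribute_link, meta))
            g.add((meta, RDF.type, cfg.attribute_template))
            g.add((meta, SPL.predicate, Literal(elem.path.render())))
            g.add((meta, SPL.minCount, Literal(elem.cardinality.min)))
            if not elem.cardinality.unbounded:
                g.add((meta, SPL.maxCount, Literal(elem.cardinality.max)))
            g.add((meta, BRIDG.isInherited, Literal(elem.is_inherited)))
            if elem.via_association is not None:
                g.add((meta, TMPL.viaAssociation, Literal(elem.via_association)))
    return CimiDocument(entry, g, cfg)


def from_cimi(turtle_text: str, config: Optional[CimiConfig] = None) -> Template:
    """Parse a CIMI template document back into a :class:`Template`.

    Raises :class:`ParseError` for non-Turtle input and
    :class:`StructureError` naming the violated invariant (entry count,
    unreachable nodes, missing metadata).
    """
    cfg = config or CimiConfig()
    if not turtle_text or not turtle_text.strip():
        raise ParseError("empty document")
    g = Graph()
    try:
        g.parse(data=turtle_text, format="turtle")
    except Exception as exc:
        raise ParseError(f"not valid Turtle: {exc}") from exc

    entries = sorted(set(g.subjects(RDF.type, cfg.entry_type)))
    if len(entries) != 1:
        raise StructureError(
            f"document must contain exactly one ENTRY node, found {len(entries)}")
    entry = entries[0]
    name = g.value(entry, RDFS.label)
    template = Template(str(name) if name else _local(entry))

    all_clusters = set(g.subjects(RDF.type, cfg.cluster_type))
    all_elements = set(g.subjects(RDF.type, cfg.element_type))
    seen_clusters: set = set()
    seen_elements: set = set()

    cnodes = [c for c in g.objects(entry, cfg.item) if c in all_clusters]
    for cnode in sorted(cnodes, key=lambda n: _index(g, n)):
        seen_clusters.add(cnode)
        class_iri = g.value(cnode, TMPL.classIri)
        label = g.value(cnode, RDFS.label)
        if class_iri is None:
            raise StructureError(f"CLUSTER <{cnode}> carries no class binding")
        cluster = TemplateCluster(str(class_iri),
                                  str(label) if label else _local(class_iri))
        enodes = [e for e in g.objects(cnode, cfg.item) if e in all_elements]
        for enode in sorted(enodes, key=lambda n: _index(g, n)):
            seen_elements.add(enode)
            cluster.elements.append(_read_element(g, enode, cfg))
        template.clusters.append(cluster)

    if all_clusters - seen_clusters:
        raise StructureError(
            f"{len(all_clusters - seen_clusters)} CLUSTER node(s) not reachable "
            "from the ENTRY")
    if all_elements - seen_elements:
        raise StructureError(
            f"{len(all_elements - seen_elements)} ELEMENT node(s) not reachable "
            "from the ENTRY through CLUSTER.item links")
    return template


def _read_element(g: Graph, enode, cfg: CimiConfig) -> TemplateElement:
    meta = g.value(enode, cfg.attribute_link)
    if meta is None:
        raise StructureError(f"ELEMENT <{enode}> carries no metadata node")
    name = g.value(meta, SPL.predicate)
    if name is None:
        raise StructureError(f"metadata of ELEMENT <{enode}> carries no name")
    min_count = g.value(meta, SPL.minCount)
    if min_count is None:
        raise StructureError(f"metadata of ELEMENT <{enode}> carries no cardinality")
    max_count = g.value(meta, SPL.maxCount)
    card = Cardinality(int(min_count),
                       UNBOUNDED if max_count is None else int(max_count))
    try:
        path = SelectionPath.parse(str(name))
    except PathError as exc:
        raise StructureError(f"element name is not a selection path: {exc}") from exc
    inherited = g.value(meta, BRIDG.isInherited)
    via = g.value(meta, TMPL.viaAssociation)
    return TemplateElement(path, card,
                           bool(inherited.toPython()) if inherited is not None else False,
                           str(via) if via is not None else None)


def sparql_insert(doc: CimiDocument, graph_iri: Optional[str] = None) -> str:
    """A SPARQL 1.1 ``INSERT DATA`` payload storing the document in a store."""
    triples = doc.graph.serialize(format="nt")
    body = "".join("    " + line + "\n"
                   for line in sorted(triples.splitlines()) if line.strip())
    if graph_iri:
        return f"INSERT DATA {{\n  GRAPH <{graph_iri}> {{\n{body}  }}\n}}\n"
    return f"INSERT DATA {{\n{body}}}\n"


def _local(node) -> str:
    s = str(node)
    for sep in ("#", "/"):
        if sep in s:
            return s.rsplit(sep, 1)[1]
    return s


def _index(g: Graph, node) -> int:
    v = g.value(node, TMPL["index"])
    return int(v) if v is not None else 10 ** 9
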