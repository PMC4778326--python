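"""Class tree, per-class metadata, and SPARQL/API agreement."""

import pytest
from rdflib import Graph
from rdflib.plugins.sparql import prepareQuery

from studytemplates import (
    class_metadata,
    class_tree,
    load_model_from_texts,
    normalize,
    run_association_query,
    run_attribute_query,
    sparql_for_associations,
    sparql_for_attributes,
)
from studytemplates.errors import NotFoundError
from studytemplates.synthetic import empty_domain

from .oracles import closure_attributes

MINI_DT = """\
@prefix dt: <http://example.org/synth/datatypes#> .
@prefix owl: <http://www.w3.org/2002/07/owl#> .
@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .
dt:P0 a owl:Class ; rdfs:label "P0" .
"""

CHAIN = """\
@prefix : <http://example.org/synth/model#> .
@prefix owl: <http://www.w3.org/2002/07/owl#> .
@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .
:A a owl:Class ; rdfs:label "A" .
:B a owl:Class ; rdfs:label "B" ; rdfs:subClassOf :A .
:C a owl:Class ; rdfs:label "C" ; rdfs:subClassOf :B .
"""

DIAMOND = """\
@prefix : <http://example.org/synth/model#> .
@prefix owl: <http://www.w3.org/2002/07/owl#> .
@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .
:Top a owl:Class .
:L a owl:Class ; rdfs:subClassOf :Top .
:R a owl:Class ; rdfs:subClassOf :Top .
:Bottom a owl:Class ; rdfs:subClassOf :L , :R .
"""


def _reparsed(normalized) -> Graph:
    g = Graph()
    g.parse(data=normalized.serialize(), format="turtle")
    return g


class TestClassTree:
    def test_empty_model(self):
        normalized = normalize(load_model_from_texts(empty_domain(), MINI_DT))
        assert class_tree(normalized) == []

    def test_chain_nests_in_order(self):
        normalized = normalize(load_model_from_texts(CHAIN, MINI_DT))
        roots = class_tree(normalized)
        assert len(roots) == 1
        a = roots[0]
        assert a.name == "A"
        assert [c.name for c in a.children] == ["B"]
        assert [c.name for c in a.children[0].children] == ["C"]

    def test_person_under_biologic_entity(self, bridg_normalized):
        roots = class_tree(bridg_normalized)
        be = next(r for r in roots if r.name == "Biologic Entity")
        assert [c.name for c in be.children] == ["Person"]

    def test_multi_parent_class_repeats_under_each_parent(self):
        normalized = normalize(load_model_from_texts(DIAMOND, MINI_DT))
        (top,) = class_tree(normalized)
        assert [c.name for c in top.children] == ["L", "R"]
        assert all(c.children and c.children[0].name == "Bottom"
                   for c in top.children)


class TestClassMetadata:
    def test_person_associations_and_flags(self, bridg_normalized):
        po = class_metadata(bridg_normalized, "Performed Observation")
        reported = [a for a in po.associations if a.role_name == "be reported by"]
        targets = {t.rsplit("#", 1)[1] for t in (a.target_class for a in reported)}
        assert targets == {"Subject", "HealthcareProvider", "Laboratory", "Device"}
        # inherited statusCode is flagged, locals are not
        flags = {a.name: a.is_inherited for a in po.attributes}
        assert flags["statusCode"] is True
        assert flags["methodCode"] is False

    def test_leaf_class_has_no_children(self, bridg_normalized):
        assert class_metadata(bridg_normalized, "Person").children == []

    def test_children_are_direct_subclasses(self, bridg_normalized):
        obs = class_metadata(bridg_normalized, "Observation")
        assert [n for _, n in obs.children] == \
            ["Defined Observation", "Performed Observation"]

    def test_dag_attribute_counts_match_oracle(self, synth_normalized):
        _, model, normalized = synth_normalized(n_classes=20,
                                                multi_parent_prob=0.3, seed=7)
        for iri in model.classes:
            meta = class_metadata(normalized, iri)
            assert len(meta.attributes) == len(closure_attributes(model, iri))

    def test_unknown_class(self, bridg_normalized):
        with pytest.raises(NotFoundError):
            class_metadata(bridg_normalized, "Nope")


class TestSparql:
    def test_query_text_is_valid_sparql(self, bridg_model):
        for iri in bridg_model.classes:
            prepareQuery(sparql_for_attributes(iri))
            prepareQuery(sparql_for_associations(iri))

    def test_row_count_equals_flattened_count(self, bridg_normalized):
        g = _reparsed(bridg_normalized)
        person = bridg_normalized.base.resolve_class("Person").iri
        rows = run_attribute_query(g, person)
        assert len(rows) == len(bridg_normalized.flattened[person].attributes) == 4

    def test_class_with_empty_ancestry_returns_no_rows(self):
        normalized = normalize(load_model_from_texts(DIAMOND, MINI_DT))
        g = _reparsed(normalized)
        bottom = normalized.base.resolve_class("Bottom").iri
        assert run_attribute_query(g, bottom) == []

    @pytest.mark.parametrize("seed,dialect", [(7, "annotation"), (3, "restriction")])
    def test_sparql_api_agreement_on_synthetic_models(self, synth_normalized,
                                                      seed, dialect):
        """Executing the generated queries over the emitted Turtle returns the
        same multisets as the in-memory API, for every class."""
        _, model, normalized = synth_normalized(
            n_classes=15, multi_parent_prob=0.3, seed=seed, dialect=dialect)
        g = _reparsed(normalized)
        for iri in model.classes:
            flat = normalized.flattened[iri]
            assert sorted((a.owner_class, a.name, a.datatype, str(a.cardinality),
                           a.is_inherited) for a in run_attribute_query(g, iri)) == \
                sorted((a.owner_class, a.name, a.datatype, str(a.cardinality),
                        a.is_inherited) for a in flat.attributes)
            assert sorted((a.owner_class, a.role_name, a.target_class,
                           str(a.cardinality), a.is_inherited)
                          for a in run_association_query(g, iri)) == \
                sorted((a.owner_class, a.role_name, a.target_class,
                        str(a.cardinality), a.is_inherited)
                       for a in flat.associations)
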