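"""Inheritance materialization against the brute-force closure oracle."""

import pytest

from studytemplates import (
    AttributeSpec,
    Cardinality,
    CycleError,
    NameCollisionError,
    NotFoundError,
    SynthConfig,
    ancestors,
    generate,
    is_inherited,
    load_model_from_texts,
    normalize,
)
from studytemplates.synthetic import cyclic_domain

from .oracles import closure_associations, closure_attributes, dfs_ancestors

MINI_DT = """\
@prefix dt: <http://example.org/synth/datatypes#> .
@prefix owl: <http://www.w3.org/2002/07/owl#> .
@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .
dt:P0 a owl:Class ; rdfs:label "P0" .
"""


def _flat_attr_set(normalized, iri):
    return {(a.owner_class, a.name) for a in normalized.flattened[iri].attributes}


def _flat_assoc_set(normalized, iri):
    return {(a.owner_class, a.role_name, a.target_class)
            for a in normalized.flattened[iri].associations}


class TestAncestors:
    def test_root_has_no_ancestors(self, bridg_model):
        assert ancestors(bridg_model, "Biologic Entity") == []

    def test_person_ancestors(self, bridg_model):
        anc = ancestors(bridg_model, "Person")
        assert [a.rsplit("#", 1)[1] for a in anc] == ["BiologicEntity"]

    def test_depth_4_chain_matches_dfs_oracle(self):
        # a pure chain: force single-parent by disabling extra roots
        sm = generate(SynthConfig(n_classes=4, max_depth=4, multi_parent_prob=0.0,
                                  seed=2))
        model = load_model_from_texts(sm.domain_ttl, sm.datatype_ttl)
        for iri in model.classes:
            assert set(ancestors(model, iri)) == dfs_ancestors(model, iri)

    def test_diamond_deduplicates(self):
        domain = """\
@prefix : <http://example.org/synth/model#> .
@prefix owl: <http://www.w3.org/2002/07/owl#> .
@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .
:Top a owl:Class .
:L a owl:Class ; rdfs:subClassOf :Top .
:R a owl:Class ; rdfs:subClassOf :Top .
:Bottom a owl:Class ; rdfs:subClassOf :L , :R .
"""
        model = load_model_from_texts(domain, MINI_DT)
        anc = ancestors(model, "Bottom")
        assert len(anc) == len(set(anc)) == 3
        # breadth-first: both direct parents precede the shared grandparent
        assert anc[-1].endswith("#Top")

    def test_cycle_raises(self):
        model = load_model_from_texts(cyclic_domain(), MINI_DT)
        with pytest.raises(CycleError):
            ancestors(model, "A")


class TestNormalize:
    def test_person_flattening_matches_named_examples(self, bridg_normalized):
        """Inherited name/birthDate and local education/marital codes."""
        person = bridg_normalized.base.resolve_class("Person")
        flags = {a.name: a.is_inherited
                 for a in bridg_normalized.flattened[person.iri].attributes}
        assert flags == {"name": True, "birthDate": True,
                         "educationLevelCode": False, "maritalStatusCode": False}

    def test_single_class_flattened_equals_local(self):
        sm = generate(SynthConfig(n_classes=1, attrs_per_class=(2, 2), seed=0))
        model = load_model_from_texts(sm.domain_ttl, sm.datatype_ttl)
        normalized = normalize(model)
        (iri,) = model.classes
        flat = normalized.flattened[iri]
        assert flat.attributes == model.classes[iri].local_attributes
        assert all(not a.is_inherited for a in flat.attributes)

    @pytest.mark.parametrize("dialect", ["annotation", "restriction"])
    def test_random_dag_matches_oracle(self, dialect):
        sm = generate(SynthConfig(n_classes=20, multi_parent_prob=0.3, seed=7,
                                  dialect=dialect))
        model = load_model_from_texts(sm.domain_ttl, sm.datatype_ttl)
        normalized = normalize(model)
        for iri in model.classes:
            assert _flat_attr_set(normalized, iri) == closure_attributes(model, iri)
            assert _flat_assoc_set(normalized, iri) == closure_associations(model, iri)

    def test_ground_truth_agrees_with_generator(self, synth_normalized):
        sm, model, normalized = synth_normalized(n_classes=15, multi_parent_prob=0.4,
                                                 seed=13)
        for iri, truth in sm.ground_truth.items():
            assert _flat_attr_set(normalized, iri) == \
                {(a["owner"], a["name"]) for a in truth["attributes"]}

    def test_idempotence(self, bridg_normalized):
        again = normalize(bridg_normalized.as_model())
        assert again.flattened == bridg_normalized.flattened

    def test_count_conservation(self, synth_normalized):
        """|flattened| equals the sum of local counts over ancestors-or-self."""
        _, model, normalized = synth_normalized(n_classes=20, multi_parent_prob=0.3,
                                                seed=21)
        for iri in model.classes:
            owners = {iri} | dfs_ancestors(model, iri)
            expected = sum(len(model.classes[o].local_attributes) for o in owners)
            assert len(normalized.flattened[iri].attributes) == expected

    def test_monotonicity_adding_ancestor_attribute(self, synth_normalized):
        _, model, before = synth_normalized(n_classes=10, multi_parent_prob=0.3,
                                            seed=3)
        root = next(i for i, c in model.classes.items() if not c.parents)
        model.classes[root].local_attributes.append(
            AttributeSpec(root, "brand_new_attr",
                          next(iter(model.datatypes)), Cardinality(0, 1)))
        after = normalize(model)
        for iri in model.classes:
            assert _flat_attr_set(before, iri) <= _flat_attr_set(after, iri)

    def test_cycle_raises(self):
        model = load_model_from_texts(cyclic_domain(), MINI_DT)
        with pytest.raises(CycleError):
            normalize(model)

    def test_name_collision_raises_and_keep_mode_keeps(self):
        sm = generate(SynthConfig(n_classes=6, seed=1, inject_collision=True))
        model = load_model_from_texts(sm.domain_ttl, sm.datatype_ttl)
        with pytest.raises(NameCollisionError) as exc:
            normalize(model)
        colliding = exc.value.name
        normalized = normalize(model, on_collision="keep")
        child = exc.value.class_iri
        matches = [a for a in normalized.flattened[child].attributes
                   if a.name == colliding]
        assert len(matches) == 2
        assert len({a.owner_class for a in matches}) == 2


class TestIsInherited:
    def test_paper_examples(self, bridg_normalized):
        person = bridg_normalized.base.resolve_class("Person").iri
        assert is_inherited(bridg_normalized, person, "name") is True
        assert is_inherited(bridg_normalized, person, "educationLevelCode") is False

    def test_single_class_model(self, synth_normalized):
        _, model, normalized = synth_normalized(n_classes=1,
                                                attrs_per_class=(1, 1), seed=4)
        (iri,) = model.classes
        name = model.classes[iri].local_attributes[0].name
        assert is_inherited(normalized, iri, name) is False

    def test_missing_attribute(self, bridg_normalized):
        with pytest.raises(NotFoundError):
            is_inherited(bridg_normalized, "Person", "noSuchAttr")


def test_emitted_turtle_is_deterministic(bridg_model):
    assert normalize(bridg_model).serialize() == normalize(bridg_model).serialize()
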