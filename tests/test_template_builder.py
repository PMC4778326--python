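"""Template assembly and selection-rule validation."""

import pytest
import yaml

from studytemplates import (
    EmptySelectionError,
    ParseError,
    TemplateSpec,
    ValidationError,
    build_path,
    build_template,
    class_metadata,
    measurement_use_case_spec,
    to_cimi,
    to_mindmap,
    validate_spec,
)


@pytest.fixture
def use_case_spec():
    return TemplateSpec.from_dict(measurement_use_case_spec())


class TestBuildTemplate:
    def test_five_measurement_classes_give_five_clusters(self, bridg_normalized,
                                                         use_case_spec):
        template = build_template(bridg_normalized, use_case_spec)
        assert [c.class_name for c in template.clusters] == [
            "Defined Observation", "Performed Observation",
            "Defined Observation Result", "Performed Observation Result",
            "Reference Result"]

    def test_use_case_shape_counts(self, bridg_normalized, use_case_spec):
        template = build_template(bridg_normalized, use_case_spec)
        assert len(template.clusters) == 5
        assert template.n_attribute_elements == 20
        assert template.n_association_elements == 5

    def test_inherited_attribute_is_selectable_and_flagged(self, bridg_normalized):
        spec = TemplateSpec.from_dict(
            {"name": "t", "selections": ["Person.name.ST"]})
        template = build_template(bridg_normalized, spec)
        (elem,) = template.clusters[0].elements
        assert elem.is_inherited is True

    def test_association_mediated_elements_join_target_cluster(self, bridg_normalized,
                                                               use_case_spec):
        template = build_template(bridg_normalized, use_case_spec)
        by_class = {c.class_name: c for c in template.clusters}
        rr = by_class["Reference Result"]
        roles = {e.via_association for e in rr.elements if e.via_association}
        assert roles == {"evaluated against", "has reference"}

    def test_element_cardinality_comes_from_model(self, bridg_normalized):
        spec = TemplateSpec.from_dict(
            {"name": "t", "selections": ["Defined Observation.nameCode.CD"]})
        template = build_template(bridg_normalized, spec)
        assert template.clusters[0].elements[0].cardinality.render() == "1..1"

    def test_empty_spec_raises(self, bridg_normalized):
        with pytest.raises(EmptySelectionError):
            build_template(bridg_normalized, TemplateSpec("empty"))

    def test_invalid_spec_raises_with_all_violations(self, bridg_normalized):
        spec = TemplateSpec.from_dict({"name": "t", "selections": [
            "Person.name.ST", "Person.noSuchAttr.CD", "Ghost.x.ST"]})
        with pytest.raises(ValidationError) as exc:
            build_template(bridg_normalized, spec)
        assert len(exc.value.violations) == 2


class TestValidateSpec:
    def test_valid_spec_has_no_violations(self, bridg_normalized, use_case_spec):
        assert validate_spec(bridg_normalized, use_case_spec) == []

    def test_unknown_attribute_cites_the_path(self, bridg_normalized):
        spec = TemplateSpec.from_dict(
            {"name": "t", "selections": ["Person.noSuchAttr.CD"]})
        (violation,) = validate_spec(bridg_normalized, spec)
        assert violation.rule == "unknown-attribute"
        assert "Person.noSuchAttr.CD" in violation.path

    def test_unknown_association_role(self, bridg_normalized):
        spec = TemplateSpec.from_dict({"name": "t", "associations": [
            {"source": "Person", "role": "be reported by",
             "path": "Subject.identifier.II"}]})
        (violation,) = validate_spec(bridg_normalized, spec)
        assert violation.rule == "unknown-association"

    def test_invalid_component_chain(self, bridg_normalized):
        spec = TemplateSpec.from_dict(
            {"name": "t", "selections": ["Person.maritalStatusCode.CD.foo.ST"]})
        (violation,) = validate_spec(bridg_normalized, spec)
        assert violation.rule == "invalid-component"

    def test_datatype_name_must_match_model(self, bridg_normalized):
        spec = TemplateSpec.from_dict(
            {"name": "t", "selections": ["Person.maritalStatusCode.ST"]})
        (violation,) = validate_spec(bridg_normalized, spec)
        assert violation.rule == "datatype-mismatch"

    def test_every_browsable_attribute_is_selectable(self, bridg_normalized):
        """Closure consistency: paths built from class metadata all validate."""
        model = bridg_normalized.base
        selections = []
        for iri in model.classes:
            meta = class_metadata(bridg_normalized, iri)
            for attr in meta.attributes:
                selections.append(
                    build_path(model, meta.name, attr, []).render())
        spec = TemplateSpec.from_dict({"name": "all", "selections": selections})
        assert validate_spec(bridg_normalized, spec) == []


class TestSpecDocuments:
    def test_yaml_roundtrip(self, tmp_path, bridg_normalized, use_case_spec):
        path = tmp_path / "spec.yaml"
        path.write_text(yaml.safe_dump(measurement_use_case_spec(), sort_keys=False))
        loaded = TemplateSpec.from_file(path)
        assert loaded == use_case_spec

    def test_malformed_spec_raises_parse_error(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("selections: [Person.name.ST]\n")  # no name
        with pytest.raises(ParseError):
            TemplateSpec.from_file(path)

    def test_identical_specs_serialize_identically(self, bridg_normalized,
                                                   use_case_spec):
        spec2 = TemplateSpec.from_dict(measurement_use_case_spec())
        t1 = build_template(bridg_normalized, use_case_spec)
        t2 = build_template(bridg_normalized, spec2)
        assert to_cimi(t1).serialize() == to_cimi(t2).serialize()
        assert to_mindmap(t1) == to_mindmap(t2)
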