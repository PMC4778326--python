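"""Assembling domain-specific templates from user selections.

A template spec names a template and lists dotted selection paths across
one or more classes, plus association-mediated selections (attributes of a
class reached through a named association role).  Building enforces the
selection rules of the browse surface:

1. selections may span multiple classes;
2. any flattened attribute — local or inherited — is selectable;
3. data-type components may be selected down the nesting, each path segment
   checked against the type definitions;
4. attributes of classes linked through a declared association role are
   selectable, and land in a cluster for the *target* class annotated with
   the role;
5. the result is a deterministic, serializable template (one cluster per
   distinct selected class, elements in selection order).

Validation is total, not fail-fast: :func:`validate_spec` reports every
violation, and :func:`build_template` raises a :class:`ValidationError`
carrying them all.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import yaml

from .datatypes import Cardinality, SegmentKind, SelectionPath
from .errors import (
    AmbiguousNameError,
    EmptySelectionError,
    NotFoundError,
    ParseError,
    PathError,
    ValidationError,
    Violation,
)
from .normalization import NormalizedGraph


@dataclass
class AssociationSelection:
    """A selection of one target-class attribute reached through a role."""

    source_class: str
    role_name: str
    path: SelectionPath  # CLASS segment names the target class

    def render(self) -> str:
        return f"{self.source_class} -[{self.role_name}]-> {self.path.render()}"


@dataclass
class TemplateSpec:
    """Input document: template name + selections."""

    template_name: str
    selections: list[SelectionPath] = field(default_factory=list)
    association_selections: list[AssociationSelection] = field(default_factory=list)

    @classmethod
    def from_dict(cls, data: dict) -> "TemplateSpec":
        try:
            name = data["name"]
            selections = [SelectionPath.parse(p) for p in data.get("selections", [])]
            assoc = [
                AssociationSelection(a["source"], a["role"],
                                     SelectionPath.parse(a["path"]))
                for a in data.get("associations", [])
            ]
        except (KeyError, TypeError, PathError) as exc:
            raise ParseError(f"malformed template spec: {exc}") from exc
        return cls(str(name), selections, assoc)

    @classmethod
    def from_file(cls, path: Union[str, Path]) -> "TemplateSpec":
        try:
            data = yaml.safe_load(Path(path).read_text())
        except yaml.YAMLError as exc:
            raise ParseError(f"cannot parse template spec {path}: {exc}") from exc
        if not isinstance(data, dict):
            raise ParseError(f"template spec {path} is not a mapping")
        return cls.from_dict(data)


@dataclass
class TemplateElement:
    path: SelectionPath
    cardinality: Cardinality
    is_inherited: bool = False
    via_association: Optional[str] = None


@dataclass
class TemplateCluster:
    class_iri: str
    class_name: str
    elements: list[TemplateElement] = field(default_factory=list)


@dataclass
class Template:
    name: str
    clusters: list[TemplateCluster] = field(default_factory=list)

    @property
    def n_elements(self) -> int:
        return sum(len(c.elements) for c in self.clusters)

    @property
    def n_attribute_elements(self) -> int:
        return sum(1 for c in self.clusters for e in c.elements
                   if e.via_association is None)

    @property
    def n_association_elements(self) -> int:
        return sum(1 for c in self.clusters for e in c.elements
                   if e.via_association is not None)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "clusters": [
                {"class": c.class_iri, "className": c.class_name,
                 "elements": [
                     {"path": e.path.render(),
                      "cardinality": e.cardinality.render(),
                      "isInherited": e.is_inherited,
                      **({"viaAssociation": e.via_association}
                         if e.via_association else {})}
                     for e in c.elements]}
                for c in self.clusters],
        }


# ---------------------------------------------------------------------------
# validation


def _check_attribute_path(normalized: NormalizedGraph, path: SelectionPath,
                          rendered: str) -> list[Violation]:
    """Check one Class.attr[.TYPE.component...] path against the model."""
    model = normalized.base
    try:
        cdef = model.resolve_class(path.class_name)
    except (NotFoundError, AmbiguousNameError) as exc:
        return [Violation(rendered, "unknown-class", str(exc))]
    flat = normalized.flattened[cdef.iri]
    try:
        attr = flat.attribute(path.attribute_name)
    except NotFoundError:
        return [Violation(
            rendered, "unknown-attribute",
            f"{path.attribute_name!r} is not a flattened attribute of {cdef.name}")]

    violations: list[Violation] = []
    rest = path.segments[2:]
    cur_type = None
    try:
        cur_type = model.resolve_datatype(attr.datatype)
    except (NotFoundError, AmbiguousNameError):
        if rest:
            return [Violation(rendered, "unresolved-datatype",
                              f"data type <{attr.datatype}> of "
                              f"{cdef.name}.{attr.name} is not defined")]
        return []
    for kind, name in rest:
        if kind is SegmentKind.DATATYPE:
            if cur_type is None or name != cur_type.name:
                violations.append(Violation(
                    rendered, "datatype-mismatch",
                    f"expected type {cur_type.name if cur_type else '?'}, "
                    f"path says {name}"))
                break
        else:  # COMPONENT
            if cur_type is None or name not in cur_type.component_names():
                violations.append(Violation(
                    rendered, "invalid-component",
                    f"{name!r} is not a component of "
                    f"{cur_type.name if cur_type else '?'}"))
                break
            comp = cur_type.component(name)
            try:
                cur_type = model.resolve_datatype(comp.datatype)
            except (NotFoundError, AmbiguousNameError):
                cur_type = None
    return violations


def validate_spec(normalized: NormalizedGraph, spec: TemplateSpec) -> list[Violation]:
    """Every rule violation in the spec; empty iff building would succeed."""
    model = normalized.base
    violations: list[Violation] = []
    for path in spec.selections:
        violations.extend(_check_attribute_path(normalized, path, path.render()))
    for sel in spec.association_selections:
        rendered = sel.render()
        try:
            source = model.resolve_class(sel.source_class)
        except (NotFoundError, AmbiguousNameError) as exc:
            violations.append(Violation(rendered, "unknown-class", str(exc)))
            continue
        try:
            target = model.resolve_class(sel.path.class_name)
        except (NotFoundError, AmbiguousNameError) as exc:
            violations.append(Violation(rendered, "unknown-class", str(exc)))
            continue
        flat = normalized.flattened[source.iri]
        matches = [a for a in flat.associations
                   if a.role_name == sel.role_name and a.target_class == target.iri]
        if not matches:
            violations.append(Violation(
                rendered, "unknown-association",
                f"{source.name} has no flattened association "
                f"{sel.role_name!r} targeting {target.name}"))
            continue
        violations.extend(_check_attribute_path(normalized, sel.path, rendered))
    return violations


# ---------------------------------------------------------------------------
# building


def build_template(normalized: NormalizedGraph, spec: TemplateSpec) -> Template:
    """Build the template; raises on empty or invalid specs.

    Clusters appear in order of first selection of their class; association-
    mediated elements join (or create) the cluster of the *target* class,
    carrying the role in ``via_association``.
    """
    if not spec.selections and not spec.association_selections:
        raise EmptySelectionError(f"template spec {spec.template_name!r} selects nothing")
    violations = validate_spec(normalized, spec)
    if violations:
        raise ValidationError(violations)

    model = normalized.base
    template = Template(spec.template_name)
    clusters: dict[str, TemplateCluster] = {}

    def cluster_for(class_iri: str) -> TemplateCluster:
        if class_iri not in clusters:
            c = TemplateCluster(class_iri, model.classes[class_iri].name)
            clusters[class_iri] = c
            template.clusters.append(c)
        return clusters[class_iri]

    def element(path: SelectionPath, role: Optional[str]) -> None:
        cdef = model.resolve_class(path.class_name)
        attr = normalized.flattened[cdef.iri].attribute(path.attribute_name)
        cluster_for(cdef.iri).elements.append(
            TemplateElement(path, attr.cardinality, attr.is_inherited, role))

    for path in spec.selections:
        element(path, None)
    for sel in spec.association_selections:
        element(sel.path, sel.role_name)
    return template
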