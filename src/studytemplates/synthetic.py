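"""Synthetic domain models and data-type ontologies with known ground truth.

Two sources of test models:

* :func:`generate` builds seeded random class hierarchies (chains, trees and
  diamonds, controlled by ``multi_parent_prob``) with local attributes and
  associations, plus a nested complex-type ontology.  The returned ground
  truth — each class's expected *flattened* attribute/association sets — is
  computed from the generator's own edge bookkeeping by plain recursive
  traversal, independent of the normalization module, so it can arbitrate
  between the pipeline and a test oracle.
* :func:`bridg_like_fixture` is a small hand-written model reproducing the
  named examples of the real BRIDG/ISO 21090 setting: Person under Biologic
  Entity with inherited ``name``/``birthDate``; ``educationLevelCode`` and
  ``maritalStatusCode`` typed ``CD``; the ``CD`` coded-concept type with its
  ``code``/``displayName``/``codeSystem``/... components; the five
  measurement classes; and Performed Observation's "be reported by"
  association to Subject, Healthcare Provider, Laboratory and Device.

All output is deterministic Turtle text: the same config and seed produce
byte-identical files.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from typing import Optional

SYNTH_MODEL = "http://example.org/synth/model#"
SYNTH_TYPEREF = "http://example.org/synth/typeref#"
SYNTH_DT = "http://example.org/synth/datatypes#"

_DOMAIN_HEADER = """\
@prefix : <{model}> .
@prefix tref: <{typeref}> .
@prefix stv: <http://studytemplates.org/vocab#> .
@prefix owl: <http://www.w3.org/2002/07/owl#> .
@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .
@prefix xsd: <http://www.w3.org/2001/XMLSchema#> .

"""

_DT_HEADER = """\
@prefix dt: <{dt}> .
@prefix stv: <http://studytemplates.org/vocab#> .
@prefix owl: <http://www.w3.org/2002/07/owl#> .
@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .

"""

_CARDINALITIES = [(0, 1), (1, 1), (0, "*"), (1, "*")]


@dataclass
class SynthConfig:
    """Parameters of one synthetic model; the seed fully determines output."""

    n_classes: int = 20
    max_depth: int = 4
    multi_parent_prob: float = 0.2
    attrs_per_class: tuple[int, int] = (1, 3)
    assocs_per_class: tuple[int, int] = (0, 2)
    datatype_nesting: int = 2
    n_primitives: int = 3
    types_per_level: int = 2
    components_per_type: tuple[int, int] = (2, 4)
    seed: int = 0
    dialect: str = "annotation"  # or "restriction"
    inject_collision: bool = False

    def validate(self) -> None:
        if self.n_classes < 0 or self.max_depth < 0 or self.datatype_nesting < 0:
            raise ValueError("counts must be non-negative")
        if not 0.0 <= self.multi_parent_prob <= 1.0:
            raise ValueError("multi_parent_prob must be a probability")
        for lo, hi in (self.attrs_per_class, self.assocs_per_class,
                       self.components_per_type):
            if lo < 0 or hi < lo:
                raise ValueError("ranges must be 0 <= lo <= hi")
        if self.n_primitives < 1 or self.types_per_level < 1:
            raise ValueError("need at least one primitive and one type per level")
        if self.dialect not in ("annotation", "restriction"):
            raise ValueError(f"unknown dialect {self.dialect!r}")
        if self.inject_collision and self.attrs_per_class[0] < 1:
            raise ValueError("collision injection needs at least one attribute per class")


@dataclass
class SyntheticModel:
    """Generator output: two Turtle documents plus constructed ground truth."""

    domain_ttl: str
    datatype_ttl: str
    ground_truth: dict[str, dict]
    config: Optional[SynthConfig] = None

    def ground_truth_json(self) -> str:
        return json.dumps(self.ground_truth, indent=2, sort_keys=True)


def generate(config: SynthConfig) -> SyntheticModel:
    """Generate a synthetic domain model + data-type ontology."""
    config.validate()
    rng = random.Random(config.seed)

    # --- data types -------------------------------------------------------
    primitives = [f"P{i}" for i in range(config.n_primitives)]
    levels: list[list[str]] = [primitives]
    type_components: dict[str, list[tuple[str, str, tuple]]] = {p: [] for p in primitives}
    for level in range(1, config.datatype_nesting + 1):
        names = [f"T{level}_{i}" for i in range(config.types_per_level)]
        for t in names:
            k = rng.randint(*config.components_per_type)
            comps = []
            for j in range(k):
                ctype = rng.choice(levels[level - 1])
                comps.append((f"{t}_c{j}", ctype, rng.choice(_CARDINALITIES)))
            type_components[t] = comps
        levels.append(names)
    all_types = [t for lv in levels for t in lv]

    dt_lines = [_DT_HEADER.format(dt=SYNTH_DT)]
    for t in all_types:
        dt_lines.append(f'dt:{t} a owl:Class ; rdfs:label "{t}"')
        for idx, (cname, ctype, (lo, hi)) in enumerate(type_components[t]):
            dt_lines.append(
                f' ;\n  stv:component [ stv:name "{cname}" ; stv:datatype dt:{ctype} ;'
                f" stv:index {idx} ; stv:minCardinality {lo} ;"
                f" stv:maxCardinality {_card_literal(hi)} ]")
        dt_lines.append(" .\n")
    datatype_ttl = "".join(dt_lines)

    # --- class hierarchy --------------------------------------------------
    class_names = [f"C{i:03d}" for i in range(config.n_classes)]
    depth: dict[str, int] = {}
    parents: dict[str, list[str]] = {}
    for i, name in enumerate(class_names):
        if i == 0 or rng.random() < 0.15:
            parents[name] = []
            depth[name] = 0
            continue
        eligible = [c for c in class_names[:i] if depth[c] < config.max_depth]
        if not eligible:
            parents[name] = []
            depth[name] = 0
            continue
        p1 = rng.choice(eligible)
        ps = [p1]
        if rng.random() < config.multi_parent_prob:
            extra = [c for c in eligible if c != p1]
            if extra:
                ps.append(rng.choice(extra))
        parents[name] = sorted(ps)
        depth[name] = max(depth[p] for p in ps) + 1

    # --- local declarations ----------------------------------------------
    attrs: dict[str, list[tuple[str, str, tuple]]] = {}
    assocs: dict[str, list[tuple[str, str, tuple]]] = {}
    for name in class_names:
        n_attr = rng.randint(*config.attrs_per_class)
        attrs[name] = [(f"attr_{name}_{j}", rng.choice(all_types),
                        rng.choice(_CARDINALITIES)) for j in range(n_attr)]
        n_assoc = rng.randint(*config.assocs_per_class)
        assocs[name] = [(f"role_{name}_{j}", rng.choice(class_names),
                         rng.choice(_CARDINALITIES)) for j in range(n_assoc)]

    if config.inject_collision:
        child = next((c for c in class_names if parents[c]), None)
        if child is not None:
            ancestor = parents[child][0]
            # same name, distinct owner: a deliberate collision
            attrs[child].append((attrs[ancestor][0][0],
                                 rng.choice(all_types), (0, 1)))

    domain_ttl = _emit_domain(class_names, parents, attrs, assocs, config.dialect)

    # --- ground truth by construction (recursive walk over the edge list) -
    def closure(name: str, seen: frozenset = frozenset()) -> list[str]:
        out: list[str] = []
        for p in parents[name]:
            if p in seen:
                continue
            for a in [p] + closure(p, seen | {p}):
                if a not in out:
                    out.append(a)
        return out

    truth: dict[str, dict] = {}
    for name in class_names:
        anc = closure(name)
        flat_attrs, flat_assocs = [], []
        seen_a: set[tuple[str, str]] = set()
        seen_s: set[tuple[str, str, str]] = set()
        for owner in [name] + anc:
            for aname, atype, _ in attrs[owner]:
                if (owner, aname) not in seen_a:
                    seen_a.add((owner, aname))
                    flat_attrs.append({"owner": SYNTH_MODEL + owner, "name": aname,
                                       "inherited": owner != name})
            for role, target, _ in assocs[owner]:
                key = (owner, role, target)
                if key not in seen_s:
                    seen_s.add(key)
                    flat_assocs.append({"owner": SYNTH_MODEL + owner, "role": role,
                                        "target": SYNTH_MODEL + target,
                                        "inherited": owner != name})
        truth[SYNTH_MODEL + name] = {
            "parents": [SYNTH_MODEL + p for p in parents[name]],
            "ancestors": [SYNTH_MODEL + a for a in anc],
            "attributes": flat_attrs,
            "associations": flat_assocs,
        }

    return SyntheticModel(domain_ttl, datatype_ttl, truth, config)


def _card_literal(hi) -> str:
    return '"*"' if hi == "*" else str(hi)


def _emit_domain(class_names, parents, attrs, assocs, dialect: str) -> str:
    lines = [_DOMAIN_HEADER.format(model=SYNTH_MODEL, typeref=SYNTH_TYPEREF)]
    for name in class_names:
        lines.append(f':{name} a owl:Class ; rdfs:label "{name}"')
        for p in parents[name]:
            lines.append(f" ;\n  rdfs:subClassOf :{p}")
        if dialect == "annotation":
            for idx, (aname, atype, (lo, hi)) in enumerate(attrs[name]):
                lines.append(
                    f' ;\n  stv:attribute [ a stv:Attribute ; stv:name "{aname}" ;'
                    f" stv:datatype tref:{atype} ; stv:index {idx} ;"
                    f" stv:minCardinality {lo} ; stv:maxCardinality {_card_literal(hi)} ]")
            for idx, (role, target, (lo, hi)) in enumerate(assocs[name]):
                lines.append(
                    f' ;\n  stv:association [ a stv:Association ; stv:roleName "{role}" ;'
                    f" stv:targetClass :{target} ; stv:index {idx} ;"
                    f" stv:minCardinality {lo} ; stv:maxCardinality {_card_literal(hi)} ]")
        else:  # restriction dialect
            for aname, atype, (lo, hi) in attrs[name]:
                lines.append(
                    f" ;\n  rdfs:subClassOf [ a owl:Restriction ;"
                    f" owl:onProperty :{aname} ; owl:allValuesFrom tref:{atype} ;"
                    f"{_owl_card(lo, hi)} ]")
            for role, target, (lo, hi) in assocs[name]:
                lines.append(
                    f" ;\n  rdfs:subClassOf [ a owl:Restriction ;"
                    f" owl:onProperty :{role} ; owl:allValuesFrom :{target} ;"
                    f"{_owl_card(lo, hi)} ]")
        lines.append(" .\n")
    return "".join(lines)


def _owl_card(lo, hi) -> str:
    s = f" owl:minCardinality {lo} ;"
    if hi != "*":
        s += f" owl:maxCardinality {hi} ;"
    return s.rstrip(";")


def cyclic_domain() -> str:
    """A tiny domain model whose subclass graph contains a cycle (A <-> B)."""
    return _DOMAIN_HEADER.format(model=SYNTH_MODEL, typeref=SYNTH_TYPEREF) + (
        ':A a owl:Class ; rdfs:label "A" ; rdfs:subClassOf :B ;\n'
        '  stv:attribute [ a stv:Attribute ; stv:name "a1" ; stv:datatype tref:P0 ;'
        " stv:minCardinality 0 ; stv:maxCardinality 1 ] .\n"
        ':B a owl:Class ; rdfs:label "B" ; rdfs:subClassOf :A .\n')


def empty_domain() -> str:
    """A domain file with no class declarations."""
    return _DOMAIN_HEADER.format(model=SYNTH_MODEL, typeref=SYNTH_TYPEREF)


# ---------------------------------------------------------------------------
# hand-written BRIDG/ISO 21090-style fixture


BRIDG_CLASSES = "http://www.bridgmodel.org/owl/classes#"
BRIDG_TYPEREF = "http://www.bridgmodel.org/iso-datatypes#"
HL7_DT = "http://www.hl7.org/owl/iso-datatypes#"

#: The coded-concept components named for the CD data type, in display order.
CD_COMPONENTS = ("code", "displayName", "codeSystem", "codeSystemName",
                 "codeSystemVersion", "valueSet", "valueSetVersion")

_FIXTURE_DATATYPES = (
    _DT_HEADER.format(dt=HL7_DT)
    + "".join(f'dt:{p} a owl:Class ; rdfs:label "{p}" .\n'
              for p in ("ST", "CS", "BL", "TS", "INT", "ANY"))
    + 'dt:CD a owl:Class ; rdfs:label "CD"'
    + "".join(
        f' ;\n  stv:component [ stv:name "{c}" ; '
        f'stv:datatype dt:{"CS" if c == "code" else "ST"} ; stv:index {i} ;'
        f" stv:minCardinality 0 ; stv:maxCardinality 1 ]"
        for i, c in enumerate(CD_COMPONENTS))
    + " .\n"
    + 'dt:II a owl:Class ; rdfs:label "II" ;\n'
    + '  stv:component [ stv:name "root" ; stv:datatype dt:ST ; stv:index 0 ;'
      " stv:minCardinality 1 ; stv:maxCardinality 1 ] ;\n"
    + '  stv:component [ stv:name "extension" ; stv:datatype dt:ST ; stv:index 1 ;'
      " stv:minCardinality 0 ; stv:maxCardinality 1 ] .\n"
)

_FIXTURE_DOMAIN = """\
@prefix : <http://www.bridgmodel.org/owl/classes#> .
@prefix tref: <http://www.bridgmodel.org/iso-datatypes#> .
@prefix stv: <http://studytemplates.org/vocab#> .
@prefix owl: <http://www.w3.org/2002/07/owl#> .
@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .

:BiologicEntity a owl:Class ; rdfs:label "Biologic Entity" ;
  stv:attribute [ a stv:Attribute ; stv:name "name" ; stv:datatype tref:ST ;
    stv:index 0 ; stv:minCardinality 0 ; stv:maxCardinality "*" ] ;
  stv:attribute [ a stv:Attribute ; stv:name "birthDate" ; stv:datatype tref:TS ;
    stv:index 1 ; stv:minCardinality 0 ; stv:maxCardinality 1 ] .

# Person declares its two coded attributes in the property-restriction
# dialect; everything else uses the annotation-instance dialect.
:Person a owl:Class ; rdfs:label "Person" ;
  rdfs:subClassOf :BiologicEntity ;
  rdfs:subClassOf [ a owl:Restriction ; owl:onProperty :educationLevelCode ;
    owl:allValuesFrom tref:CD ; owl:minCardinality 0 ; owl:maxCardinality 1 ] ;
  rdfs:subClassOf [ a owl:Restriction ; owl:onProperty :maritalStatusCode ;
    owl:allValuesFrom tref:CD ; owl:minCardinality 0 ; owl:maxCardinality 1 ] .
:educationLevelCode a owl:DatatypeProperty .
:maritalStatusCode a owl:DatatypeProperty .

:Subject a owl:Class ; rdfs:label "Subject" ;
  stv:attribute [ a stv:Attribute ; stv:name "identifier" ; stv:datatype tref:II ;
    stv:index 0 ; stv:minCardinality 0 ; stv:maxCardinality "*" ] ;
  stv:attribute [ a stv:Attribute ; stv:name "statusCode" ; stv:datatype tref:CD ;
    stv:index 1 ; stv:minCardinality 0 ; stv:maxCardinality 1 ] .

:HealthcareProvider a owl:Class ; rdfs:label "Healthcare Provider" ;
  stv:attribute [ a stv:Attribute ; stv:name "identifier" ; stv:datatype tref:II ;
    stv:index 0 ; stv:minCardinality 0 ; stv:maxCardinality "*" ] .

:Laboratory a owl:Class ; rdfs:label "Laboratory" ;
  stv:attribute [ a stv:Attribute ; stv:name "identifier" ; stv:datatype tref:II ;
    stv:index 0 ; stv:minCardinality 0 ; stv:maxCardinality "*" ] .

:Device a owl:Class ; rdfs:label "Device" ;
  stv:attribute [ a stv:Attribute ; stv:name "identifier" ; stv:datatype tref:II ;
    stv:index 0 ; stv:minCardinality 0 ; stv:maxCardinality "*" ] .

:Observation a owl:Class ; rdfs:label "Observation" ;
  stv:attribute [ a stv:Attribute ; stv:name "statusCode" ; stv:datatype tref:CD ;
    stv:index 0 ; stv:minCardinality 0 ; stv:maxCardinality 1 ] .

:DefinedObservation a owl:Class ; rdfs:label "Defined Observation" ;
  rdfs:subClassOf :Observation ;
  stv:attribute [ a stv:Attribute ; stv:name "nameCode" ; stv:datatype tref:CD ;
    stv:index 0 ; stv:minCardinality 1 ; stv:maxCardinality 1 ] ;
  stv:attribute [ a stv:Attribute ; stv:name "categoryCode" ; stv:datatype tref:CD ;
    stv:index 1 ; stv:minCardinality 0 ; stv:maxCardinality "*" ] ;
  stv:attribute [ a stv:Attribute ; stv:name "safetyIndicator" ; stv:datatype tref:BL ;
    stv:index 2 ; stv:minCardinality 0 ; stv:maxCardinality 1 ] ;
  stv:association [ a stv:Association ; stv:roleName "produces" ;
    stv:targetClass :DefinedObservationResult ; stv:index 0 ;
    stv:minCardinality 0 ; stv:maxCardinality "*" ] .

:PerformedObservation a owl:Class ; rdfs:label "Performed Observation" ;
  rdfs:subClassOf :Observation ;
  stv:attribute [ a stv:Attribute ; stv:name "bodyPositionCode" ; stv:datatype tref:CD ;
    stv:index 0 ; stv:minCardinality 0 ; stv:maxCardinality 1 ] ;
  stv:attribute [ a stv:Attribute ; stv:name "methodCode" ; stv:datatype tref:CD ;
    stv:index 1 ; stv:minCardinality 0 ; stv:maxCardinality "*" ] ;
  stv:attribute [ a stv:Attribute ; stv:name "comment" ; stv:datatype tref:ST ;
    stv:index 2 ; stv:minCardinality 0 ; stv:maxCardinality 1 ] ;
  stv:association [ a stv:Association ; stv:roleName "be reported by" ;
    stv:targetClass :Subject ; stv:index 0 ;
    stv:minCardinality 0 ; stv:maxCardinality "*" ] ;
  stv:association [ a stv:Association ; stv:roleName "be reported by" ;
    stv:targetClass :HealthcareProvider ; stv:index 1 ;
    stv:minCardinality 0 ; stv:maxCardinality "*" ] ;
  stv:association [ a stv:Association ; stv:roleName "be reported by" ;
    stv:targetClass :Laboratory ; stv:index 2 ;
    stv:minCardinality 0 ; stv:maxCardinality "*" ] ;
  stv:association [ a stv:Association ; stv:roleName "be reported by" ;
    stv:targetClass :Device ; stv:index 3 ;
    stv:minCardinality 0 ; stv:maxCardinality "*" ] ;
  stv:association [ a stv:Association ; stv:roleName "instantiates" ;
    stv:targetClass :DefinedObservation ; stv:index 4 ;
    stv:minCardinality 0 ; stv:maxCardinality 1 ] ;
  stv:association [ a stv:Association ; stv:roleName "produces" ;
    stv:targetClass :PerformedObservationResult ; stv:index 5 ;
    stv:minCardinality 0 ; stv:maxCardinality "*" ] .

:ObservationResult a owl:Class ; rdfs:label "Observation Result" ;
  stv:attribute [ a stv:Attribute ; stv:name "reportedDate" ; stv:datatype tref:TS ;
    stv:index 0 ; stv:minCardinality 0 ; stv:maxCardinality 1 ] .

:DefinedObservationResult a owl:Class ; rdfs:label "Defined Observation Result" ;
  rdfs:subClassOf :ObservationResult ;
  stv:attribute [ a stv:Attribute ; stv:name "typeCode" ; stv:datatype tref:CD ;
    stv:index 0 ; stv:minCardinality 0 ; stv:maxCardinality 1 ] ;
  stv:attribute [ a stv:Attribute ; stv:name "unitCode" ; stv:datatype tref:CD ;
    stv:index 1 ; stv:minCardinality 0 ; stv:maxCardinality 1 ] ;
  stv:attribute [ a stv:Attribute ; stv:name "referenceFlag" ; stv:datatype tref:BL ;
    stv:index 2 ; stv:minCardinality 0 ; stv:maxCardinality 1 ] ;
  stv:association [ a stv:Association ; stv:roleName "has reference" ;
    stv:targetClass :ReferenceResult ; stv:index 0 ;
    stv:minCardinality 0 ; stv:maxCardinality "*" ] .

:PerformedObservationResult a owl:Class ; rdfs:label "Performed Observation Result" ;
  rdfs:subClassOf :ObservationResult ;
  stv:attribute [ a stv:Attribute ; stv:name "value" ; stv:datatype tref:ANY ;
    stv:index 0 ; stv:minCardinality 0 ; stv:maxCardinality 1 ] ;
  stv:attribute [ a stv:Attribute ; stv:name "valueCode" ; stv:datatype tref:CD ;
    stv:index 1 ; stv:minCardinality 0 ; stv:maxCardinality 1 ] ;
  stv:attribute [ a stv:Attribute ; stv:name "valueUnit" ; stv:datatype tref:ST ;
    stv:index 2 ; stv:minCardinality 0 ; stv:maxCardinality 1 ] ;
  stv:association [ a stv:Association ; stv:roleName "evaluated against" ;
    stv:targetClass :ReferenceResult ; stv:index 0 ;
    stv:minCardinality 0 ; stv:maxCardinality "*" ] .

:ReferenceResult a owl:Class ; rdfs:label "Reference Result" ;
  rdfs:subClassOf :ObservationResult ;
  stv:attribute [ a stv:Attribute ; stv:name "lowValue" ; stv:datatype tref:ANY ;
    stv:index 0 ; stv:minCardinality 0 ; stv:maxCardinality 1 ] ;
  stv:attribute [ a stv:Attribute ; stv:name "highValue" ; stv:datatype tref:ANY ;
    stv:index 1 ; stv:minCardinality 0 ; stv:maxCardinality 1 ] ;
  stv:attribute [ a stv:Attribute ; stv:name "rangeText" ; stv:datatype tref:ST ;
    stv:index 2 ; stv:minCardinality 0 ; stv:maxCardinality 1 ] .

:AdverseEventSeriousness a owl:Class ; rdfs:label "AdverseEventSeriousness" ;
  stv:attribute [ a stv:Attribute ; stv:name "seriousnessCode" ; stv:datatype tref:CD ;
    stv:index 0 ; stv:minCardinality 1 ; stv:maxCardinality 1 ] ;
  stv:attribute [ a stv:Attribute ; stv:name "seriousnessText" ; stv:datatype tref:ST ;
    stv:index 1 ; stv:minCardinality 0 ; stv:maxCardinality 1 ] .
"""


def bridg_like_fixture() -> tuple[str, str]:
    """The hand-written domain + data-type fixture (Turtle texts)."""
    return _FIXTURE_DOMAIN, _FIXTURE_DATATYPES


def measurement_use_case_spec() -> dict:
    """The "Measurement on a Subject" template spec: 5 classes, 20 attribute
    paths (one inherited per class), 5 association-mediated selections whose
    targets stay within the 5 selected classes."""
    return {
        "name": "Measurement on a Subject",
        "selections": [
            "Defined Observation.statusCode.CD",
            "Defined Observation.nameCode.CD.displayName.ST",
            "Defined Observation.categoryCode.CD",
            "Defined Observation.safetyIndicator.BL",
            "Performed Observation.statusCode.CD",
            "Performed Observation.bodyPositionCode.CD.code.CS",
            "Performed Observation.methodCode.CD",
            "Performed Observation.comment.ST",
            "Defined Observation Result.reportedDate.TS",
            "Defined Observation Result.typeCode.CD",
            "Defined Observation Result.unitCode.CD.code.CS",
            "Defined Observation Result.referenceFlag.BL",
            "Performed Observation Result.reportedDate.TS",
            "Performed Observation Result.value.ANY",
            "Performed Observation Result.valueCode.CD.displayName.ST",
            "Performed Observation Result.valueUnit.ST",
            "Reference Result.reportedDate.TS",
            "Reference Result.lowValue.ANY",
            "Reference Result.highValue.ANY",
            "Reference Result.rangeText.ST",
        ],
        "associations": [
            {"source": "Performed Observation", "role": "instantiates",
             "path": "Defined Observation.nameCode.CD"},
            {"source": "Performed Observation", "role": "produces",
             "path": "Performed Observation Result.value.ANY"},
            {"source": "Defined Observation", "role": "produces",
             "path": "Defined Observation Result.typeCode.CD"},
            {"source": "Performed Observation Result", "role": "evaluated against",
             "path": "Reference Result.lowValue.ANY"},
            {"source": "Defined Observation Result", "role": "has reference",
             "path": "Reference Result.rangeText.ST"},
        ],
    }
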