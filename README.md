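# studytemplates

Tools for generating **domain-specific clinical-study metadata templates**
from a UML-derived domain analysis model (a BRIDG-style class hierarchy in
OWL/RDF) integrated with a complex data-type ontology (ISO 21090 / HL7 V3
style data types in OWL).

Standards developers building clinical-research information models work
from a large shared domain model: hundreds of classes in an
`rdfs:subClassOf` hierarchy, each with attributes typed by complex data
types (a coded concept `CD` decomposes into `code`, `displayName`,
`codeSystem`, …, each with a type of its own) and named associations to
other classes ("be reported by", "produces", …).  A *template* for a
concept area — say, a measurement on a study subject — is a curated
selection of attributes (and data-type components, and attributes of
associated classes) across several of those classes.  `studytemplates`
makes that workflow computable:

1. **Load & unify** (`model_io`): parse both ontologies with rdflib, merge
   them under a declarative namespace-rewrite table so the domain model's
   data-type references resolve against the type ontology, and index
   classes, attributes, associations and data types.  Two attribute
   declaration dialects (OWL property restrictions and annotation
   instances) are normalized to one structured view.
2. **Materialize inheritance** (`normalization`): copy every ancestor's
   attributes and associations onto each class — the flattened form every
   downstream query relies on.  Each flattened entry is emitted as RDF: a
   SPIN-style metadata node (`spl:Attribute` with name, value type,
   `spl:minCount`/`spl:maxCount`) attached via `bridg:attributeProperty` /
   `bridg:associationProperty`, with `bridg:isInherited` flagging
   provenance.
3. **Browse & query** (`query`, `datatypes`): class tree, per-class
   Children/Attributes/Associations, recursive data-type component
   expansion, and generated SPARQL 1.1 queries that return exactly what the
   in-memory API returns when run over the emitted Turtle.
4. **Build templates** (`template_builder`): validate dotted selection
   paths like `Person.maritalStatusCode.CD.displayName.ST` (class,
   attribute, then alternating data-type/component names) against the
   flattened model, including inherited attributes and association-mediated
   selections.
5. **Export** (`cimi_export`, `mindmap_export`): serialize a template as
   CIMI reference-model RDF — the template is an `ENTRY`, each class a
   `CLUSTER`, each selected path an `ELEMENT`, linked by
   `cimi:CLUSTER.item` — in deterministic Turtle (and parse it back), or as
   a Freemind `.mm` mind map.
6. **Test without real artifacts** (`synthetic`): seeded random class
   hierarchies with constructed ground-truth closures, plus a hand-written
   example model reproducing the classic Person / Biologic Entity /
   coded-concept setting.

## Worked example

Write the bundled example model and build the "Measurement on a Subject"
template from the shell:

```bash
studytemplates fixture --out model
studytemplates normalize --domain model/domain.ttl --datatypes model/datatypes.ttl --out build
```

```
wrote build/normalized.ttl
classes: 14  flattened attributes: 35  flattened associations: 9
  ...
  Performed Observation: 4 attributes, 6 associations
  Person: 4 attributes, 0 associations
  ...
```

`Person` reports 4 flattened attributes: its two local coded attributes
(`educationLevelCode`, `maritalStatusCode`, both typed `CD`) plus `name`
and `birthDate` inherited from `Biologic Entity`.  `Performed Observation`
carries 6 flattened associations, four of which are the "be reported by"
links to Subject, Healthcare Provider, Laboratory and Device.

```bash
studytemplates template --domain model/domain.ttl --datatypes model/datatypes.ttl \
    --spec model/measurement_spec.yaml --out build
```

```
wrote build/Measurement_on_a_Subject.ttl
wrote build/Measurement_on_a_Subject.mm
clusters: 5  elements: 25 (20 attribute, 5 association-mediated)
```

The spec selects 20 attribute paths across the five measurement classes
(Defined/Performed Observation, their Results, Reference Result) and 5
attributes reached through associations; the exported Turtle contains one
`cimi:ENTRY`, 5 `cimi:CLUSTER`s and 25 `cimi:ELEMENT`s, each element
carrying its full path and cardinality on a `spl:Attribute` metadata node:

```turtle
<...template/Measurement_on_a_Subject> a cimi:ENTRY ;
    rdfs:label "Measurement on a Subject" ;
    cimi:CLUSTER.item <...cluster/0-Defined_Observation> , ... .
```

The same template as a mind map (root → class → selection path):

```xml
<map version="1.0.1">
  <node TEXT="Measurement on a Subject">
    <node TEXT="Defined Observation">
      <node TEXT="Defined Observation.statusCode.CD" />
      ...
```

The same pipeline from Python:

```python
import studytemplates as st

model = st.load_model(domain_path, datatype_path)      # or load_model_from_texts
normalized = st.normalize(model)
st.is_inherited(normalized, "Person", "name")          # True
spec = st.TemplateSpec.from_dict(st.measurement_use_case_spec())
template = st.build_template(normalized, spec)
turtle = st.to_cimi(template).serialize()
assert st.from_cimi(turtle) == template                # lossless round trip
```

A read-only HTTP layer (`studytemplates serve`) exposes `/classes`,
`/classes/{name}` and `/templates/{name}` with Turtle/JSON content
negotiation.

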