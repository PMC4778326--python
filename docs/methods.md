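# Methods

## The model and what the pipeline computes

The input is a pair of OWL/RDF ontologies.  The *domain model* is a class
hierarchy under `rdfs:subClassOf` in which each class declares local
attributes (name, data-type reference, `min..max` cardinality) and local
associations (role name, target class, cardinality).  The *data-type
ontology* defines the attribute types: a type is primitive exactly when it
has no components; a complex type (e.g. the coded concept `CD`) lists
ordered, named components, each typed by another (possibly complex) type.
The semantics follow the object-oriented source of such models: a class
inherits every attribute and association asserted on any of its ancestors.

The central computation is **inheritance materialization**: for each class
`C`, the flattened declaration set

> flat(C) = ⋃ { local(A) : A ∈ ancestors-or-self(C) }

with each entry flagged `isInherited := (owner ≠ C)`.  Ancestor traversal
is breadth-first from `C`, ties within a level broken lexicographically by
IRI and first occurrence kept, which makes the order deterministic on any
DAG.  Multiple inheritance is a union over all ancestor paths: a diamond
contributes each declaration once, deduplicated by `(owner, name)` for
attributes and `(owner, role, target)` for associations.

The flattened model is emitted as RDF so that per-class retrieval needs no
hierarchy traversal: each entry becomes a metadata node typed
`spl:Attribute` (the SPIN standard-library template), carrying
`spl:predicate` (the name), `spl:valueType` (type IRI, or the target class
for associations via a dedicated predicate), `spl:minCount`/`spl:maxCount`,
`bridg:isInherited` and `bridg:ownerClass`, attached to the class through
`bridg:attributeProperty` / `bridg:associationProperty`.  An unbounded
upper cardinality is expressed by *omitting* `spl:maxCount`; the generated
SPARQL queries read it back through an `OPTIONAL` clause.

## Input dialects and namespace unification

No canonical RDF shape exists for attribute declarations in UML-derived
OWL exports, so the loader accepts two dialects and normalizes both:

* property restrictions (`owl:onProperty` + `owl:allValuesFrom` with
  `owl:minCardinality`/`owl:maxCardinality`), where a filler that is itself
  a domain class makes the restriction an association;
* annotation instances in the package's `stv:` vocabulary
  (`stv:attribute`/`stv:association` nodes with explicit name, type/target,
  cardinality and an ordering index).

Annotation-style declarations keep their declared index order; restriction
nodes carry no usable order in RDF, so they are appended sorted by property
name — this is what makes two loads of the same file produce identical
indices.  Domain and type ontologies historically reference the same data
types under different IRI bases; unification is a declarative prefix-rewrite
table (part of `NamespacePolicy`, user-extendable via a YAML/JSON config)
applied to every IRI during the merge.  References that still fail to
resolve are recorded on the model and logged, and raise only under
`strict=True`.  A declaration with no cardinality at all defaults to `0..1`
with a logged warning; an explicit minimum with no maximum is read as an
open upper bound, matching OWL restriction semantics.

## Degenerate inputs and tie-breaks

* A cycle in `rdfs:subClassOf` raises `CycleError` naming the cycle
  (detected with networkx before flattening).
* Two *distinct* owners contributing the same attribute name to one
  flattened class raise `NameCollisionError` by default, because the source
  models define no override/redefinition semantics; `on_collision="keep"`
  retains both entries qualified by owner.
* Class display names may contain spaces while IRIs cannot; the canonical
  name is the `rdfs:label` when present, else the IRI local name, and
  bare-name lookup accepts either alias, raising `AmbiguousNameError` when
  a name maps to several IRIs.
* Serialization order of metadata nodes is `(isInherited, name, owner)`;
  emitted blank nodes and template node IRIs are skolemized from stable
  strings (class/owner/name, or template-name/path), so all Turtle output
  is reproducible byte for byte.

## Selection paths and templates

A selection path alternates names and type names —
`Class.attribute.TYPE[.component.TYPE …]` — and its grammar is
position-determined, so parsing needs no model; validation against the
model checks class existence, membership of the attribute in the *flattened*
class (inherited attributes are first-class selectable), agreement of every
type name, and membership of every component in the preceding type.  Paths
may stop at a complex type without descending to a primitive leaf; the
interposed type names make paths verbose but unambiguous.  Component
expansion (`expand_type`) recurses into complex component types with a
default depth limit of 5 expansion levels — deep enough for real ISO
21090-style nesting while keeping self-referential type systems finite;
nodes cut off by the limit are marked truncated.

Template building is selection-order driven: clusters appear in order of
first selection of their class, elements in selection order within the
cluster.  An association-mediated selection (an attribute of a class
reached through a declared role) lands in the cluster of the *target*
class, annotated with the role — clusters are keyed to classes, and this
keeps that invariant under requirement-4-style selections.  An element's
cardinality is the attribute's model cardinality; component-level
cardinalities are not composed into it.  Validation is total: every
violation is reported, not just the first.

## CIMI serialization

A template maps to the CIMI reference model as ENTRY (the template) →
CLUSTER (one per class) → ELEMENT (one per selected path).  Both
containment levels use `cimi:CLUSTER.item`, the one containment term the
reference model provides for cluster contents.  The exact term IRIs are
configurable (`CimiConfig`); no canonical published IRI set exists for the
reference model, so the default uses a `cimi:` namespace with the term
names as written.  Each ELEMENT links via `spl:attribute` (lowercase
property, by analogy with the uppercase `spl:Attribute` node type) to a
metadata node holding the full path string as its name, the cardinality and
the inheritance flag.  RDF triples are unordered, so integer `tmpl:index`
literals preserve cluster/element positions; this is what lets
`from_cimi(to_cimi(T)) = T` hold exactly rather than only up to
reordering.  Mapping ISO 21090 data types onto CIMI data types is out of
scope; the ELEMENT binds its leaf path string only.  `sparql_insert`
produces a SPARQL 1.1 `INSERT DATA` payload for storing documents in any
update-capable endpoint; no particular triple store is assumed anywhere —
the query contract is defined against any graph loaded with the emitted
Turtle.

## Synthetic models: what they emulate, and what they do not

The generator emulates the structural features the pipeline depends on:
multi-level hierarchies (depth ≤ 4 by default), a configurable
multi-parent probability (0.2 by default) producing diamonds, 1–3 local
attributes and 0–2 associations per class with mixed `0..1 / 1..1 / 0..* /
1..*` cardinalities, and a two-level nested complex-type system over three
primitives.  Sizes default to 20 classes — large enough to contain chains,
trees and diamonds simultaneously while keeping a full randomized sweep
(hundreds of models in the tests and the acceptance script) under a few
seconds.  Attribute names are globally unique by construction so closure
tests are collision-free; a `inject_collision` flag deliberately violates
this to exercise the collision error path.  Ground truth is computed from
the generator's own edge bookkeeping by plain recursive traversal,
independent of the normalization module.

What the generator does *not* emulate: the size and class-degree
distribution of real released domain models, multilingual labels,
annotation properties beyond labels/comments, and OWL constructs outside
the two declaration dialects (no unions, equivalences or property
hierarchies — reasoning beyond `rdfs:subClassOf` traversal is a declared
non-goal).  Passing tests therefore demonstrate correctness of the closure,
query, template and serialization logic on faithful structural analogues,
not robustness to every OWL dialect found in the wild; the dual-dialect
loader remains to be validated against specific published release files.

The hand-written example fixture reproduces the named textbook examples:
Person under Biologic Entity with inherited `name`/`birthDate`;
`educationLevelCode`/`maritalStatusCode` typed `CD`; `CD` with seven
components (`code`, `displayName`, `codeSystem`, `codeSystemName`,
`codeSystemVersion`, `valueSet`, `valueSetVersion` — the first six are the
commonly cited set, `valueSetVersion` accompanies `valueSet` for value-set
binding); "be reported by" from Performed Observation to Subject,
Healthcare Provider, Laboratory and Device; and the five measurement
classes with enough attributes to support a 5-class / 20-attribute /
5-association use-case template whose association targets stay within the
selected classes.

## Service and CLI

The HTTP layer is a read-only convenience over the library (stdlib
threading HTTP server): `/classes`, `/classes/{name}`, `/templates/{name}`
with Turtle/JSON content negotiation; template authoring via SPARQL UPDATE
is deliberately not exposed.  CLI exit codes separate failure classes: 2
for selection/spec validation, 3 for file I/O, 4 for model errors (parse,
cycle, collision, unresolved references, malformed template documents).

## Known limitations

* No UML redefinition/override semantics; a genuine attribute override in
  the source model surfaces as a name collision.
* Associations are not navigated in the inverse direction unless declared.
* The `ANY` data type is left unconstrained.
* Template editing/reload and full-text search over classes are not
  provided; templates are rebuilt from their spec documents.
* CIMI conformance of the exported documents has not been certified against
  an external validator; the exporter guarantees the structural invariants
  stated above (single ENTRY, reachability, per-element metadata).
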