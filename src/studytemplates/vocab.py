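"""RDF vocabulary used across the pipeline.

Three groups of terms:

* ``BRIDG`` / ``SPL`` — the output vocabulary of the normalization step:
  ``bridg:attributeProperty`` / ``bridg:associationProperty`` attach one
  SPIN-style metadata node (typed ``spl:Attribute``) per flattened attribute
  or association to its class; ``bridg:isInherited`` flags provenance.
* ``CIMI`` — the ENTRY / CLUSTER / ELEMENT reference-model terms used by the
  template export, with ``cimi:CLUSTER.item`` as the containment link.
* ``STV`` — the package's own structural vocabulary for the
  annotation-instance input dialect (class attribute/association
  declarations, data-type components) and ``TMPL`` for template documents
  (stable ordering indices, association roles).

All of these are defaults; the classes that consume them accept overrides.
"""

from rdflib import Namespace
from rdflib.namespace import OWL, RDF, RDFS, XSD  # noqa: F401  (re-exported)

#: Normalization output namespace (the domain-model vocabulary of the
#: flattened representation).
BRIDG = Namespace("http://www.bridgmodel.org/owl#")

#: SPARQL Inference Notation standard-library namespace; ``spl:Attribute``
#: is the metadata-template class, ``spl:attribute`` the property linking an
#: element to its metadata node, ``spl:predicate`` / ``spl:valueType`` /
#: ``spl:minCount`` / ``spl:maxCount`` the argument properties.
SPL = Namespace("http://spinrdf.org/spl#")

#: CIMI reference-model namespace (configurable; the reference model has no
#: canonical published IRI).
CIMI = Namespace("http://www.opencimi.org/rm#")

#: Structural vocabulary for the annotation-instance input dialect.
STV = Namespace("http://studytemplates.org/vocab#")

#: Template-document vocabulary (ordering indices, class bindings, roles).
TMPL = Namespace("http://studytemplates.org/template#")

#: Default prefix bindings for serialized output, sorted on emission.
DEFAULT_PREFIXES = {
    "bridg": BRIDG,
    "cimi": CIMI,
    "owl": OWL,
    "rdf": RDF,
    "rdfs": RDFS,
    "spl": SPL,
    "stv": STV,
    "tmpl": TMPL,
    "xsd": XSD,
}
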