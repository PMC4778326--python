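"""Independent brute-force oracles for inheritance closure.

These walk the loaded model's parent lists by plain recursive DFS and union
local declarations over every ancestor path.  They deliberately share no
code with the normalization module so they can arbitrate its output.
"""

from __future__ import annotations


def dfs_ancestors(model, class_iri: str) -> set[str]:
    """Transitive ancestor set by recursive DFS over direct parents."""
    out: set[str] = set()

    def walk(iri: str) -> None:
        for p in model.classes[iri].parents:
            if p in model.classes and p not in out:
                out.add(p)
                walk(p)

    walk(class_iri)
    return out


def closure_attributes(model, class_iri: str) -> set[tuple[str, str]]:
    """Expected flattened attribute set: {(owner IRI, name)}."""
    owners = {class_iri} | dfs_ancestors(model, class_iri)
    return {(a.owner_class, a.name)
            for o in owners for a in model.classes[o].local_attributes}


def closure_associations(model, class_iri: str) -> set[tuple[str, str, str]]:
    """Expected flattened association set: {(owner IRI, role, target IRI)}."""
    owners = {class_iri} | dfs_ancestors(model, class_iri)
    return {(a.owner_class, a.role_name, a.target_class)
            for o in owners for a in model.classes[o].local_associations}
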