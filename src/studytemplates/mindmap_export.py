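"""Freemind mind-map rendering of templates.

Targets the Freemind 1.0.x ``.mm`` dialect: a ``<map>`` root holding
``<node TEXT="...">`` elements.  The template name is the central node, each
cluster (class) a child, and each element a grandchild labelled with its
full selection path; association-mediated elements are prefixed with their
role name.  Output is deterministic, so a template always renders to the
same bytes.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from pathlib import Path
from typing import Union

from .errors import EmptyTemplateError
from .template_builder import Template

MAP_VERSION = "1.0.1"


def to_mindmap(template: Template, destination: Union[str, Path, None] = None) -> str:
    """Render a template as Freemind XML; node count = 1 + #clusters + #elements."""
    if not template.clusters or not any(c.elements for c in template.clusters):
        raise EmptyTemplateError(f"template {template.name!r} has no elements")
    root = ET.Element("map", {"version": MAP_VERSION})
    center = ET.SubElement(root, "node", {"TEXT": template.name})
    for cluster in template.clusters:
        cnode = ET.SubElement(center, "node", {"TEXT": cluster.class_name})
        for elem in cluster.elements:
            text = elem.path.render()
            if elem.via_association is not None:
                text = f"{elem.via_association}: {text}"
            ET.SubElement(cnode, "node", {"TEXT": text})
    ET.indent(root)
    text = '<?xml version="1.0" encoding="UTF-8"?>\n' + ET.tostring(
        root, encoding="unicode") + "\n"
    if destination is not None:
        Path(destination).write_text(text)
    return text
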