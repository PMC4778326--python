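"""Thin read-only HTTP layer over a normalized model and stored templates.

Endpoints (GET only):

* ``/classes`` — the class hierarchy tree;
* ``/classes/{name}`` — one class's Children/Attributes/Associations;
* ``/templates/{name}`` — one stored template document.

Responses honour the ``Accept`` header: ``text/turtle`` returns RDF
(the class's flattened triples, or the stored CIMI document), anything else
JSON.  Unknown classes and templates yield 404; malformed paths 400.
Implemented on the standard library's threading HTTP server; no write
endpoints are exposed.
"""

from __future__ import annotations

import json
import threading
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer
from pathlib import Path
from typing import Optional, Union
from urllib.parse import unquote, urlparse

from rdflib import Graph, URIRef

from . import cimi_export, query
from .errors import AmbiguousNameError, NotFoundError
from .normalization import NormalizedGraph
from .vocab import DEFAULT_PREFIXES


class TemplateStore:
    """Stored template documents, keyed by name (Turtle text values)."""

    def __init__(self, documents: Optional[dict[str, str]] = None):
        self.documents = dict(documents or {})

    @classmethod
    def from_directory(cls, directory: Union[str, Path]) -> "TemplateStore":
        docs = {}
        for path in sorted(Path(directory).glob("*.ttl")):
            docs[path.stem] = path.read_text()
        return cls(docs)

    def get(self, name: str) -> Optional[str]:
        return self.documents.get(name)


def _tree_to_dict(node: query.ClassTreeNode) -> dict:
    return {"iri": node.iri, "name": node.name,
            "children": [_tree_to_dict(c) for c in node.children]}


def _class_turtle(normalized: NormalizedGraph, class_iri: str) -> str:
    """The class's own flattened subgraph (its triples + metadata nodes)."""
    g = Graph()
    for prefix, ns in sorted(DEFAULT_PREFIXES.items()):
        g.bind(prefix, ns)
    c = URIRef(class_iri)
    meta_preds = {normalized.vocab.attribute_property,
                  normalized.vocab.association_property}
    for s, p, o in normalized.graph.triples((c, None, None)):
        g.add((s, p, o))
        if p in meta_preds:
            for t in normalized.graph.triples((o, None, None)):
                g.add(t)
    return g.serialize(format="turtle")


class _Handler(BaseHTTPRequestHandler):
    normalized: NormalizedGraph
    store: TemplateStore

    def log_message(self, *args):  # quiet by default
        pass

    def _send(self, code: int, body: str, content_type: str) -> None:
        data = body.encode()
        self.send_response(code)
        self.send_header("Content-Type", content_type + "; charset=utf-8")
        self.send_header("Content-Length", str(len(data)))
        self.end_headers()
        self.wfile.write(data)

    def _json(self, code: int, obj) -> None:
        self._send(code, json.dumps(obj, indent=2), "application/json")

    def _wants_turtle(self) -> bool:
        return "text/turtle" in self.headers.get("Accept", "")

    def do_GET(self) -> None:  # noqa: N802 (http.server API)
        parts = [unquote(p) for p in urlparse(self.path).path.split("/") if p]
        if not parts:
            self._json(200, {"endpoints": ["/classes", "/classes/{name}",
                                           "/templates/{name}"]})
            return
        if parts[0] == "classes" and len(parts) == 1:
            if self._wants_turtle():
                self._send(200, self.normalized.serialize(), "text/turtle")
            else:
                self._json(200, [_tree_to_dict(r)
                                 for r in query.class_tree(self.normalized)])
            return
        if parts[0] == "classes" and len(parts) == 2:
            try:
                meta = query.class_metadata(self.normalized, parts[1])
            except (NotFoundError, AmbiguousNameError) as exc:
                self._json(404, {"error": str(exc)})
                return
            if self._wants_turtle():
                self._send(200, _class_turtle(self.normalized, meta.iri),
                           "text/turtle")
            else:
                self._json(200, meta.to_dict())
            return
        if parts[0] == "templates" and len(parts) == 2:
            doc = self.store.get(parts[1])
            if doc is None:
                self._json(404, {"error": f"no template named {parts[1]!r}"})
                return
            if self._wants_turtle():
                self._send(200, doc, "text/turtle")
            else:
                self._json(200, cimi_export.from_cimi(doc).to_dict())
            return
        self._json(400, {"error": f"malformed request path {self.path!r}"})


def make_server(normalized: NormalizedGraph, store: Optional[TemplateStore] = None,
                host: str = "127.0.0.1", port: int = 8000) -> ThreadingHTTPServer:
    """Build (but do not start) the HTTP server; port 0 picks a free port."""
    handler = type("Handler", (_Handler,),
                   {"normalized": normalized, "store": store or TemplateStore()})
    return ThreadingHTTPServer((host, port), handler)


def serve_forever_in_thread(server: ThreadingHTTPServer) -> threading.Thread:
    """Start the server on a daemon thread (used by tests and the CLI)."""
    t = threading.Thread(target=server.serve_forever, daemon=True)
    t.start()
    return t
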