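"""Complex data types, their components, and dotted selection paths.

ISO 21090 / HL7 V3-style data types are either primitive (``ST``, ``BL``,
``TS``, ``ANY`` — no components) or complex: a coded concept ``CD`` carries
named components such as ``code``, ``displayName``, ``codeSystem``, each
with a data type of its own, which may again be complex.  A *selection
path* names one selectable leaf through this nesting, alternating names and
type names exactly as the browse surface displays it::

    Person.maritalStatusCode.CD.displayName.ST
    CLASS  ATTRIBUTE         DT  COMPONENT  DT

The grammar is CLASS, ATTRIBUTE, then zero or more (DATATYPE, COMPONENT)
pairs, optionally terminated by a final DATATYPE (the leaf's type).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Optional, Sequence

from .errors import NotFoundError, PathError

if TYPE_CHECKING:  # pragma: no cover
    from .model_io import AttributeSpec, ModelGraph


class Unbounded:
    """Singleton sentinel for an unbounded upper cardinality (``*``)."""

    _instance: Optional["Unbounded"] = None

    def __new__(cls) -> "Unbounded":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "UNBOUNDED"


UNBOUNDED = Unbounded()


@dataclass(frozen=True)
class Cardinality:
    """A ``min..max`` multiplicity; ``max`` may be :data:`UNBOUNDED`."""

    min: int = 0
    max: int | Unbounded = 1

    def __post_init__(self) -> None:
        if self.min < 0:
            raise ValueError(f"negative min cardinality: {self.min}")
        if not isinstance(self.max, Unbounded):
            if self.max < 0:
                raise ValueError(f"negative max cardinality: {self.max}")
            if self.min > self.max:
                raise ValueError(f"min {self.min} exceeds max {self.max}")

    @property
    def unbounded(self) -> bool:
        return isinstance(self.max, Unbounded)

    @classmethod
    def parse(cls, text: str) -> "Cardinality":
        """Parse ``"0..1"``, ``"1..*"``, ``"1"`` (meaning 1..1), or ``"*"``."""
        text = text.strip()
        if text == "*":
            return cls(0, UNBOUNDED)
        if ".." in text:
            lo, hi = text.split("..", 1)
            return cls(int(lo), UNBOUNDED if hi.strip() == "*" else int(hi))
        n = int(text)
        return cls(n, n)

    def render(self) -> str:
        hi = "*" if self.unbounded else str(self.max)
        return f"{self.min}..{hi}"

    def __str__(self) -> str:
        return self.render()


@dataclass(frozen=True)
class ComponentDef:
    """One named, typed sub-component of a complex data type."""

    name: str
    datatype: str  # IRI, after namespace unification
    cardinality: Cardinality = field(default_factory=Cardinality)


@dataclass
class DataTypeDef:
    """A data type: primitive iff it has no components."""

    iri: str
    name: str
    components: list[ComponentDef] = field(default_factory=list)

    @property
    def is_primitive(self) -> bool:
        return not self.components

    def component(self, name: str) -> ComponentDef:
        for c in self.components:
            if c.name == name:
                return c
        raise NotFoundError(f"data type {self.name} has no component {name!r}")

    def component_names(self) -> list[str]:
        return [c.name for c in self.components]


class SegmentKind(enum.Enum):
    CLASS = "CLASS"
    ATTRIBUTE = "ATTRIBUTE"
    DATATYPE = "DATATYPE"
    COMPONENT = "COMPONENT"


@dataclass(frozen=True)
class SelectionPath:
    """A dotted path identifying one selectable leaf.

    ``segments`` is a tuple of ``(SegmentKind, name)`` pairs obeying the
    grammar documented in the module docstring; :meth:`render` joins the
    names with ``"."`` and :meth:`parse` inverts it (the grammar is
    position-determined, so parsing needs no model).
    """

    segments: tuple[tuple[SegmentKind, str], ...]

    def __post_init__(self) -> None:
        kinds = [k for k, _ in self.segments]
        if len(kinds) < 2 or kinds[0] is not SegmentKind.CLASS or kinds[1] is not SegmentKind.ATTRIBUTE:
            raise PathError(f"path must start CLASS.ATTRIBUTE: {self.render()!r}")
        rest = kinds[2:]
        i = 0
        while i < len(rest):
            if rest[i] is not SegmentKind.DATATYPE:
                raise PathError(f"expected DATATYPE segment at position {i + 2}: {self.render()!r}")
            if i + 1 < len(rest) and rest[i + 1] is not SegmentKind.COMPONENT:
                raise PathError(f"expected COMPONENT segment at position {i + 3}: {self.render()!r}")
            i += 2

    @property
    def class_name(self) -> str:
        return self.segments[0][1]

    @property
    def attribute_name(self) -> str:
        return self.segments[1][1]

    @property
    def component_names(self) -> list[str]:
        return [n for k, n in self.segments if k is SegmentKind.COMPONENT]

    @property
    def leaf(self) -> tuple[SegmentKind, str]:
        return self.segments[-1]

    def render(self) -> str:
        return ".".join(n for _, n in self.segments)

    def __str__(self) -> str:
        return self.render()

    @classmethod
    def parse(cls, text: str) -> "SelectionPath":
        names = [n.strip() for n in text.split(".")]
        if len(names) < 2 or any(not n for n in names):
            raise PathError(f"cannot parse selection path {text!r}")
        segs: list[tuple[SegmentKind, str]] = [
            (SegmentKind.CLASS, names[0]),
            (SegmentKind.ATTRIBUTE, names[1]),
        ]
        rest = names[2:]
        # After the attribute, segments alternate DATATYPE, COMPONENT,
        # DATATYPE, ... — position parity determines the kind.
        for i, name in enumerate(rest):
            kind = SegmentKind.DATATYPE if i % 2 == 0 else SegmentKind.COMPONENT
            segs.append((kind, name))
        return cls(tuple(segs))


@dataclass
class TypeNode:
    """One node of an expanded component tree.

    The root carries the type itself (``component_name`` is None); children
    carry the component name through which the type was reached.  A node at
    the depth limit whose type still has components is marked ``truncated``.
    """

    type_name: str
    type_iri: str
    component_name: Optional[str] = None
    cardinality: Optional[Cardinality] = None
    children: list["TypeNode"] = field(default_factory=list)
    truncated: bool = False

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def depth(self) -> int:
        """Longest expansion depth below this node, in edges (leaf = 0)."""
        return 0 if not self.children else 1 + max(c.depth() for c in self.children)


def expand_type(model: "ModelGraph", type_iri: str, depth_limit: int = 5) -> TypeNode:
    """Expand a data type into its component tree.

    ``depth_limit`` counts component-expansion levels below the root: with
    a limit of 1 a complex type shows its immediate components, and any
    complex component at the limit is left unexpanded and marked truncated.
    Self-referential type systems therefore always terminate.
    """
    if depth_limit <= 0:
        raise ValueError(f"depth_limit must be positive, got {depth_limit}")
    dt = model.resolve_datatype(type_iri)

    def build(dt: DataTypeDef, component_name: Optional[str],
              card: Optional[Cardinality], level: int) -> TypeNode:
        node = TypeNode(dt.name, dt.iri, component_name, card)
        if dt.is_primitive:
            return node
        if level >= depth_limit:
            node.truncated = True
            return node
        for comp in dt.components:
            try:
                child_dt = model.resolve_datatype(comp.datatype)
            except NotFoundError:
                # unresolved component type: render as an opaque leaf
                node.children.append(
                    TypeNode(_local_name(comp.datatype), comp.datatype,
                             comp.name, comp.cardinality))
                continue
            node.children.append(build(child_dt, comp.name, comp.cardinality, level + 1))
        return node

    return build(dt, None, None, 0)


def build_path(model: "ModelGraph", class_name: str, attr: "AttributeSpec",
               component_chain: Sequence[ComponentDef | str] = ()) -> SelectionPath:
    """Build the canonical dotted path for an attribute selection.

    The rendering is ``Class.attribute.TYPE[.component.TYPE ...]`` — the
    data-type name is interposed after the attribute and after every
    component, so the path always terminates at a type name.  Each component
    in the chain must be a member of the preceding type's definition,
    otherwise :class:`PathError` is raised.
    """
    segs: list[tuple[SegmentKind, str]] = [
        (SegmentKind.CLASS, class_name),
        (SegmentKind.ATTRIBUTE, attr.name),
    ]
    cur = model.resolve_datatype(attr.datatype)
    segs.append((SegmentKind.DATATYPE, cur.name))
    for comp in component_chain:
        comp_name = comp if isinstance(comp, str) else comp.name
        members = cur.component_names()
        if comp_name not in members:
            raise PathError(
                f"{comp_name!r} is not a component of {cur.name} "
                f"(components: {', '.join(members) or 'none'})")
        comp_def = cur.component(comp_name)
        segs.append((SegmentKind.COMPONENT, comp_name))
        cur = model.resolve_datatype(comp_def.datatype)
        segs.append((SegmentKind.DATATYPE, cur.name))
    return SelectionPath(tuple(segs))


def _local_name(iri: str) -> str:
    for sep in ("#", "/"):
        if sep in iri:
            return iri.rsplit(sep, 1)[1]
    return iri
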