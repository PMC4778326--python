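"""Exception hierarchy.

Every error raised by the package derives from :class:`StudyTemplatesError`
so callers (and the CLI exit-code mapping) can distinguish package errors
from programming errors.
"""

from __future__ import annotations


class StudyTemplatesError(Exception):
    """Base class for all package errors."""


class ParseError(StudyTemplatesError):
    """Input could not be parsed (malformed RDF/Turtle, bad spec document)."""


class NotFoundError(StudyTemplatesError):
    """A class, data type, attribute or template was looked up and does not exist."""


class AmbiguousNameError(StudyTemplatesError):
    """A bare name matched more than one IRI."""

    def __init__(self, name: str, candidates: list[str]):
        self.name = name
        self.candidates = sorted(candidates)
        super().__init__(
            f"name {name!r} is ambiguous; candidates: {', '.join(self.candidates)}"
        )


class UnresolvedTypeError(StudyTemplatesError):
    """An attribute's data type could not be resolved under a strict namespace policy."""

    def __init__(self, unresolved: list[tuple[str, str, str]]):
        self.unresolved = unresolved
        lines = ", ".join(f"{c}.{a} -> {t}" for c, a, t in unresolved[:5])
        more = "" if len(unresolved) <= 5 else f" (+{len(unresolved) - 5} more)"
        super().__init__(f"unresolved data-type references: {lines}{more}")


class CycleError(StudyTemplatesError):
    """The rdfs:subClassOf graph contains a cycle."""

    def __init__(self, cycle: list[str]):
        self.cycle = cycle
        super().__init__("subclass cycle: " + " -> ".join(cycle))


class NameCollisionError(StudyTemplatesError):
    """Two distinct owner classes contribute same-named attributes to one flattened class."""

    def __init__(self, class_iri: str, name: str, owners: list[str]):
        self.class_iri = class_iri
        self.name = name
        self.owners = sorted(owners)
        super().__init__(
            f"attribute name {name!r} in flattened class <{class_iri}> "
            f"is contributed by multiple owners: {', '.join(self.owners)}"
        )


class PathError(StudyTemplatesError):
    """A selection path violates the path grammar or type-component membership."""


class Violation:
    """One rule violation found while validating a template spec."""

    __slots__ = ("path", "rule", "message")

    def __init__(self, path: str, rule: str, message: str):
        self.path = path
        self.rule = rule
        self.message = message

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Violation({self.path!r}, {self.rule!r}, {self.message!r})"

    def __str__(self) -> str:
        return f"[{self.rule}] {self.path}: {self.message}"


class ValidationError(StudyTemplatesError):
    """A template spec failed validation; carries every violation, not just the first."""

    def __init__(self, violations: list[Violation]):
        self.violations = violations
        super().__init__(
            f"{len(violations)} invalid selection(s):\n"
            + "\n".join(f"  - {v}" for v in violations)
        )


class EmptySelectionError(StudyTemplatesError):
    """A template spec selects nothing."""


class EmptyTemplateError(StudyTemplatesError):
    """A template with no clusters cannot be exported."""


class StructureError(StudyTemplatesError):
    """A CIMI document violates a structural invariant; names the invariant."""
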