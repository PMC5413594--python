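"""Exception types shared across the package."""

from __future__ import annotations


class OntoSearchError(Exception):
    """Base class for all package-specific errors."""


class UnknownConceptError(OntoSearchError, KeyError):
    """A CURIE does not name any concept in the ontology."""

    def __init__(self, curie: str):
        super().__init__(curie)
        self.curie = curie

    def __str__(self) -> str:  # KeyError quotes its arg; keep a plain message
        return f"unknown concept: {self.curie!r}"


class UnknownHierarchyError(OntoSearchError, KeyError):
    """A hierarchy id does not name any hierarchy in the ontology."""

    def __init__(self, hierarchy_id: str):
        super().__init__(hierarchy_id)
        self.hierarchy_id = hierarchy_id

    def __str__(self) -> str:
        return f"unknown hierarchy: {self.hierarchy_id!r}"


class UnknownTermError(OntoSearchError, ValueError):
    """A free-text query term matched no vocabulary entry.

    Carries up to five auto-complete suggestions for the user.
    """

    def __init__(self, term: str, suggestions: tuple[str, ...] = ()):
        super().__init__(term)
        self.term = term
        self.suggestions = tuple(suggestions)[:5]

    def __str__(self) -> str:
        msg = f"unknown term: {self.term!r}"
        if self.suggestions:
            msg += " (did you mean: " + ", ".join(self.suggestions) + "?)"
        return msg


class NamespaceError(OntoSearchError, ValueError):
    """A CURIE prefix or IRI base is not registered."""


class FormatError(OntoSearchError, ValueError):
    """Malformed serialized ontology or instance data."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message)
        self.line = line

    def __str__(self) -> str:
        base = self.args[0]
        return f"line {self.line}: {base}" if self.line is not None else base
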