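"""Free-text term resolution and auto-complete over the ontology vocabulary.

Every preferred label and every synonym of every concept contributes one
surface string to the vocabulary.  Strings are compared after a light
normalization (case folding, whitespace collapsing, en/em-dash unification),
so "Sprague–Dawley" and "sprague-dawley" are the same vocabulary key.

A normalized key that maps to more than one concept is a *homonym* (e.g. a
"granule layer" existing in several brain regions); resolution returns all of
them and downstream query logic decides how to combine the matches.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .errors import UnknownTermError
from .model import Ontology

__all__ = ["normalize", "VocabularyEntry", "TermIndex"]

_WS_RUN = re.compile(r"\s+")
_DASHES = str.maketrans({"–": "-", "—": "-"})  # en dash, em dash


def normalize(s: str) -> str:
    """Canonical form of a surface string; idempotent.

    Lowercases, trims, collapses internal whitespace runs to a single space
    and maps en/em dashes to the ASCII hyphen.  Diacritics are preserved.
    """
    return _WS_RUN.sub(" ", s.strip().translate(_DASHES)).lower()


@dataclass(frozen=True)
class VocabularyEntry:
    """One vocabulary surface string and the concepts it names.

    ``surface_form`` is a representative original spelling (the preferred
    label when the string is preferred for some concept, else the
    lexicographically smallest synonym spelling).  ``preferred_for`` is the
    subset of ``concept_ids`` for which this string is the preferred label;
    the entry is a homonym iff it names more than one concept.
    """

    surface_form: str
    normalized_key: str
    concept_ids: tuple[str, ...]
    preferred_for: tuple[str, ...]

    @property
    def is_homonym(self) -> bool:
        return len(self.concept_ids) > 1


class TermIndex:
    """Lookup structure mapping normalized strings to concepts."""

    def __init__(self, ontology: Ontology):
        self.ontology = ontology
        collected: dict[str, dict[str, set[str]]] = {}
        # key -> {"concepts": ids, "preferred": ids, "surfaces": spellings}
        surfaces: dict[str, set[str]] = {}
        preferred_surface: dict[str, str] = {}
        for concept in ontology.concepts():
            for label, is_pref in [(concept.preferred_label, True)] + [
                (s, False) for s in sorted(concept.synonyms)
            ]:
                key = normalize(label)
                if not key:
                    continue
                slot = collected.setdefault(key, {"concepts": set(), "preferred": set()})
                slot["concepts"].add(concept.id)
                if is_pref:
                    slot["preferred"].add(concept.id)
                    preferred_surface.setdefault(key, label)
                surfaces.setdefault(key, set()).add(label)
        self._entries: dict[str, VocabularyEntry] = {}
        for key in sorted(collected):
            slot = collected[key]
            surface = preferred_surface.get(key, min(surfaces[key]))
            self._entries[key] = VocabularyEntry(
                surface_form=surface,
                normalized_key=key,
                concept_ids=tuple(sorted(slot["concepts"])),
                preferred_for=tuple(sorted(slot["preferred"])),
            )
        self._sorted_keys = sorted(self._entries)

    # ------------------------------------------------------------------ query

    def __len__(self) -> int:
        return len(self._entries)

    def entries(self) -> tuple[VocabularyEntry, ...]:
        """All vocabulary entries in key order."""
        return tuple(self._entries[k] for k in self._sorted_keys)

    def resolve(self, term: str) -> list[str]:
        """All concepts whose preferred label or synonym matches ``term``.

        Matching is up to :func:`normalize`; the result is in deterministic
        CURIE-lexicographic order and empty when the term is unknown.
        """
        entry = self._entries.get(normalize(term))
        return list(entry.concept_ids) if entry else []

    def entry(self, term: str) -> VocabularyEntry | None:
        return self._entries.get(normalize(term))

    def autocomplete(self, prefix: str, limit: int = 10) -> list[VocabularyEntry]:
        """Vocabulary entries whose key starts with the normalized prefix.

        Ranked with entries that are a preferred label for some concept ahead
        of synonym-only entries; ties broken lexicographically on the key.
        """
        if limit < 1:
            raise ValueError("limit must be >= 1")
        key = normalize(prefix)
        if not key:
            raise ValueError("auto-complete prefix must be non-empty")
        matches = [
            self._entries[k] for k in self._sorted_keys if k.startswith(key)
        ]
        matches.sort(key=lambda e: (0 if e.preferred_for else 1, e.normalized_key))
        return matches[:limit]

    def suggestions_for(self, term: str, limit: int = 5) -> tuple[str, ...]:
        """Best-effort auto-complete suggestions for an unknown term."""
        key = normalize(term)
        for probe in (key, key[:4], key[:2], key[:1]):
            if not probe:
                continue
            try:
                hits = self.autocomplete(probe, limit=limit)
            except ValueError:
                continue
            if hits:
                return tuple(e.surface_form for e in hits)
        return ()

    def require(self, term: str) -> VocabularyEntry:
        """Resolve or raise :class:`UnknownTermError` with suggestions."""
        entry = self.entry(term)
        if entry is None:
            raise UnknownTermError(term, self.suggestions_for(term))
        return entry
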