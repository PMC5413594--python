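"""The query engine: direct hits (D) and possible hits (P) for a search term.

Given a term, the engine resolves it against the vocabulary and partitions
the instance set:

* **direct hits** — instances whose annotations *entail* the query concept
  with certainty: annotated at the concept itself, at a merged equivalent, at
  any descendant, or at a concept whose hooks imply it;
* **possible hits** — instances that are merely *consistent* with the query
  concept: nothing they entail is mutually exclusive with anything the query
  concept entails.  These are records whose annotation is too coarse to
  decide (e.g. annotated "rat" when searching for a specific strain), in any
  dimension.

D and P are disjoint by construction.  A homonym term (one string, several
concepts) returns the union of the per-concept direct hits and no possible
hits, because the generalization logic is ill-defined across conflicting
parent concepts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .annotations import AnnotationStore, Instance
from .model import Ontology
from .term_index import TermIndex

__all__ = ["QueryResult", "GroupedCounts", "OntoSearch"]


@dataclass(frozen=True)
class QueryResult:
    """Result of one query: matched concepts plus the D and P instance sets."""

    term: str
    matched_concepts: tuple[str, ...]
    direct: frozenset[str]
    possible: frozenset[str]
    is_homonym: bool

    def __post_init__(self) -> None:
        assert not (self.direct & self.possible), "D and P must be disjoint"
        assert self.is_homonym == (len(self.matched_concepts) > 1)
        assert not (self.is_homonym and self.possible), "homonym query has P = {}"

    def to_json_dict(self, groups: dict | None = None) -> dict:
        d = {
            "term": self.term,
            "matched_concepts": list(self.matched_concepts),
            "is_homonym": self.is_homonym,
            "direct": sorted(self.direct),
            "possible": sorted(self.possible),
        }
        if groups is not None:
            d["groups"] = groups
        return d

    def to_json(self, groups: dict | None = None) -> str:
        return json.dumps(self.to_json_dict(groups), ensure_ascii=False, indent=2)


@dataclass(frozen=True)
class GroupedCounts:
    """Hit counts grouped by a hierarchy's depth-1 concepts.

    Keys are depth-1 CURIEs of the grouping hierarchy, or ``"unspecified"``
    for instances annotated at the root of (or not at all in) that
    hierarchy.  Direct and possible hits are counted separately; the counts
    sum to |D| + |P|.
    """

    direct: dict[str, int] = field(default_factory=dict)
    possible: dict[str, int] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "direct": dict(sorted(self.direct.items())),
            "possible": dict(sorted(self.possible.items())),
        }

    def total(self) -> int:
        return sum(self.direct.values()) + sum(self.possible.values())


class OntoSearch:
    """Query engine over one ontology and one instance store.

    The engine caches per-instance entailed sets; the ontology's own closure
    memos do the rest.  For an independent, cache-free reference computation
    see :mod:`ontosearch.oracle`.
    """

    def __init__(self, ontology: Ontology, store: AnnotationStore | None = None):
        self.ontology = ontology
        self.store = store if store is not None else AnnotationStore(ontology)
        self.index: TermIndex = self.store.index
        self._entailed_memo: dict[str, frozenset[str]] = {}

    # ------------------------------------------------------------- entailment

    def entailed_set(self, instance: Instance | str) -> frozenset[str]:
        """Everything an instance's annotations imply.

        The union of the implication closures of all annotated concepts: all
        ancestors (through equivalences) plus everything reachable through
        hooks.  Empty for an unannotated instance.
        """
        inst = self.store.instance(instance) if isinstance(instance, str) else instance
        key = inst.id
        cached = self._entailed_memo.get(key)
        if cached is not None:
            return cached
        entailed: set[str] = set()
        for curie in inst.annotations.values():
            entailed |= self.ontology.implication_closure(curie)
        out = frozenset(entailed)
        self._entailed_memo[key] = out
        return out

    def entails(self, instance: Instance | str, curie: str) -> bool:
        """True iff the instance certainly matches the concept."""
        self.ontology.concept(curie)
        return bool(self.ontology.merged_class(curie) & self.entailed_set(instance))

    def consistent(self, instance: Instance | str, curie: str) -> bool:
        """True iff nothing the instance entails excludes the concept."""
        onto = self.ontology
        closure = onto.implication_closure(curie)
        entailed = self.entailed_set(instance)
        return not any(
            onto.is_disjoint(x, y) for x in entailed for y in closure
        )

    # ------------------------------------------------------------------- hits

    def direct_hits(self, curie: str) -> frozenset[str]:
        """Instances annotated at the concept, an equivalent, a descendant,
        or whose hooks entail it."""
        self.ontology.concept(curie)
        return frozenset(
            inst.id for inst in self.store if self.entails(inst, curie)
        )

    def possible_hits(self, curie: str) -> frozenset[str]:
        """Consistent instances that are not direct hits."""
        self.ontology.concept(curie)
        return frozenset(
            inst.id
            for inst in self.store
            if self.consistent(inst, curie) and not self.entails(inst, curie)
        )

    # ------------------------------------------------------------------ query

    def query(self, term: str) -> QueryResult:
        """Resolve a free-text term and compute D and P.

        Raises :class:`~ontosearch.errors.UnknownTermError` (with up to five
        auto-complete suggestions) when the term is not in the vocabulary.
        Homonyms return the union of per-concept direct hits and an empty
        possible set.
        """
        entry = self.index.require(term)
        matched = entry.concept_ids
        if len(matched) == 1:
            concept = matched[0]
            direct = self.direct_hits(concept)
            possible = self.possible_hits(concept)
        else:
            direct = frozenset().union(*(self.direct_hits(c) for c in matched))
            possible = frozenset()
        return QueryResult(
            term=term,
            matched_concepts=matched,
            direct=direct,
            possible=possible,
            is_homonym=len(matched) > 1,
        )

    # --------------------------------------------------------------- grouping

    def _group_label(self, instance_id: str, hierarchy_id: str) -> str:
        onto = self.ontology
        effective = self.store.effective_annotation(instance_id, hierarchy_id)
        root = onto.root_of(hierarchy_id)
        if effective == root:
            return "unspecified"
        c = onto.concept(effective)
        while c.parent is not None and c.parent != root:
            c = onto.concept(c.parent)
        return c.id

    def group_results(self, result: QueryResult, hierarchy_id: str) -> GroupedCounts:
        """Count each hit once under its depth-1 ancestor in a hierarchy.

        Instances without an annotation in the grouping hierarchy (or
        annotated at its root) are counted under ``"unspecified"``; direct
        and possible hits are tallied separately so totals are preserved.
        """
        self.ontology.hierarchy(hierarchy_id)
        grouped = GroupedCounts()
        for iid in sorted(result.direct):
            label = self._group_label(iid, hierarchy_id)
            grouped.direct[label] = grouped.direct.get(label, 0) + 1
        for iid in sorted(result.possible):
            label = self._group_label(iid, hierarchy_id)
            grouped.possible[label] = grouped.possible.get(label, 0) + 1
        return grouped
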