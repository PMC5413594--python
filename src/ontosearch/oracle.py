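"""Brute-force reference implementation of the query logic.

This module recomputes everything from the raw ontology data on every call —
pairwise fixpoint closure for equivalence classes, iterative set expansion
for upward/downward reachability, per-instance re-derivation of entailment
and consistency — with no shared caches or indexes.  It exists solely as an
independent cross-check for :class:`ontosearch.reasoner.OntoSearch`: the two
must agree exactly on every input.
"""

from __future__ import annotations

from .annotations import AnnotationStore
from .model import Ontology
from .reasoner import QueryResult
from .term_index import TermIndex

__all__ = ["oracle_query", "oracle_direct_hits", "oracle_possible_hits"]


def _equivalence_classes(ontology: Ontology) -> dict[str, frozenset[str]]:
    """Partition by repeated pairwise merging of the declared pairs."""
    classes: list[set[str]] = [{c.id} for c in ontology.concepts()]
    pairs = list(ontology.equivalences)
    changed = True
    while changed:
        changed = False
        for a, b in pairs:
            ca = next((s for s in classes if a in s), None)
            cb = next((s for s in classes if b in s), None)
            if ca is None or cb is None or ca is cb:
                continue
            classes.remove(ca)
            classes.remove(cb)
            classes.append(ca | cb)
            changed = True
    return {cid: frozenset(s) for s in classes for cid in s}


def _upward(ontology: Ontology, merged: dict[str, frozenset[str]], curie: str) -> set[str]:
    """Fixpoint of { add merged equivalents; add parents }."""
    result = {curie}
    while True:
        new = set(result)
        for x in result:
            new |= merged[x]
            p = ontology.concept(x).parent
            if p is not None:
                new.add(p)
        if new == result:
            return result
        result = new


def _downward(ontology: Ontology, merged: dict[str, frozenset[str]], curie: str) -> set[str]:
    """Inverse of :func:`_upward`, derived literally from its definition."""
    return {
        c.id
        for c in ontology.concepts()
        if curie in _upward(ontology, merged, c.id)
    }


def _closure(ontology: Ontology, merged: dict[str, frozenset[str]], curie: str) -> set[str]:
    """Implication closure: upward set plus transitively fired hooks."""
    closure = _upward(ontology, merged, curie)
    while True:
        new = set(closure)
        for s, t in ontology.hooks:
            if s in new:
                new |= _upward(ontology, merged, t)
        if new == closure:
            return closure
        closure = new


def _disjoint(
    ontology: Ontology, merged: dict[str, frozenset[str]], a: str, b: str
) -> bool:
    hier_a = {ontology.concept(m).hierarchy for m in merged[a]}
    hier_b = {ontology.concept(m).hierarchy for m in merged[b]}
    if not hier_a & hier_b:
        return False
    if a in _upward(ontology, merged, b) or b in _upward(ontology, merged, a):
        return False
    return True


def _hits_for_concept(
    ontology: Ontology, store: AnnotationStore, merged: dict[str, frozenset[str]], curie: str
) -> tuple[set[str], set[str]]:
    # Per-call tables only: ancestors and pairwise disjointness are derived
    # here from scratch and discarded when the query returns.
    up: dict[str, set[str]] = {
        c.id: _upward(ontology, merged, c.id) for c in ontology.concepts()
    }

    def disjoint(a: str, b: str) -> bool:
        hier_a = {ontology.concept(m).hierarchy for m in merged[a]}
        hier_b = {ontology.concept(m).hierarchy for m in merged[b]}
        if not hier_a & hier_b:
            return False
        return a not in up[b] and b not in up[a]

    def closure(c: str) -> set[str]:
        result = set(up[c])
        changed = True
        while changed:
            changed = False
            for s, t in ontology.hooks:
                if s in result and not up[t] <= result:
                    result |= up[t]
                    changed = True
        return result

    target_closure = closure(curie)
    target_class = merged[curie]
    direct: set[str] = set()
    possible: set[str] = set()
    for inst in store:
        entailed: set[str] = set()
        for a in inst.annotations.values():
            entailed |= closure(a)
        if entailed & target_class:
            direct.add(inst.id)
        elif not any(disjoint(x, y) for x in entailed for y in target_closure):
            possible.add(inst.id)
    return direct, possible


def oracle_direct_hits(ontology: Ontology, store: AnnotationStore, curie: str) -> frozenset[str]:
    merged = _equivalence_classes(ontology)
    direct, _ = _hits_for_concept(ontology, store, merged, curie)
    return frozenset(direct)


def oracle_possible_hits(ontology: Ontology, store: AnnotationStore, curie: str) -> frozenset[str]:
    merged = _equivalence_classes(ontology)
    _, possible = _hits_for_concept(ontology, store, merged, curie)
    return frozenset(possible)


def oracle_query(
    ontology: Ontology, store: AnnotationStore, term: str, index: TermIndex | None = None
) -> QueryResult:
    """Same contract as :meth:`OntoSearch.query`, computed by brute force."""
    index = index if index is not None else store.index
    entry = index.require(term)
    matched = entry.concept_ids
    merged = _equivalence_classes(ontology)
    if len(matched) == 1:
        direct, possible = _hits_for_concept(ontology, store, merged, matched[0])
    else:
        direct = set()
        for c in matched:
            d, _ = _hits_for_concept(ontology, store, merged, c)
            direct |= d
        possible = set()
    return QueryResult(
        term=term,
        matched_concepts=matched,
        direct=frozenset(direct),
        possible=frozenset(possible),
        is_homonym=len(matched) > 1,
    )
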