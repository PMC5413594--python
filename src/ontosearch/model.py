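"""In-memory ontology model: hierarchies, equivalence, hooks, disjointness.

The knowledge structure is a forest of single-parent concept hierarchies
(subsumption via ``is_a`` or ``is_part_of``), augmented with two kinds of
cross-hierarchy links:

* **equivalence** — unordered pairs identifying the same concept in two
  parallel hierarchies of one dimension (e.g. a brain region appearing in both
  a sub-region and a laminar parcellation);
* **hooks (implication)** — ordered pairs stating that membership in the
  source concept entails membership in the target concept in another
  hierarchy (e.g. a cell type found exclusively in one brain region).

All reasoning (ancestor/descendant closure, disjointness of siblings,
implication closure) is computed here.  Equivalent concepts are merged into
classes (union-find) before any graph traversal, so every closure is invariant
across the members of a merged class.

Concepts are identified by CURIEs (``prefix:local``); the ontology carries a
namespace table mapping each prefix to its IRI base.  Instances of an
``Ontology`` are treated as immutable once constructed: traversal results are
memoised internally.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

from .errors import UnknownConceptError, UnknownHierarchyError

__all__ = [
    "Concept",
    "Hierarchy",
    "Ontology",
    "Violation",
    "CURIE_RE",
    "split_curie",
]

#: Syntactic shape of a CURIE: prefix ":" local-name, no whitespace.
CURIE_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_.\-]*:[A-Za-z0-9_.\-]+$")

#: Dimensions with a fixed name; anything else uses "other:<name>".
_KNOWN_DIMENSIONS = {"species", "brain_region", "cell_type"}

_RELATION_KINDS = {"is_a", "is_part_of"}


def split_curie(curie: str) -> tuple[str, str]:
    """Split a CURIE into (prefix, local-name); raises ValueError if malformed."""
    if not CURIE_RE.match(curie):
        raise ValueError(f"not a CURIE: {curie!r}")
    prefix, local = curie.split(":", 1)
    return prefix, local


@dataclass(frozen=True)
class Concept:
    """A node of one hierarchy.

    Parameters
    ----------
    id:
        The concept's CURIE, unique across the whole ontology.
    preferred_label:
        The canonical surface string for the concept.
    hierarchy:
        Id of the hierarchy this concept belongs to.
    parent:
        CURIE of the parent concept within the same hierarchy; ``None`` for
        the hierarchy root (and only for the root).
    synonyms:
        Alternate surface strings; never contains the preferred label.
    dbxrefs:
        Cross-references to external resources (free-form strings).
    """

    id: str
    preferred_label: str
    hierarchy: str
    parent: str | None = None
    synonyms: frozenset[str] = frozenset()
    dbxrefs: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "synonyms", frozenset(self.synonyms))
        object.__setattr__(self, "dbxrefs", frozenset(self.dbxrefs))

    @property
    def labels(self) -> frozenset[str]:
        """Preferred label plus all synonyms."""
        return self.synonyms | {self.preferred_label}


@dataclass(frozen=True)
class Hierarchy:
    """A rooted single-parent tree of concepts along one metadata dimension.

    ``dimension`` is one of ``species``, ``brain_region``, ``cell_type`` or
    ``other:<name>``; several hierarchies may share a dimension (orthogonal
    parcellations of the same axis).  ``relation_kind`` records whether the
    parent link reads *is_a* (hypernym/hyponym) or *is_part_of*
    (holonym/meronym); the subsumption semantics are identical either way.
    """

    id: str
    dimension: str
    relation_kind: str
    concepts: tuple[Concept, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "concepts", tuple(self.concepts))

    def __iter__(self) -> Iterator[Concept]:
        return iter(self.concepts)

    def __len__(self) -> int:
        return len(self.concepts)

    @property
    def concept_ids(self) -> tuple[str, ...]:
        return tuple(c.id for c in self.concepts)

    def root(self) -> Concept:
        """The unique parentless concept (assumes a valid hierarchy)."""
        roots = [c for c in self.concepts if c.parent is None]
        if len(roots) != 1:
            raise ValueError(
                f"hierarchy {self.id!r} has {len(roots)} roots, expected exactly 1"
            )
        return roots[0]


@dataclass(frozen=True)
class Violation:
    """One well-formedness failure found by :meth:`Ontology.validate`."""

    rule: str
    elements: tuple[str, ...]
    message: str

    def __str__(self) -> str:
        return f"[{self.rule}] {self.message}"


class Ontology:
    """The full knowledge model: hierarchies + equivalences + hooks + namespaces.

    Parameters
    ----------
    hierarchies:
        The hierarchy forest.
    equivalences:
        Unordered CURIE pairs identifying one concept across two hierarchies.
    hooks:
        Ordered (source, target) CURIE pairs: source membership implies
        target membership.
    namespaces:
        Prefix -> IRI base; every base must end with ``#``, ``/`` or ``_``.
    """

    def __init__(
        self,
        hierarchies: Iterable[Hierarchy],
        equivalences: Iterable[tuple[str, str]] = (),
        hooks: Iterable[tuple[str, str]] = (),
        namespaces: Mapping[str, str] | None = None,
    ):
        self.hierarchies: tuple[Hierarchy, ...] = tuple(
            sorted(hierarchies, key=lambda h: h.id)
        )
        self.equivalences: tuple[tuple[str, str], ...] = tuple(
            sorted(tuple(sorted(p)) for p in equivalences)
        )
        self.hooks: tuple[tuple[str, str], ...] = tuple(sorted(tuple(p) for p in hooks))
        self.namespaces: dict[str, str] = dict(namespaces or {})

        # Indexes assume a valid ontology; validate() below works on raw data.
        self._concepts: dict[str, Concept] = {}
        self._children: dict[str, tuple[str, ...]] = {}
        self._hierarchy_by_id: dict[str, Hierarchy] = {h.id: h for h in self.hierarchies}
        children: dict[str, list[str]] = {}
        for h in self.hierarchies:
            for c in h.concepts:
                self._concepts.setdefault(c.id, c)
                if c.parent is not None:
                    children.setdefault(c.parent, []).append(c.id)
        self._children = {p: tuple(sorted(ks)) for p, ks in children.items()}

        self._merged: dict[str, frozenset[str]] | None = None
        self._ancestor_memo: dict[str, frozenset[str]] = {}
        self._descendant_memo: dict[str, frozenset[str]] = {}
        self._closure_memo: dict[str, frozenset[str]] = {}

    # ------------------------------------------------------------------ basics

    def _canonical(self):
        """Order-insensitive content signature, used for model equality."""
        return (
            tuple(
                (
                    h.id,
                    h.dimension,
                    h.relation_kind,
                    tuple(
                        sorted(
                            (
                                c.id,
                                c.preferred_label,
                                c.parent or "",
                                tuple(sorted(c.synonyms)),
                                tuple(sorted(c.dbxrefs)),
                            )
                            for c in h.concepts
                        )
                    ),
                )
                for h in self.hierarchies
            ),
            self.equivalences,
            self.hooks,
            tuple(sorted(self.namespaces.items())),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Ontology):
            return NotImplemented
        return self._canonical() == other._canonical()

    def __hash__(self) -> int:
        return hash(self._canonical())

    def __contains__(self, curie: str) -> bool:
        return curie in self._concepts

    def __len__(self) -> int:
        return len(self._concepts)

    def concepts(self) -> Iterator[Concept]:
        """All concepts in deterministic (CURIE-lexicographic) order."""
        for cid in sorted(self._concepts):
            yield self._concepts[cid]

    def concept(self, curie: str) -> Concept:
        try:
            return self._concepts[curie]
        except KeyError:
            raise UnknownConceptError(curie) from None

    def hierarchy(self, hierarchy_id: str) -> Hierarchy:
        try:
            return self._hierarchy_by_id[hierarchy_id]
        except KeyError:
            raise UnknownHierarchyError(hierarchy_id) from None

    def children(self, curie: str) -> tuple[str, ...]:
        """Direct children of a concept within its own hierarchy."""
        self.concept(curie)
        return self._children.get(curie, ())

    def root_of(self, hierarchy_id: str) -> str:
        return self.hierarchy(hierarchy_id).root().id

    def depth(self, curie: str) -> int:
        """Number of parent steps (within the hierarchy) from the root."""
        d = 0
        c = self.concept(curie)
        while c.parent is not None:
            c = self.concept(c.parent)
            d += 1
        return d

    # ------------------------------------------------------ equivalence merge

    def _merged_map(self) -> dict[str, frozenset[str]]:
        """Union-find over the declared equivalence pairs."""
        if self._merged is not None:
            return self._merged
        parent: dict[str, str] = {cid: cid for cid in self._concepts}

        def find(x: str) -> str:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for a, b in self.equivalences:
            if a in parent and b in parent:
                ra, rb = find(a), find(b)
                if ra != rb:
                    # Deterministic union: smaller CURIE becomes the root.
                    if rb < ra:
                        ra, rb = rb, ra
                    parent[rb] = ra
        groups: dict[str, set[str]] = {}
        for cid in parent:
            groups.setdefault(find(cid), set()).add(cid)
        self._merged = {
            cid: frozenset(members)
            for members in groups.values()
            for cid in members
        }
        return self._merged

    def merged_class(self, curie: str) -> frozenset[str]:
        """The transitive equivalence class of a concept (always contains it)."""
        self.concept(curie)
        return self._merged_map()[curie]

    # ------------------------------------------------------------- traversals

    def ancestors(self, curie: str) -> frozenset[str]:
        """The upward closure of a concept.

        Contains the concept itself and everything reachable by repeatedly
        taking parents, where any member of a merged equivalence class may be
        stepped through.  Identical for all members of a merged class.
        """
        self.concept(curie)
        rep = min(self.merged_class(curie))
        cached = self._ancestor_memo.get(rep)
        if cached is not None:
            return cached
        result: set[str] = set()
        frontier: list[str] = [curie]
        while frontier:
            x = frontier.pop()
            if x in result:
                continue
            result.add(x)
            for m in self.merged_class(x):
                if m not in result:
                    frontier.append(m)
            p = self._concepts[x].parent
            if p is not None and p not in result:
                frontier.append(p)
        out = frozenset(result)
        self._ancestor_memo[rep] = out
        return out

    def descendants(self, curie: str) -> frozenset[str]:
        """The downward closure: exact inverse of :meth:`ancestors`."""
        self.concept(curie)
        rep = min(self.merged_class(curie))
        cached = self._descendant_memo.get(rep)
        if cached is not None:
            return cached
        result: set[str] = set()
        frontier: list[str] = [curie]
        while frontier:
            x = frontier.pop()
            if x in result:
                continue
            result.add(x)
            for m in self.merged_class(x):
                if m not in result:
                    frontier.append(m)
            for k in self._children.get(x, ()):
                if k not in result:
                    frontier.append(k)
        out = frozenset(result)
        self._descendant_memo[rep] = out
        return out

    # ----------------------------------------------------------- disjointness

    def _class_hierarchies(self, curie: str) -> frozenset[str]:
        return frozenset(self._concepts[m].hierarchy for m in self.merged_class(curie))

    def is_disjoint(self, a: str, b: str) -> bool:
        """Mutual exclusivity of two concepts.

        Within a single-parent hierarchy, any two concepts neither of which
        subsumes the other are mutually exclusive (sibling disjointness
        propagates to all incomparable pairs).  Two concepts are compared in a
        shared hierarchy after equivalence merging; concepts living only in
        orthogonal hierarchies are never disjoint.  Symmetric and irreflexive.
        """
        self.concept(a)
        self.concept(b)
        if not (self._class_hierarchies(a) & self._class_hierarchies(b)):
            return False
        if a in self.ancestors(b) or b in self.ancestors(a):
            return False
        return True

    # ----------------------------------------------------- implication (hook)

    def implication_closure(self, curie: str) -> frozenset[str]:
        """Least fixpoint of ancestors + hook firing.

        Starts from ``ancestors(curie)``; whenever a hook source lies in the
        set, the target's ancestors are added; repeats to fixpoint.  Hook
        cycles terminate because the concept set is finite.
        """
        self.concept(curie)
        rep = min(self.merged_class(curie))
        cached = self._closure_memo.get(rep)
        if cached is not None:
            return cached
        closure: set[str] = set(self.ancestors(curie))
        changed = True
        while changed:
            changed = False
            for source, target in self.hooks:
                if source in closure and target not in closure:
                    add = self.ancestors(target)
                    if not add <= closure:
                        closure |= add
                        changed = True
        out = frozenset(closure)
        self._closure_memo[rep] = out
        return out

    # --------------------------------------------------------------- validate

    def validate(self) -> list[Violation]:
        """Check every structural invariant; violations are data, not errors.

        Returns an empty list iff the ontology is well-formed.  Never raises
        on malformed content.
        """
        violations: list[Violation] = []

        def bad(rule: str, elements: tuple[str, ...], message: str) -> None:
            violations.append(Violation(rule, elements, message))

        for prefix, base in sorted(self.namespaces.items()):
            if not base.endswith(("#", "/", "_")):
                bad(
                    "namespace-suffix",
                    (prefix,),
                    f"namespace {prefix!r} base {base!r} must end with '#', '/' or '_'",
                )

        seen: dict[str, str] = {}  # curie -> hierarchy id of first sighting
        per_hier_parent: dict[tuple[str, str], set[str | None]] = {}
        for h in self.hierarchies:
            if h.dimension not in _KNOWN_DIMENSIONS and not h.dimension.startswith(
                "other:"
            ):
                bad(
                    "unknown-dimension",
                    (h.id,),
                    f"hierarchy {h.id!r} dimension {h.dimension!r} is not recognised",
                )
            if h.relation_kind not in _RELATION_KINDS:
                bad(
                    "unknown-relation-kind",
                    (h.id,),
                    f"hierarchy {h.id!r} relation kind {h.relation_kind!r}",
                )
            local_ids = {c.id for c in h.concepts}
            roots = []
            for c in h.concepts:
                if not CURIE_RE.match(c.id):
                    bad("malformed-curie", (c.id,), f"{c.id!r} is not a CURIE")
                else:
                    prefix = c.id.split(":", 1)[0]
                    if prefix not in self.namespaces:
                        bad(
                            "unregistered-prefix",
                            (c.id,),
                            f"concept {c.id} uses unregistered prefix {prefix!r}",
                        )
                if c.id in seen and seen[c.id] != h.id:
                    bad(
                        "duplicate-curie",
                        (c.id,),
                        f"concept id {c.id} appears in hierarchies "
                        f"{seen[c.id]!r} and {h.id!r}",
                    )
                seen.setdefault(c.id, h.id)
                per_hier_parent.setdefault((h.id, c.id), set()).add(c.parent)
                if not c.preferred_label:
                    bad("empty-label", (c.id,), f"concept {c.id} has an empty label")
                if c.preferred_label in c.synonyms:
                    bad(
                        "label-in-synonyms",
                        (c.id,),
                        f"preferred label of {c.id} is also listed as a synonym",
                    )
                if c.parent is None:
                    roots.append(c.id)
                elif c.parent not in local_ids:
                    bad(
                        "foreign-parent",
                        (c.id, c.parent),
                        f"parent {c.parent} of {c.id} is not in hierarchy {h.id!r}",
                    )
            if len(set(roots)) != 1:
                bad(
                    "root-count",
                    (h.id,),
                    f"hierarchy {h.id!r} has {len(set(roots))} roots, expected 1",
                )
            # Cycle check on parent links (restricted to this hierarchy).
            parent_of = {c.id: c.parent for c in h.concepts}
            for start in parent_of:
                slow: str | None = start
                trail: set[str] = set()
                while slow is not None and slow in parent_of:
                    if slow in trail:
                        bad(
                            "cycle",
                            (start,),
                            f"parent links of {start} in {h.id!r} form a cycle",
                        )
                        break
                    trail.add(slow)
                    slow = parent_of[slow]

        for (hid, cid), parents in sorted(per_hier_parent.items()):
            if len(parents) > 1:
                bad(
                    "multiple-parent",
                    (cid,),
                    f"concept {cid} in hierarchy {hid!r} is given "
                    f"{len(parents)} different parents",
                )

        for a, b in self.equivalences:
            missing = [x for x in (a, b) if x not in seen]
            if missing:
                bad(
                    "equivalence-unknown-concept",
                    tuple(missing),
                    f"equivalence ({a}, {b}) references unknown concept(s)",
                )
                continue
            if seen[a] == seen[b]:
                bad(
                    "equivalence-within-hierarchy",
                    (a, b),
                    f"equivalence ({a}, {b}) links two concepts of "
                    f"hierarchy {seen[a]!r}",
                )
        for s, t in self.hooks:
            missing = [x for x in (s, t) if x not in seen]
            if missing:
                bad(
                    "hook-unknown-concept",
                    tuple(missing),
                    f"hook ({s} -> {t}) references unknown concept(s)",
                )
                continue
            if seen[s] == seen[t]:
                bad(
                    "hook-within-hierarchy",
                    (s, t),
                    f"hook ({s} -> {t}) links two concepts of hierarchy {seen[s]!r}",
                )
        return violations
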