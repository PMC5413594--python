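"""Instance records, curation-checked annotation, and context-filtered menus.

An *instance* is one annotated data record (for neuromorphology, one traced
neuron): an identifier plus at most one concept per hierarchy and free-form
string attributes.  Absence of an annotation in a hierarchy means
"unspecified" and is interpreted as the hierarchy root — maximally general.

:meth:`AnnotationStore.annotate` performs the controlled-vocabulary checks a
curator would otherwise do by hand: synonyms are mapped to their existing
concept (never minting a new one), homonym strings are refused until
disambiguated with an explicit CURIE, and annotations that conflict with or
are redundant given the instance's existing annotations are rejected with an
explanatory report rather than stored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .errors import FormatError
from .model import Ontology
from .term_index import TermIndex, normalize

__all__ = ["Instance", "AnnotationReport", "AnnotationStore"]


@dataclass
class Instance:
    """One annotated record: id, per-hierarchy concept, free attributes."""

    id: str
    annotations: dict[str, str] = field(default_factory=dict)
    attributes: dict[str, str] = field(default_factory=dict)
    extra: dict = field(default_factory=dict)  # unknown JSON keys, round-tripped

    def to_json_dict(self) -> dict:
        d = {
            "id": self.id,
            "annotations": dict(sorted(self.annotations.items())),
            "attributes": dict(sorted(self.attributes.items())),
        }
        d.update(self.extra)
        return d


#: Possible outcomes of an annotation attempt.
_ACTIONS = (
    "accepted",
    "mapped_to_preferred",
    "rejected_homonym",
    "rejected_conflict",
    "rejected_redundant",
    "unknown_term",
)


@dataclass(frozen=True)
class AnnotationReport:
    """Outcome of one :meth:`AnnotationStore.annotate` call.

    ``resolved`` is present exactly when the annotation was stored
    (``accepted`` or ``mapped_to_preferred``).
    """

    raw_term: str
    resolved: str | None
    action: str
    message: str

    def __post_init__(self) -> None:
        assert self.action in _ACTIONS, self.action
        assert (self.resolved is not None) == (
            self.action in ("accepted", "mapped_to_preferred")
        )

    @property
    def stored(self) -> bool:
        return self.resolved is not None


class AnnotationStore:
    """Instances plus the curation logic that keeps them consistent."""

    def __init__(
        self,
        ontology: Ontology,
        instances: Iterable[Instance] = (),
        index: TermIndex | None = None,
    ):
        self.ontology = ontology
        self.index = index if index is not None else TermIndex(ontology)
        self.instances: dict[str, Instance] = {}
        for inst in instances:
            if inst.id in self.instances:
                raise ValueError(f"duplicate instance id {inst.id!r}")
            self.instances[inst.id] = inst

    def __iter__(self) -> Iterator[Instance]:
        for iid in sorted(self.instances):
            yield self.instances[iid]

    def __len__(self) -> int:
        return len(self.instances)

    def instance(self, instance_id: str) -> Instance:
        return self.instances[instance_id]

    def add(self, instance: Instance) -> None:
        if instance.id in self.instances:
            raise ValueError(f"duplicate instance id {instance.id!r}")
        self.instances[instance.id] = instance

    # ------------------------------------------------------------- annotation

    def annotate(self, instance: Instance | str, term: str, refine: bool = False) -> AnnotationReport:
        """Attempt to annotate an instance with a free-text term.

        Synonym input is mapped to its concept's preferred identity
        (``mapped_to_preferred``); homonym strings are rejected — pass the
        CURIE to :meth:`annotate_concept` to disambiguate.  Conflicting
        (mutually exclusive with existing annotations, directly or through
        hooks), and redundant (ancestor of an existing same-hierarchy
        annotation, or a merged duplicate of any existing annotation) terms
        are rejected; a more specific concept in an already-annotated
        hierarchy replaces the old one only when ``refine=True``.
        """
        inst = self.instance(instance) if isinstance(instance, str) else instance
        matches = self.index.resolve(term)
        if not matches:
            return AnnotationReport(
                term, None, "unknown_term", f"{term!r} matches no vocabulary entry"
            )
        if len(matches) > 1:
            return AnnotationReport(
                term,
                None,
                "rejected_homonym",
                f"{term!r} is a homonym of {len(matches)} concepts "
                f"({', '.join(matches)}); annotate with an explicit CURIE",
            )
        return self._annotate_resolved(inst, term, matches[0], refine)

    def annotate_concept(
        self, instance: Instance | str, curie: str, refine: bool = False
    ) -> AnnotationReport:
        """Annotate with an explicit concept id (homonym disambiguation path)."""
        inst = self.instance(instance) if isinstance(instance, str) else instance
        self.ontology.concept(curie)
        return self._annotate_resolved(inst, curie, curie, refine)

    def _annotate_resolved(
        self, inst: Instance, raw_term: str, curie: str, refine: bool
    ) -> AnnotationReport:
        onto = self.ontology
        concept = onto.concept(curie)
        # Explicit-CURIE input counts as accepted, not as a synonym mapping.
        mapped = raw_term != curie and normalize(raw_term) != normalize(
            concept.preferred_label
        )

        existing_same = inst.annotations.get(concept.hierarchy)
        if existing_same is not None:
            if curie in onto.ancestors(existing_same):
                return AnnotationReport(
                    raw_term,
                    None,
                    "rejected_redundant",
                    f"{curie} subsumes the existing {existing_same} annotation",
                )
            if existing_same in onto.ancestors(curie):
                if not refine:
                    return AnnotationReport(
                        raw_term,
                        None,
                        "rejected_redundant",
                        f"{curie} refines existing {existing_same}; "
                        "pass refine=True to replace it",
                    )
                # fall through: refinement replaces the coarser annotation
            else:
                return AnnotationReport(
                    raw_term,
                    None,
                    "rejected_conflict",
                    f"{curie} is mutually exclusive with existing {existing_same}",
                )

        # Merged duplicates across hierarchies are redundant, not conflicting.
        for h, a in sorted(inst.annotations.items()):
            if h == concept.hierarchy:
                continue
            if onto.merged_class(curie) & onto.merged_class(a):
                return AnnotationReport(
                    raw_term,
                    None,
                    "rejected_redundant",
                    f"{curie} is equivalent to the existing {a} annotation",
                )

        # Hook-aware consistency against everything the instance entails.
        target_closure = onto.implication_closure(curie)
        for h, a in sorted(inst.annotations.items()):
            if h == concept.hierarchy:
                continue  # same-hierarchy relation already settled above
            for x in sorted(onto.implication_closure(a)):
                for y in sorted(target_closure):
                    if onto.is_disjoint(x, y):
                        return AnnotationReport(
                            raw_term,
                            None,
                            "rejected_conflict",
                            f"{curie} entails {y} which excludes {x} "
                            f"entailed by the existing {a} annotation",
                        )

        inst.annotations[concept.hierarchy] = curie
        if mapped:
            return AnnotationReport(
                raw_term,
                curie,
                "mapped_to_preferred",
                f"{raw_term!r} is a synonym of {concept.preferred_label!r} ({curie})",
            )
        return AnnotationReport(raw_term, curie, "accepted", f"stored {curie}")

    # ---------------------------------------------------------------- queries

    def effective_annotation(self, instance: Instance | str, hierarchy_id: str) -> str:
        """The stored concept for a hierarchy, or its root when unspecified."""
        inst = self.instance(instance) if isinstance(instance, str) else instance
        stored = inst.annotations.get(hierarchy_id)
        if stored is not None:
            self.ontology.hierarchy(hierarchy_id)
            return stored
        return self.ontology.root_of(hierarchy_id)

    def suggest_options(self, instance: Instance | str, hierarchy_id: str) -> set[str]:
        """Context-filtered annotation menu for one hierarchy.

        Concepts whose implication closure is mutually exclusive with
        anything the instance already entails are excluded — e.g. a brain
        region hooked to an insect species is not offered for a mouse.  An
        unannotated instance sees every concept of the hierarchy.
        """
        inst = self.instance(instance) if isinstance(instance, str) else instance
        onto = self.ontology
        hierarchy = onto.hierarchy(hierarchy_id)
        entailed: set[str] = set()
        for a in inst.annotations.values():
            entailed |= onto.implication_closure(a)
        options: set[str] = set()
        for c in hierarchy.concepts:
            closure = onto.implication_closure(c.id)
            if any(onto.is_disjoint(x, y) for x in entailed for y in closure):
                continue
            options.add(c.id)
        return options

    # ------------------------------------------------------------------- I/O

    @staticmethod
    def _parse_record(record: dict, ontology: Ontology, index: TermIndex, line: int) -> Instance:
        if "id" not in record or not record["id"]:
            raise FormatError("instance record lacks a non-empty 'id'", line)
        annotations: dict[str, str] = {}
        for hid, value in record.get("annotations", {}).items():
            ontology.hierarchy(hid)
            if value in ontology:
                curie = value
            else:
                matches = index.resolve(value)
                if not matches:
                    raise FormatError(
                        f"annotation {value!r} is neither a known CURIE nor a vocabulary term",
                        line,
                    )
                if len(matches) > 1:
                    raise FormatError(
                        f"annotation term {value!r} is ambiguous ({', '.join(matches)})",
                        line,
                    )
                curie = matches[0]
            if ontology.concept(curie).hierarchy != hid:
                raise FormatError(
                    f"concept {curie} does not belong to hierarchy {hid!r}", line
                )
            if hid in annotations:
                raise FormatError(f"two annotations for hierarchy {hid!r}", line)
            annotations[hid] = curie
        extra = {
            k: v for k, v in record.items() if k not in ("id", "annotations", "attributes")
        }
        return Instance(
            id=record["id"],
            annotations=annotations,
            attributes=dict(record.get("attributes", {})),
            extra=extra,
        )

    @classmethod
    def read_jsonl(cls, path: str | Path, ontology: Ontology) -> "AnnotationStore":
        """Load instances from a JSON-lines file; unknown keys are preserved."""
        index = TermIndex(ontology)
        instances = []
        for lineno, raw in enumerate(
            Path(path).read_text(encoding="utf-8").splitlines(), start=1
        ):
            if not raw.strip():
                continue
            try:
                record = json.loads(raw)
            except json.JSONDecodeError as exc:
                raise FormatError(f"invalid JSON: {exc}", lineno) from exc
            instances.append(cls._parse_record(record, ontology, index, lineno))
        return cls(ontology, instances, index=index)

    def write_jsonl(self, path: str | Path) -> None:
        lines = [
            json.dumps(inst.to_json_dict(), ensure_ascii=False, sort_keys=False)
            for inst in self
        ]
        Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")
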