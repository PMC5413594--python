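"""Ontology serialization: tabbed hierarchies, triple TSV, OWL/XML, JSON.

Three interchange formats are supported, all mutually convertible without
loss over the model's fields:

* **tab-indented hierarchy text** — the curator-facing format: one concept
  per line, depth encoded by leading TABs, optional synonyms and CURIE
  (``Label | syn1; syn2 | PREFIX:0001``).  One file per hierarchy.
* **triple TSV** — subject / predicate / object rows using the closed
  predicate set ``rdfs:subClassOf``, ``owl:equivalentClass``, ``hasHook``,
  ``rdfs:label``, ``oboInOwl:hasExactSynonym``, ``oboInOwl:hasDBXref``.
  Hierarchy membership and dimension/relation-kind metadata are not
  expressible in bare triples; they ride in a JSON sidecar mapping each CURIE
  prefix to its hierarchy (one prefix per hierarchy in this format).
* **OWL/XML subset** — class declarations, subclass and equivalent-class
  axioms, hooks and hierarchy metadata as annotation assertions with the
  standard ``rdfs:label`` / ``oboInOwl:hasExactSynonym`` /
  ``oboInOwl:hasDBXref`` annotation properties.

Serialization is deterministic: an identical model produces byte-identical
output.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

from lxml import etree

from .errors import FormatError, NamespaceError
from .model import CURIE_RE, Concept, Hierarchy, Ontology
from .term_index import normalize

__all__ = [
    "Triple",
    "expand_curie",
    "contract_iri",
    "parse_tabbed",
    "serialize_tabbed",
    "to_triples",
    "from_triples",
    "write_triples",
    "read_triples",
    "write_owl",
    "read_owl",
    "to_json_dict",
    "from_json_dict",
    "write_json",
    "read_json",
]

logger = logging.getLogger(__name__)

#: Closed predicate set for the triple format.
PREDICATES = (
    "rdfs:subClassOf",
    "owl:equivalentClass",
    "hasHook",
    "rdfs:label",
    "oboInOwl:hasExactSynonym",
    "oboInOwl:hasDBXref",
)
_LITERAL_PREDICATES = {"rdfs:label", "oboInOwl:hasExactSynonym", "oboInOwl:hasDBXref"}

OWL_NS = "http://www.w3.org/2002/07/owl#"
#: Annotation-property IRIs used in the OWL subset.
RDFS_LABEL_IRI = "http://www.w3.org/2000/01/rdf-schema#label"
SYNONYM_IRI = "http://www.geneontology.org/formats/oboInOwl#hasExactSynonym"
DBXREF_IRI = "http://www.geneontology.org/formats/oboInOwl#hasDBXref"
HOOK_IRI = "http://ontosearch.dev/meta#hasHook"
HIERARCHY_META_IRI = "http://ontosearch.dev/meta#hierarchy"


@dataclass(frozen=True)
class Triple:
    """One subject/predicate/object row; objects are CURIEs or literals."""

    subject: str
    predicate: str
    object: str
    object_is_literal: bool = False

    def __post_init__(self) -> None:
        if self.predicate not in PREDICATES:
            raise FormatError(f"unknown predicate {self.predicate!r}")
        if self.object_is_literal != (self.predicate in _LITERAL_PREDICATES):
            raise FormatError(
                f"predicate {self.predicate!r} takes "
                f"{'a literal' if self.predicate in _LITERAL_PREDICATES else 'a CURIE'} object"
            )


# --------------------------------------------------------------- CURIE / IRI


def expand_curie(curie: str, namespaces: dict[str, str]) -> str:
    """CURIE -> IRI using the registered namespace table."""
    if not CURIE_RE.match(curie):
        raise NamespaceError(f"not a CURIE: {curie!r}")
    prefix, local = curie.split(":", 1)
    try:
        base = namespaces[prefix]
    except KeyError:
        raise NamespaceError(f"unregistered prefix {prefix!r} in {curie!r}") from None
    return base + local


def contract_iri(iri: str, namespaces: dict[str, str]) -> str:
    """IRI -> CURIE, using the longest matching registered base."""
    best: tuple[str, str] | None = None
    for prefix, base in namespaces.items():
        if iri.startswith(base) and (best is None or len(base) > len(best[1])):
            best = (prefix, base)
    if best is None:
        raise NamespaceError(f"no registered namespace matches IRI {iri!r}")
    prefix, base = best
    return f"{prefix}:{iri[len(base):]}"


# ------------------------------------------------------------ tabbed format


def parse_tabbed(
    text: str,
    hierarchy_id: str,
    dimension: str = "other:unnamed",
    relation_kind: str = "is_a",
    prefix: str | None = None,
    start_index: int = 1,
) -> Hierarchy:
    """Parse a tab-indented hierarchy.

    Line format: ``<TABS><Preferred Label>[ | syn1; syn2][ | CURIE]`` — the
    number of leading TABs is the depth, the first non-blank line is the root
    (depth 0) and each line attaches to the nearest preceding line one level
    up.  A single trailing field is read as a CURIE when it is one syntactic
    token of the form ``prefix:local``, otherwise as synonyms.  Concepts
    without an explicit CURIE receive sequential ids ``{prefix}:{n:04d}``
    (``prefix`` defaults to the hierarchy id).
    """
    prefix = prefix if prefix is not None else hierarchy_id
    concepts: list[Concept] = []
    stack: list[tuple[int, str]] = []  # (depth, curie) of open lineage
    counter = start_index
    seen_any = False
    sibling_keys: dict[str | None, set[str]] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        if not raw.strip():
            continue
        depth = len(raw) - len(raw.lstrip("\t"))
        body = raw.strip()
        fields = [f.strip() for f in body.split("|")]
        label = fields[0]
        synonyms: list[str] = []
        curie: str | None = None
        rest = fields[1:]
        if len(rest) == 2:
            synonyms = [s.strip() for s in rest[0].split(";") if s.strip()]
            curie = rest[1]
        elif len(rest) == 1:
            if CURIE_RE.match(rest[0]) and " " not in rest[0]:
                curie = rest[0]
            else:
                synonyms = [s.strip() for s in rest[0].split(";") if s.strip()]
        elif len(rest) > 2:
            raise FormatError(f"too many '|' fields in {body!r}", lineno)
        if not label:
            raise FormatError("empty concept label", lineno)
        if not seen_any:
            if depth != 0:
                raise FormatError("first concept line must be unindented (root)", lineno)
            seen_any = True
        while stack and stack[-1][0] >= depth:
            stack.pop()
        if depth > 0 and (not stack or stack[-1][0] != depth - 1):
            raise FormatError(
                f"indentation jumps to depth {depth} with no parent at depth {depth - 1}",
                lineno,
            )
        parent = stack[-1][1] if depth > 0 else None
        key = normalize(label)
        taken = sibling_keys.setdefault(parent, set())
        if key in taken:
            raise FormatError(f"duplicate sibling label {label!r}", lineno)
        taken.add(key)
        if curie is None:
            curie = f"{prefix}:{counter:04d}"
            counter += 1
        concepts.append(
            Concept(
                id=curie,
                preferred_label=label,
                hierarchy=hierarchy_id,
                parent=parent,
                synonyms=frozenset(synonyms),
            )
        )
        stack.append((depth, curie))
    if not concepts:
        raise FormatError("empty tabbed hierarchy input")
    return Hierarchy(
        id=hierarchy_id,
        dimension=dimension,
        relation_kind=relation_kind,
        concepts=tuple(concepts),
    )


def serialize_tabbed(hierarchy: Hierarchy, include_curies: bool = True) -> str:
    """Deterministic tabbed rendering (children sorted by label)."""
    by_parent: dict[str | None, list[Concept]] = {}
    for c in hierarchy.concepts:
        by_parent.setdefault(c.parent, []).append(c)
    for kids in by_parent.values():
        kids.sort(key=lambda c: (c.preferred_label, c.id))
    lines: list[str] = []

    def emit(concept: Concept, depth: int) -> None:
        parts = [concept.preferred_label]
        if concept.synonyms:
            parts.append("; ".join(sorted(concept.synonyms)))
        if include_curies:
            parts.append(concept.id)
        lines.append("\t" * depth + " | ".join(parts))
        for child in by_parent.get(concept.id, []):
            emit(child, depth + 1)

    emit(hierarchy.root(), 0)
    return "\n".join(lines) + "\n"


# ------------------------------------------------------------ triple format


def to_triples(ontology: Ontology) -> list[Triple]:
    """Flatten a valid ontology to the closed-predicate triple list.

    Child->parent pairs become ``rdfs:subClassOf``; equivalences are emitted
    once with the lexicographically smaller subject; hooks as ``hasHook``;
    labels, synonyms and dbxrefs as literal annotation triples.  Output order
    is deterministic.
    """
    violations = ontology.validate()
    if violations:
        raise FormatError(
            "refusing to serialize an invalid ontology: " + str(violations[0])
        )
    triples: list[Triple] = []
    for concept in ontology.concepts():
        triples.append(Triple(concept.id, "rdfs:label", concept.preferred_label, True))
        for syn in sorted(concept.synonyms):
            triples.append(Triple(concept.id, "oboInOwl:hasExactSynonym", syn, True))
        for ref in sorted(concept.dbxrefs):
            triples.append(Triple(concept.id, "oboInOwl:hasDBXref", ref, True))
        if concept.parent is not None:
            triples.append(Triple(concept.id, "rdfs:subClassOf", concept.parent))
    for a, b in ontology.equivalences:
        lo, hi = sorted((a, b))
        triples.append(Triple(lo, "owl:equivalentClass", hi))
    for s, t in ontology.hooks:
        triples.append(Triple(s, "hasHook", t))
    triples.sort(key=lambda t: (t.subject, PREDICATES.index(t.predicate), t.object))
    return triples


def _hierarchy_meta(ontology: Ontology) -> dict:
    """Sidecar metadata: namespaces plus prefix -> hierarchy mapping."""
    prefix_to_hier: dict[str, dict] = {}
    for h in ontology.hierarchies:
        prefixes = {c.id.split(":", 1)[0] for c in h.concepts}
        for p in sorted(prefixes):
            if p in prefix_to_hier and prefix_to_hier[p]["id"] != h.id:
                raise FormatError(
                    f"prefix {p!r} is used by hierarchies "
                    f"{prefix_to_hier[p]['id']!r} and {h.id!r}; the triple "
                    "format requires one prefix per hierarchy"
                )
            prefix_to_hier[p] = {
                "id": h.id,
                "dimension": h.dimension,
                "relation_kind": h.relation_kind,
            }
    return {
        "namespaces": dict(sorted(ontology.namespaces.items())),
        "prefix_hierarchies": dict(sorted(prefix_to_hier.items())),
    }


def from_triples(triples: list[Triple], meta: dict) -> Ontology:
    """Rebuild an ontology from triples + the JSON sidecar metadata."""
    prefix_hier = meta.get("prefix_hierarchies", {})
    namespaces = dict(meta.get("namespaces", {}))

    def hierarchy_of(curie: str) -> str:
        prefix = curie.split(":", 1)[0]
        if prefix not in prefix_hier:
            raise FormatError(
                f"CURIE {curie!r} uses prefix {prefix!r} absent from the metadata header"
            )
        return prefix_hier[prefix]["id"]

    labels: dict[str, str] = {}
    synonyms: dict[str, set[str]] = {}
    dbxrefs: dict[str, set[str]] = {}
    parents: dict[str, list[str]] = {}
    equivalences: list[tuple[str, str]] = []
    hooks: list[tuple[str, str]] = []
    concept_ids: set[str] = set()
    for t in triples:
        concept_ids.add(t.subject)
        if t.predicate == "rdfs:label":
            labels[t.subject] = t.object
        elif t.predicate == "oboInOwl:hasExactSynonym":
            synonyms.setdefault(t.subject, set()).add(t.object)
        elif t.predicate == "oboInOwl:hasDBXref":
            dbxrefs.setdefault(t.subject, set()).add(t.object)
        elif t.predicate == "rdfs:subClassOf":
            concept_ids.add(t.object)
            parents.setdefault(t.subject, []).append(t.object)
        elif t.predicate == "owl:equivalentClass":
            concept_ids.add(t.object)
            equivalences.append((t.subject, t.object))
        elif t.predicate == "hasHook":
            concept_ids.add(t.object)
            hooks.append((t.subject, t.object))

    # Reject subsumption cycles up front (they cannot form a hierarchy).
    for start in sorted(parents):
        seen: set[str] = set()
        cur: str | None = start
        while cur is not None:
            if cur in seen:
                raise FormatError(f"rdfs:subClassOf cycle through {start!r}")
            seen.add(cur)
            ps = parents.get(cur, [])
            cur = ps[0] if ps else None

    hier_concepts: dict[str, list[Concept]] = {}
    for cid in sorted(concept_ids):
        hid = hierarchy_of(cid)
        plist = parents.get(cid, [])
        for parent in plist or [None]:
            hier_concepts.setdefault(hid, []).append(
                Concept(
                    id=cid,
                    preferred_label=labels.get(cid, ""),
                    hierarchy=hid,
                    parent=parent,
                    synonyms=frozenset(synonyms.get(cid, ())),
                    dbxrefs=frozenset(dbxrefs.get(cid, ())),
                )
            )
    hierarchies = []
    for prefix in sorted(prefix_hier):
        info = prefix_hier[prefix]
        hid = info["id"]
        if hid in {h.id for h in hierarchies}:
            continue
        hierarchies.append(
            Hierarchy(
                id=hid,
                dimension=info["dimension"],
                relation_kind=info["relation_kind"],
                concepts=tuple(hier_concepts.get(hid, ())),
            )
        )
    return Ontology(
        hierarchies=hierarchies,
        equivalences=equivalences,
        hooks=hooks,
        namespaces=namespaces,
    )


def write_triples(ontology: Ontology, tsv_path: str | Path, meta_path: str | Path | None = None) -> None:
    """Write the TSV (3 columns, literals double-quoted) and its JSON sidecar."""
    tsv_path = Path(tsv_path)
    meta_path = Path(meta_path) if meta_path else tsv_path.with_suffix(tsv_path.suffix + ".meta.json")
    rows = []
    for t in to_triples(ontology):
        obj = json.dumps(t.object, ensure_ascii=False) if t.object_is_literal else t.object
        rows.append(f"{t.subject}\t{t.predicate}\t{obj}")
    tsv_path.write_text("\n".join(rows) + "\n", encoding="utf-8")
    meta_path.write_text(
        json.dumps(_hierarchy_meta(ontology), indent=2, sort_keys=True) + "\n",
        encoding="utf-8",
    )


def read_triples(tsv_path: str | Path, meta_path: str | Path | None = None) -> Ontology:
    tsv_path = Path(tsv_path)
    meta_path = Path(meta_path) if meta_path else tsv_path.with_suffix(tsv_path.suffix + ".meta.json")
    meta = json.loads(meta_path.read_text(encoding="utf-8"))
    triples: list[Triple] = []
    for lineno, raw in enumerate(tsv_path.read_text(encoding="utf-8").splitlines(), start=1):
        if not raw.strip():
            continue
        cols = raw.split("\t")
        if len(cols) != 3:
            raise FormatError(f"expected 3 tab-separated columns, got {len(cols)}", lineno)
        subject, predicate, obj = cols
        if predicate not in PREDICATES:
            raise FormatError(f"unknown predicate {predicate!r}", lineno)
        is_literal = predicate in _LITERAL_PREDICATES
        if is_literal:
            if not (obj.startswith('"') and obj.endswith('"')):
                raise FormatError(f"literal object must be double-quoted: {obj!r}", lineno)
            obj = json.loads(obj)
        triples.append(Triple(subject, predicate, obj, is_literal))
    return from_triples(triples, meta)


# --------------------------------------------------------------- OWL subset


def _owl(tag: str) -> str:
    return f"{{{OWL_NS}}}{tag}"


def write_owl(ontology: Ontology, path: str | Path) -> None:
    """Write the OWL/XML subset; deterministic element ordering."""
    violations = ontology.validate()
    if violations:
        raise FormatError(
            "refusing to serialize an invalid ontology: " + str(violations[0])
        )
    nsmap = {None: OWL_NS}
    root = etree.Element(_owl("Ontology"), nsmap=nsmap)
    root.set("ontologyIRI", "http://ontosearch.dev/export")
    for prefix, base in sorted(ontology.namespaces.items()):
        el = etree.SubElement(root, _owl("Prefix"))
        el.set("name", prefix)
        el.set("IRI", base)

    def iri(curie: str) -> str:
        return expand_curie(curie, ontology.namespaces)

    for h in ontology.hierarchies:
        ann = etree.SubElement(root, _owl("Annotation"))
        prop = etree.SubElement(ann, _owl("AnnotationProperty"))
        prop.set("IRI", HIERARCHY_META_IRI)
        lit = etree.SubElement(ann, _owl("Literal"))
        lit.text = json.dumps(
            {
                "id": h.id,
                "dimension": h.dimension,
                "relation_kind": h.relation_kind,
                "concepts": [c.id for c in sorted(h.concepts, key=lambda c: c.id)],
            },
            sort_keys=True,
        )

    for concept in ontology.concepts():
        decl = etree.SubElement(root, _owl("Declaration"))
        etree.SubElement(decl, _owl("Class")).set("IRI", iri(concept.id))
    for concept in ontology.concepts():
        if concept.parent is not None:
            ax = etree.SubElement(root, _owl("SubClassOf"))
            etree.SubElement(ax, _owl("Class")).set("IRI", iri(concept.id))
            etree.SubElement(ax, _owl("Class")).set("IRI", iri(concept.parent))
    for a, b in ontology.equivalences:
        ax = etree.SubElement(root, _owl("EquivalentClasses"))
        for cid in sorted((a, b)):
            etree.SubElement(ax, _owl("Class")).set("IRI", iri(cid))

    def annotation_assertion(prop_iri: str, subject: str, value: str, literal: bool) -> None:
        ax = etree.SubElement(root, _owl("AnnotationAssertion"))
        etree.SubElement(ax, _owl("AnnotationProperty")).set("IRI", prop_iri)
        etree.SubElement(ax, _owl("IRI")).text = iri(subject)
        if literal:
            etree.SubElement(ax, _owl("Literal")).text = value
        else:
            etree.SubElement(ax, _owl("IRI")).text = iri(value)

    for concept in ontology.concepts():
        annotation_assertion(RDFS_LABEL_IRI, concept.id, concept.preferred_label, True)
        for syn in sorted(concept.synonyms):
            annotation_assertion(SYNONYM_IRI, concept.id, syn, True)
        for ref in sorted(concept.dbxrefs):
            annotation_assertion(DBXREF_IRI, concept.id, ref, True)
    for s, t in ontology.hooks:
        annotation_assertion(HOOK_IRI, s, t, False)

    tree = etree.ElementTree(root)
    tree.write(
        str(path), xml_declaration=True, encoding="UTF-8", pretty_print=True
    )


def read_owl(path: str | Path) -> Ontology:
    """Parse the OWL/XML subset; unknown constructs are skipped with a warning."""
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise FormatError(f"malformed XML: {exc}") from exc
    root = tree.getroot()
    if root.tag != _owl("Ontology"):
        raise FormatError(f"expected an owl Ontology document, got {root.tag!r}")
    namespaces: dict[str, str] = {}
    hier_meta: list[dict] = []
    declared: set[str] = set()
    sub_edges: list[tuple[str, str]] = []
    equivalences: list[tuple[str, str]] = []
    hooks: list[tuple[str, str]] = []
    labels: dict[str, str] = {}
    synonyms: dict[str, set[str]] = {}
    dbxrefs: dict[str, set[str]] = {}

    for el in root:
        if el.tag == _owl("Prefix"):
            namespaces[el.get("name")] = el.get("IRI")

    def contract(iri_text: str) -> str:
        try:
            return contract_iri(iri_text, namespaces)
        except NamespaceError:
            raise FormatError(
                f"IRI {iri_text!r} does not match any registered namespace"
            ) from None

    for el in root:
        if el.tag == _owl("Prefix"):
            continue
        if el.tag == _owl("Annotation"):
            prop = el.find(_owl("AnnotationProperty"))
            lit = el.find(_owl("Literal"))
            if prop is not None and prop.get("IRI") == HIERARCHY_META_IRI and lit is not None:
                hier_meta.append(json.loads(lit.text))
            else:
                logger.warning("skipping unrecognised ontology annotation")
        elif el.tag == _owl("Declaration"):
            cls = el.find(_owl("Class"))
            if cls is not None:
                declared.add(contract(cls.get("IRI")))
            else:
                logger.warning("skipping non-class declaration")
        elif el.tag == _owl("SubClassOf"):
            classes = el.findall(_owl("Class"))
            if len(classes) == 2:
                sub_edges.append((contract(classes[0].get("IRI")), contract(classes[1].get("IRI"))))
            else:
                logger.warning("skipping complex SubClassOf axiom")
        elif el.tag == _owl("EquivalentClasses"):
            classes = el.findall(_owl("Class"))
            if len(classes) == 2:
                equivalences.append((contract(classes[0].get("IRI")), contract(classes[1].get("IRI"))))
            else:
                logger.warning("skipping n-ary EquivalentClasses axiom")
        elif el.tag == _owl("AnnotationAssertion"):
            prop = el.find(_owl("AnnotationProperty"))
            iris = el.findall(_owl("IRI"))
            lit = el.find(_owl("Literal"))
            if prop is None or not iris:
                logger.warning("skipping malformed AnnotationAssertion")
                continue
            prop_iri = prop.get("IRI")
            subject = contract(iris[0].text)
            if prop_iri == RDFS_LABEL_IRI and lit is not None:
                labels[subject] = lit.text or ""
            elif prop_iri == SYNONYM_IRI and lit is not None:
                synonyms.setdefault(subject, set()).add(lit.text or "")
            elif prop_iri == DBXREF_IRI and lit is not None:
                dbxrefs.setdefault(subject, set()).add(lit.text or "")
            elif prop_iri == HOOK_IRI and len(iris) == 2:
                hooks.append((subject, contract(iris[1].text)))
            else:
                logger.warning("skipping unrecognised annotation property %r", prop_iri)
        else:
            logger.warning("skipping unknown OWL construct %r", el.tag)

    parent_of: dict[str, str] = {}
    for child, parent in sub_edges:
        parent_of[child] = parent
        declared.update((child, parent))
    hierarchies: list[Hierarchy] = []
    assigned: set[str] = set()
    for meta in sorted(hier_meta, key=lambda m: m["id"]):
        members = [cid for cid in meta.get("concepts", []) if cid in declared]
        concepts = tuple(
            Concept(
                id=cid,
                preferred_label=labels.get(cid, ""),
                hierarchy=meta["id"],
                parent=parent_of.get(cid),
                synonyms=frozenset(synonyms.get(cid, ())),
                dbxrefs=frozenset(dbxrefs.get(cid, ())),
            )
            for cid in members
        )
        assigned.update(members)
        hierarchies.append(
            Hierarchy(
                id=meta["id"],
                dimension=meta["dimension"],
                relation_kind=meta["relation_kind"],
                concepts=concepts,
            )
        )
    orphans = declared - assigned
    if orphans and not hier_meta:
        # Minimal hand-written files without hierarchy metadata: put every
        # class in one default is_a hierarchy.
        concepts = tuple(
            Concept(
                id=cid,
                preferred_label=labels.get(cid, cid.split(":", 1)[1]),
                hierarchy="H1",
                parent=parent_of.get(cid),
                synonyms=frozenset(synonyms.get(cid, ())),
                dbxrefs=frozenset(dbxrefs.get(cid, ())),
            )
            for cid in sorted(declared)
        )
        hierarchies.append(
            Hierarchy(id="H1", dimension="other:default", relation_kind="is_a", concepts=concepts)
        )
    elif orphans:
        logger.warning("skipping %d classes outside any declared hierarchy", len(orphans))
    return Ontology(
        hierarchies=hierarchies,
        equivalences=equivalences,
        hooks=hooks,
        namespaces=namespaces,
    )


# -------------------------------------------------------------- JSON export


def to_json_dict(ontology: Ontology) -> dict:
    """Full, lossless JSON rendering of the model."""
    return {
        "namespaces": dict(sorted(ontology.namespaces.items())),
        "hierarchies": [
            {
                "id": h.id,
                "dimension": h.dimension,
                "relation_kind": h.relation_kind,
                "concepts": [
                    {
                        "id": c.id,
                        "preferred_label": c.preferred_label,
                        "parent": c.parent,
                        "synonyms": sorted(c.synonyms),
                        "dbxrefs": sorted(c.dbxrefs),
                    }
                    for c in sorted(h.concepts, key=lambda c: c.id)
                ],
            }
            for h in ontology.hierarchies
        ],
        "equivalences": [list(p) for p in ontology.equivalences],
        "hooks": [list(p) for p in ontology.hooks],
    }


def from_json_dict(data: dict) -> Ontology:
    hierarchies = [
        Hierarchy(
            id=h["id"],
            dimension=h["dimension"],
            relation_kind=h["relation_kind"],
            concepts=tuple(
                Concept(
                    id=c["id"],
                    preferred_label=c["preferred_label"],
                    hierarchy=h["id"],
                    parent=c.get("parent"),
                    synonyms=frozenset(c.get("synonyms", ())),
                    dbxrefs=frozenset(c.get("dbxrefs", ())),
                )
                for c in h["concepts"]
            ),
        )
        for h in data["hierarchies"]
    ]
    return Ontology(
        hierarchies=hierarchies,
        equivalences=[tuple(p) for p in data.get("equivalences", ())],
        hooks=[tuple(p) for p in data.get("hooks", ())],
        namespaces=data.get("namespaces", {}),
    )


def write_json(ontology: Ontology, path: str | Path) -> None:
    Path(path).write_text(
        json.dumps(to_json_dict(ontology), indent=2, ensure_ascii=False, sort_keys=False)
        + "\n",
        encoding="utf-8",
    )


def read_json(path: str | Path) -> Ontology:
    try:
        data = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise FormatError(f"invalid JSON ontology file: {exc}") from exc
    return from_json_dict(data)
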