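# ontosearch

Ontology-based semantic search over annotated metadata, built for the kind
of curation problem neuroinformatics repositories face: thousands of records
(e.g. digitally reconstructed neurons) annotated with free-text species,
brain-region and cell-type terms that are riddled with synonyms, homonyms
and incomplete detail. `ontosearch` models the metadata as interconnected
concept hierarchies and answers queries with logical inference instead of
string matching.

## The model in brief

Concepts live in rooted single-parent hierarchies (subsumption: *is_a* /
*is_part_of*), grouped into dimensions (species, brain region, cell type,
other). Three relations drive the reasoning:

* **subsumption** — every property of a parent applies to its children;
  sibling (more generally, incomparable same-hierarchy) concepts are
  mutually exclusive;
* **equivalence** — the same concept in two parallel hierarchies of one
  dimension (sub-region CA3 ≡ laminar CA3);
* **implication ("hooks")** — directed cross-hierarchy constraints
  (Purkinje cell → cerebellum; fronto-insula → human).

A query for concept *c* splits the instances into two disjoint sets:

* **direct hits** `D(c) = { i : merged(c) ∩ entailed(i) ≠ ∅ }` — records
  annotated at *c*, an equivalent, a descendant, or whose hooks entail *c*;
* **possible hits** `P(c) = { i : entailed(i) consistent with closure(c) } \ D(c)`
  — records whose annotation is too coarse to decide, kept only if nothing
  they entail is disjoint with anything *c* entails.

Here `entailed(i)` is the union of the implication closures of the
instance's annotations, and an unannotated dimension counts as the
hierarchy root ("unspecified"). One string naming several concepts (a
homonym, like "granule layer") returns the union of the per-concept direct
hits and no possible hits.

## Worked example

```python
from ontosearch import AnnotationStore, OntoSearch, fixture

ontology, instances = fixture("rodent_strains")
engine = OntoSearch(ontology, AnnotationStore(ontology, instances))

result = engine.query("rattus")          # synonym of "rat"
print(sorted(result.direct))             # ['i1', 'i2', 'i3']
print(sorted(result.possible))           # ['i5']

result = engine.query("Wistar")
print(sorted(result.direct))             # ['i1']
print(sorted(result.possible))           # ['i3', 'i5']
```

Searching for the synonym *rattus* retrieves the rat-annotated record and
both strain-level records as direct hits, plus the rodent-level record as a
possible hit. Searching for the *Wistar* strain returns the one Wistar
record directly; the rat- and rodent-level records are possible hits
(their annotation does not exclude Wistar), while the Sprague-Dawley record
is excluded as a disjoint sibling and the mouse record as a disjoint
species.

The same engine is available from the shell:

```sh
ontosearch fixture rodent_strains --out demo/
ontosearch --ontology demo/ontology.json --instances demo/instances.jsonl \
    search "wistar" --json
```

Other entry points: `ontosearch suggest` (auto-complete), `validate`
(structural invariants), `convert` (JSON / OWL-XML / triple-TSV),
`annotate` (curation-checked annotation of an instance record). See
`docs/methods.md` for the full semantics, the synthetic-data generator and
the design choices.

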