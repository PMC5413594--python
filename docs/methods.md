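# Methods

## The knowledge model

Metadata is organized along *dimensions* (animal species, brain region, cell
type, plus free-form "other" axes). Each dimension is covered by one or more
**hierarchies**: rooted trees in which every non-root concept has exactly one
parent and the parent link reads either *is_a* (taxonomies) or *is_part_of*
(anatomical parcellations). Subsumption is inherited: every property of a
parent applies to all of its children. Sibling concepts under one parent are
mutually exclusive, and because each tree is single-parent this exclusivity
propagates to **every incomparable pair within a shared hierarchy** — two
concepts in one tree are disjoint exactly when neither subsumes the other.
Concepts that live only in orthogonal hierarchies (say, a cytoarchitectonic
layer versus a sub-region) are never directly disjoint.

Two cross-hierarchy relations interconnect the forest:

* **Equivalence** identifies the same concept in two parallel hierarchies of
  one dimension (the hippocampus appearing in both the sub-region and the
  laminar parcellation). Equivalences are merged into classes with a
  union-find before any traversal, so all closures are invariant across the
  members of a class. Union by lexicographically-smallest representative
  keeps the partition deterministic.
* **Hooks (implication)** are directed pairs: membership in the source
  concept entails membership in the target concept of another hierarchy
  (a Purkinje cell is found only in the cerebellum; the fronto-insula exists
  only in humans).

Closures are defined as:

* `ancestors(c)` — least set containing `c` that is closed under taking
  parents and under equivalence-class membership (a concept is its own
  ancestor; this simplifies the set algebra and the hit definitions below
  compensate).
* `descendants(c)` — the exact inverse relation.
* `implication_closure(c)` — least fixpoint of `ancestors(c)` under hook
  firing: whenever a hook source is in the set, the target's ancestors are
  added. Hook cycles are legal; the fixpoint terminates on the finite
  concept set.

## Query semantics: direct and possible hits

An instance (an annotated record, e.g. a traced neuron) carries at most one
concept per hierarchy; absence of an annotation means "unspecified" and is
read as the hierarchy root, i.e. maximally general. The set an instance
*entails* is the union of the implication closures of its annotations.

For a query concept `c`:

* **Direct hits (D)** are instances that entail `c` with certainty:
  `merged_class(c) ∩ entailed(i) ≠ ∅`. This covers annotation at `c`
  itself, at an equivalent concept, at any descendant — and at a hook source
  (a Purkinje-annotated, region-unspecified neuron is a direct hit for
  "cerebellum", since implication means certainty).
* **Possible hits (P)** are instances merely *consistent* with `c`: no
  member of `entailed(i)` is disjoint with any member of
  `implication_closure(c)`, and the instance is not already a direct hit.
  This global-consistency formulation coincides with "crawling up the
  hierarchy past non-disjoint ancestors" under the absent-equals-root
  convention, and it extends across dimensions without special cases: a
  query for a human-hooked region automatically drops rat-annotated records,
  and a cuticle-hooked cell class keeps location-unspecified records in P.

D and P are disjoint by construction. Completely unannotated instances are
consistent with everything and therefore appear in P of every single-concept
query.

Free-text terms resolve through a vocabulary built from every preferred
label and synonym, compared after normalization (lower-casing, whitespace
collapsing, en/em-dash → hyphen; diacritics preserved). A normalized string
naming several concepts is a **homonym**: the query returns the union of the
per-concept direct hits and *no* possible hits, because generalization across
conflicting parent concepts is ill-defined. Auto-complete is prefix-only and
ranks entries that are a preferred label ahead of synonym-only entries, ties
alphabetical; ranking by usage frequency would need corpus statistics the
package does not model.

## Curation rules

`AnnotationStore.annotate` resolves a free-text term and then applies, in
order: homonym rejection (explicit CURIE required), same-hierarchy
redundancy (a new annotation subsuming the existing one is rejected; a more
specific one replaces it only with an explicit `refine` flag),
cross-hierarchy merged-duplicate redundancy (annotating the layer-side twin
of an already-annotated region adds nothing), and hook-aware consistency:
the implication closure of the candidate is checked pairwise against
everything the instance already entails. The same consistency predicate
drives `suggest_options`, the context-filtered menu (mushroom bodies are not
offered for a mouse; Purkinje cells are not offered for a neocortical
record). Cross-hierarchy pairs related by ancestry *through equivalence*
(region CA3 plus layer stratum lucidum) are deliberately accepted — the
layer refines the region — while exact merged duplicates are rejected as
redundant.

## Serialization

Three lossless formats, all deterministic (identical model → byte-identical
output):

* tab-indented hierarchy text, one file per hierarchy
  (`Label | syn1; syn2 | CURIE`, TAB depth);
* triple TSV over the closed predicate set `rdfs:subClassOf`,
  `owl:equivalentClass`, `hasHook`, `rdfs:label`,
  `oboInOwl:hasExactSynonym`, `oboInOwl:hasDBXref`, with a JSON sidecar
  carrying what bare triples cannot express (the namespace table and a
  prefix → hierarchy map; this format therefore assumes one CURIE prefix per
  hierarchy, which all shipped fixtures and the generator observe);
* an OWL/XML subset (class declarations, subclass and equivalent-class
  axioms, hooks and hierarchy metadata as annotation assertions), written
  and parsed with `lxml`; unknown constructs are skipped with a warning.
* a self-contained JSON export used as the command-line default.

Concept identifiers are CURIEs; the namespace table maps prefixes to IRI
bases, which must end in `#`, `/` or `_`. Expansion/contraction are exact
inverses; contraction picks the longest matching base.

## Synthetic data

The generator emulates the structural features the reasoning must survive:
1–3 dimensions, 1–3 hierarchies per dimension, ragged trees (depth ≤ 5,
branching ≤ 4), a 20 % synonym rate, a 10 % rate of homonym collisions
(an existing label reused as another concept's synonym), equivalences placed
between root-adjacent concepts of parallel hierarchies, and hooks whose
addition is accepted only if every concept's implication closure stays free
of internally disjoint pairs — the condition under which a consistent
annotation always exists. Each generated instance carries a hidden true leaf
per dimension, drawn consistently with the leaves already fixed for other
dimensions; the stored annotation is either absent (default 25 %) or the
leaf's ancestor at a depth drawn from a configurable specificity
distribution. This yields a ground truth with two provable properties the
suite checks: the reported annotation is always an ancestor of the hidden
leaf, and every instance lies in D ∪ P for every concept on the leaf's
ancestor path.

What the generator does **not** emulate: real anatomical nomenclature and
its messiness (abbreviation clashes, near-duplicate spellings), usage
frequency, deep strain catalogs, or curator disagreement. Passing tests
demonstrate the logic, not coverage of any real repository's content. The
six named fixtures likewise simplify real anatomy (e.g. stratum oriens is
placed only under CA3); they are logic fixtures, not anatomical references.

## Verification strategy and problem sizes

Every query path is cross-checked against `ontosearch.oracle`, an
independent brute-force implementation that recomputes equivalence classes
by pairwise merging and closures by naive fixpoint iteration on every call,
with no caches or shared indexes. The acceptance suite compares engine and
oracle set-for-set on every vocabulary term of all six fixtures and of 200
randomly generated ontologies (seeds 0–199, at most 6 hierarchies, depth
≤ 5, branching ≤ 4, 10–300 instances, skewed small so the brute force stays
cheap); the ground-truth containment check runs at 1000 instances. The full
suite runs in under two minutes on one CPU.

## Numerical and tie-break choices

* All set outputs are ordered lexicographically (CURIEs, instance ids) when
  rendered, so golden-file comparisons are stable.
* Equivalence canonical direction in triples: lexicographically smaller
  subject.
* Grouping counts each hit once under the depth-1 ancestor of its effective
  annotation in the grouping hierarchy, with an `unspecified` bucket for
  root-level or absent annotations; direct and possible tallies are kept
  separate and sum to |D| + |P|.
* `validate` returns violations as data (rule name + offending elements)
  and never raises on malformed content; serializers refuse invalid models.

## Known limitations

* Single-parent trees only: no multi-parent DAGs, no probabilistic
  subsumption, no description-logic constructs beyond subsumption,
  equivalence and hooks.
* No fuzzy matching, stemming or multilingual labels in the term index.
* The triple exchange format requires one CURIE prefix per hierarchy.
* Boolean composition of several user terms and hit ranking are out of
  scope; a homonym query deliberately returns no possible hits.
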