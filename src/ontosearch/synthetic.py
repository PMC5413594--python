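"""Synthetic ontologies, instances with known ground truth, and named fixtures.

The random generator emulates the structural features the query logic has to
cope with in real metadata: several dimensions each covered by one or more
parallel hierarchies, synonyms, homonym label collisions, equivalence links
near the roots of co-dimensional hierarchies, and cross-dimension hooks.
Every instance carries a hidden *true* leaf per dimension; the reported
annotation (when present) is an ancestor of that leaf at a random depth,
which models incomplete metadata annotation.

The named fixtures are small, hand-built logic fixtures — they deliberately
simplify real anatomy (e.g. stratum oriens is placed only under CA3) and
should never be read as anatomical references.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .annotations import AnnotationStore, Instance
from .model import Concept, Hierarchy, Ontology

__all__ = [
    "GeneratorParams",
    "GroundTruth",
    "generate_ontology",
    "generate_instances",
    "fixture",
    "sample_scenario",
    "FIXTURE_NAMES",
]

_DIMENSION_NAMES = ["species", "brain_region", "cell_type"]


@dataclass(frozen=True)
class GeneratorParams:
    """Knobs of the random ontology generator.

    Defaults produce a small two-dimension ontology with two parallel
    hierarchies per dimension, mild synonymy and rare homonymy — enough to
    exercise every reasoning path without dwarfing the fixtures.
    """

    n_dimensions: int = 2
    hierarchies_per_dimension: int = 2
    max_depth: int = 3
    max_branching: int = 3
    synonym_rate: float = 0.2
    homonym_rate: float = 0.05
    n_equivalences: int = 2
    n_hooks: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_dimensions", "hierarchies_per_dimension", "max_depth", "max_branching"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("n_equivalences", "n_hooks"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("synonym_rate", "homonym_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class GroundTruth:
    """Hidden per-instance truth: the true leaf and the reported depth.

    ``leaves[instance_id][dimension]`` is the concept the instance truly
    belongs to; ``reported_depth`` is the depth of the stored annotation on
    the leaf's root path, or ``None`` when the dimension was left
    unannotated.
    """

    leaves: dict[str, dict[str, str]] = field(default_factory=dict)
    reported_depth: dict[str, dict[str, int | None]] = field(default_factory=dict)


# ------------------------------------------------------------ random builder


def generate_ontology(params: GeneratorParams) -> Ontology:
    """Deterministic random ontology; identical seeds give identical output."""
    if params.n_equivalences > 0 and params.hierarchies_per_dimension < 2:
        raise ValueError(
            "equivalences need at least two hierarchies in some dimension"
        )
    if params.n_hooks > 0 and params.n_dimensions < 2:
        raise ValueError("hooks need at least two dimensions")
    rng = random.Random(params.seed)
    namespaces: dict[str, str] = {}
    hierarchies: list[Hierarchy] = []
    dim_hier_ids: dict[str, list[str]] = {}
    label_pool: list[str] = []
    counter = 0

    for d in range(params.n_dimensions):
        dim = (
            _DIMENSION_NAMES[d]
            if d < len(_DIMENSION_NAMES)
            else f"other:axis{d}"
        )
        dim_hier_ids[dim] = []
        for j in range(params.hierarchies_per_dimension):
            prefix = f"D{d}H{j}"
            namespaces[prefix] = f"http://ontosearch.dev/gen/{prefix}.owl#"
            concepts: list[Concept] = []

            def new_concept(parent: str | None, depth: int) -> str:
                nonlocal counter
                counter += 1
                cid = f"{prefix}:{counter:04d}"
                label = f"{prefix.lower()} node {counter}"
                synonyms: set[str] = set()
                if rng.random() < params.synonym_rate:
                    synonyms.add(f"{label} alias")
                if label_pool and rng.random() < params.homonym_rate:
                    synonyms.add(rng.choice(label_pool))
                concepts.append(
                    Concept(
                        id=cid,
                        preferred_label=label,
                        hierarchy=prefix,
                        parent=parent,
                        synonyms=frozenset(synonyms),
                    )
                )
                label_pool.append(label)
                if depth < params.max_depth:
                    # Lean towards small fan-outs; occasional leaves above
                    # max depth keep the trees ragged like real parcellations.
                    n_children = rng.randint(0 if depth > 0 else 1, params.max_branching)
                    for _ in range(n_children):
                        new_concept(cid, depth + 1)
                return cid

            new_concept(None, 0)
            hierarchies.append(
                Hierarchy(
                    id=prefix,
                    dimension=dim,
                    relation_kind=rng.choice(["is_a", "is_part_of"]),
                    concepts=tuple(concepts),
                )
            )
            dim_hier_ids[dim].append(prefix)

    # Equivalences: pair root-adjacent concepts (depth <= 1) of two parallel
    # hierarchies of one dimension; each concept joins at most one pair.
    equivalences: list[tuple[str, str]] = []
    used: set[str] = set()
    candidate_dims = [d for d, hs in dim_hier_ids.items() if len(hs) >= 2]
    by_id = {h.id: h for h in hierarchies}
    attempts = 0
    while len(equivalences) < params.n_equivalences and attempts < 200:
        attempts += 1
        dim = rng.choice(candidate_dims)
        ha, hb = rng.sample(dim_hier_ids[dim], 2)

        def near_root(hid: str) -> list[str]:
            h = by_id[hid]
            root = h.root().id
            return [c.id for c in h.concepts if c.parent is None or c.parent == root]

        a = rng.choice(near_root(ha))
        b = rng.choice(near_root(hb))
        if a in used or b in used:
            continue
        used.update((a, b))
        equivalences.append((a, b))
    if len(equivalences) < params.n_equivalences:
        raise ValueError(
            f"could not place {params.n_equivalences} equivalences "
            f"(placed {len(equivalences)}) with these parameters"
        )

    onto = Ontology(hierarchies, equivalences, (), namespaces)

    # Hooks: source in one dimension, target in another; a candidate is kept
    # only if every concept's implication closure stays free of disjoint
    # pairs, so generated annotations can always be consistent.
    hooks: list[tuple[str, str]] = []
    dims = list(dim_hier_ids)
    attempts = 0
    while len(hooks) < params.n_hooks and attempts < 400:
        attempts += 1
        src_dim, tgt_dim = rng.sample(dims, 2)
        src_h = by_id[rng.choice(dim_hier_ids[src_dim])]
        tgt_h = by_id[rng.choice(dim_hier_ids[tgt_dim])]
        source = rng.choice([c.id for c in src_h.concepts])
        tgt_root = tgt_h.root().id
        target = rng.choice(
            [c.id for c in tgt_h.concepts if c.parent is None or c.parent == tgt_root]
        )
        candidate = Ontology(hierarchies, equivalences, hooks + [(source, target)], namespaces)
        ok = True
        for c in candidate.concepts():
            closure = sorted(candidate.implication_closure(c.id))
            if any(
                candidate.is_disjoint(x, y)
                for i, x in enumerate(closure)
                for y in closure[i + 1 :]
            ):
                ok = False
                break
        if ok:
            hooks.append((source, target))
    if len(hooks) < params.n_hooks:
        raise ValueError(
            f"could not place {params.n_hooks} consistent hooks "
            f"(placed {len(hooks)}) with these parameters"
        )
    return Ontology(hierarchies, equivalences, hooks, namespaces)


def generate_instances(
    ontology: Ontology,
    n: int,
    specificity: dict[int, float] | None = None,
    unannotated_rate: float = 0.25,
    seed: int = 0,
) -> tuple[AnnotationStore, GroundTruth]:
    """Draw instances with hidden true leaves and partial annotations.

    Per instance and dimension: one hierarchy of the dimension is chosen,
    a true leaf is drawn uniformly among leaves consistent (through hooks)
    with the leaves already fixed for other dimensions, and the stored
    annotation is either absent (probability ``unannotated_rate``) or the
    leaf's ancestor at a depth drawn from ``specificity`` (a depth ->
    weight map, default uniform over the root path).
    """
    if not 0.0 <= unannotated_rate <= 1.0:
        raise ValueError("unannotated_rate must be in [0, 1]")
    rng = random.Random(seed)
    dims: dict[str, list[Hierarchy]] = {}
    for h in ontology.hierarchies:
        dims.setdefault(h.dimension, []).append(h)
    leaves_of: dict[str, list[str]] = {
        h.id: sorted(c.id for c in h.concepts if not ontology.children(c.id))
        for h in ontology.hierarchies
    }

    def consistent_with(chosen: list[str], candidate: str) -> bool:
        closure = set(ontology.implication_closure(candidate))
        for c in chosen:
            other = ontology.implication_closure(c)
            if any(ontology.is_disjoint(x, y) for x in other for y in closure):
                return False
        return True

    def root_path(curie: str) -> list[str]:
        path = [curie]
        c = ontology.concept(curie)
        while c.parent is not None:
            path.append(c.parent)
            c = ontology.concept(c.parent)
        return path[::-1]  # root first

    instances: list[Instance] = []
    truth = GroundTruth()
    for k in range(n):
        iid = f"inst{k:05d}"
        chosen: list[str] = []
        leaves: dict[str, str] = {}
        depths: dict[str, int | None] = {}
        annotations: dict[str, str] = {}
        for dim in sorted(dims):
            hierarchy = rng.choice(sorted(dims[dim], key=lambda h: h.id))
            pool = list(leaves_of[hierarchy.id])
            rng.shuffle(pool)
            leaf = next((c for c in pool if consistent_with(chosen, c)), None)
            if leaf is None:
                # No leaf fits the other dimensions (hook interplay); fall
                # back to any consistent concept, else leave the dimension out.
                inner = sorted(c.id for c in hierarchy.concepts)
                rng.shuffle(inner)
                leaf = next((c for c in inner if consistent_with(chosen, c)), None)
            if leaf is None:
                depths[dim] = None
                continue
            chosen.append(leaf)
            leaves[dim] = leaf
            if rng.random() < unannotated_rate:
                depths[dim] = None
                continue
            path = root_path(leaf)
            if specificity:
                weights = [specificity.get(d, 0.0) for d in range(len(path))]
                if sum(weights) <= 0:
                    weights = [1.0] * len(path)
            else:
                weights = [1.0] * len(path)
            depth = rng.choices(range(len(path)), weights=weights)[0]
            depths[dim] = depth
            annotations[hierarchy.id] = path[depth]
        truth.leaves[iid] = leaves
        truth.reported_depth[iid] = depths
        instances.append(Instance(id=iid, annotations=annotations))
    return AnnotationStore(ontology, instances), truth


def sample_scenario(seed: int) -> tuple[GeneratorParams, int]:
    """Draw one randomized test scenario: generator params + instance count.

    Used by the property suites: sizes vary per seed within a small regime
    (at most 6 hierarchies, depth <= 5, branching <= 4, up to 300 instances,
    skewed towards small ontologies so brute-force cross-checks stay cheap).
    """
    rng = random.Random(seed * 7919 + 13)
    ndim, hpd = rng.choice([(1, 1), (1, 2), (2, 1), (2, 2), (2, 3), (3, 1), (3, 2)])
    params = GeneratorParams(
        n_dimensions=ndim,
        hierarchies_per_dimension=hpd,
        max_depth=rng.choice([2, 3, 3, 4, 5]),
        max_branching=rng.choice([2, 2, 3, 4]),
        synonym_rate=0.2,
        homonym_rate=0.1,
        n_equivalences=rng.choice([0, 1, 2]) if hpd >= 2 else 0,
        n_hooks=rng.choice([0, 1, 2]) if ndim >= 2 else 0,
        seed=seed,
    )
    n_instances = rng.choice([10, 20, 50, 100, 300])
    return params, n_instances


# ----------------------------------------------------------- named fixtures


def _concepts(
    hierarchy_id: str,
    spec: list[tuple[str, str, str | None, tuple[str, ...]]],
) -> tuple[Concept, ...]:
    """spec rows: (curie, label, parent curie or None, synonyms)."""
    return tuple(
        Concept(
            id=cid,
            preferred_label=label,
            hierarchy=hierarchy_id,
            parent=parent,
            synonyms=frozenset(syns),
        )
        for cid, label, parent, syns in spec
    )


def _ns(*prefixes: str) -> dict[str, str]:
    return {p: f"http://ontosearch.dev/fixtures/{p}.owl#" for p in prefixes}


def _species_hierarchy(prefix: str = "SP") -> Hierarchy:
    p = prefix
    return Hierarchy(
        id=p,
        dimension="species",
        relation_kind="is_a",
        concepts=_concepts(
            p,
            [
                (f"{p}:0001", "animal", None, ()),
                (f"{p}:0002", "rodent", f"{p}:0001", ()),
                (f"{p}:0003", "mouse", f"{p}:0002", ()),
                (f"{p}:0004", "rat", f"{p}:0002", ("rattus",)),
                (f"{p}:0005", "Wistar", f"{p}:0004", ()),
                (f"{p}:0006", "Fischer", f"{p}:0004", ()),
                (f"{p}:0007", "Sprague–Dawley", f"{p}:0004", ()),
                (f"{p}:0008", "primate", f"{p}:0001", ()),
                (f"{p}:0009", "human", f"{p}:0008", ()),
            ],
        ),
    )


def _fixture_rodent_strains() -> tuple[Ontology, list[Instance]]:
    onto = Ontology([_species_hierarchy()], namespaces=_ns("SP"))
    instances = [
        Instance("i1", {"SP": "SP:0005"}),  # Wistar
        Instance("i2", {"SP": "SP:0007"}),  # Sprague–Dawley
        Instance("i3", {"SP": "SP:0004"}),  # rat
        Instance("i4", {"SP": "SP:0003"}),  # mouse
        Instance("i5", {"SP": "SP:0002"}),  # rodent
    ]
    return onto, instances


def _fixture_hippocampus_layers() -> tuple[Ontology, list[Instance]]:
    sub = Hierarchy(
        id="SUB",
        dimension="brain_region",
        relation_kind="is_part_of",
        concepts=_concepts(
            "SUB",
            [
                ("SUB:0001", "brain", None, ()),
                ("SUB:0002", "hippocampus", "SUB:0001", ()),
                ("SUB:0003", "CA1", "SUB:0002", ()),
                ("SUB:0004", "CA3", "SUB:0002", ()),
                ("SUB:0005", "CA3a", "SUB:0004", ()),
                ("SUB:0006", "CA3b", "SUB:0004", ()),
                ("SUB:0007", "CA3c", "SUB:0004", ()),
                ("SUB:0008", "DG", "SUB:0002", ()),
                ("SUB:0009", "suprapyramidal", "SUB:0008", ()),
                ("SUB:0010", "crest", "SUB:0008", ()),
                ("SUB:0011", "neocortex", "SUB:0001", ()),
            ],
        ),
    )
    lay = Hierarchy(
        id="LAY",
        dimension="brain_region",
        relation_kind="is_part_of",
        concepts=_concepts(
            "LAY",
            [
                ("LAY:0001", "brainL", None, ()),
                ("LAY:0002", "hippocampusL", "LAY:0001", ()),
                ("LAY:0003", "CA3L", "LAY:0002", ()),
                ("LAY:0004", "stratum oriens", "LAY:0003", ()),
                ("LAY:0005", "stratum lucidum", "LAY:0003", ()),
                ("LAY:0006", "stratum radiatum", "LAY:0003", ()),
                ("LAY:0007", "DGL", "LAY:0002", ()),
                ("LAY:0008", "stratum moleculare", "LAY:0007", ("molecular layer",)),
                ("LAY:0009", "inner molecular layer", "LAY:0008", ()),
                ("LAY:0010", "outer molecular layer", "LAY:0008", ()),
                ("LAY:0011", "stratum granulosum", "LAY:0007", ()),
                ("LAY:0012", "hilus", "LAY:0007", ()),
            ],
        ),
    )
    onto = Ontology(
        [sub, lay],
        equivalences=[
            ("SUB:0001", "LAY:0001"),  # brain ≡ brainL
            ("SUB:0002", "LAY:0002"),  # hippocampus ≡ hippocampusL
            ("SUB:0004", "LAY:0003"),  # CA3 ≡ CA3L
            ("SUB:0008", "LAY:0007"),  # DG ≡ DGL
        ],
        namespaces=_ns("SUB", "LAY"),
    )
    instances = [
        Instance("n1", {"SUB": "SUB:0005"}),  # CA3a
        Instance("n2", {"SUB": "SUB:0004", "LAY": "LAY:0005"}),  # CA3 + s. lucidum
        Instance("n3", {"LAY": "LAY:0004"}),  # stratum oriens
        Instance("n4", {"SUB": "SUB:0002"}),  # hippocampus
        Instance("n5", {"SUB": "SUB:0008", "LAY": "LAY:0012"}),  # DG + hilus
        Instance("n6", {"SUB": "SUB:0011"}),  # neocortex
        Instance("n7", {"LAY": "LAY:0009"}),  # inner molecular layer
        Instance("n8", {"SUB": "SUB:0010"}),  # crest
    ]
    return onto, instances


def _fixture_fronto_insula() -> tuple[Ontology, list[Instance]]:
    reg = Hierarchy(
        id="REG",
        dimension="brain_region",
        relation_kind="is_part_of",
        concepts=_concepts(
            "REG",
            [
                ("REG:0001", "brain", None, ()),
                ("REG:0002", "neocortex", "REG:0001", ()),
                ("REG:0003", "insula", "REG:0002", ()),
                ("REG:0004", "fronto-insula", "REG:0003", ()),
            ],
        ),
    )
    onto = Ontology(
        [reg, _species_hierarchy()],
        hooks=[("REG:0004", "SP:0009")],  # fronto-insula -> human
        namespaces=_ns("REG", "SP"),
    )
    instances = [
        Instance("h1", {"REG": "REG:0004"}),
        Instance("h2", {"REG": "REG:0003", "SP": "SP:0009"}),
        Instance("h3", {"REG": "REG:0003", "SP": "SP:0004"}),
        Instance("h4", {"REG": "REG:0003"}),
        Instance("h5", {"REG": "REG:0002", "SP": "SP:0009"}),
    ]
    return onto, instances


def _fixture_purkinje_hook() -> tuple[Ontology, list[Instance]]:
    reg = Hierarchy(
        id="REG",
        dimension="brain_region",
        relation_kind="is_part_of",
        concepts=_concepts(
            "REG",
            [
                ("REG:0001", "brain", None, ()),
                ("REG:0002", "cerebellum", "REG:0001", ()),
                ("REG:0003", "neocortex", "REG:0001", ()),
            ],
        ),
    )
    cells = Hierarchy(
        id="CT",
        dimension="cell_type",
        relation_kind="is_a",
        concepts=_concepts(
            "CT",
            [
                ("CT:0001", "neuron", None, ()),
                ("CT:0002", "Purkinje", "CT:0001", ()),
                ("CT:0003", "granule cell", "CT:0001", ()),
                ("CT:0004", "pyramidal", "CT:0001", ()),
            ],
        ),
    )
    onto = Ontology(
        [reg, cells],
        hooks=[("CT:0002", "REG:0002")],  # Purkinje -> cerebellum
        namespaces=_ns("REG", "CT"),
    )
    instances = [
        Instance("c1", {"CT": "CT:0002"}),
        Instance("c2", {"REG": "REG:0002"}),
        Instance("c3", {"REG": "REG:0002", "CT": "CT:0003"}),
        Instance("c4", {"REG": "REG:0003"}),
    ]
    return onto, instances


def _fixture_granule_homonym() -> tuple[Ontology, list[Instance]]:
    reg = Hierarchy(
        id="REG",
        dimension="brain_region",
        relation_kind="is_part_of",
        concepts=_concepts(
            "REG",
            [
                ("REG:0001", "brain", None, ()),
                ("REG:0002", "cerebellar cortex", "REG:0001", ()),
                ("REG:0003", "stratum granulare", "REG:0002", ("granule layer",)),
                ("REG:0004", "dentate gyrus", "REG:0001", ()),
                ("REG:0005", "granule layer", "REG:0004", ()),
                ("REG:0006", "olfactory bulb", "REG:0001", ()),
                ("REG:0007", "granule cell layer of olfactory bulb", "REG:0006", ("granule layer",)),
            ],
        ),
    )
    onto = Ontology([reg], namespaces=_ns("REG"))
    instances = [
        Instance("g1", {"REG": "REG:0003"}),
        Instance("g2", {"REG": "REG:0005"}),
        Instance("g3", {"REG": "REG:0007"}),
        Instance("g4", {"REG": "REG:0002"}),
    ]
    return onto, instances


def _fixture_class_iii_cuticle() -> tuple[Ontology, list[Instance]]:
    body = Hierarchy(
        id="BODY",
        dimension="brain_region",
        relation_kind="is_part_of",
        concepts=_concepts(
            "BODY",
            [
                ("BODY:0001", "body", None, ()),
                ("BODY:0002", "cuticle", "BODY:0001", ()),
            ],
        ),
    )
    cells = Hierarchy(
        id="CT",
        dimension="cell_type",
        relation_kind="is_a",
        concepts=_concepts(
            "CT",
            [
                ("CT:0001", "neuron", None, ()),
                ("CT:0002", "multidendritic DA", "CT:0001", ()),
                ("CT:0003", "class I", "CT:0002", ()),
                ("CT:0004", "class II", "CT:0002", ()),
                ("CT:0005", "class III", "CT:0002", ()),
                ("CT:0006", "VdaD", "CT:0005", ()),
                ("CT:0007", "class IV", "CT:0002", ()),
            ],
        ),
    )
    onto = Ontology(
        [body, cells],
        hooks=[("CT:0005", "BODY:0002")],  # class III -> cuticle
        namespaces=_ns("BODY", "CT"),
    )
    instances = [
        Instance("d1", {"CT": "CT:0006"}),  # VdaD
        Instance("d2", {"CT": "CT:0005"}),  # class III
        Instance("d3", {"CT": "CT:0002"}),  # multidendritic DA
        Instance("d4", {"BODY": "BODY:0002"}),  # cuticle
        Instance("d5", {"BODY": "BODY:0001"}),  # body
        Instance("d6", {"CT": "CT:0007"}),  # class IV
    ]
    return onto, instances


_FIXTURES = {
    "rodent_strains": _fixture_rodent_strains,
    "hippocampus_layers": _fixture_hippocampus_layers,
    "fronto_insula": _fixture_fronto_insula,
    "purkinje_hook": _fixture_purkinje_hook,
    "granule_homonym": _fixture_granule_homonym,
    "class_iii_cuticle": _fixture_class_iii_cuticle,
}

FIXTURE_NAMES = tuple(sorted(_FIXTURES))


def fixture(name: str) -> tuple[Ontology, list[Instance]]:
    """One of the six named worked-example fixtures.

    Available: ``rodent_strains``, ``hippocampus_layers``, ``fronto_insula``,
    ``purkinje_hook``, ``granule_homonym``, ``class_iii_cuticle``.
    """
    try:
        build = _FIXTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown fixture {name!r}; choose from {', '.join(FIXTURE_NAMES)}"
        ) from None
    return build()
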