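"""Curation-checked annotation, effective annotations and context menus."""

import json

import pytest

from ontosearch import (
    AnnotationStore,
    Concept,
    Hierarchy,
    Instance,
    Ontology,
    UnknownHierarchyError,
    fixture,
    generate_ontology,
    sample_scenario,
)


def _frog_store():
    """Species tree with 'edible green frog' carrying a Latin synonym."""
    h = Hierarchy(
        id="SP", dimension="species", relation_kind="is_a",
        concepts=(
            Concept("SP:1", "animal", "SP"),
            Concept("SP:2", "amphibian", "SP", "SP:1"),
            Concept(
                "SP:3", "edible green frog", "SP", "SP:2",
                synonyms=frozenset({"Pelophylax esculentus"}),
            ),
        ),
    )
    onto = Ontology([h], namespaces={"SP": "http://ontosearch.dev/test/SP.owl#"})
    return AnnotationStore(onto, [Instance("x")])


def _mushroom_body_store():
    """Region hierarchy with an insect-only structure hooked to fruit fly."""
    species = Hierarchy(
        id="SP", dimension="species", relation_kind="is_a",
        concepts=(
            Concept("SP:1", "animal", "SP"),
            Concept("SP:2", "mouse", "SP", "SP:1"),
            Concept("SP:3", "fruit fly", "SP", "SP:1"),
        ),
    )
    regions = Hierarchy(
        id="REG", dimension="brain_region", relation_kind="is_part_of",
        concepts=(
            Concept("REG:1", "brain", "REG"),
            Concept("REG:2", "mushroom body", "REG", "REG:1"),
            Concept("REG:3", "neocortex", "REG", "REG:1"),
        ),
    )
    onto = Ontology(
        [species, regions],
        hooks=[("REG:2", "SP:3")],
        namespaces={
            "SP": "http://ontosearch.dev/test/SP.owl#",
            "REG": "http://ontosearch.dev/test/REG.owl#",
        },
    )
    return AnnotationStore(onto, [Instance("m1", {"SP": "SP:2"})])


class TestAnnotate:
    def test_synonym_maps_to_existing_concept_without_minting_one(self):
        store = _frog_store()
        n_before = len(store.ontology)
        report = store.annotate("x", "Pelophylax esculentus")
        assert report.action == "mapped_to_preferred"
        assert report.resolved == "SP:3"
        assert store.instance("x").annotations["SP"] == "SP:3"
        assert len(store.ontology) == n_before

    def test_preferred_label_is_accepted_as_is(self):
        store = _frog_store()
        report = store.annotate("x", "edible green frog")
        assert report.action == "accepted"
        assert report.resolved == "SP:3"

    def test_preferred_and_synonym_store_the_same_concept(self):
        via_synonym = _frog_store()
        via_synonym.annotate("x", "Pelophylax esculentus")
        via_label = _frog_store()
        via_label.annotate("x", "edible green frog")
        assert (
            via_synonym.instance("x").annotations
            == via_label.instance("x").annotations
        )

    def test_homonym_term_is_rejected_until_disambiguated(self):
        onto, instances = fixture("granule_homonym")
        store = AnnotationStore(onto, [Instance("x")])
        report = store.annotate("x", "granule layer")
        assert report.action == "rejected_homonym"
        assert store.instance("x").annotations == {}
        explicit = store.annotate_concept("x", "REG:0005")
        assert explicit.action == "accepted"
        assert store.instance("x").annotations == {"REG": "REG:0005"}

    def test_disjoint_annotation_is_rejected(self):
        onto, _ = fixture("rodent_strains")
        store = AnnotationStore(onto, [Instance("i1", {"SP": "SP:0005"})])  # Wistar
        report = store.annotate("i1", "mouse")
        assert report.action == "rejected_conflict"
        assert store.instance("i1").annotations == {"SP": "SP:0005"}

    def test_ancestor_of_existing_is_redundant(self):
        onto, _ = fixture("rodent_strains")
        store = AnnotationStore(onto, [Instance("i1", {"SP": "SP:0005"})])
        report = store.annotate("i1", "rodent")
        assert report.action == "rejected_redundant"

    def test_descendant_replaces_only_with_refine_flag(self):
        onto, _ = fixture("rodent_strains")
        store = AnnotationStore(onto, [Instance("i3", {"SP": "SP:0004"})])  # rat
        rejected = store.annotate("i3", "Wistar")
        assert rejected.action == "rejected_redundant"
        assert store.instance("i3").annotations == {"SP": "SP:0004"}
        refined = store.annotate("i3", "Wistar", refine=True)
        assert refined.action == "accepted"
        assert store.instance("i3").annotations == {"SP": "SP:0005"}

    def test_merged_duplicate_across_hierarchies_is_redundant(self):
        onto, _ = fixture("hippocampus_layers")
        store = AnnotationStore(onto, [Instance("n", {"SUB": "SUB:0002"})])
        report = store.annotate("n", "hippocampusL")
        assert report.action == "rejected_redundant"

    def test_cross_hierarchy_refinement_through_equivalence_is_meaningful(self):
        # SUB:CA3 plus LAY:stratum lucidum may coexist (fixture n2 does)
        onto, _ = fixture("hippocampus_layers")
        store = AnnotationStore(onto, [Instance("n", {"SUB": "SUB:0004"})])
        report = store.annotate("n", "stratum lucidum")
        assert report.action == "accepted"
        assert store.instance("n").annotations == {
            "SUB": "SUB:0004", "LAY": "LAY:0005",
        }

    def test_hook_conflict_across_dimensions_is_rejected(self):
        store = _mushroom_body_store()
        report = store.annotate("m1", "mushroom body")  # hooked to fruit fly
        assert report.action == "rejected_conflict"

    def test_unknown_term_is_reported_not_raised(self):
        store = _frog_store()
        report = store.annotate("x", "unicorn")
        assert report.action == "unknown_term"
        assert not report.stored

    @pytest.mark.parametrize("seed", [1, 11, 29])
    def test_random_annotate_sequences_never_break_instance_invariants(self, seed):
        import random

        params, _ = sample_scenario(seed)
        onto = generate_ontology(params)
        store = AnnotationStore(onto, [Instance("x")])
        rng = random.Random(seed)
        terms = [e.surface_form for e in store.index.entries()]
        for term in rng.sample(terms, min(40, len(terms))):
            store.annotate("x", term, refine=rng.random() < 0.5)
        inst = store.instance("x")
        annotated = sorted(inst.annotations.items())
        for hid, cid in annotated:
            assert onto.concept(cid).hierarchy == hid
        for _, a in annotated:
            for _, b in annotated:
                assert not onto.is_disjoint(a, b)


class TestEffectiveAnnotation:
    def test_unannotated_hierarchy_defaults_to_root(self, hippocampus):
        store = hippocampus.store
        assert store.effective_annotation("n4", "LAY") == "LAY:0001"

    def test_annotated_hierarchy_returns_the_annotation(self, hippocampus):
        assert hippocampus.store.effective_annotation("n2", "LAY") == "LAY:0005"

    def test_unknown_hierarchy_raises(self, hippocampus):
        with pytest.raises(UnknownHierarchyError):
            hippocampus.store.effective_annotation("n2", "NOPE")

    def test_result_always_belongs_to_the_hierarchy(self, any_fixture):
        _, onto, instances = any_fixture
        store = AnnotationStore(onto, instances)
        for inst in store:
            for h in onto.hierarchies:
                effective = store.effective_annotation(inst.id, h.id)
                assert onto.concept(effective).hierarchy == h.id


class TestSuggestOptions:
    def test_hooked_insect_region_excluded_for_a_mouse(self):
        store = _mushroom_body_store()
        options = store.suggest_options("m1", "REG")
        assert "REG:2" not in options  # mushroom body
        assert {"REG:1", "REG:3"} <= options

    def test_purkinje_excluded_for_neocortex_instance(self, purkinje):
        onto = purkinje.ontology
        store = AnnotationStore(onto, [Instance("n", {"REG": "REG:0003"})])
        options = store.suggest_options("n", "CT")
        assert "CT:0002" not in options  # Purkinje hooks to cerebellum
        assert {"CT:0001", "CT:0003", "CT:0004"} <= options

    def test_unannotated_instance_sees_every_concept(self, purkinje):
        onto = purkinje.ontology
        store = AnnotationStore(onto, [Instance("n")])
        for h in onto.hierarchies:
            assert store.suggest_options("n", h.id) == set(h.concept_ids)

    def test_root_is_always_offered_to_consistent_instances(self, any_fixture):
        _, onto, instances = any_fixture
        store = AnnotationStore(onto, instances)
        for inst in store:
            for h in onto.hierarchies:
                assert onto.root_of(h.id) in store.suggest_options(inst.id, h.id)


class TestJsonLines:
    def test_round_trip_preserves_unknown_keys(self, tmp_path):
        onto, instances = fixture("rodent_strains")
        instances[0].extra["archive_note"] = {"curated": True}
        instances[0].attributes["archive"] = "labX"
        store = AnnotationStore(onto, instances)
        path = tmp_path / "instances.jsonl"
        store.write_jsonl(path)
        reread = AnnotationStore.read_jsonl(path, onto)
        assert [i.to_json_dict() for i in reread] == [i.to_json_dict() for i in store]

    def test_terms_in_files_are_resolved_to_curies(self, tmp_path):
        onto, _ = fixture("rodent_strains")
        path = tmp_path / "instances.jsonl"
        path.write_text(
            json.dumps({"id": "a", "annotations": {"SP": "rattus"}}) + "\n",
            encoding="utf-8",
        )
        store = AnnotationStore.read_jsonl(path, onto)
        assert store.instance("a").annotations == {"SP": "SP:0004"}

    def test_ambiguous_term_in_file_is_an_error(self, tmp_path):
        from ontosearch import FormatError

        onto, _ = fixture("granule_homonym")
        path = tmp_path / "instances.jsonl"
        path.write_text(
            json.dumps({"id": "a", "annotations": {"REG": "granule layer"}}) + "\n",
            encoding="utf-8",
        )
        with pytest.raises(FormatError):
            AnnotationStore.read_jsonl(path, onto)
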