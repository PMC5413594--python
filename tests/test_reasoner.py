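"""Direct/possible hit logic, homonym queries, grouping, oracle agreement."""

import pytest

from ontosearch import (
    AnnotationStore,
    Instance,
    OntoSearch,
    UnknownTermError,
    generate_instances,
    generate_ontology,
    oracle_query,
    sample_scenario,
)


class TestEntailment:
    def test_hook_membership_is_entailed(self, purkinje):
        assert "REG:0002" in purkinje.entailed_set("c1")  # Purkinje -> cerebellum
        assert purkinje.entails("c1", "REG:0002")

    def test_unannotated_instance_entails_nothing(self, purkinje):
        store = AnnotationStore(purkinje.ontology, [Instance("empty")])
        engine = OntoSearch(purkinje.ontology, store)
        assert engine.entailed_set("empty") == frozenset()

    def test_entailed_set_is_the_union_of_annotation_closures(self, hippocampus):
        onto = hippocampus.ontology
        expected = onto.implication_closure("SUB:0004") | onto.implication_closure("LAY:0005")
        assert hippocampus.entailed_set("n2") == expected

    def test_ancestor_chain_entailment(self, rodents):
        assert rodents.entails("i1", "SP:0002")  # Wistar entails rodent

    def test_parent_annotation_does_not_entail_a_child(self, rodents):
        assert not rodents.entails("i3", "SP:0005")  # rat does not entail Wistar


class TestConsistency:
    def test_disjoint_sibling_strain_is_inconsistent(self, rodents):
        assert not rodents.consistent("i2", "SP:0005")  # Sprague–Dawley vs Wistar

    def test_hooked_species_excludes_other_species(self, insula):
        assert not insula.consistent("h3", "REG:0004")  # rat insula vs fronto-insula

    def test_unannotated_instance_is_consistent_with_everything(self, insula):
        store = AnnotationStore(insula.ontology, [Instance("empty")])
        engine = OntoSearch(insula.ontology, store)
        for c in insula.ontology.concepts():
            assert engine.consistent("empty", c.id)


class TestHits:
    def test_direct_hits_include_descendants_and_self(self, rodents):
        assert rodents.direct_hits("SP:0004") == {"i1", "i2", "i3"}

    def test_root_query_collects_every_annotated_instance(self, rodents):
        assert rodents.direct_hits("SP:0001") == {"i1", "i2", "i3", "i4", "i5"}

    def test_hook_entailed_instance_is_a_direct_hit_of_the_target(self, purkinje):
        assert purkinje.direct_hits("REG:0002") == {"c1", "c2", "c3"}

    def test_possible_hits_exclude_disjoint_siblings(self, rodents):
        assert rodents.possible_hits("SP:0005") == {"i3", "i5"}

    def test_possible_hits_through_equivalence(self, hippocampus):
        # CA3a counts via CA3≡CA3L; hippocampus-level counts; disjoint layers,
        # DG/hilus and neocortex are excluded
        assert hippocampus.direct_hits("LAY:0005") == {"n2"}
        assert hippocampus.possible_hits("LAY:0005") == {"n1", "n4"}

    def test_orthogonal_subregions_stay_possible(self, hippocampus):
        # crest is in the sub-region tree, orthogonal to the layer query;
        # hilus and stratum granulosum are disjoint layers
        assert hippocampus.possible_hits("LAY:0008") == {"n4", "n8"}

    def test_possible_hits_of_purkinje_is_unspecified_cerebellar(self, purkinje):
        assert purkinje.possible_hits("CT:0002") == {"c2"}


class TestQuery:
    def test_homonym_query_unions_direct_and_suppresses_possible(self, granule):
        result = granule.query("granule layer")
        assert result.is_homonym
        assert result.direct == {"g1", "g2", "g3"}
        assert result.possible == frozenset()

    def test_hooked_query_excludes_wrong_species(self, insula):
        result = insula.query("fronto-insula")
        assert result.direct == {"h1"}
        assert result.possible == {"h2", "h4", "h5"}

    def test_subtype_query_with_hook(self, cuticle):
        result = cuticle.query("class III")
        assert result.direct == {"d1", "d2"}
        assert result.possible == {"d3", "d4", "d5"}

    def test_unknown_term_raises_with_suggestions(self, hippocampus):
        with pytest.raises(UnknownTermError) as excinfo:
            hippocampus.query("stratum lucidorum")
        assert 1 <= len(excinfo.value.suggestions) <= 5

    def test_json_export_shape(self, rodents):
        import json

        result = rodents.query("Wistar")
        payload = json.loads(result.to_json())
        assert payload == {
            "term": "Wistar",
            "matched_concepts": ["SP:0005"],
            "is_homonym": False,
            "direct": ["i1"],
            "possible": ["i3", "i5"],
        }


class TestGrouping:
    def test_species_grouping_at_depth_one(self, rodents):
        result = rodents.query("rattus")
        grouped = rodents.group_results(result, "SP")
        assert grouped.direct == {"SP:0002": 3}  # all three under rodent
        assert grouped.possible == {"SP:0002": 1}  # the rodent-level instance
        assert grouped.total() == len(result.direct) + len(result.possible)

    def test_empty_result_groups_to_nothing(self, granule):
        result = granule.query("granule layer")
        # group by a hierarchy once the result has no hits at all
        empty = type(result)(
            term=result.term, matched_concepts=result.matched_concepts,
            direct=frozenset(), possible=frozenset(), is_homonym=True,
        )
        grouped = granule.group_results(empty, "REG")
        assert grouped.direct == {} and grouped.possible == {}

    def test_unspecified_bucket_for_other_dimension(self, purkinje):
        result = purkinje.query("cerebellum")
        grouped = purkinje.group_results(result, "CT")
        # c1 annotated Purkinje (depth-1 under neuron); c2 unannotated in CT
        assert grouped.direct == {"CT:0002": 1, "CT:0003": 1, "unspecified": 1}

    def test_counts_are_conserved(self, any_fixture):
        name, onto, instances = any_fixture
        engine = OntoSearch(onto, AnnotationStore(onto, instances))
        for entry in engine.index.entries():
            result = engine.query(entry.surface_form)
            for h in onto.hierarchies:
                grouped = engine.group_results(result, h.id)
                assert grouped.total() == len(result.direct) + len(result.possible)


class TestOracleAgreement:
    def test_engine_equals_oracle_on_every_fixture_term(self, any_fixture):
        _, onto, instances = any_fixture
        store = AnnotationStore(onto, instances)
        engine = OntoSearch(onto, store)
        for entry in store.index.entries():
            term = entry.surface_form
            fast = engine.query(term)
            slow = oracle_query(onto, store, term)
            assert fast.matched_concepts == slow.matched_concepts
            assert fast.direct == slow.direct
            assert fast.possible == slow.possible

    @pytest.mark.parametrize("seed", range(0, 40, 4))
    def test_engine_equals_oracle_on_random_ontologies(self, seed):
        params, n = sample_scenario(seed)
        onto = generate_ontology(params)
        store, _ = generate_instances(onto, n=min(n, 50), seed=seed + 1)
        engine = OntoSearch(onto, store)
        for entry in store.index.entries():
            fast = engine.query(entry.surface_form)
            slow = oracle_query(onto, store, entry.surface_form)
            assert fast.direct == slow.direct
            assert fast.possible == slow.possible


class TestInvariants:
    @pytest.mark.parametrize("seed", [2, 19, 33])
    def test_direct_and_possible_are_disjoint_and_monotone(self, seed):
        params, n = sample_scenario(seed)
        onto = generate_ontology(params)
        store, _ = generate_instances(onto, n=min(n, 60), seed=seed + 1)
        engine = OntoSearch(onto, store)
        for c in onto.concepts():
            direct = engine.direct_hits(c.id)
            assert not direct & engine.possible_hits(c.id)
            for anc in onto.ancestors(c.id):
                assert direct <= engine.direct_hits(anc)

    @pytest.mark.parametrize("seed", [5, 23])
    def test_root_query_completeness(self, seed):
        params, n = sample_scenario(seed)
        onto = generate_ontology(params)
        store, _ = generate_instances(onto, n=min(n, 60), seed=seed + 1)
        engine = OntoSearch(onto, store)
        for h in onto.hierarchies:
            root = onto.root_of(h.id)
            direct = engine.direct_hits(root)
            possible = engine.possible_hits(root)
            for inst in store:
                if h.id in inst.annotations:
                    assert inst.id in direct
                    assert inst.id not in possible

    @pytest.mark.parametrize("seed", [7, 31])
    def test_ground_truth_containment(self, seed):
        """Every instance is in D or P of each concept on its true leaf's path."""
        params, n = sample_scenario(seed)
        onto = generate_ontology(params)
        store, truth = generate_instances(onto, n=min(n, 60), seed=seed + 1)
        engine = OntoSearch(onto, store)
        for iid, leaves in truth.leaves.items():
            for leaf in leaves.values():
                for c in onto.ancestors(leaf):
                    assert engine.entails(iid, c) or engine.consistent(iid, c)
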