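import math

import numpy as np
import pytest
from hypothesis import HealthCheck, given, settings
from hypothesis import strategies as st

from genecontent import (
    BirthDeathParams,
    InputError,
    ancestral_hgs,
    classify_all,
    core_filter,
    lost_hgs,
    mrca,
    novel_hgs,
    presence_at_node,
    simulate_hg_histories,
    summarize,
)
from genecontent.classify import integer_percentage, percentage

from helpers import all_possessor_patterns, occ_from_patterns
from oracle_dollo import oracle_classify


class TestPresenceAtNode:
    def test_full_possession_present_everywhere(self, tree5):
        everyone = set(tree5.leaf_names)
        for node in tree5.labels:
            for mode in ("dollo", "two_lineage"):
                assert presence_at_node(tree5, everyone, node, mode)

    def test_single_possessor_present_only_at_that_leaf(self, tree5):
        for node in tree5.labels:
            for mode in ("dollo", "two_lineage"):
                assert presence_at_node(tree5, {"C"}, node, mode) == (node == "C")

    def test_outgroup_witness_separates_the_modes(self, tree5):
        # possessors {C, D, E}: gained at R, lost in M
        poss = {"C", "D", "E"}
        dollo_present = {n for n in tree5.labels if presence_at_node(tree5, poss, n, "dollo")}
        assert dollo_present == {"R", "P", "O", "C", "D", "E"}
        two_lineage = {
            n
            for n in tree5.labels
            if presence_at_node(tree5, poss, n, "two_lineage")
        }
        assert two_lineage == {"R", "O", "C", "D", "E"}

    def test_unknown_inputs_rejected(self, tree5):
        with pytest.raises(InputError):
            presence_at_node(tree5, {"Z"}, "P")
        with pytest.raises(InputError):
            presence_at_node(tree5, {"A"}, "P", mode="parsimony")


class TestAncestral:
    def test_present_in_both_children_is_ancestral_in_both_modes(self, tree4):
        occ = occ_from_patterns(tree4, {"HG1": {"A", "C"}})
        for mode in ("dollo", "two_lineage"):
            assert ancestral_hgs(tree4, occ, "R", mode) == {"HG1"}

    def test_one_lineage_plus_outgroup_splits_the_modes(self, tree5):
        # inside P only via clade M, but witnessed outside by E
        occ = occ_from_patterns(tree5, {"HG1": {"A", "B", "E"}})
        assert ancestral_hgs(tree5, occ, "P", "dollo") == {"HG1"}
        assert ancestral_hgs(tree5, occ, "P", "two_lineage") == frozenset()

    def test_all_zero_occupancy_gives_empty_set(self, tree4):
        occ = occ_from_patterns(tree4, {"HG1": set()})
        assert ancestral_hgs(tree4, occ, "R") == frozenset()

    def test_leaf_rejected(self, tree4):
        occ = occ_from_patterns(tree4, {"HG1": {"A"}})
        with pytest.raises(InputError, match="internal"):
            ancestral_hgs(tree4, occ, "A")


class TestNovel:
    def test_clade_exclusive_hg_is_novel_at_its_mrca(self, tree4):
        occ = occ_from_patterns(tree4, {"HG1": {"A", "B"}})
        assert novel_hgs(tree4, occ, "M") == {"HG1"}
        assert novel_hgs(tree4, occ, "R") == frozenset()

    def test_universal_hg_is_novel_at_root_only(self, tree4):
        occ = occ_from_patterns(tree4, {"HG1": set(tree4.leaf_names)})
        assert novel_hgs(tree4, occ, "R") == {"HG1"}
        for node in ("M", "O", "A"):
            assert novel_hgs(tree4, occ, node) == frozenset()

    def test_species_exclusive_hg_is_novel_at_the_leaf(self, tree4):
        occ = occ_from_patterns(tree4, {"HG1": {"B"}, "HG2": {"B", "C"}})
        assert novel_hgs(tree4, occ, "B") == {"HG1"}

    def test_every_possessed_hg_is_novel_at_exactly_one_node(self, tree5):
        patterns = {f"HG{i}": poss for i, poss in enumerate(all_possessor_patterns(tree5))}
        occ = occ_from_patterns(tree5, patterns)
        for hg, poss in patterns.items():
            origins = [n for n in tree5.labels if hg in novel_hgs(tree5, occ, n)]
            assert origins == [mrca(tree5, poss)]


class TestCoreFilter:
    def test_full_presence_retained(self, tree4):
        occ = occ_from_patterns(tree4, {"HG1": {"A", "B", "C", "D"}})
        assert core_filter(tree4, occ, "R", {"HG1"}) == {"HG1"}

    def test_two_absences_dropped_with_one_allowed(self, tree5):
        # {A, C} occupies both lineages of P but is absent in B and D
        occ = occ_from_patterns(tree5, {"HG1": {"A", "C"}})
        assert core_filter(tree5, occ, "P", {"HG1"}, allowed_absences=1) == frozenset()
        assert core_filter(tree5, occ, "P", {"HG1"}, allowed_absences=2) == {"HG1"}

    def test_unbalanced_clade_rule_application(self):
        # clade (A,(B,C)): one absence tolerated only if both child
        # lineages keep a possessor
        from genecontent import SpeciesTree

        tree = SpeciesTree.from_newick("((A,(B,C)Inner)Clade,out)R;")
        occ = occ_from_patterns(tree, {"HGab": {"A", "B"}, "HGbc": {"B", "C"}})
        kept = core_filter(tree, occ, "Clade", {"HGab", "HGbc"})
        assert kept == {"HGab"}

    def test_lineage_condition_can_be_relaxed(self):
        from genecontent import SpeciesTree

        tree = SpeciesTree.from_newick("((A,(B,C)Inner)Clade,out)R;")
        occ = occ_from_patterns(tree, {"HGbc": {"B", "C"}})
        kept = core_filter(
            tree, occ, "Clade", {"HGbc"}, require_two_lineages=False
        )
        assert kept == {"HGbc"}

    def test_negative_allowance_rejected(self, tree4):
        occ = occ_from_patterns(tree4, {"HG1": {"A"}})
        with pytest.raises(InputError):
            core_filter(tree4, occ, "R", {"HG1"}, allowed_absences=-1)


class TestLost:
    def test_loss_witnessed_by_sibling_and_outgroup(self, tree5):
        occ = occ_from_patterns(tree5, {"HG1": {"C", "D", "E"}})
        assert lost_hgs(tree5, occ, "M") == {"HG1"}

    def test_never_present_at_parent_is_not_lost(self, tree5):
        # novel at O; P never had it, so M cannot have lost it
        occ = occ_from_patterns(tree5, {"HG1": {"C", "D"}})
        assert lost_hgs(tree5, occ, "M") == frozenset()

    def test_present_inside_clade_never_lost(self, tree5):
        occ = occ_from_patterns(tree5, {"HG1": {"A", "C", "E"}})
        assert lost_hgs(tree5, occ, "M") == frozenset()

    def test_root_rejected_and_root_children_defined_empty(self, tree5, caplog):
        occ = occ_from_patterns(tree5, {"HG1": {"C", "D", "E"}})
        with pytest.raises(InputError, match="root"):
            lost_hgs(tree5, occ, "R")
        with caplog.at_level("WARNING", logger="genecontent.classify"):
            assert lost_hgs(tree5, occ, "P") == frozenset()
        assert "root" in caplog.text


class TestClassifyAll:
    def test_empty_occupancy_all_sets_empty(self, tree5):
        occ = occ_from_patterns(tree5, {"HG1": set(), "HG2": set()})
        result = classify_all(tree5, occ)
        for _, cats in result.items():
            for cat in ("ancestral", "novel", "novel_core", "ancestral_core", "lost"):
                assert cats.get(cat) == frozenset()

    def test_species_mismatch_lists_offenders(self, tree4):
        occ = occ_from_patterns(tree4, {"HG1": {"A"}})
        occ = occ.rename(columns={"D": "Zebra"})
        with pytest.raises(InputError, match="Zebra") as err:
            classify_all(tree4, occ)
        assert "D" in str(err.value)

    def test_lossless_simulation_recovers_every_origin(self, tree5):
        occ, truth = simulate_hg_histories(
            tree5, BirthDeathParams(origins_per_branch=30, loss_prob=0.0, seed=21)
        )
        result = classify_all(tree5, occ)
        for node in tree5.labels:
            expected = {hg for hg, o in truth.origin.items() if o == node}
            assert result[node].novel == expected

    def test_agrees_with_bruteforce_oracle_on_all_patterns(self, tree5):
        patterns = {
            f"HG{i}": poss for i, poss in enumerate(all_possessor_patterns(tree5))
        }
        occ = occ_from_patterns(tree5, patterns)
        expected = oracle_classify(tree5, patterns)
        for mode, anc_key, core_key in (
            ("dollo", "ancestral_dollo", "ancestral_core_dollo"),
            ("two_lineage", "ancestral_two_lineage", "ancestral_core_two_lineage"),
        ):
            result = classify_all(tree5, occ, mode=mode)
            for node in tree5.labels:
                cats = result[node]
                assert cats.novel == expected[node]["novel"], (mode, node)
                assert cats.lost == expected[node]["lost"], (mode, node)
                if not tree5.is_leaf(node):
                    assert cats.ancestral == expected[node][anc_key], (mode, node)
                    assert cats.novel_core == expected[node]["novel_core"], (mode, node)
                    assert cats.ancestral_core == expected[node][core_key], (mode, node)

    @settings(
        derandomize=True,
        max_examples=60,
        deadline=None,
        suppress_health_check=[HealthCheck.function_scoped_fixture],
    )
    @given(
        possessors=st.sets(st.sampled_from(["A", "B", "C", "D", "E"]), min_size=1),
        extra=st.sampled_from(["A", "B", "C", "D", "E"]),
    )
    def test_adding_a_possessor_never_shrinks_ancestral(self, tree5, possessors, extra):
        occ1 = occ_from_patterns(tree5, {"HG1": possessors})
        occ2 = occ_from_patterns(tree5, {"HG1": possessors | {extra}})
        for mode in ("dollo", "two_lineage"):
            r1 = classify_all(tree5, occ1, mode=mode)
            r2 = classify_all(tree5, occ2, mode=mode)
            for node in tree5.internal_labels:
                assert r1[node].ancestral <= r2[node].ancestral


class TestSummarize:
    def test_counts_and_fractions(self, tree5):
        occ = occ_from_patterns(
            tree5,
            {
                "HG1": {"A", "B", "C", "D", "E"},  # novel at R
                "HG2": {"A", "B", "C", "D"},  # novel (and core) at P
                "HG3": {"A", "C"},  # novel at P, not core
                "HG4": {"C", "D", "E"},  # lost in M
            },
        )
        summary = summarize(classify_all(tree5, occ, mode="dollo")).set_index("node")
        row = summary.loc["P"]
        assert row["n_ancestral"] == 4
        assert row["n_novel"] == 2
        assert row["n_novel_core"] == 1
        assert row["novel_fraction_pct"] == 50.0
        m = summary.loc["M"]
        assert m["n_lost"] == 1

    def test_undefined_fractions_are_nan_not_zero(self, tree4):
        occ = occ_from_patterns(tree4, {"HG1": set()})
        summary = summarize(classify_all(tree4, occ)).set_index("node")
        assert math.isnan(summary.loc["M", "novel_fraction_pct"])
        assert math.isnan(summary.loc["M", "core_novel_fraction_pct"])

    def test_novel_equals_ancestral_gives_100_percent(self):
        assert percentage(7, 7) == 100.0
        assert integer_percentage(7, 7) == 100.0
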