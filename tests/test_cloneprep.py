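import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bcrtrees as bt
from conftest import make_bundle


class TestResolveLightChains:
    def test_single_compatible_grouping(self):
        bundles = [
            make_bundle(f"c{i}", "ACGTACGT", "GGCCGGCC", light_v="IGKV1-39*01",
                        light_j="IGKJ2*01", light_junction=33)
            for i in range(3)
        ]
        assignments = bt.resolve_light_chains(bundles)
        subs = {sub.subgroup_index for _, sub in assignments}
        assert subs == {1}
        (sub,) = {id(s): s for _, s in assignments}.values()
        assert sub.light_v_gene == "IGKV1-39"
        assert len(sub.members) == 3

    def _two_subgroup_clone(self):
        # S1: 5 cells with IGKV1 lights; S2: 2 cells with IGLV2 lights
        bundles = [
            make_bundle(f"s1_{i}", "AAAAAAAA", "GGCCGGCC", light_v="IGKV1-1*01")
            for i in range(5)
        ]
        bundles += [
            make_bundle(f"s2_{i}", "TTTTTTTT", "CCGGCCGG", light_v="IGLV2-2*01")
            for i in range(2)
        ]
        return bundles

    def test_lightless_cell_joins_nearest_heavy(self):
        bundles = self._two_subgroup_clone()
        # Hamming 2 from S1 heavies, Hamming 6 from S2 heavies
        bundles.append(make_bundle("orphan", "AAAAAATT"))
        assignments = dict((b.cell_id, s) for b, s in bt.resolve_light_chains(bundles))
        assert assignments["orphan"].subgroup_index == assignments["s1_0"].subgroup_index

    def test_hamming_tie_goes_to_larger_subgroup(self):
        bundles = self._two_subgroup_clone()
        # equidistant (Hamming 4) from both subgroups' heavies
        bundles.append(make_bundle("orphan", "AAAATTTT"))
        assignments = dict((b.cell_id, s) for b, s in bt.resolve_light_chains(bundles))
        orphan_sub = assignments["orphan"]
        assert orphan_sub.subgroup_index == assignments["s1_0"].subgroup_index
        assert orphan_sub.subgroup_index == 1  # the larger group got index 1

    def test_clone_without_lights_degenerates_to_one_subgroup(self):
        bundles = [make_bundle(f"c{i}", "ACGTACGT") for i in range(4)]
        assignments = bt.resolve_light_chains(bundles)
        assert {s.subgroup_index for _, s in assignments} == {1}

    def test_ambiguous_vj_joins_largest_compatible_group(self):
        bundles = [
            make_bundle(f"a{i}", "ACGTACGT", "GGGGCCCC", light_v="IGKV1-1*01")
            for i in range(3)
        ]
        bundles.append(
            make_bundle("b0", "ACGTACGT", "GGGGCCCC", light_v="IGKV9-9*01")
        )
        # ambiguous cell compatible with both IGKV1-1 and IGKV9-9
        bundles.append(
            make_bundle("amb", "ACGTACGT", "GGGGCCCC",
                        light_v="IGKV1-1*01,IGKV9-9*01")
        )
        assignments = dict((b.cell_id, s) for b, s in bt.resolve_light_chains(bundles))
        assert assignments["amb"].light_v_gene == "IGKV1-1"
        assert len(assignments["amb"].members) == 4

    def test_input_order_invariance(self):
        bundles = self._two_subgroup_clone() + [make_bundle("orphan", "AAAATTTT")]
        forward = {
            b.cell_id: s.clone_subgroup_id
            for b, s in bt.resolve_light_chains(bundles)
        }
        backward = {
            b.cell_id: s.clone_subgroup_id
            for b, s in bt.resolve_light_chains(list(reversed(bundles)))
        }
        assert forward == backward

    def test_assignment_total_and_disjoint(self):
        bundles = self._two_subgroup_clone() + [make_bundle("orphan", "AAAATTTT")]
        assignments = bt.resolve_light_chains(bundles)
        assert len(assignments) == len(bundles)
        seen = [b.cell_id for b, _ in assignments]
        assert sorted(seen) == sorted(b.cell_id for b in bundles)
        sizes = {}
        for _, sub in assignments:
            sizes[sub.subgroup_index] = len(sub.members)
        # subgroup 1 is (one of) the largest
        assert sizes[1] == max(sizes.values())


class TestSplitSubgroups:
    def test_two_subgroups_give_two_sets(self):
        bundles = [
            make_bundle("a", "AAAAAAAA", "GGCCGGCC", light_v="IGKV1-1*01"),
            make_bundle("b", "TTTTTTTT", "CCGGCCGG", light_v="IGLV2-2*01"),
        ]
        sets = bt.split_subgroups(bt.resolve_light_chains(bundles))
        assert len(sets) == 2
        assert all(len(members) == 1 for _, members in sets)

    def test_single_subgroup_identity(self):
        bundles = [make_bundle(f"c{i}", "ACGTACGT", "GGCCGGCC") for i in range(3)]
        ((sub, members),) = bt.split_subgroups(bt.resolve_light_chains(bundles))
        assert sub.clone_subgroup_id == "clone1_1"
        assert len(members) == 3


class TestCloneGermline:
    def test_identical_inputs_returned(self):
        recs = [make_bundle(f"c{i}", "ACGT", heavy_germ="ACGT").heavy for i in range(3)]
        assert bt.build_clone_germline(recs) == "ACGT"

    def test_majority_wins(self):
        germs = ["AAAA", "AAAA", "GAAA"]
        recs = [make_bundle(f"c{i}", "ACGT", heavy_germ=g).heavy for i, g in enumerate(germs)]
        assert bt.build_clone_germline(recs)[0] == "A"

    def test_tie_and_all_n_become_n(self):
        germs = ["ANCA", "GNCA"]
        recs = [make_bundle(f"c{i}", "ACGT", heavy_germ=g).heavy for i, g in enumerate(germs)]
        out = bt.build_clone_germline(recs)
        assert out[0] == "N"  # A vs G tie
        assert out[1] == "N"  # all-N column

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            bt.build_clone_germline([])


class TestFormatClone:
    def _subgroup(self, bundles):
        ((sub, members),) = bt.split_subgroups(bt.resolve_light_chains(bundles))
        return sub, members

    def test_concatenation(self):
        sub, members = self._subgroup([make_bundle("c1", "ACGT", "GGCC"),
                                       make_bundle("c2", "ACGA", "GGCA")])
        aln = bt.format_clone(sub, members)
        assert aln.tip_sequences["c1"] == "ACGTGGCC"
        assert aln.heavy_interval == (0, 4)
        assert aln.light_interval == (4, 8)

    def test_missing_light_becomes_n_run(self):
        sub, members = self._subgroup([make_bundle("c1", "ACGT", "GGCC"),
                                       make_bundle("c2", "AAAA")])
        aln = bt.format_clone(sub, members)
        assert aln.tip_sequences["c2"] == "AAAANNNN"
        assert aln.light_present["c2"] is False

    def test_ambiguity_only_differences_collapse(self):
        sub, members = self._subgroup([make_bundle("c1", "ACGT", "GGCC"),
                                       make_bundle("c2", "ACGT", "GGCN")])
        aln = bt.format_clone(sub, members)
        assert aln.n_tips == 1
        assert aln.collapse_map["c1"] == {"c1", "c2"}
        # informative characters fill in over the N
        assert aln.tip_sequences["c1"] == "ACGTGGCC"

    def test_collapse_can_be_disabled(self):
        sub, members = self._subgroup([make_bundle("c1", "ACGT", "GGCC"),
                                       make_bundle("c2", "ACGT", "GGCN")])
        aln = bt.format_clone(sub, members, collapse=False)
        assert aln.n_tips == 2

    def test_mixed_heavy_lengths_error(self):
        sub, members = self._subgroup([make_bundle("c1", "ACGT", "GGCC"),
                                       make_bundle("c2", "ACGTA", "GGCC")])
        with pytest.raises(ValueError, match="heavy"):
            bt.format_clone(sub, members)

    def test_all_strings_equal_length(self, small_clone_alignments):
        for aln in small_clone_alignments:
            assert len(aln.germline) == aln.length
            assert all(len(s) == aln.length for s in aln.tip_sequences.values())


class TestMakeHeavyOnly:
    def test_matched_filtering_keeps_tip_set(self):
        sub_bundles = [
            make_bundle("c1", "ACGT", "GGCC"),
            make_bundle("c2", "ACGT", "TTAA"),  # same heavy, distinct light
            make_bundle("c3", "AAAA", "GGCC"),
        ]
        ((sub, members),) = bt.split_subgroups(bt.resolve_light_chains(sub_bundles))
        aln = bt.format_clone(sub, members)
        heavy = bt.make_heavy_only(aln)
        assert heavy.tip_names == aln.tip_names  # no re-collapsing
        assert heavy.tip_sequences["c1"] == "ACGT"
        assert heavy.tip_sequences["c2"] == "ACGT"
        assert heavy.germline == aln.germline[:4]
        assert heavy.light_interval[0] == heavy.light_interval[1]


class TestShmFrequency:
    def test_identical_is_zero(self):
        assert bt.shm_frequency("ACGT" * 100, "ACGT" * 100) == 0.0

    def test_mismatch_fraction(self):
        germ = "A" * 312
        seq = "T" * 3 + "A" * 309
        assert bt.shm_frequency(seq, germ) == pytest.approx(3 / 312)

    def test_ambiguous_positions_excluded(self):
        germ = "AANN"
        seq = "ATGC"
        # region covers all 4; N columns dropped from both counts
        assert bt.shm_frequency(seq, germ, region=(1, 4)) == pytest.approx(1 / 2)

    def test_all_n_region_is_missing(self):
        assert math.isnan(bt.shm_frequency("ACGT", "NNNN", region=(1, 4)))


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=10, deadline=None)
def test_pipeline_partitions_cells(seed):
    """Every simulated cell lands in exactly one tip's collapse group."""
    sim = bt.simulate_clone(n_tips=6, branch_mean_events=2.0, seed=seed,
                            heavy_length=30, light_length=18)
    aln = sim.to_clone_alignment()
    cells = [c for group in aln.collapse_map.values() for c in group]
    assert sorted(cells) == sorted(sim.cells)
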