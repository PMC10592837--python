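import numpy as np
import pytest

import bcrtrees as bt
from bcrtrees.likelihood import LikelihoodEngine, MIN_BRANCH
from bcrtrees.models import GTRModel, PartitionScheme

from conftest import make_alignment
from oracles import brute_force_log_likelihood


class TestGTRModel:
    def test_rate_matrix_properties(self):
        model = GTRModel(pi=[0.1, 0.2, 0.3, 0.4], rates=[1, 2, 3, 4, 5, 1])
        assert np.allclose(model.Q.sum(axis=1), 0.0, atol=1e-12)
        # detailed balance pi_i q_ij == pi_j q_ji
        flux = model.pi[:, None] * model.Q
        assert np.allclose(flux, flux.T, atol=1e-12)
        # mean rate normalized to 1
        assert np.isclose(-np.dot(model.pi, np.diag(model.Q)), 1.0)

    def test_transition_matrix_limits(self):
        model = GTRModel(pi=[0.3, 0.2, 0.2, 0.3], rates=[1, 4, 1, 1, 4, 1])
        assert np.allclose(model.transition_matrix(0.0), np.eye(4), atol=1e-12)
        P_inf = model.transition_matrix(500.0)
        assert np.allclose(P_inf, np.tile(model.pi, (4, 1)), atol=1e-8)
        P = model.transition_matrix(0.1)
        assert np.all(P >= 0) and np.allclose(P.sum(axis=1), 1.0)


def _random_scheme(aln, rng, scaled=True):
    pi = rng.dirichlet(np.ones(4) * 10)
    rates = rng.uniform(0.3, 3.0, size=6)
    rates[5] = 1.0
    heavy = GTRModel(pi=pi, rates=rates)
    if not scaled:
        return PartitionScheme.single(aln.length, model=heavy)
    light = GTRModel(pi=rng.dirichlet(np.ones(4) * 10))
    return PartitionScheme(
        [
            bt.Partition("heavy", aln.heavy_interval, 1.0, heavy),
            bt.Partition("light", aln.light_interval, rng.uniform(0.3, 1.5), light),
        ],
        "scaled",
    )


class TestPruningOracle:
    @pytest.mark.parametrize("seed", range(4))
    def test_matches_ancestral_sum_on_small_instances(self, seed):
        """Pruning equals brute-force summation over all ancestral states
        on <=5-tip, <=50-site instances."""
        rng = np.random.default_rng(seed)
        sim = bt.simulate_clone(
            n_tips=4, branch_mean_events=2.5, seed=seed,
            heavy_length=26, light_length=15,
        )
        aln = sim.to_clone_alignment(collapse=False)
        tree = bt.neighbor_joining_tree(aln)
        for node in tree.postorder():
            if node.parent is not None:
                node.length = rng.uniform(0.001, 0.4)
        scheme = _random_scheme(aln, rng, scaled=bool(seed % 2))
        fast = bt.partitioned_log_likelihood(tree, aln, scheme)
        slow = brute_force_log_likelihood(tree, aln, scheme)
        assert fast == pytest.approx(slow, abs=1e-8)

    def test_missing_data_tip_has_all_ones_vector(self):
        """A tip that is entirely N contributes nothing to the likelihood."""
        aln3 = make_alignment(
            {"A": "ACGTAC", "B": "ACGAAC", "C": "NNNNNN"},
            "ACGTAC", heavy_len=6,
        )
        aln2 = make_alignment(
            {"A": "ACGTAC", "B": "ACGAAC"}, "ACGTAC", heavy_len=6
        )
        t3 = bt.read_newick("(((A:0.1,B:0.1):0.05,C:0.2):0.01,Germline:0.02);")
        t2 = bt.read_newick("((A:0.1,B:0.1):0.06,Germline:0.02);")
        s3 = PartitionScheme.single(6)
        s2 = PartitionScheme.single(6)
        l3 = bt.partitioned_log_likelihood(t3, aln3, s3)
        l2 = bt.partitioned_log_likelihood(t2, aln2, s2)
        assert l3 == pytest.approx(l2, abs=1e-9)


class TestLikelihoodInvariants:
    def _fixture(self, seed=0):
        rng = np.random.default_rng(seed)
        sim = bt.simulate_clone(n_tips=5, branch_mean_events=3.0, seed=seed,
                                heavy_length=30, light_length=18)
        aln = sim.to_clone_alignment(collapse=False)
        tree = bt.neighbor_joining_tree(aln)
        for node in tree.postorder():
            if node.parent is not None:
                node.length = rng.uniform(0.01, 0.3)
        return aln, tree

    def test_rerooting_invariance(self):
        aln, tree = self._fixture()
        scheme = PartitionScheme.single(aln.length)
        base = bt.partitioned_log_likelihood(tree, aln, scheme)
        for label in sorted(aln.tip_names)[:3]:
            rerooted = tree.root_on(label)
            again = bt.partitioned_log_likelihood(rerooted, aln, scheme)
            assert again == pytest.approx(base, abs=1e-8)

    def test_scaled_with_unit_scalar_nests_single(self):
        aln, tree = self._fixture(1)
        shared = GTRModel(pi=[0.27, 0.23, 0.25, 0.25], rates=[1, 2, 1, 1, 2, 1])
        single = PartitionScheme.single(aln.length, model=shared)
        scaled = PartitionScheme(
            [
                bt.Partition("heavy", aln.heavy_interval, 1.0, shared),
                bt.Partition("light", aln.light_interval, 1.0, shared),
            ],
            "scaled",
        )
        l1 = bt.partitioned_log_likelihood(tree, aln, single)
        l2 = bt.partitioned_log_likelihood(tree, aln, scaled)
        assert l1 == pytest.approx(l2, abs=1e-10)

    def test_two_tip_zero_branch_closed_form(self):
        """t=0 with identical sequences: lnL = sum(log pi(state))."""
        aln = make_alignment({"A": "ACGT"}, "ACGT", heavy_len=4)
        tree = bt.read_newick("(A:0,Germline:0);")
        model = GTRModel(pi=[0.1, 0.2, 0.3, 0.4])
        scheme = PartitionScheme.single(4, model=model)
        expected = np.log([0.1, 0.2, 0.3, 0.4]).sum()
        assert bt.partitioned_log_likelihood(tree, aln, scheme) == pytest.approx(
            expected, abs=1e-10
        )

    def test_branch_optimization_monotone(self):
        aln, tree = self._fixture(2)
        scheme = PartitionScheme.single(aln.length)
        engine = LikelihoodEngine(aln, scheme, tree)
        lnl = engine.log_likelihood()
        for node in tree.postorder():
            if node.parent is None:
                continue
            new = engine.optimize_branch(node)
            assert new >= lnl - 1e-9
            lnl = new

    def test_two_tip_jc_closed_form(self):
        """ML distance between two sequences equals the analytic JC distance."""
        rng = np.random.default_rng(5)
        n, k = 600, 60
        germ = "".join(rng.choice(list("ACGT"), size=n))
        seq = list(germ)
        pos = rng.choice(n, size=k, replace=False)
        for p in pos:
            seq[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq[p]]
        aln = make_alignment({"A": "".join(seq)}, germ, heavy_len=n)
        tree = bt.read_newick("(A:0.05,Germline:0.05);")
        scheme = PartitionScheme.single(n)  # uniform pi, unit rates == JC
        engine = LikelihoodEngine(aln, scheme, tree)
        engine.sweep_branch_lengths()
        total = bt.tree_length(tree)
        p_hat = k / n
        jc = -0.75 * np.log(1 - 4 * p_hat / 3)
        assert total == pytest.approx(jc, abs=1e-6)

    def test_identical_sequences_hit_lower_bound(self):
        aln = make_alignment({"A": "ACGT" * 30, "B": "ACGT" * 30}, "ACGT" * 30,
                             heavy_len=120)
        tree = bt.read_newick("((A:0.1,B:0.1):0.05,Germline:0.1);")
        scheme = PartitionScheme.single(120)
        engine = LikelihoodEngine(aln, scheme, tree)
        engine.sweep_branch_lengths()
        for node in tree.postorder():
            if node.parent is not None:
                assert node.length <= 1e-6 or node.length == pytest.approx(MIN_BRANCH)


class TestMlSearch:
    def test_recovers_clear_split(self):
        """10 sites support ((A,B),(C,D)); brute-force over the 3 unrooted
        topologies confirms the winner."""
        block = "ACGTACGTAC"
        a = block + "A" * 10
        c = block + "T" * 10
        aln = make_alignment(
            {"A": a, "B": a, "C": c, "D": c},
            block + "A" * 5 + "T" * 5,
            heavy_len=20,
        )
        res = bt.ml_search(aln, mode="single", nni=True, estimate_rates=False)
        clades = bt.evaluate.clade_sets(res.tree)
        assert frozenset({"A", "B"}) in clades or frozenset({"C", "D"}) in clades

    def test_scaled_fixed_unit_scalar_matches_single(self, small_clone_alignments):
        aln = small_clone_alignments[0]
        shared = GTRModel()
        single = PartitionScheme.single(aln.length, model=shared)
        scaled = PartitionScheme(
            [
                bt.Partition("heavy", aln.heavy_interval, 1.0, shared),
                bt.Partition("light", aln.light_interval, 1.0, shared),
            ],
            "scaled",
        )
        tree1 = bt.neighbor_joining_tree(aln)
        tree2 = tree1.copy()
        l1 = LikelihoodEngine(aln, single, tree1).sweep_branch_lengths()
        l2 = LikelihoodEngine(aln, scaled, tree2).sweep_branch_lengths()
        assert l1 == pytest.approx(l2, abs=1e-6)

    def test_tip_order_invariance(self, small_clone_alignments):
        aln = small_clone_alignments[1]
        reordered = bt.CloneAlignment(
            clone_subgroup_id=aln.clone_subgroup_id,
            tip_sequences=dict(reversed(list(aln.tip_sequences.items()))),
            germline=aln.germline,
            heavy_interval=aln.heavy_interval,
            light_interval=aln.light_interval,
            collapse_map=aln.collapse_map,
            light_present=aln.light_present,
        )
        r1 = bt.ml_search(aln, mode="single", estimate_rates=False)
        r2 = bt.ml_search(reordered, mode="single", estimate_rates=False)
        assert r1.log_likelihood == pytest.approx(r2.log_likelihood, abs=1e-6)

    def test_all_n_light_partition_pins_scalar(self):
        heavy = {"A": "ACGTACGTACGTACGTACGT", "B": "ACGAACGTACGTACCTACGT",
                 "C": "ACGTACGTAAGTACGTACGT"}
        aln = make_alignment(
            {k: v + "N" * 9 for k, v in heavy.items()},
            "ACGTACGTACGTACGTACGT" + "N" * 9,
            heavy_len=20,
        )
        with pytest.warns(UserWarning, match="scalar fixed at 1"):
            res = bt.ml_search(aln, mode="scaled", estimate_rates=False)
        assert res.light_scalar == 1.0

    def test_tree_length_invariant_under_rerooting(self, small_clone_alignments):
        res = bt.ml_search(small_clone_alignments[2], mode="single",
                           estimate_rates=False)
        base = bt.tree_length(res.tree)
        for label in sorted(res.tree.tip_labels)[:3]:
            assert bt.tree_length(res.tree.root_on(label)) == pytest.approx(
                base, abs=1e-9
            )
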