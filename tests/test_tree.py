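"""Tree building, node scores and reduced-error pruning."""

import itertools

import numpy as np
import pytest

from ships.tree import (
    Partition,
    TreeNode,
    build_tree,
    node_quality,
    node_ss,
    prune_sequence,
)


def cross_leaf_quality(node, S):
    """Direct oracle: sum of squared similarities over pairs in different leaves."""
    leaves = node.leaves()
    total = 0.0
    for a, b in itertools.combinations(leaves, 2):
        sub = S[np.ix_(a.members, b.members)]
        total += float(np.sum(sub * sub))
    return total


def is_coarsening(fine, coarse):
    """Every cluster of the finer partition sits inside one coarse cluster."""
    for c in range(1, fine.k + 1):
        members = np.flatnonzero(fine.labels == c)
        if len(set(coarse.labels[members].tolist())) != 1:
            return False
    return True


class TestNodeScores:
    def test_singleton_ss_is_zero(self):
        S = np.full((4, 4), 2.0)
        assert node_ss(np.array([2]), S) == 0.0

    def test_pair_ss(self):
        S = np.array([[2.0, 2.0], [2.0, 2.0]])
        assert node_ss(np.array([0, 1]), S) == pytest.approx(4.0)

    def test_three_sample_hand_sum(self):
        # pairwise similarities 2, 1, 0 -> 4 + 1 + 0
        S = np.array([[2.0, 2.0, 1.0], [2.0, 2.0, 0.0], [1.0, 0.0, 2.0]])
        assert node_ss(np.array([0, 1, 2]), S) == pytest.approx(5.0)

    def test_quality_zero_when_leaves_fully_dissimilar(self, two_block_similarity):
        S, labels = two_block_similarity
        root = TreeNode(members=np.arange(len(labels)), ss=node_ss(np.arange(len(labels)), S))
        left = TreeNode(members=np.flatnonzero(labels == 0))
        right = TreeNode(members=np.flatnonzero(labels == 1))
        for leaf in (left, right):
            leaf.ss = node_ss(leaf.members, S)
        root.children = (left, right)
        assert node_quality(root, S) == pytest.approx(0.0)

    def test_quality_hand_enumeration(self):
        # {a,b,c,d} split into {a,b} and {c,d}, all similarities 2:
        # 4 cross pairs, each squared similarity 4 -> quality 16
        S = np.full((4, 4), 2.0)
        root = TreeNode(members=np.arange(4), ss=node_ss(np.arange(4), S))
        left = TreeNode(members=np.array([0, 1]), ss=node_ss(np.array([0, 1]), S))
        right = TreeNode(members=np.array([2, 3]), ss=node_ss(np.array([2, 3]), S))
        root.children = (left, right)
        assert node_quality(root, S) == pytest.approx(16.0)

    def test_quality_on_leaf_is_an_error(self):
        leaf = TreeNode(members=np.arange(3))
        with pytest.raises(ValueError):
            node_quality(leaf, np.eye(3))

    def test_ss_difference_equals_cross_leaf_sum(self, rng):
        """The two published forms of the quality agree on random trees."""
        for _ in range(5):
            values = rng.integers(0, 3, size=(14, 30))
            from ships.similarity import asd_similarity_values

            S = asd_similarity_values(values)
            root = build_tree(S, rng, min_node_size=3)
            for node in root.internal_nodes():
                assert node_quality(node, S) == pytest.approx(
                    cross_leaf_quality(node, S), abs=1e-9
                )


class TestBuildTree:
    @staticmethod
    def node_sets(root):
        sets = set()
        stack = [root]
        while stack:
            node = stack.pop()
            sets.add(frozenset(node.members.tolist()))
            if not node.is_leaf:
                stack.extend(node.children)
        return sets

    def test_two_blocks_split_first(self, two_block_similarity, rng):
        """The root split separates the blocks exactly (they may be
        subdivided further; pruning merges those spurious cuts back)."""
        S, labels = two_block_similarity
        root = build_tree(S, rng)
        child_sets = {frozenset(c.members.tolist()) for c in root.children}
        assert child_sets == {
            frozenset(np.flatnonzero(labels == 0).tolist()),
            frozenset(np.flatnonzero(labels == 1).tolist()),
        }

    def test_three_blocks_appear_as_nodes_regardless_of_split_order(
        self, three_block_similarity
    ):
        S, labels = three_block_similarity
        for seed in range(8):  # different seeds may pick either first split
            root = build_tree(S, np.random.default_rng(seed))
            sets = self.node_sets(root)
            for c in (1, 2, 3):
                assert frozenset(np.flatnonzero(labels == c).tolist()) in sets

    def test_realistic_three_population_pruning_recovers_blocks(self):
        """On genotype-like data the k=3 nested partition matches the
        three populations: noise splits carry few cross pairs, so their
        quality is smallest and they are collapsed first."""
        from ships.evaluation import adjusted_rand_index
        from ships.popsim import PopulationModel, simulate_structured
        from ships.similarity import asd_similarity_values

        rng = np.random.default_rng(3)
        model = PopulationModel(pop_sizes=[10, 10, 10], n_loci=500, branch_f=0.3)
        geno, truth = simulate_structured(model, rng)
        S = asd_similarity_values(geno.values)
        root = build_tree(S, rng)
        at_3 = next(p for p in prune_sequence(root, S) if p.k == 3)
        assert adjusted_rand_index(at_3.labels, truth.labels) == 1.0

    def test_children_partition_parent(self, rng):
        from ships.similarity import asd_similarity_values

        S = asd_similarity_values(rng.integers(0, 3, size=(16, 25)))
        root = build_tree(S, rng)
        for node in root.internal_nodes():
            left, right = node.children
            combined = np.sort(np.concatenate([left.members, right.members]))
            assert np.array_equal(combined, np.sort(node.members))

    def test_root_covers_all_samples(self, rng):
        S = np.full((5, 5), 2.0)
        np.fill_diagonal(S, 2.0)
        root = build_tree(S, rng)
        assert np.array_equal(np.sort(root.members), np.arange(5))


class TestPruneSequence:
    def test_single_split_gives_two_partitions(self, two_block_similarity):
        S, labels = two_block_similarity
        root = TreeNode(members=np.arange(len(labels)), ss=node_ss(np.arange(len(labels)), S))
        left = TreeNode(members=np.flatnonzero(labels == 0))
        right = TreeNode(members=np.flatnonzero(labels == 1))
        for leaf in (left, right):
            leaf.ss = node_ss(leaf.members, S)
        root.children = (left, right)
        partitions = prune_sequence(root, S)
        assert [p.k for p in partitions] == [2, 1]

    def test_sequence_spans_k_built_down_to_one(self, rng):
        from ships.similarity import asd_similarity_values

        S = asd_similarity_values(rng.integers(0, 3, size=(20, 30)))
        root = build_tree(S, rng)
        partitions = prune_sequence(root, S)
        ks = [p.k for p in partitions]
        assert ks[0] == len(root.leaves())
        assert ks[-1] == 1
        assert all(a > b for a, b in zip(ks, ks[1:]))  # strictly decreasing

    def test_partitions_are_nested(self, rng):
        from ships.similarity import asd_similarity_values

        S = asd_similarity_values(rng.integers(0, 3, size=(18, 30)))
        root = build_tree(S, rng)
        partitions = prune_sequence(root, S)
        for fine, coarse in zip(partitions, partitions[1:]):
            assert is_coarsening(fine, coarse)

    def test_fringe_only_prunes_in_unit_steps(self, rng):
        from ships.similarity import asd_similarity_values

        S = asd_similarity_values(rng.integers(0, 3, size=(18, 30)))
        root = build_tree(S, rng)
        partitions = prune_sequence(root, S, fringe_only=True)
        ks = [p.k for p in partitions]
        assert ks == list(range(ks[0], 0, -1))

    def test_pruning_leaves_original_tree_intact(self, rng):
        from ships.similarity import asd_similarity_values

        S = asd_similarity_values(rng.integers(0, 3, size=(12, 30)))
        root = build_tree(S, rng)
        before = len(root.leaves())
        prune_sequence(root, S)
        assert len(root.leaves()) == before

    def test_deterministic_for_fixed_tree(self, rng):
        from ships.similarity import asd_similarity_values

        S = asd_similarity_values(rng.integers(0, 3, size=(15, 30)))
        root = build_tree(S, rng)
        seq_a = prune_sequence(root, S)
        seq_b = prune_sequence(root, S)
        for pa, pb in zip(seq_a, seq_b):
            assert np.array_equal(pa.labels, pb.labels)


class TestPartition:
    def test_labels_must_be_contiguous(self):
        with pytest.raises(ValueError):
            Partition(np.array([1, 3, 1]))

    def test_cluster_members_cover_everything(self):
        part = Partition(np.array([1, 2, 1, 3, 2]))
        members = np.sort(np.concatenate(part.cluster_members()))
        assert np.array_equal(members, np.arange(5))
        assert part.k == 3
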