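import numpy as np
import pytest

from orthospace import (
    TreeParams,
    branch_mutation_fraction,
    cross_tree_correlation,
    inheritance_matrix,
    node_depth,
    parent_index,
    sample_mutation_vectors,
    simulate_tree,
    species_matrix,
    spectrum_experiment,
)

# ancestor-path indicator matrix of the depth-2 tree, written by hand from
# the heap layout (root 1, children 2-3, grandchildren 4-7)
C_DEPTH2 = np.array(
    [
        [1, 1, 1, 1, 1, 1, 1],
        [0, 1, 0, 1, 1, 0, 0],
        [0, 0, 1, 0, 0, 1, 1],
        [0, 0, 0, 1, 0, 0, 0],
        [0, 0, 0, 0, 1, 0, 0],
        [0, 0, 0, 0, 0, 1, 0],
        [0, 0, 0, 0, 0, 0, 1],
    ]
)


def walking_oracle(d):
    """Build C by explicitly walking parent pointers per node."""
    n = 2 ** (d + 1) - 1
    C = np.zeros((n, n), dtype=int)
    for k in range(1, n + 1):
        path = [k]
        while path[-1] > 1:
            path.append(path[-1] // 2)
        for m in path:
            C[m - 1, k - 1] = 1
    return C


class TestInheritanceMatrix:
    def test_root_only(self):
        np.testing.assert_array_equal(inheritance_matrix(0), [[1]])

    def test_depth_two_matches_hand_layout(self):
        np.testing.assert_array_equal(inheritance_matrix(2), C_DEPTH2)

    @pytest.mark.parametrize("d", range(7))
    def test_matches_parent_walking_oracle(self, d):
        np.testing.assert_array_equal(inheritance_matrix(d), walking_oracle(d))

    @pytest.mark.parametrize("d", [1, 3, 5])
    def test_column_sums_are_depth_plus_one(self, d):
        C = inheritance_matrix(d)
        for k in range(1, C.shape[0] + 1):
            assert C[:, k - 1].sum() == node_depth(k) + 1

    def test_upper_triangular_unit_diagonal(self):
        C = inheritance_matrix(4)
        assert np.array_equal(np.triu(C), C)
        assert (np.diag(C) == 1).all()

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            inheritance_matrix(-1)


class TestIndexing:
    def test_parent_map(self):
        assert [parent_index(m) for m in [2, 3, 4, 5, 6, 7]] == [1, 1, 2, 2, 3, 3]

    def test_root_has_no_parent(self):
        with pytest.raises(ValueError):
            parent_index(1)

    def test_node_depths(self):
        assert [node_depth(m) for m in [1, 2, 3, 4, 7, 8, 15]] == [
            0, 1, 1, 2, 2, 3, 3,
        ]


class TestMutationVectors:
    def test_zero_rate_means_no_mutations(self):
        V = sample_mutation_vectors(TreeParams(3, 100, 0.0, seed=0))
        assert (V[:, 1:] == 0).all()
        assert set(np.unique(V[:, 0])) <= {0, 1, 2, 3}

    def test_nonzero_fraction_z4_full(self):
        # a drawn nucleotide is zero with prob 1/4, so the nonzero
        # fraction is (3/4) p_b
        params = TreeParams(1, 10_000, 0.4, seed=5)
        V = sample_mutation_vectors(params)
        frac = np.count_nonzero(V[:, 1:]) / V[:, 1:].size
        se = np.sqrt(0.3 * 0.7 / V[:, 1:].size)
        assert abs(frac - 0.3) <= 3 * se

    def test_entry_mean_is_mu_times_pb(self):
        # E[X] = 1.5 under the full alphabet, so E[v] = 1.5 p_b
        params = TreeParams(1, 10_000, 0.2, seed=6)
        V = sample_mutation_vectors(params)
        entries = V[:, 1:].ravel()
        se = entries.std() / np.sqrt(entries.size)
        assert abs(entries.mean() - 1.5 * 0.2) <= 3 * se

    def test_nonzero_alphabet_never_draws_silent_changes(self):
        params = TreeParams(2, 2000, 1.0, change_alphabet="nonzero", seed=7)
        V = sample_mutation_vectors(params)
        assert (V[:, 1:] != 0).all()


class TestSpeciesMatrix:
    def test_zero_rate_clones_the_ancestor(self):
        tree = simulate_tree(TreeParams(3, 80, 0.0, seed=1))
        for k in range(tree.params.n_species):
            np.testing.assert_array_equal(tree.S[:, k], tree.S[:, 0])

    def test_column_five_combines_v1_v2_v5(self, small_tree):
        # root path of heap node 5 is {1, 2, 5}
        expected = (small_tree.V[:, 0] + small_tree.V[:, 1] + small_tree.V[:, 4]) % 4
        np.testing.assert_array_equal(small_tree.S[:, 4], expected)

    def test_child_minus_parent_recovers_mutation_vector(self, small_tree):
        for k in range(2, small_tree.params.n_species + 1):
            diff = (small_tree.S[:, k - 1] - small_tree.S[:, parent_index(k) - 1]) % 4
            np.testing.assert_array_equal(diff, small_tree.V[:, k - 1] % 4)

    def test_agrees_with_recursive_chain_construction(self):
        # second construction path: walk the tree and add mutations node
        # by node, never forming C
        params = TreeParams(4, 60, 0.3, seed=42)
        tree = simulate_tree(params)
        chain = np.zeros_like(tree.S)
        chain[:, 0] = tree.V[:, 0]
        for k in range(2, params.n_species + 1):
            chain[:, k - 1] = (chain[:, parent_index(k) - 1] + tree.V[:, k - 1]) % 4
        np.testing.assert_array_equal(tree.S, chain % 4)

    def test_entries_in_z4(self, small_tree):
        assert set(np.unique(small_tree.S)) <= {0, 1, 2, 3}

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            species_matrix(np.zeros((10, 7)), np.zeros((3, 3)))

    def test_reproducible_and_seed_sensitive(self):
        a = simulate_tree(TreeParams(3, 50, 0.2, seed=9))
        b = simulate_tree(TreeParams(3, 50, 0.2, seed=9))
        c = simulate_tree(TreeParams(3, 50, 0.2, seed=10))
        np.testing.assert_array_equal(a.S, b.S)
        assert (a.S != c.S).any()


class TestBranchMutationFraction:
    def test_zero_rate(self):
        assert branch_mutation_fraction(simulate_tree(TreeParams(2, 50, 0.0, seed=0))) == 0.0

    def test_nonzero_alphabet_matches_pb(self):
        tree = simulate_tree(TreeParams(1, 10_000, 0.1, change_alphabet="nonzero", seed=3))
        se = np.sqrt(0.1 * 0.9 / 10_000)
        assert abs(branch_mutation_fraction(tree) - 0.1) <= 3 * se * 2

    def test_full_alphabet_matches_three_quarters_pb(self):
        tree = simulate_tree(TreeParams(1, 10_000, 0.1, seed=4))
        se = np.sqrt(0.075 * 0.925 / 10_000)
        assert abs(branch_mutation_fraction(tree) - 0.075) <= 3 * se * 2

    def test_root_only_tree_rejected(self):
        with pytest.raises(ValueError):
            branch_mutation_fraction(simulate_tree(TreeParams(0, 50, 0.1, seed=0)))


class TestCrossTreeCorrelation:
    def test_independent_trees_uncorrelated(self):
        M = 10_000
        a = simulate_tree(TreeParams(2, M, 0.2, seed=21))
        b = simulate_tree(TreeParams(2, M, 0.2, seed=22))
        summary = cross_tree_correlation(a, b)
        assert abs(summary.mean) < 3 / np.sqrt(M)

    def test_parent_child_share_ancestry(self):
        a = simulate_tree(TreeParams(2, 10_000, 0.1, seed=23))
        summary = cross_tree_correlation(a, a)
        # centered product of a parent-child pair stays far above the
        # independent-tree noise floor
        assert summary.products[0, 1] > 3 / np.sqrt(10_000)

    def test_self_correlation_maximal_on_diagonal(self):
        a = simulate_tree(TreeParams(2, 5000, 0.1, seed=24))
        products = cross_tree_correlation(a, a).products
        assert (np.diag(products) >= products.max(axis=1) - 1e-12).all()

    def test_length_mismatch_rejected(self):
        a = simulate_tree(TreeParams(1, 100, 0.1, seed=0))
        b = simulate_tree(TreeParams(1, 101, 0.1, seed=0))
        with pytest.raises(ValueError):
            cross_tree_correlation(a, b)


class TestSpectrumExperiment:
    def test_zero_rate_gives_rank_one(self):
        df = spectrum_experiment([TreeParams(3, 64, 0.0, seed=1)], replicates=5)
        assert (df["r_modal"] == 1).all()
        assert (df["r_energy"] == 1).all()

    def test_row_count_and_columns(self):
        grid = [TreeParams(2, 64, 0.1, seed=1), TreeParams(3, 64, 0.1, seed=2)]
        df = spectrum_experiment(grid, replicates=4)
        assert len(df) == 8
        assert {"p_b", "depth", "r_modal", "r_energy"} <= set(df.columns)

    def test_modal_rank_nondecreasing_in_depth(self):
        grid = [TreeParams(d, 64, 0.1, seed=100 + d) for d in range(1, 5)]
        df = spectrum_experiment(grid, replicates=50)
        by_depth = df.groupby("depth")["r_modal"].mean().sort_index()
        assert by_depth.is_monotonic_increasing

    def test_energy_rank_increases_with_mutation_rate(self):
        grid = [TreeParams(4, 64, pb, seed=int(pb * 100)) for pb in (0.1, 0.3, 0.5)]
        df = spectrum_experiment(grid, replicates=30)
        means = df.groupby("p_b")["r_energy"].mean().sort_index()
        assert means.is_monotonic_increasing
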