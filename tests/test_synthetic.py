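"""Phylogeny simulation, network construction, response models, augmentation."""

import numpy as np
import pytest

import bayesnetreg as bnr
from bayesnetreg.simulate import (
    REDUNDANCY_CAPS,
    SimulationConfig,
    augment_dataset,
    brownian_covariance,
    generate_B_theoretical,
    generate_main_effects,
    generate_node_influence,
    generate_response,
    inverse_distance_adjacency,
    patristic_distances,
    sample_taxa_and_adjacency,
    simulate_dataset,
    simulate_tree,
)


class TestTree:
    def test_minimal_tree(self, rng):
        t = simulate_tree(2, rng)
        assert t.V == 2 and t.n_edges == 2

    def test_edge_count_30_taxa(self, rng):
        t = simulate_tree(30, rng)
        assert t.V == 30 and t.n_edges == 58
        assert len(list(t.tree.leaf_node_iter())) == 30

    def test_too_few_leaves(self, rng):
        with pytest.raises(ValueError):
            simulate_tree(1, rng)

    def test_branch_lengths_unit_interval(self, rng):
        t = simulate_tree(12, rng)
        lengths = [
            e.length for e in t.tree.preorder_edge_iter()
            if e.head_node is not t.tree.seed_node
        ]
        assert len(lengths) == 22
        assert all(0 < b < 1 for b in lengths)

    @pytest.mark.parametrize("V", [5, 9])
    def test_splitting_process_oracle(self, V):
        """Cherry counts match a plain re-implementation of leaf splitting.

        Driven by the same seeded uniform choices, a minimal list/dict
        replica of the edge-splitting process must produce a tree with the
        same number of cherries (internal nodes subtending two leaves) as
        the dendropy-backed builder, seed by seed.
        """

        def replica_cherries(V, rng):
            children = {0: [1, 2]}
            leaves = [1, 2]
            nxt = 3
            while len(leaves) < V:
                idx = int(rng.integers(len(leaves)))
                node = leaves.pop(idx)
                children[node] = [nxt, nxt + 1]
                leaves += [nxt, nxt + 1]
                nxt += 2
            leafset = set(leaves)
            return sum(1 for kids in children.values()
                       if all(c in leafset for c in kids))

        for seed in range(200):
            t = simulate_tree(V, np.random.default_rng(seed))
            cherries = sum(
                1 for node in t.tree.preorder_node_iter()
                if node.child_nodes() and all(c.is_leaf() for c in node.child_nodes())
            )
            assert cherries == replica_cherries(V, np.random.default_rng(seed))


class TestDistances:
    def test_two_leaf_path(self):
        from bayesnetreg.io import read_tree

        t = read_tree("(A:0.3,B:0.7);")
        D = patristic_distances(t)
        assert D[0, 1] == pytest.approx(1.0)
        assert D[0, 0] == D[1, 1] == 0.0

    def test_graph_shortest_path_oracle(self, rng):
        import networkx as nx

        t = simulate_tree(6, rng)
        G = nx.Graph()
        for node in t.tree.preorder_node_iter():
            if node is t.tree.seed_node:
                continue
            G.add_edge(id(node.parent_node), id(node), weight=node.edge.length)
        leaves = {leaf.taxon.label: id(leaf) for leaf in t.tree.leaf_node_iter()}
        D = patristic_distances(t)
        for i, a in enumerate(t.labels):
            for j, b in enumerate(t.labels):
                if i < j:
                    sp = nx.shortest_path_length(G, leaves[a], leaves[b], weight="weight")
                    assert D[i, j] == pytest.approx(sp, abs=1e-9)

    def test_brownian_cherry_covariance(self):
        from bayesnetreg.io import read_tree

        # cherry (A,B) on a shared stem of length 0.4
        t = read_tree("((A:0.5,B:0.2):0.4,C:0.9);")
        Sigma = brownian_covariance(t)
        lab = {l: i for i, l in enumerate(t.labels)}
        assert Sigma[lab["A"], lab["B"]] == pytest.approx(0.4)
        assert Sigma[lab["A"], lab["C"]] == pytest.approx(0.0)
        assert Sigma[lab["A"], lab["A"]] == pytest.approx(0.9)


class TestInfluenceAndEffects:
    def test_influence_extremes(self, rng):
        assert not generate_node_influence(20, 0.0, rng).any()
        assert generate_node_influence(20, 1.0, rng).all()

    def test_influence_binomial_mean(self, rng):
        from scipy import stats as st

        hits = sum(int(generate_node_influence(30, 0.3, rng).sum())
                   for _ in range(10_000))
        p = st.binomtest(hits, 10_000 * 30, 0.3).pvalue
        assert p > 1e-6

    def test_B_all_noninfluential(self, rng):
        assert not generate_B_theoretical(np.zeros(6), 1.6, 1.0, rng).any()

    def test_B_entry_distribution(self, rng):
        xi = np.ones(8)
        entries = []
        for _ in range(2000):
            B = generate_B_theoretical(xi, 0.8, 1.0, rng)
            entries.extend(B[np.triu_indices(8, 1)])
        entries = np.asarray(entries)
        assert abs(entries.mean() - 0.8) < 3 * entries.std() / np.sqrt(entries.size)

    def test_edge_sparsity_pi_squared(self, rng):
        # edges within one replicate share xi, so use replicate-level fractions
        off = np.triu_indices(12, 1)
        fracs = []
        for _ in range(500):
            xi = generate_node_influence(12, 0.3, rng)
            B = generate_B_theoretical(xi, 1.6, 1.0, rng)
            fracs.append(np.count_nonzero(B[off]) / off[0].size)
        fracs = np.asarray(fracs)
        se = fracs.std(ddof=1) / np.sqrt(fracs.size)
        assert abs(fracs.mean() - 0.09) < 3 * se

    def test_main_effects_random_moments(self, rng):
        t = simulate_tree(6, rng)
        draws = np.array([generate_main_effects(t, 1.6, "random", rng) for _ in range(4000)])
        assert abs(draws.mean() - 1.6) < 3 * 1.0 / np.sqrt(draws.size)

    def test_main_effects_brownian_covariance(self, rng):
        t = simulate_tree(5, rng)
        Sigma = brownian_covariance(t)
        draws = np.array(
            [generate_main_effects(t, 0.8, "phylogenetic", rng) for _ in range(10_000)]
        )
        emp = np.cov(draws.T)
        # entrywise MC standard error of a covariance estimate
        se = np.sqrt((np.outer(np.diag(Sigma), np.diag(Sigma)) + Sigma**2) / 10_000)
        assert np.all(np.abs(emp - Sigma) < 4 * se)

    def test_phylogenetic_effects_track_the_tree(self, rng):
        """Closely related leaves have more correlated effects."""
        from scipy import stats as st

        t = simulate_tree(10, rng)
        D = patristic_distances(t)
        draws = np.array(
            [generate_main_effects(t, 0.0, "phylogenetic", rng) for _ in range(2000)]
        )
        corr = np.corrcoef(draws.T)
        iu = np.triu_indices(10, 1)
        rho = st.spearmanr(D[iu], corr[iu]).statistic
        assert rho < -0.5


class TestAdjacency:
    def test_full_sample_all_edges(self, rng):
        t = simulate_tree(6, rng)
        D = patristic_distances(t)
        subset, A = sample_taxa_and_adjacency(D, 6, "zero", rng)
        off = np.triu_indices(6, 1)
        assert np.all(A[off] > 0)

    def test_absent_taxon_zero_row(self, rng):
        t = simulate_tree(6, rng)
        D = patristic_distances(t)
        subset, A = sample_taxa_and_adjacency(D, 3, "presence", rng)
        absent = np.setdiff1d(np.arange(6), subset)
        assert not A[absent].any() and not A[:, absent].any()
        assert np.all(np.diag(A)[subset] == 1.0)

    def test_inverse_distance_value(self):
        D = np.array([[0.0, 2.0], [2.0, 0.0]])
        A = inverse_distance_adjacency(D, np.array([True, True]), "zero")
        assert A[0, 1] == 0.5

    def test_zero_distance_rejected(self):
        D = np.zeros((3, 3))
        with pytest.raises(ValueError, match="positive"):
            inverse_distance_adjacency(D, np.ones(3, dtype=bool), "zero")


class TestResponses:
    def _setup(self, model, rng, **kw):
        cfg = SimulationConfig(V=8, k=4, pi=0.5, mu=1.6, n=5, model=model, **kw)
        ds, truth = simulate_dataset(cfg, rng)
        return cfg, ds, truth

    def test_no_influential_taxa_pure_noise(self, rng):
        cfg = SimulationConfig(V=6, k=3, pi=0.0, mu=1.6, n=300, model="additive")
        ds, truth = simulate_dataset(cfg, rng)
        assert abs(ds.response.mean()) < 3 / np.sqrt(300)

    def test_redundancy_cap_never_exceeded(self, rng):
        cfg = SimulationConfig(V=10, k=8, pi=0.8, mu=1.6, n=200, model="redundant")
        assert cfg.L == REDUNDANCY_CAPS[(0.8, 1.6)] == 30.0
        ds, _ = simulate_dataset(cfg, rng)
        assert np.all(ds.response <= cfg.L)

    def test_capped_fraction_monotone_in_L(self):
        fracs = []
        for L in (1.0, 3.0, 7.0, 15.0):
            cfg = SimulationConfig(V=10, k=8, pi=0.8, mu=1.6, n=200, model="redundant",
                                   L=L)
            ds, _ = simulate_dataset(cfg, np.random.default_rng(5))
            fracs.append(np.mean(ds.response == L))
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))

    def test_interaction_adds_pairwise_terms(self, rng):
        """Interaction response equals the additive part plus a_jl * b_jl terms."""
        cfg, ds, truth = self._setup("interaction", rng, noise_sd=0.0)
        for i in range(ds.n):
            S = truth.sampled_taxa[i]
            infl = [j for j in S if truth.xi_true[j]]
            expected = sum(truth.b_main[j] for j in infl)
            for a, j in enumerate(infl):
                for l in infl[a + 1:]:
                    expected += ds.adjacency[i][j, l] * truth.b_interaction[j, l]
            assert ds.response[i] == pytest.approx(expected, abs=1e-12)

    def test_redundant_requires_cap(self):
        with pytest.raises(ValueError, match="cap"):
            SimulationConfig(V=6, k=3, pi=0.5, mu=1.0, n=5, model="redundant")

    def test_theoretical_matches_frobenius(self, rng):
        cfg, ds, truth = self._setup("theoretical", rng, noise_sd=0.0)
        for i in range(ds.n):
            assert ds.response[i] == pytest.approx(
                np.sum(ds.adjacency[i] * truth.B_true), abs=1e-12
            )


class TestAugmentation:
    def _small(self, rng, n=6):
        cfg = SimulationConfig(V=8, k=4, pi=0.5, mu=1.6, n=n, model="additive")
        ds, truth = simulate_dataset(cfg, rng)
        return cfg, ds, truth

    def _builder(self, truth):
        return lambda mask: inverse_distance_adjacency(truth.distances, mask, "presence")

    def test_round_robin_and_size(self, rng):
        cfg, ds, truth = self._small(rng)
        aug, presence = augment_dataset(ds, truth.sampled_taxa, 20, rng,
                                        self._builder(truth))
        assert aug.n == 20 and len(presence) == 20
        np.testing.assert_array_equal(aug.response[:6], ds.response)

    def test_positivity_fix(self, rng):
        cfg, ds, truth = self._small(rng)
        ds.response[:] = -5.0  # forces negative augmented responses
        aug, _ = augment_dataset(ds, truth.sampled_taxa, 200, rng,
                                 self._builder(truth), positivity_fix=True)
        assert np.all(aug.response[6:] > 0)

    def test_needs_two_originals(self, rng):
        cfg = SimulationConfig(V=6, k=3, pi=0.5, mu=1.6, n=1, model="additive")
        ds, truth = simulate_dataset(cfg, rng)
        with pytest.raises(ValueError, match="at least 2"):
            augment_dataset(ds, truth.sampled_taxa, 5, rng, self._builder(truth))

    def test_augmented_networks_follow_presence(self, rng):
        cfg, ds, truth = self._small(rng)
        aug, presence = augment_dataset(ds, truth.sampled_taxa, 12, rng,
                                        self._builder(truth))
        for i in range(6, 12):
            mask = np.zeros(8, dtype=bool)
            mask[presence[i]] = True
            np.testing.assert_array_equal(
                aug.adjacency[i],
                inverse_distance_adjacency(truth.distances, mask, "presence"),
            )
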