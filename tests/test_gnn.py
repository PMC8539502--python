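import numpy as np
import pytest

from conftest import make_graph, permute_graph
from oracle_impl import naive_forward

from dgin import nn
from dgin.gnn import (
    ARCHITECTURES,
    ConfigurationError,
    GNNConfig,
    GNNModel,
    GraphBatch,
    aggregate_node_messages,
    combine_node,
    edge_message_pass,
    edge_messages,
    gin_update,
    init_edge_hidden,
    sum_pool,
)
from dgin.nn import Tensor, identity


def single_batch(g):
    return GraphBatch.from_graphs([g])


class TestEdgePhase:
    def test_init_identity_collapse(self):
        """With an identity map and identity activation the initial edge
        state is exactly cat(x_u, x_e_uw)."""
        rng = np.random.default_rng(0)
        g = make_graph(3, [(0, 1), (1, 2)], d=2, b=2, rng=rng)
        h0 = init_edge_hidden(single_batch(g), lambda t: t, identity)
        for e in range(g.n_edges):
            np.testing.assert_array_equal(
                h0.data[e], np.concatenate([g.X[g.src[e]], g.E[e]])
            )

    def test_init_zero_features_relu(self):
        g = make_graph(2, [(0, 1)], d=3, b=2)
        g.X[:] = 0.0
        g.E[:] = 0.0
        rng = np.random.default_rng(1)
        lin = nn.Linear(rng, 5, 4, bias=False)
        h0 = init_edge_hidden(single_batch(g), lin, nn.relu)
        np.testing.assert_array_equal(h0.data, 0.0)

    def test_two_node_messages_always_zero(self):
        """Backtracking exclusion: on a single bond the reverse edge is the
        only incoming edge, so every message is exactly zero at every t."""
        rng = np.random.default_rng(2)
        g = make_graph(2, [(0, 1)], d=3, b=2, rng=rng)
        batch = single_batch(g)
        H = Tensor(rng.normal(size=(2, 4)))
        for _ in range(5):
            m = edge_messages(H, batch)
            np.testing.assert_array_equal(m.data, 0.0)
            H = Tensor(rng.normal(size=(2, 4)))

    def test_path_exclusion_rule(self):
        """On a path a-b-c: the message into b->c is h_{a->b}; the message
        into b->a is h_{c->b}."""
        g = make_graph(3, [(0, 1), (1, 2)], d=1, b=1)
        batch = single_batch(g)
        # edge order: 0:(0->1) 1:(1->0) 2:(1->2) 3:(2->1)
        H = Tensor(np.arange(8.0).reshape(4, 2) + 1)
        m = edge_messages(H, batch).data
        np.testing.assert_array_equal(m[2], H.data[0])  # m_{bc} = h_{ab}
        np.testing.assert_array_equal(m[1], H.data[3])  # m_{ba} = h_{cb}
        np.testing.assert_array_equal(m[0], 0.0)        # nothing enters a but b->a
        np.testing.assert_array_equal(m[3], 0.0)

    def test_update_skip_is_initial_state(self):
        """h^{t+1} = act(h0 + W_m m): on a 2-node graph (zero messages) every
        iterate equals act(h0), not a compounding of previous iterates."""
        rng = np.random.default_rng(3)
        g = make_graph(2, [(0, 1)], d=3, b=2, rng=rng)
        batch = single_batch(g)
        lin = nn.Linear(rng, 5, 4)
        w_m = nn.Linear(rng, 4, 4, bias=False)
        H0 = init_edge_hidden(batch, lin, nn.relu)
        H = H0
        for _ in range(3):
            H = edge_message_pass(H, H0, batch, w_m, nn.relu)
            np.testing.assert_allclose(H.data, np.maximum(H0.data, 0.0))

    def test_star_graph_matches_double_loop(self):
        rng = np.random.default_rng(4)
        g = make_graph(4, [(0, 1), (0, 2), (0, 3)], d=2, b=2, rng=rng)
        batch = single_batch(g)
        lin = nn.Linear(rng, 4, 5)
        w_m = nn.Linear(rng, 5, 5, bias=False)
        H0 = init_edge_hidden(batch, lin, nn.relu)
        H = edge_message_pass(H0, H0, batch, w_m, nn.relu)
        edges = list(zip(g.src, g.dst))
        for e, (u, w) in enumerate(edges):
            m = np.zeros(5)
            for e2, (k, tgt) in enumerate(edges):
                if tgt == u and k != w:
                    m += H0.data[e2]
            expected = np.maximum(H0.data[e] + m @ w_m.W.data, 0.0)
            np.testing.assert_allclose(H.data[e], expected, atol=1e-12)


class TestNodePhase:
    def test_isolated_node_zero_message(self):
        g = make_graph(1, [], d=2, b=3)
        m_u = aggregate_node_messages(Tensor(np.zeros((0, 4))), single_batch(g))
        np.testing.assert_array_equal(m_u.data, np.zeros((1, 4)))

    def test_ethane_single_incoming_edge(self):
        g = make_graph(2, [(0, 1)], d=2, b=2)
        H = Tensor(np.array([[1.0, 2.0], [3.0, 4.0]]))
        m_u = aggregate_node_messages(H, single_batch(g)).data
        np.testing.assert_array_equal(m_u[1], H.data[0])  # edge 0->1 lands on 1
        np.testing.assert_array_equal(m_u[0], H.data[1])

    def test_total_message_mass_conserved(self, random_small_graphs):
        for g in random_small_graphs[:5]:
            batch = single_batch(g)
            H = Tensor(np.random.default_rng(0).normal(size=(g.n_edges, 3)))
            m_u = aggregate_node_messages(H, batch)
            np.testing.assert_allclose(m_u.data.sum(axis=0), H.data.sum(axis=0))

    def test_combine_node_variants(self):
        m_u = Tensor(np.zeros((2, 3)))
        X = np.array([[1.0, 2.0], [3.0, 4.0]])
        out = combine_node(m_u, X, "d-gin")
        assert out.shape == (2, 5)  # c + d
        out2 = combine_node(m_u, X, "d-mpnn", w_agg=lambda t: t)
        np.testing.assert_array_equal(out.data, out2.data)
        np.testing.assert_array_equal(out.data[:, 3:], X)


class TestGINUpdate:
    def test_isolated_node_identity(self):
        g = make_graph(1, [], d=3, b=1)
        h = Tensor(np.array([[1.0, -2.0, 0.5]]))
        out = gin_update(h, single_batch(g), Tensor(np.zeros(1)), lambda t: t)
        np.testing.assert_array_equal(out.data, h.data)

    def test_two_equal_nodes_double(self):
        g = make_graph(2, [(0, 1)], d=3, b=1)
        h = Tensor(np.tile([1.0, 2.0, 3.0], (2, 1)))
        out = gin_update(h, single_batch(g), Tensor(np.zeros(1)), lambda t: t)
        np.testing.assert_allclose(out.data, 2 * h.data)

    def test_eps_minus_one_is_pure_neighbor_sum(self):
        rng = np.random.default_rng(7)
        g = make_graph(4, [(0, 1), (1, 2), (2, 3), (3, 0)], d=2, b=1, rng=rng)
        h = Tensor(rng.normal(size=(4, 2)))
        out = gin_update(h, single_batch(g), Tensor(-np.ones(1)), lambda t: t)
        for v in range(4):
            nbrs = [int(u) for u, w in zip(g.src, g.dst) if w == v]
            np.testing.assert_allclose(out.data[v], h.data[nbrs].sum(axis=0))


class TestReadout:
    def test_single_node_pool(self):
        g = make_graph(1, [], d=3, b=1)
        h = Tensor(np.array([[1.0, 2.0, 3.0]]))
        np.testing.assert_array_equal(sum_pool(h, single_batch(g)).data, h.data)

    def test_constant_head(self):
        rng = np.random.default_rng(8)
        model = GNNModel(GNNConfig(architecture="gin", strategy_id=5, c=8,
                                   T=1, T2=1, readout_hidden=(), n_props=2,
                                   seed=0))
        model.readout.layers[-1].W.data[:] = 0.0
        beta = np.array([1.25, -0.5])
        model.readout.layers[-1].b.data[:] = beta
        from dgin.molgraph import graph_from_smiles

        pred = model.predict([graph_from_smiles("CCO", 5),
                              graph_from_smiles("c1ccccc1", 5)])
        np.testing.assert_allclose(pred, np.tile(beta, (2, 1)))


class TestForward:
    @pytest.mark.parametrize("arch", ARCHITECTURES)
    def test_matches_naive_loop_oracle(self, arch, random_small_graphs):
        """Vectorized forward equals an explicit per-edge/per-node loop
        implementation on >= 20 random graphs with <= 8 nodes."""
        model = GNNModel(GNNConfig(architecture=arch, strategy_id=3, c=6,
                                   T=2, T2=2, readout_hidden=(5,), n_props=2,
                                   seed=3))
        assert len(random_small_graphs) >= 20
        batch = GraphBatch.from_graphs(random_small_graphs)
        pred = model.forward(batch).data
        for i, g in enumerate(random_small_graphs):
            assert g.n <= 8
            np.testing.assert_allclose(pred[i], naive_forward(model, g),
                                       atol=1e-6)

    @pytest.mark.parametrize("arch", ARCHITECTURES)
    def test_permutation_invariance(self, arch, random_small_graphs):
        model = GNNModel(GNNConfig(architecture=arch, strategy_id=3, c=8,
                                   T=2, T2=2, readout_hidden=(8,), n_props=1,
                                   seed=4))
        rng = np.random.default_rng(9)
        for g in random_small_graphs[:3]:
            base_embed = model.embed(single_batch(g)).data
            base_pred = model.forward(single_batch(g)).data
            for _ in range(20):
                perm = rng.permutation(g.n)
                gp = permute_graph(g, perm)
                np.testing.assert_allclose(model.embed(single_batch(gp)).data,
                                           base_embed, rtol=1e-5, atol=1e-8)
                np.testing.assert_allclose(model.forward(single_batch(gp)).data,
                                           base_pred, rtol=1e-5, atol=1e-8)

    def test_deterministic_inference(self, random_small_graphs):
        model = GNNModel(GNNConfig(strategy_id=3, c=8, T=2, T2=1,
                                   readout_hidden=(8,), n_props=1, seed=5))
        p1 = model.predict(random_small_graphs[:5])
        p2 = model.predict(random_small_graphs[:5])
        np.testing.assert_array_equal(p1, p2)

    def test_output_count_matches_properties(self, random_small_graphs):
        for k in (1, 2, 3):
            model = GNNModel(GNNConfig(strategy_id=3, c=4, T=1, T2=1,
                                       readout_hidden=(), n_props=k, seed=0))
            assert model.predict(random_small_graphs[:2]).shape == (2, k)

    def test_dgin_without_gin_phase_follows_dmpnn_path(self,
                                                       random_small_graphs):
        """With T2=0 the composite reduces to the directed-edge pipeline:
        sharing the edge-phase weights and an identity aggregation map, the
        two architectures produce identical predictions."""
        dgin = GNNModel(GNNConfig(architecture="d-gin", strategy_id=3, c=6,
                                  T=2, T2=0, readout_hidden=(4,), n_props=1,
                                  seed=6))
        dmpnn = GNNModel(GNNConfig(architecture="d-mpnn", strategy_id=3, c=6,
                                   T=2, T2=0, readout_hidden=(4,), n_props=1,
                                   seed=7))
        dmpnn.w_init.W.data = dgin.w_init.W.data.copy()
        dmpnn.w_init.b.data = dgin.w_init.b.data.copy()
        dmpnn.w_m.W.data = dgin.w_m.W.data.copy()
        dmpnn.w_agg = lambda t: t  # identity aggregation map
        dmpnn.readout = dgin.readout
        batch = GraphBatch.from_graphs(random_small_graphs[:6])
        np.testing.assert_allclose(dmpnn.forward(batch).data,
                                   dgin.forward(batch).data, atol=1e-12)

    def test_single_atom_molecule_flows_through(self):
        from dgin.molgraph import graph_from_smiles

        for arch in ARCHITECTURES:
            model = GNNModel(GNNConfig(architecture=arch, strategy_id=3, c=4,
                                       T=1, T2=1, readout_hidden=(), n_props=1,
                                       seed=1))
            pred = model.predict([graph_from_smiles("C", 3)])
            assert np.isfinite(pred).all()

    def test_dimension_mismatch_raises(self, random_small_graphs):
        model = GNNModel(GNNConfig(strategy_id=5, c=4, T=1, T2=1,
                                   readout_hidden=(), n_props=1, seed=0))
        with pytest.raises(ConfigurationError):
            model.forward(GraphBatch.from_graphs(random_small_graphs[:2]))


class TestWLPair:
    """Naphthalene vs 1,1-bi(cyclopentane) skeletons.

    The two 10-node skeletons are non-isomorphic but equivalent under 1-WL
    color refinement AND under non-backtracking directed-edge refinement at
    every depth.  Message-passing networks compute refinement-bounded
    functions, so with uniform features every architecture here provably
    collapses the pair; what actually separates the molecules in practice is
    chemistry — ring size, aromaticity — carried by the featurization.
    """

    @pytest.mark.parametrize("arch", ARCHITECTURES)
    def test_uniform_features_collapse_the_pair(self, arch):
        from dgin.synthetic import wl_pair

        naph, bicp = wl_pair()
        model = GNNModel(
            GNNConfig(architecture=arch, strategy_id=3, c=8, T=4, T2=2,
                      readout_hidden=(), n_props=1, seed=12),
            d=1, b=1,
        )
        e1 = model.embed(single_batch(naph)).data
        e2 = model.embed(single_batch(bicp)).data
        np.testing.assert_allclose(e1, e2, rtol=1e-9, atol=1e-9)

    @pytest.mark.parametrize("arch", ARCHITECTURES)
    def test_chemical_features_separate_the_molecules(self, arch):
        from dgin.molgraph import graph_from_smiles

        naph = graph_from_smiles("c1ccc2ccccc2c1", 3)
        bicp = graph_from_smiles("C1CCC(C1)C1CCCC1", 3)
        model = GNNModel(GNNConfig(architecture=arch, strategy_id=3, c=8,
                                   T=2, T2=2, readout_hidden=(), n_props=1,
                                   seed=12))
        e1 = model.embed(single_batch(naph)).data
        e2 = model.embed(single_batch(bicp)).data
        assert np.linalg.norm(e1 - e2) > 1e-3


class TestCheckpoint:
    def test_round_trip_bit_exact(self, tmp_path, random_small_graphs):
        model = GNNModel(GNNConfig(architecture="d-gin", strategy_id=4, c=6,
                                   T=2, T2=2, readout_hidden=(6,), n_props=2,
                                   seed=13))
        model.save(tmp_path / "ckpt")
        loaded = GNNModel.load(tmp_path / "ckpt")
        for a, b in zip(model.parameters(), loaded.parameters()):
            np.testing.assert_array_equal(a.data, b.data)
        g4 = [g for g in random_small_graphs]
        from dgin.molgraph import build_graph, parse_molecule
        from dgin.synthetic import generate_library

        graphs = [build_graph(parse_molecule(s), 4)
                  for s in generate_library(5, seed=2, max_atoms=6)]
        np.testing.assert_array_equal(model.predict(graphs),
                                      loaded.predict(graphs))

    def test_bad_config_rejected(self):
        with pytest.raises(ValueError):
            GNNConfig(architecture="mpnn")
        with pytest.raises(ValueError):
            GNNConfig(T=0)
        with pytest.raises(ValueError):
            GNNConfig(architecture="gin", T2=0)
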