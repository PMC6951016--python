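"""Architecture semantics: oracle equivalence, attention normalization,
no-backflow, receptive fields, isomorphism invariance, config validation."""

import numpy as np
import pytest
from rdkit import Chem

import molmpnn as mm
from molmpnn import autodiff as ad
from molmpnn.autodiff import Tensor
from molmpnn.models import ConfigError, _segment_softmax

from conftest import (tiny_config, mlp_np, gru_np, mpnn_message_oracle,
                      ampnn_message_oracle, emnn_message_oracle,
                      readout_oracle, sigmoid_np)


def _single(graph):
    return mm.batch_graphs([graph])


class TestMpnnMessage:
    def test_isolated_node_zero_message(self):
        model = mm.build_model(tiny_config("selu-mpnn"), 40, 1, seed=0)
        g = mm.featurize_molecule("O")
        batch = _single(g)
        h = model.initial_states(batch)
        m = model.aggregate(h, batch)
        np.testing.assert_array_equal(m.data, np.zeros((1, model.D)))

    def test_matches_loop_oracle_on_small_graphs(self, small_graphs):
        model = mm.build_model(tiny_config("selu-mpnn"), 40, 1, seed=1)
        for g in small_graphs:
            batch = _single(g)
            h = model.initial_states(batch)
            m = model.aggregate(h, batch)
            np.testing.assert_allclose(
                m.data, mpnn_message_oracle(model, h.data, g), atol=1e-6)


class TestAmpnnAttention:
    def test_single_neighbour_weight_is_one(self):
        model = mm.build_model(tiny_config("ampnn"), 40, 1, seed=2)
        g = mm.featurize_molecule("CO")
        batch = _single(g)
        h = model.initial_states(batch)
        m = model.aggregate(h, batch)
        # with one neighbour the message is exactly f(h_w)
        for v in range(2):
            w = 1 - v
            c = int(np.argmax(g.edge_features[0]))
            np.testing.assert_allclose(
                m.data[v], mlp_np(model.f_nets[c], h.data[w]), atol=1e-10)

    def test_identical_neighbours_split_evenly(self):
        model = mm.build_model(tiny_config("ampnn"), 40, 1, seed=3)
        g = mm.featurize_molecule("OCO")  # center C with two identical O
        batch = _single(g)
        h = model.initial_states(batch)
        m = model.aggregate(h, batch)
        c = int(np.argmax(g.edge_features[0]))
        center = 1
        nbr = 0
        np.testing.assert_allclose(
            m.data[center], mlp_np(model.f_nets[c], h.data[nbr]), atol=1e-8)

    def test_matches_softmax_loop_oracle(self, small_graphs):
        model = mm.build_model(tiny_config("ampnn"), 40, 1, seed=4)
        for g in small_graphs:
            batch = _single(g)
            h = model.initial_states(batch)
            m = model.aggregate(h, batch)
            np.testing.assert_allclose(
                m.data, ampnn_message_oracle(model, h.data, g), atol=1e-6)

    def test_weights_sum_to_one_per_element(self, small_graphs):
        model = mm.build_model(tiny_config("ampnn"), 40, 1, seed=5)
        for g in small_graphs:
            if g.n_directed_edges == 0:
                continue
            batch = _single(g)
            h = model.initial_states(batch)
            h_w = ad.gather_rows(h, batch.edge_index[:, 1])
            from molmpnn.models import _per_class_apply
            scores = _per_class_apply(model.g_nets, h_w, batch.edge_features)
            att = _segment_softmax(scores, batch.edge_index[:, 0],
                                   batch.n_atoms)
            sums = np.zeros((batch.n_atoms, model.D))
            np.add.at(sums, batch.edge_index[:, 0], att.data)
            occupied = np.unique(batch.edge_index[:, 0])
            np.testing.assert_allclose(sums[occupied], 1.0, atol=1e-6)


class TestEmnn:
    def test_edge_embed_symmetric_endpoints(self):
        model = mm.build_model(tiny_config("emnn"), 40, 1, seed=6)
        g = mm.featurize_molecule("CC")  # identical endpoints
        e = model.edge_embed(_single(g))
        np.testing.assert_allclose(e.data[0], e.data[1], atol=1e-12)

    def test_edge_embed_order_sensitive(self):
        model = mm.build_model(tiny_config("emnn"), 40, 1, seed=7)
        g = mm.featurize_molecule("CO")  # distinct endpoints
        e = model.edge_embed(_single(g))
        assert np.abs(e.data[0] - e.data[1]).max() > 1e-8

    def test_edge_embed_zero_weights_gives_bias(self):
        model = mm.build_model(tiny_config("emnn"), 40, 1, seed=8)
        for layer in model.embed_net.layers:
            layer.W.data[:] = 0.0
        model.embed_net.layers[-1].b.data[:] = 0.25
        e = model.edge_embed(_single(mm.featurize_molecule("CCO")))
        # hidden SELU(0)=0, so output = final bias exactly
        np.testing.assert_allclose(e.data, 0.25, atol=1e-12)

    def test_terminal_edge_message_is_f_of_edge_embedding(self):
        model = mm.build_model(tiny_config("emnn"), 40, 1, seed=9)
        g = mm.featurize_molecule("CCO")
        batch = _single(g)
        e = model.edge_embed(batch)
        inc, owners = model.incoming_structure(batch)
        h_e = Tensor(np.random.default_rng(0).normal(
            size=(g.n_directed_edges, model.E)))
        m = model.aggregate(h_e, e, inc, owners, g.n_directed_edges)
        view = mm.build_directed_edge_view(g)
        for i in range(g.n_directed_edges):
            if len(view.incoming_lists[i]) == 0:  # tail has degree 1
                np.testing.assert_allclose(
                    m.data[i], mlp_np(model.f_net, e.data[i]), atol=1e-8)

    def test_matches_loop_oracle(self, small_graphs):
        model = mm.build_model(tiny_config("emnn"), 40, 1, seed=10)
        rng = np.random.default_rng(1)
        for g in small_graphs:
            if g.n_directed_edges == 0:
                continue
            batch = _single(g)
            e = model.edge_embed(batch)
            inc, owners = model.incoming_structure(batch)
            h_e = Tensor(rng.normal(size=(g.n_directed_edges, model.E)))
            m = model.aggregate(h_e, e, inc, owners, g.n_directed_edges)
            np.testing.assert_allclose(
                m.data, emnn_message_oracle(model, h_e.data, e.data, g),
                atol=1e-6)

    def test_no_backflow_on_path(self):
        """On A-B-C, the message to (B,C) ignores the state of (C,B) exactly."""
        model = mm.build_model(tiny_config("emnn"), 40, 1, seed=11)
        g = mm.featurize_molecule("CCO")
        batch = _single(g)
        e = model.edge_embed(batch)
        inc, owners = model.incoming_structure(batch)
        pos = {tuple(p): i for i, p in enumerate(map(tuple, g.edge_index))}
        bc, cb = pos[(1, 2)], pos[(2, 1)]
        rng = np.random.default_rng(2)
        h1 = rng.normal(size=(g.n_directed_edges, model.E))
        h2 = h1.copy()
        h2[cb] = 0.0  # zero the reverse edge state
        m1 = model.aggregate(Tensor(h1), e, inc, owners, g.n_directed_edges)
        m2 = model.aggregate(Tensor(h2), e, inc, owners, g.n_directed_edges)
        np.testing.assert_array_equal(m1.data[bc], m2.data[bc])

    def test_collapse_matches_per_node_loop(self, small_graphs):
        model = mm.build_model(tiny_config("emnn"), 40, 1, seed=12)
        rng = np.random.default_rng(3)
        for g in small_graphs:
            batch = _single(g)
            h_e = rng.normal(size=(g.n_directed_edges, model.E))
            out = model.collapse(Tensor(h_e), batch)
            expected = np.zeros((g.n_atoms, model.E))
            for i, (v, w) in enumerate(g.edge_index):
                expected[v] += h_e[i]
            np.testing.assert_allclose(out.data, expected, atol=1e-12)

    def test_attention_weights_sum_to_one_including_self(self, small_graphs):
        model = mm.build_model(tiny_config("emnn"), 40, 1, seed=13)
        rng = np.random.default_rng(4)
        for g in small_graphs:
            if g.n_directed_edges == 0:
                continue
            batch = _single(g)
            e = model.edge_embed(batch)
            inc, owners = model.incoming_structure(batch)
            h_e = Tensor(rng.normal(size=(g.n_directed_edges, model.E)))
            g_self = model.g_net(e)
            if len(inc):
                g_in = model.g_net(ad.gather_rows(h_e, inc))
                att_in, att_self = _segment_softmax(
                    g_in, owners, g.n_directed_edges, extra=g_self)
                sums = att_self.data.copy()
                np.add.at(sums, owners, att_in.data)
            else:
                _, att_self = _segment_softmax(
                    Tensor(np.zeros((0, model.E))), owners,
                    g.n_directed_edges, extra=g_self)
                sums = att_self.data
            np.testing.assert_allclose(sums, 1.0, atol=1e-6)


class TestReadoutAndForward:
    def test_single_node_readout(self):
        model = mm.build_model(tiny_config("selu-mpnn", message_passes=0),
                               40, 1, seed=14)
        g = mm.featurize_molecule("O")
        batch = _single(g)
        h0 = model.initial_states(batch)
        y = model.head.readout(h0, h0, batch.node_membership, 1)
        np.testing.assert_allclose(y.data[0],
                                   readout_oracle(model, h0.data, h0.data, g),
                                   atol=1e-10)

    def test_readout_additive_over_fragments(self, architecture):
        model = mm.build_model(tiny_config(architecture), 40, 1, seed=15)
        both = mm.featurize_molecule("CCO.CCN")
        a = mm.featurize_molecule("CCO")
        b = mm.featurize_molecule("CCN")
        # fragments exchange no messages, so everything up to the output
        # head is additive; compare at the readout vector
        def graph_vec(graph):
            batch = _single(graph)
            if architecture == "emnn":
                e = model.edge_embed(batch)
                inc, owners = model.incoming_structure(batch)
                h = Tensor(np.zeros((graph.n_directed_edges, model.E)))
                for _ in range(model.config.message_passes):
                    h = model.gru(model.aggregate(h, e, inc, owners,
                                                  graph.n_directed_edges), h)
                hv = model.collapse(h, batch)
                h0 = Tensor(batch.node_features)
            else:
                h0 = model.initial_states(batch)
                hv = h0
                for _ in range(model.config.message_passes):
                    hv = model.gru(model.aggregate(hv, batch), hv)
            return model.head.readout(hv, h0, batch.node_membership, 1).data[0]

        np.testing.assert_allclose(graph_vec(both),
                                   graph_vec(a) + graph_vec(b), atol=1e-8)

    def test_k0_uses_initial_states_only(self):
        cfg = tiny_config("selu-mpnn", message_passes=0)
        model = mm.build_model(cfg, 40, 1, seed=16)
        g = mm.featurize_molecule("CCO")
        out = model.forward(g)
        batch = _single(g)
        h0 = model.initial_states(batch)
        y = model.head.readout(h0, h0, batch.node_membership, 1)
        expected = model.head.output(y, model.rng, training=False)
        np.testing.assert_allclose(out.data, expected.data, atol=1e-12)

    def test_isomorphic_smiles_identical_output(self, architecture):
        model = mm.build_model(tiny_config(architecture), 40, 2, seed=17)
        o1 = model.forward(mm.featurize_molecule("OCC")).data
        o2 = model.forward(mm.featurize_molecule("CCO")).data
        np.testing.assert_allclose(o1, o2, atol=1e-6)

    def test_full_forward_hand_trace_k1(self):
        """3-atom molecule, K=1 SELU-MPNN: trace the whole pass by hand."""
        cfg = tiny_config("selu-mpnn", message_passes=1)
        model = mm.build_model(cfg, 40, 1, seed=18)
        g = mm.featurize_molecule("CCO")
        batch = _single(g)
        h0 = model.initial_states(batch).data
        m = mpnn_message_oracle(model, h0, g)
        h1 = gru_np(model.gru, m, h0)
        r = readout_oracle(model, h1, h0, g)
        y = r
        for i, layer in enumerate(model.head.out_layers):
            y = y @ layer.W.data + layer.b.data
            if i < len(model.head.out_layers) - 1:
                from conftest import selu_np
                y = selu_np(y)
        out = model.forward(g)
        np.testing.assert_allclose(out.data[0], y, atol=1e-8)

    def test_receptive_field_bound(self):
        """Perturbing an atom > K bonds away leaves h_v^(K) unchanged."""
        cfg = tiny_config("ampnn", message_passes=2)
        model = mm.build_model(cfg, 40, 1, seed=19)
        g = mm.featurize_molecule("CCCCCCCO")  # 8-atom path
        batch1 = _single(g)
        batch2 = _single(g)
        batch2.node_features = batch2.node_features.copy()
        batch2.node_features[7] += 1.0  # perturb the far end

        def states(batch):
            h = model.initial_states(batch)
            for _ in range(cfg.message_passes):
                h = model.gru(model.aggregate(h, batch), h)
            return h.data

        h1, h2 = states(batch1), states(batch2)
        # atom 0 is 7 bonds from atom 7; K=2 cannot reach it
        np.testing.assert_array_equal(h1[0], h2[0])
        for v in range(3):  # atoms within distance > 2 of the perturbation
            np.testing.assert_array_equal(h1[v], h2[v])
        assert np.abs(h1[6] - h2[6]).max() > 0  # within reach: does change


class TestConfig:
    def test_selu_mpnn_rejects_attention_dim(self):
        with pytest.raises(ConfigError):
            mm.ModelConfig(architecture="selu-mpnn", att_hidden_dim=50).validate()

    def test_ampnn_requires_attention_dim(self):
        with pytest.raises(ConfigError):
            mm.ModelConfig(architecture="ampnn").validate()

    def test_emnn_rejects_message_size(self):
        with pytest.raises(ConfigError):
            mm.ModelConfig(architecture="emnn", message_size=25,
                           att_hidden_dim=50, edge_emb_hidden_dim=60,
                           edge_embedding_size=30).validate()

    def test_unknown_architecture(self):
        with pytest.raises(ConfigError):
            mm.ModelConfig(architecture="gcn").validate()

    def test_text_round_trip(self):
        cfg = tiny_config("emnn")
        back = mm.ModelConfig.from_text(cfg.to_text())
        assert back == cfg
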