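"""Shared fixtures: tiny model configs, small molecule sets, numpy oracles.

The `*_np` helpers re-evaluate the models' building blocks with plain Python
loops and NumPy, reading the learned weights directly — an independent
execution path against which the batched implementations are checked.
"""

import numpy as np
import pytest

import molmpnn as mm

SELU_ALPHA = 1.6732632423543772848170429916717
SELU_LAMBDA = 1.0507009873554804934193349852946


# ---- tiny configs ---------------------------------------------------------

def tiny_config(architecture: str, message_passes: int = 2) -> mm.ModelConfig:
    base = dict(architecture=architecture, learn_rate=1e-3,
                message_passes=message_passes, msg_hidden_dim=10,
                gather_width=8, gather_emb_hidden_dim=6,
                gather_att_hidden_dim=6, out_hidden_dim=12,
                out_dropout_p=0.0, out_layer_shrinkage=0.5)
    if architecture == "selu-mpnn":
        return mm.ModelConfig(message_size=9, **base)
    if architecture == "ampnn":
        return mm.ModelConfig(message_size=9, att_hidden_dim=8, **base)
    return mm.ModelConfig(message_size=None, att_hidden_dim=8,
                          edge_emb_hidden_dim=10, edge_embedding_size=9, **base)


@pytest.fixture(params=["selu-mpnn", "ampnn", "emnn"])
def architecture(request):
    return request.param


# ---- molecule sets --------------------------------------------------------

SMALL_MOLECULES = [
    "O",            # single heavy atom
    "CCO",          # path
    "CC(C)O",       # branch
    "C1CCC1",       # ring
    "c1ccoc1",      # aromatic 5-ring, <=6 atoms
    "CC#N",         # triple bond
    "C=CC",         # double bond
    "CC(=O)O",      # mixed
]


@pytest.fixture(scope="session")
def small_graphs():
    return [mm.featurize_molecule(s) for s in SMALL_MOLECULES]


@pytest.fixture(scope="session")
def fixture_molecules():
    spec = mm.FixtureSpec(n_molecules=100, seed=42)
    return mm.gen_molecules(spec)


# ---- numpy oracles --------------------------------------------------------

def selu_np(x):
    return np.where(x > 0, SELU_LAMBDA * x,
                    SELU_LAMBDA * SELU_ALPHA * np.expm1(x))


def sigmoid_np(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def mlp_np(mlp, x):
    """Evaluate an autodiff MLP on a single numpy row vector."""
    x = np.asarray(x, dtype=np.float64)
    n = len(mlp.layers)
    for i, layer in enumerate(mlp.layers):
        x = x @ layer.W.data + layer.b.data
        if i < n - 1 or mlp.final_activation:
            x = selu_np(x)
    return x


def gru_np(gru, x, h):
    z = sigmoid_np(x @ gru.Wz.data + h @ gru.Uz.data + gru.bz.data)
    r = sigmoid_np(x @ gru.Wr.data + h @ gru.Ur.data + gru.br.data)
    n = np.tanh(x @ gru.Wn.data + r * (h @ gru.Un.data + gru.bhn.data)
                + gru.bn.data)
    return (1 - z) * n + z * h


def neighbours_of(graph, v):
    return [(int(w), graph.edge_features[i])
            for i, (t, w) in enumerate(graph.edge_index) if t == v]


def mpnn_message_oracle(model, h, graph):
    """Per-node double loop over neighbours: m_v = sum f^(class)(h_w)."""
    m = np.zeros((graph.n_atoms, model.D))
    for v in range(graph.n_atoms):
        for w, onehot in neighbours_of(graph, v):
            c = int(np.argmax(onehot))
            m[v] += mlp_np(model.msg_nets[c], h[w])
    return m


def ampnn_message_oracle(model, h, graph):
    """Explicit per-node softmax loop for the attention aggregation."""
    m = np.zeros((graph.n_atoms, model.D))
    for v in range(graph.n_atoms):
        nbrs = neighbours_of(graph, v)
        if not nbrs:
            continue
        embs, scores = [], []
        for w, onehot in nbrs:
            c = int(np.argmax(onehot))
            embs.append(mlp_np(model.f_nets[c], h[w]))
            scores.append(mlp_np(model.g_nets[c], h[w]))
        scores = np.array(scores)
        scores -= scores.max(axis=0)
        weights = np.exp(scores) / np.exp(scores).sum(axis=0)
        m[v] = (np.array(embs) * weights).sum(axis=0)
    return m


def emnn_message_oracle(model, h_e, e_emb, graph):
    """Per-directed-edge loop over S' = incoming states + own e'."""
    view = mm.build_directed_edge_view(graph)
    n_edges = graph.n_directed_edges
    m = np.zeros((n_edges, model.E))
    for i in range(n_edges):
        members = [h_e[j] for j in view.incoming_lists[i]] + [e_emb[i]]
        fs = np.array([mlp_np(model.f_net, x) for x in members])
        gs = np.array([mlp_np(model.g_net, x) for x in members])
        gs -= gs.max(axis=0)
        weights = np.exp(gs) / np.exp(gs).sum(axis=0)
        m[i] = (fs * weights).sum(axis=0)
    return m


def readout_oracle(model, h_final, h_init, graph):
    """Single-molecule gated readout by explicit summation."""
    head = model.head
    out = np.zeros(head.p.layers[-1].b.data.shape)
    for v in range(graph.n_atoms):
        p = mlp_np(head.p, h_final[v])
        q = mlp_np(head.q, np.concatenate([h_final[v], h_init[v]]))
        out = out + p * sigmoid_np(q)
    return out
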