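"""The three message-passing architectures: SELU-MPNN, AMPNN, EMNN.

All three follow the message / update / readout decomposition over molecular
graphs:

* **SELU-MPNN** — the baseline: per-bond-class feed-forward message networks,
  messages summed over the neighbourhood, GRU state update, gated (GGNN-style)
  readout. SELU activations throughout stand in for explicit normalization
  layers.
* **AMPNN** — replaces the plain neighbour sum with an elementwise attention:
  per-bond-class embedding networks f and weighting networks g of equal output
  width; the weights are softmax-normalized along the neighbour axis, so every
  output element carries its own convex combination of neighbour embeddings.
* **EMNN** — keeps a hidden state on every *directed* edge. A static edge
  embedding e' is computed once from the bond one-hot and the two raw endpoint
  atom feature vectors (order-sensitive). Each step, the state of edge (v, w)
  attends over the states of incoming edges (k, v) with k != w — never its own
  reverse, so information cannot flow straight back — plus its own e'. After K
  passes the edge states are collapsed onto nodes by summation and the same
  gated readout applies.

Classification heads emit pre-sigmoid scores; regression heads emit values in
normalized target space.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, fields as dc_fields

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .chem_graph import (BatchedGraph, MolecularGraph, batch_graphs,
                         build_directed_edge_view)

__all__ = ["ModelConfig", "ConfigError", "SeluMPNN", "AMPNN", "EMNN",
           "build_model", "ARCHITECTURES"]

ARCHITECTURES = ("selu-mpnn", "ampnn", "emnn")
N_BOND_CLASSES = 4


class ConfigError(ValueError):
    """Raised on architecture / hyperparameter mismatches."""


@dataclass
class ModelConfig:
    """Architecture selector plus the tunable hyperparameters.

    ``message_size`` is the node hidden width D (SELU-MPNN / AMPNN only; the
    EMNN's edge state width is ``edge_embedding_size``). ``att_hidden_dim``
    is the hidden width of the attention weighting networks (AMPNN / EMNN
    only). The output head is a 3-layer shrinking feed-forward stack whose
    first width is ``out_hidden_dim`` and whose successive widths scale by
    ``out_layer_shrinkage``.
    """

    architecture: str = "selu-mpnn"
    learn_rate: float = 1e-4
    message_size: int | None = 25
    message_passes: int = 3
    msg_hidden_dim: int = 50
    gather_width: int = 45
    gather_emb_hidden_dim: int = 26
    gather_att_hidden_dim: int = 26
    out_hidden_dim: int = 360
    out_dropout_p: float = 0.0
    out_layer_shrinkage: float = 0.5
    att_hidden_dim: int | None = None
    edge_emb_hidden_dim: int | None = None
    edge_embedding_size: int | None = None

    def validate(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ConfigError(f"unknown architecture {self.architecture!r}")
        if self.message_passes < 0:
            raise ConfigError("message_passes must be >= 0")
        needs_attention = self.architecture in ("ampnn", "emnn")
        if needs_attention and self.att_hidden_dim is None:
            raise ConfigError(f"{self.architecture} requires att_hidden_dim")
        if not needs_attention and self.att_hidden_dim is not None:
            raise ConfigError("att_hidden_dim is not applicable to selu-mpnn")
        if self.architecture == "emnn":
            if self.edge_emb_hidden_dim is None or self.edge_embedding_size is None:
                raise ConfigError("emnn requires edge_emb_hidden_dim and "
                                  "edge_embedding_size")
            if self.message_size is not None:
                raise ConfigError("message_size is not applicable to emnn "
                                  "(the edge state width is edge_embedding_size)")
        else:
            if self.message_size is None:
                raise ConfigError(f"{self.architecture} requires message_size")
            if self.edge_emb_hidden_dim is not None or self.edge_embedding_size is not None:
                raise ConfigError("edge embedding sizes apply only to emnn")

    # -- round-trippable key: value serialization --------------------------
    def to_text(self) -> str:
        lines = []
        for f in dc_fields(self):
            v = getattr(self, f.name)
            lines.append(f"{f.name}: {'' if v is None else v}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "ModelConfig":
        kwargs = {}
        types = {f.name: f.type for f in dc_fields(cls)}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, raw = line.partition(":")
            key, raw = key.strip(), raw.strip()
            if key not in types:
                raise ConfigError(f"unknown config key {key!r}")
            if raw == "":
                kwargs[key] = None
            elif key == "architecture":
                kwargs[key] = raw
            elif key in ("learn_rate", "out_dropout_p", "out_layer_shrinkage"):
                kwargs[key] = float(raw)
            else:
                kwargs[key] = int(float(raw))
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------

def _segment_softmax(scores: Tensor, owners: np.ndarray, n_segments: int,
                     extra: Tensor | None = None):
    """Stable elementwise softmax of `scores` rows grouped by `owners`.

    When ``extra`` is given it is an [n_segments, W] tensor treated as one
    additional member of every segment (the EMNN's e' self-member). Returns
    the normalized weights for the grouped rows and, if present, the extra
    member.
    """
    w = scores.data.shape[1]
    shift = np.full((n_segments, w), -np.inf)
    if len(owners):
        np.maximum.at(shift, owners, scores.data)
    if extra is not None:
        shift = np.maximum(shift, extra.data)
    shift[~np.isfinite(shift).all(axis=1)] = 0.0  # empty segments
    ex = ad.exp(scores - Tensor(shift[owners])) if len(owners) else None
    denom = (ad.segment_sum(ex, owners, n_segments) if ex is not None
             else Tensor(np.zeros((n_segments, w))))
    if extra is not None:
        ex_extra = ad.exp(extra - Tensor(shift))
        denom = denom + ex_extra
        att_extra = ex_extra / denom
        att = ex / ad.gather_rows(denom, owners) if ex is not None else None
        return att, att_extra
    att = ex / ad.gather_rows(denom, owners) if ex is not None else None
    return att


def _per_class_apply(nets, x: Tensor, class_onehot: np.ndarray) -> Tensor:
    """Apply one network per bond class and blend by the class indicator."""
    out = None
    for c, net in enumerate(nets):
        term = net(x) * Tensor(class_onehot[:, c:c + 1])
        out = term if out is None else out + term
    return out


class _Head:
    """Gated readout (GGNN style) + shrinking output feed-forward stack."""

    def __init__(self, state_width: int, init_width: int, cfg: ModelConfig,
                 n_tasks: int, rng: np.random.Generator):
        self.p = ad.MLP([state_width, cfg.gather_emb_hidden_dim,
                         cfg.gather_width], rng)
        self.q = ad.MLP([state_width + init_width, cfg.gather_att_hidden_dim,
                         cfg.gather_width], rng)
        w1 = cfg.out_hidden_dim
        w2 = max(1, round(w1 * cfg.out_layer_shrinkage))
        w3 = max(1, round(w2 * cfg.out_layer_shrinkage))
        self.out_layers = [ad.Linear(a, b, rng) for a, b in
                           zip([cfg.gather_width, w1, w2, w3],
                               [w1, w2, w3, n_tasks])]
        self.dropout_p = cfg.out_dropout_p

    def readout(self, h_final: Tensor, h_init: Tensor,
                membership: np.ndarray, n_molecules: int) -> Tensor:
        gate = ad.sigmoid(self.q(ad.concat([h_final, h_init], axis=1)))
        return ad.segment_sum(self.p(h_final) * gate, membership, n_molecules)

    def output(self, y: Tensor, rng: np.random.Generator,
               training: bool) -> Tensor:
        for i, layer in enumerate(self.out_layers):
            y = layer(y)
            if i < len(self.out_layers) - 1:
                y = ad.selu(y)
                y = ad.dropout(y, self.dropout_p, rng, training)
        return y

    def parameters(self):
        ps = self.p.parameters() + self.q.parameters()
        for layer in self.out_layers:
            ps += layer.parameters()
        return ps


class _NodeModelBase:
    """Shared plumbing for the node-state architectures."""

    def __init__(self, config: ModelConfig, d_node: int, n_tasks: int,
                 seed: int = 0):
        config.validate()
        self.config = config
        self.d_node = d_node
        self.n_tasks = n_tasks
        self.rng = np.random.default_rng(seed)
        D = config.message_size
        self.D = D
        # h_v^(0): zero-pad the atom features to D, or project when d_node > D.
        self.embed = (ad.Linear(d_node, D, self.rng) if d_node > D else None)
        self._build(self.rng)
        self.gru = ad.GRUCell(D, D, self.rng)
        self.head = _Head(D, D, config, n_tasks, self.rng)

    def initial_states(self, batch: BatchedGraph) -> Tensor:
        x = Tensor(batch.node_features)
        if self.embed is not None:
            return self.embed(x)
        if self.d_node == self.D:
            return x
        pad = np.zeros((batch.n_atoms, self.D - self.d_node))
        return ad.concat([x, Tensor(pad)], axis=1)

    def forward(self, batch: BatchedGraph | MolecularGraph,
                training: bool = False) -> Tensor:
        if isinstance(batch, MolecularGraph):
            batch = batch_graphs([batch])
        h0 = self.initial_states(batch)
        h = h0
        for _ in range(self.config.message_passes):
            m = self.aggregate(h, batch)
            h = self.gru(m, h)
        y = self.head.readout(h, h0, batch.node_membership, batch.n_molecules)
        return self.head.output(y, self.rng, training)

    def parameters(self):
        ps = [] if self.embed is None else self.embed.parameters()
        ps = ps + self._message_parameters() + self.gru.parameters() \
            + self.head.parameters()
        return ps


class SeluMPNN(_NodeModelBase):
    """Baseline MPNN: per-bond-class message networks, neighbour sum, GRU."""

    def _build(self, rng):
        cfg = self.config
        self.msg_nets = [ad.MLP([self.D, cfg.msg_hidden_dim, self.D], rng)
                         for _ in range(N_BOND_CLASSES)]

    def _message_parameters(self):
        return [p for net in self.msg_nets for p in net.parameters()]

    def aggregate(self, h: Tensor, batch: BatchedGraph) -> Tensor:
        """m_v = sum over neighbours w of f^(bond class)(h_w)."""
        if batch.n_directed_edges == 0:
            return Tensor(np.zeros((batch.n_atoms, self.D)))
        tails = batch.edge_index[:, 0]
        heads = batch.edge_index[:, 1]
        h_w = ad.gather_rows(h, heads)
        msgs = _per_class_apply(self.msg_nets, h_w, batch.edge_features)
        return ad.segment_sum(msgs, tails, batch.n_atoms)


class AMPNN(_NodeModelBase):
    """Attention MPNN: elementwise softmax-weighted sum over neighbours."""

    def _build(self, rng):
        cfg = self.config
        self.f_nets = [ad.MLP([self.D, cfg.msg_hidden_dim, self.D], rng)
                       for _ in range(N_BOND_CLASSES)]
        self.g_nets = [ad.MLP([self.D, cfg.att_hidden_dim, self.D], rng)
                       for _ in range(N_BOND_CLASSES)]

    def _message_parameters(self):
        return [p for net in self.f_nets + self.g_nets
                for p in net.parameters()]

    def aggregate(self, h: Tensor, batch: BatchedGraph) -> Tensor:
        """m_v = sum_w f(h_w) * softmax over N(v) of g(h_w), elementwise."""
        if batch.n_directed_edges == 0:
            return Tensor(np.zeros((batch.n_atoms, self.D)))
        tails = batch.edge_index[:, 0]
        heads = batch.edge_index[:, 1]
        h_w = ad.gather_rows(h, heads)
        emb = _per_class_apply(self.f_nets, h_w, batch.edge_features)
        scores = _per_class_apply(self.g_nets, h_w, batch.edge_features)
        att = _segment_softmax(scores, tails, batch.n_atoms)
        return ad.segment_sum(emb * att, tails, batch.n_atoms)


class EMNN:
    """Edge-memory network: hidden states on directed edges.

    The attention set of edge (v, w) is the states of incoming edges at its
    tail — excluding the reverse edge (w, v) — plus the edge's own static
    embedding e'. f and g are shared across bond classes (edge identity
    already lives in e').
    """

    def __init__(self, config: ModelConfig, d_node: int, n_tasks: int,
                 seed: int = 0):
        config.validate()
        if config.architecture != "emnn":
            raise ConfigError("EMNN requires architecture 'emnn'")
        self.config = config
        self.d_node = d_node
        self.n_tasks = n_tasks
        self.rng = np.random.default_rng(seed)
        cfg = config
        E = cfg.edge_embedding_size
        self.E = E
        self.embed_net = ad.MLP(
            [N_BOND_CLASSES + 2 * d_node, cfg.edge_emb_hidden_dim, E], self.rng)
        self.f_net = ad.MLP([E, cfg.msg_hidden_dim, E], self.rng)
        self.g_net = ad.MLP([E, cfg.att_hidden_dim, E], self.rng)
        self.gru = ad.GRUCell(E, E, self.rng)
        self.head = _Head(E, d_node, cfg, n_tasks, self.rng)

    # -- pieces ------------------------------------------------------------
    def edge_embed(self, batch: BatchedGraph) -> Tensor:
        """e'_vw = FFNN(concat(e_vw, x_v, x_w)) — order-sensitive."""
        x = batch.node_features
        inp = Tensor(np.concatenate(
            [batch.edge_features, x[batch.edge_index[:, 0]],
             x[batch.edge_index[:, 1]]], axis=1))
        return self.embed_net(inp)

    @staticmethod
    def incoming_structure(batch: BatchedGraph):
        """Flattened (member edge, owner edge) arrays for the incoming sets."""
        view = build_directed_edge_view(batch)
        inc_edges = np.concatenate([lst for lst in view.incoming_lists]) \
            if view.incoming_lists else np.zeros(0, dtype=np.intp)
        owners = np.concatenate(
            [np.full(len(lst), i, dtype=np.intp)
             for i, lst in enumerate(view.incoming_lists)]) \
            if view.incoming_lists else np.zeros(0, dtype=np.intp)
        return inc_edges.astype(np.intp), owners

    def aggregate(self, h_e: Tensor, e_emb: Tensor, inc_edges: np.ndarray,
                  owners: np.ndarray, n_edges: int) -> Tensor:
        """Attention over {incoming edge states} ∪ {e'} per directed edge."""
        f_self, g_self = self.f_net(e_emb), self.g_net(e_emb)
        if len(inc_edges):
            h_in = ad.gather_rows(h_e, inc_edges)
            f_in, g_in = self.f_net(h_in), self.g_net(h_in)
            att_in, att_self = _segment_softmax(g_in, owners, n_edges,
                                                extra=g_self)
            return ad.segment_sum(f_in * att_in, owners, n_edges) \
                + f_self * att_self
        _, att_self = _segment_softmax(
            Tensor(np.zeros((0, self.E))), owners, n_edges, extra=g_self)
        return f_self * att_self

    def collapse(self, h_e: Tensor, batch: BatchedGraph) -> Tensor:
        """h_v = sum over w in N(v) of h_vw (edges whose tail is v)."""
        return ad.segment_sum(h_e, batch.edge_index[:, 0], batch.n_atoms)

    # -- forward -----------------------------------------------------------
    def forward(self, batch: BatchedGraph | MolecularGraph,
                training: bool = False) -> Tensor:
        if isinstance(batch, MolecularGraph):
            batch = batch_graphs([batch])
        n_edges = batch.n_directed_edges
        e_emb = self.edge_embed(batch)
        inc_edges, owners = self.incoming_structure(batch)
        h_e = Tensor(np.zeros((n_edges, self.E)))
        for _ in range(self.config.message_passes):
            m = self.aggregate(h_e, e_emb, inc_edges, owners, n_edges)
            h_e = self.gru(m, h_e)
        h_v = self.collapse(h_e, batch)
        h0 = Tensor(batch.node_features)
        y = self.head.readout(h_v, h0, batch.node_membership, batch.n_molecules)
        return self.head.output(y, self.rng, training)

    def parameters(self):
        return (self.embed_net.parameters() + self.f_net.parameters()
                + self.g_net.parameters() + self.gru.parameters()
                + self.head.parameters())


def build_model(config: ModelConfig, d_node: int, n_tasks: int, seed: int = 0):
    """Instantiate the architecture selected by the config."""
    config.validate()
    cls = {"selu-mpnn": SeluMPNN, "ampnn": AMPNN, "emnn": EMNN}[config.architecture]
    return cls(config, d_node, n_tasks, seed)
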