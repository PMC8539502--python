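"""Directed-edge GIN (D-GIN) and its two sub-architectures.

The composite network runs two information-propagation phases:

1. *Directed-edge message passing* (the D-MPNN phase).  Hidden states live on
   directed edges; the message into edge ``u->w`` sums the hidden states of
   edges arriving at ``u`` excluding the reverse edge ``w->u``, so information
   never immediately backtracks.  Each update keeps a skip connection to the
   initial edge state.
2. *Graph-isomorphism updates* (the GIN phase).  Node states are updated as
   ``MLP((1 + eps) * h_u + sum of neighbor states)`` with a learnable scalar
   ``eps`` per layer, the form whose discriminative power matches the 1-WL
   graph-isomorphism test.

D-GIN chains phase 1 into phase 2; D-MPNN runs phase 1 only (with a learned
linear node aggregation); GIN runs phase 2 only, starting from raw node
features.  All variants finish with sum pooling over nodes and a feed-forward
readout producing one value per trained property.

Graphs are processed in batches as one disjoint union, with segment sums
routing edge->node and node->graph aggregations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .molgraph import MolecularGraph, get_strategy
from .nn import Tensor, ACTIVATIONS, concat, gather, segment_sum

ARCHITECTURES = ("d-gin", "d-mpnn", "gin")


class ConfigurationError(ValueError):
    """Raised when weight shapes and featurization dimensions disagree."""


@dataclass
class GraphBatch:
    """Disjoint union of molecular graphs, ready for the network.

    Directed edges keep the reverse-pair layout (``rev[e] = e ^ 1``).
    """

    X: np.ndarray            # (N, d) node features
    E: np.ndarray            # (M, b) directed-edge features
    src: np.ndarray          # (M,) global source node ids
    dst: np.ndarray          # (M,) global target node ids
    rev: np.ndarray          # (M,) index of each edge's reverse edge
    node_graph: np.ndarray   # (N,) graph id per node
    n_graphs: int

    @property
    def n_nodes(self) -> int:
        return self.X.shape[0]

    @classmethod
    def from_graphs(cls, graphs: list[MolecularGraph]) -> "GraphBatch":
        xs, es, srcs, dsts, gids = [], [], [], [], []
        node_offset = 0
        edge_offset = 0
        revs = []
        for gid, g in enumerate(graphs):
            xs.append(g.X)
            es.append(g.E)
            srcs.append(g.src + node_offset)
            dsts.append(g.dst + node_offset)
            gids.append(np.full(g.n, gid, dtype=np.int64))
            m = g.n_edges
            revs.append((np.arange(m, dtype=np.int64) ^ 1) + edge_offset)
            node_offset += g.n
            edge_offset += m
        return cls(
            X=np.concatenate(xs, axis=0),
            E=np.concatenate(es, axis=0) if es else np.zeros((0, 0)),
            src=np.concatenate(srcs) if srcs else np.zeros(0, dtype=np.int64),
            dst=np.concatenate(dsts) if dsts else np.zeros(0, dtype=np.int64),
            rev=np.concatenate(revs) if revs else np.zeros(0, dtype=np.int64),
            node_graph=np.concatenate(gids),
            n_graphs=len(graphs),
        )


# ---------------------------------------------------------------------------
# Functional pieces of the forward pass
# ---------------------------------------------------------------------------

def init_edge_hidden(batch: GraphBatch, w_init, act) -> Tensor:
    """Initial directed-edge states: act(W_init(cat(x_src, x_edge)))."""
    x_src = gather(Tensor(batch.X), batch.src)
    inp = concat([x_src, Tensor(batch.E)], axis=1)
    return act(w_init(inp))


def edge_messages(H: Tensor, batch: GraphBatch) -> Tensor:
    """Message into each directed edge u->w: sum of states of edges k->u with
    k != w (incoming sum at the source node minus the reverse edge)."""
    in_sum = segment_sum(H, batch.dst, batch.n_nodes)
    return nn.sub(gather(in_sum, batch.src), gather(H, batch.rev))


def edge_message_pass(H: Tensor, H0: Tensor, batch: GraphBatch, w_m, act) -> Tensor:
    """One directed-edge update: act(h0 + W_m m); the skip is always h0."""
    m = edge_messages(H, batch)
    return act(nn.add(H0, w_m(m)))


def aggregate_node_messages(H: Tensor, batch: GraphBatch,
                            incoming: bool = True) -> Tensor:
    """Per-node message: sum of final edge states over incoming directed
    edges (``incoming=False`` sums outgoing edges instead)."""
    seg = batch.dst if incoming else batch.src
    return segment_sum(H, seg, batch.n_nodes)


def combine_node(m_u: Tensor, X: np.ndarray, variant: str, w_agg=None) -> Tensor:
    """Join aggregated messages with raw node features.

    D-GIN keeps the plain concatenation; D-MPNN maps it through a learned
    linear aggregation.
    """
    cat = concat([m_u, Tensor(X)], axis=1)
    if variant == "d-gin":
        return cat
    if variant == "d-mpnn":
        if w_agg is None:
            raise ConfigurationError("d-mpnn variant requires the aggregation map")
        return w_agg(cat)
    raise ValueError(f"unknown variant {variant!r}")


def neighbor_sum(h: Tensor, batch: GraphBatch) -> Tensor:
    """For each node u: sum of h_w over neighbors w (via directed edges)."""
    return segment_sum(gather(h, batch.src), batch.dst, batch.n_nodes)


def gin_update(h: Tensor, batch: GraphBatch, eps: Tensor, mlp) -> Tensor:
    """One GIN layer: mlp((1 + eps) * h + neighbor sum)."""
    scale = nn.add(eps, Tensor(1.0))
    return mlp(nn.add(nn.mul(h, scale), neighbor_sum(h, batch)))


def sum_pool(h: Tensor, batch: GraphBatch) -> Tensor:
    """Graph embedding h_G: sum of node states per graph."""
    return segment_sum(h, batch.node_graph, batch.n_graphs)


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------

@dataclass
class GNNConfig:
    """Hyperparameters of one network instance.

    ``c`` is the hidden width, ``T`` the number of directed-edge updates,
    ``T2`` the number of GIN layers, ``readout_hidden`` the widths of the
    feed-forward readout's hidden layers, and ``n_props`` the number of
    property outputs (one per trained property).
    """

    architecture: str = "d-gin"
    strategy_id: int = 3
    c: int = 128
    T: int = 3
    T2: int = 2
    readout_hidden: tuple[int, ...] = (128, 128)
    n_props: int = 1
    activation: str = "relu"
    incoming_aggregation: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture {self.architecture!r}")
        if self.T < 1:
            raise ValueError("T must be >= 1")
        if self.T2 < 0 or (self.architecture == "gin" and self.T2 < 1):
            raise ValueError("T2 must be >= 1 (>= 0 only for the d-gin ablation)")
        self.readout_hidden = tuple(self.readout_hidden)


class GNNModel:
    """A D-GIN, D-MPNN or GIN regressor with explicit NumPy parameters."""

    def __init__(self, config: GNNConfig, d: int | None = None,
                 b: int | None = None):
        self.config = config
        if d is None or b is None:
            strategy = get_strategy(config.strategy_id)
            d = strategy.d if d is None else d
            b = strategy.b if b is None else b
        self.d, self.b = d, b
        rng = np.random.default_rng(config.seed)
        act_name = config.activation
        c = config.c

        self.w_init = None
        self.w_m = None
        self.w_agg = None
        self.gin_layers: list[tuple[Tensor, nn.MLP]] = []

        uses_edge_phase = config.architecture in ("d-gin", "d-mpnn")
        if uses_edge_phase:
            self.w_init = nn.Linear(rng, self.d + self.b, c, name="w_init")
            self.w_m = nn.Linear(rng, c, c, bias=False, name="w_m")
        if config.architecture == "d-mpnn":
            self.w_agg = nn.Linear(rng, c + self.d, c, name="w_agg_edgephase")

        if config.architecture == "d-gin":
            gin_in = c + self.d
        elif config.architecture == "gin":
            gin_in = self.d
        else:
            gin_in = None
        if gin_in is not None:
            dims_in = gin_in
            for layer in range(config.T2):
                mlp = nn.MLP(rng, [dims_in, c, c], activation=act_name,
                             name=f"gin{layer}")
                eps = Tensor(np.zeros(1), requires_grad=True, name=f"eps{layer}")
                self.gin_layers.append((eps, mlp))
                dims_in = c

        if config.architecture == "d-mpnn":
            pool_dim = c
        elif config.T2 == 0:  # d-gin ablation: pool the concatenation directly
            pool_dim = c + self.d
        else:
            pool_dim = c
        self.readout = nn.MLP(
            rng, [pool_dim, *config.readout_hidden, config.n_props],
            activation=act_name, name="readout",
        )
        self._act = ACTIVATIONS[act_name]

    # -- forward ------------------------------------------------------------
    def embed(self, batch: GraphBatch) -> Tensor:
        """Graph embeddings h_G for a batch (before the readout)."""
        cfg = self.config
        if batch.X.shape[1] != self.d:
            raise ConfigurationError(
                f"node feature width {batch.X.shape[1]} != strategy d={self.d}"
            )
        act = self._act
        if cfg.architecture in ("d-gin", "d-mpnn"):
            if batch.E.shape[1] != self.b:
                raise ConfigurationError(
                    f"edge feature width {batch.E.shape[1]} != strategy b={self.b}"
                )
            H0 = init_edge_hidden(batch, self.w_init, act)
            H = H0
            for _ in range(cfg.T):
                H = edge_message_pass(H, H0, batch, self.w_m, act)
            m_u = aggregate_node_messages(H, batch, cfg.incoming_aggregation)
            h = combine_node(m_u, batch.X, cfg.architecture, self.w_agg)
        else:
            h = Tensor(batch.X)
        for eps, mlp in self.gin_layers:
            h = gin_update(h, batch, eps, mlp)
        return sum_pool(h, batch)

    def forward(self, batch: GraphBatch) -> Tensor:
        """Predictions, one row per graph and one column per property."""
        return self.readout(self.embed(batch))

    def predict(self, graphs: list[MolecularGraph]) -> np.ndarray:
        return self.forward(GraphBatch.from_graphs(graphs)).data

    # -- parameters / persistence -------------------------------------------
    def parameters(self) -> list[Tensor]:
        params = []
        for lin in (self.w_init, self.w_m, self.w_agg):
            if lin is not None:
                params.extend(lin.parameters())
        for eps, mlp in self.gin_layers:
            params.append(eps)
            params.extend(mlp.parameters())
        params.extend(self.readout.parameters())
        return params

    def named_parameters(self) -> dict[str, Tensor]:
        return {f"p{i}_{p.name}": p for i, p in enumerate(self.parameters())}

    def get_weights(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def set_weights(self, weights: list[np.ndarray]):
        params = self.parameters()
        if len(weights) != len(params):
            raise ConfigurationError("weight list length mismatch")
        for p, w in zip(params, weights):
            if p.data.shape != w.shape:
                raise ConfigurationError(
                    f"shape mismatch for {p.name}: {p.data.shape} vs {w.shape}"
                )
            p.data = np.asarray(w, dtype=np.float64).copy()

    def save(self, path: str | Path):
        """Write a checkpoint directory (meta.json + weights.npz)."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        meta = {"format_version": 1, "config": asdict(self.config),
                "d": self.d, "b": self.b}
        (path / "meta.json").write_text(json.dumps(meta, indent=2))
        arrays = {f"w{i}": p.data for i, p in enumerate(self.parameters())}
        eps_values = [float(eps.data[0]) for eps, _ in self.gin_layers]
        np.savez(path / "weights.npz", **arrays)
        (path / "eps.json").write_text(json.dumps(eps_values))

    @classmethod
    def load(cls, path: str | Path) -> "GNNModel":
        path = Path(path)
        meta = json.loads((path / "meta.json").read_text())
        cfg = meta["config"]
        cfg["readout_hidden"] = tuple(cfg["readout_hidden"])
        model = cls(GNNConfig(**cfg), d=meta.get("d"), b=meta.get("b"))
        with np.load(path / "weights.npz") as data:
            weights = [data[f"w{i}"] for i in range(len(data.files))]
        model.set_weights(weights)
        return model
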