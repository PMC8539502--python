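"""Naive per-edge / per-node loop reference for the network equations.

Deliberately written with explicit Python loops and dictionaries — no
vectorization, no segment sums — so it checks the batched implementation's
message routing independently.  Weights are read from the model under test.
"""

from __future__ import annotations

import numpy as np


def _act(name):
    if name == "relu":
        return lambda x: np.maximum(x, 0.0)
    if name == "sigmoid":
        return lambda x: 1.0 / (1.0 + np.exp(-x))
    return lambda x: x


def _apply_linear(lin, x: np.ndarray) -> np.ndarray:
    out = x @ lin.W.data
    if lin.b is not None:
        out = out + lin.b.data
    return out


def _apply_mlp(mlp, x: np.ndarray, act) -> np.ndarray:
    for i, layer in enumerate(mlp.layers):
        x = _apply_linear(layer, x)
        if i < len(mlp.layers) - 1:
            x = act(x)
    return x


def naive_forward(model, graph) -> np.ndarray:
    """Recompute one graph's prediction with explicit loops over edges/nodes."""
    cfg = model.config
    act = _act(cfg.activation)
    edges = list(zip(graph.src.tolist(), graph.dst.tolist()))

    if cfg.architecture in ("d-gin", "d-mpnn"):
        # edge initialization: h0_uw = act(W_init(cat(x_u, x_e_uw)))
        h0 = {}
        for e, (u, w) in enumerate(edges):
            h0[e] = act(_apply_linear(model.w_init,
                                      np.concatenate([graph.X[u], graph.E[e]])))
        h = dict(h0)
        # T iterations: message excludes the reverse edge, skip is always h0
        for _ in range(cfg.T):
            new_h = {}
            for e, (u, w) in enumerate(edges):
                m = np.zeros(cfg.c)
                for e2, (k, tgt) in enumerate(edges):
                    if tgt == u and k != w:
                        m = m + h[e2]
                new_h[e] = act(h0[e] + _apply_linear(model.w_m, m))
            h = new_h
        # per-node aggregation over incoming (or outgoing) final edge states
        m_u = {v: np.zeros(cfg.c) for v in range(graph.n)}
        for e, (u, w) in enumerate(edges):
            node = w if cfg.incoming_aggregation else u
            m_u[node] = m_u[node] + h[e]
        hn = {}
        for v in range(graph.n):
            cat = np.concatenate([m_u[v], graph.X[v]])
            hn[v] = cat if cfg.architecture == "d-gin" else _apply_linear(
                model.w_agg, cat)
    else:
        hn = {v: graph.X[v].copy() for v in range(graph.n)}

    # GIN layers: mlp((1 + eps) * h_v + neighbor sum)
    for eps, mlp in model.gin_layers:
        new_hn = {}
        for v in range(graph.n):
            nbr = np.zeros_like(hn[v])
            for (u, w) in edges:
                if w == v:
                    nbr = nbr + hn[u]
            new_hn[v] = _apply_mlp(mlp, (1.0 + eps.data[0]) * hn[v] + nbr, act)
        hn = new_hn

    h_g = np.zeros(len(next(iter(hn.values()))) if hn else 0)
    for v in range(graph.n):
        h_g = h_g + hn[v]
    return _apply_mlp(model.readout, h_g, act)
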