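"""Directed message-passing graph encoder.

The default encoder propagates hidden states along *directed* bonds: the
message into edge i->j sums the states of edges k->i over neighbors k of
i excluding j, so information never immediately flows back along the
reverse edge.  Edge states are initialized from the source atom and bond
features, updated by a GRU cell whose input is the initial edge state
plus the incoming message, and read out per atom by aggregating incoming
edge states.  A conventional node-message MPNN is available as a
config-selectable variant sharing the same readout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .mol_graph import ATOM_FDIM, BOND_FDIM, FeaturizedGraph


@dataclass
class EncoderConfig:
    hidden_size: int = 256
    depth: int = 10
    dropout: float = 0.15
    variant: str = "dmpnn"  # "dmpnn" | "mpnn"

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.variant not in ("dmpnn", "mpnn"):
            raise ValueError(f"unknown encoder variant {self.variant!r}")


def init_encoder_params(
    rng: np.random.Generator, config: EncoderConfig
) -> dict[str, Tensor]:
    """Glorot-initialized encoder parameters (shared across depth)."""
    h = config.hidden_size
    p: dict[str, np.ndarray] = {}
    if config.variant == "dmpnn":
        p["enc.W_i"] = ag.glorot(rng, ATOM_FDIM + BOND_FDIM, h)
    else:
        p["enc.W_i"] = ag.glorot(rng, ATOM_FDIM, h)
        p["enc.W_m"] = ag.glorot(rng, h + BOND_FDIM, h)
    for gate in ("r", "z", "n"):
        p[f"enc.gru.Wx{gate}"] = ag.glorot(rng, h, h)
        p[f"enc.gru.Wh{gate}"] = ag.glorot(rng, h, h)
        p[f"enc.gru.b{gate}"] = np.zeros((1, h))
    p["enc.gru.bhn"] = np.zeros((1, h))
    p["enc.W_o"] = ag.glorot(rng, ATOM_FDIM + h, h)
    p["enc.c"] = np.zeros((1, h))
    return {k: Tensor(v) for k, v in p.items()}


def _gru(params: dict[str, Tensor], x: Tensor, h: Tensor) -> Tensor:
    r = ag.sigmoid(x @ params["enc.gru.Wxr"] + h @ params["enc.gru.Whr"]
                   + params["enc.gru.br"])
    z = ag.sigmoid(x @ params["enc.gru.Wxz"] + h @ params["enc.gru.Whz"]
                   + params["enc.gru.bz"])
    n = ag.tanh(x @ params["enc.gru.Wxn"] + params["enc.gru.bn"]
                + r * (h @ params["enc.gru.Whn"] + params["enc.gru.bhn"]))
    one = ag.constant(np.ones_like(z.data))
    return (one - z) * n + z * h


def encode_graph(
    fg: FeaturizedGraph,
    params: dict[str, Tensor],
    config: EncoderConfig,
    dropout_rng: Optional[np.random.Generator] = None,
    edge_trace: Optional[list] = None,
) -> Tensor:
    """Per-atom hidden states (n_atoms, hidden_size).

    Deterministic when ``dropout_rng`` is None (evaluation mode).
    Isolated atoms receive an all-zero neighbor sum, never an error.
    ``edge_trace``, if a list, collects each layer's directed-edge state
    array (analysis/testing aid; D-MPNN variant only).
    """
    n = fg.atom_x.shape[0]
    h_dim = config.hidden_size
    X = ag.constant(fg.atom_x)

    if fg.edge_src.size == 0:
        agg = ag.constant(np.zeros((n, h_dim)))
    elif config.variant == "dmpnn":
        E = ag.constant(fg.edge_x)
        h0 = ag.concat([ag.rows(X, fg.edge_src), E], axis=1) @ params["enc.W_i"]
        h = h0
        if edge_trace is not None:
            edge_trace.append(h.data.copy())
        for _ in range(config.depth):
            incoming = ag.segment_sum(h, fg.edge_dst, n)
            msg = ag.rows(incoming, fg.edge_src) - ag.rows(h, fg.rev)
            h = _gru(params, h0 + msg, h)
            if edge_trace is not None:
                edge_trace.append(h.data.copy())
        agg = ag.segment_sum(h, fg.edge_dst, n)
    else:
        E = ag.constant(fg.edge_x)
        h0 = X @ params["enc.W_i"]
        h = h0
        for _ in range(config.depth):
            msg_e = ag.concat([ag.rows(h, fg.edge_src), E], axis=1) @ params["enc.W_m"]
            msg = ag.segment_sum(msg_e, fg.edge_dst, n)
            h = _gru(params, h0 + msg, h)
        agg = ag.segment_sum(ag.rows(h, fg.edge_src), fg.edge_dst, n)

    out = ag.relu(ag.concat([X, agg], axis=1) @ params["enc.W_o"] + params["enc.c"])
    return ag.dropout(out, config.dropout, dropout_rng)
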