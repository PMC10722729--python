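"""Undirected training PPI graph and GIN feature propagation.

The graph has one node per protein (test-only proteins included as isolated
nodes so they remain encodable) and one structural edge per training
interaction pair, regardless of how many interaction-type labels the pair
carries. Node features come from the sequence encoder. A GIN layer updates

    g_p <- MLP((1 + eps) * g_p + sum_{p' in N(p)} g_{p'})

with eps a learnable scalar (initialized to 0) and the MLP two linear
layers with a ReLU between, hidden width d_node.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, glorot
from .io_formats import EdgeRecord, ProteinRecord
from .seq_encoder import NodeVector


@dataclass
class PPIGraph:
    node_ids: list
    adjacency: np.ndarray  # (n, n) symmetric 0/1, zero diagonal
    features: np.ndarray  # (n, d_node)

    @property
    def index(self) -> dict:
        return {p: i for i, p in enumerate(self.node_ids)}


@dataclass
class GINLayerParams:
    """One GIN layer: learnable eps and an MLP (or identity if mlp is None)."""

    epsilon: Tensor
    mlp: tuple | None  # (W1, b1, W2, b2) or None for the identity map

    def parameters(self) -> list[Tensor]:
        ps = [self.epsilon]
        if self.mlp is not None:
            ps += list(self.mlp)
        return ps


def init_gin_params(rng: np.random.Generator, d_node: int) -> GINLayerParams:
    W1 = glorot(rng, (d_node, d_node))
    b1 = Tensor(np.zeros(d_node), requires_grad=True)
    W2 = glorot(rng, (d_node, d_node))
    b2 = Tensor(np.zeros(d_node), requires_grad=True)
    return GINLayerParams(epsilon=Tensor(0.0, requires_grad=True), mlp=(W1, b1, W2, b2))


def identity_gin_params(epsilon: float = 0.0) -> GINLayerParams:
    """Eps fixed, identity MLP — the closed-form oracle configuration."""
    return GINLayerParams(epsilon=Tensor(float(epsilon)), mlp=None)


def build_graph(
    proteins: list[ProteinRecord],
    node_vectors: list[NodeVector],
    train_edges: list[EdgeRecord],
) -> PPIGraph:
    """Assemble the undirected simple graph over all proteins from training edges."""
    vec_by_id = {v.protein_id: v.values for v in node_vectors}
    node_ids = [p.id for p in proteins]
    index = {p: i for i, p in enumerate(node_ids)}
    missing = [p for p in node_ids if p not in vec_by_id]
    if missing:
        raise ValueError(f"no node vector for protein(s): {missing}")
    n = len(node_ids)
    A = np.zeros((n, n))
    for e in train_edges:
        for endpoint in (e.protein_a, e.protein_b):
            if endpoint not in index:
                raise ValueError(f"edge endpoint {endpoint!r} has no node vector")
        i, j = index[e.protein_a], index[e.protein_b]
        A[i, j] = A[j, i] = 1.0
    features = np.stack([vec_by_id[p] for p in node_ids])
    return PPIGraph(node_ids=node_ids, adjacency=A, features=features)


def gin_forward(A: Tensor, H: Tensor, params: GINLayerParams) -> Tensor:
    """Differentiable GIN update on a feature Tensor (n, d)."""
    agg = A @ H + (1.0 + params.epsilon) * H
    if params.mlp is None:
        return agg
    W1, b1, W2, b2 = params.mlp
    if W1.shape[0] != H.shape[1]:
        raise ValueError(
            f"feature dimension {H.shape[1]} does not match MLP input {W1.shape[0]}"
        )
    return (agg @ W1 + b1).relu() @ W2 + b2


def gin_update(graph: PPIGraph, params: GINLayerParams) -> np.ndarray:
    """Apply one GIN layer to the graph's node features (numpy in/out)."""
    out = gin_forward(Tensor(graph.adjacency), Tensor(graph.features), params)
    return out.data
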