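"""Pairwise relational head: self-attention, NTN / FRN scoring, multi-label classifier.

For a protein pair the two node features are stacked into a 2-row matrix and
refined by scaled dot-product self-attention. The refined pair (e1, e2) is
scored either by the neural-tensor form

    g(e1, R, e2) = u_R^T tanh(e1^T W^[1:k] e2 + V_R [e1; e2] + b_R)

or by the feature-relational form, which injects explicit distance and
direction information,

    F(e1, R, e2) = tanh((e1 + e2)^T W^[1:k] (e1 - e2)
                        + V_R [e1; e2] * cos(e1, e2) + b_R),

a k-vector whose bilinear term is antisymmetric under swapping the pair and
vanishes at e1 = e2. A fully connected classifier (hidden ReLU stage, 7
sigmoid outputs) maps the fused pair representation to per-interaction-type
probabilities; training minimizes the multi-task binary cross-entropy summed
over the 7 label tasks and all pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, concat, glorot
from .io_formats import INTERACTION_TYPES

N_LABELS = len(INTERACTION_TYPES)  # 7
LOSS_EPS = 1e-7
_COS_GUARD = 1e-24  # keeps the cosine denominator differentiable; exact zeros return 0


# -- self-attention -----------------------------------------------------------


@dataclass
class AttentionParams:
    W_Q: Tensor
    W_K: Tensor
    W_V: Tensor
    scale: bool = True  # divide scores by sqrt(d_k)

    @property
    def d_k(self) -> int:
        return self.W_Q.shape[1]

    def parameters(self) -> list[Tensor]:
        return [self.W_Q, self.W_K, self.W_V]


def init_attention_params(
    rng: np.random.Generator, d_node: int, d_k: int | None = None, scale: bool = True
) -> AttentionParams:
    d_k = d_node if d_k is None else d_k
    if d_k == 0:
        raise ValueError("attention dimension d_k must be positive")
    return AttentionParams(
        W_Q=glorot(rng, (d_node, d_k)),
        W_K=glorot(rng, (d_node, d_k)),
        W_V=glorot(rng, (d_node, d_k)),
        scale=scale,
    )


def attention_batch(X: Tensor, params: AttentionParams) -> Tensor:
    """Self-attention on a (..., n, d_node) Tensor -> (..., n, d_k)."""
    if params.d_k == 0:
        raise ValueError("attention dimension d_k must be positive")
    Q = X @ params.W_Q
    K = X @ params.W_K
    V = X @ params.W_V
    scores = Q @ K.transpose(*range(K.ndim - 2), K.ndim - 1, K.ndim - 2)
    if params.scale:
        scores = scores * (1.0 / np.sqrt(params.d_k))
    W = scores.softmax(axis=-1)
    return W @ V


def self_attention(X: np.ndarray, params: AttentionParams) -> np.ndarray:
    """Numpy-facing self-attention on an (n, d_node) matrix."""
    return attention_batch(Tensor(np.atleast_2d(X)), params).data


def attention_weights(X: np.ndarray, params: AttentionParams) -> np.ndarray:
    """The (n, n) row-stochastic attention-weight matrix (for inspection)."""
    Xt = Tensor(np.atleast_2d(X))
    Q, K = Xt @ params.W_Q, Xt @ params.W_K
    scores = Q @ K.transpose(1, 0)
    if params.scale:
        scores = scores * (1.0 / np.sqrt(params.d_k))
    return scores.softmax(axis=-1).data


# -- relational scorers -------------------------------------------------------


@dataclass
class FRNParams:
    """Tensor slices and standard layer shared by the FRN and NTN scorers."""

    W: Tensor  # (k, d, d)
    V: Tensor  # (k, 2d)
    b: Tensor  # (k,)
    u: Tensor | None = None  # (k,), used only by the NTN score

    @property
    def k(self) -> int:
        return self.W.shape[0]

    @property
    def d(self) -> int:
        return self.W.shape[1]

    def parameters(self) -> list[Tensor]:
        ps = [self.W, self.V, self.b]
        if self.u is not None:
            ps.append(self.u)
        return ps


def init_frn_params(
    rng: np.random.Generator, d: int, k: int = 8, with_u: bool = True
) -> FRNParams:
    scale = 1.0 / np.sqrt(d)
    return FRNParams(
        W=Tensor(rng.normal(0.0, scale / np.sqrt(d), size=(k, d, d)), requires_grad=True),
        V=Tensor(rng.normal(0.0, scale, size=(k, 2 * d)), requires_grad=True),
        b=Tensor(np.zeros(k), requires_grad=True),
        u=Tensor(rng.normal(0.0, 1.0 / np.sqrt(k), size=k), requires_grad=True)
        if with_u
        else None,
    )


def _check_dims(e1: np.ndarray, e2: np.ndarray, params: FRNParams) -> None:
    if e1.shape != e2.shape or e1.shape[-1] != params.d:
        raise ValueError(
            f"entity vectors of dim {e1.shape}/{e2.shape} do not match tensor slices d={params.d}"
        )


def _bilinear(E1: Tensor, E2: Tensor, W: Tensor) -> Tensor:
    """Batched per-slice bilinear form E1^T W^[i] E2 -> (m, k)."""
    m, d = E1.shape
    k = W.shape[0]
    Wmat = W.transpose(1, 0, 2).reshape(d, k * d)  # [a, i*d + b] = W[i, a, b]
    left = (E1 @ Wmat).reshape(m, k, d)  # [m, i, b] = sum_a E1[m,a] W[i,a,b]
    return (left * E2.reshape(m, 1, d)).sum(axis=2)


def cosine_batch(E1: Tensor, E2: Tensor) -> Tensor:
    """Row-wise cosine similarity -> (m, 1); zero-norm rows give 0."""
    dot = (E1 * E2).sum(axis=1, keepdims=True)
    n1 = (E1 * E1).sum(axis=1, keepdims=True)
    n2 = (E2 * E2).sum(axis=1, keepdims=True)
    return dot / (n1 * n2 + _COS_GUARD).sqrt()


def cosine(e1, e2) -> float:
    """Cosine similarity of two vectors; 0 by convention if either norm is 0."""
    e1 = np.asarray(e1, dtype=np.float64)
    e2 = np.asarray(e2, dtype=np.float64)
    n1, n2 = np.linalg.norm(e1), np.linalg.norm(e2)
    if n1 == 0.0 or n2 == 0.0:
        return 0.0
    return float(e1 @ e2 / (n1 * n2))


def ntn_hidden_batch(E1: Tensor, E2: Tensor, params: FRNParams) -> Tensor:
    """NTN pre-projection vector tanh(e1^T W e2 + V [e1; e2] + b) -> (m, k)."""
    lin = concat([E1, E2], axis=1) @ params.V.transpose(1, 0)
    return (_bilinear(E1, E2, params.W) + lin + params.b).tanh()


def ntn_score(e1, e2, params: FRNParams) -> float:
    """Scalar NTN relational score u^T tanh(e1^T W e2 + V [e1;e2] + b)."""
    e1 = np.asarray(e1, dtype=np.float64)
    e2 = np.asarray(e2, dtype=np.float64)
    _check_dims(e1, e2, params)
    if params.u is None:
        raise ValueError("ntn_score requires the output projection u")
    h = ntn_hidden_batch(Tensor(e1[None, :]), Tensor(e2[None, :]), params)
    return float((h @ params.u.reshape(params.k, 1)).data[0, 0])


def frn_batch(E1: Tensor, E2: Tensor, params: FRNParams) -> Tensor:
    """Batched FRN score -> (m, k), entries strictly inside (-1, 1)."""
    bil = _bilinear(E1 + E2, E1 - E2, params.W)
    lin = concat([E1, E2], axis=1) @ params.V.transpose(1, 0)
    cos = cosine_batch(E1, E2)
    return (bil + lin * cos + params.b).tanh()


def frn_score(e1, e2, params: FRNParams) -> np.ndarray:
    """FRN relational score of a single pair -> vector of length k."""
    e1 = np.asarray(e1, dtype=np.float64)
    e2 = np.asarray(e2, dtype=np.float64)
    _check_dims(e1, e2, params)
    return frn_batch(Tensor(e1[None, :]), Tensor(e2[None, :]), params).data[0]


# -- classifier and loss ------------------------------------------------------


@dataclass
class ClassifierParams:
    """Fully connected classifier: hidden ReLU stage, 7 sigmoid outputs."""

    W1: Tensor
    b1: Tensor
    W2: Tensor
    b2: Tensor
    threshold: float = 0.5

    def parameters(self) -> list[Tensor]:
        return [self.W1, self.b1, self.W2, self.b2]


def init_classifier_params(
    rng: np.random.Generator, in_dim: int, hidden: int = 64, threshold: float = 0.5
) -> ClassifierParams:
    return ClassifierParams(
        W1=glorot(rng, (in_dim, hidden)),
        b1=Tensor(np.zeros(hidden), requires_grad=True),
        W2=glorot(rng, (hidden, N_LABELS)),
        b2=Tensor(np.zeros(N_LABELS), requires_grad=True),
        threshold=threshold,
    )


def logits_batch(R: Tensor, params: ClassifierParams) -> Tensor:
    """Pair representations (m, in_dim) -> raw logits (m, 7)."""
    return (R @ params.W1 + params.b1).relu() @ params.W2 + params.b2


def classify_batch(R: Tensor, params: ClassifierParams) -> Tensor:
    """Pair representations (m, in_dim) -> probabilities (m, 7)."""
    return logits_batch(R, params).sigmoid()


def classify(pair_repr, params: ClassifierParams):
    """One pair representation -> (7 probabilities, predicted label set)."""
    pair_repr = np.asarray(pair_repr, dtype=np.float64)
    if pair_repr.shape[-1] != params.W1.shape[0]:
        raise ValueError(
            f"pair representation dim {pair_repr.shape[-1]} does not match "
            f"classifier input {params.W1.shape[0]}"
        )
    probs = classify_batch(Tensor(pair_repr[None, :]), params).data[0]
    labels = {t for t, p in zip(INTERACTION_TYPES, probs) if p >= params.threshold}
    return probs, labels


def bce_loss_tensor(probs: Tensor, y: np.ndarray) -> Tensor:
    """Differentiable multi-task BCE, summed over pairs and the 7 label tasks."""
    y = np.asarray(y, dtype=np.float64)
    if probs.shape != y.shape:
        raise ValueError(f"shape mismatch: probabilities {probs.shape} vs labels {y.shape}")
    p = probs.clip(LOSS_EPS, 1.0 - LOSS_EPS)
    yt = Tensor(y)
    return -(yt * p.log() + (1.0 - yt) * (1.0 - p).log()).sum()


def bce_logits_tensor(logits: Tensor, y: np.ndarray) -> Tensor:
    """BCE from raw logits via the softplus identity (saturation-safe).

    -y log sigmoid(z) - (1-y) log(1 - sigmoid(z)) = softplus(z) - y z,
    with softplus(z) = relu(z) + log(1 + exp(-|z|)).
    """
    y = np.asarray(y, dtype=np.float64)
    if logits.shape != y.shape:
        raise ValueError(f"shape mismatch: logits {logits.shape} vs labels {y.shape}")
    absz = logits.relu() + (-logits).relu()
    softplus = logits.relu() + (1.0 + (-absz).exp()).log()
    return (softplus - Tensor(y) * logits).sum()


def bce_multilabel_loss(y_hat, y) -> float:
    """Multi-task binary cross-entropy on (n_pairs, 7) probability/label arrays."""
    return float(bce_loss_tensor(Tensor(np.asarray(y_hat, dtype=np.float64)), y).data)
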