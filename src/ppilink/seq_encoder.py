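"""Inception-style 1-D convolutional encoder for protein residue matrices.

A stack of ``n_submodules`` identical blocks; each block runs four parallel
branches over the temporal axis — convolutions with kernel sizes 1, 3 and 5,
plus a max-pooling branch followed by a 1x1 projection — and concatenates
their channels. All branches are length-preserving (same zero-padding,
stride 1). After the last block, global average pooling over the temporal
axis collapses the sequence to a fixed-size node vector, so proteins of any
length map to vectors of identical dimension.

Branch normalization (per-channel standardization over the valid sequence
positions of each protein, with learnable scale/shift) is applied between
each convolution and its ReLU; it is toggleable.

Batched encoding pads proteins to a common length and masks invalid
positions after every operation; because convolution, zero-padded max
pooling and masked normalization all preserve "padded positions are zero",
the batched result is identical to encoding each protein alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autodiff import Tensor, concat, conv1d_same, he, maxpool1d_same
from .embedding import RESIDUE_DIM, ResidueMatrix

_KERNELS = (1, 3, 5)
_NORM_EPS = 1e-5


@dataclass
class _Branch:
    w: Tensor
    b: Tensor
    gamma: Tensor | None = None
    beta: Tensor | None = None

    def parameters(self) -> list[Tensor]:
        ps = [self.w, self.b]
        if self.gamma is not None:
            ps += [self.gamma, self.beta]
        return ps


@dataclass
class InceptionBlockParams:
    conv1: _Branch
    conv3: _Branch
    conv5: _Branch
    pool_proj: _Branch

    def parameters(self) -> list[Tensor]:
        return (
            self.conv1.parameters()
            + self.conv3.parameters()
            + self.conv5.parameters()
            + self.pool_proj.parameters()
        )


@dataclass
class InceptionParams:
    """Parameters of the full encoder stack."""

    blocks: list = field(default_factory=list)
    channels_per_branch: int = 32
    norm: bool = True
    pooling: str = "avg"  # or "max": how the temporal axis is collapsed

    @property
    def d_node(self) -> int:
        return 4 * self.channels_per_branch

    def parameters(self) -> list[Tensor]:
        return [p for blk in self.blocks for p in blk.parameters()]


@dataclass
class NodeVector:
    values: np.ndarray
    protein_id: str


def init_inception_params(
    rng: np.random.Generator,
    in_channels: int = RESIDUE_DIM,
    channels_per_branch: int = 32,
    n_submodules: int = 4,
    norm: bool = True,
    pooling: str = "avg",
) -> InceptionParams:
    def branch(c_in: int, k: int) -> _Branch:
        w = he(rng, (channels_per_branch, c_in, k), fan_in=c_in * k)
        b = Tensor(np.zeros(channels_per_branch), requires_grad=True)
        if norm:
            gamma = Tensor(np.ones((1, channels_per_branch, 1)), requires_grad=True)
            beta = Tensor(np.zeros((1, channels_per_branch, 1)), requires_grad=True)
            return _Branch(w, b, gamma, beta)
        return _Branch(w, b)

    blocks = []
    c_in = in_channels
    for _ in range(n_submodules):
        blocks.append(
            InceptionBlockParams(
                conv1=branch(c_in, 1),
                conv3=branch(c_in, 3),
                conv5=branch(c_in, 5),
                pool_proj=branch(c_in, 1),
            )
        )
        c_in = 4 * channels_per_branch
    return InceptionParams(
        blocks=blocks, channels_per_branch=channels_per_branch, norm=norm, pooling=pooling
    )


def _norm_relu(h: Tensor, br: _Branch, mask: Tensor, lengths: Tensor) -> Tensor:
    """Optional per-channel normalization over valid positions, then ReLU, then mask."""
    if br.gamma is not None:
        mean = (h * mask).sum(axis=2, keepdims=True) / lengths
        centered = h - mean
        var = ((centered * centered) * mask).sum(axis=2, keepdims=True) / lengths
        h = centered / (var + _NORM_EPS).sqrt() * br.gamma + br.beta
    return h.relu() * mask


def inception_block(
    X: Tensor,
    params: InceptionBlockParams,
    mask: Tensor | None = None,
    lengths: Tensor | None = None,
) -> Tensor:
    """One sub-module on a (B, C_in, L) batch -> (B, 4*channels, L).

    ``mask`` is (B, 1, L) with 1 on valid positions; omitted means all valid.
    """
    X = Tensor._lift(X)
    B, _, L = X.shape
    if L < 1:
        raise ValueError("inception_block: sequence length must be >= 1")
    if mask is None:
        mask = Tensor(np.ones((B, 1, L)))
        lengths = Tensor(np.full((B, 1, 1), float(L)))
    b1 = _norm_relu(conv1d_same(X, params.conv1.w, params.conv1.b), params.conv1, mask, lengths)
    b3 = _norm_relu(conv1d_same(X, params.conv3.w, params.conv3.b), params.conv3, mask, lengths)
    b5 = _norm_relu(conv1d_same(X, params.conv5.w, params.conv5.b), params.conv5, mask, lengths)
    pooled = maxpool1d_same(X * mask, 3)
    bp = _norm_relu(
        conv1d_same(pooled, params.pool_proj.w, params.pool_proj.b),
        params.pool_proj,
        mask,
        lengths,
    )
    return concat([b1, b3, b5, bp], axis=1)


def encode_batch(matrices: list[np.ndarray], params: InceptionParams) -> Tensor:
    """Encode a list of (13, L_i) residue matrices into a (n, d_node) Tensor."""
    if not matrices:
        raise ValueError("encode_batch: empty input")
    lens = np.array([m.shape[1] for m in matrices])
    Lmax = int(lens.max())
    B = len(matrices)
    C = matrices[0].shape[0]
    X = np.zeros((B, C, Lmax))
    mask = np.zeros((B, 1, Lmax))
    for i, m in enumerate(matrices):
        X[i, :, : m.shape[1]] = m
        mask[i, 0, : m.shape[1]] = 1.0
    mask_t = Tensor(mask)
    lengths = Tensor(lens.reshape(B, 1, 1).astype(np.float64))

    h = Tensor(X)
    for blk in params.blocks:
        h = inception_block(h, blk, mask_t, lengths)
    if params.pooling == "max":
        # pad positions forced far below any activation before the temporal max
        neg = Tensor((mask - 1.0) * 1e30)
        return _temporal_max(h, neg)
    pooled = (h * mask_t).sum(axis=2) / lengths.reshape(B, 1)
    return pooled


def _temporal_max(h: Tensor, neg: Tensor) -> Tensor:
    shifted = h + neg  # (B, C, L); padded positions ~ -1e30
    B, C, L = shifted.shape
    arg = shifted.data.argmax(axis=2)
    bi, ci = np.indices((B, C))
    return shifted[(bi.ravel(), ci.ravel(), arg.ravel())].reshape(B, C)


def encode_protein(X: ResidueMatrix, params: InceptionParams) -> NodeVector:
    """Encode one protein to its fixed-dimension node vector."""
    out = encode_batch([X.values], params)
    return NodeVector(values=out.data[0].copy(), protein_id=X.protein_id)
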