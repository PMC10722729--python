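"""Dual amino-acid embedding: skip-gram co-occurrence vectors + physicochemical classes.

Each residue is encoded as a 13-dimensional vector: a 5-dim co-occurrence
subembedding pre-trained with skip-gram/negative-sampling on overlapping
3-mer windows of the corpus, concatenated with an 8-way one-hot of the
residue's physicochemical class (the 7 conjoint-triad groups of the 20
canonical amino acids, plus an eighth class that absorbs selenocysteine U,
pyrrolysine O and every other non-canonical letter). A protein becomes a
(13, L) residue matrix, truncated on the right at ``max_length``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_formats import ProteinRecord

logger = logging.getLogger(__name__)

#: Conjoint-triad grouping of the 20 canonical amino acids by dipole and
#: side-chain volume; class indices 1..7 in this order.
CONJOINT_TRIAD_CLASSES = ("AGV", "ILFP", "YMTS", "HNQW", "RK", "DE", "C")

N_CLASSES = 8  # 7 canonical groups + 1 unknown/U/O class
COOC_DIM = 5
RESIDUE_DIM = COOC_DIM + N_CLASSES  # 13


@dataclass(frozen=True)
class ClassMap:
    """Residue letter -> physicochemical class index in 1..8."""

    residue_to_class: dict

    def class_of(self, letter: str) -> int:
        return self.residue_to_class.get(letter, N_CLASSES)

    def to_json(self) -> dict:
        return dict(sorted(self.residue_to_class.items()))


def build_class_map() -> ClassMap:
    """The conjoint-triad 7-class partition; all other letters map to class 8."""
    mapping = {}
    for idx, group in enumerate(CONJOINT_TRIAD_CLASSES, start=1):
        for letter in group:
            mapping[letter] = idx
    return ClassMap(mapping)


@dataclass
class CooccurrenceVocab:
    """Per-token co-occurrence vectors learned by skip-gram.

    Tokens absent from the training corpus map to the zero vector.
    ``token_mode`` is ``"residue"`` (tokens are single residues, context
    window 1 so each center's context is its overlapping 3-mer) or
    ``"kmer"`` (tokens are 3-mers; a residue's vector is the mean of the
    vectors of the up-to-3 3-mers covering it).
    """

    token_vectors: dict
    dim: int = COOC_DIM
    token_mode: str = "residue"
    training_meta: dict = field(default_factory=dict)

    def vector(self, token: str) -> np.ndarray:
        v = self.token_vectors.get(token)
        return np.zeros(self.dim) if v is None else v

    def residue_vector(self, sequence: str, i: int) -> np.ndarray:
        if self.token_mode == "residue":
            return self.vector(sequence[i])
        # kmer mode: average the overlapping 3-mers covering position i
        L = len(sequence)
        covering = [
            sequence[s : s + 3]
            for s in range(max(0, i - 2), min(i, L - 3) + 1)
        ]
        if not covering:
            return np.zeros(self.dim)
        return np.mean([self.vector(k) for k in covering], axis=0)

    def to_json(self) -> dict:
        return {
            "dim": self.dim,
            "token_mode": self.token_mode,
            "training_meta": self.training_meta,
            "token_vectors": {t: list(map(float, v)) for t, v in self.token_vectors.items()},
        }

    @classmethod
    def from_json(cls, payload: dict) -> "CooccurrenceVocab":
        return cls(
            token_vectors={t: np.asarray(v) for t, v in payload["token_vectors"].items()},
            dim=payload["dim"],
            token_mode=payload["token_mode"],
            training_meta=payload.get("training_meta", {}),
        )


def _tokenize(sequence: str, token_mode: str) -> list[str]:
    if token_mode == "residue":
        return list(sequence)
    return [sequence[i : i + 3] for i in range(len(sequence) - 2)]


def train_cooccurrence(
    proteins: list[ProteinRecord],
    dim: int = COOC_DIM,
    window: int = 1,
    negatives: int = 5,
    seed: int = 0,
    epochs: int = 3,
    lr: float = 0.025,
    token_mode: str = "residue",
) -> CooccurrenceVocab:
    """Train skip-gram with negative sampling on the corpus token streams.

    With ``token_mode="residue"`` the tokens are single residues and the
    context window is 1 on each side, so every center token's context is
    exactly its overlapping 3-mer; this yields one ``dim``-vector per
    residue directly. Deterministic given (corpus, seed).
    """
    if not proteins or not any(len(p.sequence) >= 3 for p in proteins):
        raise ValueError("co-occurrence training needs at least one sequence of length >= 3")
    if dim != COOC_DIM:
        logger.warning(
            "co-occurrence dimension %d deviates from the standard value %d", dim, COOC_DIM
        )

    streams = [_tokenize(p.sequence, token_mode) for p in proteins]
    counts: dict[str, int] = {}
    for s in streams:
        for tok in s:
            counts[tok] = counts.get(tok, 0) + 1
    # deterministic vocab order: frequency desc, then lexicographic
    vocab = sorted(counts, key=lambda t: (-counts[t], t))
    index = {t: i for i, t in enumerate(vocab)}
    V = len(vocab)

    rng = np.random.default_rng(seed)
    W_in = (rng.random((V, dim)) - 0.5) / dim
    W_out = np.zeros((V, dim))

    freq = np.array([counts[t] for t in vocab], dtype=np.float64)
    noise = freq**0.75
    noise /= noise.sum()

    n_pairs_total = sum(
        sum(min(i, window) + min(len(s) - 1 - i, window) for i in range(len(s)))
        for s in streams
    ) * epochs
    step = 0
    for _ in range(epochs):
        for s in streams:
            ids = [index[t] for t in s]
            n = len(ids)
            for i, c in enumerate(ids):
                for j in range(max(0, i - window), min(n, i + window + 1)):
                    if j == i:
                        continue
                    alpha = lr * max(1e-4, 1.0 - step / max(1, n_pairs_total))
                    step += 1
                    targets = np.empty(negatives + 1, dtype=np.int64)
                    targets[0] = ids[j]
                    targets[1:] = rng.choice(V, size=negatives, p=noise)
                    labels = np.zeros(negatives + 1)
                    labels[0] = 1.0
                    vin = W_in[c]
                    vout = W_out[targets]
                    z = 1.0 / (1.0 + np.exp(-vout @ vin))
                    gradc = (labels - z) @ vout
                    W_out[targets] += alpha * np.outer(labels - z, vin)
                    W_in[c] += alpha * gradc

    return CooccurrenceVocab(
        token_vectors={t: W_in[index[t]].copy() for t in vocab},
        dim=dim,
        token_mode=token_mode,
        training_meta={
            "window": window,
            "negatives": negatives,
            "seed": seed,
            "epochs": epochs,
            "lr": lr,
            "n_tokens": int(freq.sum()),
        },
    )


@dataclass
class ResidueMatrix:
    """Per-protein (13, L) matrix: 5 co-occurrence rows + 8 one-hot class rows."""

    values: np.ndarray
    protein_id: str


def encode_sequence(
    protein: ProteinRecord,
    vocab: CooccurrenceVocab,
    classes: ClassMap,
    max_length: int = 2000,
) -> ResidueMatrix:
    """Encode one protein; sequences longer than ``max_length`` are right-truncated."""
    seq = protein.sequence[:max_length]
    L = len(seq)
    X = np.zeros((RESIDUE_DIM, L))
    for i, letter in enumerate(seq):
        X[:COOC_DIM, i] = vocab.residue_vector(seq, i)
        X[COOC_DIM + classes.class_of(letter) - 1, i] = 1.0
    return ResidueMatrix(values=X, protein_id=protein.id)
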