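"""Synthetic multi-label PPI networks with sequence-determined interaction labels.

Emulates a STRING-like dataset at desk scale: random protein sequences over
the 20-letter alphabet (with rare U/X letters), a hub-skewed undirected edge
set built by preferential attachment, and per-edge label subsets of the 7
interaction types driven by planted sequence motifs — an edge carries type t
whenever both endpoints contain motif t, so sequence content (not just graph
position) predicts the labels. Edges whose endpoints share no motif receive
a fallback label chosen deterministically from the two sequences (favoring
types whose motif occurs in exactly one endpoint), so that with zero label
noise the sequences->labels mapping is an exact function.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import INTERACTION_TYPES, EdgeRecord, ProteinRecord

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: Default planted motifs, one distinct 4-mer per interaction type.
DEFAULT_MOTIFS = {
    "activation": "WHWD",
    "binding": "CQCY",
    "catalysis": "HMHK",
    "expression": "WDCE",
    "inhibition": "YHYR",
    "ptmod": "KCKW",
    "reaction": "DWDH",
}

#: Probability of planting 0, 1, 2 or 3 motifs in a protein.
_MOTIF_COUNT_PROBS = (0.1, 0.2, 0.3, 0.4)

_RARE_LETTER_RATE = 0.001  # U/X substitution rate per residue


@dataclass
class SyntheticConfig:
    n_proteins: int = 50
    length_range: tuple = (50, 200)
    n_edges: int = 150
    motif_table: dict = field(default_factory=lambda: dict(DEFAULT_MOTIFS))
    label_noise: float = 0.0
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.length_range
        if lo < 4 or hi < lo:
            raise ValueError(f"invalid length_range {self.length_range}")
        max_pairs = self.n_proteins * (self.n_proteins - 1) // 2
        if self.n_edges > max_pairs:
            raise ValueError(
                f"n_edges={self.n_edges} exceeds possible pairs {max_pairs}"
            )
        motifs = list(self.motif_table.values())
        if any(not m for m in motifs) or len(set(motifs)) != len(motifs):
            raise ValueError("motifs must be non-empty and distinct")


def gen_proteins(cfg: SyntheticConfig) -> list[ProteinRecord]:
    """Generate ``cfg.n_proteins`` random sequences with 0-3 planted motifs each."""
    rng = np.random.default_rng(cfg.seed)
    lo, hi = cfg.length_range
    types = list(INTERACTION_TYPES)
    records = []
    for i in range(cfg.n_proteins):
        L = int(rng.integers(lo, hi + 1))
        seq = list(rng.choice(list(AMINO_ACIDS), size=L))
        rare = rng.random(L) < _RARE_LETTER_RATE
        for j in np.flatnonzero(rare):
            seq[j] = "U" if rng.random() < 0.5 else "X"
        n_motifs = int(rng.choice(4, p=_MOTIF_COUNT_PROBS))
        chosen = rng.choice(types, size=min(n_motifs, len(types)), replace=False)
        occupied: list[tuple] = []
        for t in chosen:
            motif = cfg.motif_table[t]
            for _ in range(20):  # rejection sampling to avoid overlapping plants
                pos = int(rng.integers(0, L - len(motif) + 1))
                span = (pos, pos + len(motif))
                if all(span[1] <= s or span[0] >= e for s, e in occupied):
                    seq[span[0] : span[1]] = list(motif)
                    occupied.append(span)
                    break
        records.append(ProteinRecord(f"P{i:04d}", "".join(seq)))
    return records


def _edge_labels(seq_a: str, seq_b: str, motif_table: dict) -> set:
    """Label set of a pair, a deterministic function of the two sequences.

    Shared motifs define the labels; a pair without any shared motif falls
    back to one type chosen deterministically from the sequences (first from
    the types whose motif occurs in exactly one endpoint), keeping the
    noise-free sequences->labels mapping exactly learnable.
    """
    shared = {t for t, m in motif_table.items() if m in seq_a and m in seq_b}
    if shared:
        return shared
    one_sided = sorted(t for t, m in motif_table.items() if (m in seq_a) != (m in seq_b))
    pool = one_sided if one_sided else sorted(motif_table)
    la, lb = sorted((len(seq_a), len(seq_b)))
    return {pool[(31 * la + lb) % len(pool)]}


def gen_network(proteins: list[ProteinRecord], cfg: SyntheticConfig) -> list[EdgeRecord]:
    """Sample ``cfg.n_edges`` distinct pairs by preferential attachment and label them."""
    rng = np.random.default_rng(cfg.seed + 1)
    n = len(proteins)
    max_pairs = n * (n - 1) // 2
    if cfg.n_edges > max_pairs:
        raise ValueError(f"n_edges={cfg.n_edges} exceeds possible pairs {max_pairs}")

    order = rng.permutation(n)
    deg = np.zeros(n)
    pairs: list[tuple] = []
    pair_set: set[tuple] = set()

    def add(i: int, j: int) -> None:
        key = (min(i, j), max(i, j))
        pairs.append(key)
        pair_set.add(key)
        deg[i] += 1
        deg[j] += 1

    # sequential attachment: each arriving node links preferentially to earlier ones
    base_m = max(1, cfg.n_edges // max(1, n - 1))
    for pos in range(1, n):
        if len(pairs) >= cfg.n_edges:
            break
        node = order[pos]
        prev = order[:pos]
        m = min(pos, base_m, cfg.n_edges - len(pairs))
        w = deg[prev] + 1.0
        targets = rng.choice(prev, size=m, replace=False, p=w / w.sum())
        for t in targets:
            add(node, int(t))
    # top up with preferentially sampled extra pairs
    while len(pairs) < cfg.n_edges:
        w = deg + 1.0
        i, j = rng.choice(n, size=2, replace=False, p=w / w.sum())
        key = (min(int(i), int(j)), max(int(i), int(j)))
        if key not in pair_set:
            add(*key)

    seqs = [p.sequence for p in proteins]
    types = list(INTERACTION_TYPES)
    edges = []
    for i, j in pairs:
        labels = _edge_labels(seqs[i], seqs[j], cfg.motif_table)
        if cfg.label_noise > 0:
            flips = rng.random(len(types)) < cfg.label_noise
            for t, flip in zip(types, flips):
                if flip:
                    labels.symmetric_difference_update({t})
            if not labels:
                labels = {types[rng.integers(len(types))]}
        edges.append(EdgeRecord(proteins[i].id, proteins[j].id, frozenset(labels)))
    return edges


def gen_dataset(cfg: SyntheticConfig) -> tuple[list[ProteinRecord], list[EdgeRecord]]:
    proteins = gen_proteins(cfg)
    return proteins, gen_network(proteins, cfg)
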