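"""End-to-end training, evaluation and prediction for multi-label PPI models.

Per optimization step: encode every protein's residue matrix to a node
vector (Inception encoder), propagate node features over the training-edge
graph (GIN), refine each training pair with self-attention, score the pair
with the FRN (or NTN) relational layer, fuse with the element-wise feature
product, classify into 7 interaction-type probabilities, and take an Adam
step on the multi-task binary cross-entropy. The graph adjacency contains
training edges only; test proteins participate as isolated nodes, so no
test-edge information leaks into training.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass

import numpy as np
import yaml

from ._autodiff import Adam, Tensor, concat, glorot, no_grad
from .embedding import (
    COOC_DIM,
    RESIDUE_DIM,
    ClassMap,
    CooccurrenceVocab,
    build_class_map,
    encode_sequence,
    train_cooccurrence,
)
from .io_formats import INTERACTION_TYPES, EdgeRecord, ProteinRecord
from .metrics import MetricsReport, micro_f1
from .partition import SplitResult
from .ppi_graph import GINLayerParams, gin_forward, init_gin_params
from .relational_head import (
    AttentionParams,
    ClassifierParams,
    FRNParams,
    attention_batch,
    bce_logits_tensor,
    frn_batch,
    init_attention_params,
    init_classifier_params,
    init_frn_params,
    logits_batch,
    ntn_hidden_batch,
)
from .seq_encoder import InceptionParams, encode_batch, init_inception_params

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Training hyperparameters; defaults follow the reference protocol."""

    learning_rate: float = 0.001
    lr_schedule: str = "constant"  # or "cosine" (anneal to 0 over the run)
    lr_warmup_epochs: int = 0  # linear ramp 0 -> lr before the schedule
    grad_clip: float | None = None  # global gradient-norm ceiling
    batch_size: int = 2048  # auto-capped at the training-set size
    epochs: int = 300
    max_length: int = 2000
    n_graph_layers: int = 1
    optimizer: str = "adam"
    seed: int = 0
    threshold: float = 0.5
    init_output_bias: bool = False  # start classifier biases at label base rates
    # collapse recovery: a run that still makes zero positive training
    # predictions at `collapse_check_epoch` (or whose training micro-F1 is
    # below `stagnation_min_f1` at `stagnation_check_epoch`, if set) is
    # re-initialized with a derived seed, at most `restart_on_collapse` times
    restart_on_collapse: int = 0
    collapse_check_epoch: int = 30
    stagnation_check_epoch: int = 0  # 0 disables the stagnation check
    stagnation_min_f1: float = 0.3
    # architecture
    channels_per_branch: int = 32
    n_submodules: int = 4
    d_k: int | None = None  # attention dim; None -> d_node
    frn_slices: int = 8
    fc_hidden: int = 64
    branch_norm: bool = True
    encoder_pooling: str = "avg"
    attention_scale: bool = True
    pair_fusion: str = "frn+product"  # or "frn" / "product"
    # ablation switches
    use_inception: bool = True
    use_attention: bool = True
    use_frn: bool = True
    use_ntn: bool = False
    # co-occurrence embedding pre-training
    cooc_dim: int = COOC_DIM
    cooc_window: int = 1
    cooc_negatives: int = 5
    cooc_epochs: int = 3
    cooc_token_mode: str = "residue"
    cooc_corpus: str = "train"  # or "all"
    # bookkeeping
    eval_every: int = 1
    early_stopping_patience: int | None = None

    @property
    def d_node(self) -> int:
        return 4 * self.channels_per_branch

    @classmethod
    def from_yaml(cls, path) -> "TrainConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


@dataclass
class Model:
    """A trained (or training) model bundle: parameters plus encoding state."""

    cfg: TrainConfig
    class_map: ClassMap
    vocab: CooccurrenceVocab
    node_ids: list
    adjacency: np.ndarray
    residue_matrices: list  # (13, L_i) arrays, aligned with node_ids
    inception: InceptionParams | None
    mean_encoder: tuple | None  # (W, b) for the encoder-ablated variant
    gin_layers: list
    attention: AttentionParams | None
    frn: FRNParams | None
    classifier: ClassifierParams

    @property
    def index(self) -> dict:
        return {p: i for i, p in enumerate(self.node_ids)}

    def parameters(self) -> list[Tensor]:
        ps: list[Tensor] = []
        if self.inception is not None:
            ps += self.inception.parameters()
        if self.mean_encoder is not None:
            ps += list(self.mean_encoder)
        for layer in self.gin_layers:
            ps += layer.parameters()
        if self.attention is not None:
            ps += self.attention.parameters()
        if self.frn is not None:
            ps += self.frn.parameters()
        ps += self.classifier.parameters()
        return ps

    # -- forward passes ------------------------------------------------------

    def node_features(self) -> Tensor:
        if self.inception is not None:
            H = encode_batch(self.residue_matrices, self.inception)
        else:
            W, b = self.mean_encoder
            means = np.stack([m.mean(axis=1) for m in self.residue_matrices])
            H = Tensor(means) @ W + b
        A = Tensor(self.adjacency)
        for layer in self.gin_layers:
            H = gin_forward(A, H, layer)
        return H

    def pair_probabilities(self, pair_idx: np.ndarray, H: Tensor | None = None) -> Tensor:
        """Probabilities (m, 7) for an (m, 2) array of node-index pairs."""
        return self.pair_logits(pair_idx, H).sigmoid()

    def pair_logits(self, pair_idx: np.ndarray, H: Tensor | None = None) -> Tensor:
        """Classifier logits (m, 7) for an (m, 2) array of node-index pairs."""
        if H is None:
            H = self.node_features()
        E1 = H[pair_idx[:, 0]]
        E2 = H[pair_idx[:, 1]]
        if self.attention is not None:
            m, d = E1.shape
            X = concat([E1.reshape(m, 1, d), E2.reshape(m, 1, d)], axis=1)
            X = attention_batch(X, self.attention)
            E1 = X[:, 0, :]
            E2 = X[:, 1, :]
        parts = []
        if self.frn is not None:
            rel = (
                ntn_hidden_batch(E1, E2, self.frn)
                if self.cfg.use_ntn
                else frn_batch(E1, E2, self.frn)
            )
            if self.cfg.pair_fusion == "frn":
                parts = [rel]
            else:
                parts = [rel, E1 * E2]
        else:
            parts = [E1 * E2]
        R = parts[0] if len(parts) == 1 else concat(parts, axis=1)
        return logits_batch(R, self.classifier)


def _build_model(
    cfg: TrainConfig,
    proteins: list[ProteinRecord],
    train_edges: list[EdgeRecord],
    vocab: CooccurrenceVocab,
    class_map: ClassMap,
    rng: np.random.Generator,
) -> Model:
    node_ids = [p.id for p in proteins]
    index = {p: i for i, p in enumerate(node_ids)}
    n = len(node_ids)
    A = np.zeros((n, n))
    for e in train_edges:
        i, j = index[e.protein_a], index[e.protein_b]
        A[i, j] = A[j, i] = 1.0
    mats = [
        encode_sequence(p, vocab, class_map, cfg.max_length).values for p in proteins
    ]

    d_node = cfg.d_node
    inception = mean_encoder = None
    if cfg.use_inception:
        inception = init_inception_params(
            rng,
            in_channels=RESIDUE_DIM,
            channels_per_branch=cfg.channels_per_branch,
            n_submodules=cfg.n_submodules,
            norm=cfg.branch_norm,
            pooling=cfg.encoder_pooling,
        )
    else:
        mean_encoder = (
            glorot(rng, (RESIDUE_DIM, d_node)),
            Tensor(np.zeros(d_node), requires_grad=True),
        )
    gin_layers = [init_gin_params(rng, d_node) for _ in range(cfg.n_graph_layers)]

    attention = None
    d_pair = d_node
    if cfg.use_attention:
        attention = init_attention_params(
            rng, d_node, cfg.d_k, scale=cfg.attention_scale
        )
        d_pair = attention.d_k

    frn = None
    if cfg.use_frn or cfg.use_ntn:
        frn = init_frn_params(rng, d_pair, k=cfg.frn_slices, with_u=True)
        in_dim = cfg.frn_slices if cfg.pair_fusion == "frn" else cfg.frn_slices + d_pair
    else:
        in_dim = d_pair
    classifier = init_classifier_params(
        rng, in_dim, hidden=cfg.fc_hidden, threshold=cfg.threshold
    )
    return Model(
        cfg=cfg,
        class_map=class_map,
        vocab=vocab,
        node_ids=node_ids,
        adjacency=A,
        residue_matrices=mats,
        inception=inception,
        mean_encoder=mean_encoder,
        gin_layers=gin_layers,
        attention=attention,
        frn=frn,
        classifier=classifier,
    )


def _label_matrix(edges: list[EdgeRecord]) -> np.ndarray:
    Y = np.zeros((len(edges), len(INTERACTION_TYPES)))
    for i, e in enumerate(edges):
        for j, t in enumerate(INTERACTION_TYPES):
            if t in e.labels:
                Y[i, j] = 1.0
    return Y


def _pair_index(edges: list[EdgeRecord], index: dict) -> np.ndarray:
    return np.array(
        [[index[e.protein_a], index[e.protein_b]] for e in edges], dtype=np.int64
    )


def train(
    proteins: list[ProteinRecord],
    edges: list[EdgeRecord],
    split: SplitResult,
    cfg: TrainConfig,
    history_path=None,
) -> tuple[Model, list[dict]]:
    """Train on ``split.train_edges``; returns the model and per-epoch history.

    ``edges`` is accepted for interface completeness but only the split's
    partitions are consulted, so deleting test edges from it does not change
    the trained model.
    """
    if not split.train_edges:
        raise ValueError("empty training set")
    by_id = {p.id: p for p in proteins}
    for e in split.train_edges + split.test_edges:
        for endpoint in (e.protein_a, e.protein_b):
            if endpoint not in by_id:
                raise ValueError(f"edge endpoint {endpoint!r} has no sequence")

    class_map = build_class_map()
    if cfg.cooc_corpus == "train":
        train_ids = {p for e in split.train_edges for p in (e.protein_a, e.protein_b)}
        corpus = [by_id[p] for p in sorted(train_ids)]
    else:
        corpus = sorted(proteins, key=lambda p: p.id)
    vocab = train_cooccurrence(
        corpus,
        dim=cfg.cooc_dim,
        window=cfg.cooc_window,
        negatives=cfg.cooc_negatives,
        seed=cfg.seed,
        epochs=cfg.cooc_epochs,
        token_mode=cfg.cooc_token_mode,
    )

    hist_fh = open(history_path, "w") if history_path else None
    try:
        for attempt in range(cfg.restart_on_collapse + 1):
            model, history, collapsed = _fit_once(
                cfg, proteins, split, vocab, class_map, attempt, hist_fh
            )
            if not collapsed:
                break
            logger.warning(
                "no positive training predictions by epoch %d; "
                "re-initializing (attempt %d)",
                cfg.collapse_check_epoch,
                attempt + 1,
            )
    finally:
        if hist_fh:
            hist_fh.close()
    return model, history


def _fit_once(
    cfg: TrainConfig,
    proteins: list[ProteinRecord],
    split: SplitResult,
    vocab: CooccurrenceVocab,
    class_map: ClassMap,
    attempt: int,
    hist_fh,
) -> tuple[Model, list[dict], bool]:
    """One training run; returns (model, history, collapsed_flag)."""
    seed = cfg.seed + 1000 * attempt
    rng = np.random.default_rng(seed + 1)
    model = _build_model(cfg, proteins, split.train_edges, vocab, class_map, rng)
    index = model.index

    train_idx = _pair_index(split.train_edges, index)
    Y_train = _label_matrix(split.train_edges)
    if cfg.init_output_bias:
        rate = Y_train.mean(axis=0).clip(1e-3, 1.0 - 1e-3)
        model.classifier.b2.data = np.log(rate / (1.0 - rate))
    test_idx = _pair_index(split.test_edges, index) if split.test_edges else None
    Y_test = _label_matrix(split.test_edges) if split.test_edges else None

    n_train = len(split.train_edges)
    batch_size = min(cfg.batch_size, n_train)
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    shuffle_rng = np.random.default_rng(seed + 2)

    history: list[dict] = []
    best_loss, patience_left = np.inf, cfg.early_stopping_patience
    for epoch in range(1, cfg.epochs + 1):
        if cfg.lr_warmup_epochs and epoch <= cfg.lr_warmup_epochs:
            opt.lr = cfg.learning_rate * epoch / cfg.lr_warmup_epochs
        elif cfg.lr_schedule == "cosine":
            frac = (epoch - 1 - cfg.lr_warmup_epochs) / max(
                1, cfg.epochs - cfg.lr_warmup_epochs
            )
            opt.lr = cfg.learning_rate * 0.5 * (1.0 + np.cos(np.pi * frac))
        perm = shuffle_rng.permutation(n_train)
        epoch_loss = 0.0
        train_probs = np.zeros_like(Y_train)
        for start in range(0, n_train, batch_size):
            batch = perm[start : start + batch_size]
            logits = model.pair_logits(train_idx[batch])
            probs = logits.sigmoid()
            loss = bce_logits_tensor(logits, Y_train[batch]) * (1.0 / len(batch))
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}: {loss.data!r}"
                )
            opt.zero_grad()
            loss.backward()
            if cfg.grad_clip is not None:
                total = np.sqrt(
                    sum(
                        float((p.grad * p.grad).sum())
                        for p in opt.params
                        if p.grad is not None
                    )
                )
                if total > cfg.grad_clip:
                    scale = cfg.grad_clip / total
                    for p in opt.params:
                        if p.grad is not None:
                            p.grad = p.grad * scale
            opt.step()
            epoch_loss += float(loss.data) * len(batch)
            train_probs[batch] = probs.data
        epoch_loss /= n_train

        train_report = micro_f1(train_probs >= cfg.threshold, Y_train)
        test_f1 = None
        if test_idx is not None and (
            epoch % cfg.eval_every == 0 or epoch == cfg.epochs
        ):
            with no_grad():
                test_probs = model.pair_probabilities(test_idx).data
            test_f1 = micro_f1(test_probs >= cfg.threshold, Y_test).micro_f1
        entry = {
            "epoch": epoch,
            "loss": epoch_loss,
            "train_micro_f1": train_report.micro_f1,
            "test_micro_f1": test_f1,
        }
        history.append(entry)
        logger.info(
            "epoch %d loss %.4f train_f1 %.4f test_f1 %s",
            epoch,
            epoch_loss,
            train_report.micro_f1,
            "n/a" if test_f1 is None else f"{test_f1:.4f}",
        )
        if hist_fh:
            hist_fh.write(json.dumps(entry) + "\n")
        if cfg.restart_on_collapse and (
            (
                epoch == cfg.collapse_check_epoch
                and train_report.tp + train_report.fp == 0
            )
            or (
                cfg.stagnation_check_epoch
                and epoch == cfg.stagnation_check_epoch
                and train_report.micro_f1 < cfg.stagnation_min_f1
            )
        ):
            return model, history, True
        if patience_left is not None:
            if epoch_loss < best_loss - 1e-6:
                best_loss, patience_left = epoch_loss, cfg.early_stopping_patience
            else:
                patience_left -= 1
                if patience_left <= 0:
                    logger.info("early stopping at epoch %d", epoch)
                    break
    return model, history, False


def evaluate(
    model: Model, proteins: list[ProteinRecord], split: SplitResult
) -> dict[str, MetricsReport]:
    """Metrics on all test edges plus the homologous / unknown strata.

    Inference uses the training-edge adjacency stored in the model; unknown
    proteins contribute only their own sequence-encoder features.
    """
    by_id = {p.id: p for p in proteins}
    for e in split.test_edges:
        for endpoint in (e.protein_a, e.protein_b):
            if endpoint not in by_id:
                raise ValueError(f"protein {endpoint!r} has no sequence")
    index = model.index
    reports: dict[str, MetricsReport] = {}
    with no_grad():
        H = model.node_features()
        for name, edges in (
            ("overall", split.test_edges),
            ("homologous", split.test_homologous),
            ("unknown", split.test_unknown),
        ):
            if not edges:
                reports[name] = MetricsReport(
                    tp=0, fp=0, fn=0, precision=0.0, recall=0.0, micro_f1=0.0, na=True
                )
                continue
            idx = _pair_index(edges, index)
            probs = model.pair_probabilities(idx, H).data
            reports[name] = micro_f1(
                probs >= model.cfg.threshold, _label_matrix(edges)
            )
    return reports


def predict(
    model: Model, proteins: list[ProteinRecord], pairs: list[tuple]
):
    """Predict 7 interaction-type probabilities for each (protein_a, protein_b) pair.

    Returns a pandas DataFrame in input order: the pair, one probability
    column per interaction type, and the thresholded label set
    (semicolon-joined).
    """
    import pandas as pd

    index = model.index
    for a, b in pairs:
        for endpoint in (a, b):
            if endpoint not in index:
                raise ValueError(f"unknown protein id {endpoint!r}")
    idx = np.array([[index[a], index[b]] for a, b in pairs], dtype=np.int64)
    with no_grad():
        probs = model.pair_probabilities(idx).data
    rows = []
    for (a, b), p in zip(pairs, probs):
        labels = ";".join(
            t for t, v in zip(INTERACTION_TYPES, p) if v >= model.cfg.threshold
        )
        rows.append([a, b, *p.tolist(), labels])
    return pd.DataFrame(
        rows, columns=["protein_a", "protein_b", *INTERACTION_TYPES, "predicted_labels"]
    )


# -- checkpointing ------------------------------------------------------------


def save_checkpoint(model: Model, path) -> None:
    """Serialize parameters + metadata to an .npz archive."""
    arrays = {f"param_{i}": p.data for i, p in enumerate(model.parameters())}
    arrays["adjacency"] = model.adjacency
    meta = {
        "cfg": asdict(model.cfg),
        "node_ids": model.node_ids,
        "vocab": model.vocab.to_json(),
        "class_map": model.class_map.to_json(),
    }
    arrays["meta_json"] = np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_checkpoint(path, proteins: list[ProteinRecord]) -> Model:
    """Rebuild a Model from a checkpoint; sequences are re-encoded from ``proteins``."""
    archive = np.load(path)
    meta = json.loads(bytes(archive["meta_json"].tolist()).decode("utf-8"))
    cfg = TrainConfig(**meta["cfg"])
    vocab = CooccurrenceVocab.from_json(meta["vocab"])
    class_map = ClassMap({k: int(v) for k, v in meta["class_map"].items()})
    by_id = {p.id: p for p in proteins}
    missing = [p for p in meta["node_ids"] if p not in by_id]
    if missing:
        raise ValueError(f"checkpoint references proteins without sequences: {missing}")
    ordered = [by_id[p] for p in meta["node_ids"]]
    rng = np.random.default_rng(cfg.seed + 1)
    model = _build_model(cfg, ordered, [], vocab, class_map, rng)
    model.adjacency = archive["adjacency"]
    for i, p in enumerate(model.parameters()):
        p.data = archive[f"param_{i}"]
    return model
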