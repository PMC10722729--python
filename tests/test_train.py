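import numpy as np
import pytest

from ppilink.io_formats import EdgeRecord
from ppilink.partition import random_split, traversal_split
from ppilink.train import (
    TrainConfig,
    evaluate,
    load_checkpoint,
    predict,
    save_checkpoint,
    train,
)

TINY = dict(
    channels_per_branch=4,
    n_submodules=2,
    frn_slices=4,
    fc_hidden=16,
    batch_size=8,
    cooc_epochs=1,
    eval_every=5,
)


@pytest.fixture(scope="module")
def tiny_split(tiny_dataset):
    proteins, edges = tiny_dataset
    return random_split(edges, ratio=0.2, seed=1)


@pytest.fixture(scope="module")
def trained(tiny_dataset, tiny_split):
    proteins, edges = tiny_dataset
    cfg = TrainConfig(epochs=5, seed=5, **TINY)
    model, history = train(proteins, edges, tiny_split, cfg)
    return model, history


class TestTrainLoop:
    def test_history_one_entry_per_epoch_finite_loss(self, trained):
        _, history = trained
        assert len(history) == 5
        assert all(np.isfinite(h["loss"]) for h in history)

    def test_same_seed_identical_final_loss(self, tiny_dataset, tiny_split):
        proteins, edges = tiny_dataset
        cfg = TrainConfig(epochs=2, seed=9, **TINY)
        _, h1 = train(proteins, edges, tiny_split, cfg)
        _, h2 = train(proteins, edges, tiny_split, cfg)
        assert h1[-1]["loss"] == h2[-1]["loss"]

    def test_loss_decreases_on_noise_free_data(self, tiny_dataset, tiny_split):
        proteins, edges = tiny_dataset
        cfg = TrainConfig(epochs=10, seed=3, **TINY)
        _, history = train(proteins, edges, tiny_split, cfg)
        assert history[9]["loss"] < history[0]["loss"]

    def test_empty_train_set_rejected(self, tiny_dataset, tiny_split):
        proteins, edges = tiny_dataset
        bad = type(tiny_split)(
            scheme="random", seed=0, train_edges=[], test_edges=list(edges)
        )
        with pytest.raises(ValueError, match="empty training set"):
            train(proteins, edges, bad, TrainConfig(epochs=1, **TINY))

    def test_missing_sequence_rejected(self, tiny_dataset, tiny_split):
        proteins, edges = tiny_dataset
        with pytest.raises(ValueError, match="ghost"):
            bad_split = type(tiny_split)(
                scheme="random",
                seed=0,
                train_edges=tiny_split.train_edges
                + [EdgeRecord("ghost", proteins[0].id, frozenset({"binding"}))],
                test_edges=tiny_split.test_edges,
            )
            train(proteins, edges, bad_split, TrainConfig(epochs=1, **TINY))

    def test_no_test_edge_leakage(self, tiny_dataset, tiny_split):
        """Deleting test edges from the edge list leaves the trained model unchanged."""
        proteins, edges = tiny_dataset
        cfg = TrainConfig(epochs=2, seed=11, **TINY)
        m1, h1 = train(proteins, edges, tiny_split, cfg)
        m2, h2 = train(proteins, list(tiny_split.train_edges), tiny_split, cfg)
        assert h1[-1]["loss"] == h2[-1]["loss"]
        np.testing.assert_array_equal(m1.adjacency, m2.adjacency)
        for p1, p2 in zip(m1.parameters(), m2.parameters()):
            np.testing.assert_array_equal(p1.data, p2.data)

    def test_adjacency_contains_only_train_edges(self, trained, tiny_split):
        model, _ = trained
        index = model.index
        assert model.adjacency.sum() == 2 * len(tiny_split.train_edges)
        for e in tiny_split.test_edges:
            i, j = index[e.protein_a], index[e.protein_b]
            assert model.adjacency[i, j] == 0


class TestAblations:
    @pytest.mark.parametrize(
        "flags",
        [
            dict(use_inception=False),
            dict(use_attention=False),
            dict(use_frn=False),
            dict(use_frn=False, use_ntn=True),
            dict(use_inception=False, use_attention=False, use_frn=False),
            dict(pair_fusion="frn"),
            dict(pair_fusion="product", use_frn=False),
        ],
    )
    def test_every_component_subset_trains_and_evaluates(
        self, tiny_dataset, tiny_split, flags
    ):
        proteins, edges = tiny_dataset
        cfg = TrainConfig(epochs=1, seed=2, **TINY, **flags)
        model, history = train(proteins, edges, tiny_split, cfg)
        assert np.isfinite(history[-1]["loss"])
        reports = evaluate(model, proteins, tiny_split)
        assert 0.0 <= reports["overall"].micro_f1 <= 1.0


class TestEvaluate:
    def test_count_conservation(self, trained, tiny_dataset, tiny_split):
        model, _ = trained
        proteins, _ = tiny_dataset
        reports = evaluate(model, proteins, tiny_split)
        total_positives = sum(len(e.labels) for e in tiny_split.test_edges)
        assert reports["overall"].tp + reports["overall"].fn == total_positives

    def test_empty_stratum_flagged_na(self, trained, tiny_dataset, tiny_split):
        model, _ = trained
        proteins, _ = tiny_dataset
        reports = evaluate(model, proteins, tiny_split)
        for name in ("homologous", "unknown"):
            if not getattr(tiny_split, f"test_{name}"):
                assert reports[name].na

    def test_overfit_on_training_edges(self, tiny_dataset):
        """A converged noise-free run predicts its own training edges well."""
        proteins, edges = tiny_dataset
        split = random_split(edges, ratio=0.2, seed=2)
        cfg = TrainConfig(
            epochs=150,
            seed=13,
            learning_rate=0.01,
            lr_schedule="cosine",
            encoder_pooling="max",
            **TINY,
        )
        model, history = train(proteins, edges, split, cfg)
        train_split = type(split)(
            scheme="random",
            seed=0,
            train_edges=split.train_edges,
            test_edges=split.train_edges,
            test_homologous=split.train_edges,
            test_unknown=[],
        )
        reports = evaluate(model, proteins, train_split)
        assert reports["overall"].micro_f1 >= 0.95


class TestPredict:
    def test_order_preserved_and_probabilities_valid(self, trained, tiny_dataset):
        model, _ = trained
        proteins, edges = tiny_dataset
        pairs = [(e.protein_a, e.protein_b) for e in edges[:5]]
        df = predict(model, proteins, pairs)
        assert list(zip(df.protein_a, df.protein_b)) == pairs
        probs = df.iloc[:, 2:9].to_numpy(dtype=float)
        assert ((probs > 0) & (probs < 1)).all()

    def test_duplicate_query_identical_rows(self, trained, tiny_dataset):
        model, _ = trained
        proteins, edges = tiny_dataset
        pair = (edges[0].protein_a, edges[0].protein_b)
        df = predict(model, proteins, [pair, pair])
        assert df.iloc[0].tolist() == df.iloc[1].tolist()

    def test_unknown_protein_named_in_error(self, trained, tiny_dataset):
        model, _ = trained
        proteins, _ = tiny_dataset
        with pytest.raises(ValueError, match="nonexistent"):
            predict(model, proteins, [(proteins[0].id, "nonexistent")])


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, trained, tiny_dataset, tmp_path):
        model, _ = trained
        proteins, edges = tiny_dataset
        path = tmp_path / "model.npz"
        save_checkpoint(model, path)
        restored = load_checkpoint(path, proteins)
        pairs = [(e.protein_a, e.protein_b) for e in edges[:4]]
        df1 = predict(model, proteins, pairs)
        df2 = predict(restored, proteins, pairs)
        assert df1.equals(df2)


class TestConfig:
    def test_defaults_match_reference_protocol(self):
        cfg = TrainConfig()
        assert cfg.learning_rate == 0.001
        assert cfg.batch_size == 2048
        assert cfg.epochs == 300
        assert cfg.max_length == 2000
        assert cfg.n_graph_layers == 1

    def test_yaml_round_trip(self, tmp_path):
        cfg = TrainConfig(epochs=7, channels_per_branch=4, use_frn=False)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        assert TrainConfig.from_yaml(path) == cfg

    def test_unknown_config_key_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("learning_rte: 0.01\n")
        with pytest.raises(ValueError, match="learning_rte"):
            TrainConfig.from_yaml(path)
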