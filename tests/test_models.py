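"""CNN building, training, inference and architecture search.

Trainings here are deliberately tiny (tens to hundreds of samples, a few
epochs): they check contracts — descent, determinism, recovery — not
benchmark accuracy.
"""

import numpy as np
import pytest

from pahsers.metrics import roc_micro_macro
from pahsers.mixtures import generate_dataset
from pahsers.models import (
    ArchitectureConfig,
    ModelError,
    TrainingConfig,
    build_model,
    predict_scores,
    search_architecture,
    train,
)
from pahsers.nn import sigmoid
from pahsers.references import NoiseConfig

SMALL_ARCH = ArchitectureConfig(conv_blocks=((4, 9, 4), (8, 9, 4)), dense_units=16, dropout=0.0)


@pytest.fixture(scope="module")
def tiny_sets(library):
    cfg = NoiseConfig(noise_sd=0.0, max_shift=0, background_scale=0.05, seed=0)
    tr = generate_dataset(120, "train", library, cfg, seed=101)
    va = generate_dataset(40, "validation", library, cfg, seed=102)
    return tr, va


class TestBuild:
    def test_classifier_scores_are_probabilities(self, tiny_sets):
        tr, _ = tiny_sets
        m = build_model(SMALL_ARCH, 660, seed=0)
        out = m.network.forward(tr.X[:8][:, None, :])
        probs = sigmoid(out)
        assert probs.shape == (8, 5)
        assert np.all((probs >= 0) & (probs <= 1))

    def test_regressor_has_six_outputs(self, tiny_sets):
        tr, _ = tiny_sets
        arch = ArchitectureConfig(
            conv_blocks=SMALL_ARCH.conv_blocks, dense_units=16, dropout=0.0, head="regressor"
        )
        m = build_model(arch, 660, seed=0)
        assert m.network.forward(tr.X[:3][:, None, :]).shape == (3, 6)

    def test_same_seed_same_initial_forward(self, tiny_sets):
        tr, _ = tiny_sets
        probe = tr.X[:4][:, None, :]
        a = build_model(SMALL_ARCH, 660, seed=7).network.forward(probe)
        b = build_model(SMALL_ARCH, 660, seed=7).network.forward(probe)
        np.testing.assert_array_equal(a, b)

    def test_even_kernel_rejected(self):
        with pytest.raises(ModelError):
            ArchitectureConfig(conv_blocks=((4, 8, 2),))

    def test_pooling_beyond_input_rejected(self):
        arch = ArchitectureConfig(conv_blocks=((4, 9, 1000),))
        with pytest.raises(ModelError):
            build_model(arch, 660)

    def test_unknown_head_rejected(self):
        with pytest.raises(ModelError):
            ArchitectureConfig(head="autoencoder")


class TestTrain:
    def test_loss_descends_on_learnable_data(self, tiny_sets):
        tr, va = tiny_sets
        m = build_model(SMALL_ARCH, 660, seed=1)
        m = train(m, tr, va, TrainingConfig(max_epochs=5, patience=4, seed=1))
        assert m.history["train_loss"][-1] < m.history["train_loss"][0]
        assert m.trained

    def test_early_stopping_restores_best_epoch(self, tiny_sets):
        tr, va = tiny_sets
        m = build_model(SMALL_ARCH, 660, seed=2)
        m = train(m, tr, va, TrainingConfig(max_epochs=6, patience=2, seed=2))
        from pahsers.models import _epoch_loss

        final = _epoch_loss(m, va.X, va.presence.astype(float), 64)
        assert final == pytest.approx(min(m.history["val_loss"]), abs=1e-9)

    def test_repeat_run_determinism(self, tiny_sets):
        tr, va = tiny_sets
        histories = []
        for _ in range(2):
            m = build_model(SMALL_ARCH, 660, seed=3)
            m = train(m, tr, va, TrainingConfig(max_epochs=3, patience=2, seed=3))
            histories.append(np.array(m.history["val_loss"]))
        np.testing.assert_allclose(histories[0], histories[1], rtol=1e-4)

    def test_input_length_mismatch_rejected(self, tiny_sets):
        tr, va = tiny_sets
        m = build_model(SMALL_ARCH, 128, seed=0)
        with pytest.raises(ModelError):
            train(m, tr, va, TrainingConfig(max_epochs=2, patience=1, seed=0))

    def test_shuffled_labels_reach_only_chance_auc(self, library):
        cfg = NoiseConfig(noise_sd=0.0, max_shift=0, background_scale=0.05, seed=0)
        tr = generate_dataset(300, "train", library, cfg, seed=201)
        va = generate_dataset(100, "validation", library, cfg, seed=202)
        rng = np.random.default_rng(0)
        tr.presence = tr.presence[rng.permutation(len(tr))]
        m = build_model(SMALL_ARCH, 660, seed=4)
        m = train(m, tr, va, TrainingConfig(max_epochs=4, patience=3, seed=4))
        scores = predict_scores(m, va)
        micro, _, _ = roc_micro_macro(scores, va.presence)
        assert abs(micro.auc - 0.5) < 0.15


class TestPredict:
    def test_untrained_model_rejected(self, tiny_sets):
        tr, _ = tiny_sets
        m = build_model(SMALL_ARCH, 660, seed=0)
        with pytest.raises(ModelError):
            predict_scores(m, tr.X[:2])

    def test_overfit_classifier_recalls_training_samples(self, library):
        cfg = NoiseConfig(noise_sd=0.0, max_shift=0, background_scale=0.05, seed=0)
        ds = generate_dataset(20, "train", library, cfg, seed=301)
        m = build_model(SMALL_ARCH, 660, seed=5)
        m = train(m, ds, ds, TrainingConfig(max_epochs=60, patience=59, seed=5,
                                            learning_rate=3e-3))
        scores = predict_scores(m, ds)
        present = ds.presence.astype(bool)
        assert np.mean(scores[present] > 0.5) > 0.95

    def test_duplicate_inputs_get_identical_scores(self, tiny_sets):
        tr, va = tiny_sets
        m = build_model(SMALL_ARCH, 660, seed=6)
        m = train(m, tr, va, TrainingConfig(max_epochs=2, patience=1, seed=6))
        X = np.vstack([tr.X[:1], tr.X[:1]])
        scores = predict_scores(m, X)
        np.testing.assert_array_equal(scores[0], scores[1])

    def test_regressor_recovers_dominant_target(self, library):
        cfg = NoiseConfig(noise_sd=0.0, max_shift=0, background_scale=0.02, seed=0)
        tr = generate_dataset(400, "train", library, cfg, seed=401)
        va = generate_dataset(80, "validation", library, cfg, seed=402)
        arch = ArchitectureConfig(conv_blocks=((8, 9, 2), (16, 9, 2), (32, 9, 2)),
                                  dense_units=64, dropout=0.0, head="regressor")
        m = build_model(arch, 660, seed=7)
        m = train(m, tr, va, TrainingConfig(max_epochs=12, patience=11, seed=7))
        # noiseless single-target probes: argmax of predicted contributions right
        from pahsers.mixtures import compose_mixture
        from pahsers.references import make_blank

        blank = make_blank(library.grid, cfg.silent())
        rng = np.random.default_rng(0)
        hits = 0
        n_probe = 20
        for j in range(n_probe):
            c = np.zeros(5)
            c[j % 5] = 1.0
            s = compose_mixture(c, library, blank, cfg.silent(), rng)
            pred = predict_scores(m, s.spectrum.intensities)[0]
            hits += int(np.argmax(pred[:5]) == j % 5)
        assert hits >= int(0.9 * n_probe)


class TestSaveLoad:
    def test_checkpoint_round_trip(self, tiny_sets, tmp_path):
        tr, va = tiny_sets
        m = build_model(SMALL_ARCH, 660, seed=8)
        m = train(m, tr, va, TrainingConfig(max_epochs=2, patience=1, seed=8))
        m.save(tmp_path / "m.npz")
        from pahsers.models import TrainedModel

        back = TrainedModel.load(tmp_path / "m.npz")
        np.testing.assert_array_equal(
            predict_scores(back, va.X[:5]), predict_scores(m, va.X[:5])
        )
        assert back.architecture == m.architecture


class TestSearch:
    def test_singleton_space_returns_default(self, tiny_sets):
        tr, _ = tiny_sets
        space = {"filters": [(4, 8)], "kernel": [9], "pool": [4],
                 "dense_units": [16], "dropout": [0.0]}
        cfg = TrainingConfig(max_epochs=2, patience=1, seed=0)
        arch = search_architecture(space, tr, n_trials=1, seed=0, trial_cfg=cfg)
        assert arch.conv_blocks == ((4, 9, 4), (8, 9, 4))
        assert arch.dense_units == 16

    def test_search_is_deterministic(self, tiny_sets):
        tr, _ = tiny_sets
        space = {"filters": [(4, 8), (8, 16)], "kernel": [7, 9], "pool": [4],
                 "dense_units": [16, 32], "dropout": [0.0, 0.2]}
        cfg = TrainingConfig(max_epochs=2, patience=1, seed=0)
        a = search_architecture(space, tr, n_trials=3, seed=9, trial_cfg=cfg)
        b = search_architecture(space, tr, n_trials=3, seed=9, trial_cfg=cfg)
        assert a == b

    def test_empty_space_rejected(self, tiny_sets):
        tr, _ = tiny_sets
        with pytest.raises(ModelError):
            search_architecture({"filters": []}, tr, n_trials=1, seed=0)
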