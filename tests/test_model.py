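import math

import numpy as np
import pytest

from dtre.corpus_io import Document, EntityMention
from dtre.instance_gen import RelationInstance, generate_instances
from dtre.model import (
    ClassifierState,
    FocalLossParams,
    HashingEncoder,
    TrainConfig,
    _focal_grad_probs,
    bce_loss,
    build_encoder,
    focal_loss,
    fuse_features,
    predict_probs,
    train,
)
from dtre.pipeline import split_docs, _build_instances
from dtre.relations import N_CLASSES
from dtre.synthetic_data import SyntheticCorpusConfig, generate_corpus


def make_instances(n=4):
    doc = Document("1", "T.", "Aspirin inhibits COX2 now.")
    ents = [
        EntityMention("T1", "1", "CHEMICAL", 3, 10, "Aspirin"),
        EntityMention("T2", "1", "GENE-Y", 20, 24, "COX2", "101"),
    ]
    inst = generate_instances(doc, ents, [])[0]
    out = []
    for i in range(n):
        label = np.zeros(N_CLASSES, dtype=np.int8)
        label[i % N_CLASSES] = 1
        out.append(
            RelationInstance(
                instance_id=f"i{i}",
                doc_id="1",
                head_id="T1",
                tail_id="T2",
                marked_text=inst.marked_text + f" extra{i}",
                label=label,
            )
        )
    return out


class TestHashingEncoder:
    def test_deterministic_across_instances(self):
        a = HashingEncoder(dim=64, seed=3).encode("aspirin inhibits cox2")
        b = HashingEncoder(dim=64, seed=3).encode("aspirin inhibits cox2")
        assert np.array_equal(a, b)

    def test_seed_changes_embedding(self):
        a = HashingEncoder(dim=64, seed=3).encode("aspirin inhibits cox2")
        b = HashingEncoder(dim=64, seed=4).encode("aspirin inhibits cox2")
        assert not np.array_equal(a, b)

    def test_output_dim_and_unit_norm(self):
        enc = HashingEncoder(dim=32, seed=0)
        v = enc.encode("one two three")
        assert v.shape == (32,)
        assert np.linalg.norm(v) == pytest.approx(1.0)

    def test_trailing_punctuation_ignored(self):
        enc = HashingEncoder(dim=64, seed=0)
        assert np.array_equal(enc.encode("levels."), enc.encode("levels"))

    def test_empty_text_rejected(self):
        with pytest.raises(ValueError):
            HashingEncoder(dim=8).encode("   ")

    def test_build_encoder_spec(self):
        enc = build_encoder("hashed:128:9")
        assert (enc.dim, enc.seed) == (128, 9)
        with pytest.raises(ValueError):
            build_encoder("bert-large")


class TestFocalLoss:
    def test_perfectly_classified_positive_contributes_zero(self):
        assert focal_loss(np.array([1.0]), np.array([1.0])) == 0.0

    def test_single_term_hand_value(self):
        # y=1, p=0.5, gamma=0.5, eps=1e-6:
        # (1-0.5)^0.5 * (-log(0.5 + 1e-6))
        expected = math.sqrt(0.5) * -math.log(0.5 + 1e-6)
        got = focal_loss(
            np.array([0.5]), np.array([1.0]), FocalLossParams(gamma=0.5, eps=1e-6)
        )
        assert got == pytest.approx(expected, abs=1e-9)

    def test_gamma_zero_eps_zero_equals_bce_oracle(self):
        rng = np.random.default_rng(23)
        p = rng.uniform(0.01, 0.99, size=1000)
        y = rng.integers(0, 2, size=1000).astype(float)
        got = focal_loss(p, y, FocalLossParams(gamma=0.0, eps=1e-300))
        # independent elementwise oracle
        expected = -sum(
            yi * math.log(pi) + (1 - yi) * math.log(1 - pi) for pi, yi in zip(p, y)
        )
        assert got == pytest.approx(expected, abs=1e-9)
        assert bce_loss(p, y) == pytest.approx(expected, abs=1e-9)

    def test_nonnegative_and_monotone_in_p_for_positives(self):
        ps = np.linspace(0.01, 0.99, 50)
        losses = [
            focal_loss(np.array([p]), np.array([1.0]), FocalLossParams(0.5, 1e-6))
            for p in ps
        ]
        assert all(l >= 0 for l in losses)
        assert all(a >= b for a, b in zip(losses, losses[1:]))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            focal_loss(np.ones((2, 3)) * 0.5, np.ones((3, 2)))

    def test_mean_reduction(self):
        p = np.full((2, 13), 0.5)
        y = np.zeros((2, 13))
        assert focal_loss(p, y, reduction="mean") == pytest.approx(
            focal_loss(p, y) / 26
        )

    def test_gradient_matches_finite_differences(self):
        params = FocalLossParams(gamma=0.5, eps=1e-6)
        rng = np.random.default_rng(5)
        p = rng.uniform(0.05, 0.95, size=20)
        y = rng.integers(0, 2, size=20).astype(float)
        grad = _focal_grad_probs(p, y, params)
        h = 1e-7
        for i in range(20):
            dp = np.zeros_like(p)
            dp[i] = h
            num = (focal_loss(p + dp, y, params) - focal_loss(p - dp, y, params)) / (2 * h)
            assert grad[i] == pytest.approx(num, rel=1e-4)


class TestFuseFeatures:
    def test_mode_none_identity(self):
        v = np.arange(8.0)
        assert fuse_features(v, None, "none") is v

    def test_concat_dims(self):
        out = fuse_features(np.zeros(8), np.zeros(576), "concat")
        assert out.shape == (584,)

    def test_projection_dims(self):
        proj = np.zeros((576, 32))
        out = fuse_features(np.zeros(8), np.zeros(576), "concat", projection=proj)
        assert out.shape == (40,)

    def test_dim_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fuse_features(np.zeros(8), np.zeros(100), "concat", projection=np.zeros((576, 32)))


class TestPredictProbs:
    def test_zero_weights_give_half(self):
        insts = make_instances(2)
        enc = HashingEncoder(dim=16, seed=0)
        state = ClassifierState(
            encoder_name=enc.name,
            weights=np.zeros((16, N_CLASSES)),
            bias=np.zeros(N_CLASSES),
            config=TrainConfig(min_feature_count=1),
        )
        probs = predict_probs(state, insts, enc)
        assert np.allclose(probs, 0.5)

    def test_same_instance_identical_rows(self):
        insts = make_instances(1) * 2
        enc = HashingEncoder(dim=16, seed=0)
        rng = np.random.default_rng(0)
        state = ClassifierState(
            encoder_name=enc.name,
            weights=rng.normal(size=(16, N_CLASSES)),
            bias=np.zeros(N_CLASSES),
            config=TrainConfig(min_feature_count=1),
        )
        probs = predict_probs(state, insts, enc)
        assert np.array_equal(probs[0], probs[1])

    def test_hand_computed_sigmoid(self):
        class OneHotEncoder:
            name = "onehot:1"
            dim = 1

            def encode(self, text):
                return np.array([1.0])

            def encode_batch(self, texts):
                return np.ones((len(texts), 1))

        w = np.zeros((1, N_CLASSES))
        w[0, 0] = 2.0
        state = ClassifierState(
            encoder_name="onehot:1",
            weights=w,
            bias=np.zeros(N_CLASSES),
            config=TrainConfig(min_feature_count=1),
        )
        probs = predict_probs(state, make_instances(1), OneHotEncoder())
        assert probs[0, 0] == pytest.approx(1 / (1 + math.exp(-2.0)))
        assert probs[0, 1] == pytest.approx(0.5)


class TestTraining:
    def test_same_seed_bit_identical_state(self):
        insts = make_instances(8)
        enc = HashingEncoder(dim=32, seed=1)
        cfg = TrainConfig(seed=5, epochs=3, min_feature_count=1)
        a = train(insts, enc, cfg).to_json()
        b = train(insts, enc, cfg).to_json()
        assert a == b

    def test_zero_epochs_equals_initialization(self):
        insts = make_instances(4)
        enc = HashingEncoder(dim=32, seed=1)
        state = train(insts, enc, TrainConfig(seed=5, epochs=0, min_feature_count=1))
        rng = np.random.default_rng(5)
        expected = rng.normal(0.0, 0.01, (32, N_CLASSES))
        assert np.array_equal(state.weights, expected)
        assert np.array_equal(state.bias, np.zeros(N_CLASSES))

    def test_empty_instances_rejected(self):
        with pytest.raises(ValueError):
            train([], HashingEncoder(dim=8), TrainConfig())

    def test_state_round_trips_through_json(self, tmp_path):
        insts = make_instances(4)
        enc = HashingEncoder(dim=16, seed=1)
        state = train(insts, enc, TrainConfig(seed=2, epochs=2))
        path = tmp_path / "model.json"
        state.save(path)
        back = ClassifierState.load(path)
        assert back.to_json() == state.to_json()
        assert np.array_equal(
            predict_probs(back, insts, enc), predict_probs(state, insts, enc)
        )

    def test_separable_corpus_reaches_high_training_f1(self):
        """Trigger-word corpora are constructed to be linearly separable."""
        corpus = generate_corpus(SyntheticCorpusConfig(n_docs=60, seed=2))
        insts, _ = _build_instances(
            corpus.docs, corpus.entities, corpus.relations, {}, {}
        )
        enc = HashingEncoder(dim=2048, seed=2)
        cfg = TrainConfig(
            seed=0, epochs=80, use_chem_desc=False, use_gene_desc=False
        )
        state = train(insts, enc, cfg)
        probs = predict_probs(state, insts, enc)
        Y = np.stack([i.label for i in insts])
        pred = probs >= 0.5
        tp = int((pred & (Y == 1)).sum())
        fp = int((pred & (Y == 0)).sum())
        fn = int((~pred & (Y == 1)).sum())
        f1 = 2 * tp / (2 * tp + fp + fn)
        assert f1 >= 0.95

    def test_bce_loss_option_trains(self):
        insts = make_instances(8)
        enc = HashingEncoder(dim=32, seed=1)
        state = train(insts, enc, TrainConfig(seed=0, epochs=2, loss="bce"))
        assert state.weights.shape == (32, N_CLASSES)
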