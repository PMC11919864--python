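"""Label mapping, splitting, the network's algebra, and training behaviour.

Training tests use reduced layer widths so they run in seconds; the
study-scale configuration is exercised by the acceptance suite.
"""

import numpy as np
import pandas as pd
import pytest

from emophys import nn
from emophys.io import TrialScores
from emophys.model import (
    AttCnnGru,
    ModelConfig,
    TrainingDivergedError,
    grid_search,
    map_score_to_class,
    map_scores_to_classes,
    split_dataset,
)
from emophys.selection import FeatureTable

SMALL = dict(conv1_filters=16, conv2_filters=16, gru_units=24, attention_dim=8,
             dense_units=16)


def separable_table(rng, n=600, n_features=9, spread=2.0, noise=0.5):
    y = rng.integers(0, 3, n)
    centers = np.zeros((3, n_features))
    for c in range(3):
        centers[c, c::3] = spread
    X = centers[y] + noise * rng.standard_normal((n, n_features))
    idx = [f"s{i}" for i in range(n)]
    df = pd.DataFrame(X, columns=[f"f{i}" for i in range(n_features)], index=idx)
    return FeatureTable(df, pd.Series(y, index=idx))


class TestScoreMapping:
    @pytest.mark.parametrize("score,expected", [(1, 0), (2, 0), (3, 1), (4, 2), (5, 2)])
    def test_mapping_rule(self, score, expected):
        assert map_score_to_class(score) == expected

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            map_score_to_class(6)

    def test_per_dimension_mapping(self):
        out = map_scores_to_classes(TrialScores(2, 3, 5))
        assert out == {"valence": 0, "arousal": 1, "dominance": 2}


class TestSplit:
    def test_1000_samples_split_720_80_200(self, rng):
        table = separable_table(rng, n=1000)
        tr, va, te = split_dataset(table, seed=0)
        assert (len(tr.df), len(va.df), len(te.df)) == (720, 80, 200)
        all_ids = sorted(tr.df.index) + sorted(va.df.index) + sorted(te.df.index)
        assert sorted(all_ids) == sorted(table.df.index)  # disjoint union

    def test_same_seed_identical_sets(self, rng):
        table = separable_table(rng, n=300)
        s1 = split_dataset(table, seed=3)
        s2 = split_dataset(table, seed=3)
        for a, b in zip(s1, s2):
            assert list(a.df.index) == list(b.df.index)

    def test_stratification_within_one_sample(self, rng):
        table = separable_table(rng, n=900)
        global_props = table.labels.value_counts(normalize=True)
        for part in split_dataset(table, seed=1):
            counts = part.labels.value_counts()
            for cls in (0, 1, 2):
                expected = global_props[cls] * len(part.df)
                assert abs(counts.get(cls, 0) - expected) <= 1.0

    def test_tiny_class_rejected(self, rng):
        table = separable_table(rng, n=40)
        table.labels[:] = 0
        table.labels.iloc[:3] = 1
        with pytest.raises(ValueError, match="stratify"):
            split_dataset(table)


class TestNetworkAlgebra:
    def test_softmax_rows_sum_to_one(self, rng):
        logits = rng.standard_normal((1000, 3)) * 50
        probs = nn.softmax(logits)
        assert np.all(probs >= 0) and np.all(probs <= 1)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_forward_outputs_distribution(self, rng):
        cfg = ModelConfig(**SMALL)
        params = nn.init_params(cfg, 9, rng)
        probs, _ = nn.forward(params, rng.standard_normal((17, 9)), cfg)
        assert probs.shape == (17, 3)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_attention_weights_normalized(self, rng):
        cfg = ModelConfig(**SMALL)
        params = nn.init_params(cfg, 12, rng)
        _, cache = nn.forward(params, rng.standard_normal((5, 12)), cfg)
        alpha = cache["alpha"]
        assert np.all(alpha >= 0)
        np.testing.assert_allclose(alpha.sum(axis=1), 1.0, atol=1e-12)

    def test_attention_identity_on_constant_sequence(self, rng):
        # all timestep vectors equal v -> convex combination returns v
        Hseq = np.tile(rng.standard_normal((3, 1, 8)), (1, 6, 1))
        Wa = rng.standard_normal((8, 4))
        ba = rng.standard_normal(4)
        va = rng.standard_normal(4)
        context, alpha, _ = nn.attention_pool(Hseq, Wa, ba, va)
        np.testing.assert_allclose(context, Hseq[:, 0, :], rtol=1e-12)

    def test_cce_perfect_prediction_zero(self):
        y = np.eye(3)
        assert nn.categorical_cross_entropy(y, y) < 1e-6

    def test_cce_uniform_is_ln3(self):
        y = np.eye(3)[[0, 2, 1]]
        pred = np.full((3, 3), 1 / 3)
        np.testing.assert_allclose(
            nn.categorical_cross_entropy(y, pred), np.log(3), rtol=1e-12
        )

    def test_cce_hand_evaluated_batch(self):
        y = np.array([[1.0, 0, 0], [0, 0, 1.0]])
        p = np.array([[0.7, 0.2, 0.1], [0.1, 0.3, 0.6]])
        expected = -(np.log(0.7) + np.log(0.6)) / 2
        np.testing.assert_allclose(nn.categorical_cross_entropy(y, p), expected, rtol=1e-12)

    def test_cce_rejects_non_distribution(self):
        with pytest.raises(ValueError, match="sum to 1"):
            nn.categorical_cross_entropy(np.eye(2), np.array([[0.9, 0.9], [0.1, 0.1]]))

    def test_gradients_match_finite_differences(self, rng):
        cfg = ModelConfig(conv1_filters=4, conv2_filters=3, gru_units=5,
                          attention_dim=3, dense_units=4)
        params = nn.init_params(cfg, 7, rng)
        X = rng.standard_normal((4, 7))
        Y = np.eye(3)[rng.integers(0, 3, 4)]
        _, cache = nn.forward(params, X, cfg)
        grads = nn.backward(params, cache, Y, cfg)
        eps = 1e-6
        check_rng = np.random.default_rng(0)
        for key, v in params.items():
            for fi in check_rng.choice(v.size, size=min(v.size, 4), replace=False):
                idx = np.unravel_index(fi, v.shape)
                orig = v[idx]
                v[idx] = orig + eps
                lp = nn.categorical_cross_entropy(Y, nn.forward(params, X, cfg)[0], eps=1e-300)
                v[idx] = orig - eps
                lm = nn.categorical_cross_entropy(Y, nn.forward(params, X, cfg)[0], eps=1e-300)
                v[idx] = orig
                num = (lp - lm) / (2 * eps)
                ana = grads[key][idx]
                assert abs(num - ana) <= 1e-4 * max(abs(num), abs(ana), 1e-3), key


class TestTraining:
    def test_learns_separable_data(self, rng):
        table = separable_table(rng, n=600)
        tr, va, te = split_dataset(table, seed=0)
        cfg = ModelConfig(seed=0, epochs=30, **SMALL)
        res = AttCnnGru.from_feature_table(tr, config=cfg).fit(validation=va)
        rep = res.evaluate(te)
        assert rep.accuracy >= 0.90

    def test_label_shuffle_drops_to_chance(self, rng):
        table = separable_table(rng, n=600)
        shuffled = FeatureTable(
            table.df,
            pd.Series(rng.permutation(table.labels.to_numpy()), index=table.df.index),
        )
        tr, va, te = split_dataset(shuffled, seed=0)
        cfg = ModelConfig(seed=0, epochs=20, **SMALL)
        res = AttCnnGru.from_feature_table(tr, config=cfg).fit(validation=va)
        rep = res.evaluate(te)
        assert rep.accuracy <= 0.45

    def test_same_seed_identical_history(self, rng):
        table = separable_table(rng, n=200)
        tr, va, _ = split_dataset(table, seed=0)
        cfg = ModelConfig(seed=9, epochs=5, **SMALL)
        h1 = AttCnnGru.from_feature_table(tr, config=cfg).fit(validation=va).history
        h2 = AttCnnGru.from_feature_table(tr, config=cfg).fit(validation=va).history
        assert h1["val_loss"].iloc[-1] == h2["val_loss"].iloc[-1]
        pd.testing.assert_frame_equal(h1, h2)

    def test_training_loss_mostly_decreasing(self, rng):
        table = separable_table(rng, n=300)
        tr, va, _ = split_dataset(table, seed=0)
        cfg = ModelConfig(seed=0, epochs=20, **SMALL)
        res = AttCnnGru.from_feature_table(tr, config=cfg).fit(validation=va)
        losses = res.history["loss"].to_numpy()
        frac_down = np.mean(np.diff(losses) <= 0)
        assert frac_down >= 0.9

    def test_feature_contract_enforced(self, rng):
        table = separable_table(rng, n=200)
        tr, va, te = split_dataset(table, seed=0)
        cfg = ModelConfig(seed=0, epochs=2, **SMALL)
        res = AttCnnGru.from_feature_table(tr, config=cfg).fit(validation=va)
        bad = te.df.rename(columns={"f0": "wrong"})
        with pytest.raises(ValueError, match="contract"):
            res.predict_proba(bad)

    def test_divergence_reported(self, rng):
        table = separable_table(rng, n=120)
        tr, _, _ = split_dataset(table, seed=0)
        cfg = ModelConfig(seed=0, epochs=5, learning_rate=0.9999, **SMALL)
        model = AttCnnGru.from_feature_table(tr, config=cfg)
        try:
            model.fit()
        except TrainingDivergedError as exc:
            assert "epoch" in str(exc)

    def test_save_load_round_trip(self, rng, tmp_path):
        from emophys.model import load_results
        table = separable_table(rng, n=200)
        tr, va, te = split_dataset(table, seed=0)
        cfg = ModelConfig(seed=0, epochs=3, **SMALL)
        res = AttCnnGru.from_feature_table(tr, config=cfg).fit(validation=va)
        res.save(tmp_path / "model.npz")
        back = load_results(tmp_path / "model.npz")
        np.testing.assert_array_equal(back.predict(te.df), res.predict(te.df))

    def test_summary_mentions_key_facts(self, rng):
        table = separable_table(rng, n=200)
        tr, va, _ = split_dataset(table, seed=0)
        cfg = ModelConfig(seed=0, epochs=2, **SMALL)
        res = AttCnnGru.from_feature_table(tr, config=cfg).fit(validation=va)
        text = res.summary()
        assert "Adam" in text and "GRU" in text and "Epochs" in text


class TestGridSearch:
    def test_single_config_single_row(self, rng):
        table = separable_table(rng, n=200)
        tr, va, _ = split_dataset(table, seed=0)
        out = grid_search([ModelConfig(seed=0, epochs=2, **SMALL)], tr, va)
        assert len(out) == 1

    def test_m1_to_m8_axes_expressible(self):
        configs = [
            ModelConfig(conv1_filters=c1, conv2_filters=c2, gru_units=g, kernel_size=3)
            for c1 in (128, 256) for c2 in (128, 256) for g in (128, 256)
        ]
        assert len(configs) == 8
        assert {(c.conv1_filters, c.conv2_filters, c.gru_units) for c in configs} == {
            (c1, c2, g) for c1 in (128, 256) for c2 in (128, 256) for g in (128, 256)
        }

    def test_capacity_beats_degenerate_config(self, rng):
        # a 1-filter bottleneck should never outrank the small-but-real net
        wins = 0
        for s in range(5):
            table = separable_table(np.random.default_rng(50 + s), n=240)
            tr, va, _ = split_dataset(table, seed=s)
            rich = ModelConfig(seed=s, epochs=10, **SMALL)
            poor = ModelConfig(seed=s, epochs=10, conv1_filters=1, conv2_filters=1,
                               gru_units=2, attention_dim=2, dense_units=2)
            out = grid_search([rich, poor], tr, va)
            accs = out.set_index("config_index")["val_accuracy"]
            wins += accs[0] >= accs[1]
        assert wins >= 4
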