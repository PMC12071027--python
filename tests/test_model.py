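"""Tests of the MinMax multiple-instance classifier."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from milanova import (
    ModelConfig,
    attention_map,
    minmax_select,
    mlp_widths_for_level,
    predict,
    score_patches,
    train_model,
)
from milanova.model import (
    bag_loss_from_scores,
    load_checkpoint,
    minmax_indices,
    save_checkpoint,
)
from milanova.synthetic import FeatureBag

from conftest import SMALL_CONFIG


def sort_oracle(scores, nt, nb):
    """Brute-force reference: full stable sort, take extremes."""
    order = sorted(range(len(scores)), key=lambda i: (-scores[i], i))
    top = [scores[i] for i in order[:nt]]
    order_asc = sorted(range(len(scores)), key=lambda i: (scores[i], i))
    bottom = [scores[i] for i in order_asc[:nb]]
    return np.array(top + bottom)


class TestMinMaxSelect:
    def test_worked_example(self):
        np.testing.assert_array_equal(
            minmax_select([0.9, 0.1, 0.5, 0.7], 2, 1), [0.9, 0.7, 0.1]
        )

    def test_no_negative_evidence(self):
        # Nb=0 is a studied factor level: output is just the maxima.
        np.testing.assert_array_equal(minmax_select([3.0, 1.0, 2.0], 2, 0), [3.0, 2.0])

    def test_all_ties(self):
        np.testing.assert_array_equal(
            minmax_select([2.0, 2.0, 2.0, 2.0], 2, 2), [2.0] * 4
        )

    def test_tie_break_by_lower_index(self):
        idx = minmax_indices([1.0, 5.0, 5.0, 0.0], 1, 1)
        assert idx[0] == 1  # first of the tied maxima
        assert idx[1] == 3

    def test_bag_too_small(self):
        with pytest.raises(ValueError, match="too small"):
            minmax_select([1.0, 2.0], 2, 1)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.floats(-100, 100, allow_nan=False).map(lambda v: round(v, 1)),
            min_size=1,
            max_size=30,
        ),
        st.data(),
    )
    def test_matches_sort_oracle(self, scores, data):
        nt = data.draw(st.integers(1, len(scores)))
        nb = data.draw(st.integers(0, len(scores) - nt))
        np.testing.assert_array_equal(
            minmax_select(scores, nt, nb), sort_oracle(scores, nt, nb)
        )


def _bag(rng, n=40, d=64, label=0):
    return FeatureBag(features=rng.standard_normal((n, d)), label=label, bag_id="t")


class TestScorePatches:
    def test_permutation_equivariance(self, trained_model, rng):
        bag = _bag(rng)
        perm = rng.permutation(bag.n_patches)
        permuted = FeatureBag(features=bag.features[perm], label=0, bag_id="p")
        np.testing.assert_allclose(
            score_patches(permuted, trained_model),
            score_patches(bag, trained_model)[perm],
            atol=1e-12,
        )

    def test_identical_patches_identical_scores(self, trained_model, rng):
        row = rng.standard_normal(64)
        feats = rng.standard_normal((10, 64))
        feats[2] = row
        feats[7] = row
        scores = score_patches(
            FeatureBag(features=feats, label=0, bag_id="d"), trained_model
        )
        np.testing.assert_array_equal(scores[2], scores[7])

    def test_zero_weights_zero_scores(self, trained_model, rng):
        zeroed = dataclasses.replace(trained_model)
        zeroed.params = {
            k: [np.zeros_like(a) for a in v] for k, v in trained_model.params.items()
        }
        scores = score_patches(_bag(rng), zeroed)
        np.testing.assert_array_equal(scores, 0.0)

    def test_dimension_mismatch(self, trained_model, rng):
        with pytest.raises(ValueError, match="feature_dim"):
            score_patches(_bag(rng, d=32), trained_model)


class TestPredict:
    def test_probabilities_normalized(self, trained_model, rng):
        for _ in range(5):
            p = predict(_bag(rng), trained_model)
            assert np.all(p >= 0)
            assert abs(p.sum() - 1.0) < 1e-6

    def test_permutation_invariance(self, trained_model, rng):
        bag = _bag(rng)
        perm = rng.permutation(bag.n_patches)
        shuffled = FeatureBag(features=bag.features[perm], label=0, bag_id="s")
        np.testing.assert_allclose(
            predict(bag, trained_model), predict(shuffled, trained_model), atol=1e-12
        )

    def test_duplication_invariance_under_ties(self, trained_model, rng):
        # Duplicating patches preserves the selected score multiset only when
        # the selection boundary is tied; the all-identical bag is the clean
        # case where the invariance holds exactly.
        row = rng.standard_normal(64)
        bag1 = FeatureBag(features=np.tile(row, (20, 1)), label=0, bag_id="a")
        bag2 = FeatureBag(features=np.tile(row, (40, 1)), label=0, bag_id="b")
        np.testing.assert_allclose(
            predict(bag1, trained_model), predict(bag2, trained_model), atol=1e-12
        )

    def test_zero_weights_uniform(self, trained_model, rng):
        zeroed = dataclasses.replace(trained_model)
        zeroed.params = {
            k: [np.zeros_like(a) for a in v] for k, v in trained_model.params.items()
        }
        np.testing.assert_allclose(predict(_bag(rng), zeroed), np.full(3, 1 / 3))


class TestTraining:
    def test_empty_and_single_class_rejected(self, rng):
        cfg = dataclasses.replace(SMALL_CONFIG, epochs=1)
        with pytest.raises(ValueError):
            train_model([], cfg)
        bags = [_bag(rng, label=1) for _ in range(4)]
        with pytest.raises(ValueError, match="two classes"):
            train_model(bags, cfg)

    def test_history_length_and_reproducibility(self, rng):
        bags = [_bag(rng, label=i % 2) for i in range(6)]
        cfg = dataclasses.replace(SMALL_CONFIG, epochs=3, seed=7)
        m1 = train_model(bags, cfg)
        m2 = train_model(bags, cfg)
        assert len(m1.history) == 3
        for key in m1.params:
            for a, b in zip(m1.params[key], m2.params[key]):
                np.testing.assert_array_equal(a, b)

    def test_weight_decay_shrinks_parameter_norms(self, rng):
        bags = [_bag(rng, label=i % 2) for i in range(8)]
        cfg0 = dataclasses.replace(SMALL_CONFIG, epochs=5, weight_decay=0.0, dropout=0.0)
        cfg1 = dataclasses.replace(cfg0, weight_decay=0.1)
        m0 = train_model(bags, cfg0)
        m1 = train_model(bags, cfg1)
        norm = lambda m: sum(
            float(np.sum(w**2)) for key in ("conv_w", "mlp_w") for w in m.params[key]
        )
        assert norm(m1) < norm(m0)

    def test_separable_dataset_reaches_high_f1(self, trained_model, eval_bags):
        from milanova import evaluate_model

        f1, auc = evaluate_model(trained_model, eval_bags)
        assert f1 > 0.9
        assert auc > 0.9


class TestGradients:
    def test_backprop_matches_finite_differences(self, rng):
        # end-to-end analytic gradient check on a tiny network
        cfg = ModelConfig(
            feature_dim=5,
            conv_widths=(4, 3),
            Nt=2,
            Nb=1,
            mlp_widths=(4,),
            dropout=0.0,
            epochs=1,
            seed=3,
        )
        from milanova.model import (
            _conv_backward,
            _conv_forward,
            _head_backward,
            _head_forward,
            _init_params,
        )

        params = _init_params(cfg, np.random.default_rng(0))
        X = rng.standard_normal((8, 5))
        label = 1

        def loss(p):
            scores, _ = _conv_forward(p, X)
            probs, _ = _head_forward(p, scores, cfg.Nt, cfg.Nb)
            return -np.log(probs[label])

        scores, conv_cache = _conv_forward(params, X)
        _, head_cache = _head_forward(params, scores, cfg.Nt, cfg.Nb)
        g_head, d_scores = _head_backward(params, head_cache, label, X.shape[0])
        g_conv = _conv_backward(params, conv_cache, d_scores)
        grads = {**g_head, **g_conv}

        eps = 1e-6
        for key in ("conv_w", "mlp_w", "conv_b", "mlp_b"):
            for li, arr in enumerate(params[key]):
                it = np.nditer(arr, flags=["multi_index"])
                for _ in range(min(arr.size, 5)):
                    ix = it.multi_index
                    orig = arr[ix]
                    arr[ix] = orig + eps
                    lp = loss(params)
                    arr[ix] = orig - eps
                    lm = loss(params)
                    arr[ix] = orig
                    num = (lp - lm) / (2 * eps)
                    assert grads[key][li][ix] == pytest.approx(num, rel=1e-4, abs=1e-7)
                    it.iternext()

    def test_unselected_patch_score_gradient_exactly_zero(self, trained_model, rng):
        bag = _bag(rng, n=30)
        scores = score_patches(bag, trained_model)
        cfg = trained_model.config
        base = bag_loss_from_scores(trained_model, scores, label=0)
        selected = {
            (p, c)
            for c in range(cfg.n_classes)
            for p in minmax_indices(scores[:, c], cfg.Nt, cfg.Nb)
        }
        unselected = [
            (p, c)
            for p in range(bag.n_patches)
            for c in range(cfg.n_classes)
            if (p, c) not in selected
        ]
        assert unselected
        for p, c in unselected[:10]:
            bumped = scores.copy()
            bumped[p, c] += 1e-7  # too small to change the selection
            assert bag_loss_from_scores(trained_model, bumped, 0) == base


class TestAttentionMap:
    def test_argmax_consistent_with_selection(self, trained_model, rng):
        bag = _bag(rng)
        for c in range(3):
            cam = attention_map(bag, trained_model, c)
            first = minmax_indices(
                score_patches(bag, trained_model)[:, c],
                trained_model.config.Nt,
                trained_model.config.Nb,
            )[0]
            assert int(np.argmax(cam)) == int(first)
            assert cam.shape == (bag.n_patches,)

    def test_independent_of_other_bags(self, trained_model, rng):
        bag = _bag(rng)
        cam1 = attention_map(bag, trained_model, 1)
        _ = predict(_bag(rng), trained_model)  # unrelated computation
        np.testing.assert_array_equal(cam1, attention_map(bag, trained_model, 1))

    def test_bad_class_index(self, trained_model, rng):
        with pytest.raises(IndexError):
            attention_map(_bag(rng), trained_model, 7)


def test_mlp_widths_for_level():
    assert mlp_widths_for_level(1) == (64,)
    assert mlp_widths_for_level(2) == (128, 64)
    assert mlp_widths_for_level(3) == (256, 128, 64)
    with pytest.raises(ValueError):
        mlp_widths_for_level(4)


def test_checkpoint_round_trip(tmp_path, trained_model, rng):
    path = tmp_path / "model.npz"
    save_checkpoint(trained_model, path)
    loaded = load_checkpoint(path)
    bag = _bag(rng)
    np.testing.assert_array_equal(predict(bag, trained_model), predict(bag, loaded))
    assert loaded.config == trained_model.config
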