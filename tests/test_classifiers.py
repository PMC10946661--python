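"""Decision rules and classifier contracts (training quality is exercised
end-to-end in the acceptance suite)."""

import numpy as np
import pandas as pd
import pytest

from grainpigment.classifiers import (
    CNNPigmentClassifier,
    MultiTaskClassifier,
    PigmentScores,
    RF13Classifier,
    TwoChannelClassifier,
    aggregate_pixels,
    decide_label,
)
from grainpigment.labels import PigmentLabel


class TestDecideLabel:
    @pytest.mark.parametrize(
        "scores,code",
        [((0.7, 0.2), "A"), ((0.5, 0.5), "NP"), ((0.9, 0.9), "AM"),
         ((0.2, 0.7), "M"), ((0.0, 0.0), "NP"), ((0.51, 0.5), "A")],
    )
    def test_strict_threshold_rule(self, scores, code):
        assert decide_label(scores).code == code
        assert decide_label(PigmentScores(*scores)).code == code

    def test_exhaustive_grid_monotonicity(self):
        """Raising a score never removes a pigment from the prediction."""
        grid = np.linspace(0, 1, 11)
        for pa in grid:
            for pm in grid:
                base = decide_label((pa, pm))
                for eps in (0.05, 0.3):
                    up = decide_label((min(pa + eps, 1.0), pm))
                    assert up.anthocyanin >= base.anthocyanin
                    assert up.melanin >= base.melanin

    def test_invalid_scores_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            PigmentScores(1.2, 0.0)


class TestAggregatePixels:
    def test_all_zero_is_np(self):
        assert aggregate_pixels(np.zeros((2, 8, 8))).code == "NP"

    def test_single_pixel_flags_pigment(self):
        m = np.zeros((2, 8, 8))
        m[0, 3, 3] = 1
        assert aggregate_pixels(m).code == "A"
        m[1, 0, 0] = 1
        assert aggregate_pixels(m).code == "AM"

    def test_exhaustive_single_pixel_enumeration(self):
        """Any one positive pixel in either channel flips that pigment."""
        for ch in (0, 1):
            for r in range(4):
                for c in range(4):
                    m = np.zeros((2, 4, 4))
                    m[ch, r, c] = 1
                    lab = aggregate_pixels(m)
                    assert lab.as_pair() == ((1, 0) if ch == 0 else (0, 1))

    def test_min_fraction_threshold(self):
        m = np.zeros((2, 20, 20))
        m[0, 0, :2] = 1  # 0.5 % of the frame
        assert aggregate_pixels(m, min_fraction=0.01).code == "NP"
        assert aggregate_pixels(m, min_fraction=0.0).code == "A"

    def test_wrong_channel_count_rejected(self):
        with pytest.raises(ValueError, match=r"\(2, H, W\)"):
            aggregate_pixels(np.zeros((3, 4, 4)))


_CLASS_PATTERNS = {
    code: np.random.default_rng(100 + i).normal(0.5, 0.3, 30)
    for i, code in enumerate(("NP", "A", "M", "AM"))
}


def _separable_features(n_per_class=12, seed=0):
    """Well-separated class means across all columns plus small noise —
    mimics color descriptors, where class signal spans many channels."""
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    for code in ("NP", "A", "M", "AM"):
        lab = PigmentLabel.from_code(code)
        for _ in range(n_per_class):
            rows.append(_CLASS_PATTERNS[code] + rng.normal(0, 0.05, 30))
            labels.append(lab)
    return pd.DataFrame(rows), labels


class TestRF13:
    def test_forest_sees_13_dimensions(self):
        X, y = _separable_features()
        model = RF13Classifier(n_trees=50, seed=0).fit(X, y)
        assert model.reduced_dim_ == 13
        assert model.transform(X).shape == (len(X), 13)
        assert model.forest_.n_features_in_ == 13

    def test_separable_classes_recovered(self):
        X, y = _separable_features()
        model = RF13Classifier(n_trees=50, seed=0).fit(X, y)
        Xt, yt = _separable_features(seed=1)
        assert model.score(Xt, yt) >= 0.95

    def test_row_order_invariance(self):
        X, y = _separable_features()
        ref = RF13Classifier(n_trees=50, seed=0).fit(X, y)
        perm = np.random.default_rng(1).permutation(len(X))
        shuf = RF13Classifier(n_trees=50, seed=0).fit(X.iloc[perm], [y[i] for i in perm])
        Xt, _ = _separable_features(seed=2)
        assert ref.predict(Xt) == shuf.predict(Xt)

    def test_predictions_ignore_filtered_columns(self):
        X, y = _separable_features()
        X["dead"] = 0.7  # constant: removed by rule 1
        model = RF13Classifier(n_trees=50, seed=0).fit(X, y)
        Xt, _ = _separable_features(seed=3)
        Xt["dead"] = 0.7
        ref = model.predict(Xt)
        Xt["dead"] = np.random.default_rng(0).random(len(Xt))
        assert model.predict(Xt) == ref

    def test_missing_class_warns(self):
        X, y = _separable_features()
        keep = [i for i, lab in enumerate(y) if lab.code != "AM"]
        with pytest.warns(UserWarning, match="absent"):
            RF13Classifier(n_trees=10, seed=0).fit(X.iloc[keep], [y[i] for i in keep])


class TestNetworkContracts:
    def test_cnn_scores_live_in_unit_interval(self, one_render):
        image, _, _ = one_render
        model = CNNPigmentClassifier(input_size=32, base_width=4, n_stages=2)
        model.net_ = model.build_net()
        scores = model.predict_scores([image])
        assert scores.shape == (1, 2)
        assert ((scores >= 0) & (scores <= 1)).all()

    def test_cnn_empty_training_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            CNNPigmentClassifier().fit([], [])

    def test_multitask_forward_contract(self, one_render):
        image, _, _ = one_render
        model = MultiTaskClassifier(input_size=32, depth=3, base_width=4)
        model.net_ = model.build_net()
        mask, scores = model.forward_pair(image)
        assert mask.shape == (32, 32)
        assert 0 <= scores.p_anthocyanin <= 1 and 0 <= scores.p_melanin <= 1

    def test_multitask_requires_masks(self, one_render):
        image, _, label = one_render
        with pytest.raises(ValueError, match="region mask"):
            MultiTaskClassifier().fit([image], None, [label])

    def test_lambda_zero_freezes_classification_head(self, small_dataset):
        model = MultiTaskClassifier(input_size=32, depth=3, base_width=4,
                                    epochs=1, lambda_cls=0.0, seed=0)
        init = model.build_net()
        head_w0 = init.head.W.value.copy()
        model.fit(small_dataset["train_images"][:4],
                  small_dataset["train_masks"][:4],
                  small_dataset["train_labels"][:4])
        assert np.array_equal(model.net_.head.W.value, head_w0)
        # the segmentation path did train
        assert not np.array_equal(model.net_.out_conv.W.value, init.out_conv.W.value)

    def test_twochannel_pixel_targets_are_label_broadcast(self, one_render):
        _, mask, _ = one_render
        t = TwoChannelClassifier.make_pixel_targets(mask, PigmentLabel(True, False), 64)
        assert t.shape == (2, 64, 64)
        assert t[0].sum() > 0 and t[1].sum() == 0

    def test_twochannel_requires_masks(self, one_render):
        image, _, label = one_render
        with pytest.raises(ValueError, match="region mask"):
            TwoChannelClassifier().fit([image], None, [label])
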