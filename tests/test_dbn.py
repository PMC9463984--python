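"""Stack training, stage transfer, and feature/map extraction."""

import numpy as np
import pytest

from vsdbn.dbn import (DBNModel, dbn_reconstruction_loss, extract_maps,
                       extract_temporal, fine_tune_subject,
                       init_subject_from_group, load_model, save_model,
                       train_group)
from vsdbn.metrics import scc
from vsdbn.rbm import RBMLayer, TrainConfig, hidden_conditional, train_rbm


@pytest.fixture(scope="module")
def toy_data():
    rng = np.random.default_rng(10)
    x = rng.standard_normal((80, 20)) @ rng.standard_normal((20, 20))
    return (x - x.mean(0)) / x.std(0)


def hand_model(W1, W2=None):
    layers = [RBMLayer(W=W1, a=np.zeros(W1.shape[0]), b=np.zeros(W1.shape[1]),
                       visible_kind="gaussian")]
    if W2 is not None:
        layers.append(RBMLayer(W=W2, a=np.zeros(W2.shape[0]),
                               b=np.zeros(W2.shape[1]),
                               visible_kind="bernoulli"))
    return DBNModel(layers=layers)


class TestTrainGroup:
    def test_single_layer_stack_equals_plain_rbm(self, toy_data):
        cfg = TrainConfig(epochs=30, seed=7)
        model = train_group(toy_data, (5,), cfg, sparsity_weight=0.5,
                            hidden_bias_init=-1.0)
        rbm, _ = train_rbm(toy_data, 5, cfg, visible_kind="gaussian",
                           sparsity_weight=0.5, hidden_bias_init=-1.0)
        np.testing.assert_array_equal(model.layers[0].W, rbm.W)
        np.testing.assert_array_equal(model.layers[0].b, rbm.b)

    def test_per_layer_losses_finite_and_logged(self, toy_data):
        model = train_group(toy_data, (6, 4, 3), TrainConfig(epochs=10, seed=1))
        assert len(model.loss_traces) == 3
        assert all(np.isfinite(t).all() for t in model.loss_traces)

    def test_layer_sizes_chain(self, toy_data):
        model = train_group(toy_data, (6, 4, 3), TrainConfig(epochs=2, seed=1))
        assert model.architecture == (6, 4, 3)
        with pytest.raises(ValueError, match="chain"):
            DBNModel(layers=[model.layers[0], model.layers[2]])

    def test_deterministic_to_the_bit(self, toy_data):
        cfg = TrainConfig(epochs=15, seed=3)
        a = train_group(toy_data, (5, 4), cfg)
        b = train_group(toy_data, (5, 4), cfg)
        for la, lb in zip(a.layers, b.layers):
            np.testing.assert_array_equal(la.W, lb.W)


class TestStageTransfer:
    def test_init_copies_weights_bit_for_bit(self, toy_data):
        group = train_group(toy_data, (5, 4), TrainConfig(epochs=10, seed=2))
        subject = init_subject_from_group(group, "s0")
        assert subject.stage == "subject:s0"
        for gl, sl in zip(group.layers, subject.layers):
            np.testing.assert_array_equal(gl.W, sl.W)
            np.testing.assert_array_equal(gl.a, sl.a)
            np.testing.assert_array_equal(gl.b, sl.b)
        subject.layers[0].W += 1.0  # deep copy: group must be untouched
        assert not np.array_equal(group.layers[0].W, subject.layers[0].W)

    def test_zero_epoch_fine_tune_gives_scc_one_everywhere(self, toy_data):
        group = train_group(toy_data, (5, 4), TrainConfig(epochs=10, seed=2))
        subject = fine_tune_subject(init_subject_from_group(group, "s0"),
                                    toy_data, TrainConfig(epochs=0, seed=5))
        gm, sm = extract_maps(group), extract_maps(subject)
        for L in (1, 2):
            for k in range(gm.layer(L).shape[0]):
                assert scc(gm.layer(L)[k], sm.layer(L)[k]) == pytest.approx(1.0)

    def test_untrained_group_rejected(self):
        with pytest.raises(RuntimeError):
            init_subject_from_group(DBNModel(layers=[]))

    def test_fine_tune_requires_subject_stage(self, toy_data):
        group = train_group(toy_data, (4,), TrainConfig(epochs=2, seed=2))
        with pytest.raises(RuntimeError):
            fine_tune_subject(group, toy_data, TrainConfig(epochs=1, seed=1))


class TestExtractTemporal:
    def test_layer1_is_rowwise_hidden_conditional(self, toy_data):
        model = train_group(toy_data, (5, 3), TrainConfig(epochs=5, seed=4))
        feats = extract_temporal(model, toy_data)
        np.testing.assert_allclose(
            feats.layer(1), hidden_conditional(model.layers[0], toy_data),
            atol=1e-15)

    def test_features_are_probabilities(self, toy_data):
        model = train_group(toy_data, (5, 3), TrainConfig(epochs=5, seed=4))
        feats = extract_temporal(model, toy_data)
        for L in (1, 2):
            assert np.all(feats.layer(L) > 0) and np.all(feats.layer(L) < 1)

    def test_group_segments_equal_per_subject_extraction(self, dataset02,
                                                         group_model):
        subjects, grp, _ = dataset02
        gfeat = extract_temporal(group_model, grp)
        for start, stop, sid in grp.segments[:3]:
            dm = next(s for s in subjects if s.subject_id == sid)
            sfeat = extract_temporal(group_model, dm)
            for L in (1, 2, 3):
                np.testing.assert_allclose(gfeat.layer(L)[start:stop],
                                           sfeat.layer(L), atol=1e-12)

    def test_dimension_mismatch_raises(self, toy_data):
        model = train_group(toy_data, (4,), TrainConfig(epochs=2, seed=4))
        with pytest.raises(ValueError):
            extract_temporal(model, toy_data[:, :7])


class TestExtractMaps:
    def test_identity_second_layer_repeats_first(self):
        rng = np.random.default_rng(3)
        W1 = rng.standard_normal((6, 3))
        model = hand_model(W1, np.eye(3))
        maps = extract_maps(model, zscore=False, sign_normalize=False)
        np.testing.assert_array_equal(maps.layer(2), maps.layer(1))

    def test_hand_computed_product(self):
        model = hand_model(np.eye(2), np.array([[2.0, 1.0], [0.0, 1.0]]))
        maps = extract_maps(model, zscore=False, sign_normalize=False)
        np.testing.assert_array_equal(maps.layer(2),
                                      np.array([[2.0, 0.0], [1.0, 1.0]]))

    def test_zscored_maps_have_unit_moments(self, toy_data):
        model = train_group(toy_data, (5, 3), TrainConfig(epochs=5, seed=4))
        maps = extract_maps(model, zscore=True)
        for L in (1, 2):
            assert np.abs(maps.layer(L).mean(axis=1)).max() < 1e-10
            assert np.abs(maps.layer(L).std(axis=1) - 1).max() < 1e-10

    def test_sign_normalized_peak_is_positive(self, toy_data):
        model = train_group(toy_data, (5, 3), TrainConfig(epochs=5, seed=4))
        maps = extract_maps(model, zscore=False, sign_normalize=True)
        for L in (1, 2):
            for row in maps.layer(L):
                assert row[np.abs(row).argmax()] > 0

    def test_map_shapes_follow_architecture(self, toy_data):
        model = train_group(toy_data, (6, 4, 3), TrainConfig(epochs=2, seed=1))
        maps = extract_maps(model)
        assert [m.shape for m in maps.maps] == [(6, 20), (4, 20), (3, 20)]


def test_model_save_load_round_trip(tmp_path, toy_data):
    model = train_group(toy_data, (5, 3), TrainConfig(epochs=5, seed=6))
    back = load_model(save_model(model, tmp_path / "m.h5"))
    assert back.stage == model.stage
    assert back.architecture == model.architecture
    for la, lb in zip(model.layers, back.layers):
        np.testing.assert_array_equal(la.W, lb.W)
        assert la.visible_kind == lb.visible_kind
    assert np.isclose(dbn_reconstruction_loss(back, toy_data),
                      dbn_reconstruction_loss(model, toy_data))
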