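import dataclasses

import numpy as np
import pytest

from petlymph import (
    Modality,
    NetworkConfig,
    PhantomConfig,
    binarize,
    build_network,
    generate_cohort,
    generate_phantom,
    load_model,
    sample_patches,
    save_model,
    train,
)
from petlymph.network import (
    TrainingError,
    _extract_pathway_inputs,
    predict_probability,
    prepare_case,
)

from conftest import tiny_network_config


class TestConfig:
    def test_output_tile_arithmetic(self):
        cfg = NetworkConfig()
        assert cfg.patch_size == 25 and cfg.n_conv == 8
        assert cfg.tile_size == 9  # 25 - 8*2

    def test_default_feature_counts(self):
        cfg = NetworkConfig()
        assert cfg.conv_features == (90, 90, 110, 110, 110, 110, 130, 130)
        assert cfg.fc_features == 250 and cfg.n_classes == 2

    def test_too_small_patch_rejected(self):
        with pytest.raises(ValueError):
            NetworkConfig(patch_size=16)

    def test_downsampled_first_pathway_rejected(self):
        with pytest.raises(ValueError):
            NetworkConfig(n_pathways=2, downsample_factors=(3, 5))


class TestArchitecture:
    def test_forward_smoke_25_to_9(self):
        cfg = tiny_network_config(patch_size=25)
        model = build_network(cfg)
        rng = np.random.default_rng(0)
        inputs, idxs = _extract_pathway_inputs(
            rng.normal(size=(40, 40, 40, 2)).astype(np.float32), np.array([10, 10, 10]), cfg
        )
        logits = model.forward(
            [v[None] for v in inputs], [None if i is None else i[None] for i in idxs]
        )
        assert logits.shape == (1, 9, 9, 9, 2)

    def test_downsampled_feature_map_matches_tile_after_upsampling(self):
        # the coarse pathway's pre-head feature map must align with the
        # full-resolution tile after nearest-neighbour upsampling
        cfg = tiny_network_config(patch_size=25)
        inputs, idxs = _extract_pathway_inputs(
            np.zeros((40, 40, 40, 2), np.float32), np.array([8, 8, 8]), cfg
        )
        # coarse pathway: ceil(9/3)+1 = 4 cells + 16 halo -> 20^3 input
        assert inputs[1].shape == (20, 20, 20, 2)
        assert idxs[1].shape == (3, 9)
        assert idxs[1].max() <= 3  # indices stay within the 4-cell map


class TestSampling:
    def test_balanced_sampling_counts(self, small_prepared):
        patches = sample_patches(small_prepared, 100, 0.5, seed=1, config=tiny_network_config())
        assert sum(p.center_is_positive for p in patches) == 50

    def test_zero_fraction_all_negative(self, small_prepared):
        patches = sample_patches(small_prepared, 10, 0.0, seed=1, config=tiny_network_config())
        assert not any(p.center_is_positive for p in patches)
        ref = small_prepared.reference
        for p in patches:
            assert not ref[p.center]

    def test_deterministic_given_seed(self, small_prepared):
        cfg = tiny_network_config()
        a = sample_patches(small_prepared, 8, 0.5, seed=3, config=cfg)
        b = sample_patches(small_prepared, 8, 0.5, seed=3, config=cfg)
        assert [p.center for p in a] == [p.center for p in b]

    def test_no_positives_rejected(self, small_phantom):
        case, _ = small_phantom
        stripped = dataclasses.replace(case, reference_mask=None)
        with pytest.raises(TrainingError):
            sample_patches(stripped, 4, 0.5, seed=0, config=tiny_network_config())


@pytest.fixture(scope="module")
def mini_cohort():
    cfg = PhantomConfig(grid_size=40, n_lesions=(1, 2), n_benign_hot=(0, 1))
    return [c for c, _ in generate_cohort(4, cfg, seed=5)]


@pytest.fixture(scope="module")
def model_and_case():
    case, _ = generate_phantom(PhantomConfig(grid_size=36, seed=21))
    pc = prepare_case(case)
    model = build_network(tiny_network_config(seed=2))
    return model, pc


class TestTraining:
    def test_loss_decreases(self, mini_cohort):
        cfg = tiny_network_config(epochs=4, batches_per_epoch=4, batch_size=4, seed=9)
        model, hist = train(mini_cohort, cfg)
        assert hist["train_loss"][-1] < hist["train_loss"][0]

    def test_same_seed_identical_weights(self, mini_cohort):
        cfg = tiny_network_config(epochs=1, batches_per_epoch=2, batch_size=2, seed=4)
        m1, _ = train(mini_cohort[:2], cfg)
        m2, _ = train(mini_cohort[:2], cfg)
        for p1, p2 in zip(m1.params(), m2.params()):
            np.testing.assert_array_equal(p1.value, p2.value)

    def test_empty_training_set_rejected(self):
        with pytest.raises(TrainingError):
            train([], tiny_network_config())

    def test_checkpoint_round_trip(self, mini_cohort, tmp_path):
        cfg = tiny_network_config(epochs=1, batches_per_epoch=1, batch_size=2, seed=6)
        model, _ = train(mini_cohort[:2], cfg)
        save_model(model, tmp_path / "ckpt.npz")
        back = load_model(tmp_path / "ckpt.npz")
        assert back.config == model.config
        for p1, p2 in zip(model.params(), back.params()):
            np.testing.assert_array_equal(p1.value, p2.value)


class TestInference:
    @staticmethod
    def _norm_volumes(pc):
        case = pc.case
        return (
            case.pet.with_data(pc.net_input[..., 0]),
            case.ct.with_data(pc.net_input[..., 1], modality=Modality.CT_HU),
        )

    def test_probability_range_and_grid(self, model_and_case):
        model, pc = model_and_case
        pet_n, ct_n = self._norm_volumes(pc)
        prob = predict_probability(model, pet_n, ct_n, body=pc.body)
        assert prob.modality is Modality.PROBABILITY
        assert prob.shape == pet_n.shape
        assert prob.data.min() >= 0.0 and prob.data.max() <= 1.0
        assert prob.data[~pc.body].max() == 0.0

    def test_tiled_equals_dense_inference(self, model_and_case):
        model, pc = model_and_case
        pet_n, ct_n = self._norm_volumes(pc)
        dense = predict_probability(model, pet_n, ct_n)
        for tile in (9, 36):
            tiled = predict_probability(model, pet_n, ct_n, tile_size=tile)
            np.testing.assert_allclose(tiled.data, dense.data, atol=1e-4)

    def test_binarize_monotone_in_cut_point(self, model_and_case):
        model, pc = model_and_case
        pet_n, ct_n = self._norm_volumes(pc)
        prob = predict_probability(model, pet_n, ct_n, body=pc.body)
        sizes = [binarize(prob, c).sum() for c in np.linspace(0, 1, 6)]
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))
        assert binarize(prob, 0.0).sum() == np.prod(prob.shape)  # p >= 0 everywhere
        with pytest.raises(ValueError):
            binarize(prob, 1.5)

    def test_grid_mismatch_rejected(self, model_and_case):
        model, pc = model_and_case
        pet_n, ct_n = self._norm_volumes(pc)
        from petlymph import Volume

        small_ct = Volume(
            np.zeros((8, 8, 8), np.float32), spacing=ct_n.spacing, modality=Modality.CT_HU
        )
        with pytest.raises(ValueError):
            predict_probability(model, pet_n, small_ct)
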