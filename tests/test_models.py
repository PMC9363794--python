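"""Segmentation networks: shape contracts, architecture audit, training loop."""

import numpy as np
import pytest

from dfa_meter import nn
from dfa_meter.models import LOW_LEVEL_TAP, ModelConfig, build_model
from dfa_meter.nn import functional as F
from dfa_meter.training import (
    EpochRecord,
    TrainConfig,
    load_checkpoint,
    predict_mask,
    save_checkpoint,
    select_best_checkpoint,
    train_model,
)


@pytest.fixture(scope="module")
def desk_model():
    config = ModelConfig(
        architecture="deeplabv3plus", input_size=128, width_multiplier=0.25
    )
    return build_model(config, seed=0)


class TestArchitecture:
    def test_output_shape_contract(self, desk_model):
        x = nn.Tensor(np.zeros((1, 3, 128, 128), dtype=np.float32))
        assert desk_model(x).shape == (1, 3, 128, 128)

    @pytest.mark.parametrize("arch", ["unet", "pspnet"])
    def test_baseline_output_shapes(self, arch):
        config = ModelConfig(architecture=arch, input_size=64, width_multiplier=0.25)
        model = build_model(config, seed=1)
        x = nn.Tensor(np.zeros((1, 3, 64, 64), dtype=np.float32))
        assert model(x).shape == (1, 3, 64, 64)

    def test_width_multiplier_shrinks_model(self):
        full = build_model(ModelConfig(input_size=64, width_multiplier=1.0), 0)
        small = build_model(ModelConfig(input_size=64, width_multiplier=0.25), 0)
        assert small.num_parameters() < full.num_parameters()

    def test_encoder_has_17_bottlenecks_partitioned_1_2_14(self, desk_model):
        encoder = desk_model.encoder
        assert len(encoder.bottlenecks) == 17
        assert encoder.low_level_index == LOW_LEVEL_TAP == 3
        # partition around the tap: 3 before (1 then 2 at stride 4), 14 after
        assert len(encoder.bottlenecks) - encoder.low_level_index == 14
        # first stage is a single expansion-1 block, then two of the next stage
        assert encoder.bottlenecks[0].expand_ratio == 1
        assert encoder.bottlenecks[1].out_channels == encoder.bottlenecks[2].out_channels

    def test_residual_addition_iff_shapes_match(self, desk_model):
        for block in desk_model.encoder.bottlenecks:
            same_shape = block.stride == 1 and block.in_channels == block.out_channels
            assert block.use_residual == same_shape

    def test_residual_block_adds_input(self):
        rng = np.random.default_rng(0)
        from dfa_meter.models import InvertedResidual

        block = InvertedResidual(8, 8, rng, stride=1)
        assert block.use_residual
        block.eval()
        x = nn.Tensor(rng.normal(size=(1, 8, 6, 6)).astype(np.float32))
        path_only = block.path(x)
        np.testing.assert_allclose(
            block(x).data, x.data + path_only.data, rtol=1e-5, atol=1e-6
        )
        strided = InvertedResidual(8, 8, rng, stride=2)
        assert not strided.use_residual

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(input_size=100, output_stride=16)
        with pytest.raises(ValueError):
            ModelConfig(architecture="segnet")


@pytest.fixture(scope="module")
def smoke_history(desk_images, desk_masks):
    config = ModelConfig(
        architecture="deeplabv3plus", input_size=64, width_multiplier=0.25
    )
    model = build_model(config, seed=3)
    history = train_model(
        model,
        (desk_images[:8], desk_masks[:8]),
        (desk_images[8:10], desk_masks[8:10]),
        TrainConfig(learning_rate=2e-3, epochs=3, batch_size=4, seed=3),
    )
    return model, history


class TestTraining:

    def test_loss_decreases_over_smoke_run(self, smoke_history):
        _, history = smoke_history
        assert history[-1].train_loss < history[0].train_loss

    def test_history_length_matches_epochs(self, smoke_history):
        _, history = smoke_history
        assert [r.epoch for r in history] == [1, 2, 3]

    def test_perfect_prediction_loss_is_lower_than_all_background(self, desk_masks):
        y = desk_masks[:2]
        size = y.shape[1]
        onehot = np.full((2, 3, size, size), -10.0, dtype=np.float32)
        for c in range(3):
            onehot[:, c][y == c] = 10.0
        perfect = F.cross_entropy(nn.Tensor(onehot), y)
        background = np.zeros((2, 3, size, size), dtype=np.float32)
        background[:, 0] = 10.0
        all_bg = F.cross_entropy(nn.Tensor(background), y)
        assert float(perfect.data) < float(all_bg.data)

    def test_empty_dataset_rejected(self, desk_images, desk_masks):
        model = build_model(ModelConfig(input_size=64, width_multiplier=0.25), 0)
        with pytest.raises(ValueError):
            train_model(
                model,
                (desk_images[:0], desk_masks[:0]),
                (desk_images[:1], desk_masks[:1]),
                TrainConfig(epochs=1),
            )

    def test_predict_mask_contract(self, smoke_history, desk_images):
        model, _ = smoke_history
        mask = predict_mask(model, desk_images[0])
        assert mask.shape == (64, 64)
        assert set(np.unique(mask)) <= {0, 1, 2}

    def test_checkpoint_round_trip(self, smoke_history, desk_images, tmp_path):
        model, history = smoke_history
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, model, history[-1])
        loaded, meta = load_checkpoint(path)
        assert meta["epoch"] == 3
        np.testing.assert_array_equal(
            predict_mask(model, desk_images[0]), predict_mask(loaded, desk_images[0])
        )


class TestCheckpointSelection:
    @staticmethod
    def _history(losses):
        return [
            EpochRecord(epoch=i + 1, train_loss=0.0, val_loss=v)
            for i, v in enumerate(losses)
        ]

    def test_minimum_selected(self):
        assert select_best_checkpoint(self._history([0.9, 0.5, 0.7])).epoch == 2

    def test_tie_goes_to_earliest(self):
        assert select_best_checkpoint(self._history([0.5, 0.5])).epoch == 1

    def test_strictly_decreasing_selects_last(self):
        assert select_best_checkpoint(self._history([0.5, 0.4, 0.3])).epoch == 3

    def test_empty_history_rejected(self):
        with pytest.raises(ValueError):
            select_best_checkpoint([])

    def test_pure_function_of_history(self):
        h = self._history([0.6, 0.2, 0.4])
        assert select_best_checkpoint(h) is select_best_checkpoint(h)
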