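"""Detector components: attention, backbone, pyramid, fusion, OHEM, cascade."""

import numpy as np
import pytest

from _oracles import full_sort_ohem
from psyllidet.model import (
    AsppConfig,
    BackboneConfig,
    CascadeConfig,
    RoiBatch,
    build_cbam,
    build_fpn,
    build_improved_backbone,
    build_sawtooth_aspp,
    build_tiny_detector,
    cascade_total_loss,
    ohem_sample,
    validate_sawtooth_rates,
)
from psyllidet.nn import Tensor


class TestCBAM:
    def test_preserves_shape(self, rng):
        block = build_cbam(16, reduction=4, rng=rng)
        x = Tensor(rng.normal(size=(2, 16, 8, 8)))
        assert block(x).shape == (2, 16, 8, 8)

    def test_zero_input_maps_to_zero(self, rng):
        block = build_cbam(8, reduction=4, rng=rng)
        out = block(Tensor(np.zeros((1, 8, 4, 4))))
        np.testing.assert_array_equal(out.data, 0.0)

    def test_gates_lie_strictly_inside_unit_interval(self, rng):
        block = build_cbam(16, reduction=4, rng=rng)
        block(Tensor(rng.normal(size=(1, 16, 8, 8))))
        for gate in (block.last_channel_gate, block.last_spatial_gate):
            assert gate is not None
            assert (gate > 0).all() and (gate < 1).all()

    def test_forced_gates_make_block_identity(self, rng):
        block = build_cbam(8, reduction=4, rng=rng)
        block.force_gates_to_one = True
        x = Tensor(rng.normal(size=(1, 8, 6, 6)))
        np.testing.assert_array_equal(block(x).data, x.data)

    def test_indivisible_channels_rejected(self):
        with pytest.raises(ValueError, match="divisible"):
            build_cbam(10, reduction=4)


class TestBackbone:
    def test_tiny_backbone_resolution_contract(self, rng):
        bb = build_improved_backbone(BackboneConfig.make_tiny(), rng=rng)
        maps = bb(Tensor(rng.normal(size=(1, 3, 64, 64))))
        assert [m.shape[2] for m in maps] == [16, 8, 4, 2]
        assert [m.shape[1] for m in maps] == [8, 16, 32, 64]

    @pytest.mark.parametrize("size", [(64, 96), (32, 32)])
    def test_resolution_contract_other_sizes(self, rng, size):
        bb = build_improved_backbone(BackboneConfig.make_tiny(), rng=rng)
        h, w = size
        maps = bb(Tensor(rng.normal(size=(1, 3, h, w))))
        for i, m in enumerate(maps):
            assert m.shape[2:] == (h // 2 ** (i + 2), w // 2 ** (i + 2))

    def test_attention_inserted_at_exactly_five_sites(self, rng):
        bb = build_improved_backbone(BackboneConfig.make_tiny(), rng=rng)
        assert len(bb.attention_blocks()) == 5

    def test_disabling_attention_keeps_shapes_and_removes_blocks(self, rng):
        bb = build_improved_backbone(BackboneConfig.make_tiny(use_attention=False), rng=rng)
        assert len(bb.attention_blocks()) == 0
        maps = bb(Tensor(rng.normal(size=(1, 3, 64, 64))))
        assert [m.shape[2] for m in maps] == [16, 8, 4, 2]

    def test_indivisible_input_rejected(self, rng):
        bb = build_improved_backbone(BackboneConfig.make_tiny(), rng=rng)
        with pytest.raises(ValueError, match="divisible by 32"):
            bb(Tensor(rng.normal(size=(1, 3, 50, 64))))


class TestSawtoothAspp:
    def test_default_rates_give_four_parallel_paths(self, rng):
        mod = build_sawtooth_aspp(AsppConfig(channels=8), rng=rng)
        assert mod.n_paths == 4  # three dilated + one pointwise

    def test_spatial_dims_preserved(self, rng):
        mod = build_sawtooth_aspp(AsppConfig(channels=8), rng=rng)
        out = mod(Tensor(rng.normal(size=(1, 8, 16, 16))))
        assert out.shape == (1, 8, 16, 16)

    def test_validator_accepts_sawtooth_and_rejects_gridding(self):
        validate_sawtooth_rates((1, 2, 5))
        with pytest.raises(ValueError, match="common divisor"):
            validate_sawtooth_rates((2, 4, 8))
        with pytest.raises(ValueError, match=">= 1"):
            validate_sawtooth_rates((0, 1, 2))
        with pytest.raises(ValueError, match="increasing"):
            validate_sawtooth_rates((1, 5, 2))


class TestFPN:
    def test_four_in_four_out_uniform_channels(self, rng):
        fpn = build_fpn([8, 16, 32, 64], out_channels=12, rng=rng)
        ins = [Tensor(rng.normal(size=(1, c, 16 // 2**i, 16 // 2**i)))
               for i, c in enumerate([8, 16, 32, 64])]
        outs = fpn(ins)
        assert len(outs) == 4
        assert all(o.shape[1] == 12 for o in outs)
        assert [o.shape[2] for o in outs] == [16, 8, 4, 2]

    def test_zero_inputs_give_zero_outputs(self, rng):
        fpn = build_fpn([4, 4, 4, 4], out_channels=4, rng=rng)
        for lat in fpn.laterals:
            lat.bias.data[:] = 0.0
        ins = [Tensor(np.zeros((1, 4, 16 // 2**i, 16 // 2**i))) for i in range(4)]
        for o in fpn(ins):
            np.testing.assert_array_equal(o.data, 0.0)

    def test_impulse_at_coarsest_level_reaches_all_finer_levels(self, rng):
        fpn = build_fpn([1, 1, 1, 1], out_channels=1, rng=rng)
        for lat in fpn.laterals:
            lat.weight.data[:] = 0.0
            lat.bias.data[:] = 0.0
        fpn.laterals[3].weight.data[0, 0, 0, 0] = 1.0  # identity on the coarsest
        ins = [Tensor(np.zeros((1, 1, 16 // 2**i, 16 // 2**i))) for i in range(4)]
        ins[3].data[0, 0, 1, 1] = 1.0  # unit impulse
        outs = fpn(ins)
        # the impulse appears in every level, upsampled nearest-neighbour
        for lvl, o in enumerate(outs):
            scale = 2 ** (3 - lvl)
            region = o.data[0, 0, scale : 2 * scale, scale : 2 * scale]
            np.testing.assert_array_equal(region, 1.0)
            assert o.data.sum() == scale * scale

    def test_wrong_branch_count_rejected(self, rng):
        with pytest.raises(ValueError, match="4"):
            build_fpn([8, 16, 32], rng=rng)
        fpn = build_fpn([4, 4, 4, 4], rng=rng)
        with pytest.raises(ValueError):
            fpn([Tensor(np.zeros((1, 4, 8, 8)))])


class TestOhem:
    def test_caps_hit_exactly_when_candidates_exceed_them(self, rng):
        losses = rng.permutation(400).astype(float)
        positive = np.zeros(400, dtype=bool)
        positive[:120] = True  # 120 positives, 280 negatives: both exceed caps
        batch = RoiBatch(losses=losses, positive=positive, indices=np.arange(400))
        pos, neg = ohem_sample(batch)
        assert len(pos) == 64 and len(neg) == 192
        # selected positives are exactly the 64 largest positive losses
        top = np.sort(losses[:120])[::-1][:64]
        assert set(losses[pos]) == set(top)
        top_neg = np.sort(losses[120:])[::-1][:192]
        assert set(losses[neg]) == set(top_neg)

    def test_under_cap_returns_everything(self, rng):
        losses = rng.random(40)
        positive = np.zeros(40, dtype=bool)
        positive[:30] = True
        pos, neg = ohem_sample(RoiBatch(losses, positive, np.arange(40)))
        assert len(pos) == 30 and len(neg) == 10

    def test_matches_full_sort_oracle_on_random_batches(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 500))
            losses = np.round(rng.random(n), 2)  # rounding forces ties
            positive = rng.random(n) < 0.3
            indices = rng.permutation(n * 2)[:n]
            batch = RoiBatch(losses, positive, indices)
            n_pos = int(rng.integers(0, 80))
            n_neg = int(rng.integers(0, 250))
            pos, neg = ohem_sample(batch, n_pos, n_neg)
            o_pos, o_neg = full_sort_ohem(losses, positive, indices, n_pos, n_neg)
            assert list(pos) == o_pos
            assert list(neg) == o_neg

    def test_non_finite_losses_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            RoiBatch(np.array([1.0, np.inf]), np.array([True, False]), np.arange(2))


class TestCascadeLoss:
    @pytest.mark.parametrize(
        "losses, expected", [((0, 0, 0), 0.0), ((1, 1, 1), 1.75), ((2, 4, 8), 6.0)]
    )
    def test_weighted_sum_examples(self, losses, expected):
        assert cascade_total_loss(losses) == pytest.approx(expected)

    def test_linearity_in_each_stage(self, rng):
        base = rng.random(3)
        w = (1.0, 0.5, 0.25)
        for i in range(3):
            bumped = base.copy()
            bumped[i] += 1.0
            assert cascade_total_loss(bumped, w) - cascade_total_loss(base, w) == pytest.approx(w[i])

    def test_negative_loss_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            cascade_total_loss((1.0, -0.5, 0.2))

    def test_config_validation(self):
        with pytest.raises(ValueError):
            CascadeConfig(stage_iou_thresholds=(0.7, 0.6, 0.5))
        with pytest.raises(ValueError):
            CascadeConfig(stage_loss_weights=(1.0, 0.0, 0.25))


@pytest.fixture(scope="module")
def tiny():
    return build_tiny_detector(seed=0)


@pytest.fixture(scope="module")
def scene():
    from psyllidet.synthetic import SceneConfig, generate_scene

    return generate_scene(
        SceneConfig(width=128, height=128, coverage=0.7, n_psyllids=3, n_flies=1,
                    psyllid_size=(5, 10), fly_size=(10, 18), seed=13)
    )


class TestDetector:

    def test_forward_returns_in_bounds_scored_boxes(self, tiny, scene):
        image, _, _ = scene
        dets = tiny.detect(image)
        for d in dets:
            assert 0 <= d.x0 < d.x1 <= 128
            assert 0 <= d.y0 < d.y1 <= 128
            assert 0.0 <= d.score <= 1.0
            assert d.class_id in (0, 1)

    def test_ohem_selection_matches_standalone_sampler(self, scene):
        image, _, anns = scene
        det_on = build_tiny_detector(seed=0, use_ohem=True)
        det_off = build_tiny_detector(seed=0, use_ohem=False)
        rng = np.random.default_rng(7)
        det_on.compute_losses(image, anns, np.random.default_rng(7))
        det_off.compute_losses(image, anns, np.random.default_rng(7))
        for stage in range(3):
            batch = det_on.last_roi_batches[stage]
            pos, neg = ohem_sample(batch, det_on.config.ohem_n_pos, det_on.config.ohem_n_neg)
            predicted = np.sort(np.concatenate([pos, neg]))
            np.testing.assert_array_equal(det_on.last_selected_rois[stage], predicted)
            # without mining, every ROI trains
            assert len(det_off.last_selected_rois[stage]) == len(det_off.last_roi_batches[stage].losses)

    def test_mismatched_component_widths_rejected(self, rng):
        from psyllidet.model import assemble_detector, build_fpn, build_improved_backbone

        bcfg = BackboneConfig.make_tiny()
        backbone = build_improved_backbone(bcfg, rng=rng)
        aspps = [build_sawtooth_aspp(AsppConfig(channels=4), rng=rng) for _ in range(4)]
        fpn = build_fpn(bcfg.widths, rng=rng)
        with pytest.raises(ValueError, match="width"):
            assemble_detector(backbone, aspps, fpn, CascadeConfig())
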