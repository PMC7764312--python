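import numpy as np
import pytest

from sauseg.inference import (PatchPlan, PipelineConfig, fuse_or_logical,
                              plan_patches, predict_patches, segment_volume,
                              to_native_space)
from sauseg.io_schema import LabelSchema, LabelVolume, SchemaEntry, Volume3D
from sauseg.metrics import StructureMask, dice
from sauseg.network import NetworkConfig
from sauseg.phantom import PhantomSpec, TissueSpec, make_phantom
from sauseg.preprocess import RigidTransform, resample_to_grid
from sauseg.training import Checkpoint, TrainConfig, run_stage


@pytest.fixture
def schema():
    return LabelSchema([SchemaEntry(0, "background"), SchemaEntry(1, "a"),
                        SchemaEntry(2, "b"), SchemaEntry(3, "c")])


def one_hot_probs(labels, n_classes):
    probs = np.zeros((n_classes,) + labels.shape, dtype=np.float32)
    gi, gj, gk = np.ogrid[[slice(0, s) for s in labels.shape]]
    probs[labels, gi, gj, gk] = 1.0
    return probs


class TestPlanPatches:
    def test_single_patch_when_sizes_match(self):
        plan = plan_patches((32, 32, 32), (32, 32, 32), (4, 4, 4))
        assert plan.origins == [(0, 0, 0)]

    def test_grid_304_with_96_patches_12_overlap(self):
        """stride 84, 4 origins per axis (last clamped), 64 patches, covered."""
        plan = plan_patches((304, 304, 304), (96, 96, 96), (12, 12, 12),
                            mode="grid")
        per_axis = sorted({o[0] for o in plan.origins})
        assert per_axis == [0, 84, 168, 208]
        assert len(plan) == 64
        assert bool(np.all(plan.coverage_count() > 0))

    def test_random_mode_has_128_patches_plus_repair(self):
        plan = plan_patches((128, 128, 128), (32, 32, 32), (12, 12, 12),
                            mode="random", n_patches=128, seed=0)
        assert len(plan) >= 128
        assert bool(np.all(plan.coverage_count() > 0))

    def test_patch_larger_than_volume(self):
        with pytest.raises(ValueError):
            plan_patches((16, 16, 16), (32, 32, 32), (4, 4, 4))

    def test_coverage_enforced_at_construction(self, schema):
        with pytest.raises(ValueError):
            PatchPlan((8, 8, 8), [(0, 0, 0)], (32, 32, 32))

    def test_origin_bounds_enforced(self):
        with pytest.raises(ValueError):
            PatchPlan((8, 8, 8), [(30, 0, 0)], (32, 32, 32))


class TestPredictPatches:
    @pytest.fixture
    def trained(self):
        spec = PhantomSpec((32, 32, 32),
                           [TissueSpec(1, (15.5, 15.5, 15.5), (10, 10, 10), 100.0)],
                           noise_sd=1.0, seed=0)
        data = [make_phantom(spec)]
        cfg = TrainConfig(stage="pretrain", iterations=2, batch_size=1,
                          patch_size=(16, 16, 16),
                          network=NetworkConfig.desk(n_classes=2), seed=0)
        ckpt, _ = run_stage(cfg, data)
        return ckpt, data[0][0]

    def test_single_patch_shape(self, trained):
        ckpt, vol = trained
        plan = plan_patches(vol.shape, (32, 32, 32), (4, 4, 4))
        out = predict_patches(ckpt, vol, plan)
        assert len(out) == 1
        assert out[0].shape == (2, 32, 32, 32)

    def test_set_semantics_order_independent(self, trained):
        ckpt, vol = trained
        plan = plan_patches(vol.shape, (16, 16, 16), (4, 4, 4))
        out = predict_patches(ckpt, vol, plan)
        reversed_plan = PatchPlan(plan.patch_size, plan.origins[::-1],
                                  plan.volume_shape, plan.mode, plan.overlap)
        out_rev = predict_patches(ckpt, vol, reversed_plan)
        for a, b in zip(out, out_rev[::-1]):
            np.testing.assert_array_equal(a, b)

    def test_deterministic(self, trained):
        ckpt, vol = trained
        plan = plan_patches(vol.shape, (16, 16, 16), (4, 4, 4))
        a = predict_patches(ckpt, vol, plan)
        b = predict_patches(ckpt, vol, plan)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x, y)

    def test_shape_mismatch(self, trained):
        ckpt, vol = trained
        plan = plan_patches((64, 64, 64), (32, 32, 32), (4, 4, 4))
        with pytest.raises(ValueError):
            predict_patches(ckpt, vol, plan)


class TestFuseOrLogical:
    def test_single_patch_identity(self, schema, rng):
        labels = rng.integers(0, 4, size=(16, 16, 16))
        probs = one_hot_probs(labels, 4)
        plan = PatchPlan((16, 16, 16), [(0, 0, 0)], (16, 16, 16))
        fused = fuse_or_logical([probs], plan, schema)
        np.testing.assert_array_equal(fused.data, labels)

    def test_agreeing_patches_preserved(self, schema, rng):
        labels = rng.integers(0, 4, size=(24, 16, 16))
        plan = PatchPlan((16, 16, 16), [(0, 0, 0), (8, 0, 0)], (24, 16, 16))
        probs = [one_hot_probs(labels[:16], 4), one_hot_probs(labels[8:], 4)]
        fused = fuse_or_logical(probs, plan, schema)
        np.testing.assert_array_equal(fused.data, labels)

    def test_background_loses_to_label(self, schema):
        """Overlap voxel: patch A background p=0.9, patch B label 3 p=0.6."""
        shape = (8, 8, 12)
        plan = PatchPlan((8, 8, 8), [(0, 0, 0), (0, 0, 4)], shape)
        pa = np.zeros((4, 8, 8, 8), dtype=np.float32)
        pa[0] = 0.9
        pa[1] = 0.1 / 3
        pa[2] = 0.1 / 3
        pa[3] = 0.1 / 3
        pb = np.zeros((4, 8, 8, 8), dtype=np.float32)
        pb[3] = 0.6
        pb[0] = 0.4 / 3
        pb[1] = 0.4 / 3
        pb[2] = 0.4 / 3
        fused = fuse_or_logical([pa, pb], plan, schema)
        # overlap region z in [4, 8): non-background claim wins
        assert np.all(fused.data[:, :, 4:8] == 3)
        assert np.all(fused.data[:, :, :4] == 0)
        assert np.all(fused.data[:, :, 8:] == 3)

    def test_conflict_resolved_by_summed_probability(self, schema):
        shape = (8, 8, 12)
        plan = PatchPlan((8, 8, 8), [(0, 0, 0), (0, 0, 4)], shape)
        pa = np.zeros((4, 8, 8, 8), dtype=np.float32)
        pa[1] = 0.8
        pa[2] = 0.2
        pb = np.zeros((4, 8, 8, 8), dtype=np.float32)
        pb[2] = 0.9
        pb[1] = 0.1
        fused = fuse_or_logical([pa, pb], plan, schema)
        # overlap: label 1 has 0.8, label 2 has 0.9 -> 2 wins
        assert np.all(fused.data[:, :, 4:8] == 2)
        assert np.all(fused.data[:, :, :4] == 1)
        assert np.all(fused.data[:, :, 8:] == 2)

    def test_tie_breaks_to_smallest_id(self, schema):
        shape = (4, 4, 6)
        plan = PatchPlan((4, 4, 4), [(0, 0, 0), (0, 0, 2)], shape)
        pa = np.zeros((4, 4, 4, 4), dtype=np.float32)
        pa[3] = 1.0
        pb = np.zeros((4, 4, 4, 4), dtype=np.float32)
        pb[1] = 1.0
        fused = fuse_or_logical([pa, pb], plan, schema)
        # overlap: labels 1 and 3 both sum to 1.0 -> smallest id wins
        assert np.all(fused.data[:, :, 2:4] == 1)

    def test_permutation_invariant(self, schema, rng):
        shape = (20, 16, 16)
        plan = plan_patches(shape, (16, 16, 16), (12, 12, 12))
        probs = [rng.random((4, 16, 16, 16)).astype(np.float32)
                 for _ in plan.origins]
        fused_a = fuse_or_logical(probs, plan, schema)
        perm = np.arange(len(plan.origins))[::-1]
        plan_b = PatchPlan(plan.patch_size, [plan.origins[i] for i in perm],
                           shape, plan.mode, plan.overlap)
        fused_b = fuse_or_logical([probs[i] for i in perm], plan_b, schema)
        np.testing.assert_array_equal(fused_a.data, fused_b.data)

    def test_idempotent_single_source(self, schema, rng):
        labels = rng.integers(0, 4, size=(8, 8, 8))
        plan = PatchPlan((8, 8, 8), [(0, 0, 0)], (8, 8, 8))
        fused = fuse_or_logical([one_hot_probs(labels, 4)], plan, schema)
        refused = fuse_or_logical([one_hot_probs(fused.data, 4)], plan, schema)
        np.testing.assert_array_equal(refused.data, fused.data)

    def test_uncovered_voxel_error(self, schema, rng):
        probs = [one_hot_probs(rng.integers(0, 4, (8, 8, 8)), 4)]
        plan = PatchPlan((8, 8, 8), [(0, 0, 0)], (8, 8, 8))
        bad = [probs[0][:, :4]]
        with pytest.raises(ValueError):
            fuse_or_logical(bad, plan, schema)


class TestToNativeSpace:
    def test_identity_unchanged(self, schema, rng):
        lv = LabelVolume(rng.integers(0, 4, (16, 16, 16)).astype(np.int32),
                         schema)
        native = Volume3D(np.zeros((16, 16, 16)))
        out = to_native_space(lv, RigidTransform(), native)
        np.testing.assert_array_equal(out.data, lv.data)

    def test_no_new_labels(self, schema, rng):
        lv = LabelVolume(rng.integers(0, 4, (16, 16, 16)).astype(np.int32),
                         schema)
        native = Volume3D(np.zeros((16, 16, 16)))
        t = RigidTransform((4.0, 2.0, -3.0), (1.0, 0.0, 0.0), (8.0, 8.0, 8.0))
        out = to_native_space(lv, t, native)
        assert set(np.unique(out.data)) <= set(np.unique(lv.data))

    def test_missing_transform(self, schema):
        lv = LabelVolume(np.zeros((8, 8, 8), dtype=np.int32), schema)
        with pytest.raises(ValueError):
            to_native_space(lv, None, Volume3D(np.zeros((8, 8, 8))))

    def test_round_trip_rotation_dice(self):
        """native -> template (5 deg) -> native keeps Dice >= 0.9 per structure."""
        spec = PhantomSpec((48, 48, 48), [
            TissueSpec(1, (17.0, 23.5, 23.5), (8, 8, 8), 1.0),
            TissueSpec(2, (33.0, 23.5, 23.5), (7, 9, 7), 1.0),
        ])
        _, lv = make_phantom(spec)
        center = tuple((np.asarray(lv.shape) - 1) / 2.0)
        fwd = RigidTransform((5.0, 0.0, 0.0), center_mm=center)
        native = Volume3D(np.zeros(lv.shape))
        # forward: resample native labels into template space under fwd
        as_vol = Volume3D(lv.data.astype(np.float64), lv.spacing, lv.affine)
        template_labels = resample_to_grid(as_vol, native, fwd, order=0)
        tl = LabelVolume(np.rint(template_labels.data).astype(np.int32),
                         lv.schema, lv.spacing, lv.affine)
        back = to_native_space(tl, fwd, native)
        for label in (1, 2):
            d = dice(StructureMask(back.data == label),
                     StructureMask(lv.data == label))
            assert d >= 0.9


@pytest.fixture(scope="module")
def trained_pipeline():
    spec = PhantomSpec((32, 32, 32),
                       [TissueSpec(1, (15.5, 15.5, 15.5), (10, 10, 10), 100.0)],
                       noise_sd=1.0, seed=0)
    data = [make_phantom(spec)]
    cfg = TrainConfig(stage="pretrain", iterations=40, batch_size=2,
                      patch_size=(16, 16, 16),
                      network=NetworkConfig.desk(n_classes=2), seed=0)
    ckpt, _ = run_stage(cfg, data)
    return ckpt, data[0]


class TestSegmentVolume:
    def test_end_to_end_native_grid_and_schema(self, trained_pipeline):
        ckpt, (vol, lv) = trained_pipeline
        cfg = PipelineConfig(schema=lv.schema, pad=(8, 8, 8),
                             patch_size=(16, 16, 16), overlap=(4, 4, 4))
        out = segment_volume(ckpt, vol, cfg)
        assert out.shape == vol.shape
        assert out.schema is lv.schema

    def test_deterministic(self, trained_pipeline):
        ckpt, (vol, _) = trained_pipeline
        cfg = PipelineConfig(schema=trained_pipeline[1][1].schema,
                             pad=(8, 8, 8), patch_size=(16, 16, 16),
                             overlap=(4, 4, 4), mode="random", n_patches=8,
                             seed=11)
        a = segment_volume(ckpt, vol, cfg)
        b = segment_volume(ckpt, vol, cfg)
        np.testing.assert_array_equal(a.data, b.data)

    def test_schema_checkpoint_mismatch(self, trained_pipeline, schema):
        ckpt, (vol, _) = trained_pipeline
        cfg = PipelineConfig(schema=schema, pad=(8, 8, 8),
                             patch_size=(16, 16, 16), overlap=(4, 4, 4))
        with pytest.raises(ValueError):
            segment_volume(ckpt, vol, cfg)
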