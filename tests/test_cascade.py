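"""ROI logic, mask re-embedding, and pipeline contracts."""

import numpy as np
import pytest

from coroseg.cascade import (
    PipelineConfig,
    PipelineError,
    ROIBox,
    embed_mask,
    extract_roi,
    run_pipeline,
    segment_coronaries,
    segment_heart,
)
from coroseg.phantoms import PhantomSpec, make_cardiac_phantom
from coroseg.preprocess import minmax_normalize
from coroseg.resdense_unet import NetworkSpec, build_network, save_checkpoint
from coroseg.volume import Mask, Volume, write_volume


@pytest.fixture(scope="module")
def phantom():
    vol, heart, vessel = make_cardiac_phantom(PhantomSpec(size=32, seed=4,
                                                          heart_center=(16, 16, 16),
                                                          heart_axes=(11, 12, 12)))
    return minmax_normalize(vol), heart, vessel


@pytest.fixture(scope="module")
def toy_model():
    return build_network(NetworkSpec(n_levels=3, base_channels=4), seed=0)


class TestExtractRoi:
    def test_margin_applied_to_tight_bounds(self):
        mask_data = np.zeros((64, 64, 64), dtype=np.uint8)
        mask_data[10:50, 10:50, 10:50] = 1
        vol = Volume(data=np.zeros((64, 64, 64)))
        crop, box = extract_roi(vol, Mask(data=mask_data), margin=8)
        assert box.bounds == ((2, 58),) * 3
        assert crop.shape == (56, 56, 56)

    def test_bounds_clipped_at_grid_edge(self):
        mask_data = np.zeros((32, 32, 32), dtype=np.uint8)
        mask_data[0:5, 2:8, 2:8] = 1
        vol = Volume(data=np.zeros((32, 32, 32)))
        _, box = extract_roi(vol, Mask(data=mask_data), margin=8)
        assert box.bounds[0][0] == 0

    def test_full_mask_gives_full_volume(self, rng):
        vol = Volume(data=rng.random((16, 16, 16)))
        crop, box = extract_roi(vol, Mask(data=np.ones((16, 16, 16), np.uint8)), 4)
        assert crop.shape == vol.shape
        assert box.bounds == ((0, 16),) * 3

    def test_empty_mask_rejected(self, rng):
        vol = Volume(data=rng.random((8, 8, 8)))
        with pytest.raises(ValueError, match="empty"):
            extract_roi(vol, Mask(data=np.zeros((8, 8, 8), np.uint8)), 4)

    def test_crop_reduces_voxel_count(self, phantom):
        pre, heart, _ = phantom
        crop, _ = extract_roi(pre, heart, margin=2)
        assert np.prod(crop.shape) < np.prod(pre.shape)


class TestEmbedMask:
    def test_embed_inverts_crop(self, rng):
        full = Mask(data=(rng.random((20, 20, 20)) > 0.8).astype(np.uint8))
        # a box containing all the foreground
        box = ROIBox(((0, 20), (0, 20), (0, 20)), margin=0, source_shape=(20, 20, 20))
        crop = Mask(data=full.data[box.slices].copy())
        back = embed_mask(crop, box, (20, 20, 20))
        np.testing.assert_array_equal(back.data, full.data)

    def test_foreground_conserved_and_outside_zero(self, rng):
        roi = Mask(data=(rng.random((5, 6, 7)) > 0.5).astype(np.uint8))
        box = ROIBox(((2, 7), (3, 9), (1, 8)), margin=0, source_shape=(12, 12, 12))
        out = embed_mask(roi, box, (12, 12, 12))
        assert out.data.sum() == roi.data.sum()
        outside = np.ones((12, 12, 12), dtype=bool)
        outside[box.slices] = False
        assert out.data[outside].sum() == 0

    def test_shape_mismatch_rejected(self):
        roi = Mask(data=np.zeros((3, 3, 3), np.uint8))
        box = ROIBox(((0, 4), (0, 4), (0, 4)), margin=0, source_shape=(8, 8, 8))
        with pytest.raises(ValueError, match="match"):
            embed_mask(roi, box, (8, 8, 8))

    def test_invalid_box_rejected(self):
        with pytest.raises(ValueError):
            ROIBox(((4, 2), (0, 4), (0, 4)), margin=0, source_shape=(8, 8, 8))


class TestSegmentHeart:
    def test_returns_binary_volume_shaped_mask(self, phantom, toy_model):
        pre, _, _ = phantom
        out = segment_heart(pre, toy_model, input_size=32)
        assert out.shape == pre.shape
        assert set(np.unique(out.data)) <= {0, 1}

    def test_largest_component_kept(self):
        from coroseg.cascade import _largest_component

        blob = np.zeros((16, 16, 16), dtype=np.uint8)
        blob[2:10, 2:10, 2:10] = 1  # large
        blob[13:15, 13:15, 13:15] = 1  # small
        out = _largest_component(blob)
        assert out[3, 3, 3] == 1 and out[14, 14, 14] == 0


class TestSegmentCoronaries:
    def test_output_binary_and_roi_shaped(self, phantom, toy_model):
        pre, heart, _ = phantom
        roi, _ = extract_roi(pre, heart, margin=2)
        out = segment_coronaries(
            roi, toy_model, use_vesselness=True, input_size=32
        )
        assert out.shape == roi.shape
        assert set(np.unique(out.data)) <= {0, 1}

    def test_weight_zero_matches_no_vesselness_path(self, phantom, toy_model):
        """The vesselness-weight-0 path is bit-identical to the ablation."""
        pre, heart, _ = phantom
        roi, _ = extract_roi(pre, heart, margin=2)
        a = segment_coronaries(
            roi, toy_model, use_vesselness=True, vessel_weight=0.0, input_size=32
        )
        b = segment_coronaries(
            roi, toy_model, use_vesselness=False, input_size=32
        )
        np.testing.assert_array_equal(a.data, b.data)


class TestRunPipeline:
    @pytest.fixture()
    def artifacts(self, tmp_path, phantom, toy_model):
        pre, heart, vessel = phantom
        ct = tmp_path / "ct.nii.gz"
        write_volume(pre, ct)
        truth = tmp_path / "truth.nii.gz"
        write_volume(vessel, truth)
        hckpt = str(tmp_path / "heart.npz")
        cckpt = str(tmp_path / "coronary.npz")
        save_checkpoint(toy_model, hckpt)
        save_checkpoint(toy_model, cckpt)
        return ct, truth, hckpt, cckpt

    def test_end_to_end_writes_binary_mask_on_input_grid(
        self, tmp_path, artifacts
    ):
        ct, truth, hckpt, cckpt = artifacts
        out = tmp_path / "mask.nii.gz"
        config = PipelineConfig(
            ced=None,
            heart_input_size=32,
            coronary_input_size=32,
        )
        report = run_pipeline(str(ct), hckpt, cckpt, str(out), config,
                              truth_path=str(truth))
        from coroseg.volume import read_volume

        assert out.exists()
        mask = read_volume(out)
        assert mask.shape == (32, 32, 32)
        assert set(np.unique(mask.data)) <= {0, 1}
        assert "metrics" in report and "dsc" in report["metrics"]
        assert set(report["stages"]) >= {
            "read", "preprocess", "segment_heart", "extract_roi",
            "segment_coronaries", "embed_mask", "write",
        }

    def test_missing_checkpoint_fails_at_startup(self, tmp_path, artifacts):
        ct, _, hckpt, _ = artifacts
        with pytest.raises(PipelineError, match="startup"):
            run_pipeline(
                str(ct), hckpt, str(tmp_path / "nope.npz"), str(tmp_path / "o.nii.gz")
            )
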