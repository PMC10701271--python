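import numpy as np
import pytest

from srsplan.grid import PlanCase, VoxelGrid
from srsplan.preprocess import (
    NormalizationSpec,
    STRUCTURE_LABELS,
    align_case,
    assign_group,
    crop_to_shape,
    decode_structures,
    denormalize_dose,
    encode_structures,
    normalize_ct,
    normalize_dose,
    restore_dose,
)


class TestNormalization:
    @pytest.mark.parametrize(
        "hu,expected",
        [(-500.0, -1.0), (-200.0, -1.0), (300.0, 1.0), (1000.0, 1.0), (50.0, 0.0), (-200.0 + 250.0, 0.0)],
    )
    def test_ct_affine_map(self, hu, expected):
        assert normalize_ct(np.array([[[hu]]]))[0, 0, 0] == pytest.approx(expected)

    def test_ct_monotone(self):
        x = np.linspace(-400, 500, 101).reshape(1, 1, -1)
        y = normalize_ct(x)
        assert np.all(np.diff(y.ravel()) >= 0)
        assert y.min() == -1.0 and y.max() == 1.0

    @pytest.mark.parametrize("dose,expected", [(0.0, -1.0), (42.0, 1.0), (21.0, 0.0)])
    def test_dose_endpoints(self, dose, expected):
        assert normalize_dose(np.array([[[dose]]]))[0, 0, 0] == pytest.approx(expected)

    def test_dose_round_trip(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(0, 42.0, size=(6, 6, 6))
        spec = NormalizationSpec()
        back = denormalize_dose(normalize_dose(d, spec), spec)
        assert np.max(np.abs(back - d)) < 1e-6 * spec.dose_ref_max

    def test_dose_above_ceiling_warns_and_clips(self):
        with pytest.warns(UserWarning):
            y = normalize_dose(np.array([[[50.0]]]))
        assert y[0, 0, 0] == pytest.approx(1.0)

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            normalize_dose(np.array([[[-1.0]]]))


class TestStructureEncoding:
    def test_round_trip_recovers_priority_resolved_masks(self, bare_case):
        label = encode_structures(bare_case.structures)
        masks = decode_structures(label)
        # overlaps resolve to the higher code, PGTV highest
        assert np.array_equal(masks["pgtv"], bare_case.pgtv.data.astype(bool))
        order = sorted(STRUCTURE_LABELS, key=STRUCTURE_LABELS.get)
        for i, name in enumerate(order):
            if name == "pgtv" or name not in bare_case.structures:
                continue
            expected = bare_case.structures[name].data.astype(bool).copy()
            for higher in order[i + 1 :]:
                if higher in bare_case.structures:
                    expected &= ~bare_case.structures[higher].data.astype(bool)
            got = masks.get(name, np.zeros_like(expected))
            assert np.array_equal(got, expected), name

    def test_pgtv_highest_priority(self):
        a = np.zeros((2, 2, 2), dtype=bool)
        a[0, 0, 0] = True
        label = encode_structures({"pgtv": a, "brainstem": a})
        assert label[0, 0, 0] == STRUCTURE_LABELS["pgtv"]


class TestAlign:
    def test_identity_is_voxel_exact(self, bare_case):
        aligned = align_case(bare_case)
        for name in bare_case.structures:
            assert np.array_equal(
                aligned.structures[name].data, bare_case.structures[name].data
            )

    def test_one_voxel_shift_realigns(self):
        rng = np.random.default_rng(1)
        ct = VoxelGrid(rng.normal(size=(12, 12, 12)), origin=(0, 0, 0), spacing=(2, 2, 2))
        dose_data = rng.uniform(0, 30, size=(12, 12, 12))
        shifted = VoxelGrid(dose_data, origin=(2, 0, 0), spacing=(2, 2, 2))
        pgtv = VoxelGrid(np.ones((12, 12, 12), np.uint8), origin=(0, 0, 0), spacing=(2, 2, 2))
        case = PlanCase(ct=ct, structures={"pgtv": pgtv, "head": pgtv}, reference_dose=shifted)
        aligned = align_case(case)
        # CT voxel i samples shifted-grid voxel i-1 along x
        assert np.allclose(aligned.reference_dose.data[1:, :, :], dose_data[:-1, :, :])

    def test_mask_resample_round_trip_dsc(self, sphere_grid):
        grid, mask = sphere_grid
        fine = VoxelGrid(np.zeros((48, 48, 48)), origin=(grid.origin[0] - 0.625,) * 3,
                         spacing=(1.25, 1.25, 1.25))
        case_up = PlanCase(ct=fine, structures={"pgtv": mask, "head": mask})
        up = align_case(case_up).structures["pgtv"]
        case_down = PlanCase(ct=grid, structures={"pgtv": up, "head": up})
        back = align_case(case_down).structures["pgtv"].data.astype(bool)
        orig = mask.data.astype(bool)
        dsc = 2 * (back & orig).sum() / (back.sum() + orig.sum())
        assert dsc >= 0.95

    def test_disjoint_grids_error(self):
        ct = VoxelGrid(np.zeros((8, 8, 8)), origin=(0, 0, 0))
        far = VoxelGrid(np.ones((8, 8, 8)), origin=(1000, 1000, 1000))
        case = PlanCase(ct=ct, structures={"pgtv": far, "head": far}, reference_dose=far)
        with pytest.raises(ValueError, match="overlap"):
            align_case(case)


class TestCrop:
    def test_window_shape_and_range(self, ref_case):
        tc = crop_to_shape(ref_case, shape=(64, 64, 32))
        assert tc.inputs.shape == (2, 64, 64, 32)
        assert tc.target.shape == (64, 64, 32)
        assert tc.inputs.min() >= -1.0 and tc.inputs.max() <= 1.0
        assert tc.target.min() >= -1.0 and tc.target.max() <= 1.0

    def test_corner_target_padded_not_raised(self, bare_case):
        # window larger than the volume forces padding on every side
        tc = crop_to_shape(bare_case, shape=(128, 128, 64))
        label = tc.inputs[0]
        assert (label > label.min()).any()  # PGTV present inside the window

    def test_restore_round_trip(self, ref_case):
        tc = crop_to_shape(ref_case, shape=(64, 64, 32))
        restored = restore_dose(tc.target, tc.meta)
        assert restored.same_geometry(ref_case.ct)
        offset = np.asarray(tc.meta["crop_offset"])
        lo = np.maximum(offset, 0)
        hi = np.minimum(offset + np.asarray([64, 64, 32]), ref_case.ct.shape)
        win = tuple(slice(a, b) for a, b in zip(lo, hi))
        ref = ref_case.reference_dose.data
        clipped = np.minimum(ref, tc.meta["dose_ref_max"])
        assert np.allclose(restored.data[win], clipped[win], atol=1e-5)

    def test_empty_pgtv_rejected(self, bare_case):
        case = PlanCase(
            ct=bare_case.ct,
            structures={**bare_case.structures, "pgtv": bare_case.ct.copy(np.zeros(bare_case.ct.shape))},
        )
        with pytest.raises(ValueError, match="PGTV"):
            crop_to_shape(case)


class TestGrouping:
    def _case_with_n_voxels(self, n: int) -> PlanCase:
        ct = VoxelGrid(np.zeros((20, 20, 20)), spacing=(2.5, 2.5, 2.5))
        mask = np.zeros((20, 20, 20), np.uint8)
        mask.ravel()[:n] = 1
        return PlanCase(ct=ct, structures={"pgtv": ct.copy(mask), "head": ct.copy(mask)})

    def test_exactly_20cc_is_small(self):
        # 2.5 mm voxels: 15.625 mm^3 each; 1280 voxels = exactly 20 cc
        assert assign_group(self._case_with_n_voxels(1280)) == "small"
        assert assign_group(self._case_with_n_voxels(1281)) == "large"

    def test_examples(self, bare_case):
        assert assign_group(bare_case) == bare_case.size_group
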