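"""SvO2 grid procedure: alignment, partition, Eq-based SvO2, hypoxic mask."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from conftest import noise_free_config
from perfrad.svo2 import (
    SvO2Params,
    affected_hemisphere_of,
    compute_unit_svo2,
    delta_svo2,
    partition_hemisphere_grid,
    segment_hypoxic,
    upright_align,
)
from perfrad.synthetic import generate_subject
from perfrad.workflows import segment_subject


class TestDeltaSvO2:
    @pytest.mark.parametrize(
        "x_ref, x_roi, expected_delta, expected_svo2",
        [
            (100.0, 100.0, 0.0, 0.70),   # equal susceptibility
            (100.0, 200.0, 0.30, 0.40),  # doubled ROI susceptibility
            (200.0, 100.0, -0.15, 0.85), # halved ROI susceptibility
        ],
    )
    def test_closed_form(self, x_ref, x_roi, expected_delta, expected_svo2):
        d = delta_svo2(x_ref, x_roi, svo2_ref=0.7)
        assert d == pytest.approx(expected_delta, abs=1e-12)
        assert 0.7 - d == pytest.approx(expected_svo2, abs=1e-12)

    def test_zero_reference_raises(self):
        with pytest.raises(ZeroDivisionError):
            delta_svo2(0.0, 100.0)

    @given(
        x_ref=st.floats(min_value=91.0, max_value=299.0),
        roi_lo=st.floats(min_value=91.0, max_value=298.0),
        step=st.floats(min_value=0.1, max_value=50.0),
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_svo2_strictly_decreasing_in_roi(self, x_ref, roi_lo, step):
        s1 = 0.7 - delta_svo2(x_ref, roi_lo)
        s2 = 0.7 - delta_svo2(x_ref, roi_lo + step)
        assert s2 < s1

    @given(
        x_ref=st.floats(min_value=91.0, max_value=299.0),
        x_roi=st.floats(min_value=91.0, max_value=299.0),
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_round_trip(self, x_ref, x_roi):
        d = delta_svo2(x_ref, x_roi)
        svo2 = 0.7 - d
        assert abs((0.7 - svo2) - d) < 1e-12


def _ellipse_mask(shape=(48, 48, 6), rx=16.0, ry=9.0):
    g = np.ogrid[: shape[0], : shape[1], : shape[2]]
    cx, cy, cz = (shape[0] - 1) / 2, (shape[1] - 1) / 2, (shape[2] - 1) / 2
    return (((g[0] - cx) / rx) ** 2 + ((g[1] - cy) / ry) ** 2 + ((g[2] - cz) / (cz + 0.5)) ** 2) <= 1


class TestUprightAlign:
    def test_symmetric_phantom_zero_angle(self):
        mask = _ellipse_mask()
        _, _, rec = upright_align(np.zeros(mask.shape), mask)
        assert abs(rec.angle_deg) <= 0.5

    def test_known_rotation_recovered(self):
        mask = _ellipse_mask()
        rotated = ndimage.rotate(mask.astype(np.uint8), 10, axes=(0, 1), reshape=False, order=0) > 0.5
        _, _, rec = upright_align(np.zeros(mask.shape), rotated)
        assert rec.angle_deg == pytest.approx(10.0, abs=1.0)

    def test_pure_translation_recovered(self):
        mask = _ellipse_mask()
        shifted = np.roll(mask, (4, -3), axis=(0, 1))
        _, aligned, rec = upright_align(np.zeros(mask.shape), shifted)
        assert rec.angle_deg == 0.0
        assert rec.shift_xy == (-4, 3)  # correction undoes the applied shift
        np.testing.assert_array_equal(aligned, mask)

    def test_degenerate_mask_warns(self):
        mask = np.zeros((10, 10, 2), dtype=bool)
        mask[5, 5, 0] = True
        with pytest.warns(UserWarning, match="degenerate"):
            _, _, rec = upright_align(np.zeros(mask.shape), mask)
        assert rec.angle_deg == 0.0


class TestPartition:
    def test_50x100_bbox_gives_5x10_units(self):
        m = np.zeros((120, 110, 1), dtype=bool)
        m[5:55, 3:103, 0] = True
        part = partition_hemisphere_grid(m, midline_x=60)
        left = [u for u in part.units if u.hemisphere == "L"]
        assert len(left) == 100
        assert {(u.x_hi - u.x_lo, u.y_hi - u.y_lo) for u in left} == {(5, 10)}

    def test_grid_111_single_unit(self):
        m = np.zeros((20, 20, 1), dtype=bool)
        m[2:9, 4:16, 0] = True
        m[11:18, 4:16, 0] = True
        part = partition_hemisphere_grid(m, midline_x=10, grid=(1, 1, 1))
        assert len(part.units) == 2
        for u in part.units:
            assert (u.x_hi - u.x_lo, u.y_hi - u.y_lo) == (7, 12)

    def test_partition_covers_bbox_without_overlap(self):
        mask = _ellipse_mask()
        part = partition_hemisphere_grid(mask)
        cover = np.zeros(mask.shape, dtype=int)
        for u in part.units:
            cover[u.x_lo:u.x_hi, u.y_lo:u.y_hi, u.z] += 1
        assert cover.max() == 1          # no overlaps
        assert (cover[mask] == 1).all()  # every in-brain voxel in one unit

    def test_mirrored_pairing_is_geometric_mirror_for_symmetric_mask(self):
        mask = _ellipse_mask()
        part = partition_hemisphere_grid(mask)
        nx = mask.shape[0]
        for u in part.units:
            if u.hemisphere != "L":
                continue
            m = part.lookup("R", u.z, u.i, u.j)
            assert m is not None
            assert (nx - u.x_hi, nx - u.x_lo) == (m.x_lo, m.x_hi)
            assert (u.y_lo, u.y_hi) == (m.y_lo, m.y_hi)


def _two_unit_phantom(roi_chi, ref_chi=150.0):
    """One slice, veins filling mirrored units; ROI unit on the right."""
    mask = np.zeros((20, 12, 1), dtype=bool)
    mask[2:18, 2:10, 0] = True
    chi = np.zeros(mask.shape)
    chi[3:6, 3:6, 0] = ref_chi   # left-hemisphere vein block
    chi[14:17, 3:6, 0] = roi_chi # mirrored right-hemisphere vein block
    return chi, mask


class TestUnitSvO2:
    def _grid(self, roi_chi):
        chi, mask = _two_unit_phantom(roi_chi)
        part = partition_hemisphere_grid(mask, midline_x=10, grid=(2, 2, 1))
        return compute_unit_svo2(chi, part, SvO2Params(grid=(2, 2, 1))), mask

    def test_equal_units_svo2_at_reference(self):
        grid, _ = self._grid(150.0)
        defined = grid.table.dropna(subset=["svo2"])
        assert len(defined) > 0
        assert np.allclose(defined.svo2, 0.7)
        assert not defined.is_hypoxic.any()

    def test_elevated_unit_flagged_hypoxic(self):
        grid, mask = self._grid(250.0)
        right = grid.table[(grid.table.hemisphere == "R") & grid.table.svo2.notna()]
        assert right.is_hypoxic.any()
        flagged_svo2 = right[right.is_hypoxic].svo2
        expected = 0.7 - (-(1 - 0.7) * (150.0 - 250.0) / 150.0)
        assert flagged_svo2.iloc[0] == pytest.approx(expected)
        hyp = segment_hypoxic(grid, mask, "R")
        unit = grid.partition.lookup("R", 0, int(right[right.is_hypoxic].iloc[0].i),
                                     int(right[right.is_hypoxic].iloc[0].j))
        expected_count = int(mask[unit.x_lo:unit.x_hi, unit.y_lo:unit.y_hi, 0].sum())
        assert hyp.voxel_count == expected_count

    def test_units_without_veins_get_no_svo2(self):
        grid, _ = self._grid(150.0)
        empty = grid.table[grid.table.n_vein == 0]
        assert empty.svo2.isna().all()
        assert not empty.is_hypoxic.any()

    def test_boundary_svo2_not_hypoxic(self):
        grid, mask = self._grid(150.0)  # all defined SvO2 exactly 0.7
        assert segment_hypoxic(grid, mask, "R").voxel_count == 0


class TestHypoxicRecovery:
    def test_designated_units_recovered_exactly(self):
        subj = generate_subject(noise_free_config(), "poor", seed=21)
        masks = segment_subject(subj)
        np.testing.assert_array_equal(masks["hypoxic"], subj.truth_masks["hypoxic"])

    def test_affected_hemisphere_detection(self):
        lesion = np.zeros((10, 4, 2), dtype=bool)
        lesion[1:3] = True
        assert affected_hemisphere_of(lesion, midline_x=5) == "L"
        assert affected_hemisphere_of(lesion[::-1], midline_x=5) == "R"
        with pytest.raises(ValueError):
            affected_hemisphere_of(np.zeros((4, 4, 1), bool), 2)
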