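import logging

import numpy as np
import pydicom
import pytest

from dose4d import (
    BinaryMask,
    DoseGrid,
    GeometryError,
    GridGeometry,
    ImageVolume,
    StructureROI,
    StructureSet,
    rasterize,
    read_ct_series,
    read_rtdose,
    read_rtstruct,
    write_ct_series,
    write_rtdose,
    write_rtstruct,
)


def random_geometry(rng, rotated=False):
    shape = tuple(int(v) for v in rng.integers(2, 12, size=3))
    spacing = tuple(rng.uniform(0.5, 4.0, size=3))
    origin = tuple(rng.uniform(-50, 50, size=3))
    direction = None
    if rotated:
        theta = rng.uniform(0, 2 * np.pi)
        c, s = np.cos(theta), np.sin(theta)
        direction = ((c, -s, 0.0), (s, c, 0.0), (0.0, 0.0, 1.0))
        return GridGeometry(origin, spacing, shape, direction)
    return GridGeometry(origin, spacing, shape)


class TestGridGeometry:
    def test_invalid_inputs_rejected(self):
        with pytest.raises(GeometryError):
            GridGeometry((0, 0, 0), (1, 1, -1), (4, 4, 4))
        with pytest.raises(GeometryError):
            GridGeometry((0, 0, 0), (1, 1, 1), (4, 0, 4))
        with pytest.raises(GeometryError):
            GridGeometry((0, 0, 0), (1, 1, 1), (4, 4, 4),
                         direction=((1, 0, 0), (1, 0, 0), (0, 0, 1)))

    @pytest.mark.parametrize("rotated", [False, True])
    def test_index_mm_round_trip_is_identity(self, rng, rotated):
        for _ in range(20):
            geom = random_geometry(rng, rotated=rotated)
            idx = np.stack(
                [rng.integers(0, n, size=50) for n in geom.shape], axis=1
            ).astype(float)
            back = geom.mm_to_index(geom.index_to_mm(idx))
            assert np.allclose(back, idx, atol=1e-9)

    def test_voxel_volume(self):
        geom = GridGeometry((0, 0, 0), (1.01, 1.01, 3.0), (4, 4, 4))
        assert geom.voxel_volume_mm3 == pytest.approx(1.01 * 1.01 * 3.0)


class TestCTSeries:
    def test_round_trip(self, tmp_path, rng):
        geom = GridGeometry((-10, -20, -30), (1.0, 2.0, 3.0), (16, 12, 8))
        hu = rng.integers(-1000, 1500, size=geom.shape).astype(float)
        vol = ImageVolume(geometry=geom, intensities=hu, phase_label=50.0)
        write_ct_series(vol, tmp_path / "ct")
        back = read_ct_series(tmp_path / "ct")
        assert back.geometry.shape == geom.shape
        assert np.allclose(back.geometry.origin, geom.origin, atol=1e-6)
        assert np.allclose(back.geometry.spacing, geom.spacing, atol=1e-6)
        assert np.array_equal(back.intensities, hu)
        assert back.phase_label == 50.0

    def test_mixed_series_uids_error(self, tmp_path, rng):
        geom = GridGeometry((0, 0, 0), (1, 1, 2), (4, 4, 3))
        hu = np.zeros(geom.shape)
        write_ct_series(ImageVolume(geom, hu), tmp_path / "ct")
        other = GridGeometry((0, 0, 50), (1, 1, 2), (4, 4, 3))
        paths = write_ct_series(ImageVolume(other, hu), tmp_path / "other")
        (tmp_path / "ct" / "extra.dcm").write_bytes(paths[0].read_bytes())
        with pytest.raises(GeometryError, match="series UIDs"):
            read_ct_series(tmp_path / "ct")

    def test_nonuniform_slice_gap_error(self, tmp_path):
        geom = GridGeometry((0, 0, 0), (1, 1, 2), (4, 4, 5))
        paths = write_ct_series(ImageVolume(geom, np.zeros(geom.shape)), tmp_path / "ct")
        ds = pydicom.dcmread(str(paths[2]))
        ipp = list(ds.ImagePositionPatient)
        ipp[2] = float(ipp[2]) + 1.0  # shift one slice by dz/2
        ds.ImagePositionPatient = ipp
        ds.save_as(str(paths[2]), enforce_file_format=True)
        with pytest.raises(GeometryError, match="[Nn]on-uniform"):
            read_ct_series(tmp_path / "ct")

    def test_empty_directory_error(self, tmp_path):
        with pytest.raises(GeometryError, match="no CT"):
            read_ct_series(tmp_path)


class TestRTDose:
    def make_dose(self, rng, max_gy=20.0):
        geom = GridGeometry((-5, -5, 0), (1.5, 1.0, 2.5), (10, 8, 6))
        dose = rng.uniform(0, max_gy, size=geom.shape)
        dose.flat[0] = max_gy  # pin the max so scaling is deterministic
        return DoseGrid(geometry=geom, dose=dose)

    def test_round_trip_within_scaling_quantum(self, tmp_path, rng):
        for i in range(20):
            dose = self.make_dose(rng)
            path = tmp_path / f"d{i}.dcm"
            write_rtdose(dose, path)
            back = read_rtdose(path)
            quantum = 20.0 / (2**32 - 1)
            assert back.geometry.approx_equal(dose.geometry)
            assert np.max(np.abs(back.dose - dose.dose)) <= quantum

    def test_zero_dose_round_trip(self, tmp_path):
        geom = GridGeometry((0, 0, 0), (1, 1, 1), (4, 4, 4))
        path = write_rtdose(DoseGrid(geom, np.zeros(geom.shape)), tmp_path / "z.dcm")
        assert np.all(read_rtdose(path).dose == 0)

    def test_relative_units_rejected(self, tmp_path, rng):
        path = write_rtdose(self.make_dose(rng), tmp_path / "d.dcm")
        ds = pydicom.dcmread(str(path))
        ds.DoseUnits = "RELATIVE"
        ds.save_as(str(path), enforce_file_format=True)
        with pytest.raises(GeometryError, match="GY"):
            read_rtdose(path)

    def test_missing_scaling_rejected(self, tmp_path, rng):
        path = write_rtdose(self.make_dose(rng), tmp_path / "d.dcm")
        ds = pydicom.dcmread(str(path))
        del ds.DoseGridScaling
        ds.save_as(str(path), enforce_file_format=True)
        with pytest.raises(GeometryError, match="DoseGridScaling"):
            read_rtdose(path)

    def test_invalid_dose_rejected_on_write(self, tmp_path):
        geom = GridGeometry((0, 0, 0), (1, 1, 1), (3, 3, 3))
        dose = DoseGrid(geom, np.ones(geom.shape))
        dose.dose[0, 0, 0] = np.nan
        with pytest.raises(GeometryError):
            write_rtdose(dose, tmp_path / "bad.dcm")
        dose.dose[0, 0, 0] = -1.0
        with pytest.raises(GeometryError):
            write_rtdose(dose, tmp_path / "bad.dcm")


def square_roi(side=10.0, z=0.0, offset=(0.0, 0.0)):
    x0, y0 = offset
    pts = np.array(
        [[x0, y0, z], [x0 + side, y0, z], [x0 + side, y0 + side, z], [x0, y0 + side, z]]
    )
    return StructureROI(name="SQ", contours=[pts])


class TestRTStruct:
    def make_ct(self):
        geom = GridGeometry((-15, -15, -15), (1.0, 1.0, 3.0), (31, 31, 11))
        return ImageVolume(geom, np.zeros(geom.shape), frame_of_reference="1.2.3.4")

    def sphere_roi(self, radius=9.0):
        contours = []
        for z in np.arange(-15, 16, 3.0):
            h2 = radius**2 - z**2
            if h2 <= 0:
                continue
            r = np.sqrt(h2)
            th = np.linspace(0, 2 * np.pi, 40, endpoint=False)
            contours.append(
                np.column_stack([r * np.cos(th), r * np.sin(th), np.full(40, z)])
            )
        return StructureROI(name="GTV", contours=contours)

    def test_round_trip(self, tmp_path):
        ct = self.make_ct()
        roi = self.sphere_roi()
        path = tmp_path / "rs.dcm"
        write_rtstruct(StructureSet(rois={"GTV": roi}), ct, path)
        back = read_rtstruct(path, ct)
        assert back.names == ["GTV"]
        assert len(back["GTV"].contours) == len(roi.contours)
        for a, b in zip(roi.contours, back["GTV"].contours):
            assert np.allclose(a, b, atol=1e-6)

    def test_empty_structure_set(self, tmp_path):
        ct = self.make_ct()
        path = tmp_path / "rs.dcm"
        write_rtstruct(StructureSet(), ct, path)
        assert read_rtstruct(path, ct).names == []

    def test_frame_of_reference_mismatch(self, tmp_path):
        ct = self.make_ct()
        path = tmp_path / "rs.dcm"
        write_rtstruct(StructureSet(rois={"GTV": self.sphere_roi()}), ct, path,
                       frame_of_reference="9.9.9")
        with pytest.raises(GeometryError, match="frame of reference"):
            read_rtstruct(path, ct)

    def test_short_contour_skipped_with_warning(self, tmp_path, caplog):
        ct = self.make_ct()
        path = tmp_path / "rs.dcm"
        write_rtstruct(StructureSet(rois={"GTV": self.sphere_roi()}), ct, path)
        ds = pydicom.dcmread(str(path))
        ds.ROIContourSequence[0].ContourSequence[0].ContourData = [0.0, 0.0, 0.0, 1.0, 0.0, 0.0]
        ds.ROIContourSequence[0].ContourSequence[0].NumberOfContourPoints = 2
        ds.save_as(str(path), enforce_file_format=True)
        with caplog.at_level(logging.WARNING):
            back = read_rtstruct(path, ct)
        assert "skipping contour" in caplog.text
        assert len(back["GTV"].contours) == len(self.sphere_roi().contours) - 1


class TestRasterize:
    def test_axis_aligned_square(self):
        geom = GridGeometry((0.5, 0.5, 0.0), (1.0, 1.0, 1.0), (20, 20, 1))
        mask = rasterize(square_roi(side=10.0, z=0.0), geom)
        assert mask.inside.sum() == 100
        ii, jj, _ = np.nonzero(mask.inside)
        assert ii.min() == 0 and ii.max() == 9 and jj.min() == 0 and jj.max() == 9

    def test_sphere_volume_within_5_percent(self):
        geom = GridGeometry((-14.5, -14.5, -14.5), (1.0, 1.0, 1.0), (30, 30, 30))
        roi = TestRTStruct().sphere_roi(radius=10.0)
        # rebuild contours on every 1 mm slice for this grid
        contours = []
        for z in np.arange(-14.5, 15.0, 1.0):
            h2 = 100.0 - z**2
            if h2 <= 0:
                continue
            r = np.sqrt(h2)
            th = np.linspace(0, 2 * np.pi, 128, endpoint=False)
            contours.append(np.column_stack([r * np.cos(th), r * np.sin(th), np.full(128, z)]))
        roi = StructureROI(name="S", contours=contours)
        mask = rasterize(roi, geom)
        analytic_cc = 4.0 / 3.0 * np.pi * 10.0**3 / 1000.0
        assert mask.volume_cc == pytest.approx(analytic_cc, rel=0.05)

    def test_polygon_outside_grid_warns_and_is_empty(self, caplog):
        geom = GridGeometry((0, 0, 0), (1, 1, 1), (5, 5, 5))
        roi = square_roi(side=3.0, z=100.0)
        with caplog.at_level(logging.WARNING):
            mask = rasterize(roi, geom)
        assert not mask.inside.any()
        assert "empty mask" in caplog.text

    def test_refinement_error_decreases_monotonically(self):
        radius = 16.0
        analytic_area = np.pi * radius**2
        theta = np.linspace(0, 2 * np.pi, 720, endpoint=False)
        pts = np.column_stack(
            [radius * np.cos(theta), radius * np.sin(theta), np.zeros(720)]
        )
        errors = []
        for h in (2.0, 1.0, 0.5):
            n = int(80 / h)
            geom = GridGeometry((-40 + h / 2, -40 + h / 2, 0.0), (h, h, 1.0), (n, n, 1))
            mask = rasterize(StructureROI("C", [pts]), geom)
            errors.append(abs(mask.inside.sum() * h * h - analytic_area))
        assert errors[0] >= errors[1] >= errors[2]


class TestBinaryMask:
    def test_volume_cc(self):
        geom = GridGeometry((0, 0, 0), (2.0, 2.0, 2.5), (4, 4, 4))
        inside = np.zeros(geom.shape, dtype=bool)
        inside[:2, :2, :2] = True
        assert BinaryMask(geom, inside).volume_cc == pytest.approx(8 * 10.0 / 1000.0)
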