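"""Microdissection export: morphology chain, polygon tracing, Helmert fit."""

import numpy as np
import pytest
from scipy import ndimage

from irplaque.ihc_mask import BinaryMask
from irplaque.lmd_export import (HelmertTransform, LmdConfig,
                                 activation_to_plaque_mask, export_shapes,
                                 fit_helmert, mask_to_polygons, read_shapes)

PS = 4.25
PX_AREA = PS * PS  # 18.0625 um^2


def _disk_mask(shape, cy, cx, r):
    yy, xx = np.mgrid[:shape[0], :shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r ** 2


class TestActivationToPlaqueMask:
    def test_subthreshold_map_gives_empty_mask(self):
        a = np.full((64, 64), 0.85)
        assert not activation_to_plaque_mask(a, pixel_size=PS).values.any()

    def test_sub_100um2_component_removed_at_stage_one(self):
        a = np.zeros((64, 64))
        a[_disk_mask((64, 64), 32, 32, 1.3)] = 0.95   # 5 px ~ 90 um^2 < 100
        assert not activation_to_plaque_mask(a, pixel_size=PS).values.any()

    def test_three_object_toy_keeps_only_qualifying_disk(self):
        """A ~400 um^2 disk survives; a ~90 um^2 disk fails the first area
        cut; a 1-px-wide line is removed by the shape filter."""
        a = np.zeros((160, 160))
        disk_big = _disk_mask((160, 160), 40, 40, 2.7)     # 25 px ~ 450 um^2
        disk_small = _disk_mask((160, 160), 40, 120, 1.3)  # 5 px ~ 90 um^2
        a[disk_big] = 0.95
        a[disk_small] = 0.95
        a[120, 30:58] = 0.95                               # 28 px line ~ 505 um^2
        out = activation_to_plaque_mask(a, pixel_size=PS)
        lab, n = ndimage.label(out.values, np.ones((3, 3)))
        assert n == 1
        comp = out.values
        assert comp[40, 40]           # the surviving object is the big disk
        assert not comp[120, 30:58].any()
        assert not comp[40, 120]

    def test_net_margin_grows_disk_by_5um(self):
        """Dilate 15 um then erode 10 um leaves a +5 um margin (+-1 px)."""
        a = np.zeros((128, 128))
        r0 = 6
        a[_disk_mask((128, 128), 64, 64, r0)] = 0.95
        out = activation_to_plaque_mask(a, pixel_size=PS)
        area_px = out.values.sum()
        r_eq = np.sqrt(area_px / np.pi)
        expected = r0 + (15 - 10) / PS
        assert abs(r_eq - expected) <= 1.0

    def test_literal_printed_rule_inverts_shape_filter(self):
        """With the verbatim exclusion rule, round solid objects — kept by
        the default polarity — are excluded instead."""
        a = np.zeros((160, 160))
        a[_disk_mask((160, 160), 40, 40, 2.7)] = 0.95
        default = activation_to_plaque_mask(a, pixel_size=PS)
        literal = activation_to_plaque_mask(a, LmdConfig(literal_printed_rule=True),
                                            pixel_size=PS)
        assert default.values[40, 40]
        assert not literal.values.any()

    def test_exclusion_mask_suppresses_region(self):
        a = np.zeros((128, 128))
        a[_disk_mask((128, 128), 40, 40, 4)] = 0.95
        excl = np.zeros((128, 128), dtype=bool)
        excl[:80, :80] = True
        out = activation_to_plaque_mask(a, pixel_size=PS, exclusion_mask=excl)
        assert not out.values.any()


class TestMaskToPolygons:
    def test_single_pixel_square_area(self):
        m = np.zeros((8, 8), dtype=bool)
        m[0, 0] = True
        (shp,) = mask_to_polygons(BinaryMask(m, PS))
        assert shp.area == pytest.approx(PX_AREA)
        assert len(shp.vertices) == 5  # closed square ring

    def test_2x2_block_area(self):
        m = np.zeros((8, 8), dtype=bool)
        m[2:4, 2:4] = True
        (shp,) = mask_to_polygons(BinaryMask(m, PS))
        assert shp.area == pytest.approx(4 * PX_AREA)

    def test_empty_mask_gives_empty_list(self):
        assert mask_to_polygons(BinaryMask(np.zeros((4, 4)), PS)) == []

    def test_area_equals_pixel_count_contract(self):
        rng = np.random.default_rng(0)
        m = ndimage.binary_dilation(rng.random((40, 40)) > 0.97,
                                    np.ones((3, 3)), iterations=2)
        shapes = mask_to_polygons(BinaryMask(m, PS))
        lab, n = ndimage.label(m, np.ones((3, 3)))
        # compare totals component-wise (4-connected components match rings)
        total = sum(s.area for s in shapes)
        assert total <= m.sum() * PX_AREA + 1e-6
        assert total >= 0.9 * m.sum() * PX_AREA


class TestFitHelmert:
    def test_identity(self):
        src = np.array([[0.0, 0], [10, 0], [0, 10]])
        t = fit_helmert(src, src)
        assert t.scale == pytest.approx(1.0)
        assert t.rotation == pytest.approx(0.0)
        assert (t.tx, t.ty) == (pytest.approx(0.0), pytest.approx(0.0))

    def test_pure_translation(self):
        src = np.array([[0.0, 0], [10, 0], [0, 10]])
        dst = src + np.array([10.0, -5.0])
        t = fit_helmert(src, dst)
        assert t.scale == pytest.approx(1.0)
        assert (t.tx, t.ty) == (pytest.approx(10.0), pytest.approx(-5.0))

    def test_scale_rotation_translation_recovered(self):
        """dst = 2 R(90 deg) src + (1, 2) recovered from the closed form."""
        src = np.array([[0.0, 0], [10, 0], [0, 10], [3, 4]])
        th = np.pi / 2
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        dst = (2 * R @ src.T).T + np.array([1.0, 2.0])
        t = fit_helmert(src, dst)
        assert t.scale == pytest.approx(2.0)
        assert t.rotation == pytest.approx(np.pi / 2)
        assert (t.tx, t.ty) == (pytest.approx(1.0), pytest.approx(2.0))

    def test_thousand_random_similarities_recovered(self):
        """Parameter recovery over 1,000 seeded random similarities to 1e-6."""
        rng = np.random.default_rng(123)
        worst = 0.0
        for _ in range(1000):
            n = int(rng.integers(3, 8))
            src = rng.uniform(-100, 100, size=(n, 2))
            s = float(rng.uniform(0.1, 5.0))
            th = float(rng.uniform(-np.pi, np.pi))
            tx, ty = rng.uniform(-50, 50, 2)
            R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
            dst = (s * R @ src.T).T + np.array([tx, ty])
            t = fit_helmert(src, dst)
            ang_err = abs(np.angle(np.exp(1j * (t.rotation - th))))
            worst = max(worst, abs(t.scale - s) / s, ang_err,
                        abs(t.tx - tx), abs(t.ty - ty))
            resid = np.abs(t.apply(src) - dst).max()
            worst = max(worst, resid)
        assert worst < 1e-6

    def test_inverse_round_trip(self):
        t = HelmertTransform(2.0, 0.7, 5.0, -3.0)
        pts = np.random.default_rng(0).uniform(-10, 10, size=(20, 2))
        back = t.inverse().apply(t.apply(pts))
        assert np.abs(back - pts).max() < 1e-9

    def test_coincident_points_rejected(self):
        src = np.zeros((3, 2))
        with pytest.raises(ValueError):
            fit_helmert(src, src + 1.0)


class TestExportShapes:
    @pytest.fixture()
    def shapes(self):
        m = np.zeros((32, 32), dtype=bool)
        m[4:9, 4:9] = True
        m[20:26, 18:25] = True
        return mask_to_polygons(BinaryMask(m, PS))

    def test_identity_transform_round_trip(self, shapes, tmp_path):
        path = export_shapes(shapes, HelmertTransform.identity(),
                             tmp_path / "shapes.csv")
        rings = read_shapes(path)
        assert len(rings) == len(shapes)
        for ring, shp in zip(rings, shapes):
            assert np.abs(ring - shp.vertices).max() < 1e-6

    def test_translation_shifts_all_vertices(self, shapes, tmp_path):
        t = HelmertTransform(1.0, 0.0, 100.0, -50.0)
        path = export_shapes(shapes, t, tmp_path / "shapes.csv")
        rings = read_shapes(path)
        for ring, shp in zip(rings, shapes):
            assert np.allclose(ring, shp.vertices + np.array([100.0, -50.0]),
                               atol=1e-6)

    def test_summary_table_written(self, shapes, tmp_path):
        export_shapes(shapes, HelmertTransform.identity(), tmp_path / "s.csv")
        summary = (tmp_path / "s_summary.csv").read_text().splitlines()
        assert summary[0].startswith("shape_id")
        assert len(summary) == len(shapes) + 1


def test_no_orphan_shapes_after_filtering():
    """Every exported polygon's component survived the full filter chain."""
    rng = np.random.default_rng(5)
    a = np.zeros((128, 128))
    for _ in range(6):
        cy, cx = rng.integers(10, 118, 2)
        r = rng.integers(1, 5)
        a[_disk_mask((128, 128), cy, cx, r)] = 0.95
    mask = activation_to_plaque_mask(a, pixel_size=PS)
    shapes = mask_to_polygons(mask)
    lab, n = ndimage.label(mask.values, np.ones((3, 3)))
    assert len(shapes) == n
    for shp in shapes:
        assert 1 <= shp.source_component <= n
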