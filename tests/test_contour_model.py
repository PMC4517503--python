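"""Contour domain types, exchange I/O, rasterization and extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from lvconsensus import (
    Contour,
    SliceGeometry,
    StudyContourSet,
    extract_contour,
    polygon_area_mm2,
    rasterize,
    read_contour_set,
    write_contour_set,
)
from lvconsensus.contour_model import (
    ContourParseError,
    ContourValidationError,
    signed_area,
)
from .conftest import make_circle, make_square


class TestContour:
    def test_clockwise_input_normalized_ccw_with_same_area(self):
        cw = np.array([[0.0, 0.0], [0.0, 3.0], [4.0, 3.0], [4.0, 0.0]])
        assert signed_area(cw) < 0
        c = Contour("endo", "ED", 0, cw)
        assert signed_area(c.points) > 0
        assert polygon_area_mm2(c) == pytest.approx(12.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ContourValidationError, match="slice 2"):
            Contour("endo", "ED", 2, np.array([[0.0, 0.0], [1.0, 1.0]]))

    def test_self_intersection_rejected(self):
        bowtie = np.array([[0.0, 0.0], [2.0, 2.0], [2.0, 0.0], [0.0, 2.0]])
        with pytest.raises(ContourValidationError, match="endo"):
            Contour("endo", "ES", 1, bowtie)

    def test_explicit_closing_point_dropped(self):
        closed = np.array([[0.0, 0.0], [4.0, 0.0], [0.0, 3.0], [0.0, 0.0]])
        c = Contour("epi", "ED", 0, closed)
        assert len(c.points) == 3

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 10 ** 6))
    def test_orientation_normalization_preserves_area(self, seed):
        # random star-shaped polygons are simple by construction
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 40))
        theta = np.sort(rng.uniform(0, 2 * np.pi, n))
        if len(np.unique(theta)) < 5:
            return
        r = rng.uniform(5.0, 20.0, len(theta))
        pts = np.column_stack([30 + r * np.cos(theta), 30 + r * np.sin(theta)])
        area = abs(signed_area(pts))
        for order in (pts, pts[::-1]):
            c = Contour("endo", "ED", 0, order)
            assert polygon_area_mm2(c) == pytest.approx(area, rel=1e-12)
            assert signed_area(c.points) > 0


class TestContourSet:
    def test_endo_must_be_smaller_than_epi_on_ed(self, geom):
        cs = StudyContourSet("c1", "r1", geom)
        cs.add(make_square(20, (10, 10), surface="endo"))
        with pytest.raises(ContourValidationError, match="endo area >= epi"):
            cs.add(make_square(10, (15, 15), surface="epi"))

    def test_out_of_bounds_rejected(self, geom):
        cs = StudyContourSet("c1", "r1", geom)
        with pytest.raises(ContourValidationError, match="bounds"):
            cs.add(make_square(30, (50, 50)))  # exceeds the 64 mm image

    def test_duplicate_key_rejected(self, geom):
        cs = StudyContourSet("c1", "r1", geom)
        cs.add(make_square(10))
        with pytest.raises(ContourValidationError, match="duplicate"):
            cs.add(make_square(12, (20, 20)))


class TestExchangeIO:
    def test_single_square_identity(self, geom, tmp_path):
        cs = StudyContourSet("c1", "r1", geom)
        cs.add(make_square(10))
        path = tmp_path / "one.csv"
        write_contour_set(cs, path)
        back = read_contour_set(path)
        assert len(back) == 1
        assert len(back.get("ED", 0, "endo").points) == 4

    def test_round_trip_equality(self, geom, tmp_path):
        cs = StudyContourSet("c7", "reader3", geom)
        cs.add(make_circle(14, (32, 32), surface="endo", slice_index=1))
        cs.add(make_circle(20, (32, 32), surface="epi", slice_index=1))
        cs.add(make_circle(9, (32, 32), frame="ES", slice_index=1))
        path = tmp_path / "set.csv"
        write_contour_set(cs, path)
        back = read_contour_set(path)
        assert back.equals(cs)  # repr-format floats round-trip exactly
        assert back.geometry == geom

    def test_clockwise_file_loads_ccw(self, geom, tmp_path):
        path = tmp_path / "cw.csv"
        rows = ["# geometry 1.0 1.0 8.0 8.0 64 64 4",
                "case_id,source_id,frame,slice_index,surface,point_index,x_mm,y_mm"]
        cw_pts = [(10, 10), (10, 20), (20, 20), (20, 10)]  # negative shoelace
        assert signed_area(np.array(cw_pts, float)) < 0
        for i, (x, y) in enumerate(cw_pts):
            rows.append(f"c1,r1,ED,0,endo,{i},{x},{y}")
        path.write_text("\n".join(rows) + "\n")
        cs = read_contour_set(path)
        c = cs.get("ED", 0, "endo")
        assert signed_area(c.points) > 0
        assert polygon_area_mm2(c) == pytest.approx(100.0)

    def test_parse_error_names_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text(
            "case_id,source_id,frame,slice_index,surface,point_index,x_mm,y_mm\n"
            "c1,r1,ED,0,endo,0,1.0,2.0\n"
            "c1,r1,ED,zero,endo,1,oops,2.0\n")
        with pytest.raises(ContourParseError, match="line 3"):
            read_contour_set(path, geometry=SliceGeometry((1, 1), 8, 8, 64, 64, 1))

    def test_validation_error_names_key(self, geom, tmp_path):
        path = tmp_path / "short.csv"
        path.write_text(
            "# geometry 1.0 1.0 8.0 8.0 64 64 4\n"
            "case_id,source_id,frame,slice_index,surface,point_index,x_mm,y_mm\n"
            "c1,r1,ES,3,endo,0,1.0,2.0\n"
            "c1,r1,ES,3,endo,1,2.0,2.0\n")
        with pytest.raises(ContourValidationError, match=r"ES, slice 3, endo"):
            read_contour_set(path)


class TestRasterize:
    def test_axis_aligned_square_exact_cover(self, geom):
        mask = rasterize(make_square(10.0, (12.0, 12.0)), geom, factor=4)
        assert mask.area_mm2() == pytest.approx(100.0, abs=0)

    def test_circle_area_analytic(self):
        geom = SliceGeometry((1.25, 1.25), 8, 8, 80, 80, 4)
        circ = make_circle(20.0, (50.0, 50.0), n=256)
        mask = rasterize(circ, geom, factor=4)
        assert mask.area_mm2() == pytest.approx(np.pi * 400.0, rel=0.005)

    def test_refinement_reduces_area_error(self):
        geom = SliceGeometry((1.25, 1.25), 8, 8, 80, 80, 4)
        circ = make_circle(20.0, (50.0, 50.0), n=256)
        target = polygon_area_mm2(circ)
        err = {f: abs(rasterize(circ, geom, factor=f).area_mm2() - target)
               for f in (1, 4)}
        assert err[4] < err[1]

    def test_out_of_bounds_contour_errors(self, geom):
        big = make_square(30, (40, 40))
        with pytest.raises(ContourValidationError, match="bounds"):
            rasterize(big, geom)

    @pytest.mark.parametrize("factor", [2, 4])
    def test_convex_fixture_relative_error_under_one_percent(self, factor):
        geom = SliceGeometry((1.5, 1.5), 8, 8, 64, 64, 4)
        circ = make_circle(15.0, (48.0, 48.0), n=128)  # diameter 20 pixels
        mask = rasterize(circ, geom, factor=factor)
        assert mask.area_mm2() == pytest.approx(polygon_area_mm2(circ), rel=0.01)


class TestPolygonArea:
    @pytest.mark.parametrize("pts,expected", [
        ([[0, 0], [1, 0], [1, 1], [0, 1]], 1.0),
        ([[0, 0], [4, 0], [0, 3]], 6.0),
    ])
    def test_closed_forms(self, pts, expected):
        c = Contour("endo", "ED", 0, np.array(pts, float))
        assert polygon_area_mm2(c) == pytest.approx(expected)

    def test_regular_64gon_approximates_disc(self):
        c = make_circle(10.0, (20, 20), n=64)
        closed = 0.5 * 64 * 100 * np.sin(2 * np.pi / 64)
        assert polygon_area_mm2(c) == pytest.approx(closed, rel=1e-12)
        assert polygon_area_mm2(c) == pytest.approx(np.pi * 100.0, rel=0.002)


class TestExtractContour:
    def test_inverse_of_rasterize_on_convex_contour(self, geom_fine):
        circ = make_circle(18.0, (50.0, 50.0), n=128)
        mask = rasterize(circ, geom_fine, factor=4)
        out = extract_contour(mask.grid.astype(float), geom_fine, factor=4,
                              frame="ED", surface="endo")
        assert polygon_area_mm2(out) == pytest.approx(polygon_area_mm2(circ),
                                                      rel=0.02)

    def test_all_zero_map_yields_no_contour(self, geom):
        assert extract_contour(np.zeros((64, 64)), geom, factor=1) is None

    def test_largest_component_only(self, geom):
        prob = np.zeros((64, 64))
        prob[10:20, 10:20] = 1.0  # 100 cells
        prob[40:41, 40:43] = 1.0  # 3 cells
        labels, n = ndimage.label(prob > 0.5)  # independent component oracle
        assert n == 2
        sizes = ndimage.sum_labels(np.ones_like(prob), labels, range(1, n + 1))
        out = extract_contour(prob, geom, factor=1, frame="ED", surface="endo")
        assert polygon_area_mm2(out) == pytest.approx(float(sizes.max()), rel=0.1)
        xs, ys = out.points[:, 0], out.points[:, 1]
        assert xs.max() < 30 and ys.max() < 30  # traced the big blob
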