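import numpy as np
import pytest

from contoursim import (
    Contour,
    make_random_polygon,
    make_regular_polygon,
    make_segmented_line,
    make_template_groups,
    make_triangle,
    perturb_contour,
    rasterize_contour,
    read_contour_csv,
    resample_contour,
    trace_boundary,
    write_contour_csv,
)
from contoursim.errors import (
    AmbiguousMaskError,
    ContourError,
    InvalidSpecError,
    NoShapeError,
    ParseError,
    TooSmallError,
)


# ---------------------------------------------------------------------------
# oracles

def segments_cross(p1, p2, p3, p4):
    """Proper-intersection test for open segments p1-p2 and p3-p4."""
    def orient(a, b, c):
        v = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
        return 0 if v == 0 else (1 if v > 0 else -1)

    o1, o2 = orient(p1, p2, p3), orient(p1, p2, p4)
    o3, o4 = orient(p3, p4, p1), orient(p3, p4, p2)
    return o1 != o2 and o3 != o4 and 0 not in (o1, o2, o3, o4)


def polygon_is_simple(points):
    """Brute-force all-pairs proper-intersection check on closed polygon edges."""
    n = len(points)
    edges = [(points[i], points[(i + 1) % n]) for i in range(n)]
    for i in range(n):
        for j in range(i + 2, n):
            if i == 0 and j == n - 1:
                continue  # adjacent through the wrap
            if segments_cross(*edges[i], *edges[j]):
                return False
    return True


# ---------------------------------------------------------------------------
# Contour type

class TestContour:
    def test_rejects_consecutive_duplicates(self):
        with pytest.raises(ContourError):
            Contour(np.array([[0, 0], [0, 0], [1, 1]]), closed=False)

    def test_closed_contour_must_not_repeat_first_point(self):
        with pytest.raises(ContourError):
            Contour(np.array([[0, 0], [1, 0], [0, 1], [0, 0]]), closed=True)

    def test_signed_area_ccw_positive(self):
        ccw = Contour(np.array([[0, 0], [1, 0], [1, 1], [0, 1]]), closed=True)
        assert ccw.signed_area() == pytest.approx(1.0)
        cw = Contour(ccw.points[::-1], closed=True)
        assert cw.signed_area() == pytest.approx(-1.0)


# ---------------------------------------------------------------------------
# generators

class TestSegmentedLine:
    def test_equal_densities_symmetric_about_midpoint(self):
        c = make_segmented_line(100, 100, 1.0)
        assert len(c) == 199
        assert not c.closed
        x = c.points[:, 0]
        # spacing mirror-symmetric about the midpoint (machine precision;
        # linspace rounding breaks bitwise palindromy of the gaps)
        gaps = np.diff(x)
        np.testing.assert_allclose(gaps, gaps[::-1], rtol=1e-12, atol=0)

    def test_unequal_densities(self):
        c = make_segmented_line(120, 100, 1.0)
        assert len(c) == 219
        gaps_first = np.diff(c.points[:120, 0])
        gaps_second = np.diff(c.points[119:, 0])
        assert gaps_first.max() < gaps_second.min()

    def test_collinear(self):
        c = make_segmented_line(7, 13, 2.0)
        assert np.all(c.points[:, 1] == 0.0)
        assert c.points[-1, 0] == pytest.approx(4.0)

    @pytest.mark.parametrize("n1,n2", [(1, 100), (100, 1), (0, 5)])
    def test_degenerate_counts_error(self, n1, n2):
        with pytest.raises(InvalidSpecError):
            make_segmented_line(n1, n2, 1.0)


class TestTriangle:
    def test_node_count_shared_vertices_once(self):
        c = make_triangle(100, 120, 120)
        assert len(c) == 337
        assert c.closed

    def test_counterclockwise_from_vertex_a(self):
        c = make_triangle(10, 10, 10)
        assert c.signed_area() > 0
        np.testing.assert_array_equal(c.points[0], [0.0, 0.0])

    def test_minimal_triangle(self):
        c = make_triangle(2, 2, 2)
        assert len(c) == 3

    def test_equilateral_sides(self):
        c = make_triangle(2, 2, 2)
        sides = c.segment_lengths()
        np.testing.assert_allclose(sides, sides[0])

    def test_count_below_two_errors(self):
        with pytest.raises(InvalidSpecError):
            make_triangle(1, 120, 120)


class TestRegularPolygon:
    @pytest.mark.parametrize("n_sides,nodes,expected", [(4, 250, 996), (5, 200, 995), (3, 2, 3)])
    def test_node_counts(self, n_sides, nodes, expected):
        assert len(make_regular_polygon(n_sides, nodes)) == expected

    def test_unit_circumradius_ccw(self):
        c = make_regular_polygon(6, 10)
        assert c.signed_area() > 0
        radii = np.linalg.norm(c.points, axis=1)
        assert radii.max() == pytest.approx(1.0)

    def test_invalid_counts(self):
        with pytest.raises(InvalidSpecError):
            make_regular_polygon(2, 10)
        with pytest.raises(InvalidSpecError):
            make_regular_polygon(4, 1)


class TestRandomPolygon:
    def test_deterministic(self):
        a = make_random_polygon(10, 42, 1000)
        b = make_random_polygon(10, 42, 1000)
        np.testing.assert_array_equal(a.points, b.points)

    def test_seed_changes_shape(self):
        a = make_random_polygon(10, 42, 200)
        b = make_random_polygon(10, 43, 200)
        assert not np.array_equal(a.points, b.points)

    @pytest.mark.parametrize("n_vertices,seed", [(3, 7), (15, 1), (10, 42), (17, 5)])
    def test_simple_polygon(self, n_vertices, seed):
        c = make_random_polygon(n_vertices, seed, 60)
        assert polygon_is_simple(c.points)

    def test_node_total(self):
        assert len(make_random_polygon(12, 0, 500)) == 500


class TestPerturbAndTemplates:
    def test_perturb_deterministic(self):
        c = make_regular_polygon(5, 20)
        a = perturb_contour(c, 0.01, 9)
        b = perturb_contour(c, 0.01, 9)
        np.testing.assert_array_equal(a.points, b.points)

    def test_perturb_amplitude_zero_is_identity(self):
        c = make_regular_polygon(5, 20)
        np.testing.assert_array_equal(perturb_contour(c, 0.0, 1).points, c.points)

    def test_template_groups_layout(self):
        groups = make_template_groups(n_groups=3, group_size=4, nodes_total=100, seed=1)
        assert [gid for gid, _ in groups] == [1, 2, 3]
        assert all(len(members) == 4 for _, members in groups)
        assert all(len(m) == 100 for _, members in groups for m in members)


# ---------------------------------------------------------------------------
# boundary tracing

class TestTraceBoundary:
    def test_3x3_ring_manual_enumeration(self):
        contour = trace_boundary(np.ones((3, 3), dtype=int))
        # manually enumerated ring of the 3x3 block, counterclockwise (positive
        # shoelace) starting from the topmost-then-leftmost pixel (0, 0)
        expected = [[0, 0], [1, 0], [2, 0], [2, 1], [2, 2], [1, 2], [0, 2], [0, 1]]
        np.testing.assert_array_equal(contour.points, expected)
        assert contour.closed

    def test_single_pixel_too_small(self):
        mask = np.zeros((5, 5), dtype=int)
        mask[2, 2] = 1
        with pytest.raises(TooSmallError):
            trace_boundary(mask)

    def test_empty_mask(self):
        with pytest.raises(NoShapeError):
            trace_boundary(np.zeros((4, 4), dtype=int))

    def test_two_blobs_ambiguous(self):
        mask = np.zeros((8, 8), dtype=int)
        mask[1:3, 1:3] = 1
        mask[5:7, 5:7] = 1
        with pytest.raises(AmbiguousMaskError):
            trace_boundary(mask)

    def test_interior_pixels_not_in_boundary(self):
        mask = np.zeros((7, 7), dtype=int)
        mask[1:6, 1:6] = 1
        contour = trace_boundary(mask)
        assert len(contour) == 16  # 5x5 block ring
        assert [3.0, 3.0] not in contour.points.tolist()

    def test_random_blobs_are_counterclockwise(self, rng):
        from scipy import ndimage

        trials = 0
        while trials < 25:
            mask = ndimage.binary_dilation(
                rng.random((24, 24)) > 0.92, iterations=3
            ).astype(int)
            labels, n = ndimage.label(
                mask, structure=[[0, 1, 0], [1, 1, 1], [0, 1, 0]]
            )
            if n != 1 or mask.sum() < 9:
                continue
            trials += 1
            assert trace_boundary(mask).signed_area() > 0

    def test_start_pixel_topmost_then_leftmost(self):
        mask = np.zeros((6, 6), dtype=int)
        mask[2:5, 1:5] = 1
        contour = trace_boundary(mask)
        np.testing.assert_array_equal(contour.points[0], [1.0, 2.0])  # (x=col, y=row)


# ---------------------------------------------------------------------------
# resampling

class TestResample:
    def test_square_corners_to_midpoints(self):
        square = Contour(np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float), closed=True)
        out = resample_contour(square, 8)
        expected = [[0, 0], [0.5, 0], [1, 0], [1, 0.5], [1, 1], [0.5, 1], [0, 1], [0, 0.5]]
        np.testing.assert_allclose(out.points, expected, atol=1e-12)

    def test_identity_on_uniform_spacing(self):
        c = make_regular_polygon(3, 2)  # 3 nodes, equal sides
        out = resample_contour(c, 3)
        np.testing.assert_allclose(out.points, c.points, atol=1e-12)

    def test_circle_radial_distance(self):
        t = np.linspace(0, 2 * np.pi, 100, endpoint=False)
        circle = Contour(np.column_stack([np.cos(t), np.sin(t)]), closed=True)
        out = resample_contour(circle, 1000)
        radii = np.linalg.norm(out.points, axis=1)
        assert np.abs(radii - 1.0).max() < 1e-3

    def test_first_node_preserved(self):
        c = make_random_polygon(8, 3, 50)
        out = resample_contour(c, 200)
        np.testing.assert_array_equal(out.points[0], c.points[0])

    def test_open_contour_keeps_endpoints(self):
        line = make_segmented_line(5, 9, 1.0)
        out = resample_contour(line, 20)
        np.testing.assert_allclose(out.points[-1], line.points[-1], atol=1e-12)

    @pytest.mark.parametrize("n_sides", [3, 5, 8, 12])
    def test_arc_length_preserved_within_1pct_regular(self, n_sides):
        c = make_regular_polygon(n_sides, 2)  # vertex-only contour
        dense = resample_contour(c, 10 * n_sides)
        assert abs(dense.arc_length() - c.arc_length()) / c.arc_length() < 0.01

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_arc_length_preserved_random_polygons(self, seed):
        # spiky random polygons cut more corner per sample; 30x oversampling
        # keeps the 1% bound with margin
        c = make_random_polygon(10, seed, 11)
        dense = resample_contour(c, 330)
        assert abs(dense.arc_length() - c.arc_length()) / c.arc_length() < 0.01

    def test_zero_length_error(self):
        with pytest.raises(ContourError):
            resample_contour(
                Contour(np.array([[0.0, 0.0], [1e-300, 0.0]]), closed=False), 10
            )


# ---------------------------------------------------------------------------
# I/O

class TestContourCSV:
    def test_round_trip(self, tmp_path, rng):
        c = make_random_polygon(9, 4, 123)
        path = tmp_path / "c.csv"
        write_contour_csv(c, path)
        back = read_contour_csv(path)
        np.testing.assert_array_equal(back.points, c.points)

    def test_two_rows_too_small(self, tmp_path):
        path = tmp_path / "tiny.csv"
        path.write_text("x,y\n0,0\n1,1\n")
        with pytest.raises(TooSmallError):
            read_contour_csv(path)

    def test_non_numeric_cell_names_line(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("0,0\n1,zap\n2,2\n")
        with pytest.raises(ParseError, match=":2:"):
            read_contour_csv(path)

    def test_headerless_file(self, tmp_path):
        path = tmp_path / "nohdr.csv"
        path.write_text("0,0\n1,0\n0.5,1\n")
        assert len(read_contour_csv(path)) == 3


class TestRasterize:
    def test_round_trip_through_tracing(self):
        c = make_regular_polygon(4, 50)
        mask = rasterize_contour(c, image_size=64)
        traced = trace_boundary(mask)
        assert traced.signed_area() > 0
        assert len(traced) > 50

    def test_open_contour_rejected(self):
        with pytest.raises(ContourError):
            rasterize_contour(make_segmented_line(5, 5, 1.0))
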