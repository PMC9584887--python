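"""Electrode geometry: construction, exact measurement, gap topology."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fractalmea.geometry import (
    ElectrodeLayout,
    GeometryIntegrityError,
    GridSpec,
    HTreeSpec,
    PAPER_GRID,
    PAPER_HTREE,
    ParameterError,
    build_grid,
    build_htree,
    export_layout,
    gap_metrics,
    grid_analytic_area_perimeter,
    htree_analytic_area_perimeter,
    import_layout_csv,
    import_layout_geojson,
    measure_geometry,
    rasterize_layout,
    union_area_perimeter,
)


class TestHTreeConstruction:
    @pytest.mark.parametrize("m", [1, 2, 3, 4, 5, 6])
    def test_branch_and_junction_counts(self, m):
        spec = HTreeSpec(D=2.0, m=m, W_CNT=1.0, W=100.0)
        layout = build_htree(spec)
        assert layout.n_rectangles == 2 ** (2 * m) - 1
        # every rectangle except the seed has exactly one parent junction
        assert layout.n_rectangles - 1 == 2 ** (2 * m) - 2

    def test_seed_length_paper_design(self, paper_htree_layout):
        # closed form: L1 = (W - W_CNT) * 16/31 for D=2, m=5
        spec = paper_htree_layout.spec
        assert spec.L1 == pytest.approx((6260 - 20) * 16 / 31, rel=1e-12)
        assert spec.L1 == pytest.approx(3220.645161, rel=1e-9)

    def test_seed_length_smallest_h(self):
        # m=1: the only horizontal generation is the seed, so the
        # centreline extent is L1 itself and W = L1 + W_CNT
        spec = HTreeSpec(D=2.0, m=1, W_CNT=20.0, W=120.0)
        layout = build_htree(spec)
        assert layout.n_rectangles == 3
        assert spec.L1 == pytest.approx(100.0)
        x0, _, x1, _ = layout.bounds
        assert x1 - x0 == pytest.approx(spec.W)
        # children are vertical, perpendicular to the seed, length L1*r
        child_lengths = [s.length for s in layout.segments if s.generation == 2]
        assert child_lengths == pytest.approx([100 / math.sqrt(2)] * 2)

    def test_total_centerline_length_closed_form(self, paper_htree_layout):
        spec = paper_htree_layout.spec
        brute = sum(s.length for s in paper_htree_layout.segments)
        assert spec.total_centerline_length == pytest.approx(brute, rel=1e-12)
        assert brute == pytest.approx(241035.082, abs=0.01)

    def test_overall_width_is_w(self, paper_htree_layout):
        x0, _, x1, _ = paper_htree_layout.bounds
        assert x1 - x0 == pytest.approx(PAPER_HTREE.W, rel=1e-12)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(D=2.0, m=0, W_CNT=20.0, W=100.0),
            dict(D=2.5, m=2, W_CNT=20.0, W=100.0),
            dict(D=2.0, m=2, W_CNT=120.0, W=100.0),
            dict(D=-1.0, m=2, W_CNT=20.0, W=100.0),
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            HTreeSpec(**kwargs)


class TestGridConstruction:
    def test_paper_design_chambers(self, paper_grid_layout):
        spec = paper_grid_layout.spec
        assert spec.chamber_side == pytest.approx((3510 - 44 * 20) / 43)
        assert spec.chamber_side == pytest.approx(61.163, abs=1e-3)
        assert paper_grid_layout.n_rectangles == 2 * (43 + 1)

    def test_single_chamber_closed_form(self):
        layout = build_grid(GridSpec(W=100.0, n=1, W_CNT=20.0))
        rep = measure_geometry(layout)
        assert rep.A_Si == pytest.approx((100 - 2 * 20) ** 2)  # 3600
        assert rep.A_Si == pytest.approx(3600.0)

    def test_two_chamber_raster_matches_closed_form(self):
        layout = build_grid(GridSpec(W=180.0, n=2, W_CNT=20.0))
        mask, _ = rasterize_layout(layout, 0.1)
        gap_area = float((~mask).sum()) * 0.1**2
        assert gap_area == pytest.approx((180 - 3 * 20) ** 2, rel=2e-3)  # 14400

    def test_invalid_grid_rejected(self):
        with pytest.raises(ParameterError):
            GridSpec(W=100.0, n=4, W_CNT=20.0)  # walls exactly fill the square


class TestExactMeasurement:
    def test_single_rectangle(self):
        area, perim = union_area_perimeter(np.array([[0.0, 0.0, 100.0, 20.0]]))
        assert area == pytest.approx(2000.0)
        assert perim == pytest.approx(240.0)

    def test_paper_fractal_values(self, paper_htree_layout):
        rep = measure_geometry(paper_htree_layout)
        a_ref, e_ref = htree_analytic_area_perimeter(PAPER_HTREE)
        assert rep.A_CNT == pytest.approx(a_ref, rel=1e-12)
        assert rep.E == pytest.approx(e_ref, rel=1e-12)
        # frozen closed-form values for the printed design
        assert rep.E == pytest.approx(461670.164, abs=0.01)
        assert rep.A_CNT == pytest.approx(4616301.641, abs=0.01)
        assert rep.A_bounding == pytest.approx(6260.0**2 / math.sqrt(2), rel=1e-12)
        assert rep.W_Si_max == pytest.approx(3220.645161, abs=1e-3)
        # E and A_CNT print in a 10:1 ratio: E ~ 2*A_CNT/W_CNT
        assert rep.E == pytest.approx(2 * rep.A_CNT / 20.0, rel=1e-3)

    def test_paper_grid_values(self, paper_grid_layout):
        rep = measure_geometry(paper_grid_layout)
        a_ref, e_ref = grid_analytic_area_perimeter(PAPER_GRID)
        assert rep.A_CNT == pytest.approx(a_ref, rel=1e-12)
        assert rep.E == pytest.approx(e_ref, rel=1e-12)
        assert rep.E == pytest.approx(466400.0)
        assert rep.A_Si == pytest.approx(6916900.0)
        assert rep.area_ratio == pytest.approx(1.280, abs=2e-3)

    def test_partition_identity(self, paper_htree_layout, paper_grid_layout):
        for layout in (paper_htree_layout, paper_grid_layout):
            rep = measure_geometry(layout)
            assert rep.A_CNT + rep.A_Si == pytest.approx(rep.A_bounding, rel=1e-14)

    def test_edge_lengths_standardized(self, paper_htree_layout, paper_grid_layout):
        # the two designs were matched on total edge length
        e_f = measure_geometry(paper_htree_layout).E
        e_g = measure_geometry(paper_grid_layout).E
        assert abs(e_f - e_g) / e_g < 0.02

    def test_shapely_cross_check(self, small_htree_layout):
        shapely = pytest.importorskip("shapely")
        from shapely.geometry import box
        from shapely.ops import unary_union

        u = unary_union([box(*r) for r in small_htree_layout.rectangles])
        area, perim = union_area_perimeter(small_htree_layout.rectangles)
        assert area == pytest.approx(u.area, rel=1e-9)
        assert perim == pytest.approx(u.length, rel=1e-9)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        D=st.floats(1.5, 2.0),
        m=st.integers(1, 4),
        w=st.floats(2000.0, 20000.0),
    )
    def test_sweep_union_equals_analytic(self, D, m, w):
        # branches must stay thin relative to the terminal gaps or
        # sibling rectangles would physically overlap
        spec = HTreeSpec(D=D, m=m, W_CNT=1.0, W=w)
        layout = build_htree(spec)
        area, perim = union_area_perimeter(layout.rectangles)
        a_ref, e_ref = htree_analytic_area_perimeter(spec)
        assert area == pytest.approx(a_ref, rel=1e-9)
        assert perim == pytest.approx(e_ref, rel=1e-9)

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(s=st.floats(0.1, 10.0))
    def test_affine_scaling(self, s, small_htree_layout):
        rep = measure_geometry(small_htree_layout)
        area, perim = union_area_perimeter(small_htree_layout.scaled(s).rectangles)
        assert area == pytest.approx(rep.A_CNT * s**2, rel=1e-9)
        assert perim == pytest.approx(rep.E * s, rel=1e-9)

    @pytest.mark.parametrize("resolution", [1.0, 0.5, 0.25])
    def test_raster_convergence(self, resolution, small_htree_layout):
        rep = measure_geometry(small_htree_layout)
        mask, _ = rasterize_layout(small_htree_layout, resolution)
        raster_area = float(mask.sum()) * resolution**2
        assert abs(raster_area - rep.A_CNT) <= rep.E * resolution

    def test_overlapping_construction_detected(self, small_htree_layout):
        # doubling a branch rectangle breaks the junction-overlap identity
        rects = np.vstack(
            [small_htree_layout.rectangles, small_htree_layout.rectangles[5:6] + 1.0]
        )
        bad = ElectrodeLayout(
            kind="htree",
            rectangles=rects,
            generations=np.zeros(len(rects), dtype=int),
            spec=small_htree_layout.spec,
        )
        with pytest.raises(GeometryIntegrityError):
            measure_geometry(bad)


class TestGapMetrics:
    def test_parallel_bars_corridor_width(self):
        # two 20 um bars separated edge-to-edge by 60 um
        spec = GridSpec(W=200.0, n=1, W_CNT=20.0)
        layout = ElectrodeLayout(
            kind="grid",
            rectangles=np.array(
                [[-100.0, -50.0, 100.0, -30.0], [-100.0, 30.0, 100.0, 50.0]]
            ),
            generations=np.zeros(2, dtype=int),
            spec=spec,
        )
        res = 0.5
        stats = gap_metrics(layout, resolution=res)
        assert stats.n_gap_components == 1
        assert stats.W_Si_min_measured == pytest.approx(60.0, abs=2 * res)

    def test_small_grid_components(self, small_grid_layout):
        stats = gap_metrics(small_grid_layout, resolution=1.0, compute_corridors=False)
        assert stats.n_gap_components == 25  # 5x5 disconnected chambers
        assert stats.largest_gap_fraction == pytest.approx(1 / 25, rel=0.05)

    def test_small_htree_connected(self, small_htree_layout):
        stats = gap_metrics(small_htree_layout, resolution=1.0, compute_corridors=False)
        assert stats.n_gap_components == 1
        assert stats.largest_gap_fraction == 1.0
        assert stats.mean_gap_distance > 0

    def test_resolution_guard(self, small_grid_layout):
        with pytest.raises(ParameterError):
            gap_metrics(small_grid_layout, resolution=10.0)


class TestExport:
    def test_csv_roundtrip(self, small_htree_layout, tmp_path):
        p = export_layout(small_htree_layout, tmp_path / "layout.csv")
        back = import_layout_csv(p, "htree", small_htree_layout.spec)
        np.testing.assert_array_equal(back.rectangles, small_htree_layout.rectangles)
        np.testing.assert_array_equal(back.generations, small_htree_layout.generations)

    def test_geojson_roundtrip(self, small_htree_layout, tmp_path):
        p = export_layout(small_htree_layout, tmp_path / "layout.geojson")
        back = import_layout_geojson(p, small_htree_layout.spec)
        assert back.n_rectangles == small_htree_layout.n_rectangles
        np.testing.assert_allclose(back.rectangles, small_htree_layout.rectangles)

    def test_svg_strip_count(self, small_grid_layout, tmp_path):
        p = export_layout(small_grid_layout, tmp_path / "layout.svg")
        text = p.read_text()
        n = small_grid_layout.spec.n
        assert text.count("<rect") == 2 * (n + 1)

    def test_unknown_format(self, small_grid_layout, tmp_path):
        with pytest.raises(ParameterError):
            export_layout(small_grid_layout, tmp_path / "layout.xyz")
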