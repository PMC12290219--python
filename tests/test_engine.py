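"""Engine: edge costs, multi-source travel time, nearest-source labels."""

import math

import numpy as np
import pytest

import traveltime as tt
from conftest import random_surface
from oracle import bellman_ford_minutes

RES = tt.RES_30_ARCSEC


def planar_surface(values, res=1000.0):
    values = np.asarray(values, dtype=float)
    nrow, ncol = values.shape
    grid = tt.GridSpec(
        extent=tt.Extent(0.0, ncol * res, 0.0, nrow * res),
        resolution_x=res,
        resolution_y=res,
        nrow=nrow,
        ncol=ncol,
        crs_kind="planar",
    )
    return tt.FrictionSurface(grid, values)


class TestEdgeCost:
    def test_hand_arithmetic_for_both_averagings(self):
        """f=(0.01, 0.03) over 1000 m: 20 min arithmetic, 15 min harmonic."""
        surf = planar_surface([[0.01, 0.03]])
        a, b = tt.CellIndex(0, 0), tt.CellIndex(0, 1)
        assert tt.edge_cost(surf, a, b, tt.EdgeModel("mean_friction")) == pytest.approx(20.0)
        assert tt.edge_cost(surf, a, b, tt.EdgeModel("mean_conductance")) == pytest.approx(15.0)

    def test_equal_frictions_make_averagings_coincide(self):
        surf = planar_surface([[0.02, 0.02]])
        a, b = tt.CellIndex(0, 0), tt.CellIndex(0, 1)
        assert tt.edge_cost(surf, a, b, tt.EdgeModel("mean_friction")) == pytest.approx(
            tt.edge_cost(surf, a, b, tt.EdgeModel("mean_conductance")), rel=1e-15
        )

    def test_equator_step_uses_geodesic_length(self):
        surf = tt.synth_friction(1, 2, "uniform", 0.01)  # equatorial 30-arcsec cells
        cost = tt.edge_cost(surf, tt.CellIndex(0, 0), tt.CellIndex(0, 1))
        # cell centers sit half a cell north of the equator, so the flat
        # R*dlon closed form is only good to ~cos(1/240 deg)
        expected = 0.01 * tt.EARTH_RADIUS_M * math.radians(RES)  # ~ f * 926.63
        assert cost == pytest.approx(expected, rel=1e-6)

    def test_symmetric_and_positive(self):
        surf = planar_surface([[0.01, 0.03], [0.05, 0.02]])
        a, b = tt.CellIndex(0, 0), tt.CellIndex(1, 1)
        assert tt.edge_cost(surf, a, b) == pytest.approx(tt.edge_cost(surf, b, a))
        assert tt.edge_cost(surf, a, b) > 0

    def test_masked_endpoint_means_no_edge(self):
        base = tt.synth_friction(2, 2, "uniform", 0.01)
        mask = np.zeros((2, 2), dtype=bool)
        mask[0, 1] = True
        surf = tt.FrictionSurface(base.grid, base.values, mask)
        with pytest.raises(tt.ValidationError, match="no edge"):
            tt.edge_cost(surf, tt.CellIndex(0, 0), tt.CellIndex(0, 1))

    def test_non_neighbors_rejected(self):
        surf = planar_surface(np.full((3, 3), 0.01))
        with pytest.raises(tt.ValidationError, match="not 8-neighbors"):
            tt.edge_cost(surf, tt.CellIndex(0, 0), tt.CellIndex(0, 2))


class TestSourceSet:
    def test_duplicate_cells_collapse(self):
        surf = tt.synth_friction(4, 4, "uniform", 0.01)
        c = surf.grid.cell_center(tt.CellIndex(1, 1))
        nudged = (c[0] + RES / 10, c[1] - RES / 10)  # same cell
        ss = tt.SourceSet.from_points([c, nudged], surf.grid, surf.nodata_mask)
        assert len(ss.points) == 2
        assert ss.cells == [tt.CellIndex(1, 1)]
        assert ss.cell_point_index == [0]

    def test_empty_points_rejected(self):
        surf = tt.synth_friction(3, 3, "uniform", 0.01)
        with pytest.raises(tt.ValidationError, match="empty"):
            tt.SourceSet.from_points([], surf.grid, surf.nodata_mask)

    def test_point_outside_extent_is_hard_error(self):
        surf = tt.synth_friction(3, 3, "uniform", 0.01)
        with pytest.raises(tt.OutOfBoundsError, match="outside"):
            tt.SourceSet.from_points([(99.0, 99.0)], surf.grid, surf.nodata_mask)

    def test_source_on_masked_cell_is_hard_error(self):
        surf = tt.synth_friction(5, 5, "corridor_with_barrier", 0.01)
        barrier_center = surf.grid.cell_center(tt.CellIndex(2, 2))
        with pytest.raises(tt.ValidationError, match="masked"):
            tt.SourceSet.from_points([barrier_center], surf.grid, surf.nodata_mask)

    def test_drop_bad_keeps_valid_points_with_warning(self):
        surf = tt.synth_friction(5, 5, "corridor_with_barrier", 0.01)
        good = surf.grid.cell_center(tt.CellIndex(2, 0))
        bad = surf.grid.cell_center(tt.CellIndex(2, 2))
        with pytest.warns(UserWarning, match="dropped 2"):
            ss = tt.SourceSet.from_points(
                [bad, good, (99.0, 99.0)], surf.grid, surf.nodata_mask, drop_bad=True
            )
        assert ss.cells == [tt.CellIndex(2, 0)]

    def test_all_points_bad_still_errors_even_when_dropping(self):
        surf = tt.synth_friction(5, 5, "corridor_with_barrier", 0.01)
        bad = surf.grid.cell_center(tt.CellIndex(2, 2))
        with pytest.raises(tt.ValidationError, match="no usable source"):
            with pytest.warns(UserWarning):
                tt.SourceSet.from_points([bad], surf.grid, surf.nodata_mask, drop_bad=True)


class TestCalculateTravelTime:
    def test_equator_strip_matches_haversine_closed_form(self):
        """1x3 uniform strip at f=0.01: ~ (0, 9.2663, 18.5326) minutes."""
        surf = tt.synth_friction(1, 3, "uniform", 0.01)
        src = surf.grid.cell_center(tt.CellIndex(0, 0))
        result = tt.calculate_travel_time(surf, [src])
        step = 0.01 * tt.EARTH_RADIUS_M * math.radians(RES)
        assert result.minutes[0] == pytest.approx([0.0, step, 2 * step], rel=1e-6)
        assert result.minutes[0, 1] == pytest.approx(9.2663, abs=1e-3)

    def test_source_cell_is_exactly_zero_and_is_the_minimum(self):
        surf = tt.synth_friction(7, 7, "random", 0.01, seed=6)
        src_cell = tt.CellIndex(3, 4)
        result = tt.calculate_travel_time(surf, [surf.grid.cell_center(src_cell)])
        assert result.minutes[3, 4] == 0.0
        assert np.nanmin(result.minutes) == 0.0
        assert np.all(result.minutes[~result.nodata_mask] >= 0)

    def test_octile_closed_form_on_uniform_planar_grid(self):
        """Planar uniform friction: time = f*s*(sqrt2*min(|dr|,|dc|) + |max-min|)."""
        f, s = 0.02, 500.0
        surf = planar_surface(np.full((9, 11), f), res=s)
        src = tt.CellIndex(4, 5)
        result = tt.calculate_travel_time(
            surf, [surf.grid.cell_center(src)], tt.EdgeModel(distance_mode="planar")
        )
        rows, cols = np.indices(surf.grid.shape)
        dr = np.abs(rows - src.row)
        dc = np.abs(cols - src.col)
        expected = f * s * (math.sqrt(2) * np.minimum(dr, dc) + np.abs(dr - dc))
        np.testing.assert_allclose(result.minutes, expected, rtol=1e-12)

    def test_barrier_makes_far_side_infinite(self):
        """Cells disconnected from every source get +inf, like unlinked islands."""
        surf = tt.synth_friction(6, 7, "corridor_with_barrier", 0.012)
        bcol = 7 // 2
        west_src = surf.grid.cell_center(tt.CellIndex(2, 0))
        result = tt.calculate_travel_time(surf, [west_src])
        assert np.isinf(result.minutes[:, bcol + 1:]).all()
        assert np.isfinite(result.minutes[:, :bcol]).all()
        assert np.isnan(result.minutes[:, bcol]).all()  # the barrier itself is nodata
        assert result.n_infinite == 6 * (7 - bcol - 1)

    def test_multi_source_equals_pointwise_min_of_single_source_runs(self):
        rng = np.random.default_rng(7)
        surf = random_surface(rng, 8, 9, mask_prob=0.15)
        cells = [tt.CellIndex(0, 0), tt.CellIndex(7, 8), tt.CellIndex(3, 4)]
        cells = [c for c in cells if not surf.nodata_mask[c.row, c.col]]
        pts = [surf.grid.cell_center(c) for c in cells]
        combined = tt.calculate_travel_time(surf, pts).minutes
        singles = np.stack(
            [tt.calculate_travel_time(surf, [p]).minutes for p in pts]
        )
        np.testing.assert_allclose(combined, np.min(singles, axis=0), rtol=1e-12)

    def test_adding_a_source_never_increases_any_cell(self):
        rng = np.random.default_rng(8)
        surf = random_surface(rng, 8, 8, mask_prob=0.1)
        open_cells = np.argwhere(~surf.nodata_mask)
        p1 = surf.grid.cell_center(tt.CellIndex(*open_cells[0]))
        p2 = surf.grid.cell_center(tt.CellIndex(*open_cells[-1]))
        base = tt.calculate_travel_time(surf, [p1]).minutes
        more = tt.calculate_travel_time(surf, [p1, p2]).minutes
        ok = ~np.isnan(base)
        assert np.all(more[ok] <= base[ok] + 1e-12)

    def test_raising_one_cells_friction_never_decreases_any_cell(self):
        rng = np.random.default_rng(9)
        surf = random_surface(rng, 7, 7)
        src = surf.grid.cell_center(tt.CellIndex(0, 0))
        base = tt.calculate_travel_time(surf, [src]).minutes
        bumped_values = surf.values.copy()
        bumped_values[3, 3] *= 10.0
        bumped = tt.FrictionSurface(surf.grid, bumped_values, surf.nodata_mask)
        after = tt.calculate_travel_time(bumped, [src]).minutes
        assert np.all(after >= base - 1e-12)

    def test_scaling_friction_scales_travel_time(self):
        rng = np.random.default_rng(10)
        surf = random_surface(rng, 6, 6, mask_prob=0.1)
        open_cells = np.argwhere(~surf.nodata_mask)
        src = surf.grid.cell_center(tt.CellIndex(*open_cells[0]))
        base = tt.calculate_travel_time(surf, [src]).minutes
        c = 3.5
        scaled = tt.FrictionSurface(surf.grid, surf.values * c, surf.nodata_mask)
        after = tt.calculate_travel_time(scaled, [src]).minutes
        finite = np.isfinite(base)
        np.testing.assert_allclose(after[finite], c * base[finite], rtol=1e-12)
        assert np.array_equal(np.isinf(after), np.isinf(base))

    def test_result_independent_of_source_ordering(self):
        rng = np.random.default_rng(11)
        surf = random_surface(rng, 8, 8, mask_prob=0.1)
        open_cells = np.argwhere(~surf.nodata_mask)
        pts = [surf.grid.cell_center(tt.CellIndex(*rc)) for rc in open_cells[:4]]
        fwd = tt.calculate_travel_time(surf, pts).minutes
        rev = tt.calculate_travel_time(surf, pts[::-1]).minutes
        np.testing.assert_array_equal(fwd, rev)

    @pytest.mark.parametrize("averaging", ["mean_friction", "mean_conductance"])
    @pytest.mark.parametrize("planar", [False, True])
    def test_matches_bellman_ford_oracle_on_random_instances(self, averaging, planar):
        """Engine equals explicit edge-list Bellman-Ford on random masked grids."""
        rng = np.random.default_rng(123 if planar else 321)
        for _ in range(15):
            nrow, ncol = rng.integers(2, 13, size=2)
            surf = random_surface(rng, int(nrow), int(ncol),
                                  mask_prob=float(rng.uniform(0, 0.4)), planar=planar)
            open_cells = np.argwhere(~surf.nodata_mask)
            if len(open_cells) == 0:
                continue
            picks = open_cells[rng.integers(0, len(open_cells), size=rng.integers(1, 4))]
            cells = [tt.CellIndex(int(r), int(c)) for r, c in picks]
            pts = [surf.grid.cell_center(c) for c in cells]
            model = tt.EdgeModel(averaging=averaging)
            got = tt.calculate_travel_time(surf, pts, model).minutes
            want = bellman_ford_minutes(surf, cells, averaging=averaging)
            assert np.array_equal(np.isnan(got), np.isnan(want))
            assert np.array_equal(np.isinf(got), np.isinf(want))
            finite = np.isfinite(got)
            np.testing.assert_allclose(got[finite], want[finite], rtol=1e-9)


class TestNearestSourceLabels:
    def test_single_source_labels_all_reachable_cells(self):
        surf = tt.synth_friction(5, 5, "corridor_with_barrier", 0.01)
        src = surf.grid.cell_center(tt.CellIndex(2, 0))
        labels = tt.nearest_source_labels(surf, [src])
        west = labels[:, :2]
        assert np.all(west == 0)
        assert np.all(labels[:, 2:] == -1)  # barrier plus unreachable east side

    def test_exact_tie_goes_to_lower_source_index(self):
        surf = tt.synth_friction(1, 5, "uniform", 0.01)
        p0 = surf.grid.cell_center(tt.CellIndex(0, 0))
        p1 = surf.grid.cell_center(tt.CellIndex(0, 4))
        labels = tt.nearest_source_labels(surf, [p0, p1])
        assert labels[0, 2] == 0  # midpoint equidistant, lower index wins
        assert labels[0, 1] == 0 and labels[0, 3] == 1

    def test_labels_agree_with_argmin_over_single_source_runs(self):
        rng = np.random.default_rng(12)
        surf = random_surface(rng, 10, 10, mask_prob=0.2)
        open_cells = np.argwhere(~surf.nodata_mask)
        picks = open_cells[:: max(1, len(open_cells) // 4)][:4]
        pts = [surf.grid.cell_center(tt.CellIndex(*rc)) for rc in picks]
        labels = tt.nearest_source_labels(surf, pts)
        singles = np.stack([tt.calculate_travel_time(surf, [p]).minutes for p in pts])
        singles = np.where(np.isnan(singles), np.inf, singles)
        expected = np.argmin(singles, axis=0)
        expected[~np.isfinite(np.min(singles, axis=0))] = -1
        expected[surf.nodata_mask] = -1
        assert np.array_equal(labels, expected)

    def test_duplicate_points_label_by_first_occurrence(self):
        surf = tt.synth_friction(3, 3, "uniform", 0.01)
        c = surf.grid.cell_center(tt.CellIndex(1, 1))
        labels = tt.nearest_source_labels(surf, [c, c])
        assert np.all(labels == 0)
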