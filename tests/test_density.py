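"""Hexagon-normalized density maps."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from centriole_polarity import (
    CellGeometry,
    CentrioleRecord,
    HexReferenceFrame,
    build_density_map,
    compare_density_maps,
    normalize_offset,
)

FRAME = HexReferenceFrame()


def hex_cell(area, label=1):
    """Synthetic CellGeometry carrying only what normalization reads."""
    return CellGeometry(label=label, centroid=(0.0, 0.0), area_px=area,
                        axial_min=-1.0, axial_max=1.0,
                        boundary=np.zeros((0, 2)))


def rec(dx, dy, label=1):
    return CentrioleRecord(position=(dx, dy), cell_label=label,
                           offset=(dx, dy))


class TestNormalizeOffset:
    def test_centroid_maps_to_center(self):
        cell = hex_cell(area=123)
        assert normalize_offset(rec(0, 0), cell, FRAME) == (0.0, 0.0)

    def test_identity_when_area_equals_reference(self):
        cell = hex_cell(area=FRAME.area)
        u, v = normalize_offset(rec(0.3, 0.0), cell, FRAME)
        assert (u, v) == pytest.approx((0.3, 0.0))

    def test_sqrt_area_scaling_halves_lengths(self):
        cell = hex_cell(area=4 * FRAME.area)
        u, v = normalize_offset(rec(2.0, 0.0), cell, FRAME)
        assert (u, v) == pytest.approx((1.0, 0.0))

    def test_out_of_hexagon_points_clamped_to_boundary(self):
        cell = hex_cell(area=FRAME.area)
        u, v = normalize_offset(rec(5.0, 0.0), cell, FRAME)
        assert (u, v) == pytest.approx((FRAME.circumradius, 0.0))

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError, match="zero area"):
            normalize_offset(rec(1, 0), hex_cell(area=0), FRAME)

    @given(
        dx=st.floats(min_value=-20, max_value=20),
        dy=st.floats(min_value=-20, max_value=20),
        area=st.floats(min_value=10, max_value=5000),
    )
    def test_direction_preserved_exactly(self, dx, dy, area):
        """Normalization must not rotate offsets, clamped or not, so the
        quartile assignment is invariant under it."""
        if dx == 0 and dy == 0:
            return
        u, v = normalize_offset(rec(dx, dy), hex_cell(int(area) + 1), FRAME)
        assert math.atan2(v, u) == pytest.approx(math.atan2(dy, dx), abs=1e-9)

    def test_scale_equivariance(self):
        s = 3.0
        u1, _ = normalize_offset(rec(0.2, 0.0), hex_cell(100), FRAME)
        u2, _ = normalize_offset(rec(0.2, 0.0), hex_cell(int(100 * s**2)), FRAME)
        assert u2 == pytest.approx(u1 / s)


class TestBuildDensityMap:
    def test_single_central_centriole_is_a_delta(self):
        cell = hex_cell(area=FRAME.area)
        dm = build_density_map([rec(0, 0)], [cell], FRAME, smoothing_sigma=0)
        assert dm.grid.sum() == pytest.approx(1.0)
        assert dm.grid.max() == 1.0
        assert dm.grid[50, 50] == 1.0  # centre pixel of the 101x101 raster

    def test_grid_sums_to_one_with_and_without_smoothing(self, scored_small):
        _, cells, records, _, _ = scored_small
        for sigma in (0.0, 2.0):
            dm = build_density_map(records, cells, FRAME, smoothing_sigma=sigma)
            assert dm.grid.sum() == pytest.approx(1.0)
            assert dm.n_centrioles == len(records)

    def test_outside_hexagon_is_zero(self, scored_small):
        _, cells, records, _, _ = scored_small
        dm = build_density_map(records, cells, FRAME, smoothing_sigma=2.0)
        assert np.all(dm.grid[~FRAME.footprint()] == 0.0)
        assert np.all(dm.grid >= 0.0)

    def test_uniform_sampling_is_uniform_within_multinomial_error(self):
        """The in-hexagon histogram of 50k uniform points is consistent
        with the flat multinomial expectation (chi-square on pixels fully
        interior to the hexagon; edge pixels only partially overlap it)."""
        from scipy import ndimage, stats

        rng = np.random.default_rng(13)
        n = 50_000
        pts = _uniform_hex_points(rng, n)
        cell = hex_cell(area=FRAME.area)
        records = [rec(x, y) for x, y in pts]
        dm = build_density_map(records, [cell], FRAME, smoothing_sigma=0)
        core = ndimage.binary_erosion(FRAME.footprint(), iterations=2)
        counts = dm.grid[core] * n
        result = stats.chisquare(counts)  # flat expectation
        assert result.pvalue > 1e-3

    def test_polarized_field_shifts_center_of_mass_distally(self):
        from centriole_polarity import (
            SimulationConfig,
            assign_centrioles,
            extract_cell_geometries,
            generate_epithelium,
        )

        coms = {}
        for kappa in (4.0, 0.0):
            cfg = SimulationConfig(n_cells_x=12, n_cells_y=8,
                                   polarization_kappa=kappa, seed=21)
            mask, table, _ = generate_epithelium(cfg)
            cells = extract_cell_geometries(mask)
            records, _ = assign_centrioles(
                mask, cells, list(zip(table["x"], table["y"])))
            coms[kappa] = build_density_map(records, cells,
                                            FRAME).center_of_mass()
        assert coms[4.0][0] > coms[0.0][0]

    def test_zero_records_rejected(self):
        with pytest.raises(ValueError):
            build_density_map([], [hex_cell(10)], FRAME)


class TestCompareDensityMaps:
    def test_map_against_itself(self, scored_small):
        _, cells, records, _, _ = scored_small
        dm = build_density_map(records, cells, FRAME)
        comp = compare_density_maps(dm, dm)
        assert comp.tv_distance == 0.0
        assert comp.displacement == (0.0, 0.0)

    def test_disjoint_deltas_have_tv_distance_one(self):
        cell = hex_cell(area=FRAME.area)
        center = build_density_map([rec(0, 0)], [cell], FRAME, smoothing_sigma=0)
        vertex = build_density_map([rec(5.0, 0.0)], [cell], FRAME,
                                   smoothing_sigma=0)
        comp = compare_density_maps(center, vertex)
        assert comp.tv_distance == 1.0
        assert comp.displacement[0] > 0.9

    def test_independent_uniform_samples_are_close(self):
        """Two smoothed maps of 50k uniform points differ by TV < 0.05."""
        cell = hex_cell(area=FRAME.area)
        maps = []
        for seed in (101, 202):
            rng = np.random.default_rng(seed)
            pts = _uniform_hex_points(rng, 50_000)
            maps.append(build_density_map([rec(x, y) for x, y in pts],
                                          [cell], FRAME))
        assert compare_density_maps(*maps).tv_distance < 0.05

    def test_shape_mismatch_rejected(self):
        cell = hex_cell(area=FRAME.area)
        small = HexReferenceFrame(raster_shape=(51, 51))
        a = build_density_map([rec(0, 0)], [cell], FRAME)
        b = build_density_map([rec(0, 0)], [cell], small)
        with pytest.raises(ValueError, match="shape mismatch"):
            compare_density_maps(a, b)


def _uniform_hex_points(rng, n):
    """Rejection-sample n points uniform in the reference hexagon."""
    out = []
    R = FRAME.circumradius
    while len(out) < n:
        cand = rng.uniform(-R, R, size=(2 * n, 2))
        keep = FRAME.contains(cand[:, 0], cand[:, 1], tol=-1e-9)
        out.extend(map(tuple, cand[keep]))
    return out[:n]
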