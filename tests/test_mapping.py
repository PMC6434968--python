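import numpy as np
import pytest
import shapely

from cordstim.field import Montage, superpose
from cordstim.mapping import (ALL_SIZES, LARGE_ONLY, MEDIAL_AND_LARGE, NONE,
                              build_grid, max_activation_depth, scan)


@pytest.fixture(scope="module")
def grid(geom):
    return build_grid(geom, spacing=0.25)


def _sol(basis, scale):
    cur = np.zeros(12)
    cur[[2, 3]] = -0.5 * scale
    cur[[0, 5]] = 0.5 * scale
    return superpose(basis, Montage(cur))


def test_grid_points_in_correct_regions(geom, grid):
    w, g = geom.white_matter_outline, geom.gray_matter_outline
    assert np.all(shapely.contains_xy(w, grid.white_points[:, 0],
                                      grid.white_points[:, 1]))
    assert not np.any(shapely.contains_xy(g, grid.white_points[:, 0],
                                          grid.white_points[:, 1]))
    assert np.all(shapely.contains_xy(g, grid.gray_points[:, 0],
                                      grid.gray_points[:, 1]))
    assert grid.cell_area_mm2 == pytest.approx(0.0625)


def test_gray_margin_subsets_gray(geom):
    full = build_grid(geom, spacing=0.25)
    banded = build_grid(geom, spacing=0.25, gray_margin=0.3)
    assert len(banded.gray_points) < len(full.gray_points)


def test_zero_montage_maps_to_none(coarse_basis, grid):
    amap = scan(_sol(coarse_basis, 0.0), grid)
    assert np.all(amap.labels == NONE)
    assert not amap.any_gray
    assert amap.total_activated_area_mm2 == 0.0


def test_label_nesting_and_area_accounting(coarse_basis, grid):
    amap = scan(_sol(coarse_basis, 4.0), grid)
    areas = amap.class_areas_mm2()
    assert areas[0] <= areas[1] <= areas[2]
    total = sum(amap.area_mm2(c) for c in
                (LARGE_ONLY, MEDIAL_AND_LARGE, ALL_SIZES))
    assert total == pytest.approx(amap.total_activated_area_mm2)
    summary = amap.summary()
    assert summary["total_activated_area_mm2"] == pytest.approx(total)


def test_activated_area_monotone_in_amplitude(coarse_basis, grid):
    a1 = scan(_sol(coarse_basis, 2.0), grid).total_activated_area_mm2
    a2 = scan(_sol(coarse_basis, 6.0), grid).total_activated_area_mm2
    assert a2 >= a1


def test_depth_zero_without_activation(coarse_basis, grid, geom):
    amap = scan(_sol(coarse_basis, 0.0), grid)
    assert max_activation_depth(amap, geom) == 0.0


def test_depth_grows_with_amplitude(coarse_basis, grid, geom):
    d1 = max_activation_depth(scan(_sol(coarse_basis, 2.0), grid), geom)
    d2 = max_activation_depth(scan(_sol(coarse_basis, 8.0), grid), geom)
    assert d2 >= d1 > 0.0


def test_unsorted_fibers_rejected(coarse_basis, grid):
    from cordstim.axon import DEFAULT_FIBER_CLASSES
    with pytest.raises(ValueError):
        scan(_sol(coarse_basis, 1.0), grid,
             fibers=DEFAULT_FIBER_CLASSES[::-1])
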